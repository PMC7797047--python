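"""Synthetic pooled-screen generator.

Emulates the study conditions of a barcoded, titratable CRISPRi selection
in a turbidostat: every (guide, barcode) lineage grows exponentially at a
relative rate set by its ground-truth knockdown strength, a small fraction
of lineages "escape" (lose CRISPRi activity and revert to wild-type
growth partway through the run), and sequencing draws multinomial counts
of fixed depth at each scheduled timepoint.

Ground truth per gene and environment is a four-parameter Hill-type
logistic in the number of compounding spacer mutations; single and double
mismatches act through per-position knockdown-retention factors.  The
normalized growth scale maps complete kill to 0 and wild-type (negC) to 1,
with raw growth rho = normalized * |floor| - |floor| so the non-targeting
reference has rho = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .counts import CountTensor
from .design import GeneTarget, GuideVariant, LibrarySpec
from .gxe import hill_logistic

__all__ = [
    "EnvironmentSpec",
    "GLUCOSE",
    "GLYCEROL",
    "LogisticTruth",
    "TruthModel",
    "EscaperLog",
    "guide_truth_growth",
    "simulate_counts",
    "ReadLayout",
    "emit_reads",
    "write_fastq",
    "synthetic_genes",
    "planted_gxe_truth",
]


@dataclass(frozen=True)
class EnvironmentSpec:
    """One growth condition: sampling schedule and the mixed-population
    turbidostat growth rate used to convert hours to generations."""

    name: str
    schedule_hours: tuple[float, ...]
    doublings_per_hour: float


GLUCOSE = EnvironmentSpec("glucose", (0, 2, 4, 6, 10, 12, 14), 0.94)
GLYCEROL = EnvironmentSpec("glycerol", (0, 2, 6, 10, 14), 0.53)


@dataclass(frozen=True)
class LogisticTruth:
    """True titration curve for one (gene, environment): normalized growth
    as a function of compounding mutation count."""

    min: float
    max: float
    hill: float
    ig50: float

    def __post_init__(self):
        if not (0 <= self.min <= self.max <= 1.15):
            raise ValueError("need 0 <= min <= max <= 1.15")
        if not (0 <= self.ig50 <= 14):
            raise ValueError("ig50 must be in [0, 14]")


@dataclass
class TruthModel:
    """Simulator ground truth and nuisance-process parameters.

    position_effect maps each single-mutation spacer position to the
    fraction of knockdown *retained* when that base is mismatched (1 =
    mutation has no effect on knockdown, 0 = knockdown abolished); for a
    single/double variant the retained knockdown is the product over its
    mutated positions.
    """

    gene_params: dict[str, dict[str, LogisticTruth]]  # gene -> env name -> curve
    position_effect: dict[int, float]
    floor_raw: float = -1.23
    escape_prob: float = 0.01
    depth: int = 1_000_000
    replicate_jitter_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.floor_raw >= 0:
            raise ValueError("floor_raw must be negative")
        if not 0 <= self.escape_prob <= 1:
            raise ValueError("escape_prob must be in [0, 1]")

    @classmethod
    def random(
        cls,
        genes: list[str] | list[GeneTarget],
        env_names: tuple[str, ...] = ("glucose", "glycerol"),
        seed: int = 0,
        shared_across_envs: bool = False,
        **kwargs,
    ) -> "TruthModel":
        """Draw realistic per-gene titration curves.

        min ~ U[0, 0.55] (most knockdowns deleterious), max ~ U[0.9, 1.1]
        (full mismatch load restores near-wild-type growth), hill ~
        U[1.5, 4], ig50 ~ U[4, 10] (inside the compounding range).  Seed
        retention is high near the PAM and low at distal positions.
        """
        rng = np.random.default_rng(seed)
        gene_ids = [g.gene_id if isinstance(g, GeneTarget) else g for g in genes]
        params: dict[str, dict[str, LogisticTruth]] = {}
        for g in gene_ids:
            per_env: dict[str, LogisticTruth] = {}
            for i, env in enumerate(env_names):
                if shared_across_envs and i > 0:
                    per_env[env] = per_env[env_names[0]]
                    continue
                per_env[env] = LogisticTruth(
                    min=float(rng.uniform(0.0, 0.55)),
                    max=float(rng.uniform(0.9, 1.1)),
                    hill=float(rng.uniform(1.5, 4.0)),
                    ig50=float(rng.uniform(4.0, 10.0)),
                )
            params[g] = per_env
        position_effect = {}
        for p in range(-1, -21, -1):
            if p >= -8:  # seed region: mismatch barely dents knockdown
                position_effect[p] = float(rng.uniform(0.85, 1.0))
            elif p >= -12:
                position_effect[p] = float(rng.uniform(0.5, 0.9))
            else:  # PAM-distal: mismatch strongly attenuates
                position_effect[p] = float(rng.uniform(0.05, 0.6))
        return cls(gene_params=params, position_effect=position_effect,
                   seed=seed, **kwargs)


@dataclass
class EscaperLog:
    """Planted escape events: (guide, barcode) lineages that reverted to
    wild-type growth at ``escape_time_hours``."""

    events: list[tuple[str, str, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)

    def lineages(self) -> set[tuple[str, str]]:
        return {(g, b) for g, b, _ in self.events}

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("guide_id\tbarcode\tescape_time_hours\n")
            for g, b, t in self.events:
                fh.write(f"{g}\t{b}\t{t:.4f}\n")


def guide_truth_growth(truth: TruthModel, v: GuideVariant, env: str) -> float:
    """True normalized growth of one library member in one environment."""
    if v.strategy == "negC":
        return 1.0
    if v.gene_id not in truth.gene_params:
        raise ValueError(f"gene {v.gene_id!r} absent from truth model")
    curve = truth.gene_params[v.gene_id][env]
    if v.strategy in ("parent", "compounding"):
        return float(hill_logistic(v.n_mut, curve.min, curve.max, curve.hill, curve.ig50))
    if v.strategy in ("single", "double"):
        retained = 1.0
        for p in v.mutated_positions:
            retained *= truth.position_effect[p]
        return curve.min + (curve.max - curve.min) * (1.0 - retained)
    raise ValueError(f"unknown strategy {v.strategy!r}")


def simulate_counts(
    truth: TruthModel,
    lib: LibrarySpec,
    env: EnvironmentSpec,
    seed: int | None = None,
) -> tuple[CountTensor, EscaperLog]:
    """Run the pooled competition and sequencing model.

    Lineage abundance follows A(tau) = A(0) * 2**(rho * tau) with tau =
    hours * doublings_per_hour and rho the (jittered) raw relative growth;
    escaped lineages hold rho = 0 from their escape time onward.  Counts at
    each timepoint are multinomial(depth) over all lineages.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    guides = [v.guide_id for v in lib.variants]
    barcodes = list(lib.barcodes)
    hours = np.asarray(env.schedule_hours, dtype=float)
    G, B, T = len(guides), len(barcodes), len(hours)
    floor = abs(truth.floor_raw)

    g_norm = np.array(
        [guide_truth_growth(truth, v, env.name) for v in lib.variants]
    )
    rho = g_norm[:, None] * floor - floor  # (G, 1) raw growth
    rho = rho + rng.normal(0.0, truth.replicate_jitter_sd, size=(G, B))
    rho = np.clip(rho, -floor, 0.15 * floor)  # keep normalized in [0, 1.15]

    u = rng.random(size=(G, B))
    escape_time = rng.uniform(0.0, hours[-1], size=(G, B))
    escaped = (u < truth.escape_prob) & (rho < 0)

    tau = hours[None, None, :] * env.doublings_per_hour
    tau_e = escape_time[:, :, None] * env.doublings_per_hour
    eff_tau = np.where(escaped[:, :, None], np.minimum(tau, tau_e), tau)
    log2_abund = rho[:, :, None] * eff_tau

    counts = np.empty((G, B, T), dtype=np.int64)
    for t in range(T):
        w = np.exp2(log2_abund[:, :, t] - log2_abund[:, :, t].max())
        p = (w / w.sum()).ravel()
        counts[:, :, t] = rng.multinomial(truth.depth, p).reshape(G, B)

    log = EscaperLog(
        [
            (guides[i], barcodes[j], float(escape_time[i, j]))
            for i, j in zip(*np.nonzero(escaped))
        ]
    )
    tensor = CountTensor(guides, barcodes, hours, counts, environment=env.name)
    return tensor, log


# ---------------------------------------------------------------------------
# Read emission (for exercising the counting stage)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadLayout:
    """Fixed amplicon layout: flank + spacer + scaffold + barcode + flank."""

    left_flank: str = "TGTAACGAAGACGG"
    scaffold: str = "GTTTTAGAGCTAGAAATAGC"
    right_flank: str = "AAGTTCACCGACTC"
    quality: int = 37  # Phred score written for every base

    @property
    def spacer_start(self) -> int:
        return len(self.left_flank)

    @property
    def barcode_start(self) -> int:
        return len(self.left_flank) + 20 + len(self.scaffold)

    @property
    def read_length(self) -> int:
        return self.barcode_start + 6 + len(self.right_flank)


def emit_reads(
    ct: CountTensor,
    lib: LibrarySpec,
    hour: float,
    layout: ReadLayout = ReadLayout(),
    corruption_rate: float = 0.0,
    seed: int = 0,
):
    """Yield (sequence, qualities) read records for one timepoint, one read
    per count.  With probability ``corruption_rate`` a read is damaged:
    either one spacer base is flipped or one spacer base quality is dropped
    to Q30 (below the strict Q>30 filter)."""
    from .readcount import ReadRecord

    rng = np.random.default_rng(seed)
    spacers = {v.guide_id: v.spacer for v in lib.variants}
    t = int(np.nonzero(ct.hours == hour)[0][0])
    base_qual = tuple([layout.quality] * layout.read_length)
    for gi, guide in enumerate(ct.guides):
        spacer = spacers[guide]
        for bi, barcode in enumerate(ct.barcodes):
            n = int(ct.counts[gi, bi, t])
            if n == 0:
                continue
            seq = layout.left_flank + spacer + layout.scaffold + barcode + layout.right_flank
            n_bad = rng.binomial(n, corruption_rate) if corruption_rate > 0 else 0
            for _ in range(n - n_bad):
                yield ReadRecord(seq, base_qual)
            for _ in range(n_bad):
                pos = layout.spacer_start + int(rng.integers(20))
                if rng.random() < 0.5:
                    bad = list(seq)
                    bad[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[bad[pos]]
                    yield ReadRecord("".join(bad), base_qual)
                else:
                    q = list(base_qual)
                    q[pos] = 30
                    yield ReadRecord(seq, tuple(q))


def write_fastq(reads, path) -> None:
    """Write read records as Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@read{i}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Synthetic inputs
# ---------------------------------------------------------------------------

def synthetic_genes(n: int = 88, length: int = 600, seed: int = 0) -> list[GeneTarget]:
    """Random ATG-initiated coding sequences long enough to carry SG1/SG2
    (within 150 bp) and SG3 (beyond 200 bp) parent guides."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    genes = []
    for i in range(n):
        body = "".join(rng.choice(bases, size=length - 3))
        genes.append(GeneTarget(gene_id=f"gene{i + 1:03d}", cds="ATG" + body))
    return genes


def planted_gxe_truth(
    interaction_genes: list[str],
    null_genes: list[str],
    seed: int = 0,
    ig50_shift: float = 3.0,
    env_names: tuple[str, str] = ("glucose", "glycerol"),
    **kwargs,
) -> TruthModel:
    """Ground truth with planted titration-only interactions.

    Interaction genes share min/max/hill across environments but shift the
    IG-50 by ``ig50_shift`` mutations in the second environment; null genes
    are identical in both.  This is the planted condition for testing
    interaction calling: differences manifest only at intermediate
    knockdown, never at maximal knockdown (the min parameter).
    """
    rng = np.random.default_rng(seed)
    base = TruthModel.random(
        interaction_genes + null_genes, env_names=env_names,
        seed=int(rng.integers(2**31)), shared_across_envs=True, **kwargs,
    )
    e1, e2 = env_names
    for g in interaction_genes:
        c = base.gene_params[g][e1]
        base.gene_params[g] = {
            e1: c,
            e2: LogisticTruth(min=c.min, max=c.max, hill=c.hill,
                              ig50=float(np.clip(c.ig50 + ig50_shift, 0.0, 14.0))),
        }
    return base
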