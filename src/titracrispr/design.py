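"""Design of titratable CRISPRi sgRNA libraries.

A parent sgRNA targets the non-template strand of a gene: its 20-nt spacer
is the reverse complement of the 20-nt protospacer found immediately 3' of a
CCN PAM motif on the sense (coding) strand.  Knockdown strength is then
titrated by mutating spacer bases to their complement, either one at a time
(``single``), in fixed pairs (``double``), or by serially compounding
mismatches inward from the PAM-distal end (``compounding``).

Spacer positions are numbered -1 (PAM-proximal) to -20 (PAM-distal), the
standard CRISPRi convention: position -k is the spacer base that pairs with
protospacer base k counting away from the PAM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GeneTarget",
    "ParentGuide",
    "GuideVariant",
    "LibrarySpec",
    "FilterResult",
    "OffTargetHit",
    "OffTargetVerdict",
    "DEFAULT_BARCODES",
    "SINGLE_MUT_POSITIONS",
    "DOUBLE_MUT_PAIRS",
    "N_COMPOUNDING",
    "scan_pam_candidates",
    "apply_sequence_filters",
    "screen_off_targets",
    "select_parents",
    "mutate_compounding",
    "mutate_singles",
    "mutate_doubles",
    "make_negc",
    "compact_subset",
    "design_library",
    "read_genes_fasta",
    "write_library_tsv",
    "read_library_tsv",
    "write_spacers_fasta",
]

# The six internal-replicate plasmid barcodes.
DEFAULT_BARCODES = ("CTTTCA", "ATCATG", "GCATGG", "GTATGA", "AGTCTA", "CCTAGT")

# Individually mutated spacer positions: -1, -2, -5, -8 and -10 .. -20.
SINGLE_MUT_POSITIONS = (-1, -2, -5, -8) + tuple(range(-10, -21, -1))

# The five fixed double-mismatch position pairs.
DOUBLE_MUT_PAIRS = (
    frozenset({-2, -12}),
    frozenset({-12, -14}),
    frozenset({-15, -17}),
    frozenset({-11, -18}),
    frozenset({-13, -19}),
)

# Length of the compounding series: -20 alone up to -20 .. -7.
N_COMPOUNDING = 14

SPACER_LEN = 20
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _check_alphabet(seq: str, what: str) -> None:
    if not set(seq) <= _VALID:
        raise ValueError(f"{what} contains non-ACGT characters")


def spacer_index(position: int) -> int:
    """0-based index into the spacer string for signed position -1..-20."""
    if not -SPACER_LEN <= position <= -1:
        raise ValueError(f"spacer position must be in -1..-{SPACER_LEN}, got {position}")
    return SPACER_LEN + position


@dataclass(frozen=True)
class GeneTarget:
    """A gene to knock down: sense-strand CDS starting at the ATG."""

    gene_id: str
    cds: str
    essential: bool = True

    def __post_init__(self):
        _check_alphabet(self.cds, f"cds of {self.gene_id}")
        if len(self.cds) < 23:
            raise ValueError(f"cds of {self.gene_id} shorter than 23 nt")


@dataclass(frozen=True)
class ParentGuide:
    """An unmutated sgRNA candidate anchored at one CCN PAM.

    ``pam_offset`` is the 1-based CDS position of the first C of the CCN;
    the protospacer is the 20 nt immediately 3' of the motif and the spacer
    is its reverse complement.
    """

    gene_id: str
    pam_offset: int
    protospacer: str
    spacer: str
    gc_fraction: float
    role: str | None = None  # SG1 / SG2 / SG3 once assigned

    @property
    def window(self) -> tuple[int, int]:
        """1-based inclusive CDS span covered by the protospacer."""
        return (self.pam_offset + 3, self.pam_offset + 2 + SPACER_LEN)


@dataclass(frozen=True)
class GuideVariant:
    """One library member: a parent spacer with a set of complement mutations."""

    guide_id: str
    gene_id: str | None
    role: str | None
    strategy: str  # parent | single | double | compounding | negC
    mutated_positions: frozenset[int]
    spacer: str
    parent: ParentGuide | None = None

    @property
    def n_mut(self) -> int:
        return len(self.mutated_positions)


@dataclass
class LibrarySpec:
    """A designed sgRNA library plus barcodes and the genes it targets."""

    variants: list[GuideVariant]
    barcodes: tuple[str, ...] = DEFAULT_BARCODES
    genes: list[GeneTarget] = field(default_factory=list)

    def __post_init__(self):
        ids = [v.guide_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("guide ids are not unique")

    def __len__(self) -> int:
        return len(self.variants)

    def by_gene(self) -> dict[str, list[GuideVariant]]:
        out: dict[str, list[GuideVariant]] = {}
        for v in self.variants:
            if v.gene_id is not None:
                out.setdefault(v.gene_id, []).append(v)
        return out

    def negc(self) -> list[GuideVariant]:
        return [v for v in self.variants if v.strategy == "negC"]

    def spacer_map(self) -> dict[str, str]:
        """spacer -> guide_id (library spacers are unique by construction)."""
        return {v.spacer: v.guide_id for v in self.variants}

    def get(self, guide_id: str) -> GuideVariant:
        for v in self.variants:
            if v.guide_id == guide_id:
                return v
        raise KeyError(guide_id)


# ---------------------------------------------------------------------------
# PAM scanning and parent selection
# ---------------------------------------------------------------------------

def scan_pam_candidates(gene: GeneTarget) -> list[ParentGuide]:
    """All sense-strand CCN sites with room for a 20-nt protospacer.

    Returns one candidate per CCN occurrence (overlapping motifs each
    count), ordered by ``pam_offset`` ascending.  No filters are applied.
    """
    cds = gene.cds
    out: list[ParentGuide] = []
    # 0-based scan: motif at i..i+2, protospacer at i+3..i+22
    for i in range(len(cds) - 22):
        if cds[i] == "C" and cds[i + 1] == "C":
            proto = cds[i + 3 : i + 23]
            out.append(
                ParentGuide(
                    gene_id=gene.gene_id,
                    pam_offset=i + 1,
                    protospacer=proto,
                    spacer=_revcomp(proto),
                    gc_fraction=_gc_fraction(proto),
                )
            )
    return out


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reasons: frozenset[str]  # subset of {gc_low, gc_high, polyT}


def apply_sequence_filters(
    candidate: ParentGuide | str,
    gc_min: float = 0.45,
    gc_max: float = 0.80,
    polyt_max: int = 4,
) -> FilterResult:
    """Manufacturability filters on the spacer: GC strictly inside
    (gc_min, gc_max) and no run of more than ``polyt_max`` consecutive T."""
    spacer = candidate if isinstance(candidate, str) else candidate.spacer
    gc = _gc_fraction(spacer)
    reasons = set()
    if gc <= gc_min:
        reasons.add("gc_low")
    if gc >= gc_max:
        reasons.add("gc_high")
    if "T" * (polyt_max + 1) in spacer:
        reasons.add("polyT")
    return FilterResult(passed=not reasons, reasons=frozenset(reasons))


@dataclass(frozen=True)
class OffTargetHit:
    background_index: int
    start: int  # 0-based window start on the forward strand
    strand: str  # "+" matches the protospacer, "-" its reverse complement
    homology: float
    pam_adjacent: bool
    region1_perfect: bool


@dataclass(frozen=True)
class OffTargetVerdict:
    redesign: bool
    rules_fired: frozenset[str]  # subset of {multi_perfect, high_homology_pam, seed_match_pam}
    hits: tuple[OffTargetHit, ...]


def _pam_adjacent(seq: str, start: int, strand: str, slack: int = 3) -> bool:
    """CCN (or NGG on the other side for '-' hits) within ``slack`` nt of the
    PAM-proximal end of the matched 20-nt window."""
    if strand == "+":
        # PAM is 5' of the window: CC at start-3-d .. start-2-d for d in 0..slack-1
        for d in range(slack):
            j = start - 3 - d
            if j >= 0 and seq[j : j + 2] == "CC":
                return True
    else:
        # site on the reverse strand: PAM reads NGG 3' of the window
        for d in range(slack):
            j = start + SPACER_LEN + 1 + d
            if j + 2 <= len(seq) and seq[j : j + 2] == "GG":
                return True
    return False


def screen_off_targets(
    candidate: ParentGuide,
    background: list[str],
    min_report_homology: float = 0.75,
) -> OffTargetVerdict:
    """Flag a candidate for redesign based on homology to background sites.

    Both strands of every background sequence are scanned with a sliding
    20-nt window; homology is the fraction of identical positions against
    the protospacer.  Redesign fires when (i) the exact 20-mer occurs at
    more than one site, (ii) a site has homology > 90% (but below 100%)
    next to a PAM, or (iii) a site has homology > 75% and < 90% next to a
    PAM with a perfect match over the eight PAM-proximal positions (the
    seed region, spacer -1..-8).  A single exact site is the intended
    target and does not by itself trigger redesign.
    """
    if not background:
        raise ValueError("off-target screening requested with empty background")
    proto = candidate.protospacer
    proto_arr = np.frombuffer(proto.encode(), dtype="S1")
    hits: list[OffTargetHit] = []
    n_perfect = 0
    rules: set[str] = set()
    for bg_i, seq in enumerate(background):
        _check_alphabet(seq, f"background[{bg_i}]")
        if len(seq) < SPACER_LEN:
            continue
        arr = np.frombuffer(seq.encode(), dtype="S1")
        windows = np.lib.stride_tricks.sliding_window_view(arr, SPACER_LEN)
        for strand in "+-":
            if strand == "+":
                matches = windows == proto_arr
            else:
                rc = np.frombuffer(_revcomp(proto).encode(), dtype="S1")
                matches = windows == rc
            hom = matches.mean(axis=1)
            for start in np.nonzero(hom > min_report_homology)[0]:
                h = float(hom[start])
                if strand == "+":
                    # protospacer coordinates run 5'->3' with the PAM at the 5' end
                    region1_ok = bool(matches[start, :8].all())
                else:
                    region1_ok = bool(matches[start, -8:].all())
                pam = _pam_adjacent(seq, int(start), strand)
                hits.append(
                    OffTargetHit(bg_i, int(start), strand, h, pam, region1_ok)
                )
                if h == 1.0:
                    n_perfect += 1
    for hit in hits:
        if hit.homology == 1.0:
            continue  # handled by the multi-site rule below
        if hit.homology > 0.90 and hit.pam_adjacent:
            rules.add("high_homology_pam")
        elif 0.75 < hit.homology < 0.90 and hit.region1_perfect and hit.pam_adjacent:
            rules.add("seed_match_pam")
    if n_perfect > 1:
        rules.add("multi_perfect")
    return OffTargetVerdict(
        redesign=bool(rules), rules_fired=frozenset(rules), hits=tuple(hits)
    )


def select_parents(
    candidates: list[ParentGuide],
    sg12_max_offset: int = 150,
    sg3_min_offset: int = 200,
) -> dict[str, ParentGuide]:
    """Assign SG1/SG2/SG3 roles among pre-filtered candidates.

    SG1 is the qualifying candidate closest to the start codon
    (pam_offset <= 150); SG2 the next closest whose protospacer window does
    not overlap SG1's; SG3 the candidate closest to, but at least at, the
    200-bp mark.  Missing roles are simply absent from the result.  Output
    does not depend on the input order (ties on equal offsets break toward
    the candidate listed first after a stable sort).
    """
    ordered = sorted(candidates, key=lambda c: c.pam_offset)
    roles: dict[str, ParentGuide] = {}
    near = [c for c in ordered if c.pam_offset <= sg12_max_offset]
    if near:
        sg1 = near[0]
        roles["SG1"] = replace(sg1, role="SG1")
        s1, e1 = sg1.window
        for c in near[1:]:
            s2, e2 = c.window
            if e2 < s1 or s2 > e1:  # non-overlapping protospacer windows
                roles["SG2"] = replace(c, role="SG2")
                break
    far = [c for c in ordered if c.pam_offset >= sg3_min_offset]
    if far:
        roles["SG3"] = replace(far[0], role="SG3")
    return roles


# ---------------------------------------------------------------------------
# Mutation series
# ---------------------------------------------------------------------------

def _mutate(spacer: str, positions) -> str:
    out = list(spacer)
    for p in positions:
        i = spacer_index(p)
        out[i] = out[i].translate(_COMPLEMENT)
    return "".join(out)


def _variant(parent: ParentGuide, strategy: str, positions, guide_id: str) -> GuideVariant:
    positions = frozenset(positions)
    return GuideVariant(
        guide_id=guide_id,
        gene_id=parent.gene_id,
        role=parent.role,
        strategy=strategy,
        mutated_positions=positions,
        spacer=_mutate(parent.spacer, positions),
        parent=parent,
    )


def mutate_compounding(parent: ParentGuide) -> list[GuideVariant]:
    """The 14-member compounding series: variant k mutates positions
    -20 .. -(21-k) to the complement base, so k=1 touches only -20 and
    k=14 reaches in to -7."""
    out = []
    for k in range(1, N_COMPOUNDING + 1):
        positions = range(-20, -(21 - k) + 1)
        out.append(
            _variant(parent, "compounding", positions, f"{_stem(parent)}_comp{k:02d}")
        )
    return out


def mutate_singles(parent: ParentGuide) -> list[GuideVariant]:
    """Fifteen single complement mismatches at -1, -2, -5, -8, -10..-20."""
    return [
        _variant(parent, "single", {p}, f"{_stem(parent)}_single{-p:02d}")
        for p in SINGLE_MUT_POSITIONS
    ]


def mutate_doubles(parent: ParentGuide) -> list[GuideVariant]:
    """The five fixed double mismatches (-2/-12, -12/-14, -15/-17, -11/-18,
    -13/-19)."""
    out = []
    for pair in DOUBLE_MUT_PAIRS:
        a, b = sorted((-p for p in pair))
        out.append(
            _variant(parent, "double", pair, f"{_stem(parent)}_double{a:02d}_{b:02d}")
        )
    return out


def _stem(parent: ParentGuide) -> str:
    role = parent.role or f"p{parent.pam_offset}"
    return f"{parent.gene_id}_{role}"


def make_negc(
    n: int = 45,
    seed: int = 0,
    background: list[str] | None = None,
    gc_min: float = 0.45,
    gc_max: float = 0.80,
    polyt_max: int = 4,
    max_draws_per_control: int = 1000,
) -> list[GuideVariant]:
    """Non-targeting controls: random 20-mers passing the sequence filters
    (and the off-target screen when a background is supplied).

    Deterministic given ``seed``.  Raises if the filters cannot be satisfied
    within the draw budget.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    out: list[GuideVariant] = []
    draws = 0
    budget = n * max_draws_per_control
    while len(out) < n:
        if draws >= budget:
            raise RuntimeError(f"could not draw {n} passing controls in {budget} tries")
        draws += 1
        spacer = "".join(rng.choice(bases, size=SPACER_LEN))
        if not apply_sequence_filters(spacer, gc_min, gc_max, polyt_max).passed:
            continue
        if background:
            probe = ParentGuide(
                gene_id="negC", pam_offset=1, protospacer=_revcomp(spacer),
                spacer=spacer, gc_fraction=_gc_fraction(spacer),
            )
            if screen_off_targets(probe, background).redesign:
                continue
        out.append(
            GuideVariant(
                guide_id=f"negC_rand_{len(out) + 1}",
                gene_id=None,
                role=None,
                strategy="negC",
                mutated_positions=frozenset(),
                spacer=spacer,
            )
        )
    return out


def compact_subset(lib: LibrarySpec) -> LibrarySpec:
    """The 16-guide-per-gene compact library: SG1 and SG3 parents plus
    their compounding variants with 4..10 mutations.  Non-targeting
    controls are carried over unchanged; genes missing a parent keep the
    half-set with a warning."""
    keep: list[GuideVariant] = []
    for gene_id, variants in lib.by_gene().items():
        present_roles = set()
        for v in variants:
            if v.role not in ("SG1", "SG3"):
                continue
            if v.strategy == "parent" or (
                v.strategy == "compounding" and 4 <= v.n_mut <= 10
            ):
                keep.append(v)
                present_roles.add(v.role)
        for role in ("SG1", "SG3"):
            if role not in present_roles:
                warnings.warn(
                    f"{gene_id}: no {role} series; compact set is incomplete",
                    stacklevel=2,
                )
    keep.extend(lib.negc())
    return LibrarySpec(variants=keep, barcodes=lib.barcodes, genes=lib.genes)


# ---------------------------------------------------------------------------
# Whole-library orchestration and IO
# ---------------------------------------------------------------------------

def design_library(
    genes: list[GeneTarget],
    background: list[str] | None = None,
    n_negc: int = 45,
    seed: int = 0,
    gc_min: float = 0.45,
    gc_max: float = 0.80,
    polyt_max: int = 4,
    barcodes: tuple[str, ...] = DEFAULT_BARCODES,
) -> LibrarySpec:
    """Design the full library: per gene, up to three parents (SG1/SG2/SG3)
    with compounding, single and double series on SG1 and SG3, plus
    ``n_negc`` non-targeting controls."""
    variants: list[GuideVariant] = []
    for gene in genes:
        candidates = [
            c
            for c in scan_pam_candidates(gene)
            if apply_sequence_filters(c, gc_min, gc_max, polyt_max).passed
        ]
        if background:
            candidates = [
                c for c in candidates if not screen_off_targets(c, background).redesign
            ]
        roles = select_parents(candidates)
        for role in ("SG1", "SG2", "SG3"):
            if role not in roles:
                continue
            parent = roles[role]
            variants.append(
                GuideVariant(
                    guide_id=_stem(parent),
                    gene_id=gene.gene_id,
                    role=role,
                    strategy="parent",
                    mutated_positions=frozenset(),
                    spacer=parent.spacer,
                    parent=parent,
                )
            )
            if role in ("SG1", "SG3"):
                variants.extend(mutate_compounding(parent))
                variants.extend(mutate_singles(parent))
                variants.extend(mutate_doubles(parent))
    variants.extend(
        make_negc(n_negc, seed=seed, background=background,
                  gc_min=gc_min, gc_max=gc_max, polyt_max=polyt_max)
    )
    return LibrarySpec(variants=variants, barcodes=barcodes, genes=list(genes))


def read_genes_fasta(path, essential: bool = True) -> list[GeneTarget]:
    return [
        GeneTarget(gene_id=rec.id, cds=str(rec.seq).upper(), essential=essential)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


_TSV_COLUMNS = [
    "guide_id", "gene_id", "role", "strategy", "n_mut",
    "mutated_positions", "spacer", "pam_offset",
]


def write_library_tsv(lib: LibrarySpec, path) -> None:
    import pandas as pd

    rows = []
    for v in lib.variants:
        rows.append(
            {
                "guide_id": v.guide_id,
                "gene_id": v.gene_id or "-",
                "role": v.role or "-",
                "strategy": v.strategy,
                "n_mut": v.n_mut,
                "mutated_positions": ",".join(
                    str(p) for p in sorted(v.mutated_positions, reverse=True)
                ) or "-",
                "spacer": v.spacer,
                "pam_offset": v.parent.pam_offset if v.parent else -1,
            }
        )
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_library_tsv(path, barcodes: tuple[str, ...] = DEFAULT_BARCODES) -> LibrarySpec:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"mutated_positions": str})
    variants = []
    for row in df.itertuples(index=False):
        positions = frozenset(
            int(p) for p in str(row.mutated_positions).split(",") if p not in ("-", "nan", "")
        )
        variants.append(
            GuideVariant(
                guide_id=row.guide_id,
                gene_id=None if row.gene_id == "-" else row.gene_id,
                role=None if row.role == "-" else row.role,
                strategy=row.strategy,
                mutated_positions=positions,
                spacer=row.spacer,
            )
        )
    return LibrarySpec(variants=variants, barcodes=barcodes)


def write_spacers_fasta(lib: LibrarySpec, path) -> None:
    with open(path, "w") as fh:
        for v in lib.variants:
            fh.write(f">{v.guide_id}\n{v.spacer}\n")
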