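"""Reference scenarios at study scale.

Each function runs one end-to-end exercise of the package under the
emulated experimental conditions (88 genes, 6 internal-replicate barcodes,
the glucose/glycerol schedules, multinomial sequencing at fixed depth) and
returns the headline numbers it computed.  Both the acceptance checks and
the reproduction script drive these; nothing here hard-codes an expected
result.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import design, growth, gxe, simulate
from .pipeline import gxe_from_results, sg1_series_points

__all__ = [
    "design_counts",
    "normalization_examples",
    "recovery_benchmark",
    "escaper_benchmark",
    "gxe_benchmark",
]


def design_counts(seed: int = 0) -> dict:
    """Series sizes from an actual design run on one synthetic gene."""
    genes = simulate.synthetic_genes(1, length=600, seed=seed)
    candidates = [
        c
        for c in design.scan_pam_candidates(genes[0])
        if design.apply_sequence_filters(c).passed
    ]
    roles = design.select_parents(candidates)
    sg1 = roles["SG1"]
    lib = design.design_library(genes, n_negc=45, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        compact = design.compact_subset(lib)
    per_gene = [v for v in compact.variants if v.strategy != "negC"]
    return {
        "compounding_series_size": len(design.mutate_compounding(sg1)),
        "single_series_size": len(design.mutate_singles(sg1)),
        "double_series_size": len(design.mutate_doubles(sg1)),
        "default_negc_count": len(lib.negc()),
        "compact_guides_per_gene": len(per_gene),
    }


def normalization_examples() -> dict:
    """The published floor/reference anchors of the affine growth rescale."""
    return {
        "normalized_at_floor": growth.normalize_growth(-1.23, -1.23),
        "normalized_at_reference": growth.normalize_growth(0.0, -1.23),
        "normalized_at_half_floor": growth.normalize_growth(-0.615, -1.23),
    }


def _simulate_and_estimate(lib, truth, env, seed, floor_raw="auto"):
    ct, esc = simulate.simulate_counts(truth, lib, env, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = growth.estimate_growth(ct, lib, env.doublings_per_hour,
                                     floor_raw=floor_raw)
    return ct, esc, res


def recovery_benchmark(seed: int = 1, n_genes: int = 88, depth: int = 1_000_000,
                       jitter: float = 0.01) -> dict:
    """Full pipeline parameter recovery on the compact library.

    Simulates the pooled glucose selection for ``n_genes`` synthetic genes
    (compact 16-guide-per-gene library, 6 barcodes, 7 timepoints,
    multinomial depth ``depth``, replicate jitter ``jitter``, 1% escape
    probability), runs escaper-corrected estimation with automatic
    reference and floor, and compares against the planted truth.
    """
    genes = simulate.synthetic_genes(n_genes, length=600, seed=seed)
    lib = design.design_library(genes, n_negc=45, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lib = design.compact_subset(lib)
    truth = simulate.TruthModel.random(
        genes, env_names=("glucose",), seed=seed, depth=depth,
        replicate_jitter_sd=jitter,
    )
    ct, _, res = _simulate_and_estimate(lib, truth, simulate.GLUCOSE, seed=seed)

    errors = []
    for row in res.estimates.itertuples(index=False):
        if row.status != "ok":
            continue
        expected = simulate.guide_truth_growth(truth, lib.get(row.guide_id), "glucose")
        errors.append(abs(row.normalized - expected))
    errors = np.array(errors)

    ig50_errors = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for gene in sorted({v.gene_id for v in lib.variants if v.gene_id}):
            pts = sg1_series_points(gene, res, lib)
            fe = gxe.gene_env_fit(pts, gene, "glucose")
            if not fe.ok:
                continue
            med = fe.medians()
            if med["ig50"] is None:
                continue
            ig50_errors.append(
                abs(med["ig50"] - truth.gene_params[gene]["glucose"].ig50)
            )
    ig50_errors = np.array(ig50_errors)
    return {
        "growth_within_0p05_pct": float(100 * np.mean(errors <= 0.05)),
        "median_abs_growth_error": float(np.median(errors)),
        "n_guides_estimated": int(errors.size),
        "ig50_within_1_pct": float(100 * np.mean(ig50_errors <= 1.0)),
        "median_abs_ig50_error": float(np.median(ig50_errors)),
        "n_genes_fit": int(ig50_errors.size),
        "auto_floor_raw": float(res.floor_raw),
    }


def escaper_benchmark(seed: int = 1, n_genes: int = 12, depth: int = 1_000_000,
                      escape_prob: float = 0.08) -> dict:
    """Escaper detection and the cost of skipping correction.

    Plants frequent escape events, then measures (i) how often an escaped
    lineage of a clearly deleterious guide is caught by the replicate
    filters, and (ii) how the standard uncorrected single-endpoint
    estimate compares with the escaper-corrected one on affected guides.
    """
    genes = simulate.synthetic_genes(n_genes, length=600, seed=seed)
    lib = design.design_library(genes, n_negc=45, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lib = design.compact_subset(lib)
    truth = simulate.TruthModel.random(
        genes, env_names=("glucose",), seed=seed, depth=depth,
        replicate_jitter_sd=0.01, escape_prob=escape_prob,
    )
    ct, esc, res = _simulate_and_estimate(lib, truth, simulate.GLUCOSE, seed=seed)
    uncorrected = growth.uncorrected_growth(ct, res.reference,
                                            simulate.GLUCOSE.doublings_per_hour)

    truth_norm = {
        v.guide_id: simulate.guide_truth_growth(truth, v, "glucose")
        for v in lib.variants
    }
    removed_by_guide: dict[str, set] = {}
    for row in res.estimates.itertuples(index=False):
        removed_by_guide[row.guide_id] = {
            item.split(":")[0] for item in str(row.removed).split(";") if ":" in item
        }

    # (i) escaped lineages of deleterious guides caught by the filters
    caught = total = 0
    escaped_guides = set()
    for guide, barcode, t_esc in esc.events:
        escaped_guides.add(guide)
        if truth_norm[guide] > 0.75 or t_esc > 10.0:
            continue  # effect too small or too late to distinguish
        total += 1
        caught += barcode in removed_by_guide.get(guide, set())

    # (ii) uncorrected vs corrected on affected guides
    n_ge = n_affected = 0
    lethal_strict = lethal_total = 0
    for row in res.estimates.itertuples(index=False):
        g = row.guide_id
        if g not in escaped_guides or row.status != "ok":
            continue
        unc = uncorrected.get(g, float("nan"))
        if np.isnan(unc):
            continue
        n_affected += 1
        n_ge += unc >= row.mean_raw - 2 * row.sem
        if truth_norm[g] <= 0.2:
            lethal_total += 1
            lethal_strict += unc > row.mean_raw
    return {
        "escapers_caught_pct": float(100 * caught / total) if total else float("nan"),
        "n_escapers_scored": int(total),
        "uncorrected_ge_corrected_pct": (
            float(100 * n_ge / n_affected) if n_affected else float("nan")
        ),
        "n_affected_guides": int(n_affected),
        "lethal_uncorrected_strictly_higher_pct": (
            float(100 * lethal_strict / lethal_total) if lethal_total else float("nan")
        ),
        "n_lethal_affected": int(lethal_total),
    }


def gxe_benchmark(seed: int = 1, n_interaction: int = 10, n_null: int = 10,
                  depth: int = 1_000_000, jitter: float = 0.02) -> dict:
    """Planted titration-only interaction recovery.

    Half the genes shift their IG-50 by 3 mutations between glucose and
    glycerol with identical min/max/Hill (detectable only through the
    titration curve); the other half are identical in both environments.
    """
    pool = simulate.synthetic_genes(n_interaction + n_null + 6, length=600,
                                    seed=seed)
    lib_full = design.design_library(pool, n_negc=45, seed=seed)
    with_sg1 = [
        g for g in pool
        if any(v.gene_id == g.gene_id and v.role == "SG1" for v in lib_full.variants)
    ][: n_interaction + n_null]
    if len(with_sg1) < n_interaction + n_null:
        raise RuntimeError("not enough designable genes for the planted study")
    keep_genes = {g.gene_id for g in with_sg1}
    variants = [
        v for v in lib_full.variants
        if v.strategy == "negC"
        or (v.gene_id in keep_genes and v.role == "SG1"
            and v.strategy in ("parent", "compounding"))
    ]
    lib = design.LibrarySpec(variants=variants, barcodes=lib_full.barcodes,
                             genes=with_sg1)
    interaction = [g.gene_id for g in with_sg1[:n_interaction]]
    nulls = [g.gene_id for g in with_sg1[n_interaction:]]
    truth = simulate.planted_gxe_truth(
        interaction, nulls, seed=seed, depth=depth, replicate_jitter_sd=jitter,
    )
    # both environments share the first environment's empirical floor, so
    # normalized scales are directly comparable (one anchor, as published)
    results = {}
    floor = "auto"
    for i, env in enumerate((simulate.GLUCOSE, simulate.GLYCEROL)):
        _, _, res = _simulate_and_estimate(lib, truth, env,
                                           seed=seed + 7919 * (i + 1),
                                           floor_raw=floor)
        floor = res.floor_raw
        results[env.name] = res
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        calls, _, _ = gxe_from_results(results, lib)
    by_gene = {c.gene_id: c for c in calls}
    detected = sum(
        1 for g in interaction
        if g in by_gene and by_gene[g].interaction_class == "titration_only"
    )
    false_calls = sum(
        1 for g in nulls
        if g in by_gene and by_gene[g].interaction_class != "none"
    )
    return {
        "titration_only_detected": int(detected),
        "n_interaction_planted": int(n_interaction),
        "null_false_calls": int(false_calls),
        "n_null_planted": int(n_null),
        "n_genes_called": int(len(calls)),
    }
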