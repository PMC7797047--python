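"""End-to-end orchestration: design -> simulate -> growth -> steps -> gxe.

Every stage writes its TSV reports into the run directory and appends to a
plain-text log; nothing mutates an earlier stage's output.  Given the same
config (and seed) the report TSVs are byte-identical across runs.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import design, growth, gxe, simulate, steps
from .config import RunConfig

__all__ = ["run_pipeline", "sg1_series_points", "gxe_from_results"]


def sg1_series_points(
    gene_id: str, result: growth.GrowthResult, lib: design.LibrarySpec
) -> dict[str, list[tuple[int, float]]]:
    """Per-barcode (n_mut, normalized growth) points for the SG1 parent +
    compounding series of one gene, from surviving replicate fits."""
    series_ids = {
        v.guide_id: v.n_mut
        for v in lib.variants
        if v.gene_id == gene_id
        and v.role == "SG1"
        and v.strategy in ("parent", "compounding")
    }
    pts: dict[str, list[tuple[int, float]]] = {}
    rf = result.replicate_fits
    if not len(rf):
        return pts
    for row in rf[rf.kept & rf.guide_id.isin(series_ids)].itertuples(index=False):
        pts.setdefault(row.barcode, []).append(
            (series_ids[row.guide_id], float(row.normalized_slope))
        )
    return pts


def gxe_from_results(
    results: dict[str, growth.GrowthResult],
    lib: design.LibrarySpec,
    gamma: float = 0.05,
    alpha: float = 0.05,
    min_points: int = gxe.MIN_POINTS,
    eligibility_threshold: float = 0.75,
) -> tuple[list[gxe.GxECall], pd.DataFrame, pd.DataFrame]:
    """Fit per-replicate titration curves in two environments and call
    interactions.

    A gene is eligible when its least-mutated measurable SG1-series guide
    has normalized growth <= 0.75 in at least one environment and both
    environments retain >= 3 replicate fits.
    """
    if len(results) != 2:
        raise ValueError("gene-by-environment calling needs exactly two environments")
    (env1, res1), (env2, res2) = sorted(results.items())
    genes = sorted({v.gene_id for v in lib.variants if v.gene_id})

    def min_mut_growth(res, gene):
        df = res.estimates
        sel = df[(df.gene_id == gene) & (df.role == "SG1") & (df.status == "ok")
                 & df.strategy.isin(["parent", "compounding"])]
        if not len(sel):
            return None
        return float(sel.sort_values("n_mut").normalized.iloc[0])

    genes_fits = {}
    fit_rows, median_rows = [], []
    for gene in genes:
        g1 = min_mut_growth(res1, gene)
        g2 = min_mut_growth(res2, gene)
        candidates = [g for g in (g1, g2) if g is not None]
        if not candidates or min(candidates) > eligibility_threshold:
            continue
        fe1 = gxe.gene_env_fit(sg1_series_points(gene, res1, lib), gene, env1,
                               min_points=min_points)
        fe2 = gxe.gene_env_fit(sg1_series_points(gene, res2, lib), gene, env2,
                               min_points=min_points)
        if not (fe1.ok and fe2.ok):
            continue
        genes_fits[gene] = (fe1, fe2)
        for fe in (fe1, fe2):
            for f in fe.fits:
                fit_rows.append(
                    {
                        "gene_id": f.gene_id, "environment": f.environment,
                        "barcode": f.barcode, "min": f.min, "max": f.max,
                        "hill": f.hill, "ig50": f.ig50, "cost": f.cost,
                        "flat": f.flat, "n_points": f.n_points,
                    }
                )
            med = fe.medians()
            median_rows.append({"gene_id": fe.gene_id, "environment": fe.environment,
                                **med})
    calls = gxe.detect_gxe(genes_fits, gamma=gamma, alpha=alpha) if genes_fits else []
    return calls, pd.DataFrame(fit_rows), pd.DataFrame(median_rows)


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Run every stage under one config; returns the run directory."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    # -- stage: genes ------------------------------------------------------
    if config.genes_fasta:
        genes = design.read_genes_fasta(config.genes_fasta)
        log(f"genes: read {len(genes)} from {config.genes_fasta}")
    else:
        genes = simulate.synthetic_genes(config.n_genes, config.gene_length,
                                         seed=config.seed)
        log(f"genes: generated {len(genes)} synthetic CDS (seed {config.seed})")

    background = None
    if config.background_fasta:
        background = [g.cds for g in design.read_genes_fasta(config.background_fasta)]

    # -- stage: design -----------------------------------------------------
    lib = design.design_library(
        genes, background=background, n_negc=config.n_negc, seed=config.seed,
        gc_min=config.gc_min, gc_max=config.gc_max, polyt_max=config.polyt_max,
    )
    if config.library == "compact":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lib = design.compact_subset(lib)
    design.write_library_tsv(lib, out / "library.tsv")
    log(f"design: {len(lib)} guides ({config.library} library), "
        f"{len(lib.negc())} controls -> library.tsv")

    # -- stage: simulate ---------------------------------------------------
    env_names = tuple(e.name for e in config.environments)
    truth = simulate.TruthModel.random(
        genes, env_names=env_names, seed=config.seed,
        floor_raw=config.floor_raw_truth, escape_prob=config.escape_prob,
        depth=config.depth, replicate_jitter_sd=config.replicate_jitter_sd,
    )
    tensors = {}
    for i, env_cfg in enumerate(config.environments):
        env = simulate.EnvironmentSpec(env_cfg.name, tuple(env_cfg.schedule_hours),
                                       env_cfg.doublings_per_hour)
        ct, esc = simulate.simulate_counts(truth, lib, env,
                                           seed=(config.seed * 1009 + i) % 2**31)
        tensors[env.name] = (ct, env)
        ct.write_tsv(out / f"counts_{env.name}.tsv")
        esc.write_tsv(out / f"escapers_{env.name}.tsv")
        log(f"simulate[{env.name}]: depth {config.depth}, "
            f"{len(esc)} escaper lineages -> counts_{env.name}.tsv")
    truth_rows = [
        {"gene_id": g, "environment": e, "min": c.min, "max": c.max,
         "hill": c.hill, "ig50": c.ig50}
        for g, per_env in sorted(truth.gene_params.items())
        for e, c in sorted(per_env.items())
    ]
    pd.DataFrame(truth_rows).to_csv(out / "truth.tsv", sep="\t", index=False)

    # -- stage: growth -----------------------------------------------------
    # with floor "auto" the first environment's empirical floor anchors
    # every environment, keeping normalized scales directly comparable
    results: dict[str, growth.GrowthResult] = {}
    floor = config.floor
    for name, (ct, env) in tensors.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = growth.estimate_growth(
                ct, lib, env.doublings_per_hour,
                reference=config.reference, floor_raw=floor,
                depth_floor=config.depth_floor, r2_min=config.r2_min,
                exempt_band=(-config.exempt, config.exempt),
                min_replicates=config.min_replicates,
            )
        floor = res.floor_raw
        results[name] = res
        res.estimates.to_csv(out / f"estimates_{name}.tsv", sep="\t", index=False)
        res.replicate_fits.to_csv(out / f"replicate_fits_{name}.tsv", sep="\t",
                                  index=False)
        n_ok = int((res.estimates.status == "ok").sum())
        log(f"growth[{name}]: reference {res.reference}, floor {res.floor_raw:.4f}, "
            f"{n_ok}/{len(res.estimates)} guides kept -> estimates_{name}.tsv")

    # -- stage: steps (first environment) ----------------------------------
    first_env = config.environments[0].name
    measures = steps.measures_from_growth(results[first_env], lib)
    if measures:
        scopes = tuple(s for s in config.scopes)
        table, _ = steps.strategy_comparison(measures, scopes=scopes,
                                             gamma=config.gamma, alpha=config.alpha)
        table.to_csv(out / "steps.tsv", sep="\t", index=False)
        log(f"steps[{first_env}]: {len(table)} (gene, scope) results -> steps.tsv")
    else:
        log(f"steps[{first_env}]: skipped, no eligible measures")

    # -- stage: gxe --------------------------------------------------------
    if len(results) == 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            calls, fits_df, medians_df = gxe_from_results(
                results, lib, gamma=config.gamma, alpha=config.alpha,
                min_points=config.min_points,
            )
        fits_df.to_csv(out / "logistic_fits.tsv", sep="\t", index=False)
        medians_df.to_csv(out / "logistic_medians.tsv", sep="\t", index=False)
        call_rows = [
            {
                "gene_id": c.gene_id,
                "interaction_class": c.interaction_class,
                "significant": ",".join(sorted(c.significant)) or "-",
                **{f"p_{k}": (v if v is not None else np.nan)
                   for k, v in c.p_values.items()},
            }
            for c in calls
        ]
        pd.DataFrame(call_rows).to_csv(out / "gxe_calls.tsv", sep="\t", index=False)
        n_int = sum(c.interaction_class != "none" for c in calls)
        log(f"gxe: {len(calls)} genes tested, {n_int} interactions -> gxe_calls.tsv")
    else:
        log("gxe: skipped, needs exactly two environments")

    config.to_yaml(out / "config.yaml")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
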