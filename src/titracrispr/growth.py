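"""Escaper-corrected relative growth rates from pooled-screen counts.

The growth statistic: for each (guide, barcode) lineage, the relative
allele frequency

    f(t) = log2(n_sg / n_nc)_t - log2(n_sg / n_nc)_{t=0}

is computed against a non-targeting reference control, the time axis is
rescaled to generations (hours x mixed-population doublings per hour), and
an ordinary least-squares line of f versus generations gives the relative
growth rate (slope; the reference is 0 by construction).  Points are used
in schedule order until the first whose guide count drops below the depth
floor — that point is still included, none after it.

Escaper correction then filters the up-to-six internal-replicate fits per
guide: fits with R^2 < 0.70 are dropped unless their slope lies in the
near-zero exemption band [-0.05, 0.05] (R^2 is uninformative for flat
lines), a single-pass Dixon Q test at 95% confidence removes at most one
outlying replicate (the signature of a lineage that escaped CRISPRi), and
guides with fewer than three surviving replicates are rejected.  Survivor
slopes are averaged (mean, SD, SEM) and affinely normalized so that an
empirical lethal floor maps to 0 and the reference to 1:

    normalized = (raw + |floor|) / |floor|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import CountTensor
from .design import LibrarySpec
from .stats import dixon_q

__all__ = [
    "FrequencySeries",
    "GrowthFit",
    "GrowthEstimate",
    "CorrectionResult",
    "TimecourseResult",
    "GrowthResult",
    "pick_reference_negc",
    "compute_frequency",
    "fit_relative_growth",
    "escaper_correct",
    "normalize_growth",
    "timecourse_growth",
    "uncorrected_growth",
    "estimate_growth",
]


@dataclass
class FrequencySeries:
    """Relative log2 frequency of one (guide, barcode) lineage.

    ``f`` is NaN at timepoints where the guide count is zero (log of zero);
    f = 0 at t = 0 by construction.
    """

    guide_id: str
    barcode: str
    generations: np.ndarray
    f: np.ndarray
    depth_sg: np.ndarray
    depth_nc: np.ndarray


@dataclass(frozen=True)
class GrowthFit:
    slope: float  # relative growth, doublings per generation
    intercept: float
    r2: float
    n_points_used: int


@dataclass
class GrowthEstimate:
    guide_id: str
    mean_raw: float
    sd: float
    sem: float
    n_replicates: int
    normalized: float = float("nan")
    removed_barcodes: tuple = ()


@dataclass
class CorrectionResult:
    """Outcome of escaper correction for one guide: an estimate, or a
    reported rejection when fewer than three replicates survive."""

    estimate: GrowthEstimate | None
    removed: tuple  # (barcode, reason) pairs; reasons: low_R2, q_test,
    #                 too_few_replicates, zero_t0, too_few_points

    @property
    def rejected(self) -> bool:
        return self.estimate is None


def pick_reference_negc(ct: CountTensor, negc_ids) -> str:
    """Choose the reference control from the center of the non-targeting
    growth distribution.

    Each control gets a provisional slope from an OLS fit of log2(its
    barcode-summed share of total reads) against hours; the control with
    the median provisional slope wins (lower median for even counts, first
    id on ties).  Controls without full coverage (a nonzero count in every
    barcode at every timepoint, so they can anchor every replicate's
    frequency) are ineligible.
    """
    negc_ids = sorted(set(negc_ids))
    if len(negc_ids) < 3:
        raise ValueError("need at least 3 non-targeting controls")
    totals = ct.totals().astype(float)
    slopes = []
    for g in negc_ids:
        per_bc = ct.guide(g)
        if np.any(per_bc == 0):
            continue
        pooled = per_bc.sum(axis=0).astype(float)
        share = np.log2(pooled / totals)
        slopes.append((g, float(np.polyfit(ct.hours, share, 1)[0])))
    if not slopes:
        raise ValueError("no non-targeting control has full timepoint coverage")
    values = sorted(s for _, s in slopes)
    median = values[(len(values) - 1) // 2]  # lower median
    return min(g for g, s in slopes if s == median)


def compute_frequency(
    ct: CountTensor, reference: str, doublings_per_hour: float
) -> list[FrequencySeries]:
    """Per-(guide, barcode) relative frequency series against the reference
    control of the same barcode.

    Requires reference counts > 0 at every timepoint in every barcode.
    Lineages with a zero count at t = 0 are dropped with a warning (their
    frequency is undefined at the anchor point).
    """
    ref = ct.guide(reference).astype(float)  # (B, T)
    if np.any(ref == 0):
        raise ValueError(f"reference {reference!r} has zero counts at some timepoint")
    generations = ct.hours * doublings_per_hour
    out: list[FrequencySeries] = []
    n_dropped = 0
    log_ref = np.log2(ref)
    for gi, guide in enumerate(ct.guides):
        cg = ct.counts[gi].astype(float)  # (B, T)
        with np.errstate(divide="ignore"):
            log_sg = np.log2(cg)
        ratio = log_sg - log_ref
        for bi, barcode in enumerate(ct.barcodes):
            if cg[bi, 0] == 0:
                n_dropped += 1
                continue
            f = ratio[bi] - ratio[bi, 0]
            out.append(
                FrequencySeries(
                    guide_id=guide,
                    barcode=barcode,
                    generations=generations,
                    f=np.where(cg[bi] > 0, f, np.nan),
                    depth_sg=ct.counts[gi, bi].copy(),
                    depth_nc=ct.guide(reference)[bi].copy(),
                )
            )
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} lineages with zero count at t=0",
                      stacklevel=2)
    return out


def _ols(x: np.ndarray, y: np.ndarray) -> GrowthFit:
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return GrowthFit(float(slope), float(intercept), r2, len(x))


def fit_relative_growth(fs: FrequencySeries, depth_floor: int = 10) -> GrowthFit | None:
    """OLS of f on generations with depth truncation.

    Points enter in schedule order; the first point with guide depth below
    ``depth_floor`` is included and ends the fit.  A zero-count point
    (undefined f) ends the fit without being included.  Returns None when
    fewer than two points are usable.
    """
    xs, ys = [], []
    for i in range(len(fs.generations)):
        if fs.depth_sg[i] == 0:
            break
        xs.append(fs.generations[i])
        ys.append(fs.f[i])
        if fs.depth_sg[i] < depth_floor:
            break
    if len(xs) < 2:
        return None
    return _ols(np.array(xs), np.array(ys))


def escaper_correct(
    guide_id: str,
    fits_by_barcode: dict[str, GrowthFit],
    r2_min: float = 0.70,
    exempt_band: tuple[float, float] = (-0.05, 0.05),
    min_replicates: int = 3,
    prior_removed: tuple = (),
) -> CorrectionResult:
    """Filter replicate fits and average the survivors.

    Order: (1) R^2 filter with the near-zero exemption; (2) single-pass
    Dixon Q at 95% on surviving slopes, removing at most one replicate;
    (3) require >= ``min_replicates`` survivors.  ``prior_removed`` carries
    (barcode, reason) pairs from upstream stages (zero t=0 count, too few
    points) into the log.
    """
    removed = list(prior_removed)
    lo, hi = exempt_band
    surviving = []
    for barcode in sorted(fits_by_barcode):
        fit = fits_by_barcode[barcode]
        if fit.r2 < r2_min and not (lo <= fit.slope <= hi):
            removed.append((barcode, "low_R2"))
        else:
            surviving.append((barcode, fit))
    if 3 <= len(surviving) <= 10:
        res = dixon_q([fit.slope for _, fit in surviving])
        if res.outlier_index is not None:
            removed.append((surviving[res.outlier_index][0], "q_test"))
            surviving.pop(res.outlier_index)
    if len(surviving) < min_replicates:
        removed.append(("*", "too_few_replicates"))
        return CorrectionResult(None, tuple(removed))
    slopes = np.array([fit.slope for _, fit in surviving])
    sd = float(np.std(slopes, ddof=1))
    return CorrectionResult(
        GrowthEstimate(
            guide_id=guide_id,
            mean_raw=float(slopes.mean()),
            sd=sd,
            sem=sd / np.sqrt(len(slopes)),
            n_replicates=len(slopes),
            removed_barcodes=tuple(removed),
        ),
        tuple(removed),
    )


def poisson_decay_slope(counts, ref_counts, generations) -> float:
    """Maximum-likelihood log2 slope of an exponentially decaying lineage.

    Counts are modelled as Poisson with mean A * 2**(slope * g) times the
    reference trajectory (which absorbs the drift of total population
    fitness).  Unlike the log-ratio OLS, this stays well behaved when late
    counts fall to single digits or zero — which is exactly the regime of
    the lethal guides that anchor the normalization floor.
    """
    from scipy.optimize import minimize

    n = np.asarray(counts, dtype=float)
    ref = np.asarray(ref_counts, dtype=float)
    g = np.asarray(generations, dtype=float)
    if np.any(ref <= 0):
        raise ValueError("reference counts must be positive")
    off = np.log(ref)
    ln2 = np.log(2.0)
    pos = n > 0
    if pos.sum() > 1:
        b0 = float(np.polyfit(g[pos], np.log2(n[pos]) - np.log2(ref[pos]), 1)[0])
    else:
        b0 = 0.0
    a0 = float(np.log(max(n[0], 0.5)) - off[0])

    def nll(x):
        eta = x[0] + x[1] * ln2 * g + off
        lam = np.exp(eta)
        return float(np.sum(lam - n * eta))

    def grad(x):
        eta = x[0] + x[1] * ln2 * g + off
        d = np.exp(eta) - n
        return np.array([d.sum(), float((d * ln2 * g).sum())])

    sol = minimize(nll, np.array([a0, b0]), jac=grad, method="BFGS")
    return float(sol.x[1])


def normalize_growth(mean_raw: float, floor_raw: float) -> float:
    """Affine rescale: lethal floor -> 0, reference (raw 0) -> 1.  Values
    outside [0, 1] are allowed (faster-than-reference or below-floor)."""
    if floor_raw >= 0:
        raise ValueError("floor_raw must be negative (a lethal growth rate)")
    return (mean_raw + abs(floor_raw)) / abs(floor_raw)


@dataclass
class TimecourseResult:
    """Stability diagnostic: slope using t=0 and each later timepoint
    alone, next to the all-points fit.  No R^2 or replicate filtering."""

    guide_id: str
    barcode: str
    endpoint_slopes: dict[float, float]  # hour -> two-point slope
    all_points: GrowthFit | None


def timecourse_growth(
    fs: FrequencySeries, hours: np.ndarray, depth_floor: int = 10
) -> TimecourseResult:
    """Two-point slopes (t0 versus each later timepoint with depth >=
    ``depth_floor`` at both ends) plus the fit over all such points."""
    ok = fs.depth_sg >= depth_floor
    endpoint: dict[float, float] = {}
    if ok[0]:
        for i in range(1, len(hours)):
            if ok[i]:
                endpoint[float(hours[i])] = float(
                    (fs.f[i] - fs.f[0]) / (fs.generations[i] - fs.generations[0])
                )
    allfit = None
    if ok.sum() >= 2:
        allfit = _ols(fs.generations[ok], fs.f[ok])
    return TimecourseResult(fs.guide_id, fs.barcode, endpoint, allfit)


def uncorrected_growth(
    ct: CountTensor, reference: str, doublings_per_hour: float
) -> dict[str, float]:
    """The standard single-endpoint estimate: counts pooled over barcodes,
    slope from t=0 and the final timepoint only, no filters of any kind.
    NaN where an endpoint count is zero."""
    pooled = ct.pooled().astype(float)
    ref = pooled[ct.guides.index(reference)]
    gen_last = ct.hours[-1] * doublings_per_hour
    out = {}
    for gi, guide in enumerate(ct.guides):
        n = pooled[gi]
        if n[0] == 0 or n[-1] == 0 or ref[0] == 0 or ref[-1] == 0:
            out[guide] = float("nan")
            continue
        f_last = np.log2(n[-1] / ref[-1]) - np.log2(n[0] / ref[0])
        out[guide] = float(f_last / gen_last)
    return out


# ---------------------------------------------------------------------------
# High-level driver
# ---------------------------------------------------------------------------

@dataclass
class GrowthResult:
    estimates: pd.DataFrame
    replicate_fits: pd.DataFrame
    reference: str
    floor_raw: float
    replicate_slopes: dict[str, np.ndarray] = field(default_factory=dict)

    def normalized(self, guide_id: str) -> float:
        row = self.estimates.loc[self.estimates.guide_id == guide_id]
        return float(row.normalized.iloc[0]) if len(row) else float("nan")


def estimate_growth(
    ct: CountTensor,
    lib: LibrarySpec,
    doublings_per_hour: float,
    reference: str = "auto",
    floor_raw: float | str = "auto",
    depth_floor: int = 10,
    r2_min: float = 0.70,
    exempt_band: tuple[float, float] = (-0.05, 0.05),
    min_replicates: int = 3,
) -> GrowthResult:
    """Full escaper-corrected growth estimation for a count tensor.

    ``reference="auto"`` picks the median non-targeting control;
    ``floor_raw="auto"`` uses the most negative parent-guide mean that kept
    all internal replicates (the empirical lethal floor).
    """
    meta = {
        v.guide_id: (v.gene_id, v.role, v.strategy, v.n_mut) for v in lib.variants
    }
    negc_ids = [v.guide_id for v in lib.negc() if v.guide_id in ct._guide_idx]
    if reference == "auto":
        reference = pick_reference_negc(ct, negc_ids)

    series = compute_frequency(ct, reference, doublings_per_hour)
    by_guide: dict[str, dict[str, GrowthFit]] = {}
    prior: dict[str, list] = {}
    fit_rows = []
    with_t0 = {(fs.guide_id, fs.barcode) for fs in series}
    for guide in ct.guides:
        for barcode in ct.barcodes:
            if (guide, barcode) not in with_t0:
                prior.setdefault(guide, []).append((barcode, "zero_t0"))
    for fs in series:
        fit = fit_relative_growth(fs, depth_floor=depth_floor)
        if fit is None:
            prior.setdefault(fs.guide_id, []).append((fs.barcode, "too_few_points"))
            continue
        by_guide.setdefault(fs.guide_id, {})[fs.barcode] = fit
        fit_rows.append(
            {
                "guide_id": fs.guide_id,
                "barcode": fs.barcode,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r2": fit.r2,
                "n_points": fit.n_points_used,
            }
        )
    replicate_fits = pd.DataFrame(fit_rows)

    corrections: dict[str, CorrectionResult] = {}
    for guide in ct.guides:
        corrections[guide] = escaper_correct(
            guide,
            by_guide.get(guide, {}),
            r2_min=r2_min,
            exempt_band=exempt_band,
            min_replicates=min_replicates,
            prior_removed=tuple(prior.get(guide, ())),
        )

    if floor_raw == "auto":
        # Empirical lethal floor: among parent guides that kept every
        # internal replicate, refit the barcode-pooled trajectories by
        # Poisson maximum likelihood (robust to the single-digit late
        # counts of lethal lineages) and take the median of the five most
        # negative slopes.  The median avoids anchoring the whole scale on
        # one extreme order statistic.
        qualifying = [
            g
            for g, c in corrections.items()
            if not c.rejected
            and meta.get(g, (None, None, None, 0))[2] == "parent"
            and c.estimate.n_replicates == len(ct.barcodes)
        ]
        if not qualifying:
            raise ValueError(
                "no parent guide with all replicates surviving; supply floor_raw"
            )
        pooled = ct.pooled().astype(float)
        ref_row = pooled[ct.guides.index(reference)]
        generations = ct.hours * doublings_per_hour
        slopes = sorted(
            poisson_decay_slope(pooled[ct.guides.index(g)], ref_row, generations)
            for g in qualifying
        )
        floor_raw = float(np.median(slopes[:5]))
        if floor_raw >= 0:
            raise ValueError(
                "auto floor is non-negative (no lethal parent guide); supply floor_raw"
            )
    floor_raw = float(floor_raw)

    removed_sets = {
        g: {b for b, _ in c.removed if b != "*"} for g, c in corrections.items()
    }
    if len(replicate_fits):
        replicate_fits["kept"] = [
            b not in removed_sets[g]
            for g, b in zip(replicate_fits.guide_id, replicate_fits.barcode)
        ]
        replicate_fits["normalized_slope"] = [
            normalize_growth(s, floor_raw) for s in replicate_fits.slope
        ]

    rows = []
    slopes_map: dict[str, np.ndarray] = {}
    for guide in ct.guides:
        gene_id, role, strategy, n_mut = meta.get(guide, (None, None, "?", 0))
        c = corrections[guide]
        if c.rejected:
            rows.append(
                {
                    "guide_id": guide, "gene_id": gene_id, "role": role,
                    "strategy": strategy, "n_mut": n_mut,
                    "mean_raw": np.nan, "sd": np.nan, "sem": np.nan,
                    "n_replicates": 0, "normalized": np.nan,
                    "status": "rejected",
                    "removed": ";".join(f"{b}:{r}" for b, r in c.removed),
                }
            )
            continue
        est = c.estimate
        est.normalized = normalize_growth(est.mean_raw, floor_raw)
        kept = [
            fit.slope
            for b, fit in sorted(by_guide.get(guide, {}).items())
            if b not in removed_sets[guide]
        ]
        slopes_map[guide] = np.array(kept)
        rows.append(
            {
                "guide_id": guide, "gene_id": gene_id, "role": role,
                "strategy": strategy, "n_mut": n_mut,
                "mean_raw": est.mean_raw, "sd": est.sd, "sem": est.sem,
                "n_replicates": est.n_replicates, "normalized": est.normalized,
                "status": "ok",
                "removed": ";".join(f"{b}:{r}" for b, r in c.removed),
            }
        )
    estimates = pd.DataFrame(rows)
    return GrowthResult(estimates, replicate_fits, reference, floor_raw, slopes_map)
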