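"""Gene-by-environment interaction calling from logistic titration fits.

For each gene, replicate titration curves (normalized growth versus number
of compounding spacer mutations) are fit with a four-parameter Hill-type
logistic,

    g(m) = min + (max - min) * m**hill / (ig50**hill + m**hill),

per internal-replicate barcode and environment.  Genes whose curve is flat
(|meanH - meanL| < 0.05, the means of the three most- and least-mutated
guides) get only min/max.  Interactions are then called per fit parameter
by Welch's t-test across the replicate estimates of the two environments,
with SGoF multiple-testing correction run separately for each parameter
over all genes.  Genes that titrate in exactly one environment receive
p = 0 for IG-50 and Hill, since a present-versus-absent titration is an
unambiguous difference.

A ``titration_only`` interaction — no detectable difference in the minimal
growth rate, but a significant shift in IG-50, Hill or max — is exactly the
class of gene-by-environment coupling that a single maximal-knockdown
screen cannot see.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .stats import sgof, welch_p

__all__ = [
    "hill_logistic",
    "LogisticFit",
    "GeneEnvFits",
    "GxECall",
    "fit_logistic_replicate",
    "gene_env_fit",
    "detect_gxe",
    "FLAT_THRESHOLD",
    "MIN_POINTS",
]

FLAT_THRESHOLD = 0.05  # |meanH - meanL| below this: no titration, flat fit
MIN_POINTS = 8  # minimum measured guides per replicate curve
PARAMETERS = ("min", "max", "hill", "ig50")


def hill_logistic(m, lo: float, hi: float, hill: float, ig50: float):
    """Increasing Hill curve from ``lo`` at m=0 toward ``hi``.

    Evaluated as 1 / (1 + (ig50/m)**hill) for numerical stability; the
    m = 0 and ig50 = 0 edges take their limiting values.
    """
    scalar = np.ndim(m) == 0
    m = np.atleast_1d(np.asarray(m, dtype=float))
    out = np.empty_like(m)
    pos = m > 0
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        if ig50 > 0:
            ratio = np.divide(ig50, m, out=np.full_like(m, np.inf), where=pos)
            frac = 1.0 / (1.0 + np.power(ratio, hill))
        else:
            # ig50 = 0: curve is a step at m = 0 (hill > 0) or constant
            frac = np.where(pos, 1.0 if hill > 0 else 0.0, 0.0)
    out[pos] = frac[pos]
    out[~pos] = 0.0 if hill > 0 else (0.5 if hill == 0 else 1.0)
    res = lo + (hi - lo) * out
    return float(res[0]) if scalar else res


@dataclass(frozen=True)
class LogisticFit:
    """One replicate titration fit.  ``flat`` fits carry no hill/ig50."""

    gene_id: str
    environment: str
    barcode: str
    min: float
    max: float
    hill: float | None
    ig50: float | None
    cost: float  # sum of squared residuals
    flat: bool
    n_points: int

    def param(self, name: str) -> float | None:
        return getattr(self, name)


def fit_logistic_replicate(
    points,
    gene_id: str = "",
    environment: str = "",
    barcode: str = "",
    min_points: int = MIN_POINTS,
    flat_threshold: float = FLAT_THRESHOLD,
) -> LogisticFit | None:
    """Fit one replicate's (n_mut, normalized growth) series.

    Requires at least ``min_points`` measured guides (returns None below
    that).  meanL/meanH are the means over the three lowest/highest
    mutation counts; a difference under ``flat_threshold`` short-circuits
    to a flat fit.  Otherwise a bounded least-squares fit is run with
    starts (min, max, hill, ig50) = (meanL, meanH, 1, 6), min/max bounded
    to [0, 1.15], ig50 to [0, 14], and hill unbounded.
    """
    pts = sorted((float(m), float(g)) for m, g in points)
    if len(pts) < min_points:
        return None
    m = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    mean_l = float(y[:3].mean())
    mean_h = float(y[-3:].mean())
    if abs(mean_h - mean_l) < flat_threshold:
        cost = float(np.sum((y - y.mean()) ** 2))
        return LogisticFit(gene_id, environment, barcode,
                           min=mean_l, max=mean_h, hill=None, ig50=None,
                           cost=cost, flat=True, n_points=len(pts))

    def residuals(x):
        lo, hi, hill, ig50 = x
        return hill_logistic(m, lo, hi, hill, ig50) - y

    x0 = np.array([np.clip(mean_l, 0, 1.15), np.clip(mean_h, 0, 1.15), 1.0, 6.0])
    sol = least_squares(
        residuals, x0,
        bounds=([0.0, 0.0, -np.inf, 0.0], [1.15, 1.15, np.inf, 14.0]),
    )
    lo, hi, hill, ig50 = sol.x
    return LogisticFit(gene_id, environment, barcode,
                       min=float(lo), max=float(hi), hill=float(hill),
                       ig50=float(ig50), cost=float(np.sum(sol.fun**2)),
                       flat=False, n_points=len(pts))


@dataclass
class GeneEnvFits:
    """All replicate fits for one (gene, environment), plus parameter
    medians (absent parameters are excluded from their median)."""

    gene_id: str
    environment: str
    fits: list[LogisticFit]
    skipped_barcodes: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return len(self.fits) >= 3

    def samples(self, name: str) -> np.ndarray:
        vals = [f.param(name) for f in self.fits]
        return np.array([v for v in vals if v is not None], dtype=float)

    def medians(self) -> dict[str, float | None]:
        out: dict[str, float | None] = {}
        for name in PARAMETERS:
            s = self.samples(name)
            out[name] = float(np.median(s)) if s.size else None
        return out

    @property
    def titrating(self) -> bool:
        """Enough sigmoidal replicates to estimate hill/ig50 (>= 2)."""
        return sum(not f.flat for f in self.fits) >= 2


def gene_env_fit(
    per_barcode_points: dict[str, list],
    gene_id: str,
    environment: str,
    min_points: int = MIN_POINTS,
) -> GeneEnvFits:
    """Fit every internal-replicate barcode of one gene in one environment.

    Barcodes with fewer than ``min_points`` measured guides are skipped and
    logged; downstream calling requires at least three successful fits.
    """
    fits, skipped = [], []
    for barcode in sorted(per_barcode_points):
        fit = fit_logistic_replicate(
            per_barcode_points[barcode], gene_id, environment, barcode,
            min_points=min_points,
        )
        if fit is None:
            skipped.append(barcode)
        else:
            fits.append(fit)
    return GeneEnvFits(gene_id, environment, fits, skipped)


@dataclass(frozen=True)
class GxECall:
    gene_id: str
    p_values: dict[str, float | None]  # per parameter; None = not testable
    significant: frozenset[str]
    interaction_class: str  # none | min_detectable | titration_only


def detect_gxe(
    genes_fits: dict[str, tuple[GeneEnvFits, GeneEnvFits]],
    gamma: float = 0.05,
    alpha: float = 0.05,
) -> list[GxECall]:
    """Call gene-by-environment interactions across all genes.

    Per gene and parameter, Welch's t-test compares the replicate-level
    parameter estimates between environments (skipped when either side has
    fewer than two values).  A gene flat in exactly one environment gets
    p = 0 for IG-50 and Hill.  SGoF (metatest alpha) is run per parameter
    over all genes; p = 0 entries are always in the rejected set.
    """
    gene_ids = sorted(genes_fits)
    pvals: dict[str, dict[str, float | None]] = {g: {} for g in gene_ids}
    for g in gene_ids:
        fa, fb = genes_fits[g]
        if not (fa.ok and fb.ok):
            warnings.warn(f"{g}: fewer than 3 replicate fits in an environment",
                          stacklevel=2)
            for name in PARAMETERS:
                pvals[g][name] = None
            continue
        one_sided_titration = fa.titrating != fb.titrating
        for name in PARAMETERS:
            if one_sided_titration and name in ("hill", "ig50"):
                pvals[g][name] = 0.0
                continue
            a, b = fa.samples(name), fb.samples(name)
            pvals[g][name] = welch_p(a, b) if (a.size >= 2 and b.size >= 2) else None

    significant: dict[str, set[str]] = {g: set() for g in gene_ids}
    for name in PARAMETERS:
        tested = [(g, pvals[g][name]) for g in gene_ids if pvals[g][name] is not None]
        if not tested:
            continue
        res = sgof([p for _, p in tested], gamma=gamma, alpha=alpha)
        rejected = {tested[i][0] for i in res.rejected_indices}
        rejected |= {g for g, p in tested if p == 0.0}
        for g in rejected:
            significant[g].add(name)

    calls = []
    for g in gene_ids:
        sig = significant[g]
        if "min" in sig:
            cls = "min_detectable"
        elif sig & {"max", "hill", "ig50"}:
            cls = "titration_only"
        else:
            cls = "none"
        calls.append(GxECall(g, pvals[g], frozenset(sig), cls))
    return calls
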