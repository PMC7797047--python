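"""Small-sample statistics used across the analysis: Welch's t-test,
Dixon's Q outlier test, and the sequential goodness-of-fit (SGoF)
multiple-testing correction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy import stats as sps

__all__ = ["welch_p", "dixon_q", "DixonResult", "sgof", "SgofResult"]


def welch_p(a, b) -> float:
    """Two-sided Welch (unequal-variance) t-test p-value, with the
    Satterthwaite degrees-of-freedom approximation.

    Identical constant samples have no testable difference: p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch test needs at least two values per sample")
    va = a.var(ddof=1) / a.size
    vb = b.var(ddof=1) / b.size
    if va == 0 and vb == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return float(2.0 * special.stdtr(df, -abs(t)))


# Two-tailed 95% critical values for Dixon's r10 ("Q") statistic,
# n = 3..10 (Rorabacher 1991).
_DIXON_Q95 = {3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625,
              7: 0.568, 8: 0.526, 9: 0.493, 10: 0.466}


@dataclass(frozen=True)
class DixonResult:
    outlier_index: int | None  # index into the input, or None
    q: float
    critical: float


def dixon_q(values, conf: float = 0.95) -> DixonResult:
    """Single-pass Dixon Q test: flags at most the one most extreme value.

    Q = gap / range for the more suspect extreme.  Only the 95% confidence
    level is tabulated; n must be 3..10.
    """
    if conf != 0.95:
        raise NotImplementedError("only the 95% confidence level is tabulated")
    x = np.asarray(values, dtype=float)
    n = x.size
    if n not in _DIXON_Q95:
        raise ValueError(f"Dixon Q tabulated for n=3..10, got n={n}")
    crit = _DIXON_Q95[n]
    order = np.argsort(x, kind="stable")
    s = x[order]
    rng = s[-1] - s[0]
    if rng == 0:
        return DixonResult(None, 0.0, crit)
    q_low = (s[1] - s[0]) / rng
    q_high = (s[-1] - s[-2]) / rng
    if q_high >= q_low:
        q, idx = q_high, int(order[-1])
    else:
        q, idx = q_low, int(order[0])
    return DixonResult(idx if q > crit else None, float(q), crit)


@dataclass(frozen=True)
class SgofResult:
    n_rejected: int
    rejected_indices: tuple[int, ...]  # indices of the smallest p-values


def sgof(pvalues, gamma: float = 0.05, alpha: float = 0.05) -> SgofResult:
    """Sequential goodness-of-fit metatest (exact binomial variant).

    With F = #{p <= gamma} among n pooled p-values, repeatedly test whether
    the current sub-gamma count F' exceeds its Binomial(n, gamma) null by a
    one-tailed exact test at ``alpha``; while it does, reject the smallest
    remaining p-value and decrement F'.  The rejected set is always the
    smallest p-values, so rejections <= F.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    current = int(np.sum(p <= gamma))
    rejected = 0
    while current > 0 and sps.binom.sf(current - 1, n, gamma) < alpha:
        rejected += 1
        current -= 1
    order = np.argsort(p, kind="stable")
    return SgofResult(rejected, tuple(int(i) for i in order[:rejected]))
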