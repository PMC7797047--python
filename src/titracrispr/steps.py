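"""Statistically resolvable growth effects per gene.

How many distinct knockdown levels does a titrating sgRNA series actually
resolve?  Within each gene, every pair of guides is compared by Welch's
t-test on replicate-level growth rates; p-values are pooled across genes
and corrected with SGoF; and the answer is the size of the largest set of
guides in which *every* pair remains significant — a maximum clique in the
pairwise-significance graph, solved exactly by branch and bound over the
guides rank-ordered by mean growth.  When several maximum sets exist, the
one with the larger dynamic range, then larger variance of means, then
lexicographically smallest guide ids is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import sgof, welch_p

__all__ = [
    "GuideMeasure",
    "StepResult",
    "SCOPES",
    "measures_from_growth",
    "pairwise_welch",
    "gene_eligible",
    "resolvable_steps",
    "strategy_comparison",
]

SCOPES = ("single", "compounding", "all", "compact")
ELIGIBILITY_THRESHOLD = 0.75  # a parent guide must knock growth below this


@dataclass(frozen=True)
class GuideMeasure:
    """Per-guide summary used by the step analysis: mean normalized growth
    plus the surviving replicate-level raw slopes."""

    guide_id: str
    gene_id: str
    role: str | None
    strategy: str
    n_mut: int
    normalized_mean: float
    replicate_slopes: tuple[float, ...]


@dataclass(frozen=True)
class StepResult:
    gene_id: str
    n_steps: int
    member_guides: tuple[str, ...]  # ordered by mean growth
    strategy_scope: str


def measures_from_growth(result, lib) -> list[GuideMeasure]:
    """Build step-analysis inputs from a GrowthResult (accepted guides with
    at least two surviving replicates; controls excluded)."""
    meta = {v.guide_id: v for v in lib.variants}
    out = []
    for row in result.estimates.itertuples(index=False):
        if row.status != "ok" or row.guide_id not in meta:
            continue
        v = meta[row.guide_id]
        if v.strategy == "negC":
            continue
        slopes = result.replicate_slopes.get(row.guide_id, np.empty(0))
        if len(slopes) < 2:
            continue
        out.append(
            GuideMeasure(
                guide_id=row.guide_id,
                gene_id=v.gene_id,
                role=v.role,
                strategy=v.strategy,
                n_mut=v.n_mut,
                normalized_mean=float(row.normalized),
                replicate_slopes=tuple(float(s) for s in slopes),
            )
        )
    return out


def pairwise_welch(measures: list[GuideMeasure]) -> dict[frozenset, float]:
    """Two-sided Welch p-value for every unordered pair of guides of one
    gene, from replicate-level slopes."""
    out: dict[frozenset, float] = {}
    for i in range(len(measures)):
        for j in range(i + 1, len(measures)):
            a, b = measures[i], measures[j]
            out[frozenset({a.guide_id, b.guide_id})] = welch_p(
                a.replicate_slopes, b.replicate_slopes
            )
    return out


def gene_eligible(gene_measures: list[GuideMeasure]) -> bool:
    """A gene enters the step analysis when it has titrating (mutated)
    guides on both SG1 and SG3 and at least one parent guide with
    normalized growth below 0.75."""
    titrating_roles = {
        m.role for m in gene_measures if m.strategy in ("single", "double", "compounding")
    }
    parent_ok = any(
        m.strategy == "parent" and m.normalized_mean < ELIGIBILITY_THRESHOLD
        for m in gene_measures
    )
    return {"SG1", "SG3"} <= titrating_roles and parent_ok


_TIE_CAP = 20_000  # maximum cliques collected for tie-breaking


def _all_maximum_cliques(nodes: list[str], adj: dict[str, set]) -> list[tuple[str, ...]]:
    """Maximum-cardinality cliques by exact bitset branch and bound.

    Phase 1 finds the maximum size with popcount pruning; phase 2
    enumerates cliques of that size (in node order, so deterministic) for
    the downstream tie-break.  The size is always exact; if a pathological
    instance has more than ``_TIE_CAP`` maximum cliques, only the first
    that many enter the tie-break.
    """
    n = len(nodes)
    if n == 0:
        return []
    index = {v: i for i, v in enumerate(nodes)}
    adj_bits = [0] * n
    for v, neighbors in adj.items():
        for u in neighbors:
            adj_bits[index[v]] |= 1 << index[u]

    def color_sort(cand: int) -> tuple[list[int], list[int]]:
        """Greedy coloring: vertices grouped into independent classes; the
        class number of a vertex bounds any clique containing it within
        ``cand``."""
        order: list[int] = []
        colors: list[int] = []
        color = 0
        while cand:
            color += 1
            avail = cand
            while avail:
                v = (avail & -avail).bit_length() - 1
                bit = 1 << v
                avail &= ~adj_bits[v] & ~bit
                cand &= ~bit
                order.append(v)
                colors.append(color)
        return order, colors

    best = 1  # a single guide is always a (trivial) clique

    def expand(size: int, cand: int) -> None:
        nonlocal best
        order, colors = color_sort(cand)
        for i in range(len(order) - 1, -1, -1):
            if size + colors[i] <= best:
                return
            v = order[i]
            if size + 1 > best:
                best = size + 1
            sub = cand & adj_bits[v]
            if sub:
                expand(size + 1, sub)
            cand &= ~(1 << v)

    full = (1 << n) - 1
    expand(0, full)

    found: list[int] = []

    def collect(clique: int, size: int, cand: int) -> None:
        if size == best:
            found.append(clique)
            return
        _, colors = color_sort(cand)
        if not colors or size + colors[-1] < best:
            return
        while cand:
            if size + cand.bit_count() < best:
                return
            v = (cand & -cand).bit_length() - 1
            cand &= cand - 1
            collect(clique | (1 << v), size + 1, cand & adj_bits[v])
            if len(found) >= _TIE_CAP:
                return

    collect(0, 0, full)
    return [
        tuple(nodes[i] for i in range(n) if mask >> i & 1) for mask in found
    ]


def resolvable_steps(
    gene_measures: list[GuideMeasure],
    significant_pairs: set[frozenset],
    scope: str = "all",
) -> StepResult:
    """Largest mutually distinguishable guide set for one gene.

    Guides are rank-ordered by mean growth; the maximum clique of the
    significance graph is found exactly, with ties broken by dynamic range,
    then variance of means, then guide ids.  A lone guide (or no
    significant pair at all) yields n_steps = 1.
    """
    if not gene_measures:
        raise ValueError("no measures supplied")
    ranked = sorted(gene_measures, key=lambda m: (m.normalized_mean, m.guide_id))
    means = {m.guide_id: m.normalized_mean for m in ranked}
    nodes = [m.guide_id for m in ranked]
    adj = {
        g: {h for h in nodes if h != g and frozenset({g, h}) in significant_pairs}
        for g in nodes
    }
    cliques = _all_maximum_cliques(nodes, adj)

    def key(clq):
        vals = np.array([means[g] for g in clq])
        dyn = vals.max() - vals.min() if len(vals) > 1 else 0.0
        var = vals.var() if len(vals) > 1 else 0.0
        return (-dyn, -var, clq)

    winner = min(cliques, key=key)
    gene_id = gene_measures[0].gene_id
    return StepResult(gene_id, len(winner), winner, scope)


def _in_scope(m: GuideMeasure, scope: str) -> bool:
    if scope == "all":
        return True
    if scope == "single":
        return m.strategy == "single" or (
            m.strategy == "parent" and m.role in ("SG1", "SG3")
        )
    if scope == "compounding":
        return m.strategy == "compounding" or (
            m.strategy == "parent" and m.role in ("SG1", "SG3")
        )
    if scope == "compact":
        return (m.strategy == "parent" and m.role in ("SG1", "SG3")) or (
            m.strategy == "compounding" and 4 <= m.n_mut <= 10
        )
    raise ValueError(f"unknown scope {scope!r}")


def strategy_comparison(
    measures: list[GuideMeasure],
    scopes: tuple[str, ...] = SCOPES,
    gamma: float = 0.05,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[tuple[str, str], StepResult]]:
    """Per-gene resolvable-step counts for each mutation-strategy scope.

    Eligibility is decided once per gene on the full measure set; within
    each scope, Welch p-values are recomputed on the scoped guides, pooled
    across all genes, and SGoF-corrected anew before the clique search.
    """
    by_gene: dict[str, list[GuideMeasure]] = {}
    for m in measures:
        by_gene.setdefault(m.gene_id, []).append(m)
    eligible = {g for g, ms in by_gene.items() if gene_eligible(ms)}

    results: dict[tuple[str, str], StepResult] = {}
    rows = []
    for scope in scopes:
        pooled: list[float] = []
        pair_index: list[tuple[str, frozenset]] = []
        scoped: dict[str, list[GuideMeasure]] = {}
        for g in sorted(eligible):
            ms = [m for m in by_gene[g] if _in_scope(m, scope)]
            scoped[g] = ms
            for pair, p in sorted(pairwise_welch(ms).items(), key=lambda kv: sorted(kv[0])):
                pooled.append(p)
                pair_index.append((g, pair))
        res = sgof(pooled, gamma=gamma, alpha=alpha)
        sig_by_gene: dict[str, set[frozenset]] = {g: set() for g in scoped}
        for i in res.rejected_indices:
            g, pair = pair_index[i]
            sig_by_gene[g].add(pair)
        for g in sorted(eligible):
            if not scoped[g]:
                continue
            sr = resolvable_steps(scoped[g], sig_by_gene[g], scope=scope)
            results[(g, scope)] = sr
            rows.append(
                {
                    "gene_id": g,
                    "scope": scope,
                    "n_steps": sr.n_steps,
                    "member_guides": ",".join(sr.member_guides),
                }
            )
    return pd.DataFrame(rows), results
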