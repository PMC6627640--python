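"""From-scratch gene set enrichment analysis (weighted running-sum GSEA).

The statistic is the classic weighted Kolmogorov–Smirnov running sum:
walking the ranked gene list, members of the query set ("hits") add their
|metric|^weight share of the total hit weight and non-members subtract
1/(N − N_hits); the enrichment score (ES) is the running-sum value of
maximal absolute deviation, and the leading edge is the hit subset at or
before the peak (positive ES) or at or after it (negative ES).

Significance uses a gene-set permutation null: random same-size subsets of
the ranked universe.  The normalized enrichment score (NES) divides the ES
by the mean of same-sign null ES values, permutation p-values carry a
pseudocount to avoid zeros at finite permutation number, and FDR q-values
follow the ratio-of-tails convention on the pooled null NES distribution.

Null distributions depend only on the ranked metric and the set size, so
one null sample per distinct size is shared across equally sized sets.
Inside a run all sizes draw from a single permutation matrix (the size-k
null uses the first k entries of each permuted row): nulls of different
sizes are therefore correlated, but each size's marginal null is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .data_io import ExpressionMatrix, GeneSet, GeneSetCollection, GroupDesign

__all__ = [
    "GseaParams",
    "RankedList",
    "EnrichmentResult",
    "ESProfile",
    "rank_by_signal_to_noise",
    "enrichment_score",
    "gene_set_permutation_null",
    "nes_and_significance",
    "run_gsea",
]


@dataclass
class GseaParams:
    """GSEA settings: size filter bounds, permutation count, hit weight, seed."""

    min_size: int = 15
    max_size: int = 500
    n_perm: int = 1000
    weight: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.min_size <= self.max_size):
            raise ValueError("need 0 < min_size <= max_size")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


@dataclass
class RankedList:
    """Genes ordered by descending metric, ties broken by symbol ascending."""

    genes: np.ndarray
    metric: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.metric = np.asarray(self.metric, dtype=float)
        if self.genes.shape != self.metric.shape or self.genes.ndim != 1:
            raise ValueError("genes and metric must be equal-length 1-D arrays")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked genes must be unique")
        d = np.diff(self.metric)
        if (d > 0).any():
            raise ValueError("metric must be sorted descending")
        self._index = {g: i for i, g in enumerate(self.genes)}

    def __len__(self) -> int:
        return len(self.genes)

    def positions(self, members: Sequence[str]) -> np.ndarray:
        """Sorted rank positions of the members present in the universe."""
        return np.sort([self._index[g] for g in members if g in self._index])


class ESProfile(NamedTuple):
    es: float
    running_sum: np.ndarray
    peak_index: int
    leading_edge: list[str]


@dataclass
class EnrichmentResult:
    """Per-set enrichment: ES, NES, permutation p, FDR q, leading edge."""

    set_name: str
    size_after_filter: int
    es: float
    nes: float
    p_perm: float
    q: float
    leading_edge: list[str]
    peak_index: int


def rank_by_signal_to_noise(
    matrix: ExpressionMatrix, design: GroupDesign
) -> RankedList:
    """Rank genes by the signal-to-noise ratio (test vs reference).

    metric = (μ_test − μ_ref) / (σ_test + σ_ref) with each group's standard
    deviation floored at max(0.2·|μ of its group|, 0.2) — the floor keeps
    near-constant genes from dominating the ranking.  Descending order;
    ties broken by gene symbol ascending.
    """
    design.validate_against(matrix)
    ref = design.samples(design.reference_group)
    test = design.samples(design.test_group)
    if len(ref) < 2 or len(test) < 2:
        raise ValueError("signal-to-noise ranking needs >= 2 samples per group")
    a = matrix.subset_samples(ref).values
    b = matrix.subset_samples(test).values
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    sd_a = a.std(axis=1, ddof=1)
    sd_b = b.std(axis=1, ddof=1)
    sd_a = np.maximum(sd_a, np.maximum(0.2 * np.abs(mu_a), 0.2))
    sd_b = np.maximum(sd_b, np.maximum(0.2 * np.abs(mu_b), 0.2))
    metric = (mu_b - mu_a) / (sd_b + sd_a)
    genes = np.asarray(matrix.gene_ids, dtype=object)
    order = np.lexsort((genes, -metric))
    return RankedList(genes[order], metric[order])


def _hit_weights(metric_abs_pow: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Normalized hit increments; uniform fallback when all hit weights vanish."""
    w = metric_abs_pow[pos]
    total = w.sum()
    if total <= 0:
        return np.full(len(pos), 1.0 / len(pos))
    return w / total


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet | Sequence[str], weight: float = 1.0
) -> ESProfile:
    """Weighted running-sum enrichment score of one gene set.

    Returns the ES, the full running-sum array over the ranked list, the
    peak position (first index of maximal |running sum|) and the leading
    edge genes.  Raises if the set does not intersect the ranked universe
    (distinct from a set filtered out by size bounds in :func:`run_gsea`).
    """
    members = gene_set.members if isinstance(gene_set, GeneSet) else gene_set
    pos = ranked.positions(list(members))
    n = len(ranked)
    if len(pos) == 0:
        raise ValueError("gene set has empty intersection with the ranked universe")
    inc = _hit_weights(np.abs(ranked.metric) ** weight, pos)
    miss_step = 1.0 / (n - len(pos)) if n > len(pos) else 0.0
    steps = np.full(n, -miss_step)
    steps[pos] = inc
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    es = float(running[peak])
    if es >= 0:
        edge_pos = pos[pos <= peak]
    else:
        edge_pos = pos[pos >= peak]
    leading_edge = [str(ranked.genes[i]) for i in edge_pos]
    return ESProfile(es, running, peak, leading_edge)


def _es_from_sorted_positions(
    pos: np.ndarray, metric_abs_pow: np.ndarray, n: int
) -> np.ndarray:
    """Vectorized ES for many same-size subsets given sorted rank positions.

    ``pos`` has shape (n_subsets, k), rows sorted ascending.  Only the
    extreme deviations are needed for the null, so the full running sum is
    never materialized: the candidate maxima sit just after each hit and
    the candidate minima just before each hit.
    """
    n_sub, k = pos.shape
    w = metric_abs_pow[pos]
    h = np.cumsum(w, axis=1)
    total = h[:, -1:]
    uniform = (np.arange(1, k + 1, dtype=float) / k)[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        hn = np.where(total > 0, h / np.where(total > 0, total, 1.0), uniform)
    miss_step = 1.0 / (n - k) if n > k else 0.0
    misses_before = (pos - np.arange(k)[None, :]) * miss_step
    after = hn - misses_before
    before = np.concatenate([np.zeros((n_sub, 1)), hn[:, :-1]], axis=1) - misses_before
    max_dev = after.max(axis=1)
    min_dev = before.min(axis=1)
    return np.where(max_dev >= -min_dev, max_dev, min_dev)


class PermutationNull:
    """Gene-set permutation null for one ranked list.

    A single (n_perm × N) permutation matrix is drawn once from the seed;
    the null for size k uses the first k entries of each row (a uniform
    k-subset).  Null ES samples are cached per size.
    """

    def __init__(self, ranked: RankedList, params: GseaParams):
        params.validate()
        self.ranked = ranked
        self.params = params
        self._metric_abs_pow = np.abs(ranked.metric) ** params.weight
        rng = np.random.default_rng(np.random.SeedSequence(params.seed))
        n = len(ranked)
        self._perm = rng.permuted(
            np.tile(np.arange(n), (params.n_perm, 1)), axis=1
        )
        self._cache: dict[int, np.ndarray] = {}

    def null_es(self, set_size: int) -> np.ndarray:
        if not (1 <= set_size <= len(self.ranked)):
            raise ValueError("set_size must be in [1, universe size]")
        if set_size not in self._cache:
            pos = np.sort(self._perm[:, :set_size], axis=1)
            self._cache[set_size] = _es_from_sorted_positions(
                pos, self._metric_abs_pow, len(self.ranked)
            )
        return self._cache[set_size]


def gene_set_permutation_null(
    ranked: RankedList, set_size: int, params: GseaParams
) -> np.ndarray:
    """Null ES sample (length n_perm) for uniformly drawn same-size sets."""
    return PermutationNull(ranked, params).null_es(set_size)


def nes_and_significance(
    observed_es: float, null_es_sample: np.ndarray
) -> tuple[float, float]:
    """NES (ES over same-sign null mean) and add-one permutation p-value.

    With no same-sign null draws the NES is undefined (NaN) and p is 1.
    """
    null_es_sample = np.asarray(null_es_sample, dtype=float)
    if null_es_sample.size == 0:
        raise ValueError("null sample must be nonempty")
    if observed_es == 0:
        return 0.0, 1.0
    same_sign = null_es_sample[np.sign(null_es_sample) == np.sign(observed_es)]
    if same_sign.size == 0:
        return math.nan, 1.0
    nes = observed_es / float(np.mean(np.abs(same_sign)))
    n_extreme = int(np.sum(np.abs(same_sign) >= abs(observed_es)))
    p = (1.0 + n_extreme) / (1.0 + same_sign.size)
    return float(nes), float(p)


def _normalized_null(null_es: np.ndarray) -> np.ndarray:
    """Null NES values: each null ES divided by its same-sign null mean."""
    out = np.array([], dtype=float)
    pos = null_es[null_es > 0]
    neg = null_es[null_es < 0]
    parts = []
    if pos.size:
        parts.append(pos / pos.mean())
    if neg.size:
        parts.append(neg / np.abs(neg).mean())
    if parts:
        out = np.concatenate(parts)
    return out


def run_gsea(
    matrix: ExpressionMatrix,
    design: GroupDesign,
    collection: GeneSetCollection,
    params: GseaParams | None = None,
) -> list[EnrichmentResult]:
    """Full GSEA of one two-group comparison against a gene-set collection.

    Sets are filtered to ``min_size <= size <= max_size`` with the size
    computed after intersecting with the ranked universe.  FDR q-values use
    the ratio-of-tails convention — for a positive-NES set, the fraction of
    pooled same-sign null NES at least as large divided by the fraction of
    observed same-sign NES at least as large, capped at 1 and enforced
    monotone in NES.  Results are sorted by NES descending.
    """
    params = params or GseaParams()
    params.validate()
    ranked = rank_by_signal_to_noise(matrix, design)
    universe = set(ranked.genes)

    kept: list[tuple[GeneSet, int]] = []
    for s in collection:
        size = len(s.members & universe)
        if params.min_size <= size <= params.max_size:
            kept.append((s, size))
    if not kept:
        return []

    null = PermutationNull(ranked, params)
    results: list[EnrichmentResult] = []
    null_nes_per_set: list[np.ndarray] = []
    for s, size in kept:
        prof = enrichment_score(ranked, s, weight=params.weight)
        null_es = null.null_es(size)
        nes, p = nes_and_significance(prof.es, null_es)
        results.append(
            EnrichmentResult(
                set_name=s.name,
                size_after_filter=size,
                es=prof.es,
                nes=nes,
                p_perm=p,
                q=math.nan,
                leading_edge=prof.leading_edge,
                peak_index=prof.peak_index,
            )
        )
        null_nes_per_set.append(_normalized_null(null_es))

    pooled = (
        np.concatenate(null_nes_per_set) if null_nes_per_set else np.array([])
    )
    pooled_pos = np.sort(pooled[pooled > 0])
    pooled_neg = np.sort(-pooled[pooled < 0])  # magnitudes, ascending
    obs_nes = np.array([r.nes for r in results])
    obs_pos = np.sort(obs_nes[np.isfinite(obs_nes) & (obs_nes > 0)])
    obs_neg = np.sort(-obs_nes[np.isfinite(obs_nes) & (obs_nes < 0)])

    def tail_frac(sorted_vals: np.ndarray, threshold: float) -> float:
        if sorted_vals.size == 0:
            return 0.0
        idx = np.searchsorted(sorted_vals, threshold, side="left")
        return (sorted_vals.size - idx) / sorted_vals.size

    for r in results:
        if not np.isfinite(r.nes) or r.nes == 0:
            continue
        if r.nes > 0:
            num = tail_frac(pooled_pos, r.nes)
            den = tail_frac(obs_pos, r.nes)
        else:
            num = tail_frac(pooled_neg, -r.nes)
            den = tail_frac(obs_neg, -r.nes)
        r.q = min(1.0, num / den) if den > 0 else 1.0

    # enforce q monotone nondecreasing as |NES| decreases, per sign
    for sign in (1, -1):
        side = [r for r in results if np.isfinite(r.nes) and sign * r.nes > 0]
        side.sort(key=lambda r: -abs(r.nes))
        running = 0.0
        for r in side:
            running = max(running, r.q)
            r.q = running

    results.sort(key=lambda r: (-r.nes if np.isfinite(r.nes) else math.inf, r.set_name))
    return results
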