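"""Consensus polycomb/H3K27me3 signature construction and signature scoring.

From per-line GSEA results, the polycomb-related gene sets are picked by a
keyword match on set names, the top-k by NES are kept per resistant line,
and their leading edges are unioned per line.  Genes whose leading-edge
occurrence spans at least ``min_lines`` resistant lines form the consensus
signature.  Samples are scored by the sum of per-gene Z-scores over the
signature genes, and samples are clustered with correlation-distance UPGMA
to check that the signature separates parental from resistant lines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, normalize_symbol
from .gsea import EnrichmentResult

__all__ = [
    "DEFAULT_SIGNATURE_TOKENS",
    "Signature",
    "SampleScore",
    "Dendrogram",
    "select_topk_polycomb_sets",
    "build_consensus_signature",
    "zscore_by_gene",
    "signature_sum_z",
    "upgma_cluster",
    "two_group_separation",
    "read_signature_txt",
    "write_signature_txt",
]

# keyword tokens operationalizing "related to PRC1, PRC2 and H3K27 methylation"
DEFAULT_SIGNATURE_TOKENS = (
    "PRC1",
    "PRC2",
    "H3K27",
    "EZH2",
    "EED",
    "SUZ12",
    "BMI1",
    "POLYCOMB",
)


@dataclass
class Signature:
    """Consensus gene list with per-line leading-edge occurrence counts."""

    genes: list[str]
    occurrence: dict[str, int]
    min_lines: int
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")
        low = [g for g in self.genes if self.occurrence.get(g, 0) < self.min_lines]
        if low:
            raise ValueError(f"genes below the occurrence threshold: {low[:5]}")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class SampleScore:
    """Per-sample sum of signature-gene Z-scores."""

    sample_id: str
    sum_z: float
    n_genes_used: int


@dataclass
class Dendrogram:
    """UPGMA merge tree: scipy-style cluster ids (leaves 0..n-1, then n...)."""

    leaves: list[str]
    merges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.leaves) - 1:
            raise ValueError("merge count must be n_leaves - 1")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be nondecreasing")

    def cluster_members(self, cluster_id: int) -> list[int]:
        """Leaf indices under a cluster id."""
        n = len(self.leaves)
        if cluster_id < n:
            return [cluster_id]
        a, b, _ = self.merges[cluster_id - n]
        return self.cluster_members(a) + self.cluster_members(b)

    def cut_two(self) -> tuple[list[str], list[str]]:
        """The two clusters obtained by removing the final merge."""
        a, b, _ = self.merges[-1]
        left = [self.leaves[i] for i in self.cluster_members(a)]
        right = [self.leaves[i] for i in self.cluster_members(b)]
        return left, right


def select_topk_polycomb_sets(
    results: Sequence[EnrichmentResult],
    keyword_tokens: Sequence[str] = DEFAULT_SIGNATURE_TOKENS,
    k: int = 20,
) -> list[EnrichmentResult]:
    """Top-k positively enriched sets whose names match a keyword token.

    The keyword filter (case-insensitive substring) runs first, then the k
    highest-NES survivors are returned; fewer are returned when fewer
    qualify.
    """
    tokens = [t.upper() for t in keyword_tokens]
    eligible = [
        r
        for r in results
        if np.isfinite(r.nes)
        and r.nes > 0
        and any(t in r.set_name.upper() for t in tokens)
    ]
    eligible.sort(key=lambda r: (-r.nes, r.set_name))
    return eligible[:k]


def build_consensus_signature(
    per_line_leading_edges: Mapping[str, Iterable[str]],
    min_lines: int = 4,
    provenance: Mapping[str, list[str]] | None = None,
) -> Signature:
    """Consensus signature: genes in the leading edges of >= min_lines lines.

    Each line contributes the union of its selected sets' leading edges, so
    a gene appearing in several sets of the same line counts once for that
    line.  Genes are sorted by (occurrence descending, symbol ascending).
    """
    if not per_line_leading_edges:
        raise ValueError("need at least one line")
    counts: dict[str, int] = {}
    for _line, genes in per_line_leading_edges.items():
        for g in set(normalize_symbol(x) for x in genes):
            counts[g] = counts.get(g, 0) + 1
    kept = sorted(
        (g for g, c in counts.items() if c >= min_lines),
        key=lambda g: (-counts[g], g),
    )
    return Signature(
        genes=kept,
        occurrence={g: counts[g] for g in kept},
        min_lines=min_lines,
        provenance=dict(provenance or {}),
    )


def zscore_by_gene(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, list[str]]:
    """Standardize each gene row to mean 0, SD 1 (sample SD, n−1 denominator).

    Zero-variance rows become all-zero and are returned in the flag list.
    """
    if matrix.shape[1] < 2:
        raise ValueError("z-scoring needs >= 2 samples")
    values = matrix.values
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    flat = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    safe_sd = np.where(sd > 0, sd, 1.0)
    z = (values - mean) / safe_sd
    z[flat, :] = 0.0
    flagged = [g for g, f in zip(matrix.gene_ids, flat) if f]
    out = ExpressionMatrix(
        pd.DataFrame(z, index=matrix.gene_ids, columns=matrix.sample_ids), "zscore"
    )
    return out, flagged


def signature_sum_z(
    zmatrix: ExpressionMatrix, signature: Signature | Sequence[str]
) -> list[SampleScore]:
    """Sum of Z-scores over the signature genes present in the matrix.

    Genes absent from the matrix are skipped (the count of genes actually
    used is recorded on every score); an entirely absent signature is an
    error.
    """
    if zmatrix.value_kind != "zscore":
        raise ValueError(f"expected zscore matrix, got {zmatrix.value_kind!r}")
    genes = signature.genes if isinstance(signature, Signature) else list(signature)
    wanted = [normalize_symbol(g) for g in genes]
    present = [g for g in wanted if g in zmatrix.data.index]
    if not present:
        raise ValueError("no signature genes present in the matrix")
    sums = zmatrix.data.loc[present].sum(axis=0)
    return [
        SampleScore(sample_id=s, sum_z=float(v), n_genes_used=len(present))
        for s, v in sums.items()
    ]


def _pairwise_correlation_distance(values: np.ndarray, sample_ids: list[str]) -> np.ndarray:
    """1 − Pearson correlation between sample columns."""
    sd = values.std(axis=0, ddof=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(
            f"sample {sample_ids[constant[0]]!r} is constant; correlation undefined"
        )
    corr = np.corrcoef(values.T)
    return 1.0 - corr


def upgma_cluster(zmatrix: ExpressionMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) clustering of samples on correlation distance.

    The merged-cluster distance is the unweighted mean of all member-pair
    leaf distances (implemented by the Lance–Williams size-weighted update).
    Ties between candidate merges are broken by the pair containing the
    smallest original leaf index, then the smallest second index.
    """
    if zmatrix.shape[1] < 2 or zmatrix.shape[0] < 2:
        raise ValueError("UPGMA needs >= 2 samples and >= 2 genes")
    samples = zmatrix.sample_ids
    dist = _pairwise_correlation_distance(zmatrix.values, samples)
    n = len(samples)

    active: dict[int, tuple[int, int]] = {i: (i, 1) for i in range(n)}
    # cluster id -> (smallest original leaf index, size)
    d: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = float(dist[i, j])

    def get(a: int, b: int) -> float:
        return d[(a, b) if a < b else (b, a)]

    merges: list[tuple[int, int, float]] = []
    next_id = n
    ids = list(range(n))
    while len(ids) > 1:
        best = None
        for x in range(len(ids)):
            for y in range(x + 1, len(ids)):
                a, b = ids[x], ids[y]
                dd = get(a, b)
                la, lb = active[a][0], active[b][0]
                key = (dd, min(la, lb), max(la, lb))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (height, _, _), a, b = best
        sa, sb = active[a][1], active[b][1]
        for c in ids:
            if c in (a, b):
                continue
            d[(min(c, next_id), max(c, next_id))] = (
                sa * get(a, c) + sb * get(b, c)
            ) / (sa + sb)
        merges.append((a, b, height))
        active[next_id] = (min(active[a][0], active[b][0]), sa + sb)
        ids = [c for c in ids if c not in (a, b)] + [next_id]
        next_id += 1
    return Dendrogram(leaves=samples, merges=merges)


def two_group_separation(
    dendrogram: Dendrogram, labels: Mapping[str, str]
) -> float:
    """Purity of the two-cluster cut against a binary labeling.

    Cuts at the final merge and returns the best fraction of label-matching
    samples over the two possible label-to-cluster assignments.
    """
    label_values = sorted(set(labels.values()))
    if len(label_values) != 2:
        raise ValueError(f"need exactly two labels, got {label_values}")
    left, right = dendrogram.cut_two()
    l0 = sum(1 for s in left if labels[s] == label_values[0])
    l1 = len(left) - l0
    r0 = sum(1 for s in right if labels[s] == label_values[0])
    r1 = len(right) - r0
    n = len(left) + len(right)
    return max(l0 + r1, l1 + r0) / n


def write_signature_txt(signature: Signature, path: str | Path) -> Path:
    """One gene per line with its occurrence count appended (tab-separated)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for g in signature.genes:
            fh.write(f"{g}\t{signature.occurrence[g]}\n")
    return path


def read_signature_txt(path: str | Path, min_lines: int = 0) -> Signature:
    """Read a signature written by :func:`write_signature_txt`."""
    genes: list[str] = []
    occurrence: dict[str, int] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            g = normalize_symbol(parts[0])
            genes.append(g)
            occurrence[g] = int(parts[1]) if len(parts) > 1 else min_lines
    return Signature(genes=genes, occurrence=occurrence, min_lines=min_lines)
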