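"""Two-group differential expression with empirical-Bayes variance moderation.

The model is the trend-free moderated t: per gene, an ordinary two-group
linear model on log-CPM values, with the residual variances s_g² shrunk
toward a common prior s0² estimated by fitting a scaled-F distribution to
the observed variances (method of moments on log s_g², trigamma inversion).
The moderated t uses d0 + d_g degrees of freedom, where d0 is the prior
degrees of freedom and d_g the residual degrees of freedom.

Multiple testing is Benjamini–Hochberg throughout.  The study-level filters
— fold-change/FDR differential calls and the cross-line recurrent
upregulation filter — live here as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq
from statsmodels.stats.multitest import multipletests

from .data_io import ExpressionMatrix, GroupDesign

__all__ = [
    "DEResult",
    "logcpm",
    "moderated_t_test",
    "bh_adjust",
    "de_genes",
    "recurrent_upregulated",
]


@dataclass
class DEResult:
    """Per-gene differential expression table plus the fitted prior.

    ``table`` is indexed by gene with columns ``log2fc`` (test minus
    reference), ``avg_expr`` (mean log-CPM), ``t_mod``, ``p`` and ``q``.
    ``prior_df`` (d0) may be ``math.inf`` when the variances show no excess
    spread over the scaled-F model.
    """

    table: pd.DataFrame
    prior_df: float
    prior_var: float

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


def logcpm(matrix: ExpressionMatrix, prior_count: float = 0.5) -> ExpressionMatrix:
    """log2 counts-per-million: log2(count / library_size * 1e6 + prior_count).

    Library size is the column sum of counts.  Scale-invariant: doubling all
    counts and library sizes leaves the result unchanged.
    """
    if matrix.value_kind != "counts":
        raise ValueError(f"logcpm expects counts, got value_kind={matrix.value_kind!r}")
    values = matrix.values
    lib = values.sum(axis=0)
    if (lib <= 0).any():
        bad = [matrix.sample_ids[i] for i in np.flatnonzero(lib <= 0)]
        raise ValueError(f"zero library size for samples {bad}")
    out = np.log2(values / lib * 1e6 + prior_count)
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.gene_ids, columns=matrix.sample_ids), "logcpm"
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by monotone root-finding."""
    if x <= 0:
        raise ValueError("trigamma inverse needs x > 0")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-8:
        return 1.0 / x
    f = lambda y: float(special.polygamma(1, y)) - x
    return brentq(f, 1e-9, 1e9, xtol=1e-13, rtol=1e-13, maxiter=200)


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F model to sample variances.

    Matches mean and variance of log s² to s0² · F(df, d0): with
    e_g = log s²_g − ψ(df/2) + log(df/2), the excess of var(e) over
    ψ′(df/2) is ψ′(d0/2), inverted via the trigamma function.  When the
    moment system has no positive solution, d0 = +inf (complete shrinkage).
    """
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return math.inf, float(np.mean(s2)) if len(s2) else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0 = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
        return d0, s0
    # no excess spread over the scaled-F model: complete shrinkage to the
    # plain average variance
    return math.inf, float(np.mean(s2[ok]))


def moderated_t_test(
    matrix: ExpressionMatrix,
    design: GroupDesign,
    prior_df: float | None = None,
) -> DEResult:
    """Moderated two-group t-test on a log-CPM matrix.

    Parameters
    ----------
    matrix
        log-CPM expression (``value_kind == "logcpm"``).
    design
        Two-group assignment; the log2 fold change is test minus reference.
    prior_df
        Override for the prior degrees of freedom d0.  ``None`` (default)
        estimates d0 and s0² from the data; ``0`` reduces to the ordinary
        pooled-variance t; ``math.inf`` forces complete shrinkage (every
        posterior variance equals s0²).
    """
    if matrix.value_kind != "logcpm":
        raise ValueError(
            f"moderated_t_test expects logcpm values, got {matrix.value_kind!r}"
        )
    design.validate_against(matrix)
    ref = design.samples(design.reference_group)
    test = design.samples(design.test_group)
    sub = matrix.subset_samples(ref + test)
    values = sub.values
    a = values[:, : len(ref)]
    b = values[:, len(ref) :]
    n1, n2 = a.shape[1], b.shape[1]
    df_resid = n1 + n2 - 2

    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    lfc = mean_b - mean_a
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid

    if prior_df is None:
        d0, s0 = _fit_f_dist(s2, df_resid)
    elif prior_df == 0:
        d0, s0 = 0.0, math.nan
    elif math.isinf(prior_df):
        _, s0 = _fit_f_dist(s2, df_resid)
        d0 = math.inf
    else:
        if prior_df < 0:
            raise ValueError("prior_df must be >= 0")
        d0 = float(prior_df)
        _, s0 = _fit_f_dist(s2, df_resid)

    if math.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = math.inf
    elif d0 == 0:
        s2_post = s2
        df_total = float(df_resid)
    else:
        s2_post = (d0 * s0 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), np.where(lfc == 0, 0.0, np.inf * np.sign(lfc)))
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    # zero residual variance with no shrinkage: t degenerate, flag p as NaN
    degenerate = (se == 0) & (lfc != 0)
    p = np.where(degenerate, np.nan, p)
    p = np.where((se == 0) & (lfc == 0), 1.0, p)

    q = np.full_like(p, np.nan)
    finite = np.isfinite(p)
    if finite.any():
        q[finite] = bh_adjust(p[finite])

    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "avg_expr": values.mean(axis=1),
            "t_mod": t,
            "p": p,
            "q": q,
        },
        index=pd.Index(sub.gene_ids, name="gene"),
    )
    return DEResult(table=table, prior_df=float(d0), prior_var=float(s0))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_genes(
    result: DEResult, fc_threshold: float = 2.0, fdr_threshold: float = 0.01
) -> tuple[list[str], list[str]]:
    """Differential genes at strict fold-change and FDR cut-offs.

    ``up`` requires fold change strictly above ``fc_threshold`` (a gene at
    exactly 2-fold is excluded) and ``q`` strictly below ``fdr_threshold``;
    ``down`` is symmetric with fold change below 1/``fc_threshold``.
    """
    if fc_threshold <= 0 or fdr_threshold <= 0:
        raise ValueError("thresholds must be > 0")
    lfc = result.table["log2fc"]
    q = result.table["q"]
    log_thr = math.log2(fc_threshold)
    up = result.table.index[(lfc > log_thr) & (q < fdr_threshold)].tolist()
    down = result.table.index[(lfc < -log_thr) & (q < fdr_threshold)].tolist()
    return up, down


def recurrent_upregulated(
    results: list[DEResult],
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    min_fraction: float = 0.8,
) -> list[str]:
    """Genes upregulated in at least ``min_fraction`` of the comparisons.

    A gene qualifies in a comparison when its fold change strictly exceeds
    ``fc_threshold`` and its unadjusted p-value is below ``p_threshold``;
    it is reported when it qualifies in at least
    ``ceil(min_fraction * n_comparisons)`` of them.
    """
    if not results:
        raise ValueError("need at least one DE result")
    universe = results[0].table.index
    for r in results[1:]:
        if set(r.table.index) != set(universe):
            raise ValueError("DE results have inconsistent gene universes")
    log_thr = math.log2(fc_threshold)
    counts = pd.Series(0, index=universe)
    for r in results:
        tab = r.table.reindex(universe)
        hit = (tab["log2fc"] > log_thr) & (tab["p"] < p_threshold)
        counts += hit.fillna(False).astype(int)
    need = math.ceil(min_fraction * len(results))
    return counts.index[counts >= need].tolist()
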