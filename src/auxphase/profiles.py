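"""Differential-expression response profiling.

Summarizes DESeq2-style result tables: DEG classification at an adjusted-p
(and optional fold-change) cutoff, activation:repression dominance, the
fold-change distribution, and a top-k/bottom-k amplitude decomposition that
asks whether high response amplitude comes from stronger activation in the
presence of auxin or deeper repression in its absence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

log = logging.getLogger(__name__)

#: pooled size at or below which the rank-sum test enumerates exactly
EXACT_RANKSUM_MAX_N = 12


def load_de_table(
    path,
    gene_col: str = "gene_id",
    lfc_col: str = "log2FoldChange",
    padj_col: str = "padj",
    expr_cols: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a DE results TSV into the standardized column layout.

    ``expr_cols`` maps condition name to column name, e.g.
    ``{"mock": "meanExprMock", "treated": "meanExprIAA"}``; the columns are
    renamed ``norm_expr_mock`` / ``norm_expr_treated``.
    """
    df = pd.read_csv(path, sep="\t")
    rename = {gene_col: "gene_id", lfc_col: "log2fc", padj_col: "padj"}
    if expr_cols:
        for condition, col in expr_cols.items():
            rename[col] = f"norm_expr_{condition}"
    df = df.rename(columns=rename)
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id in DE table: {dup}")
    return df


def classify_degs(
    table: pd.DataFrame, alpha: float = 0.05, lfc_threshold: float = 0.0
) -> pd.DataFrame:
    """Partition genes into {up, down, ns} by adjusted p and fold change.

    up: padj < alpha and log2fc > lfc_threshold; down: padj < alpha and
    log2fc < -lfc_threshold; everything else (including missing padj) is ns.
    Returns a copy of the table with a ``deg_class`` column.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if lfc_threshold < 0:
        raise ValueError("lfc_threshold must be >= 0")
    out = table.copy()
    padj = out["padj"]
    sig = padj.notna() & (padj < alpha)
    out["deg_class"] = "ns"
    out.loc[sig & (out["log2fc"] > lfc_threshold), "deg_class"] = "up"
    out.loc[sig & (out["log2fc"] < -lfc_threshold), "deg_class"] = "down"
    return out


@dataclass(frozen=True)
class ResponseProfile:
    """Direction and amplitude summary of a DEG set."""

    n_up: int
    n_down: int
    mean_l2fc: float
    hist_edges: tuple[float, ...]
    hist_counts: tuple[int, ...]

    @property
    def up_fraction(self) -> float:
        return self.n_up / (self.n_up + self.n_down)

    @property
    def ratio_string(self) -> str:
        return f"{self.n_up}:{self.n_down}"


def response_summary(classified: pd.DataFrame, bin_width: float = 0.25) -> ResponseProfile:
    """Counts, up fraction, mean fold change and a fixed-width histogram of DEGs."""
    degs = classified[classified["deg_class"].isin(["up", "down"])]
    if degs.empty:
        raise ValueError("empty DEG set")
    l2fc = degs["log2fc"].to_numpy(float)
    lo = math.floor(l2fc.min() / bin_width) * bin_width
    hi = math.ceil(l2fc.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(l2fc, bins=edges)
    return ResponseProfile(
        n_up=int((degs["deg_class"] == "up").sum()),
        n_down=int((degs["deg_class"] == "down").sum()),
        mean_l2fc=float(l2fc.mean()),
        hist_edges=tuple(float(e) for e in edges),
        hist_counts=tuple(int(c) for c in counts),
    )


@dataclass(frozen=True)
class AmplitudeDecomposition:
    """Top-k vs bottom-k (by |log2fc|) expression decomposition of one direction."""

    k: int
    direction: str
    top_genes: tuple[str, ...]
    bottom_genes: tuple[str, ...]
    top_mock_mean: float
    bottom_mock_mean: float
    top_treated_mean: float
    bottom_treated_mean: float
    mock_p: float
    treated_p: float
    k_clamped: bool
    per_gene: pd.DataFrame = field(repr=False, compare=False, default=None)


def amplitude_decomposition(
    classified: pd.DataFrame, k: int = 20, direction: str = "up"
) -> AmplitudeDecomposition:
    """Contrast the k strongest with the k weakest responders of one direction.

    DEGs of the chosen direction are ranked by |log2fc|; ``top_genes`` are the
    k largest, ``bottom_genes`` the k smallest.  Group means of mock and
    treated normalized expression are reported with a two-sided rank-sum test
    (top vs bottom) on each condition.  When fewer than 2k DEGs exist, k is
    clamped to the number available (groups may then overlap) and flagged.
    """
    if direction not in {"up", "down"}:
        raise ValueError("direction must be 'up' or 'down'")
    degs = classified[classified["deg_class"] == direction]
    if degs.empty:
        raise ValueError(f"no DEGs in direction {direction!r}")
    ranked = degs.reindex(
        degs["log2fc"].abs().sort_values(ascending=False, kind="mergesort").index
    )
    clamped = False
    if len(ranked) < 2 * k:
        k = len(ranked) if len(ranked) < k else k
        clamped = True
        log.warning("k clamped to %d: only %d %s-regulated DEGs", k, len(ranked), direction)
    top = ranked.head(k)
    bottom = ranked.tail(k)
    mock_p = rank_sum_test(
        top["norm_expr_mock"].tolist(), bottom["norm_expr_mock"].tolist(), "two-sided"
    )
    treated_p = rank_sum_test(
        top["norm_expr_treated"].tolist(), bottom["norm_expr_treated"].tolist(), "two-sided"
    )
    per_gene = pd.concat(
        [top.assign(group="top"), bottom.assign(group="bottom")], ignore_index=True
    )[["gene_id", "group", "log2fc", "norm_expr_mock", "norm_expr_treated"]]
    return AmplitudeDecomposition(
        k=k,
        direction=direction,
        top_genes=tuple(top["gene_id"]),
        bottom_genes=tuple(bottom["gene_id"]),
        top_mock_mean=float(top["norm_expr_mock"].mean()),
        bottom_mock_mean=float(bottom["norm_expr_mock"].mean()),
        top_treated_mean=float(top["norm_expr_treated"].mean()),
        bottom_treated_mean=float(bottom["norm_expr_treated"].mean()),
        mock_p=mock_p,
        treated_p=treated_p,
        k_clamped=clamped,
        per_gene=per_gene,
    )


def rank_sum_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    alternative: str = "two-sided",
    method: str = "auto",
) -> float:
    """Wilcoxon rank-sum p-value: exact by enumeration for small pooled n.

    With ``method='auto'``, samples with ``n_a + n_b <= EXACT_RANKSUM_MAX_N``
    get the exact null distribution of A's rank sum (tie-corrected
    mid-ranks) by enumeration; larger samples use the normal approximation
    with continuity and tie corrections.  ``method='exact'`` or
    ``'asymptotic'`` forces a branch.  ``alternative='less'`` tests A
    shifted low, ``'greater'`` A shifted high.
    """
    a = [float(x) for x in sample_a]
    b = [float(x) for x in sample_b]
    if not a or not b:
        raise ValueError("both samples must be non-empty")
    if alternative not in {"two-sided", "less", "greater"}:
        raise ValueError("alternative must be 'two-sided', 'less' or 'greater'")
    if method not in {"auto", "exact", "asymptotic"}:
        raise ValueError("method must be 'auto', 'exact' or 'asymptotic'")
    pooled = np.asarray(a + b)
    ranks = rankdata(pooled)  # mid-ranks for ties
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    w_obs = float(ranks[:n_a].sum())

    if method == "exact" or (method == "auto" and n <= EXACT_RANKSUM_MAX_N):
        sums = np.array([ranks[list(idx)].sum() for idx in combinations(range(n), n_a)])
        eps = 1e-9
        p_less = float(np.mean(sums <= w_obs + eps))
        p_greater = float(np.mean(sums >= w_obs - eps))
        if alternative == "less":
            return p_less
        if alternative == "greater":
            return p_greater
        return min(1.0, 2.0 * min(p_less, p_greater))

    mu = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts) / (n * (n - 1))).sum())
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var == 0:  # all values identical
        return 1.0
    sd = math.sqrt(var)
    # Edgeworth kurtosis correction: the tie-free fourth cumulant of the
    # rank sum is kappa4 = -n_a*n_b*(n+1)*(n_a^2+n_b^2+n_a*n_b+n)/120,
    # which tightens the plain normal tail considerably at moderate n.
    kappa4 = -n_a * n_b * (n + 1) / 120.0 * (n_a**2 + n_b**2 + n_a * n_b + n)
    gamma2 = kappa4 / var**2

    def tail_cdf(z: float) -> float:
        value = norm.cdf(z) - gamma2 / 24.0 * (z**3 - 3 * z) * norm.pdf(z)
        return min(1.0, max(0.0, float(value)))

    tiny = float(np.nextafter(0.0, 1.0))  # keep p in (0, 1]
    p_less = max(tiny, tail_cdf((w_obs - mu + 0.5) / sd))
    p_greater = max(tiny, 1.0 - tail_cdf((w_obs - mu - 0.5) / sd))
    if alternative == "less":
        return p_less
    if alternative == "greater":
        return p_greater
    return min(1.0, 2.0 * min(p_less, p_greater))


def zscore_normalize(matrix, axis: str = "gene"):
    """Per-gene (row) z-score with sample SD (ddof=1); constant rows map to 0.

    Accepts an ndarray or DataFrame (genes x samples); ``axis='sample'``
    normalizes columns instead.
    """
    df = isinstance(matrix, pd.DataFrame)
    values = np.asarray(matrix, dtype=float)
    if axis == "sample":
        values = values.T
    elif axis != "gene":
        raise ValueError("axis must be 'gene' or 'sample'")
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("each normalized row needs at least 2 values")
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    if axis == "sample":
        z = z.T
    if df:
        return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    return z
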