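"""One-sided Pearson co-expression screening of circRNA-mRNA pairs.

A circRNA acting as a ceRNA de-represses its shared-miRNA mRNA targets, so
candidate partners should rise and fall together across samples. The screen
correlates every DE circRNA with every DE mRNA over the same ordered sample
set (log2-CPM scale is recommended), tests for positive correlation with the
upper tail of t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom, adjusts
jointly with Benjamini-Hochberg, and keeps pairs with r > 0.90 and adjusted
p < 0.05 (both strict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .diff_expr import bh_adjust


@dataclass(frozen=True)
class CoexprPair:
    circ_id: str
    gene_id: str
    r: float
    p_value: float
    adj_p: float
    n_samples: int


def pearson_one_sided(x, y) -> tuple[float, float]:
    """Sample Pearson r and the one-sided (positive-association) p-value.

    Requires n >= 3 and nonzero variance in both vectors; r = +1 gives p = 0
    and r = -1 gives p = 1 (opposite tail).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt(np.sum(xd**2))
    sy = np.sqrt(np.sum(yd**2))
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(np.clip(np.sum(xd * yd) / (sx * sy), -1.0, 1.0))
    return r, _upper_tail_p(np.array([r]), n)[0]


def _upper_tail_p(r: np.ndarray, n: int) -> np.ndarray:
    p = np.empty_like(r)
    lim_hi = r >= 1.0
    lim_lo = r <= -1.0
    mid = ~(lim_hi | lim_lo)
    p[lim_hi] = 0.0
    p[lim_lo] = 1.0
    t = r[mid] * np.sqrt((n - 2) / (1.0 - r[mid] ** 2))
    p[mid] = t_dist.sf(t, df=n - 2)
    return p


def coexpressed_pairs(
    circ_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    r_min: float = 0.90,
    max_adj_p: float = 0.05,
    return_all: bool = False,
) -> list[CoexprPair]:
    """Screen all circRNA x mRNA combinations for positive co-expression.

    Both matrices are feature x sample with identical ordered sample
    columns. All combinations are tested; BH adjustment is computed jointly
    over the full grid; retained pairs satisfy r > r_min and adjusted
    p < max_adj_p (strict). With ``return_all`` the full tested grid is
    returned regardless of thresholds (used for reporting).

    Constant (zero-variance) features cannot be correlated and are excluded
    with a warning.
    """
    if list(circ_expr.columns) != list(mrna_expr.columns):
        raise ValueError("circRNA and mRNA matrices must share the same ordered samples")
    n = circ_expr.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples for correlation")

    def _drop_constant(df: pd.DataFrame, what: str) -> pd.DataFrame:
        sd = df.std(axis=1, ddof=1)
        if (sd == 0).any():
            dropped = list(df.index[sd == 0])
            warnings.warn(f"excluding {len(dropped)} constant {what} feature(s): {dropped[:3]}")
            df = df.loc[sd > 0]
        return df

    circ_expr = _drop_constant(circ_expr, "circRNA")
    mrna_expr = _drop_constant(mrna_expr, "mRNA")
    if circ_expr.empty or mrna_expr.empty:
        return []

    zc = _standardize(circ_expr.values)
    zm = _standardize(mrna_expr.values)
    R = np.clip(zc @ zm.T / (n - 1), -1.0, 1.0)
    P = _upper_tail_p(R.ravel(), n)
    adj = bh_adjust(P)

    circ_ids = list(circ_expr.index)
    gene_ids = list(mrna_expr.index)
    out = []
    k = 0
    for i, c in enumerate(circ_ids):
        for j, g in enumerate(gene_ids):
            r, p, q = float(R[i, j]), float(P[k]), float(adj[k])
            k += 1
            if return_all or (r > r_min and q < max_adj_p):
                out.append(CoexprPair(c, g, r, p, q, n))
    out.sort(key=lambda pr: (pr.circ_id, pr.gene_id))
    return out


def _standardize(a: np.ndarray) -> np.ndarray:
    mu = a.mean(axis=1, keepdims=True)
    sd = a.std(axis=1, ddof=1, keepdims=True)
    return (a - mu) / sd


def pairs_to_frame(pairs: list[CoexprPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.circ_id, p.gene_id, p.r, p.p_value, p.adj_p) for p in pairs],
        columns=["circ_id", "gene_id", "r", "p_value", "adj_p"],
    )
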