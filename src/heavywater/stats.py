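"""Two-way factorial ANOVA with Tukey-Kramer post hoc comparisons.

Self-contained implementation of the study design's statistics: a two-factor
ANOVA (genotype x treatment) by cell-means model comparison (Type-II sums of
squares by default, Type-III optional), and all-pairs Tukey-Kramer
comparisons on the cell means using a numerically integrated studentized
range distribution.  Cross-checked in the test suite against statsmodels and
scipy's studentized_range.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import integrate
from scipy.stats import chi as chi_dist
from scipy.stats import f as f_dist
from scipy.stats import norm

__all__ = [
    "AnovaResult",
    "PairwiseComparison",
    "two_way_anova",
    "tukey_kramer",
    "studentized_range_sf",
]

_Z_LIM = 12.0  # standard-normal integration window; tails < 1e-33


@dataclass(frozen=True)
class AnovaResult:
    factor_a: str
    factor_b: str
    ss: dict[str, float]            # A, B, A:B, residual, total
    df: dict[str, int]
    f_stats: dict[str, float]       # A, B, A:B (NaN when degenerate)
    p_values: dict[str, float]
    mse: float
    cell_means: dict[tuple[str, str], float]
    cell_counts: dict[tuple[str, str], int]
    degenerate: bool = False
    ss_type: int = 2

    def to_frame(self):
        import pandas as pd

        terms = [self.factor_a, self.factor_b, f"{self.factor_a}:{self.factor_b}"]
        keys = ["A", "B", "A:B"]
        rows = [
            {
                "term": term,
                "df": self.df[key],
                "sum_sq": self.ss[key],
                "F": self.f_stats[key],
                "p": self.p_values[key],
            }
            for term, key in zip(terms, keys)
        ]
        rows.append(
            {
                "term": "residual",
                "df": self.df["residual"],
                "sum_sq": self.ss["residual"],
                "F": float("nan"),
                "p": float("nan"),
            }
        )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class PairwiseComparison:
    group_i: tuple[str, str]
    group_j: tuple[str, str]
    mean_difference: float
    q: float
    p: float
    significant: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("adjusted p must be in [0, 1]")


def _dummy(labels: np.ndarray, levels: Sequence) -> np.ndarray:
    """Treatment-coded dummy columns (first level as reference)."""
    return np.column_stack([(labels == lv).astype(float) for lv in levels[1:]])


def _effect(labels: np.ndarray, levels: Sequence) -> np.ndarray:
    """Sum-to-zero (effect) coded columns, needed for Type-III tests."""
    cols = []
    ref = levels[-1]
    for lv in levels[:-1]:
        col = (labels == lv).astype(float)
        col[labels == ref] = -1.0
        cols.append(col)
    return np.column_stack(cols)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _interaction(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    if A.size == 0 or B.size == 0:
        return np.empty((len(A), 0))
    return np.column_stack([A[:, i] * B[:, j] for i in range(A.shape[1]) for j in range(B.shape[1])])


def two_way_anova(
    values,
    factor_a_labels,
    factor_b_labels,
    ss_type: int = 2,
    factor_a: str = "A",
    factor_b: str = "B",
) -> AnovaResult:
    """Two-way factorial ANOVA with interaction.

    Sums of squares by model comparison on least-squares fits: Type II
    (default; each main effect adjusted for the other, interaction last) or
    Type III (each term adjusted for all others under sum-to-zero coding —
    identical on balanced designs).  Every design cell must be occupied.
    A flat response (zero total SS) is reported as degenerate with NaN F/p
    rather than propagating division errors.
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(factor_a_labels)
    b = np.asarray(factor_b_labels)
    if not (len(y) == len(a) == len(b)):
        raise ValueError("values and factor labels must have equal length")
    levels_a = sorted(set(a.tolist()))
    levels_b = sorted(set(b.tolist()))
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("each factor needs >= 2 levels")
    cells = {}
    for la, lb in itertools.product(levels_a, levels_b):
        mask = (a == la) & (b == lb)
        n = int(mask.sum())
        if n == 0:
            raise ValueError(
                f"empty design cell ({la}, {lb}): interaction inestimable"
            )
        cells[(la, lb)] = (float(y[mask].mean()), n)
    n_total = len(y)
    n_cells = len(levels_a) * len(levels_b)
    df_resid = n_total - n_cells
    if df_resid < 2:
        raise ValueError("need >= 2 residual degrees of freedom")

    coder = _dummy if ss_type == 2 else _effect
    if ss_type not in (2, 3):
        raise ValueError("ss_type must be 2 or 3")
    A = coder(a, levels_a)
    B = coder(b, levels_b)
    AB = _interaction(A, B)
    ones = np.ones((n_total, 1))

    rss_full = _rss(np.hstack([ones, A, B, AB]), y)
    rss_ab = _rss(np.hstack([ones, A, B]), y)
    if ss_type == 2:
        rss_a_only = _rss(np.hstack([ones, A]), y)
        rss_b_only = _rss(np.hstack([ones, B]), y)
        ss_a = rss_b_only - rss_ab
        ss_b = rss_a_only - rss_ab
    else:
        ss_a = _rss(np.hstack([ones, B, AB]), y) - rss_full
        ss_b = _rss(np.hstack([ones, A, AB]), y) - rss_full
    ss_inter = rss_ab - rss_full
    ss_resid = rss_full
    ss_total = float(((y - y.mean()) ** 2).sum())

    df_a = len(levels_a) - 1
    df_b = len(levels_b) - 1
    df_ab = df_a * df_b
    mse = ss_resid / df_resid
    degenerate = ss_total <= 1e-12 * max(1.0, float(np.abs(y).max()) ** 2)

    f_stats, p_values = {}, {}
    for key, ss_term, df_term in (("A", ss_a, df_a), ("B", ss_b, df_b), ("A:B", ss_inter, df_ab)):
        if degenerate or mse == 0.0:
            f_stats[key] = float("nan")
            p_values[key] = float("nan")
        else:
            F = max(ss_term, 0.0) / df_term / mse
            f_stats[key] = F
            p_values[key] = float(f_dist.sf(F, df_term, df_resid))

    return AnovaResult(
        factor_a=factor_a,
        factor_b=factor_b,
        ss={"A": ss_a, "B": ss_b, "A:B": ss_inter, "residual": ss_resid, "total": ss_total},
        df={"A": df_a, "B": df_b, "A:B": df_ab, "residual": df_resid, "total": n_total - 1},
        f_stats=f_stats,
        p_values=p_values,
        mse=mse,
        cell_means={k: v[0] for k, v in cells.items()},
        cell_counts={k: v[1] for k, v in cells.items()},
        degenerate=degenerate,
        ss_type=ss_type,
    )


def _gauss_legendre(n: int, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n)
    mid, half = (hi + lo) / 2.0, (hi - lo) / 2.0
    return mid + half * x, half * w


def _range_cdf(r: np.ndarray, k: int, n_nodes: int = 400) -> np.ndarray:
    """CDF of the range of k iid standard normals, vectorized over r."""
    from scipy.special import ndtr

    r = np.atleast_1d(np.asarray(r, dtype=float))
    z, wz = _gauss_legendre(n_nodes, -_Z_LIM, _Z_LIM + float(r.max()))
    # rows: r values, cols: z nodes
    inner = ndtr(z)[None, :] - ndtr(z[None, :] - r[:, None])
    np.clip(inner, 0.0, None, out=inner)
    integrand = norm.pdf(z)[None, :] * inner ** (k - 1)
    return k * (integrand @ wz)


def studentized_range_sf(q: float, k: int, df: int) -> float:
    """Upper-tail probability of the studentized range Q_{k, df}.

    Double numerical integration by Gauss-Legendre quadrature: the range CDF
    of k standard normals (400 nodes) mixed over the chi-distributed scale
    sqrt(chi2_df / df) (160 nodes over the central 1 - 2e-11 of the scale
    distribution).  Absolute accuracy ~1e-9 for k <= 10, df >= 2 (checked
    against the k = 2 t-distribution identity and Monte Carlo in the test
    suite), well below the 1e-6 agreement required of the pooled-t identity.
    """
    if q < 0:
        raise ValueError("q must be >= 0")
    if not float(k).is_integer() or k < 2:
        raise ValueError("k must be an integer >= 2")
    if df < 1:
        raise ValueError("df must be >= 1")
    k = int(k)
    if q == 0.0:
        return 1.0
    scale_dist = chi_dist(df, scale=1.0 / math.sqrt(df))
    lo, hi = scale_dist.ppf(1e-11), scale_dist.isf(1e-11)
    s, ws = _gauss_legendre(160, lo, hi)
    cdf = float(np.dot(ws, scale_dist.pdf(s) * _range_cdf(q * s, k)))
    return float(min(max(1.0 - cdf, 0.0), 1.0))


def tukey_kramer(
    result: AnovaResult,
    alpha: float = 0.05,
    require_significant_f: bool = True,
) -> list[PairwiseComparison]:
    """All-pairs Tukey-Kramer comparisons of the design's cell means.

    q = |m_i - m_j| / sqrt(MSE/2 * (1/n_i + 1/n_j)), referred to the
    studentized range with k = number of cells and the residual df; the
    Kramer form reduces to Tukey's HSD when group sizes are equal.  By
    default comparisons are only made when at least one ANOVA F test is
    significant at ``alpha`` (override with ``require_significant_f=False``).
    """
    if result.degenerate:
        raise ValueError("post hoc comparisons undefined for a degenerate ANOVA")
    cells = list(result.cell_means)
    if len(cells) < 2:
        return []
    if require_significant_f:
        if not any(p <= alpha for p in result.p_values.values() if not math.isnan(p)):
            return []
    k = len(cells)
    df = result.df["residual"]
    out = []
    for gi, gj in itertools.combinations(cells, 2):
        diff = result.cell_means[gi] - result.cell_means[gj]
        ni, nj = result.cell_counts[gi], result.cell_counts[gj]
        se = math.sqrt(result.mse / 2.0 * (1.0 / ni + 1.0 / nj))
        q = abs(diff) / se if se > 0 else float("inf")
        p = studentized_range_sf(q, k, df) if math.isfinite(q) else 0.0
        out.append(
            PairwiseComparison(
                group_i=gi,
                group_j=gj,
                mean_difference=diff,
                q=q,
                p=p,
                significant=p <= alpha,
            )
        )
    return out
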