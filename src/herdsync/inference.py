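"""Rank-based inference for session x role synchrony counts.

Three procedures, matching how proximity-graded synchrony is usually tested
in repeated scan-sample designs:

* a tie-corrected Friedman test across the four comparison roles, with the
  session as the block (synchrony counts out of 15 scans are heavily tied,
  so the tie-corrected statistic is the default);
* Conover's pairwise rank comparisons for the Friedman design, with
  Bonferroni correction over the 6 role pairs;
* a one-sample Wilcoxon signed-rank test of the per-session focal-control
  synchrony proportions against the independence expectation
  ``a**2 + (1 - a)**2``.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import COMPARISON_ROLES, SyncMatrix

__all__ = [
    "FriedmanResult",
    "PosthocResult",
    "SignedRankResult",
    "friedman_test",
    "conover_posthoc",
    "one_sample_signed_rank",
]


def _as_block_matrix(matrix) -> tuple[np.ndarray, list[str]]:
    """Coerce a SyncMatrix / DataFrame / array to (n blocks x k) float array."""
    if isinstance(matrix, SyncMatrix):
        return matrix.to_numpy(), [r.value for r in COMPARISON_ROLES]
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float), [str(c) for c in matrix.columns]
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D blocks x treatments matrix")
    return arr, [f"col{j}" for j in range(arr.shape[1])]


@dataclasses.dataclass
class FriedmanResult:
    """Friedman chi-square test result.

    ``statistic`` is on the chi-square scale with ``df = k - 1``;
    ``tie_corrected`` records whether the tie-corrected form was used.
    A matrix whose within-block ranks carry no information (every block
    completely tied) is degenerate: statistic 0, p 1.
    """

    statistic: float
    df: int
    p_value: float
    tie_corrected: bool
    n_blocks: int
    k_treatments: int
    degenerate: bool = False

    def __post_init__(self):
        assert self.statistic >= 0 and 0.0 <= self.p_value <= 1.0


def _friedman_parts(x: np.ndarray):
    """Within-block mid-ranks and the sums entering the tie-corrected form."""
    n, k = x.shape
    ranks = stats.rankdata(x, axis=1)
    col_sums = ranks.sum(axis=0)  # R_j
    a1 = float((ranks ** 2).sum())  # sum of squared ranks
    c1 = n * k * (k + 1) ** 2 / 4.0  # its value under complete ties
    return ranks, col_sums, a1, c1


def friedman_test(matrix, tie_correction: bool = True) -> FriedmanResult:
    """Friedman test across k treatments in n blocks, mid-ranks for ties.

    With ``tie_correction`` (the default) the statistic is

        T1 = (k - 1) * sum_j (R_j - n(k+1)/2)^2 / (A1 - C1),

    where ``R_j`` are column rank sums, ``A1`` the sum of squared
    within-block ranks and ``C1 = n k (k+1)^2 / 4``; without ties this
    reduces to the classical ``12/(n k (k+1)) * sum R_j^2 - 3 n (k+1)``,
    which is also what ``tie_correction=False`` computes.  The p-value is
    the upper tail of chi-square with ``k - 1`` degrees of freedom.
    """
    x, _ = _as_block_matrix(matrix)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need at least 2 blocks and 2 treatments, got {n}x{k}")
    if np.isnan(x).any():
        raise ValueError("missing cells are not allowed")
    _, col_sums, a1, c1 = _friedman_parts(x)
    df = k - 1
    if tie_correction:
        denom = a1 - c1
        if denom <= 0:
            # every block completely tied: ranks carry no information
            return FriedmanResult(0.0, df, 1.0, True, n, k, degenerate=True)
        stat = df * float(((col_sums - n * (k + 1) / 2.0) ** 2).sum()) / denom
    else:
        stat = 12.0 / (n * k * (k + 1)) * float((col_sums ** 2).sum()) - 3.0 * n * (k + 1)
        stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df))
    return FriedmanResult(float(stat), df, p, tie_correction, n, k)


@dataclasses.dataclass
class PosthocResult:
    """All-pairs Conover comparisons after a Friedman test.

    ``table`` has one row per unordered treatment pair with the t statistic,
    raw p and Bonferroni-adjusted p (``m = k(k-1)/2`` pairs).
    """

    table: pd.DataFrame
    method: str
    adjustment: str
    df: int
    n_blocks: int
    k_treatments: int

    def p_matrix(self, adjusted: bool = True) -> pd.DataFrame:
        """Symmetric treatment x treatment matrix of (adjusted) p-values."""
        names = sorted(set(self.table["treatment_a"]) | set(self.table["treatment_b"]))
        m = pd.DataFrame(np.nan, index=names, columns=names)
        col = "adjusted_p" if adjusted else "raw_p"
        for _, row in self.table.iterrows():
            m.loc[row["treatment_a"], row["treatment_b"]] = row[col]
            m.loc[row["treatment_b"], row["treatment_a"]] = row[col]
        return m


def conover_posthoc(matrix, alpha: float = 0.05,
                    p_adjust: str = "bonferroni") -> PosthocResult:
    """Conover's pairwise rank comparisons for the Friedman design.

    For treatments i, j the statistic is

        t = |R_i - R_j| / sqrt( 2 n (A1 - C1) (1 - T1 / (n (k-1)))
                                / ((n-1)(k-1)) ),

    referred to Student's t with ``(n-1)(k-1)`` degrees of freedom, where
    ``T1`` is the tie-corrected Friedman statistic.  Two-sided raw p-values
    are Bonferroni-adjusted over all ``k(k-1)/2`` pairs.  A completely tied
    matrix is degenerate: every adjusted p is 1.
    """
    if p_adjust not in ("bonferroni", "none"):
        raise ValueError(f"unsupported adjustment {p_adjust!r}")
    x, names = _as_block_matrix(matrix)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need at least 2 blocks and 2 treatments, got {n}x{k}")
    _, col_sums, a1, c1 = _friedman_parts(x)
    df = (n - 1) * (k - 1)
    m_pairs = k * (k - 1) // 2
    rows = []
    denom_info = a1 - c1
    if denom_info <= 0:
        for i, j in itertools.combinations(range(k), 2):
            rows.append((names[i], names[j], 0.0, 1.0, 1.0))
    else:
        t1 = (k - 1) * float(((col_sums - n * (k + 1) / 2.0) ** 2).sum()) / denom_info
        scale_sq = 2.0 * n * denom_info * (1.0 - t1 / (n * (k - 1))) / df
        scale = math.sqrt(max(scale_sq, 0.0))
        for i, j in itertools.combinations(range(k), 2):
            diff = abs(col_sums[i] - col_sums[j])
            if scale == 0.0:
                # all rank-sum variation explained: any difference is infinite
                t = math.inf if diff > 0 else 0.0
            else:
                t = diff / scale
            raw_p = float(2.0 * stats.t.sf(t, df)) if math.isfinite(t) else 0.0
            raw_p = min(raw_p, 1.0)
            adj = raw_p if p_adjust == "none" else min(1.0, m_pairs * raw_p)
            rows.append((names[i], names[j], float(t), raw_p, adj))
    table = pd.DataFrame(
        rows, columns=["treatment_a", "treatment_b", "statistic", "raw_p", "adjusted_p"]
    )
    table["significant"] = table["adjusted_p"] < alpha
    return PosthocResult(
        table=table,
        method="conover",
        adjustment=p_adjust,
        df=df,
        n_blocks=n,
        k_treatments=k,
    )


@dataclasses.dataclass
class SignedRankResult:
    """One-sample Wilcoxon signed-rank test result.

    ``statistic`` is W+, the sum of mid-ranks of positive differences from
    the hypothesised median.  ``chi_square_1`` is a companion statistic —
    the squared standardised (tie-corrected, continuity-corrected) normal
    approximation, on 1 df — offered because some reports quote this test
    on a chi-square scale.
    """

    statistic: float
    p_value: float
    hypothesised_median: float
    n_nonzero: int
    method: str
    chi_square_1: float
    chi_square_1_p: float
    zero_method: str = "wilcox"
    alternative: str = "two-sided"
    degenerate: bool = False


def one_sample_signed_rank(
    values: Sequence[float],
    mu0: float,
    alternative: str = "two-sided",
    zero_method: str = "wilcox",
    exact_threshold: int = 25,
) -> SignedRankResult:
    """Wilcoxon signed-rank test of a sample median against ``mu0``.

    Differences equal to zero are dropped by default (``zero_method=
    "wilcox"``; ``"pratt"`` ranks them then discards, keeping their effect
    on the ranks of the rest).  The exact null distribution is used when the
    number of non-zero differences is at most ``exact_threshold`` and the
    absolute differences are untied; otherwise the normal approximation with
    tie and continuity corrections.  If every value equals ``mu0`` the test
    is degenerate: p = 1.
    """
    d = np.asarray(values, dtype=float) - float(mu0)
    if d.size == 0:
        raise ValueError("empty sample")
    nonzero = d[d != 0]
    n = int(nonzero.size)
    if n == 0:
        return SignedRankResult(
            statistic=0.0, p_value=1.0, hypothesised_median=float(mu0),
            n_nonzero=0, method="degenerate", chi_square_1=0.0,
            chi_square_1_p=1.0, zero_method=zero_method,
            alternative=alternative, degenerate=True,
        )

    if zero_method == "wilcox":
        ranks = stats.rankdata(np.abs(nonzero))
        w_plus = float(ranks[nonzero > 0].sum())
        rank_base = nonzero
    elif zero_method == "pratt":
        ranks_all = stats.rankdata(np.abs(d))
        w_plus = float(ranks_all[d > 0].sum())
        rank_base = d
    else:
        raise ValueError(f"unknown zero_method {zero_method!r}")

    has_ties = np.unique(np.abs(nonzero)).size < n
    use_exact = n <= exact_threshold and not has_ties and zero_method == "wilcox"
    method = "exact" if use_exact else "approx"
    res = stats.wilcoxon(
        d, zero_method=zero_method, correction=True,
        alternative=alternative, method=method,
    )
    p = float(res.pvalue)

    # chi-square companion: squared standardised W+ (normal approximation
    # with tie correction and 0.5 continuity correction), 1 df
    mean_w = n * (n + 1) / 4.0
    if zero_method == "pratt":
        nz = int(d.size) - n
        mean_w = (d.size * (d.size + 1) / 4.0) - nz * (nz + 1) / 4.0
    _, tie_counts = np.unique(stats.rankdata(np.abs(rank_base)), return_counts=True)
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - float(
        ((tie_counts ** 3 - tie_counts)).sum()
    ) / 48.0
    if var_w <= 0:
        chi2_stat, chi2_p = 0.0, 1.0
    else:
        z = (abs(w_plus - mean_w) - 0.5) / math.sqrt(var_w)
        z = max(z, 0.0)
        chi2_stat = z * z
        chi2_p = float(stats.chi2.sf(chi2_stat, 1))

    return SignedRankResult(
        statistic=w_plus,
        p_value=p,
        hypothesised_median=float(mu0),
        n_nonzero=n,
        method=method,
        chi_square_1=float(chi2_stat),
        chi_square_1_p=chi2_p,
        zero_method=zero_method,
        alternative=alternative,
    )
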