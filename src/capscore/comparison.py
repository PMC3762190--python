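"""Paired comparison of two severity criteria's per-patient classifications.

Two criteria applied to the same cohort yield paired binary classifications.
Within a subgroup (patients with the event, for comparing sensitivities;
patients without, for specificities) the per-patient differences are compared
with the Wilcoxon signed-rank test.  Because the paired values are binary the
absolute differences are maximally tied, so the exact null distribution is
computed by enumerating sign assignments over midranks rather than delegating
to a tie-free table.  An exact McNemar test is offered as the conventional
companion analysis for paired binary classifiers.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import binomtest, norm, rankdata

__all__ = [
    "ZeroPolicy",
    "WilcoxonResult",
    "McNemarResult",
    "wilcoxon_signed_rank",
    "mcnemar_exact",
]

# exact enumeration up to this many non-zero differences; normal approx above
_EXACT_LIMIT = 25


class ZeroPolicy(str, enum.Enum):
    drop = "drop"  # classical: discard zero differences before ranking
    pratt = "pratt"  # rank zeros too, then drop their ranks from the statistic


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    pvalue: float
    n_used: int  # non-zero differences contributing to the statistic
    exact: bool
    warning: Optional[str] = None


@dataclass(frozen=True)
class McNemarResult:
    discordant: tuple[int, int]  # (A-only positives, B-only positives)
    pvalue: float
    warning: Optional[str] = None


def _exact_pvalue(doubled_ranks: np.ndarray, w_plus_doubled: int) -> float:
    """Two-sided exact p by DP over the 2^n equiprobable sign assignments.

    Works on ranks doubled to integers so midranks (multiples of 0.5) stay
    exact.  Builds the null distribution of 2·W+ as the coefficient array of
    the generating polynomial ∏(1 + x^{2r_i}).
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts += shifted
    n_assign = counts.sum()  # == 2^n
    lower = counts[: w_plus_doubled + 1].sum() / n_assign
    upper = counts[w_plus_doubled:].sum() / n_assign
    return min(1.0, 2.0 * min(lower, upper))


def _approx_pvalue(ranks: np.ndarray, w_plus: float, n_zero: int) -> float:
    """Normal approximation with tie and continuity corrections.

    ``n_zero`` > 0 applies the Pratt adjustment for zero differences that
    occupied the lowest ranks but are excluded from the statistic.
    """
    n = len(ranks) + n_zero
    mean = (n * (n + 1) - n_zero * (n_zero + 1)) / 4.0
    var = (n * (n + 1) * (2 * n + 1) - n_zero * (n_zero + 1) * (2 * n_zero + 1)) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return 1.0
    d = w_plus - mean
    z = (d - 0.5 * np.sign(d)) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def wilcoxon_signed_rank(
    a: Sequence[float],
    b: Sequence[float],
    zero_policy: ZeroPolicy = ZeroPolicy.drop,
) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired observations.

    Exact two-sided p-value by sign-assignment enumeration when at most 25
    non-zero differences remain; tie-corrected normal approximation with
    continuity correction above that.  All-zero differences yield p = 1 with
    a warning flag rather than an error.
    """
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    if a_arr.shape != b_arr.shape or a_arr.ndim != 1 or len(a_arr) == 0:
        raise ValueError("a and b must be equal-length non-empty 1-d sequences")
    diffs = a_arr - b_arr
    nonzero = diffs != 0
    n_zero = int((~nonzero).sum())

    if not nonzero.any():
        return WilcoxonResult(0.0, 1.0, 0, True, warning="all differences zero")

    if zero_policy is ZeroPolicy.drop:
        d = diffs[nonzero]
        ranks = rankdata(np.abs(d))
        n_zero_ranked = 0
    else:  # Pratt: zeros participate in ranking, not in the statistic
        ranks_all = rankdata(np.abs(diffs))
        d = diffs[nonzero]
        ranks = ranks_all[nonzero]
        n_zero_ranked = n_zero

    w_plus = float(ranks[d > 0].sum())
    n_used = len(d)

    if n_used <= _EXACT_LIMIT:
        # valid under both policies: only the non-zero ranks carry random signs
        doubled = np.round(2 * ranks).astype(int)
        p = _exact_pvalue(doubled, int(round(2 * w_plus)))
        return WilcoxonResult(w_plus, p, n_used, True)
    p = _approx_pvalue(ranks, w_plus, n_zero_ranked)
    return WilcoxonResult(w_plus, p, n_used, False)


def mcnemar_exact(a: Sequence[int], b: Sequence[int]) -> McNemarResult:
    """Exact McNemar test on paired binary classifications.

    The test conditions on the discordant pairs: under the null their split
    is Binomial(n_discordant, 1/2).  Zero discordance yields p = 1 with a
    warning flag.
    """
    a_arr = np.asarray(a, dtype=int)
    b_arr = np.asarray(b, dtype=int)
    if a_arr.shape != b_arr.shape or a_arr.ndim != 1 or len(a_arr) == 0:
        raise ValueError("a and b must be equal-length non-empty 1-d sequences")
    if not (np.isin(a_arr, (0, 1)).all() and np.isin(b_arr, (0, 1)).all()):
        raise ValueError("entries must be binary (0/1)")
    n10 = int(((a_arr == 1) & (b_arr == 0)).sum())
    n01 = int(((a_arr == 0) & (b_arr == 1)).sum())
    if n10 + n01 == 0:
        return McNemarResult((0, 0), 1.0, warning="no discordant pairs")
    p = binomtest(n10, n10 + n01, 0.5, alternative="two-sided").pvalue
    return McNemarResult((n10, n01), float(min(1.0, p)))
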