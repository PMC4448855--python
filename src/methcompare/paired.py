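"""Paired Region Averaging: the non-parametric Yule-Simpson correction.

Each boundary instance contributes one (left mean, right mean) pair,
computed over the observed cells within a fixed window from the boundary.
Instances lacking data on either side — for which no regional average can
be assigned — are discarded; this exclusion is what removes the
missing-data bias, at the cost of data loss and of any absolute
quantitation: the retained pairs support only a *relative* comparison of
the two sides (the regions that were dropped are preferentially the
sparse, i.e. more methylated, ones).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .matrix import JunctionMatrixPair

__all__ = ["PairedAveragingResult", "paired_region_averages",
           "compare_paired"]

QUANTITATIVE_CAVEAT = (
    "Paired region averaging supports relative cross-boundary comparison "
    "only; because discarded instances are preferentially the sparse "
    "(more methylated) ones, the retained means are not quantitative "
    "estimates of absolute methylation tendency.")


@dataclass
class PairedAveragingResult:
    """Per-junction mean pairs after the exclusion rule, plus the rank
    test outcome once :func:`compare_paired` has been applied."""

    pairs: pd.DataFrame            # columns: region, left_mean, right_mean
    n_retained: int
    n_discarded: int
    mean_difference: float         # mean(right) - mean(left)
    window: int
    statistic: float = None
    p_value: float = None
    method: str = None
    degenerate: bool = False
    note: str = QUANTITATIVE_CAVEAT

    def summary(self) -> str:
        lines = [
            "Paired region averaging",
            f"  window (bp from boundary) : {self.window}",
            f"  retained / discarded      : {self.n_retained} / "
            f"{self.n_discarded}",
            f"  mean difference (R - L)   : {self.mean_difference:+.6f}",
        ]
        if self.method is not None:
            lines.append(f"  test                      : {self.method}")
            lines.append(f"  statistic                 : {self.statistic:.6g}")
            lines.append(f"  two-sided p               : {self.p_value:.6g}")
            if self.degenerate:
                lines.append("  (degenerate: all paired differences zero)")
        lines.append(f"  note: {self.note}")
        return "\n".join(lines) + "\n"


def paired_region_averages(pair: JunctionMatrixPair,
                           window: int = None) -> PairedAveragingResult:
    """Per-region left/right means with the exclusion rule applied.

    ``window`` restricts each side to its first ``window`` columns (base
    pairs from the boundary at site resolution); ``None`` uses each
    side's full span.  Rows without at least one observed cell on *each*
    side within the window are discarded.  Raises
    :class:`~methcompare.errors.ValidationError` when no rows survive.
    """
    if window is None:
        w_left, w_right = pair.left.m, pair.right.m
        window_out = max(w_left, w_right)
    else:
        if window < 1:
            raise ValidationError("window must be >= 1")
        if window > pair.left.m or window > pair.right.m:
            raise ValidationError(
                f"window {window} exceeds matrix span "
                f"({pair.left.m} / {pair.right.m} columns)")
        w_left = w_right = window_out = int(window)

    lm, lv = pair.left.mask[:, :w_left], pair.left.values[:, :w_left]
    rm, rv = pair.right.mask[:, :w_right], pair.right.values[:, :w_right]
    lcnt = lm.sum(axis=1)
    rcnt = rm.sum(axis=1)
    keep = (lcnt > 0) & (rcnt > 0)
    n_keep = int(keep.sum())
    if n_keep == 0:
        raise ValidationError(
            "no comparable regions: every boundary lacks data on at "
            "least one side")
    lmeans = np.where(lm, lv, 0.0).sum(axis=1)[keep] / lcnt[keep]
    rmeans = np.where(rm, rv, 0.0).sum(axis=1)[keep] / rcnt[keep]
    labels = [lab for lab, k in zip(pair.row_labels, keep) if k]
    pairs = pd.DataFrame({"region": labels, "left_mean": lmeans,
                          "right_mean": rmeans})
    return PairedAveragingResult(
        pairs=pairs, n_retained=n_keep,
        n_discarded=pair.n - n_keep,
        mean_difference=float(rmeans.mean() - lmeans.mean()),
        window=window_out)


def _exact_rank_sum_p(left, right):
    """Exact two-sided permutation p of the rank-sum statistic.

    Uses midranks, so ties are handled correctly; the null enumerates
    every split of the pooled sample, and the two-sided p doubles the
    smaller tail (capped at 1).  Cost grows as C(n1+n2, n1) — callers
    gate on the pooled size.
    """
    import itertools
    import math

    pooled = np.concatenate([left, right])
    ranks = stats.rankdata(pooled)  # midranks
    n1 = len(left)
    observed = ranks[:n1].sum()
    count_le = count_ge = 0
    total = math.comb(len(pooled), n1)
    for comb in itertools.combinations(range(len(pooled)), n1):
        t = ranks[list(comb)].sum()
        if t <= observed + 1e-9:
            count_le += 1
        if t >= observed - 1e-9:
            count_ge += 1
    return min(1.0, 2.0 * min(count_le, count_ge) / total)


def compare_paired(result: PairedAveragingResult,
                   method: str = "rank_sum") -> PairedAveragingResult:
    """Rank-based two-sided comparison of the retained left vs right means.

    ``rank_sum`` is the two-sample Mann-Whitney-Wilcoxon test: exact for
    small samples (scipy's exact null without ties, an in-house
    permutation enumeration when ties are present and the pooled sample
    is small enough to enumerate), and the tie-corrected normal
    approximation otherwise.  ``signed_rank`` is the paired Wilcoxon
    test, offered because the pairs are intrinsically coupled.  When all
    paired differences are zero under ``signed_rank`` the result is
    returned with ``p_value = 1`` and ``degenerate = True``.
    """
    if result.n_retained < 2:
        raise ValidationError("need at least 2 retained pairs to test")
    left = result.pairs["left_mean"].to_numpy()
    right = result.pairs["right_mean"].to_numpy()
    degenerate = False
    if method == "rank_sum":
        pooled = np.concatenate([left, right])
        has_ties = np.unique(pooled).size < pooled.size
        res = stats.mannwhitneyu(left, right, alternative="two-sided",
                                 method="asymptotic")
        statistic = float(res.statistic)
        if len(left) <= 50 and not has_ties:
            res = stats.mannwhitneyu(left, right,
                                     alternative="two-sided",
                                     method="exact")
            p = float(res.pvalue)
        elif has_ties and len(pooled) <= 16:
            p = _exact_rank_sum_p(left, right)
        else:
            p = float(res.pvalue)
    elif method == "signed_rank":
        diffs = right - left
        if np.all(diffs == 0):
            statistic, p, degenerate = 0.0, 1.0, True
        else:
            res = stats.wilcoxon(right, left, zero_method="wilcox",
                                 alternative="two-sided")
            statistic, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValidationError(
            f"method must be 'rank_sum' or 'signed_rank', got {method!r}")
    return dataclasses.replace(result, statistic=statistic,
                               p_value=min(p, 1.0), method=method,
                               degenerate=degenerate)
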