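"""Per-rater Wilcoxon signed-rank tests of automated minus manual scores.

With a 4-point scale the paired differences live in {-3, ..., 3} and are
dominated by zeros and ties, so the implementation is explicit about both:
zeros can be dropped (classic Wilcoxon) or kept in the ranking (Pratt), ranks
are tie-averaged, and the exact null distribution of the positive-rank sum is
computed by enumerating sign flips (as a convolution over the rank multiset)
whenever the number of nonzero differences is small enough.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ratings import RatingDataset, pair_by_method

EXACT_LIMIT = 25  # max nonzero differences for the exact null distribution


@dataclass
class PairedScores:
    """Automated-minus-manual score differences for one rater."""

    rater_id: str
    differences: np.ndarray

    def __post_init__(self) -> None:
        self.differences = np.asarray(self.differences, dtype=float)


@dataclass
class WilcoxonResult:
    statistic: float  # W+, the positive-rank sum
    pvalue: float
    n_nonzero: int
    n_total: int
    mode: str  # "exact" or "normal"
    zero_method: str


def _signed_ranks(diffs: np.ndarray, zero_method: str) -> tuple[np.ndarray, np.ndarray]:
    """Tie-averaged ranks of |d| and the matching signs, zeros handled."""
    d = np.asarray(diffs, dtype=float)
    if zero_method == "wilcox":
        d = d[d != 0]
        ranks = stats.rankdata(np.abs(d)) if d.size else np.array([])
        return ranks, np.sign(d)
    if zero_method == "pratt":
        ranks = stats.rankdata(np.abs(d))
        keep = d != 0
        return ranks[keep], np.sign(d[keep])
    raise ValueError(f"unknown zero_method {zero_method!r}")


def _exact_distribution(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Support and probabilities of W+ under random sign flips.

    Tie-averaged ranks are half-integers; doubling makes them integers so the
    distribution is a convolution over a small integer lattice (equivalent to
    full enumeration of the 2^n sign assignments).
    """
    doubled = np.rint(2 * ranks).astype(np.int64)
    total = int(doubled.sum())
    probs = np.zeros(total + 1)
    probs[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(probs)
        shifted[r:] = probs[: total + 1 - r]
        probs = 0.5 * (probs + shifted)
    support = np.arange(total + 1) / 2.0
    return support, probs


def wilcoxon_signed_rank(
    ps: PairedScores | Sequence[float],
    zero_method: str = "wilcox",
    mode: str = "auto",
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test.

    Parameters
    ----------
    ps
        A :class:`PairedScores` or a plain sequence of differences.
    zero_method
        ``wilcox`` drops zero differences before ranking; ``pratt`` ranks
        them (inflating the other ranks) but excludes them from the statistic.
    mode
        ``exact`` enumerates the sign-flip null distribution (only allowed up
        to 25 nonzero differences); ``normal`` uses the tie-corrected normal
        approximation with continuity correction; ``auto`` picks ``exact``
        when feasible.

    The two-sided p-value in exact mode is the null probability of a
    positive-rank sum at least as far from its mean as the observed one,
    which is symmetric under sign negation even with tied ranks.
    """
    diffs = ps.differences if isinstance(ps, PairedScores) else np.asarray(ps, float)
    if diffs.size == 0:
        raise ValueError("empty differences")
    ranks, signs = _signed_ranks(diffs, zero_method)
    n_nonzero = len(ranks)
    statistic = float(ranks[signs > 0].sum())

    if n_nonzero == 0:
        return WilcoxonResult(statistic, 1.0, 0, len(diffs), "degenerate", zero_method)

    if mode == "auto":
        mode = "exact" if n_nonzero <= EXACT_LIMIT else "normal"
    if mode == "exact":
        if n_nonzero > EXACT_LIMIT:
            raise ValueError(f"exact mode limited to {EXACT_LIMIT} nonzero differences")
        support, probs = _exact_distribution(ranks)
        mean = ranks.sum() / 2.0
        dev = abs(statistic - mean)
        p = float(probs[np.abs(support - mean) >= dev - 1e-9].sum())
        p = min(p, 1.0)
    elif mode == "normal":
        mean = ranks.sum() / 2.0
        sd = float(np.sqrt((ranks**2).sum()) / 2.0)
        if sd == 0:
            p = 1.0
        else:
            # continuity correction towards the mean
            dev = max(abs(statistic - mean) - 0.5, 0.0)
            p = float(2.0 * stats.norm.sf(dev / sd))
            p = min(p, 1.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return WilcoxonResult(statistic, p, n_nonzero, len(diffs), mode, zero_method)


def paired_scores_by_rater(ds: RatingDataset) -> list[PairedScores]:
    """Extract per-rater automated-minus-manual differences from a dataset."""
    view = pair_by_method(ds)
    out = []
    for rater in ds.raters:
        d = view.for_rater(rater)["diff"].to_numpy(dtype=float)
        out.append(PairedScores(rater_id=rater, differences=d))
    return out


def per_rater_table(ds: RatingDataset, zero_method: str = "wilcox") -> pd.DataFrame:
    """Per-rater mean scores and Wilcoxon p-values, one row per rater.

    Mirrors the usual reporting layout: rater, mean manual score, mean
    automated score over paired items, two-sided p and number of pairs.
    """
    view = pair_by_method(ds)
    rows = []
    for rater in ds.raters:
        sub = view.for_rater(rater)
        if len(sub) == 0:
            rows.append((rater, np.nan, np.nan, np.nan, 0))
            continue
        res = wilcoxon_signed_rank(
            PairedScores(rater, sub["diff"].to_numpy(float)), zero_method=zero_method
        )
        rows.append(
            (
                rater,
                sub["score_manual"].mean(),
                sub["score_automated"].mean(),
                res.pvalue,
                len(sub),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["rater_id", "mean_manual", "mean_automated", "pvalue", "n_pairs"],
    )
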