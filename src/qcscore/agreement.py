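"""Gwet's chance-corrected agreement coefficients for multiple raters.

Implements the second-order agreement coefficient (AC2): weighted percent
agreement corrected by a chance-agreement term built from marginal category
propensities.  Unlike kappa-type statistics, the chance term does not
collapse when one category dominates — which is exactly the situation for
quality scores that cluster at the top of the scale.

For ``n`` subjects scored into ``q`` ordered categories by up to ``r`` raters
(missing ratings allowed), with agreement weights ``w_kl`` and
``r_ik`` = number of raters placing subject ``i`` in category ``k``:

    p_a  = (1/n') sum_{i: r_i>=2} sum_k r_ik (rbar*_ik - 1) / (r_i (r_i - 1))
    rbar*_ik = sum_l w_kl r_il
    pi_k = (1/n) sum_i r_ik / r_i
    p_e  = (T_w / (q (q-1))) sum_k pi_k (1 - pi_k),   T_w = sum_kl w_kl
    AC2  = (p_a - p_e) / (1 - p_e)

``n'`` counts subjects rated by at least two raters; singly-rated subjects
still inform the marginals ``pi_k``.  The variance uses Gwet's subject-level
linearization, and the confidence interval a Student-t quantile on ``n - 1``
degrees of freedom, truncated to [-1, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ratings import ITEM_COLUMNS, RatingDataset

WEIGHT_FAMILIES = ("identity", "ordinal", "linear", "quadratic")


class DegenerateAgreementError(Exception):
    """Chance agreement equals 1; the coefficient is undefined."""


# ----------------------------------------------------------------- weights
@dataclass(frozen=True)
class WeightMatrix:
    """q x q agreement weights: 1 on the diagonal, 0 for extreme disagreement."""

    q: int
    w: np.ndarray
    family: str

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.shape != (self.q, self.q):
            raise ValueError("weight matrix shape mismatch")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if not np.allclose(np.diag(w), 1.0):
            raise ValueError("diagonal weights must be 1")
        if (w < -1e-12).any() or (w > 1 + 1e-12).any():
            raise ValueError("weights must lie in [0, 1]")
        object.__setattr__(self, "w", w)

    @property
    def total(self) -> float:
        """T_w, the sum of all weights."""
        return float(self.w.sum())


def ordinal_weights(q: int) -> WeightMatrix:
    """Combinatorial ordinal weights.

    The penalty for confusing categories ``k`` and ``l`` is the number of
    category pairs the error spans, ``M_kl = C(|k-l|+1, 2)``, rescaled so the
    worst confusion (the two scale extremes) gets weight 0 and exact
    agreement weight 1.  For q=4 the off-diagonal weights are 5/6, 1/2, 0.
    """
    if q < 2:
        raise ValueError("q must be >= 2")
    k = np.arange(q)
    d = np.abs(k[:, None] - k[None, :])
    m = (d + 1) * d // 2  # C(d+1, 2)
    w = 1.0 - m / m.max()
    return WeightMatrix(q=q, w=w, family="ordinal")


def identity_weights(q: int) -> WeightMatrix:
    if q < 2:
        raise ValueError("q must be >= 2")
    return WeightMatrix(q=q, w=np.eye(q), family="identity")


def linear_weights(q: int) -> WeightMatrix:
    if q < 2:
        raise ValueError("q must be >= 2")
    k = np.arange(q)
    d = np.abs(k[:, None] - k[None, :])
    return WeightMatrix(q=q, w=1.0 - d / (q - 1), family="linear")


def quadratic_weights(q: int) -> WeightMatrix:
    if q < 2:
        raise ValueError("q must be >= 2")
    k = np.arange(q)
    d = np.abs(k[:, None] - k[None, :])
    return WeightMatrix(q=q, w=1.0 - (d / (q - 1)) ** 2, family="quadratic")


def weights(q: int, family: str = "ordinal") -> WeightMatrix:
    """Build a weight matrix by family name."""
    try:
        return {
            "identity": identity_weights,
            "ordinal": ordinal_weights,
            "linear": linear_weights,
            "quadratic": quadratic_weights,
        }[family](q)
    except KeyError:
        raise ValueError(f"unknown weight family {family!r}") from None


# ------------------------------------------------------------------ counts
@dataclass
class SubjectCountMatrix:
    """Per-subject category counts r_ik with row sums r_i (raters per subject)."""

    r: np.ndarray  # (n, q) integer counts
    categories: tuple[int, ...]
    subject_ids: np.ndarray  # (n,) opaque labels, aligned with rows
    n_raters: int  # distinct raters contributing

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r)
        if (self.r < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.row_sums < 1).any():
            raise ValueError("every subject needs at least one rating")

    @property
    def n(self) -> int:
        return self.r.shape[0]

    @property
    def q(self) -> int:
        return self.r.shape[1]

    @property
    def row_sums(self) -> np.ndarray:
        return self.r.sum(axis=1)

    @property
    def n_multi(self) -> int:
        """n', the number of subjects rated by >= 2 raters."""
        return int((self.row_sums >= 2).sum())


def build_counts(
    ds: RatingDataset, subject_key: Sequence[str] = tuple(ITEM_COLUMNS)
) -> SubjectCountMatrix:
    """Tabulate rater counts per category for each distinct subject.

    The default subject is one presented item — (image, slice, contour type,
    phase, method) — so agreement is measured across raters scoring the very
    same contour overlay.
    """
    if len(ds) == 0:
        raise ValueError("empty dataset")
    key = list(subject_key)
    cats = list(ds.categories)
    tab = (
        ds.df.groupby(key + ["score"], observed=True)
        .size()
        .unstack("score", fill_value=0)
        .reindex(columns=cats, fill_value=0)
    )
    subject_ids = np.array([str(ix) for ix in tab.index.tolist()], dtype=object)
    return SubjectCountMatrix(
        r=tab.to_numpy(dtype=np.int64),
        categories=tuple(cats),
        subject_ids=subject_ids,
        n_raters=len(ds.raters),
    )


# --------------------------------------------------------------------- AC2
@dataclass
class AgreementEstimate:
    """AC2 point estimate with its uncertainty and benchmark inputs."""

    coefficient: float
    pa: float
    pe: float
    se: float
    ci: tuple[float, float]
    ci_level: float
    n_subjects: int
    n_raters: int
    weight_family: str = "ordinal"
    # subject-level linearization (kappa*_i), used for paired comparisons
    subject_ids: np.ndarray | None = field(default=None, repr=False)
    influence: np.ndarray | None = field(default=None, repr=False)

    @classmethod
    def from_point_ci(
        cls, coefficient: float, ci: tuple[float, float], ci_level: float = 0.95
    ) -> "AgreementEstimate":
        """Reconstruct an estimate from a published point value and CI.

        The standard error is recovered assuming the interval is symmetric
        and normal-based: se = half-width / z_{(1+level)/2}.
        """
        z = stats.norm.ppf(0.5 + ci_level / 2)
        se = (ci[1] - ci[0]) / (2 * z)
        return cls(
            coefficient=float(coefficient),
            pa=math.nan,
            pe=math.nan,
            se=float(se),
            ci=(float(ci[0]), float(ci[1])),
            ci_level=ci_level,
            n_subjects=0,
            n_raters=0,
        )


def ac2(
    counts: SubjectCountMatrix,
    weight_matrix: WeightMatrix | None = None,
    ci_level: float = 0.95,
    fpc: float = 0.0,
) -> AgreementEstimate:
    """Gwet's AC2 with weights, linearized variance and t-based CI.

    Parameters
    ----------
    counts
        Subject-by-category rater counts.
    weight_matrix
        Agreement weights; defaults to ordinal weights for ``counts.q``.
    fpc
        Finite-population sampling fraction ``f``; 0 treats the subjects as a
        sample from an infinite population.
    """
    if weight_matrix is None:
        weight_matrix = ordinal_weights(counts.q)
    if weight_matrix.q != counts.q:
        raise ValueError("weight matrix and counts disagree on q")

    r = counts.r.astype(float)
    n, q = r.shape
    ri = r.sum(axis=1)
    multi = ri >= 2
    n_multi = int(multi.sum())
    if n_multi < 1:
        raise ValueError("need at least one subject with >= 2 raters")

    w = weight_matrix.w
    tw = weight_matrix.total

    # weighted percent agreement among multiply-rated subjects
    rstar = r @ w.T  # rbar*_ik = sum_l w_kl r_il
    with np.errstate(invalid="ignore", divide="ignore"):
        pa_i = np.where(
            multi,
            ((r * (rstar - 1.0)).sum(axis=1)) / (ri * (ri - 1.0)),
            0.0,
        )
    pa = pa_i[multi].sum() / n_multi

    # chance agreement from marginal propensities over all subjects
    pi = (r / ri[:, None]).sum(axis=0) / n
    pe = tw / (q * (q - 1)) * float((pi * (1.0 - pi)).sum())
    if 1.0 - pe <= 0:
        raise DegenerateAgreementError("chance agreement p_e = 1; AC2 undefined")

    coef = (pa - pe) / (1.0 - pe)

    # subject-level linearization (Gwet)
    kappa_i = np.where(multi, (n / n_multi) * (pa_i - pe) / (1.0 - pe), 0.0)
    pe_i = tw / (q * (q - 1)) * ((r / ri[:, None]) * (1.0 - pi)[None, :]).sum(axis=1)
    kappa_star = kappa_i - 2.0 * (1.0 - coef) * (pe_i - pe) / (1.0 - pe)
    if n > 1:
        var = (1.0 - fpc) / (n * (n - 1.0)) * float(((kappa_star - coef) ** 2).sum())
    else:
        var = 0.0
    se = math.sqrt(max(var, 0.0))
    tq = stats.t.ppf(0.5 + ci_level / 2, df=max(n - 1, 1))
    ci = (max(coef - tq * se, -1.0), min(coef + tq * se, 1.0))

    return AgreementEstimate(
        coefficient=float(coef),
        pa=float(pa),
        pe=float(pe),
        se=float(se),
        ci=ci,
        ci_level=ci_level,
        n_subjects=n,
        n_raters=counts.n_raters,
        weight_family=weight_matrix.family,
        subject_ids=counts.subject_ids,
        influence=kappa_star,
    )


def agreement_from_dataset(
    ds: RatingDataset,
    subject_key: Sequence[str] = tuple(ITEM_COLUMNS),
    family: str = "ordinal",
    ci_level: float = 0.95,
) -> AgreementEstimate:
    """Convenience: counts + weights + AC2 in one call."""
    counts = build_counts(ds, subject_key=subject_key)
    return ac2(counts, weights(counts.q, family), ci_level=ci_level)


# --------------------------------------------------------------- benchmark
@dataclass(frozen=True)
class BenchmarkScale:
    """Ordered reliability intervals, best first: (low, high, label)."""

    intervals: tuple[tuple[float, float, str], ...]

    def __post_init__(self) -> None:
        for (lo, hi, _), (lo2, hi2, _) in zip(self.intervals, self.intervals[1:]):
            if not (lo > lo2 and math.isclose(lo, hi2)):
                raise ValueError("intervals must be contiguous and descending")
            if hi <= lo:
                raise ValueError("empty interval")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for _, _, lab in self.intervals)


#: Gwet-style scale; "substantial" (0.6, 0.8] is the study's acceptability bar.
DEFAULT_BENCHMARK = BenchmarkScale(
    intervals=(
        (0.8, 1.0, "very good"),
        (0.6, 0.8, "substantial"),
        (0.4, 0.6, "moderate"),
        (0.2, 0.4, "fair"),
        (-1.0, 0.2, "poor"),
    )
)


@dataclass
class BenchmarkResult:
    label: str
    memberships: dict[str, float]
    cumulative: dict[str, float]
    threshold: float


def benchmark(
    est: AgreementEstimate,
    scale: BenchmarkScale = DEFAULT_BENCHMARK,
    threshold: float = 0.95,
) -> BenchmarkResult:
    """Probabilistic benchmarking of a reliability coefficient.

    Treats the true coefficient as normal around the estimate with the
    estimate's standard error; the membership probability of interval
    ``(a, b]`` is ``Phi((est-a)/se) - Phi((est-b)/se)``.  The outermost
    interval bounds are opened to +/- infinity so memberships sum to one.
    Scanning from the best interval down, the selected label is the first at
    which the cumulative membership exceeds ``threshold``.
    """
    coef, se = est.coefficient, est.se
    memberships: dict[str, float] = {}
    last = len(scale.intervals) - 1
    for j, (lo, hi, lab) in enumerate(scale.intervals):
        if se == 0.0:
            inside = (coef > lo or j == last) and (coef <= hi or j == 0)
            memberships[lab] = 1.0 if inside else 0.0
            continue
        upper = math.inf if j == 0 else hi
        lower = -math.inf if j == last else lo
        memberships[lab] = float(
            stats.norm.cdf((coef - lower) / se) - stats.norm.cdf((coef - upper) / se)
        )
    label = scale.intervals[-1][2]
    cum = 0.0
    cumulative: dict[str, float] = {}
    chosen = None
    for _, _, lab in scale.intervals:
        cum += memberships[lab]
        cumulative[lab] = cum
        if chosen is None and cum > threshold:
            chosen = lab
    if chosen is None:  # numerical shortfall; fall back to worst interval
        chosen = label
    return BenchmarkResult(
        label=chosen, memberships=memberships, cumulative=cumulative,
        threshold=threshold,
    )


# -------------------------------------------------------------- comparison
@dataclass
class CoefficientComparison:
    diff: float
    se_diff: float
    z: float
    pvalue: float
    mode: str


def compare_coefficients(
    a: AgreementEstimate, b: AgreementEstimate, mode: str = "independent"
) -> CoefficientComparison:
    """Two-sided z-test for the difference of two agreement coefficients.

    ``independent`` combines the two standard errors in quadrature.
    ``paired`` differences the subject-level linearization components, which
    requires both estimates to carry influence values for the same subjects
    (in any order); it accounts for the correlation induced by shared
    subjects and is the stricter test.
    """
    diff = a.coefficient - b.coefficient
    if mode == "independent":
        se_diff = math.hypot(a.se, b.se)
    elif mode == "paired":
        if a.influence is None or b.influence is None:
            raise ValueError("paired mode needs subject-level influence values")
        ida = np.asarray(a.subject_ids)
        idb = np.asarray(b.subject_ids)
        if ida.shape != idb.shape or set(ida) != set(idb):
            raise ValueError("paired mode requires the same subjects in both estimates")
        order_a = np.argsort(ida, kind="stable")
        order_b = np.argsort(idb, kind="stable")
        d = a.influence[order_a] - b.influence[order_b]
        n = d.size
        se_diff = math.sqrt(float(((d - d.mean()) ** 2).sum()) / (n * (n - 1))) if n > 1 else 0.0
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if se_diff == 0.0:
        z = 0.0
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / se_diff
        p = 2.0 * stats.norm.sf(abs(z))
    return CoefficientComparison(diff=diff, se_diff=se_diff, z=z, pvalue=p, mode=mode)
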