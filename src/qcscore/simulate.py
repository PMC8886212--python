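"""Synthetic rating cohorts with the structure the analyses assume.

The generator is the probabilistic twin of the fitted model: each image
carries a latent normal random intercept, each rating is drawn from a
proportional-odds 4-category distribution whose linear predictor collects
the segmentation-method effect, rater leniency, contour-type / slice-level /
pathology effects and their method interactions.  Defaults emulate the
study cohort this package was built around: 217 subjects with a heterogeneous
pathology mix, three contour types, five short-axis slices per image (one
apical, one basal, three mid), two cardiac phases, and four raters with
strongly unequal completion, producing a right-skewed score distribution
with overall mean quality near 3.78.

Cutpoints are calibrated numerically (see :func:`calibrate_thresholds`) so
the *marginal* score distribution — after integrating the random intercept
and averaging over the design mix — hits target category probabilities,
rather than fixing conditional probabilities at a single linear-predictor
value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .ratings import (
    CONTOUR_TYPES,
    DEFAULT_CATEGORIES,
    PHASES,
    RatingDataset,
)

#: marginal category probabilities the default cutpoints are calibrated to:
#: P(score=4) ~ 0.82 and mean score ~ 3.78
TARGET_MARGINAL = (0.01, 0.02, 0.15, 0.82)

DEFAULT_PATHOLOGY_COUNTS: Mapping[str, int] = {
    "DCM": 33,
    "HTN": 107,
    "HCM": 13,
    "IHD_normal_EF": 10,
    "IHD_reduced_EF": 5,
    "LVNC": 6,
    "myocarditis": 1,
    "healthy": 42,
}

#: slices per image by level; mid-dominant, one apical and one basal cap
DEFAULT_SLICE_LEVELS: Mapping[str, int] = {"apical": 1, "mid": 3, "basal": 1}


@dataclass(frozen=True)
class RaterProfile:
    """One rater: completion probability per item and leniency offset.

    ``completion`` is the probability that the rater scored a given item at
    all (both method variants together — partial raters skipped whole items,
    not single contours).  ``leniency`` shifts the rater's latent propensity;
    positive values mean systematically higher scores.
    """

    rater_id: str
    completion: float = 1.0
    leniency: float = 0.0


DEFAULT_RATERS = (
    RaterProfile("A", completion=1.0, leniency=1.0),
    RaterProfile("B", completion=0.69, leniency=-0.7),
    RaterProfile("C", completion=1.0, leniency=0.2),
    RaterProfile("D", completion=0.17, leniency=-0.6),
)

# qualitative defaults: epicardial and basal/apical contours score lower,
# with the contour-type gap larger for manual and the basal drop larger for
# automated segmentation
DEFAULT_FACTOR_EFFECTS: Mapping[str, Mapping[str, float]] = {
    "contour_type": {"lv_endo": 3.1, "rv_endo": 1.8},  # reference lv_epi
    "slice_level": {"basal": -1.7, "apical": -0.8},  # reference mid
}
DEFAULT_METHOD_INTERACTIONS: Mapping[str, Mapping[str, float]] = {
    "contour_type": {"lv_endo": -0.8, "rv_endo": -1.3},
    "slice_level": {"basal": -1.1, "apical": -0.4},
    "pathology": {"DCM": -0.7, "HTN": 0.85},
}

#: method effect at the reference cell (lv_epi, mid, healthy).  The default
#: interactions average to about -0.687 over the design mix, so this value
#: puts the design-averaged automated-vs-manual log-odds at log(1.17), the
#: overall odds ratio the cohort emulates, while keeping the two methods'
#: marginal mean scores nearly equal.
DEFAULT_BETA_METHOD = math.log(1.17) + 0.687


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative specification for one synthetic rating cohort."""

    n_images: int = 217
    slice_levels: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SLICE_LEVELS)
    )
    contour_types: tuple[str, ...] = CONTOUR_TYPES
    phases: tuple[str, ...] = PHASES
    pathology_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PATHOLOGY_COUNTS)
    )
    raters: tuple[RaterProfile, ...] = DEFAULT_RATERS
    beta_method: float = DEFAULT_BETA_METHOD
    factor_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_FACTOR_EFFECTS.items()}
    )
    method_interactions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_METHOD_INTERACTIONS.items()
        }
    )
    sigma_image: float = 1.0
    thresholds: tuple[float, float, float] | None = None  # None -> calibrated
    target_marginal: tuple[float, ...] = TARGET_MARGINAL
    rater_threshold_scale: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if sum(self.pathology_counts.values()) != self.n_images:
            raise ValueError("pathology counts must sum to n_images")
        if sum(self.slice_levels.values()) < 1:
            raise ValueError("need at least one slice per image")
        for r in self.raters:
            if not (0.0 < r.completion <= 1.0):
                raise ValueError(f"completion for {r.rater_id} must be in (0, 1]")
        if self.thresholds is not None:
            t = np.asarray(self.thresholds, float)
            if t.ndim != 1 or (np.diff(t) <= 0).any():
                raise ValueError("thresholds must be strictly increasing")
        if self.sigma_image < 0:
            raise ValueError("sigma_image must be >= 0")
        tm = np.asarray(self.target_marginal, float)
        if tm.min() <= 0 or abs(tm.sum() - 1.0) > 1e-9:
            raise ValueError("target_marginal must be positive and sum to 1")

    def plain(self, **overrides) -> "SimulationConfig":
        """Copy with all factor effects and interactions removed.

        Convenient for recovery studies where the method effect must be the
        only systematic difference besides rater leniency.
        """
        base = replace(self, factor_effects={}, method_interactions={})
        return replace(base, **overrides) if overrides else base


# ---------------------------------------------------------------- design
def _image_table(cfg: SimulationConfig) -> pd.DataFrame:
    ids = [f"img{i:03d}" for i in range(cfg.n_images)]
    pathology = []
    for name, count in cfg.pathology_counts.items():
        pathology.extend([name] * count)
    return pd.DataFrame({"image_id": ids, "pathology": pathology})


def _slice_table(cfg: SimulationConfig) -> pd.DataFrame:
    levels: list[str] = []
    for name, count in cfg.slice_levels.items():
        levels.extend([name] * count)
    return pd.DataFrame(
        {"slice_index": np.arange(len(levels)), "slice_level": levels}
    )


def build_design(cfg: SimulationConfig) -> pd.DataFrame:
    """All potential rating rows with their fixed-effect linear predictor.

    Returns one row per (image, slice, contour, phase, method, rater) with
    column ``eta_fixed`` holding every systematic term except the image
    random intercept, plus the item index used for completion draws.
    """
    images = _image_table(cfg)
    slices = _slice_table(cfg)
    items = (
        images.merge(slices, how="cross")
        .merge(pd.DataFrame({"contour_type": list(cfg.contour_types)}), how="cross")
        .merge(pd.DataFrame({"phase": list(cfg.phases)}), how="cross")
    )
    items["item_index"] = np.arange(len(items))
    rows = items.merge(
        pd.DataFrame({"method": ["manual", "automated"]}), how="cross"
    ).merge(
        pd.DataFrame(
            {
                "rater_id": [r.rater_id for r in cfg.raters],
                "_leniency": [r.leniency for r in cfg.raters],
            }
        ),
        how="cross",
    )

    auto = (rows["method"] == "automated").to_numpy(float)
    eta = cfg.beta_method * auto + rows["_leniency"].to_numpy()
    for factor, levels in cfg.factor_effects.items():
        eta = eta + rows[factor].map(lambda v: levels.get(v, 0.0)).to_numpy()
    for factor, levels in cfg.method_interactions.items():
        eta = eta + auto * rows[factor].map(lambda v: levels.get(v, 0.0)).to_numpy()
    rows["eta_fixed"] = eta
    return rows.drop(columns=["_leniency"])


# ----------------------------------------------------------- calibration
def _gauss_hermite(n: int = 21) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.hermite.hermgauss(n)
    return math.sqrt(2.0) * x, w / math.sqrt(math.pi)


def calibrate_thresholds(cfg: SimulationConfig) -> tuple[float, float, float]:
    """Solve for cutpoints hitting the target marginal score distribution.

    For each cumulative target ``p_c`` finds ``tau_c`` with

        mean_rows  E_Z[ F(tau_c - eta_fixed(row) - sigma Z) ] = p_c

    where rows are weighted by their rater's completion probability and the
    expectation over the random intercept uses Gauss-Hermite quadrature.
    Each equation is monotone in ``tau_c``, so a bracketed scalar solve per
    cutpoint suffices; ordering of the solutions is automatic because the
    targets are ordered.
    """
    rows = build_design(cfg)
    completion = {r.rater_id: r.completion for r in cfg.raters}
    w_rows = rows["rater_id"].map(completion).to_numpy()
    eta, inv = np.unique(rows["eta_fixed"].to_numpy(), return_inverse=True)
    weights = np.bincount(inv, weights=w_rows)
    weights = weights / weights.sum()
    z, wz = _gauss_hermite(21)

    def marginal_cum(tau: float) -> float:
        grid = tau - eta[:, None] - cfg.sigma_image * z[None, :]
        return float((weights[:, None] * wz[None, :] * special.expit(grid)).sum())

    targets = np.cumsum(cfg.target_marginal)[:-1]
    taus = []
    for p in targets:
        taus.append(optimize.brentq(lambda t: marginal_cum(t) - p, -40.0, 40.0))
    return tuple(taus)  # type: ignore[return-value]


def resolved_thresholds(cfg: SimulationConfig) -> np.ndarray:
    if cfg.thresholds is not None:
        return np.asarray(cfg.thresholds, dtype=float)
    return np.asarray(calibrate_thresholds(cfg), dtype=float)


# -------------------------------------------------------------- generate
def generate(cfg: SimulationConfig, seed: int | None = None) -> RatingDataset:
    """Draw one synthetic cohort.

    Per image a latent intercept ``u_i ~ N(0, sigma_image^2)`` is drawn once;
    each retained row's score comes from the proportional-odds distribution
    ``P(score <= c) = F(tau_c - eta_fixed - u_i)``.  Items are dropped per
    rater with one completion draw per item (covering both method variants),
    mimicking raters who stopped partway.  Fully deterministic given the
    config and seed; the same seed with a larger method effect yields
    scores that are pathwise greater or equal, because each score uses a
    single shared uniform against shifted cumulative probabilities.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    tau = resolved_thresholds(cfg)
    rows = build_design(cfg)

    n_items = int(rows["item_index"].max()) + 1
    u = rng.normal(0.0, cfg.sigma_image, size=cfg.n_images)
    keep_by_rater = {
        r.rater_id: rng.random(n_items) < r.completion for r in cfg.raters
    }
    score_u = rng.random(len(rows))

    image_codes = pd.factorize(rows["image_id"], sort=False)[0]
    eta = rows["eta_fixed"].to_numpy() + u[image_codes]

    scale = rows["rater_id"].map(
        lambda r: cfg.rater_threshold_scale.get(r, 1.0)
    ).to_numpy()[:, None]
    tau_rows = tau.mean() + scale * (tau[None, :] - tau.mean())
    cum = special.expit(tau_rows - eta[:, None])
    scores = 1 + (score_u[:, None] > cum).sum(axis=1)

    keep = np.fromiter(
        (
            keep_by_rater[r][i]
            for r, i in zip(rows["rater_id"].to_numpy(), rows["item_index"].to_numpy())
        ),
        dtype=bool,
        count=len(rows),
    )
    out = rows.loc[keep, :].copy()
    out["score"] = scores[keep]
    return RatingDataset(
        out,
        raters=[r.rater_id for r in cfg.raters],
        categories=DEFAULT_CATEGORIES,
    )


def generate_known_agreement(
    q: int,
    n_subjects: int,
    n_raters: int,
    target_regime: str,
    seed: int = 0,
) -> RatingDataset:
    """Fixture cohorts whose agreement level is known by construction.

    ``perfect``: every rater gives the subject's own (random) category, so
    weighted percent agreement is exactly 1.  ``independent-uniform``: all
    ratings are i.i.d. uniform over the ``q`` categories, so any
    chance-corrected coefficient tends to 0 as ``n_subjects`` grows.
    """
    if q < 2 or n_raters < 2:
        raise ValueError("need q >= 2 and n_raters >= 2")
    rng = np.random.default_rng(seed)
    if target_regime == "perfect":
        per_subject = rng.integers(1, q + 1, size=n_subjects)
        scores = np.repeat(per_subject, n_raters)
    elif target_regime == "independent-uniform":
        scores = rng.integers(1, q + 1, size=n_subjects * n_raters)
    else:
        raise ValueError(f"unknown regime {target_regime!r}")
    frame = pd.DataFrame(
        {
            "image_id": np.repeat([f"s{i:05d}" for i in range(n_subjects)], n_raters),
            "slice_index": 0,
            "slice_level": "mid",
            "contour_type": "lv_endo",
            "phase": "ED",
            "method": "manual",
            "rater_id": np.tile([f"r{j}" for j in range(n_raters)], n_subjects),
            "score": scores,
            "pathology": "healthy",
        }
    )
    return RatingDataset(frame, categories=tuple(range(1, q + 1)))
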