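import numpy as np
import pandas as pd
import pytest

from qcscore.ratings import RatingDataset
from qcscore.simulate import RaterProfile, SimulationConfig


def make_frame(rows):
    """Rows as (image, slice, level, contour, phase, method, rater, score, path)."""
    return pd.DataFrame(
        rows,
        columns=[
            "image_id",
            "slice_index",
            "slice_level",
            "contour_type",
            "phase",
            "method",
            "rater_id",
            "score",
            "pathology",
        ],
    )


@pytest.fixture
def tiny_dataset() -> RatingDataset:
    """Two images, one slice/contour/phase, two raters, both methods scored."""
    rows = []
    for img in ("img0", "img1"):
        for method in ("manual", "automated"):
            for rater, score in (("A", 4), ("B", 3)):
                rows.append(
                    (img, 0, "mid", "lv_endo", "ED", method, rater, score, "healthy")
                )
    return RatingDataset(make_frame(rows))


@pytest.fixture
def small_null_config() -> SimulationConfig:
    """Small cohort with no method effect and identical raters."""
    return SimulationConfig(
        n_images=60,
        slice_levels={"mid": 2},
        contour_types=("lv_endo",),
        phases=("ED", "ES"),
        pathology_counts={"healthy": 60},
        raters=(RaterProfile("A"), RaterProfile("B")),
        beta_method=0.0,
        factor_effects={},
        method_interactions={},
        sigma_image=0.8,
        thresholds=(-3.0, -2.0, -0.5),
        seed=0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
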