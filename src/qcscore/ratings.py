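"""Long-format blinded rating tables: data model, IO, pairing, stratification.

A rating is one quality judgment of one contour item.  An *item* is a
(image, slice, contour type, cardiac phase, segmentation method) tuple; each
rater scores an item on an ordinal 1-4 rubric without knowing whether the
contour was drawn manually or by the segmentation algorithm.  Datasets are
stored long-format, one row per rating, so that every downstream stage
(agreement, ordinal regression, paired tests) can build its own view.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

SLICE_LEVELS = ("apical", "basal", "mid")
CONTOUR_TYPES = ("lv_endo", "lv_epi", "rv_endo")
PHASES = ("ED", "ES")
METHODS = ("manual", "automated")
PATHOLOGIES = (
    "DCM",
    "HCM",
    "HTN",
    "IHD_normal_EF",
    "IHD_reduced_EF",
    "LVNC",
    "myocarditis",
    "healthy",
)
DEFAULT_CATEGORIES = (1, 2, 3, 4)

#: columns identifying a single rating (unique within a dataset)
KEY_COLUMNS = ["image_id", "slice_index", "contour_type", "phase", "method", "rater_id"]
#: columns identifying a scored item irrespective of rater
ITEM_COLUMNS = ["image_id", "slice_index", "contour_type", "phase", "method"]
#: canonical serialized column order
COLUMNS = [
    "image_id",
    "slice_index",
    "slice_level",
    "contour_type",
    "phase",
    "method",
    "rater_id",
    "score",
    "pathology",
]

STRATIFY_FACTORS = {
    "contour_type": "contour_type",
    "slice_level": "slice_level",
    "pathology": "pathology",
    "rater": "rater_id",
    "method": "method",
}


class RatingsError(Exception):
    """Base class for rating-table errors."""


class SchemaError(RatingsError):
    """A required column is missing or mis-typed."""


class ValidationError(RatingsError):
    """One or more rows violate a record invariant.

    ``rows`` holds 1-based data-row indices (header not counted) so the
    message can point at the offending lines of the source CSV.
    """

    def __init__(self, message: str, rows: Sequence[int] = ()):  # noqa: D107
        super().__init__(message)
        self.rows = list(rows)


class UniquenessError(ValidationError):
    """Duplicate (image, slice, contour, phase, method, rater) key."""


@dataclass(frozen=True)
class RatingRecord:
    """One blinded quality score with its full stratification metadata."""

    image_id: str
    slice_index: int
    slice_level: str
    contour_type: str
    phase: str
    method: str
    rater_id: str
    score: int
    pathology: str

    def validate(self, categories: Sequence[int] = DEFAULT_CATEGORIES) -> None:
        if self.slice_index < 0:
            raise ValidationError(f"slice_index must be >= 0, got {self.slice_index}")
        if self.slice_level not in SLICE_LEVELS:
            raise ValidationError(f"unknown slice_level {self.slice_level!r}")
        if self.contour_type not in CONTOUR_TYPES:
            raise ValidationError(f"unknown contour_type {self.contour_type!r}")
        if self.phase not in PHASES:
            raise ValidationError(f"unknown phase {self.phase!r}")
        if self.method not in METHODS:
            raise ValidationError(f"unknown method {self.method!r}")
        if self.pathology not in PATHOLOGIES:
            raise ValidationError(f"unknown pathology {self.pathology!r}")
        if self.score not in categories:
            raise ValidationError(
                f"score {self.score} outside categories {tuple(categories)}"
            )


@dataclass(frozen=True)
class Rubric:
    """The 4-point quality rubric used by the raters.

    The rubric is documentation carried alongside the data: the visual
    judgment it encodes (e.g. leniency towards very small contours, or the
    rule that two disjoint basal RV contours merit a 3 when they cover the
    anatomy) is applied by human raters, not by this package.
    """

    levels: Mapping[int, tuple[str, str]]
    notes: str = ""

    def __post_init__(self) -> None:
        if len(self.levels) != 4:
            raise ValueError("rubric must have exactly 4 levels")
        labels = [lab for lab, _ in self.levels.values()]
        if len(set(labels)) != len(labels):
            raise ValueError("rubric labels must be unique")


DEFAULT_RUBRIC = Rubric(
    levels={
        1: ("unacceptable", "significantly inaccurate segmentation, clinically unacceptable"),
        2: ("poor", "bad quality, requires significant manual correction"),
        3: ("acceptable", "fair quality, minor inaccuracies without clinical relevance"),
        4: ("good", "good quality, no changes needed"),
    },
    notes=(
        "Small contours and small deviations are rarely scored <= 2. "
        "Basal RV slices may legitimately show two disjoint contours; score 3 "
        "if they encompass the anatomy, else 2 or 1."
    ),
)


class RatingDataset:
    """A validated collection of :class:`RatingRecord` rows.

    Wraps a :class:`pandas.DataFrame` in canonical column order.  ``raters``
    and ``categories`` are carried explicitly so that per-rater counts and the
    ordinal scale survive subsetting even when levels drop out of the data.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        raters: Sequence[str] | None = None,
        categories: Sequence[int] = DEFAULT_CATEGORIES,
        validate: bool = True,
    ):
        frame = frame.loc[:, COLUMNS].reset_index(drop=True)
        frame = frame.astype(
            {
                "image_id": str,
                "slice_index": np.int64,
                "slice_level": str,
                "contour_type": str,
                "phase": str,
                "method": str,
                "rater_id": str,
                "score": np.int64,
                "pathology": str,
            }
        )
        self.df = frame
        self.categories = tuple(int(c) for c in categories)
        if raters is None:
            raters = sorted(frame["rater_id"].unique())
        self.raters = tuple(str(r) for r in raters)
        if validate:
            self._validate()

    # ------------------------------------------------------------------ basic
    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RatingDataset):
            return NotImplemented
        a = self.df.sort_values(KEY_COLUMNS).reset_index(drop=True)
        b = other.df.sort_values(KEY_COLUMNS).reset_index(drop=True)
        return (
            a.equals(b)
            and self.categories == other.categories
            and set(self.raters) == set(other.raters)
        )

    @property
    def records(self) -> Iterator[RatingRecord]:
        for row in self.df.itertuples(index=False):
            yield RatingRecord(
                image_id=row.image_id,
                slice_index=int(row.slice_index),
                slice_level=row.slice_level,
                contour_type=row.contour_type,
                phase=row.phase,
                method=row.method,
                rater_id=row.rater_id,
                score=int(row.score),
                pathology=row.pathology,
            )

    @classmethod
    def from_records(
        cls,
        records: Iterable[RatingRecord],
        raters: Sequence[str] | None = None,
        categories: Sequence[int] = DEFAULT_CATEGORIES,
    ) -> "RatingDataset":
        frame = pd.DataFrame([r.__dict__ for r in records], columns=COLUMNS)
        return cls(frame, raters=raters, categories=categories)

    def _validate(self) -> None:
        df = self.df
        bad_rows: list[int] = []
        msgs: list[str] = []

        def check(mask: pd.Series, what: str) -> None:
            if mask.any():
                rows = (df.index[mask] + 1).tolist()
                bad_rows.extend(rows)
                msgs.append(f"{what} on row(s) {rows}")

        check(~df["score"].isin(self.categories), f"score outside {self.categories}")
        check(df["slice_index"] < 0, "negative slice_index")
        check(~df["slice_level"].isin(SLICE_LEVELS), "unknown slice_level")
        check(~df["contour_type"].isin(CONTOUR_TYPES), "unknown contour_type")
        check(~df["phase"].isin(PHASES), "unknown phase")
        check(~df["method"].isin(METHODS), "unknown method")
        check(~df["pathology"].isin(PATHOLOGIES), "unknown pathology")
        check(~df["rater_id"].isin(self.raters), "rater_id not in rater list")
        if msgs:
            raise ValidationError("; ".join(msgs), rows=sorted(set(bad_rows)))

        dup = df.duplicated(subset=KEY_COLUMNS, keep=False)
        if dup.any():
            rows = (df.index[dup] + 1).tolist()
            raise UniquenessError(
                f"duplicate rating key on row(s) {rows}", rows=rows
            )

    # -------------------------------------------------------------- summaries
    def counts_by(self, *columns: str) -> pd.Series:
        """Exact rating counts per combination of metadata columns."""
        cols = [STRATIFY_FACTORS.get(c, c) for c in columns]
        return self.df.groupby(cols, observed=True).size()

    def subset(self, mask: pd.Series) -> "RatingDataset":
        return RatingDataset(
            self.df.loc[mask], raters=self.raters, categories=self.categories,
            validate=False,
        )


# ---------------------------------------------------------------------- IO
def read_ratings(
    path,
    schema: Mapping[str, str] | None = None,
    categories: Sequence[int] = DEFAULT_CATEGORIES,
) -> RatingDataset:
    """Read a long-format rating CSV.

    Parameters
    ----------
    path
        CSV file with one row per rating.
    schema
        Optional map from the file's column names to the canonical names in
        :data:`COLUMNS` (e.g. ``{"subject": "image_id"}``).
    """
    df = pd.read_csv(path, dtype={"image_id": str, "rater_id": str})
    if schema:
        df = df.rename(columns=dict(schema))
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    if not pd.api.types.is_integer_dtype(df["score"]):
        # accept floats that are exact integers, reject everything else
        scores = pd.to_numeric(df["score"], errors="coerce")
        bad = scores.isna() | (scores != scores.round())
        if bad.any():
            raise ValidationError(
                f"non-integer score on row(s) {(df.index[bad] + 1).tolist()}",
                rows=(df.index[bad] + 1).tolist(),
            )
        df["score"] = scores.astype(np.int64)
    return RatingDataset(df, categories=categories)


def write_ratings(ds: RatingDataset, path) -> None:
    """Write a dataset as CSV with the stable canonical column order."""
    ds.df.loc[:, COLUMNS].to_csv(path, index=False)


# ----------------------------------------------------------------- pairing
@dataclass
class PairedView:
    """Manual/automated score pairs per rater plus exclusion bookkeeping."""

    pairs: pd.DataFrame  # item key columns (minus method) + score_manual/score_automated/diff
    n_excluded: int
    pair_counts: pd.Series  # per rater

    def for_rater(self, rater_id: str) -> pd.DataFrame:
        return self.pairs[self.pairs["rater_id"] == rater_id]


def pair_by_method(ds: RatingDataset) -> PairedView:
    """Match each rater's manual and automated score for the same item.

    A pair exists for a (image, slice, contour, phase, rater) cell only when
    both methods were scored; unmatched ratings are excluded from paired
    testing (but remain available to the agreement and regression stages,
    which tolerate missingness).  ``diff`` is automated minus manual.
    """
    key = ["image_id", "slice_index", "contour_type", "phase", "rater_id"]
    df = ds.df
    man = df[df["method"] == "manual"][key + ["score"]].rename(
        columns={"score": "score_manual"}
    )
    aut = df[df["method"] == "automated"][key + ["score"]].rename(
        columns={"score": "score_automated"}
    )
    pairs = man.merge(aut, on=key, how="inner")
    pairs["diff"] = pairs["score_automated"] - pairs["score_manual"]
    n_excluded = len(df) - 2 * len(pairs)
    counts = (
        pairs.groupby("rater_id").size().reindex(list(ds.raters), fill_value=0)
    )
    return PairedView(pairs=pairs, n_excluded=n_excluded, pair_counts=counts)


# --------------------------------------------------------------- stratify
def stratify(ds: RatingDataset, factor: str) -> dict[str, RatingDataset]:
    """Partition a dataset by one metadata factor.

    Strata are disjoint and their union is the input; every factor level
    present in the data appears as a key.
    """
    if factor not in STRATIFY_FACTORS:
        raise ValueError(
            f"unknown factor {factor!r}; expected one of {sorted(STRATIFY_FACTORS)}"
        )
    col = STRATIFY_FACTORS[factor]
    return {
        str(level): ds.subset(ds.df[col] == level)
        for level in sorted(ds.df[col].unique())
    }
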