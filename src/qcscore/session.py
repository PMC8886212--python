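"""Headless blinded scoring workflow: shuffled queues, resumable sessions.

Mirrors the rating application the analyses consume data from: a
coordinator builds an item manifest (which knows each contour's true source),
each rater works through a seeded random permutation of the items seeing
only blinded metadata, and completed sessions are unblinded and merged into
a standard :class:`~qcscore.ratings.RatingDataset`.

Blinding is enforced structurally: the rater-facing session file simply has
no method field, so no serialization path can leak the contour source.
State files are written atomically (write to a sibling temp file, then
rename) so an interrupted session resumes exactly where it stopped.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ratings import DEFAULT_CATEGORIES, RatingDataset


class SessionError(Exception):
    pass


@dataclass(frozen=True)
class ScoringItem:
    """One contour to score.  ``hidden_method`` never reaches the rater."""

    item_id: str
    image_id: str
    slice_index: int
    slice_level: str
    contour_type: str
    phase: str
    pathology: str
    hidden_method: str
    image_ref: str = ""
    contour_ref: str = ""

    def blinded(self) -> dict:
        """Rater-facing view: everything except the contour source."""
        return {
            "item_id": self.item_id,
            "image_id": self.image_id,
            "slice_index": self.slice_index,
            "slice_level": self.slice_level,
            "contour_type": self.contour_type,
            "phase": self.phase,
            "pathology": self.pathology,
            "image_ref": self.image_ref,
            "contour_ref": self.contour_ref,
        }


@dataclass
class Manifest:
    """The coordinator's item list, including the unblinding key."""

    items: tuple[ScoringItem, ...]

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SessionError(f"duplicate item id(s): {dupes}")

    def by_id(self, item_id: str) -> ScoringItem:
        return {it.item_id: it for it in self.items}[item_id]

    def save(self, path) -> None:
        payload = [it.__dict__ for it in self.items]
        _atomic_write_json(path, {"items": payload})

    @classmethod
    def load(cls, path) -> "Manifest":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(items=tuple(ScoringItem(**d) for d in payload["items"]))


def manifest_from_design(design: pd.DataFrame) -> Manifest:
    """Build a manifest from rows with the standard item columns + method.

    Rows are deduplicated to one entry per presented item (a design table
    may carry one row per rater; the manifest is rater-agnostic).
    """
    item_cols = [
        "image_id", "slice_index", "slice_level", "contour_type", "phase",
        "pathology", "method",
    ]
    design = design.loc[:, item_cols].drop_duplicates().reset_index(drop=True)
    items = []
    for i, row in enumerate(design.itertuples(index=False)):
        items.append(
            ScoringItem(
                item_id=f"item{i:06d}",
                image_id=str(row.image_id),
                slice_index=int(row.slice_index),
                slice_level=row.slice_level,
                contour_type=row.contour_type,
                phase=row.phase,
                pathology=row.pathology,
                hidden_method=row.method,
            )
        )
    return Manifest(items=tuple(items))


@dataclass
class Session:
    """One rater's scoring state: a fixed queue, a cursor, recorded scores."""

    rater_id: str
    queue: tuple[dict, ...]  # blinded item views, presentation order
    seed: int
    cursor: int = 0
    scores: list[int] = field(default_factory=list)
    categories: tuple[int, ...] = DEFAULT_CATEGORIES

    @property
    def complete(self) -> bool:
        return self.cursor >= len(self.queue)

    @property
    def current(self) -> dict:
        if self.complete:
            raise SessionError("session already complete")
        return self.queue[self.cursor]


def create_session(
    items: Sequence[ScoringItem] | Manifest, rater_id: str, seed: int
) -> Session:
    """Seeded uniform random permutation of the blinded items.

    Both contour sources are interleaved in one queue; the rater cannot tell
    which entry is which because the queue entries carry no method field.
    """
    if isinstance(items, Manifest):
        items = items.items
    if not items:
        raise SessionError("no items to score")
    ids = [it.item_id for it in items]
    if len(set(ids)) != len(ids):
        raise SessionError("duplicate item ids")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    queue = tuple(items[i].blinded() for i in order)
    return Session(rater_id=rater_id, queue=queue, seed=seed)


def record_score(session: Session, score: int) -> Session:
    """Record the rubric score for the current item and advance the cursor."""
    if session.complete:
        raise SessionError("session already complete")
    if score not in session.categories:
        raise SessionError(
            f"score {score!r} not in rubric categories {session.categories}"
        )
    session.scores.append(int(score))
    session.cursor += 1
    return session


def step_back(session: Session) -> Session:
    """Revisit the previous item, discarding its score (opt-in workflow)."""
    if session.cursor == 0:
        raise SessionError("already at the first item")
    session.cursor -= 1
    session.scores.pop()
    return session


def _atomic_write_json(path, payload) -> None:
    path = os.fspath(path)
    directory = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(payload, fh, indent=1)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def save_session(session: Session, path) -> None:
    """Persist rater-facing state.  Contains no contour-source information."""
    _atomic_write_json(
        path,
        {
            "rater_id": session.rater_id,
            "seed": session.seed,
            "cursor": session.cursor,
            "scores": session.scores,
            "categories": list(session.categories),
            "queue": list(session.queue),
        },
    )


def load_session(path) -> Session:
    with open(path) as fh:
        payload = json.load(fh)
    return Session(
        rater_id=payload["rater_id"],
        queue=tuple(payload["queue"]),
        seed=payload["seed"],
        cursor=payload["cursor"],
        scores=list(payload["scores"]),
        categories=tuple(payload["categories"]),
    )


def finalize(
    sessions: Iterable[Session],
    manifest: Manifest,
    allow_partial: bool = True,
) -> RatingDataset:
    """Unblind and merge rater sessions into a rating dataset.

    Each scored queue entry is joined back to the manifest to recover the
    contour source.  Conflicting duplicate scores for one (item, rater) are
    an error; unscored items are simply absent (downstream stages treat them
    as missing data).
    """
    sessions = list(sessions)
    rows = []
    seen: set[tuple[str, str]] = set()
    for session in sessions:
        if not allow_partial and not session.complete:
            raise SessionError(f"session for {session.rater_id} is incomplete")
        for entry, score in zip(session.queue, session.scores):
            key = (entry["item_id"], session.rater_id)
            if key in seen:
                raise SessionError(
                    f"conflicting duplicate score for item {key[0]} by {key[1]}"
                )
            seen.add(key)
            item = manifest.by_id(entry["item_id"])
            rows.append(
                {
                    "image_id": item.image_id,
                    "slice_index": item.slice_index,
                    "slice_level": item.slice_level,
                    "contour_type": item.contour_type,
                    "phase": item.phase,
                    "method": item.hidden_method,
                    "rater_id": session.rater_id,
                    "score": score,
                    "pathology": item.pathology,
                }
            )
    if not rows:
        raise SessionError("no scores recorded in any session")
    frame = pd.DataFrame(rows)
    raters = sorted({s.rater_id for s in sessions} | set(frame["rater_id"]))
    return RatingDataset(frame, raters=raters)
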