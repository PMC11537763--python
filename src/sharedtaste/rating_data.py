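"""Data model for crossed rating experiments.

A rating experiment is stored long-format: one row per
(rater, stimulus, session) with an integer liking rating on a 1-9 Likert
scale, plus stimulus metadata mapping each stimulus to a performer
(singer), melody and vocalization style.  All agreement statistics in this
package operate on the wide :class:`RatingMatrix` view (raters x stimuli),
obtained by pooling the two test-retest sessions with
:func:`average_sessions`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "STYLES",
    "RatingTable",
    "SchemaError",
    "IncompleteDesignError",
    "read_ratings",
    "write_ratings",
    "read_participants",
    "filter_flat_raters",
    "average_sessions",
    "slice_by_style",
]

#: Vocalization styles of the study design: three singing styles and two
#: speech registers (adult-directed, infant-directed).
STYLES = ("lullaby", "pop", "opera", "AD", "ID")

RATING_MIN, RATING_MAX = 1, 9

RECORD_COLUMNS = ["rater_id", "stimulus_id", "session", "rating"]
META_COLUMNS = ["stimulus_id", "singer_id", "melody_id", "style"]


class SchemaError(ValueError):
    """A ratings or metadata file violates the expected schema."""


class IncompleteDesignError(ValueError):
    """An operation requiring a balanced crossed design met missing cells."""

    def __init__(self, message: str, cells: list | None = None):
        super().__init__(message)
        self.cells = cells or []


@dataclass
class RatingTable:
    """Long-format ratings plus stimulus metadata.

    Parameters
    ----------
    records
        DataFrame with columns ``rater_id, stimulus_id, session, rating``.
    meta
        DataFrame with columns ``stimulus_id, singer_id, melody_id, style``,
        one row per stimulus.
    """

    records: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.records = self.records.reset_index(drop=True)
        self.meta = self.meta.reset_index(drop=True)
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self, strict_likert: bool | None = None) -> None:
        """Check invariants.

        ``strict_likert`` forces integer 1-9 ratings; by default ratings
        must be numeric and, when they are all whole numbers, inside 1-9
        (continuous synthetic data is allowed through).
        """
        for col in RECORD_COLUMNS:
            if col not in self.records.columns:
                raise SchemaError(f"records missing column {col!r}")
        for col in META_COLUMNS:
            if col not in self.meta.columns:
                raise SchemaError(f"meta missing column {col!r}")
        if self.meta["stimulus_id"].duplicated().any():
            dup = self.meta.loc[self.meta["stimulus_id"].duplicated(), "stimulus_id"]
            raise SchemaError(f"duplicate stimulus metadata for {sorted(set(dup))}")
        dups = self.records.duplicated(subset=["rater_id", "stimulus_id", "session"])
        if dups.any():
            first = self.records.loc[dups].iloc[0]
            raise SchemaError(
                "duplicate (rater, stimulus, session) row, first at "
                f"({first.rater_id!r}, {first.stimulus_id!r}, {first.session})"
            )
        known = set(self.meta["stimulus_id"])
        unknown = set(self.records["stimulus_id"]) - known
        if unknown:
            raise SchemaError(f"records reference unknown stimuli: {sorted(unknown)[:5]}")
        ratings = self.records["rating"]
        if not np.issubdtype(ratings.dtype, np.number):
            raise SchemaError("ratings must be numeric")
        integral = bool(np.all(np.asarray(ratings) == np.round(ratings)))
        if strict_likert is None:
            strict_likert = integral
        if strict_likert:
            bad = ~ratings.between(RATING_MIN, RATING_MAX) | (ratings != np.round(ratings))
            if bad.any():
                row = self.records.loc[bad].iloc[0]
                raise SchemaError(
                    f"rating {row.rating!r} outside integer 1-9 scale at "
                    f"({row.rater_id!r}, {row.stimulus_id!r}, session {row.session})"
                )

    # -- derived views ---------------------------------------------------

    @property
    def raters(self) -> list:
        return sorted(self.records["rater_id"].unique().tolist())

    @property
    def stimuli(self) -> list:
        return sorted(self.meta["stimulus_id"].unique().tolist())

    @property
    def sessions(self) -> list:
        return sorted(self.records["session"].unique().tolist())

    @property
    def styles(self) -> list:
        return sorted(self.meta["style"].unique().tolist())

    @property
    def balanced(self) -> bool:
        """True when every rater rated every stimulus in both test-retest sessions."""
        if len(self.sessions) < 2:
            return False
        n_expected = len(self.raters) * len(self.stimuli) * len(self.sessions)
        return len(self.records) == n_expected

    def merged(self) -> pd.DataFrame:
        """Records joined with stimulus metadata."""
        return self.records.merge(self.meta, on="stimulus_id", validate="m:1")

    def subset_raters(self, keep) -> "RatingTable":
        keep = set(keep)
        rec = self.records[self.records["rater_id"].isin(keep)]
        return RatingTable(rec.copy(), self.meta.copy())

    def subset_style(self, style: str) -> "RatingTable":
        if style not in set(self.meta["style"]):
            raise KeyError(f"unknown style {style!r}; have {self.styles}")
        meta = self.meta[self.meta["style"] == style]
        rec = self.records[self.records["stimulus_id"].isin(set(meta["stimulus_id"]))]
        return RatingTable(rec.copy(), meta.copy())

    def equals(self, other: "RatingTable") -> bool:
        a = self.records.sort_values(RECORD_COLUMNS).reset_index(drop=True)
        b = other.records.sort_values(RECORD_COLUMNS).reset_index(drop=True)
        ma = self.meta.sort_values("stimulus_id").reset_index(drop=True)
        mb = other.meta.sort_values("stimulus_id").reset_index(drop=True)
        return a.equals(b) and ma.equals(mb)


# ---------------------------------------------------------------------------
# I/O


def read_ratings(path, meta_path) -> RatingTable:
    """Read a ratings CSV and its stimulus-metadata CSV into a RatingTable.

    The ratings file must have the header ``rater_id,stimulus_id,session,
    rating`` with integer ratings in 1-9 and sessions in {1, 2}; the
    metadata file maps every stimulus to a (singer, melody, style) triple.
    """
    records = pd.read_csv(path, dtype={"rater_id": str, "stimulus_id": str})
    meta = pd.read_csv(meta_path, dtype=str)
    for col in RECORD_COLUMNS:
        if col not in records.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    ratings = pd.to_numeric(records["rating"], errors="coerce")
    bad = ratings.isna() | (ratings != np.round(ratings))
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise SchemaError(f"{path}: non-integer rating {records['rating'].iloc[i]!r} in row {i + 2}")
    records["rating"] = ratings.astype(int)
    out_of_range = ~records["rating"].between(RATING_MIN, RATING_MAX)
    if out_of_range.any():
        i = int(np.flatnonzero(out_of_range)[0])
        raise SchemaError(
            f"{path}: rating {records['rating'].iloc[i]} outside 1-9 in row {i + 2}"
        )
    records["session"] = pd.to_numeric(records["session"]).astype(int)
    table = RatingTable(records[RECORD_COLUMNS], meta[META_COLUMNS])
    table.validate(strict_likert=True)
    return table


def write_ratings(table: RatingTable, path, meta_path) -> None:
    """Write a RatingTable to CSV files readable by :func:`read_ratings`."""
    table.records[RECORD_COLUMNS].to_csv(path, index=False)
    table.meta[META_COLUMNS].to_csv(meta_path, index=False)


def read_participants(path) -> pd.DataFrame:
    """Read the optional participant-covariate CSV (rater_id + free columns)."""
    df = pd.read_csv(path, dtype={"rater_id": str})
    if "rater_id" not in df.columns:
        raise SchemaError(f"{path}: missing column 'rater_id'")
    return df


# ---------------------------------------------------------------------------
# Registered exclusion filter


def filter_flat_raters(
    table: RatingTable, threshold: float = 0.85, per_session: bool = False
) -> tuple[RatingTable, list]:
    """Exclude raters whose modal rating covers more than ``threshold`` of trials.

    The registered criterion: a rater is dropped when a single scale value
    accounts for *strictly more* than 85% of their trials.  Trials are
    pooled over both sessions and all styles by default; ``per_session=True``
    instead excludes a rater whose modal share exceeds the threshold in
    either session alone.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")

    def modal_share(group: pd.DataFrame) -> float:
        return group["rating"].value_counts().iloc[0] / len(group)

    excluded: set = set()
    if per_session:
        for (rater, _), grp in table.records.groupby(["rater_id", "session"]):
            if modal_share(grp) > threshold:
                excluded.add(rater)
    else:
        for rater, grp in table.records.groupby("rater_id"):
            if modal_share(grp) > threshold:
                excluded.add(rater)
    keep = [r for r in table.raters if r not in excluded]
    return table.subset_raters(keep), sorted(excluded)


# ---------------------------------------------------------------------------
# Session pooling and style slicing


def average_sessions(table: RatingTable) -> pd.DataFrame:
    """Pool the test-retest sessions into a raters x stimuli matrix.

    Each cell is the mean of that rater's ratings of that stimulus over all
    sessions (the study has two).  Raises :class:`IncompleteDesignError`
    if any (rater, stimulus) pair misses a session.
    """
    sessions = table.sessions
    if len(sessions) < 2:
        raise IncompleteDesignError(
            f"need at least two sessions to pool, found {sessions}"
        )
    counts = table.records.pivot_table(
        index="rater_id", columns="stimulus_id", values="rating", aggfunc="count"
    )
    full = counts.reindex(index=table.raters, columns=table.stimuli)
    bad = full.isna() | (full != len(sessions))
    if bad.to_numpy().any():
        cells = [
            (r, c) for r, c in zip(*np.nonzero(bad.to_numpy()))
        ]
        named = [(full.index[r], full.columns[c]) for r, c in cells[:10]]
        raise IncompleteDesignError(
            f"{len(cells)} (rater, stimulus) cells lack a complete session pair, "
            f"first: {named}",
            cells=named,
        )
    matrix = table.records.pivot_table(
        index="rater_id", columns="stimulus_id", values="rating", aggfunc="mean"
    )
    return matrix.loc[table.raters, table.stimuli].astype(float)


def slice_by_style(data, style: str, meta: pd.DataFrame | None = None):
    """Restrict a RatingTable or rating matrix to stimuli of one style.

    For a matrix input the stimulus metadata must be supplied.  Returns the
    same kind of object that went in; for the study design each style slice
    has 66 stimulus columns (22 singers x 3 melodies).
    """
    if isinstance(data, RatingTable):
        return data.subset_style(style)
    if meta is None:
        raise ValueError("meta is required to slice a matrix by style")
    if style not in set(meta["style"]):
        raise KeyError(f"unknown style {style!r}; have {sorted(set(meta['style']))}")
    wanted = meta.loc[meta["style"] == style, "stimulus_id"]
    cols = [c for c in data.columns if c in set(wanted)]
    if not cols:
        raise KeyError(f"style {style!r} has no stimuli in this matrix")
    return data[cols]
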