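"""Domain types and I/O for longitudinal dendritic-protrusion annotations.

Chronic two-photon imaging studies score each dendritic protrusion
(spine or filopodium) as present, absent, or filopodia at every imaging
session, typically on a fixed schedule of days relative to the first
session.  This module defines the in-memory containers for those
annotations — :class:`FeatureTrack`, :class:`DendriteRecord`,
:class:`MouseDataset` — together with a tidy long-format CSV
representation (one row per feature per session) and a validation
report.

The long format was chosen over a wide (one column per session) layout
because imaging schedules are ragged across studies and age groups; a
tidy table survives schedule changes without schema changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "STATUSES",
    "ADULT_SCHEDULE",
    "JUVENILE_SCHEDULE",
    "ImagingSchedule",
    "FeatureTrack",
    "DendriteRecord",
    "MouseDataset",
    "MorphologyScore",
    "ValidationReport",
    "TrackTableError",
    "read_track_table",
    "write_track_table",
    "validate_dataset",
]

#: Canonical per-session status values.
STATUSES = ("present", "absent", "filopodia")

#: Columns of the long-format track table, in order.
TRACK_TABLE_COLUMNS = [
    "mouse_id",
    "genotype",
    "age_group",
    "dendrite_id",
    "feature_id",
    "session_day",
    "status",
    "x_um",
    "y_um",
    "z_um",
]

#: Minimum day-0 protrusion count below which validation warns; chronic
#: imaging studies of this kind analyse at least 150 protrusions per
#: animal (typical averages are 250-300).
MIN_PROTRUSIONS = 150


class TrackTableError(ValueError):
    """Raised for malformed track tables (missing columns, bad statuses,
    inconsistent per-mouse metadata)."""


@dataclass(frozen=True)
class ImagingSchedule:
    """Ordered imaging days, in integer days relative to the first session.

    The first element must be 0 (the first day of imaging) and days must
    be strictly increasing, e.g. ``(0, 1, 2, 7, 14, 21, 28, 42)`` for a
    six-week adult protocol or ``(0, 1, 2)`` for juveniles.
    """

    session_days: tuple[int, ...]

    def __post_init__(self) -> None:
        days = tuple(int(d) for d in self.session_days)
        object.__setattr__(self, "session_days", days)
        if len(days) < 2:
            raise ValueError("schedule needs at least 2 sessions")
        if days[0] != 0:
            raise ValueError("first session day must be 0")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("session days must be strictly increasing")

    def __len__(self) -> int:
        return len(self.session_days)

    def __iter__(self) -> Iterator[int]:
        return iter(self.session_days)

    def index(self, day: int) -> int:
        return self.session_days.index(day)

    def __contains__(self, day: int) -> bool:
        return day in self.session_days


#: Standard adult six-week chronic imaging schedule (days).
ADULT_SCHEDULE = ImagingSchedule((0, 1, 2, 7, 14, 21, 28, 42))
#: Juvenile two-day schedule (days).
JUVENILE_SCHEDULE = ImagingSchedule((0, 1, 2))


@dataclass
class FeatureTrack:
    """One protrusion's status (and optional µm coordinates) per session.

    ``status_by_session`` maps each scheduled session day to one of
    ``present``/``absent``/``filopodia``; ``position_by_session`` maps a
    session day to an (x, y, z) tuple in µm and may omit sessions where
    the feature was absent.
    """

    feature_id: str
    dendrite_id: str
    status_by_session: dict[int, str]
    position_by_session: dict[int, tuple[float, float, float]] = field(
        default_factory=dict
    )

    def status(self, day: int) -> str:
        return self.status_by_session[day]

    def statuses(self, schedule: ImagingSchedule) -> list[str]:
        """Statuses in schedule order."""
        return [self.status_by_session[d] for d in schedule]


@dataclass(eq=False)
class DendriteRecord:
    """A dendritic segment of one mouse and its tracked features.

    ``segment_length_um`` (optional) is the traced segment length and is
    the denominator of spine density.  Equality is field-by-field with
    the track collection compared order-insensitively (by feature_id).
    """

    dendrite_id: str
    mouse_id: str
    tracks: list[FeatureTrack] = field(default_factory=list)
    segment_length_um: float | None = None

    def __eq__(self, other) -> bool:
        if not isinstance(other, DendriteRecord):
            return NotImplemented
        key = lambda t: t.feature_id
        return (
            self.dendrite_id == other.dendrite_id
            and self.mouse_id == other.mouse_id
            and self.segment_length_um == other.segment_length_um
            and sorted(self.tracks, key=key) == sorted(other.tracks, key=key)
        )

    def __post_init__(self) -> None:
        if self.segment_length_um is not None and not self.segment_length_um > 0:
            raise ValueError("segment_length_um must be > 0 when given")
        ids = [t.feature_id for t in self.tracks]
        if len(set(ids)) != len(ids):
            raise ValueError(
                f"duplicate feature_ids within dendrite {self.dendrite_id!r}"
            )


@dataclass(eq=False)
class MouseDataset:
    """All tracked dendrites of one animal, with genotype/age labels.

    All dendrites share the mouse's :class:`ImagingSchedule`; every track
    must carry a status for every scheduled day (an explicit
    present/absent/filopodia call — missing sessions are an error, never
    imputed).  Equality compares dendrite collections order-insensitively.
    """

    mouse_id: str
    genotype: str
    age_group: str
    schedule: ImagingSchedule
    dendrites: list[DendriteRecord] = field(default_factory=list)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MouseDataset):
            return NotImplemented
        key = lambda d: d.dendrite_id
        return (
            self.mouse_id == other.mouse_id
            and self.genotype == other.genotype
            and self.age_group == other.age_group
            and self.schedule == other.schedule
            and sorted(self.dendrites, key=key) == sorted(other.dendrites, key=key)
        )

    def iter_tracks(self) -> Iterator[FeatureTrack]:
        for dend in self.dendrites:
            yield from dend.tracks

    @property
    def n_features(self) -> int:
        return sum(len(d.tracks) for d in self.dendrites)


@dataclass(frozen=True)
class MorphologyScore:
    """Day-0 morphological class of one protrusion.

    ``morph_class`` is one of ``mushroom`` (bright bulbous head),
    ``intermediate`` (thin, dim/small or headless) or ``filopodia``
    (dim, elongated, headless).
    """

    feature_id: str
    morph_class: str

    def __post_init__(self) -> None:
        if self.morph_class not in ("mushroom", "intermediate", "filopodia"):
            raise ValueError(f"unknown morphology class {self.morph_class!r}")


# ---------------------------------------------------------------------------
# I/O: tidy long-format CSV, one row per feature per session
# ---------------------------------------------------------------------------


def _position_tuple(row) -> tuple[float, float, float] | None:
    x, y, z = row
    if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in (x, y, z)):
        return None
    return (float(x), float(y), float(z))


def read_track_table(path) -> list[MouseDataset]:
    """Read a long-format track table into one :class:`MouseDataset` per mouse.

    The file must be UTF-8 CSV with header columns ``mouse_id, genotype,
    age_group, dendrite_id, feature_id, session_day, status, x_um, y_um,
    z_um`` (coordinates blank when a feature is absent).  The schedule of
    each mouse is inferred as its sorted distinct session days; statuses
    are normalised case-insensitively.  Row order does not matter.

    Raises
    ------
    TrackTableError
        On missing columns, unknown status values (the offending row is
        named), or inconsistent genotype/age labels within a mouse.
    """
    df = pd.read_csv(path, dtype={"mouse_id": str, "dendrite_id": str, "feature_id": str})
    missing = [c for c in TRACK_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise TrackTableError(f"track table missing required columns: {missing}")

    df = df.copy()
    df["status"] = df["status"].astype(str).str.strip().str.lower()
    bad = ~df["status"].isin(STATUSES)
    if bad.any():
        i = int(df.index[bad][0])
        raise TrackTableError(
            f"row {i}: status {df.loc[i, 'status']!r} not in {STATUSES}"
        )

    datasets: list[MouseDataset] = []
    for mouse_id, mdf in df.groupby("mouse_id", sort=True):
        for col in ("genotype", "age_group"):
            vals = mdf[col].unique()
            if len(vals) != 1:
                raise TrackTableError(
                    f"mouse {mouse_id!r}: inconsistent {col} values {sorted(map(str, vals))}"
                )
        schedule = ImagingSchedule(tuple(sorted(mdf["session_day"].unique())))
        dendrites: list[DendriteRecord] = []
        for dendrite_id, ddf in mdf.groupby("dendrite_id", sort=True):
            tracks: list[FeatureTrack] = []
            for feature_id, fdf in ddf.groupby("feature_id", sort=True):
                status_by_session: dict[int, str] = {}
                position_by_session: dict[int, tuple[float, float, float]] = {}
                for _, row in fdf.iterrows():
                    day = int(row["session_day"])
                    status_by_session[day] = row["status"]
                    pos = _position_tuple((row["x_um"], row["y_um"], row["z_um"]))
                    if pos is not None:
                        position_by_session[day] = pos
                tracks.append(
                    FeatureTrack(
                        feature_id=str(feature_id),
                        dendrite_id=str(dendrite_id),
                        status_by_session=status_by_session,
                        position_by_session=position_by_session,
                    )
                )
            seg = ddf["segment_length_um"].iloc[0] if "segment_length_um" in ddf else None
            if seg is not None and (isinstance(seg, float) and math.isnan(seg)):
                seg = None
            dendrites.append(
                DendriteRecord(
                    dendrite_id=str(dendrite_id),
                    mouse_id=str(mouse_id),
                    tracks=tracks,
                    segment_length_um=None if seg is None else float(seg),
                )
            )
        datasets.append(
            MouseDataset(
                mouse_id=str(mouse_id),
                genotype=str(mdf["genotype"].iloc[0]),
                age_group=str(mdf["age_group"].iloc[0]),
                schedule=schedule,
                dendrites=dendrites,
            )
        )
    return datasets


def write_track_table(datasets: Iterable[MouseDataset], path) -> None:
    """Write datasets as a tidy CSV re-readable by :func:`read_track_table`.

    Statuses are written in lowercase canonical form; coordinates are
    blank for sessions without a recorded position.  An empty collection
    yields a header-only file.  Includes a ``segment_length_um`` column
    when any dendrite carries a length.
    """
    rows = []
    any_length = False
    for ds in datasets:
        for dend in ds.dendrites:
            if dend.segment_length_um is not None:
                any_length = True
            for tr in dend.tracks:
                for day in ds.schedule:
                    pos = tr.position_by_session.get(day)
                    rows.append(
                        {
                            "mouse_id": ds.mouse_id,
                            "genotype": ds.genotype,
                            "age_group": ds.age_group,
                            "dendrite_id": dend.dendrite_id,
                            "feature_id": tr.feature_id,
                            "session_day": day,
                            "status": tr.status_by_session[day],
                            "x_um": None if pos is None else pos[0],
                            "y_um": None if pos is None else pos[1],
                            "z_um": None if pos is None else pos[2],
                            "segment_length_um": dend.segment_length_um,
                        }
                    )
    columns = TRACK_TABLE_COLUMNS + (["segment_length_um"] if any_length else [])
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_dataset`: errors, warnings, and counts."""

    mouse_id: str
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    n_day0_features: int = 0
    day0_status_counts: dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_dataset(dataset: MouseDataset) -> ValidationReport:
    """Check a dataset against the schedule/status contracts.

    Errors: a track missing a scheduled session, an unknown status, a
    track absent at every session, duplicate feature ids.  Warning: fewer
    than 150 features scored non-absent at day 0 (the conventional
    minimum per animal).  The dataset is never mutated.
    """
    rep = ValidationReport(mouse_id=dataset.mouse_id)
    days = set(dataset.schedule)
    seen_ids: set[str] = set()
    day0 = dataset.schedule.session_days[0]
    counts = {s: 0 for s in STATUSES}
    for tr in dataset.iter_tracks():
        key = (tr.dendrite_id, tr.feature_id)
        if key in seen_ids:
            rep.errors.append(f"duplicate feature {tr.feature_id!r} in dendrite {tr.dendrite_id!r}")
        seen_ids.add(key)
        track_days = set(tr.status_by_session)
        if track_days != days:
            miss = sorted(days - track_days)
            extra = sorted(track_days - days)
            rep.errors.append(
                f"feature {tr.feature_id!r}: sessions do not match schedule"
                + (f" (missing {miss})" if miss else "")
                + (f" (extra {extra})" if extra else "")
            )
        for day, st in tr.status_by_session.items():
            if st not in STATUSES:
                rep.errors.append(
                    f"feature {tr.feature_id!r} day {day}: unknown status {st!r}"
                )
        if all(s == "absent" for s in tr.status_by_session.values()):
            rep.errors.append(f"feature {tr.feature_id!r}: absent at every session")
        st0 = tr.status_by_session.get(day0)
        if st0 in counts:
            counts[st0] += 1
    rep.day0_status_counts = counts
    rep.n_day0_features = counts["present"] + counts["filopodia"]
    if rep.n_day0_features < MIN_PROTRUSIONS:
        rep.warnings.append(
            f"{rep.n_day0_features} day-0 features is below the {MIN_PROTRUSIONS} minimum"
        )
    return rep
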