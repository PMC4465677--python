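"""Camera-trap observation data model.

Raw image records (site, timestamp, species, age, sex) are reduced to
weekly detection histories: a site x week matrix of observation codes with
a parallel matrix of sampling effort (days the camera was active in each
week, 0-7).  Observation codes are

* binary histories: ``0`` no detection, ``1`` species detected;
* multistate histories: ``0`` none, ``1`` species detected but no adult
  male, ``2`` adult male detected (code 2 subsumes 1 within a week);
* ``-1`` marks weeks with zero effort (camera inoperative), which are
  treated as missing by every downstream likelihood.

Seasons are blocks of consecutive weeks shared by all sites; weeks are
7-day blocks counted from each season's first day, with a trailing block
of fewer than 7 days kept at its true length.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, replace
from datetime import date, datetime, timedelta
from typing import Iterable, Sequence

import numpy as np

SPECIES = ("rusa", "red")
AGES = ("adult", "juvenile")
SEXES = ("male", "female", "unknown")

MISSING = -1


@dataclass(frozen=True, order=True)
class ImageRecord:
    """One independent camera-trap image event."""

    site_id: str
    timestamp: datetime
    species: str
    age: str = "adult"
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.age not in AGES:
            raise ValueError(f"unknown age class {self.age!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")

    @property
    def is_adult_male(self) -> bool:
        return self.age == "adult" and self.sex == "male"


@dataclass(frozen=True)
class Season:
    """A contiguous block of weekly occasions.

    ``label`` is the season level ('winter' or 'summer') shared across
    years; parameters in the occupancy models are tied to the level, not
    the year.  ``start`` anchors week boundaries on the calendar and is
    only needed when aggregating raw records.
    """

    label: str
    year: int
    first_week: int
    n_weeks: int
    start: date | None = None

    def __post_init__(self) -> None:
        if self.label not in ("winter", "summer"):
            raise ValueError(f"season label must be winter/summer, got {self.label!r}")
        if self.n_weeks < 1:
            raise ValueError("season must contain at least one week")

    @property
    def week_slice(self) -> slice:
        return slice(self.first_week, self.first_week + self.n_weeks)


@dataclass(frozen=True)
class SeasonLayout:
    """Ordered, contiguous, non-overlapping seasons shared by all sites."""

    seasons: tuple[Season, ...]

    def __post_init__(self) -> None:
        expected = 0
        for s in self.seasons:
            if s.first_week != expected:
                raise ValueError(
                    f"season {s.label} {s.year}: weeks not contiguous "
                    f"(first_week {s.first_week}, expected {expected})"
                )
            expected += s.n_weeks

    @classmethod
    def from_lengths(
        cls,
        labels_years: Sequence[tuple[str, int]],
        n_weeks: int | Sequence[int],
        starts: Sequence[date] | None = None,
    ) -> "SeasonLayout":
        if isinstance(n_weeks, int):
            n_weeks = [n_weeks] * len(labels_years)
        seasons = []
        first = 0
        for i, ((label, year), nw) in enumerate(zip(labels_years, n_weeks)):
            start = starts[i] if starts is not None else None
            seasons.append(Season(label, year, first, nw, start))
            first += nw
        return cls(tuple(seasons))

    @property
    def total_weeks(self) -> int:
        return sum(s.n_weeks for s in self.seasons)

    @property
    def n_seasons(self) -> int:
        return len(self.seasons)

    def week_labels(self) -> np.ndarray:
        """Season level ('winter'/'summer') of each weekly occasion."""
        out = np.empty(self.total_weeks, dtype=object)
        for s in self.seasons:
            out[s.week_slice] = s.label
        return out

    def week_season_index(self) -> np.ndarray:
        """Index of the season (primary period) containing each week."""
        out = np.empty(self.total_weeks, dtype=int)
        for i, s in enumerate(self.seasons):
            out[s.week_slice] = i
        return out

    def locate(self, ts: datetime) -> tuple[int, int] | None:
        """(season index, global week index) of a timestamp, or None."""
        d = ts.date()
        for i, s in enumerate(self.seasons):
            if s.start is None:
                raise ValueError("season start dates required to locate timestamps")
            end = s.start + timedelta(days=7 * s.n_weeks)
            if s.start <= d < end:
                week = (d - s.start).days // 7
                return i, s.first_week + min(week, s.n_weeks - 1)
        return None


@dataclass
class DetectionHistory:
    """Site x weekly-occasion observation matrix with effort.

    ``observations[i, w]`` holds the code for site ``i`` in week ``w``;
    ``effort[i, w]`` the number of active camera days (0-7).  The
    invariant ``observations == MISSING`` exactly where ``effort == 0``
    is enforced at construction.
    """

    site_ids: list[str]
    layout: SeasonLayout
    observations: np.ndarray
    effort: np.ndarray
    kind: str = "binary"  # 'binary' | 'multistate'
    species: str | None = None

    def __post_init__(self) -> None:
        self.observations = np.asarray(self.observations, dtype=int)
        self.effort = np.asarray(self.effort, dtype=int)
        n, w = self.observations.shape
        if self.effort.shape != (n, w):
            raise ValueError("observations and effort shapes differ")
        if len(self.site_ids) != n:
            raise ValueError("site_ids length does not match observations")
        if w != self.layout.total_weeks:
            raise ValueError(
                f"layout declares {self.layout.total_weeks} weeks, matrix has {w}"
            )
        if np.any((self.effort == 0) != (self.observations == MISSING)):
            raise ValueError("observations must be -1 exactly where effort is 0")
        codes = {-1, 0, 1} if self.kind == "binary" else {-1, 0, 1, 2}
        if not set(np.unique(self.observations)) <= codes:
            raise ValueError(f"invalid codes for kind={self.kind!r}")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def season_block(self, season_index: int) -> np.ndarray:
        return self.observations[:, self.layout.seasons[season_index].week_slice]

    def binarised(self) -> "DetectionHistory":
        """Collapse multistate codes to detected / not detected."""
        obs = np.where(self.observations > 0, 1, self.observations)
        return replace(self, observations=obs, kind="binary")

    def camera_days(self, season_index: int) -> int:
        return int(self.effort[:, self.layout.seasons[season_index].week_slice].sum())


@dataclass(frozen=True)
class TwoSpeciesHistory:
    """Paired binary weekly histories for two species on the same grid."""

    a: DetectionHistory
    b: DetectionHistory

    def __post_init__(self) -> None:
        if self.a.site_ids != self.b.site_ids:
            raise ValueError("species histories cover different sites")
        if self.a.layout != self.b.layout:
            raise ValueError("species histories use different layouts")
        if self.a.kind != "binary" or self.b.kind != "binary":
            raise ValueError("two-species histories must be binary")


def filter_independent_images(
    records: Iterable[ImageRecord],
    window: timedelta = timedelta(minutes=5),
) -> list[ImageRecord]:
    """Drop consecutive non-independent images.

    Within each (site, species) stream, a record closer than ``window``
    to the previously *retained* record of that stream is discarded (the
    first image of a burst anchors the window).  Input order is
    preserved; the operation is idempotent.
    """
    recs = list(records)
    order = sorted(range(len(recs)), key=lambda i: (recs[i].site_id, recs[i].species, recs[i].timestamp, i))
    last: dict[tuple[str, str], datetime] = {}
    keep = np.zeros(len(recs), dtype=bool)
    for i in order:
        rec = recs[i]
        key = (rec.site_id, rec.species)
        anchor = last.get(key)
        if anchor is not None and rec.timestamp - anchor < window:
            continue
        last[key] = rec.timestamp
        keep[i] = True
    return [r for i, r in enumerate(recs) if keep[i]]


def read_image_csv(path) -> tuple[list[ImageRecord], list[str]]:
    """Read raw image records from CSV.

    Expected columns: site_id, datetime (ISO-8601), species, age, sex.
    Rows with unparseable timestamps or out-of-vocabulary categories are
    rejected; the second return value reports them by line.
    """
    records: list[ImageRecord] = []
    rejected: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"site_id", "datetime", "species"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: need columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                ts = datetime.fromisoformat(row["datetime"])
                records.append(
                    ImageRecord(
                        site_id=row["site_id"],
                        timestamp=ts,
                        species=row["species"],
                        age=row.get("age") or "adult",
                        sex=row.get("sex") or "unknown",
                    )
                )
            except (ValueError, KeyError) as exc:
                rejected.append(f"line {lineno}: {exc}")
    return records, rejected


def _effort_matrix(effort_log, site_ids: list[str], total_weeks: int) -> np.ndarray:
    effort = np.asarray(effort_log, dtype=int)
    if effort.shape != (len(site_ids), total_weeks):
        raise ValueError(
            f"effort shape {effort.shape} does not match "
            f"({len(site_ids)}, {total_weeks})"
        )
    if effort.min() < 0 or effort.max() > 7:
        raise ValueError("effort must be active days in 0..7")
    return effort


def aggregate_weekly(
    records: Iterable[ImageRecord],
    layout: SeasonLayout,
    effort_log,
    site_ids: list[str],
    species: str = "rusa",
    multistate: bool = False,
) -> DetectionHistory:
    """Aggregate independence-filtered records to a weekly history.

    Binary: code 1 iff >=1 record of ``species`` in the site-week.
    Multistate (rusa only): code 2 iff >=1 adult-male record, else 1 iff
    >=1 other record of the species.  Weeks with zero effort are coded
    missing regardless of records; records at unknown sites or outside
    the layout's date range are discarded with a warning.
    """
    effort = _effort_matrix(effort_log, site_ids, layout.total_weeks)
    obs = np.where(effort == 0, MISSING, 0)
    index = {s: i for i, s in enumerate(site_ids)}
    dropped = 0
    for rec in records:
        if rec.species != species:
            continue
        if rec.site_id not in index:
            dropped += 1
            continue
        loc = layout.locate(rec.timestamp)
        if loc is None:
            dropped += 1
            continue
        _, week = loc
        i = index[rec.site_id]
        if effort[i, week] == 0:
            continue
        if multistate:
            code = 2 if rec.is_adult_male else 1
            obs[i, week] = max(obs[i, week], code)
        else:
            obs[i, week] = 1
    if dropped:
        warnings.warn(
            f"{dropped} record(s) outside the season layout or site list "
            "were discarded",
            stacklevel=2,
        )
    return DetectionHistory(
        site_ids=list(site_ids),
        layout=layout,
        observations=obs,
        effort=effort,
        kind="multistate" if multistate else "binary",
        species=species,
    )


def subset_seasons(history: DetectionHistory, indices: Sequence[int]) -> DetectionHistory:
    """Restrict a history to a subset of seasons (weeks re-indexed from 0)."""
    seasons = []
    cols = []
    first = 0
    for idx in indices:
        s = history.layout.seasons[idx]
        seasons.append(Season(s.label, s.year, first, s.n_weeks, s.start))
        cols.append(np.arange(s.first_week, s.first_week + s.n_weeks))
        first += s.n_weeks
    take = np.concatenate(cols)
    return DetectionHistory(
        site_ids=list(history.site_ids),
        layout=SeasonLayout(tuple(seasons)),
        observations=history.observations[:, take],
        effort=history.effort[:, take],
        kind=history.kind,
        species=history.species,
    )


def naive_occupancy(history: DetectionHistory, season_index: int | None = None) -> float:
    """Proportion of sites with at least one detection.

    ``season_index`` restricts to one season; ``None`` takes the union
    over all seasons (a site counts if it was ever detected).  Detection
    means any code > 0; missing weeks are ignored.  Raises if the chosen
    season has no surveyed weeks at all.
    """
    if season_index is None:
        block = history.observations
    else:
        if not 0 <= season_index < history.layout.n_seasons:
            raise IndexError(f"no season {season_index}")
        block = history.season_block(season_index)
    if np.all(block == MISSING):
        raise ValueError("no surveyed weeks in the requested season")
    detected = (block > 0).any(axis=1)
    return float(detected.sum() / history.n_sites)
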