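"""Camera-trap capture records to two-species detection histories.

Camera stations run for a deployment window; captures are time-stamped
records of one species at one station.  For occupancy analysis the daily
record is pooled into multi-day *occasions* (default 6 trap-days), coded
1 (detected at least once), 0 (camera active, no detection) or missing
(camera inactive for every day of the occasion, the field convention '-').
Capture clock times are separately converted to radians for the circular
activity analysis.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CaptureRecord",
    "Deployment",
    "DetectionPair",
    "pool_occasions",
    "collapse_within_occasion",
    "align_pair",
    "time_to_radians",
    "read_captures",
    "read_deployments",
    "write_matrix",
    "read_matrix",
]

SEASONS = ("summer", "winter")
REGIONS = ("trans_himalaya", "greater_himalaya")


@dataclass(frozen=True)
class CaptureRecord:
    """One time-stamped detection of a species at a camera station."""

    station_id: str
    species: str
    timestamp: _dt.datetime
    season: str | None = None
    region: str | None = None

    def __post_init__(self) -> None:
        if self.season is not None and self.season not in SEASONS:
            raise ValueError(f"unknown season {self.season!r}; expected one of {SEASONS}")
        if self.region is not None and self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; expected one of {REGIONS}")


@dataclass(frozen=True)
class Deployment:
    """Active window of one camera station, dates inclusive."""

    station_id: str
    start_date: _dt.date
    end_date: _dt.date

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValueError(
                f"deployment {self.station_id}: start {self.start_date} after end {self.end_date}"
            )

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1


@dataclass
class DetectionPair:
    """Aligned detection matrices of two species over the same stations.

    ``matrix_A`` (dominant species) and ``matrix_B`` (subordinate) are
    sites x occasions arrays of 0/1 with NaN for missing; the missing
    pattern is identical in both by construction.
    """

    station_ids: list[str]
    matrix_A: np.ndarray
    matrix_B: np.ndarray
    occasion_length_days: int = 6

    def __post_init__(self) -> None:
        self.matrix_A = np.asarray(self.matrix_A, dtype=float)
        self.matrix_B = np.asarray(self.matrix_B, dtype=float)
        if self.matrix_A.shape != self.matrix_B.shape:
            raise ValueError(
                f"matrix shapes differ: {self.matrix_A.shape} vs {self.matrix_B.shape}"
            )
        if len(self.station_ids) != self.matrix_A.shape[0]:
            raise ValueError("station_ids length does not match matrix rows")
        if not np.array_equal(np.isnan(self.matrix_A), np.isnan(self.matrix_B)):
            raise ValueError("missing patterns of the two matrices differ")

    @property
    def n_sites(self) -> int:
        return self.matrix_A.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.matrix_A.shape[1]


def pool_occasions(
    records: list[CaptureRecord],
    deployments: list[Deployment],
    species: str,
    occasion_days: int = 6,
    *,
    vocabulary: set[str] | None = None,
    calendar_anchor: _dt.date | None = None,
) -> tuple[list[str], np.ndarray]:
    """Pool daily captures of one species into an occasion matrix.

    Occasion windows are anchored to each station's own deployment start
    (day 1 of the deployment opens occasion 1), or to a common
    ``calendar_anchor`` date when given.  Occasion ``o`` (0-based) covers
    deployment days ``o*d+1 .. (o+1)*d``.  A trailing partial window with
    at least one active day is kept as a valid occasion; a window with no
    active day is missing (NaN).  Returns the station order and a
    sites x occasions float matrix of 1/0/NaN.

    Raises ``ValueError`` for a record at an unknown station, outside its
    station's deployment window, or (when ``vocabulary`` is given) for a
    species code absent from the vocabulary.
    """
    if occasion_days < 1:
        raise ValueError(f"occasion_days must be >= 1, got {occasion_days}")
    if vocabulary is not None and species not in vocabulary:
        raise ValueError(f"unknown species code {species!r}; not in vocabulary")

    depl = {d.station_id: d for d in deployments}
    if len(depl) != len(deployments):
        raise ValueError("duplicate station_id in deployments")

    for r in records:
        if r.station_id not in depl:
            raise ValueError(f"record at unknown station {r.station_id!r}: {r}")
        d = depl[r.station_id]
        if not (d.start_date <= r.timestamp.date() <= d.end_date):
            raise ValueError(
                f"record outside deployment window of {r.station_id} "
                f"({d.start_date}..{d.end_date}): {r}"
            )
        if vocabulary is not None and r.species not in vocabulary:
            raise ValueError(f"unknown species code {r.species!r} in record {r}")

    stations = sorted(depl)

    def day_index(station: str, date: _dt.date) -> int:
        # 1-based day within the station's occasion frame
        anchor = calendar_anchor if calendar_anchor is not None else depl[station].start_date
        return (date - anchor).days + 1

    n_occ_per_station = {}
    for s in stations:
        last = day_index(s, depl[s].end_date)
        n_occ_per_station[s] = int(np.ceil(last / occasion_days))
    n_occ = max(n_occ_per_station.values())

    counts = np.zeros((len(stations), n_occ))
    active = np.zeros((len(stations), n_occ), dtype=int)
    for i, s in enumerate(stations):
        first = day_index(s, depl[s].start_date)
        last = day_index(s, depl[s].end_date)
        for day in range(first, last + 1):
            if day < 1:
                raise ValueError(
                    f"deployment of {s} starts before the calendar anchor {calendar_anchor}"
                )
            active[i, (day - 1) // occasion_days] += 1

    for r in records:
        if r.species != species:
            continue
        i = stations.index(r.station_id)
        day = day_index(r.station_id, r.timestamp.date())
        counts[i, (day - 1) // occasion_days] += 1

    counts[active == 0] = np.nan
    return stations, collapse_within_occasion(counts)


def collapse_within_occasion(matrix: np.ndarray) -> np.ndarray:
    """Collapse per-occasion capture counts to binary detection.

    Multiple photo captures within one occasion count as a single
    detection: counts >= 1 map to 1; zeros and missing (NaN) pass through.
    """
    m = np.asarray(matrix, dtype=float)
    if np.nanmin(m, initial=0) < 0:
        raise ValueError("negative capture count in occasion matrix")
    out = m.copy()
    out[np.nan_to_num(m) >= 1] = 1.0
    return out


def align_pair(
    stations_a: list[str],
    matrix_a: np.ndarray,
    stations_b: list[str],
    matrix_b: np.ndarray,
    occasion_length_days: int = 6,
) -> DetectionPair:
    """Align two single-species matrices into a :class:`DetectionPair`.

    Station sets must match; missing patterns are unified (an entry
    missing in either species becomes missing in both).
    """
    if set(stations_a) != set(stations_b):
        only_a = sorted(set(stations_a) - set(stations_b))
        only_b = sorted(set(stations_b) - set(stations_a))
        raise ValueError(
            f"station sets differ: only in A {only_a}, only in B {only_b}"
        )
    order = {s: i for i, s in enumerate(stations_b)}
    a = np.asarray(matrix_a, dtype=float).copy()
    b = np.asarray(matrix_b, dtype=float)[[order[s] for s in stations_a]].copy()
    if a.shape != b.shape:
        raise ValueError(f"occasion structures differ: {a.shape} vs {b.shape}")
    miss = np.isnan(a) | np.isnan(b)
    a[miss] = np.nan
    b[miss] = np.nan
    return DetectionPair(list(stations_a), a, b, occasion_length_days)


def time_to_radians(t: _dt.time | _dt.datetime | float | str) -> float:
    """Map a clock time to an angle in [0, 2*pi).

    Accepts a ``time``/``datetime``, an ``HH:MM[:SS]`` string, or a
    number of hours in [0, 24).  Midnight -> 0, 06:00 -> pi/2.
    """
    if isinstance(t, _dt.datetime):
        t = t.time()
    if isinstance(t, str):
        parts = [float(x) for x in t.split(":")]
        hours = parts[0] + parts[1] / 60 + (parts[2] if len(parts) > 2 else 0.0) / 3600
    elif isinstance(t, _dt.time):
        hours = t.hour + t.minute / 60 + t.second / 3600 + t.microsecond / 3.6e9
    else:
        hours = float(t)
    if not 0 <= hours < 24:
        raise ValueError(f"clock time out of range [0, 24h): {t!r}")
    return 2 * np.pi * hours / 24


# ---------------------------------------------------------------------------
# CSV interfaces

def read_captures(path) -> list[CaptureRecord]:
    """Read capture records CSV: station_id,species,datetime[,region,season]."""
    df = pd.read_csv(path)
    required = {"station_id", "species", "datetime"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"capture CSV missing column(s): {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            CaptureRecord(
                station_id=str(row.station_id),
                species=str(row.species),
                timestamp=pd.Timestamp(row.datetime).to_pydatetime(),
                season=getattr(row, "season", None),
                region=getattr(row, "region", None),
            )
        )
    return out


def read_deployments(path) -> list[Deployment]:
    """Read deployments CSV: station_id,start_date,end_date."""
    df = pd.read_csv(path)
    missing = {"station_id", "start_date", "end_date"} - set(df.columns)
    if missing:
        raise ValueError(f"deployment CSV missing column(s): {sorted(missing)}")
    return [
        Deployment(
            str(r.station_id),
            pd.Timestamp(r.start_date).date(),
            pd.Timestamp(r.end_date).date(),
        )
        for r in df.itertuples(index=False)
    ]


def write_matrix(path, stations: list[str], matrix: np.ndarray) -> None:
    """Write a detection matrix CSV, one row per station, NA for missing."""
    cols = [f"occ{j + 1}" for j in range(matrix.shape[1])]
    df = pd.DataFrame(matrix, index=pd.Index(stations, name="station_id"), columns=cols)
    df.to_csv(path, na_rep="NA", float_format="%.0f")


def read_matrix(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, index_col="station_id", na_values=["NA", "-"])
    return [str(s) for s in df.index], df.to_numpy(dtype=float)
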