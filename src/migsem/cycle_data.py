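"""Annual-cycle tracking records: data model, I/O, and derivation rules.

A :class:`TrackRecord` is one tracked individual or population with four
event dates delimiting the annual cycle (departure from the non-breeding
site, arrival at the breeding site, departure from the breeding site,
arrival at the non-breeding site). Derivations follow fixed conventions:

* Day index: days since Jan 1 of the tracking year, with Jan 1 = 1;
  events after Dec 31 continue past 365. Means are linear, not circular.
* The non-breeding period runs from arrival at the first non-breeding
  site to departure from the last non-breeding site, i.e. it wraps to the
  record's own departure date one calendar year later, so the four
  durations always sum to the record's cycle length (365 or 366 days).
* Spring migration distance is measured from the last non-breeding site
  to the breeding site; autumn distance from the breeding site to the
  first non-breeding site.
* Body mass is the sex-specific minimum mass from the trait table, or
  the mean of the female and male minima when sex is unknown.

Rows that violate the record invariants are rejected with a reason and
reported, never silently dropped.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geodesy import GeoPoint, great_circle_km

__all__ = [
    "TRACKING_COLUMNS",
    "TRAIT_COLUMNS",
    "TrackRecord",
    "CycleDerived",
    "SpeciesTraits",
    "RejectedRow",
    "TableReadResult",
    "read_tracking_table",
    "write_tracking_table",
    "read_trait_table",
    "write_trait_table",
    "resolve_body_mass",
    "derive_cycle",
    "derive_table",
    "summarize_timing",
    "paired_t_autumn_vs_spring",
]

logger = logging.getLogger(__name__)

TRACKING_COLUMNS = [
    "record_id",
    "species",
    "level",
    "paper_id",
    "year",
    "sex",
    "capture_site_class",
    "breed_lat",
    "breed_lon",
    "nb_first_lat",
    "nb_first_lon",
    "nb_last_lat",
    "nb_last_lon",
    "dep_nb",
    "arr_b",
    "dep_b",
    "arr_nb",
    "flight_mode",
]

TRAIT_COLUMNS = ["species", "order", "family", "min_mass_female", "min_mass_male"]

_LEVELS = {"individual", "population"}
_SEXES = {"male", "female", "unknown"}
_CAPTURE_CLASSES = {"breeding", "nonbreeding", "stopover"}
_FLIGHT_MODES = {"soaring", "flapping"}


@dataclass(frozen=True)
class SpeciesTraits:
    """Species-level taxonomy and minimum (lean) body masses in grams."""

    species: str
    order: str
    family: str
    min_mass_female: float
    min_mass_male: float

    def __post_init__(self) -> None:
        if self.min_mass_female <= 0 or self.min_mass_male <= 0:
            raise ValueError(f"{self.species}: body masses must be > 0")


@dataclass(frozen=True)
class TrackRecord:
    """One tracked individual or population over a single annual cycle."""

    record_id: str
    species: str
    level: str
    paper_id: str
    year: int
    sex: str
    capture_site_class: str
    breed_lat: float
    breed_lon: float
    nb_first_lat: float
    nb_first_lon: float
    nb_last_lat: float
    nb_last_lon: float
    dep_nb: dt.date
    arr_b: dt.date
    dep_b: dt.date
    arr_nb: dt.date
    flight_mode: str

    def validate(self) -> None:
        """Raise ``ValueError`` with a short reason on the first violation."""
        if self.level not in _LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        if self.sex not in _SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.capture_site_class not in _CAPTURE_CLASSES:
            raise ValueError(f"unknown capture_site_class {self.capture_site_class!r}")
        if self.flight_mode not in _FLIGHT_MODES:
            raise ValueError(f"unknown flight_mode {self.flight_mode!r}")
        for name in ("breed_lat", "nb_first_lat", "nb_last_lat"):
            v = getattr(self, name)
            if not -90.0 <= v <= 90.0:
                raise ValueError(f"{name}={v} outside [-90, 90]")
        for name in ("breed_lon", "nb_first_lon", "nb_last_lon"):
            v = getattr(self, name)
            if not -180.0 <= v <= 180.0:
                raise ValueError(f"{name}={v} outside [-180, 180]")
        if self.breed_lat <= 0:
            raise ValueError("southern-hemisphere breeder")
        if not (self.dep_nb < self.arr_b < self.dep_b < self.arr_nb):
            raise ValueError("event order")


@dataclass(frozen=True)
class CycleDerived:
    """Quantities derived deterministically from one valid record."""

    record_id: str
    species: str
    paper_id: str
    year: int
    sex: str
    capture_site_class: str
    flight_mode: str
    breed_lat: float
    nonbreed_lat_abs: float
    spring_duration: int
    breeding_duration: int
    autumn_duration: int
    nonbreeding_duration: int
    cycle_length: int
    spring_distance: float
    autumn_distance: float
    dep_nb_doy: float
    arr_b_doy: float
    dep_b_doy: float
    arr_nb_doy: float
    body_mass: float


@dataclass(frozen=True)
class RejectedRow:
    row_index: int
    record_id: str
    reason: str


@dataclass
class TableReadResult:
    records: list[TrackRecord] = field(default_factory=list)
    rejected: list[RejectedRow] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _parse_date(raw: str) -> dt.date:
    return dt.date.fromisoformat(str(raw).strip())


def read_tracking_table(path, delimiter: str = ",") -> TableReadResult:
    """Read and validate a tracking table (CSV/TSV, ISO-8601 dates).

    Returns the valid records plus every rejected row with its reason.
    A missing required column is a hard error naming the column.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in TRACKING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tracking table missing required column(s): {missing}")

    result = TableReadResult()
    for idx, row in df.iterrows():
        rid = row["record_id"]
        try:
            rec = TrackRecord(
                record_id=rid,
                species=row["species"],
                level=row["level"],
                paper_id=row["paper_id"],
                year=int(row["year"]),
                sex=row["sex"],
                capture_site_class=row["capture_site_class"],
                breed_lat=float(row["breed_lat"]),
                breed_lon=float(row["breed_lon"]),
                nb_first_lat=float(row["nb_first_lat"]),
                nb_first_lon=float(row["nb_first_lon"]),
                nb_last_lat=float(row["nb_last_lat"]),
                nb_last_lon=float(row["nb_last_lon"]),
                dep_nb=_parse_date(row["dep_nb"]),
                arr_b=_parse_date(row["arr_b"]),
                dep_b=_parse_date(row["dep_b"]),
                arr_nb=_parse_date(row["arr_nb"]),
                flight_mode=row["flight_mode"],
            )
            rec.validate()
        except (ValueError, TypeError) as exc:
            result.rejected.append(RejectedRow(int(idx), rid, str(exc)))
            continue
        result.records.append(rec)

    if result.rejected:
        logger.warning(
            "rejected %d of %d rows: %s",
            len(result.rejected),
            len(df),
            "; ".join(f"row {r.row_index} ({r.record_id}): {r.reason}" for r in result.rejected),
        )
    return result


def write_tracking_table(records: Iterable[TrackRecord], path, delimiter: str = ",") -> None:
    """Write records in the exact dialect :func:`read_tracking_table` reads."""
    rows = []
    for rec in records:
        row = {f.name: getattr(rec, f.name) for f in fields(TrackRecord)}
        for key in ("dep_nb", "arr_b", "dep_b", "arr_nb"):
            row[key] = row[key].isoformat()
        rows.append(row)
    pd.DataFrame(rows, columns=TRACKING_COLUMNS).to_csv(path, sep=delimiter, index=False)


def read_trait_table(path, delimiter: str = ",") -> dict[str, SpeciesTraits]:
    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trait table missing required column(s): {missing}")
    traits: dict[str, SpeciesTraits] = {}
    for _, row in df.iterrows():
        sp = str(row["species"])
        if sp in traits:
            raise ValueError(f"duplicate species in trait table: {sp!r}")
        traits[sp] = SpeciesTraits(
            species=sp,
            order=str(row["order"]),
            family=str(row["family"]),
            min_mass_female=float(row["min_mass_female"]),
            min_mass_male=float(row["min_mass_male"]),
        )
    return traits


def write_trait_table(traits: Mapping[str, SpeciesTraits], path, delimiter: str = ",") -> None:
    rows = [
        {
            "species": t.species,
            "order": t.order,
            "family": t.family,
            "min_mass_female": t.min_mass_female,
            "min_mass_male": t.min_mass_male,
        }
        for t in traits.values()
    ]
    pd.DataFrame(rows, columns=TRAIT_COLUMNS).to_csv(path, sep=delimiter, index=False)


def resolve_body_mass(record: TrackRecord, traits: SpeciesTraits | Mapping[str, SpeciesTraits]) -> float:
    """Minimum body mass in grams for a record, by its reported sex."""
    if isinstance(traits, Mapping):
        try:
            traits = traits[record.species]
        except KeyError:
            raise KeyError(f"species {record.species!r} absent from trait table") from None
    if record.sex == "female":
        return traits.min_mass_female
    if record.sex == "male":
        return traits.min_mass_male
    return 0.5 * (traits.min_mass_female + traits.min_mass_male)


def _same_date_next_year(d: dt.date) -> dt.date:
    # Feb 29 maps to Feb 28 of the following (non-leap) year
    try:
        return d.replace(year=d.year + 1)
    except ValueError:
        return d.replace(year=d.year + 1, day=28)


def _day_index(d: dt.date, anchor_year: int) -> int:
    """Days since Jan 1 of *anchor_year*, Jan 1 = 1; continues past 365."""
    return (d - dt.date(anchor_year, 1, 1)).days + 1


def derive_cycle(record: TrackRecord, traits: SpeciesTraits | Mapping[str, SpeciesTraits]) -> CycleDerived:
    """Durations, distances, day indices, and body mass for one record.

    The non-breeding duration wraps from the autumn arrival to the same
    departure date one year later, so the four durations sum exactly to
    the cycle length (365 or 366 days).
    """
    record.validate()
    next_dep = _same_date_next_year(record.dep_nb)
    cycle_length = (next_dep - record.dep_nb).days
    spring = (record.arr_b - record.dep_nb).days
    breeding = (record.dep_b - record.arr_b).days
    autumn = (record.arr_nb - record.dep_b).days
    nonbreeding = (next_dep - record.arr_nb).days
    if nonbreeding <= 0:
        raise ValueError("annual cycle longer than one year (non-breeding duration <= 0)")

    breed = GeoPoint(record.breed_lat, record.breed_lon)
    nb_first = GeoPoint(record.nb_first_lat, record.nb_first_lon)
    nb_last = GeoPoint(record.nb_last_lat, record.nb_last_lon)
    anchor = record.dep_nb.year

    return CycleDerived(
        record_id=record.record_id,
        species=record.species,
        paper_id=record.paper_id,
        year=record.year,
        sex=record.sex,
        capture_site_class=record.capture_site_class,
        flight_mode=record.flight_mode,
        breed_lat=record.breed_lat,
        nonbreed_lat_abs=abs(record.nb_last_lat),
        spring_duration=spring,
        breeding_duration=breeding,
        autumn_duration=autumn,
        nonbreeding_duration=nonbreeding,
        cycle_length=cycle_length,
        spring_distance=great_circle_km(nb_last, breed),
        autumn_distance=great_circle_km(breed, nb_first),
        dep_nb_doy=float(_day_index(record.dep_nb, anchor)),
        arr_b_doy=float(_day_index(record.arr_b, anchor)),
        dep_b_doy=float(_day_index(record.dep_b, anchor)),
        arr_nb_doy=float(_day_index(record.arr_nb, anchor)),
        body_mass=resolve_body_mass(record, traits),
    )


def derive_table(
    records: Iterable[TrackRecord], traits: Mapping[str, SpeciesTraits]
) -> pd.DataFrame:
    """Derive all records into a tidy DataFrame (one row per record)."""
    derived = [derive_cycle(rec, traits) for rec in records]
    if not derived:
        raise ValueError("no records to derive")
    return pd.DataFrame(
        [{f: getattr(d, f) for f in d.__dataclass_fields__} for d in derived]
    )


_EVENT_COLS = ["dep_nb_doy", "arr_b_doy", "dep_b_doy", "arr_nb_doy"]
_DURATION_COLS = [
    "spring_duration",
    "breeding_duration",
    "autumn_duration",
    "nonbreeding_duration",
]


def _doy_to_date_label(doy: float, year: int = 2001) -> str:
    """Render a (possibly fractional, possibly >365) day index as a date."""
    d = dt.date(year, 1, 1) + dt.timedelta(days=round(doy) - 1)
    return d.strftime("%d %b")


def summarize_timing(
    derived: pd.DataFrame | Sequence[CycleDerived],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-stage timing summary: within species, then across species.

    Returns ``(species_means, grand_summary)``. The grand mean weights
    every species equally regardless of its record count; the SD is the
    SD of the species means. Species with a single record get a NaN SD.
    """
    if not isinstance(derived, pd.DataFrame):
        derived = pd.DataFrame(
            [{f: getattr(d, f) for f in d.__dataclass_fields__} for d in derived]
        )
    if derived.empty:
        raise ValueError("summarize_timing: empty input")
    cols = _EVENT_COLS + _DURATION_COLS
    grp = derived.groupby("species")[cols]
    species_means = grp.mean()
    species_means["n_records"] = grp.size()

    total_duration = float(sum(species_means[c].mean() for c in _DURATION_COLS))
    rows = []
    for col in cols:
        vals = species_means[col]
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else math.nan
        row = {
            "variable": col,
            "grand_mean": mean,
            "sd_across_species": sd,
            "n_species": int(len(vals)),
        }
        if col in _EVENT_COLS:
            row["mean_date"] = _doy_to_date_label(mean)
        if col in _DURATION_COLS:
            row["share_of_cycle_pct"] = 100.0 * mean / total_duration
        rows.append(row)
    return species_means.reset_index(), pd.DataFrame(rows)


def paired_t_autumn_vs_spring(
    derived: pd.DataFrame | Sequence[CycleDerived],
) -> tuple[float, int, float]:
    """Classical paired t test of autumn vs spring migration duration.

    Returns ``(t, df, p)`` with ``df = n - 1`` over individual records.
    """
    if not isinstance(derived, pd.DataFrame):
        derived = pd.DataFrame(
            [{f: getattr(d, f) for f in d.__dataclass_fields__} for d in derived]
        )
    autumn = np.asarray(derived["autumn_duration"], dtype=float)
    spring = np.asarray(derived["spring_duration"], dtype=float)
    n = len(autumn)
    if n < 2:
        raise ValueError("paired t test needs at least 2 records")
    diffs = autumn - spring
    if np.std(diffs, ddof=1) == 0.0:
        # degenerate zero-variance case: t = 0 by the symmetry convention
        if diffs[0] == 0.0:
            return 0.0, n - 1, 1.0
        return math.copysign(math.inf, diffs[0]), n - 1, 0.0
    res = stats.ttest_rel(autumn, spring)
    return float(res.statistic), n - 1, float(res.pvalue)
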