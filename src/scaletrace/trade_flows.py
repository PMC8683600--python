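"""Origin / transit / import role classification and trade-flow aggregation.

Each seizure record carries an ordered route of countries.  The first country
is the shipment origin, the last is the import country (when the route has at
least two stops), and intermediate countries are transit stops.  Roles are
aggregated per country over analysis time intervals, converted to ternary
(barycentric) coordinates for composition plots, and flattened into flow
edge lists from consecutive route positions.

Warehouse and unknown-mode confiscations carry no route information beyond
the seizure site and are excluded from flow aggregation.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .seizure_io import SeizureRecord

__all__ = [
    "ROLES",
    "DEFAULT_INTERVALS",
    "Interval",
    "CountryRoleProfile",
    "classify_country_roles",
    "aggregate_roles",
    "ternary_coordinates",
    "flow_edges",
    "summarize_destinations",
    "summarize_detection_methods",
]

ROLES = ("origin", "transit", "import")


@dataclass(frozen=True)
class Interval:
    """A closed analysis interval in calendar time."""

    label: str
    start: _dt.date
    end: _dt.date

    def contains(self, date: _dt.date) -> bool:
        return self.start <= date <= self.end


# The study windows: three 3-year bins then a final bin truncated at the end
# of September 2021 where reporting stops.
DEFAULT_INTERVALS = (
    Interval("2010-2012", _dt.date(2010, 1, 1), _dt.date(2012, 12, 31)),
    Interval("2013-2015", _dt.date(2013, 1, 1), _dt.date(2015, 12, 31)),
    Interval("2016-2018", _dt.date(2016, 1, 1), _dt.date(2018, 12, 31)),
    Interval("2019-2021", _dt.date(2019, 1, 1), _dt.date(2021, 9, 30)),
)


@dataclass
class CountryRoleProfile:
    """Per-country role counts within one interval, with normalised proportions."""

    country: str
    interval: str
    n_origin: int
    n_transit: int
    n_import: int

    @property
    def total(self) -> int:
        return self.n_origin + self.n_transit + self.n_import

    @property
    def proportions(self) -> tuple[float, float, float]:
        if self.total == 0:
            raise ValueError(f"no role counts for {self.country} in {self.interval}")
        t = float(self.total)
        return (self.n_origin / t, self.n_transit / t, self.n_import / t)


def classify_country_roles(record: SeizureRecord) -> list[tuple[str, str]]:
    """Assign origin/transit/import roles along one record's route.

    A single-location route yields only an origin; two locations yield origin
    and import; longer routes add transit roles for intermediate countries.
    Each country is counted at most once per role per record even if it
    appears at several route positions.
    """
    route = record.route
    roles: list[tuple[str, str]] = [(route[0], "origin")]
    if len(route) >= 2:
        roles.append((route[-1], "import"))
    seen_transit: set[str] = set()
    for country in route[1:-1]:
        if country not in seen_transit:
            roles.append((country, "transit"))
            seen_transit.add(country)
    return roles


def _flow_usable(record: SeizureRecord) -> bool:
    return record.mode not in ("warehouse", "unknown")


def aggregate_roles(
    records: Iterable[SeizureRecord],
    intervals: Sequence[Interval] = DEFAULT_INTERVALS,
    include_all_modes: bool = False,
) -> list[CountryRoleProfile]:
    """Count origin/transit/import roles per country per interval.

    Warehouse and unknown-mode records are excluded unless
    ``include_all_modes`` is set.  Records dated outside every interval are
    dropped (an interval list covering the study period avoids this).
    Profiles are only emitted for (country, interval) pairs with at least one
    role occurrence.
    """
    counts: dict[tuple[str, str], dict[str, int]] = {}
    for r in records:
        if not include_all_modes and not _flow_usable(r):
            continue
        date = r.seizure_date.approx()
        interval = next((iv for iv in intervals if iv.contains(date)), None)
        if interval is None:
            continue
        for country, role in classify_country_roles(r):
            key = (country, interval.label)
            counts.setdefault(key, {role_name: 0 for role_name in ROLES})[role] += 1
    return [
        CountryRoleProfile(
            country=country,
            interval=label,
            n_origin=c["origin"],
            n_transit=c["transit"],
            n_import=c["import"],
        )
        for (country, label), c in sorted(counts.items())
    ]


def ternary_coordinates(
    profile: CountryRoleProfile | tuple[float, float, float],
) -> tuple[float, float, float]:
    """Barycentric (origin, transit, import) coordinates summing to one."""
    if isinstance(profile, CountryRoleProfile):
        counts = (profile.n_origin, profile.n_transit, profile.n_import)
    else:
        counts = tuple(profile)
    total = float(sum(counts))
    if total <= 0:
        raise ValueError("cannot place a zero-count profile on the ternary simplex")
    return tuple(c / total for c in counts)  # type: ignore[return-value]


def flow_edges(
    records: Iterable[SeizureRecord],
    intervals: Sequence[Interval] = DEFAULT_INTERVALS,
) -> pd.DataFrame:
    """Directed edge list from consecutive route positions.

    Columns: ``from_country, to_country, interval, mass_kg, n_records``.  The
    record's full known mass is attributed to every leg it travels.
    """
    rows = []
    for r in records:
        if not _flow_usable(r) or len(r.route) < 2:
            continue
        date = r.seizure_date.approx()
        interval = next((iv for iv in intervals if iv.contains(date)), None)
        if interval is None:
            continue
        mass = r.total_mass_kg if r.mass_known else 0.0
        for a, b in zip(r.route[:-1], r.route[1:]):
            rows.append(
                {"from_country": a, "to_country": b, "interval": interval.label, "mass_kg": mass}
            )
    if not rows:
        return pd.DataFrame(columns=["from_country", "to_country", "interval", "mass_kg", "n_records"])
    frame = pd.DataFrame(rows)
    out = (
        frame.groupby(["from_country", "to_country", "interval"], as_index=False)
        .agg(mass_kg=("mass_kg", "sum"), n_records=("mass_kg", "size"))
        .sort_values(["interval", "from_country", "to_country"], ignore_index=True)
    )
    return out


def summarize_destinations(records: Iterable[SeizureRecord]) -> pd.DataFrame:
    """Total destined mass and record count per import country.

    Only records with a route of length >= 2 have an import country; masses of
    mass-unknown records contribute zero but the record is still counted.
    Sorted by descending mass.
    """
    rows = []
    for r in records:
        if len(r.route) < 2:
            continue
        rows.append(
            {
                "country": r.route[-1],
                "mass_kg": r.total_mass_kg if r.mass_known else 0.0,
            }
        )
    if not rows:
        return pd.DataFrame(columns=["country", "mass_kg", "n_records"])
    frame = pd.DataFrame(rows)
    return (
        frame.groupby("country", as_index=False)
        .agg(mass_kg=("mass_kg", "sum"), n_records=("mass_kg", "size"))
        .sort_values("mass_kg", ascending=False, ignore_index=True)
    )


def summarize_detection_methods(records: Iterable[SeizureRecord]) -> pd.DataFrame:
    """Mass and incident counts per (seizure country, detection method).

    Records with unknown detection method are excluded.  A grand-total row
    (country and method ``"total"``) is appended.
    """
    rows = [
        {
            "country": r.seizure_country,
            "method": r.detection_method,
            "mass_kg": r.total_mass_kg if r.mass_known else 0.0,
        }
        for r in records
        if r.detection_method != "unknown"
    ]
    if not rows:
        return pd.DataFrame(columns=["country", "method", "mass_kg", "n_incidents"])
    frame = pd.DataFrame(rows)
    table = (
        frame.groupby(["country", "method"], as_index=False)
        .agg(mass_kg=("mass_kg", "sum"), n_incidents=("mass_kg", "size"))
        .sort_values(["method", "country"], ignore_index=True)
    )
    total = pd.DataFrame(
        [
            {
                "country": "total",
                "method": "total",
                "mass_kg": table["mass_kg"].sum(),
                "n_incidents": int(table["n_incidents"].sum()),
            }
        ]
    )
    return pd.concat([table, total], ignore_index=True)
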