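"""Seizure-record data model, CSV I/O, unit harmonisation and multi-source deduplication.

A *seizure record* is one reported confiscation event of wildlife derivatives
(here: pangolin scales, meat, claws and other parts).  The same event is often
reported by several monitoring databases with slightly different dates and
masses, so the module provides tolerance-based record linkage against a
designated reference database, resolving mass conflicts by keeping the lowest
reported mass (the conservative choice for downstream quantity estimates).

Masses are harmonised to kilograms at parse time; dates may be partial
(year-only or year-month) because open-source seizure reports frequently omit
the day.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "DERIVATIVE_KINDS",
    "TRANSPORT_MODES",
    "DETECTION_METHODS",
    "PartialDate",
    "SeizureRecord",
    "DedupKey",
    "MergeEvent",
    "normalize_country",
    "parse_mass",
    "read_seizures",
    "write_seizures",
    "deduplicate",
    "classify_transport_mode",
    "total_mass",
]

DERIVATIVE_KINDS = ("scales", "meat", "claws", "other")
TRANSPORT_MODES = ("air", "land", "sea", "warehouse", "unknown")
DETECTION_METHODS = (
    "intelligence",
    "routine_inspection",
    "scanner",
    "sniffer_dogs",
    "unknown",
)

# kg per unit; parsed case-insensitively
_UNIT_TO_KG = {
    "kg": 1.0,
    "kgs": 1.0,
    "kilogram": 1.0,
    "kilograms": 1.0,
    "g": 0.001,
    "gram": 0.001,
    "grams": 0.001,
    "t": 1000.0,
    "tonne": 1000.0,
    "tonnes": 1000.0,
    "ton": 1000.0,
    "tons": 1000.0,
    "lb": 0.45359237,
    "lbs": 0.45359237,
}

_MASS_RE = re.compile(r"^\s*(-?[\d][\d,]*\.?\d*)\s*([a-zA-Z]*)\s*$")

# ISO-3166 alpha-3 lookup for countries and territories seen in Nigeria-linked
# pangolin trade reporting, plus common aliases.  Territories that act as
# distinct trade nodes (e.g. Hong Kong) keep their own codes.
_COUNTRY_ALIASES = {
    "nigeria": "NGA",
    "china": "CHN",
    "hong kong": "HKG",
    "hong kong sar": "HKG",
    "vietnam": "VNM",
    "viet nam": "VNM",
    "cameroon": "CMR",
    "gabon": "GAB",
    "niger": "NER",
    "ghana": "GHA",
    "kenya": "KEN",
    "malaysia": "MYS",
    "turkey": "TUR",
    "france": "FRA",
    "netherlands": "NLD",
    "the netherlands": "NLD",
    "singapore": "SGP",
    "thailand": "THA",
    "laos": "LAO",
    "lao pdr": "LAO",
    "lao people's democratic republic": "LAO",
    "cambodia": "KHM",
    "cote d'ivoire": "CIV",
    "côte d'ivoire": "CIV",
    "ivory coast": "CIV",
    "democratic republic of the congo": "COD",
    "democratic republic of congo": "COD",
    "dr congo": "COD",
    "drc": "COD",
    "republic of congo": "COG",
    "republic of the congo": "COG",
    "congo": "COG",
    "central african republic": "CAF",
    "car": "CAF",
    "benin": "BEN",
    "togo": "TGO",
    "guinea": "GIN",
    "india": "IND",
    "indonesia": "IDN",
    "south africa": "ZAF",
    "zimbabwe": "ZWE",
    "uganda": "UGA",
}

_ALPHA3_RE = re.compile(r"^[A-Z]{3}$")


def normalize_country(name: str) -> str:
    """Return the ISO-3166 alpha-3 code for a country name or code.

    Already-valid three-letter codes pass through unchanged; names are matched
    case-insensitively against an internal alias table.
    """
    token = name.strip()
    if _ALPHA3_RE.match(token.upper()) and (
        token.upper() in _COUNTRY_ALIASES.values() or token.lower() not in _COUNTRY_ALIASES
    ):
        return token.upper()
    key = token.lower()
    if key in _COUNTRY_ALIASES:
        return _COUNTRY_ALIASES[key]
    raise ValueError(f"unrecognised country or territory: {name!r}")


def parse_mass(text: str) -> float:
    """Parse a mass string with optional unit suffix into kilograms.

    Accepted units: kg (default), g, t/tonnes, lb.  The result is rounded to
    three decimals (gram precision).  Negative masses raise ``ValueError``.
    """
    m = _MASS_RE.match(text)
    if not m:
        raise ValueError(f"unparseable mass: {text!r}")
    value = float(m.group(1).replace(",", ""))
    unit = m.group(2).lower() or "kg"
    if unit not in _UNIT_TO_KG:
        raise ValueError(f"unknown mass unit {unit!r} in {text!r}")
    kg = value * _UNIT_TO_KG[unit]
    if kg < 0:
        raise ValueError(f"negative mass: {text!r}")
    return round(kg, 3)


@dataclass(frozen=True, order=True)
class PartialDate:
    """A calendar date whose month and day may be unknown.

    Year is mandatory.  ``approx()`` maps the partial date to a concrete date
    (mid-year / mid-month) so that date-window comparisons remain defined for
    incompletely dated records.
    """

    year: int
    month: int | None = None
    day: int | None = None

    def __post_init__(self) -> None:
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None:
            if self.month is None:
                raise ValueError("day given without month")
            _dt.date(self.year, self.month, self.day)  # validates

    @classmethod
    def parse(cls, text: str) -> "PartialDate":
        token = text.strip()
        parts = token.split("-")
        if not 1 <= len(parts) <= 3 or not all(p.isdigit() for p in parts):
            raise ValueError(f"malformed date: {text!r} (expected YYYY[-MM[-DD]])")
        year = int(parts[0])
        if year < 1900 or year > 2100:
            raise ValueError(f"implausible year in date: {text!r}")
        month = int(parts[1]) if len(parts) > 1 else None
        day = int(parts[2]) if len(parts) > 2 else None
        return cls(year, month, day)

    def approx(self) -> _dt.date:
        return _dt.date(self.year, self.month or 6, self.day or 15)

    def isoformat(self) -> str:
        out = f"{self.year:04d}"
        if self.month is not None:
            out += f"-{self.month:02d}"
        if self.day is not None:
            out += f"-{self.day:02d}"
        return out


@dataclass
class SeizureRecord:
    """One confiscation event of pangolin derivatives.

    ``route`` is the ordered list of implicated countries (alpha-3 codes) from
    shipment origin to final destination; ``seizure_country`` is where the
    confiscation happened and must lie on the route.  ``masses`` maps
    derivative kind (scales/meat/claws/other) to kilograms; records known only
    by item counts (e.g. "23 sacks") carry ``mass_known=False`` and an
    ``item_count``.
    """

    record_id: str
    seizure_date: PartialDate
    masses: dict[str, float] = field(default_factory=dict)
    mass_known: bool = True
    route: list[str] = field(default_factory=list)
    seizure_country: str = ""
    mode: str = "unknown"
    detection_method: str = "unknown"
    suspects_arrested: int | None = None
    prosecuted: int | None = None
    source_db: str = ""
    co_seized: str = ""
    item_count: int | None = None

    def __post_init__(self) -> None:
        for kind, kg in self.masses.items():
            if kind not in DERIVATIVE_KINDS:
                raise ValueError(f"unknown derivative kind {kind!r}")
            if kg < 0:
                raise ValueError(f"negative mass for {kind!r}: {kg}")
        if self.mass_known != bool(self.masses):
            raise ValueError("mass_known must be True exactly when mass fields are present")
        if not self.route:
            raise ValueError("route must contain at least one country")
        self.route = [normalize_country(c) for c in self.route]
        self.seizure_country = normalize_country(self.seizure_country)
        if self.seizure_country not in self.route:
            raise ValueError(
                f"seizure country {self.seizure_country} not on route {self.route}"
            )
        if self.mode not in TRANSPORT_MODES:
            raise ValueError(f"unknown transport mode {self.mode!r}")
        if self.mode == "warehouse" and len(self.route) != 1:
            raise ValueError("warehouse seizures have a single-country route")
        if self.detection_method not in DETECTION_METHODS:
            raise ValueError(f"unknown detection method {self.detection_method!r}")
        for label, v in (("suspects_arrested", self.suspects_arrested), ("prosecuted", self.prosecuted)):
            if v is not None and v < 0:
                raise ValueError(f"{label} must be non-negative")

    @property
    def total_mass_kg(self) -> float:
        return sum(self.masses.values())

    @property
    def year(self) -> int:
        return self.seizure_date.year


def total_mass(records: Iterable[SeizureRecord], kind: str | None = None) -> float:
    """Total mass in kg across records with known mass (optionally one derivative kind)."""
    out = 0.0
    for r in records:
        if not r.mass_known:
            continue
        out += r.masses.get(kind, 0.0) if kind else r.total_mass_kg
    return out


@dataclass(frozen=True)
class DedupKey:
    """Deterministic blocking key for duplicate detection.

    Buckets the record by seizure country, coarse date window and quantised
    mass (or item count).  Two records can only be duplicates if their keys
    fall in the same or adjacent buckets.
    """

    country: str
    date_bucket: int
    quantity_bucket: int

    @classmethod
    def from_record(
        cls, record: SeizureRecord, date_window: int = 7, mass_rtol: float = 0.10
    ) -> "DedupKey":
        ordinal = record.seizure_date.approx().toordinal()
        if record.mass_known and record.total_mass_kg > 0:
            import math

            q = int(math.log1p(record.total_mass_kg) / max(mass_rtol, 1e-6))
        elif record.item_count is not None:
            q = -record.item_count
        else:
            q = 0
        return cls(record.seizure_country, ordinal // max(date_window, 1), q)


def _masses_compatible(a: SeizureRecord, b: SeizureRecord, rtol: float) -> bool:
    if a.mass_known and b.mass_known:
        ma, mb = a.total_mass_kg, b.total_mass_kg
        if ma == mb == 0:
            return True
        return abs(ma - mb) <= rtol * max(ma, mb)
    if a.item_count is not None and b.item_count is not None:
        return a.item_count == b.item_count
    # one side has mass, the other only a count (or nothing): no quantity
    # evidence either way -> rely on date+country alone
    return True


def records_match(
    a: SeizureRecord,
    b: SeizureRecord,
    date_window: int = 7,
    mass_rtol: float = 0.10,
) -> bool:
    """True when two records plausibly report the same seizure event."""
    if a.seizure_country != b.seizure_country:
        return False
    delta = abs((a.seizure_date.approx() - b.seizure_date.approx()).days)
    if delta > date_window:
        return False
    return _masses_compatible(a, b, mass_rtol)


@dataclass
class MergeEvent:
    kept_id: str
    merged_ids: list[str]
    sources: list[str]
    chosen_mass_kg: float | None
    discarded_masses_kg: list[float]

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)


def deduplicate(
    records: Sequence[SeizureRecord],
    reference_db: str = "TRAFFIC",
    date_window: int = 7,
    mass_rtol: float = 0.10,
) -> tuple[list[SeizureRecord], list[MergeEvent]]:
    """Merge duplicate reports of the same seizure across source databases.

    Records are clustered transitively by :func:`records_match` (same country,
    dates within ``date_window`` days, masses within ``mass_rtol`` relative
    tolerance or equal item counts).  Within each cluster:

    * the representative is the record from ``reference_db`` when present
      (its record id and date are kept), otherwise the first record;
    * when members disagree on mass, the **lowest** reported total mass is
      kept — a conservative rule for downstream quantity estimation;
    * provenance of all members is recorded in the merge log.

    The operation is idempotent: running it on its own output changes nothing.
    """
    n = len(records)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        for j in range(i + 1, n):
            if records_match(records[i], records[j], date_window, mass_rtol):
                union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    merged: list[SeizureRecord] = []
    log: list[MergeEvent] = []
    for idxs in clusters.values():
        members = [records[i] for i in idxs]
        if len(members) == 1:
            merged.append(members[0])
            continue
        ref = next((m for m in members if m.source_db == reference_db), members[0])
        with_mass = [m for m in members if m.mass_known]
        if with_mass:
            lowest = min(with_mass, key=lambda m: m.total_mass_kg)
            masses = dict(lowest.masses)
            mass_known = True
            chosen = lowest.total_mass_kg
            discarded = sorted(m.total_mass_kg for m in with_mass if m is not lowest)
        else:
            masses, mass_known, chosen, discarded = {}, False, None, []
        sources = sorted({m.source_db for m in members if m.source_db})
        keep = replace(
            ref,
            masses=masses,
            mass_known=mass_known,
            source_db="+".join(sources) if sources else ref.source_db,
        )
        merged.append(keep)
        log.append(
            MergeEvent(
                kept_id=ref.record_id,
                merged_ids=sorted(m.record_id for m in members),
                sources=sources,
                chosen_mass_kg=chosen,
                discarded_masses_kg=discarded,
            )
        )
    merged.sort(key=lambda r: (r.seizure_date.approx(), r.record_id))
    return merged, log


def classify_transport_mode(
    legs: Sequence[tuple[str, str, float]], premises: bool = False
) -> str:
    """Classify a shipment's transport mode from its route legs.

    ``legs`` is a sequence of ``(leg_label, mode, extent)`` where ``extent``
    is a distance or rank proxy for leg length.  The shipment takes the mode
    of its **longest** leg.  A premises confiscation with no route information
    is a ``warehouse`` seizure; absent mode information yields ``unknown``.
    """
    if premises and not legs:
        return "warehouse"
    informative = [
        (label, mode, extent)
        for label, mode, extent in legs
        if mode in ("air", "land", "sea")
    ]
    if not informative:
        return "unknown"
    return max(informative, key=lambda leg: leg[2])[1]


# ---------------------------------------------------------------------------
# CSV schema
# ---------------------------------------------------------------------------

CSV_FIELDS = [
    "record_id",
    "seizure_date",
    "mass_scales",
    "mass_meat",
    "mass_claws",
    "mass_other",
    "route",
    "seizure_country",
    "mode",
    "detection_method",
    "suspects_arrested",
    "prosecuted",
    "source_db",
    "co_seized",
    "item_count",
]

_ROUTE_SEP = ">"


def _record_from_row(row: Mapping[str, str]) -> SeizureRecord:
    masses: dict[str, float] = {}
    for kind in DERIVATIVE_KINDS:
        cell = (row.get(f"mass_{kind}") or "").strip()
        if cell:
            masses[kind] = parse_mass(cell)
    route = [c for c in (row.get("route") or "").split(_ROUTE_SEP) if c.strip()]

    def _opt_int(key: str) -> int | None:
        cell = (row.get(key) or "").strip()
        return int(cell) if cell else None

    return SeizureRecord(
        record_id=(row.get("record_id") or "").strip(),
        seizure_date=PartialDate.parse(row.get("seizure_date") or ""),
        masses=masses,
        mass_known=bool(masses),
        route=[c.strip() for c in route],
        seizure_country=(row.get("seizure_country") or "").strip(),
        mode=(row.get("mode") or "unknown").strip() or "unknown",
        detection_method=(row.get("detection_method") or "unknown").strip() or "unknown",
        suspects_arrested=_opt_int("suspects_arrested"),
        prosecuted=_opt_int("prosecuted"),
        source_db=(row.get("source_db") or "").strip(),
        co_seized=(row.get("co_seized") or "").strip(),
        item_count=_opt_int("item_count"),
    )


def read_seizures(path: str | Path) -> tuple[list[SeizureRecord], list[tuple[int, str]]]:
    """Read seizure records from CSV.

    Returns ``(records, rejects)`` where ``rejects`` lists ``(row_number,
    reason)`` for rows that failed validation (malformed dates, negative
    masses, unknown countries, ...).  Row numbers are 1-based including the
    header row.
    """
    path = Path(path)
    records: list[SeizureRecord] = []
    rejects: list[tuple[int, str]] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(CSV_FIELDS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"CSV header missing required columns: {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(_record_from_row(row))
            except (ValueError, KeyError) as exc:
                rejects.append((lineno, str(exc)))
    return records, rejects


def write_seizures(records: Iterable[SeizureRecord], path: str | Path) -> None:
    """Write records to the documented CSV schema (lossless round-trip)."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=CSV_FIELDS)
        writer.writeheader()
        for r in records:
            row = {
                "record_id": r.record_id,
                "seizure_date": r.seizure_date.isoformat(),
                "route": _ROUTE_SEP.join(r.route),
                "seizure_country": r.seizure_country,
                "mode": r.mode,
                "detection_method": r.detection_method,
                "suspects_arrested": "" if r.suspects_arrested is None else r.suspects_arrested,
                "prosecuted": "" if r.prosecuted is None else r.prosecuted,
                "source_db": r.source_db,
                "co_seized": r.co_seized,
                "item_count": "" if r.item_count is None else r.item_count,
            }
            for kind in DERIVATIVE_KINDS:
                row[f"mass_{kind}"] = repr(r.masses[kind]) if kind in r.masses else ""
            writer.writerow(row)


def write_merge_log(log: Iterable[MergeEvent], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for event in log:
            fh.write(event.to_json() + "\n")
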