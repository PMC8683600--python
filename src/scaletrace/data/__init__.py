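"""Packaged reference fixtures for the Nigeria-linked pangolin trade analysis.

These small CSVs carry published summary quantities used as inputs and
cross-checks:

* ``conversion_factors_derived.csv`` — mass-to-individual conversion factors
  (kg dried scales+claws per animal).  The exact field-measured values are
  not published; these are *derived* by dividing the published per-group
  estimated seizure masses by the published MNIs, and are labelled as such.
* ``mni_reference.csv`` — the published per-group estimated seizure masses
  with 95% CI bounds and the published MNI values, used for arithmetic
  round-trip checks.
* ``detection_methods.csv`` — per-country, per-method seized mass and
  incident counts as published.
* ``pooled_composition.csv`` — pooled sorted scale mass per species group
  from the 67-sack warehouse sample.

``REPORTED_IDENTIFIED_MASS_KG`` (291 kg) is the published total of scales
identified to species.  Note the published components sum to 247.87 kg, an
internal inconsistency of the source reporting that
:func:`scaletrace.mni_core.composition_shares` surfaces rather than hides.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..mni_core import ConversionFactor

__all__ = [
    "DEFAULT_M_CS_KG",
    "REPORTED_IDENTIFIED_MASS_KG",
    "packaged_conversion_factors",
    "load_mni_reference",
    "load_detection_table",
    "load_pooled_composition",
    "fixture_path",
]

# Total confiscated scale mass (kg) across the curated seizure database.
DEFAULT_M_CS_KG = 190_404.0

# Published total of scale mass identified to species (kg).
REPORTED_IDENTIFIED_MASS_KG = 291.0


def fixture_path(name: str):
    return resources.files(__package__) / name


def _read(name: str) -> pd.DataFrame:
    with resources.as_file(fixture_path(name)) as p:
        return pd.read_csv(p)


def packaged_conversion_factors() -> dict[str, ConversionFactor]:
    frame = _read("conversion_factors_derived.csv")
    out: dict[str, ConversionFactor] = {}
    for _, row in frame.iterrows():
        out[row["group"]] = ConversionFactor(
            group=row["group"],
            cf=float(row["cf_kg"]),
            n_samples=int(row["n"]) if pd.notna(row["n"]) else None,
        )
    return out


def load_mni_reference() -> pd.DataFrame:
    return _read("mni_reference.csv")


def load_detection_table() -> pd.DataFrame:
    return _read("detection_methods.csv")


def load_pooled_composition() -> dict[str, float]:
    frame = _read("pooled_composition.csv")
    return dict(zip(frame["group"], frame["sorted_mass_kg"]))
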