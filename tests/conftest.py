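from __future__ import annotations

import pytest

from scaletrace.seizure_io import PartialDate, SeizureRecord


@pytest.fixture
def make_record():
    """Factory for seizure records with sensible defaults."""

    def _make(
        record_id: str = "R1",
        date: str = "2018-05-10",
        scales_kg: float | None = 1000.0,
        route: tuple[str, ...] = ("NGA", "VNM"),
        seizure_country: str | None = None,
        mode: str = "sea",
        source_db: str = "TRAFFIC",
        **kwargs,
    ) -> SeizureRecord:
        masses = {} if scales_kg is None else {"scales": scales_kg}
        return SeizureRecord(
            record_id=record_id,
            seizure_date=PartialDate.parse(date),
            masses=masses,
            mass_known=bool(masses),
            route=list(route),
            seizure_country=seizure_country or route[0],
            mode=mode,
            source_db=source_db,
            **kwargs,
        )

    return _make
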