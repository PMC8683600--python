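"""Seeded generators for synthetic seizure databases and sack samples.

The generators reproduce the statistical structure the analysis pipeline
assumes so that every stage can be exercised end-to-end without restricted
seizure data:

* seizure masses are lognormal (base-10) per transport mode with a linear
  year trend on the log10 scale — by default maritime shipments grow while
  air and land shipments decline;
* routes are 1–4 countries drawn from origin/transit/import pools with
  Nigeria as the pivot country;
* sack compositions mix single-species sacks (mostly white-bellied, a few
  black-bellied) with Dirichlet-distributed mixed sacks, matching the
  observed warehouse sampling pattern of 43/3/21 single-white, single-black
  and mixed sacks out of 67.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .seizure_io import PartialDate, SeizureRecord
from .mni_core import SPECIES_GROUPS, SackSample

__all__ = [
    "SeizureSimConfig",
    "SackSimConfig",
    "DuplicateInjectConfig",
    "generate_seizures",
    "generate_sacks",
    "duplicate_injector",
]

_ORIGIN_POOL = ("CMR", "GAB", "COD", "COG", "CIV", "NER", "CAF", "NGA")
_TRANSIT_POOL = ("NGA", "GHA", "KEN", "TUR", "FRA", "NLD", "SGP", "MYS", "THA")
_IMPORT_POOL = ("CHN", "VNM", "HKG", "LAO", "KHM")


class SeizureSimConfig(BaseModel):
    """Generating model for a synthetic seizure database.

    ``mode_probs`` gives the transport-mode mix; per-mode log10-mass
    baselines are intercepts at ``year_start`` and ``trends`` are yearly
    drifts on the log10 scale.  Defaults emulate an 80-record database over
    2010–2021 dominated by large maritime consignments with growing mass and
    smaller, shrinking air/land shipments.
    """

    n_records: int = 80
    year_start: int = 2010
    year_end: int = 2021
    mode_probs: dict[str, float] = Field(
        default_factory=lambda: {
            "air": 0.25,
            "land": 0.18,
            "sea": 0.30,
            "warehouse": 0.12,
            "unknown": 0.15,
        }
    )
    log10_baseline: dict[str, float] = Field(
        default_factory=lambda: {"air": 2.4, "land": 2.6, "sea": 3.0}
    )
    log10_trend: dict[str, float] = Field(
        default_factory=lambda: {"air": -0.08, "land": -0.05, "sea": 0.15}
    )
    log10_sd: float = 0.45
    route_length_probs: tuple[float, ...] = (0.15, 0.45, 0.30, 0.10)  # lengths 1..4
    p_mass_unknown: float = 0.04
    seed: int | None = None

    @field_validator("log10_sd")
    @classmethod
    def _sd_positive(cls, v: float) -> float:
        if v < 0:
            raise ValueError("log10_sd must be non-negative")
        return v

    @model_validator(mode="after")
    def _probs_valid(self) -> "SeizureSimConfig":
        for name, probs in (
            ("mode_probs", list(self.mode_probs.values())),
            ("route_length_probs", list(self.route_length_probs)),
        ):
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be non-negative and sum to 1")
        if self.year_end < self.year_start:
            raise ValueError("year_end before year_start")
        return self


def _sample_route(rng: np.random.Generator, length: int, mode: str) -> list[str]:
    if mode == "warehouse" or length == 1:
        return ["NGA"]
    origin = str(rng.choice(_ORIGIN_POOL))
    dest = str(rng.choice(_IMPORT_POOL))
    middle: list[str] = []
    for _ in range(length - 2):
        candidates = [c for c in _TRANSIT_POOL if c != origin and c not in middle]
        middle.append(str(rng.choice(candidates)))
    route = [origin, *middle, dest]
    if "NGA" not in route:
        # Nigeria is the pivot of the emulated trade: force it onto the route
        if length == 2:
            route[0] = "NGA"
        else:
            route[rng.integers(1, length - 1)] = "NGA"
    # collapse accidental immediate repeats
    dedup = [route[0]]
    for c in route[1:]:
        if c != dedup[-1]:
            dedup.append(c)
    return dedup


def generate_seizures(
    cfg: SeizureSimConfig, seed: int | None = None
) -> list[SeizureRecord]:
    """Draw a synthetic seizure database from the configured generating model.

    ``seed`` overrides ``cfg.seed``; the output is deterministic given the
    pair.  Mass-unknown records carry an item count instead of masses.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    modes = list(cfg.mode_probs)
    mode_p = np.array([cfg.mode_probs[m] for m in modes])
    lengths = np.arange(1, len(cfg.route_length_probs) + 1)

    records: list[SeizureRecord] = []
    for i in range(cfg.n_records):
        year = int(rng.integers(cfg.year_start, cfg.year_end + 1))
        month = int(rng.integers(1, 13)) if year < 2021 else int(rng.integers(1, 10))
        day = int(rng.integers(1, 29))
        mode = str(rng.choice(modes, p=mode_p))
        length = int(rng.choice(lengths, p=np.asarray(cfg.route_length_probs)))
        route = _sample_route(rng, length, mode)
        seizure_country = str(rng.choice(route))

        mass_unknown = bool(rng.random() < cfg.p_mass_unknown)
        if mass_unknown:
            masses: dict[str, float] = {}
            item_count: int | None = int(rng.integers(1, 40))
        else:
            trend_mode = mode if mode in cfg.log10_baseline else "land"
            mu = cfg.log10_baseline[trend_mode] + cfg.log10_trend[trend_mode] * (
                year - cfg.year_start
            )
            log10_mass = rng.normal(mu, cfg.log10_sd) if cfg.log10_sd > 0 else mu
            masses = {"scales": round(float(10.0**log10_mass), 3)}
            item_count = None
        records.append(
            SeizureRecord(
                record_id=f"SYN-{i:04d}",
                seizure_date=PartialDate(year, month, day),
                masses=masses,
                mass_known=not mass_unknown,
                route=route,
                seizure_country=seizure_country,
                mode=mode,
                detection_method=str(
                    rng.choice(
                        ["intelligence", "routine_inspection", "scanner", "sniffer_dogs", "unknown"],
                        p=[0.25, 0.35, 0.1, 0.05, 0.25],
                    )
                ),
                suspects_arrested=int(rng.integers(0, 5)) if rng.random() < 0.5 else None,
                source_db="SYNTH",
                item_count=item_count,
            )
        )
    return records


class SackSimConfig(BaseModel):
    """Generating model for sampled sacks of confiscated scales.

    A sack is single-species white-bellied with probability
    ``p_single_white``, single-species black-bellied with ``p_single_black``,
    otherwise mixed with composition drawn from a Dirichlet whose mean is
    ``mixed_mean`` (order: white-bellied, black-bellied, smutsia,
    unidentified) and concentration ``mixed_concentration`` — low
    concentration makes most mixed sacks dominated by one or two groups, as
    seen in practice.  Defaults emulate the observed 43/3/21 split of 67
    sacks of 6–104 kg.
    """

    n_sacks: int = 67
    sack_mass_range: tuple[float, float] = (6.0, 104.0)
    p_single_white: float = 43.0 / 67.0
    p_single_black: float = 3.0 / 67.0
    mixed_mean: tuple[float, float, float, float] = (0.09, 0.21, 0.67, 0.03)
    mixed_concentration: float = 3.0
    sampled_fraction_beta: tuple[float, float] = (2.0, 8.0)
    unsorted_fraction: float = 0.005
    seed: int | None = None

    @model_validator(mode="after")
    def _valid(self) -> "SackSimConfig":
        if self.n_sacks < 1:
            raise ValueError("n_sacks must be >= 1")
        lo, hi = self.sack_mass_range
        if not 0 < lo <= hi:
            raise ValueError("sack mass range must be positive and ordered")
        if not 0 <= self.p_single_white <= 1 or not 0 <= self.p_single_black <= 1:
            raise ValueError("single-species probabilities must be in [0, 1]")
        if self.p_single_white + self.p_single_black > 1:
            raise ValueError("single-species probabilities exceed 1")
        if any(m < 0 for m in self.mixed_mean) or abs(sum(self.mixed_mean) - 1.0) > 1e-9:
            raise ValueError("mixed_mean must be a point on the simplex")
        if self.mixed_concentration <= 0:
            raise ValueError("mixed_concentration must be positive")
        return self

    def mean_composition(self) -> dict[str, float]:
        """Analytic mean p_rm per group implied by the mixture model."""
        p_mix = 1.0 - self.p_single_white - self.p_single_black
        means = {}
        for g, m in zip(SPECIES_GROUPS, self.mixed_mean):
            means[g] = p_mix * m
        means["white_bellied"] += self.p_single_white
        means["black_bellied"] += self.p_single_black
        return means


def generate_sacks(cfg: SackSimConfig, seed: int | None = None) -> list[SackSample]:
    """Draw synthetic sampled sacks from the configured composition mixture."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    alpha = cfg.mixed_concentration * np.asarray(cfg.mixed_mean)
    lo, hi = cfg.sack_mass_range
    a_frac, b_frac = cfg.sampled_fraction_beta

    sacks: list[SackSample] = []
    for i in range(cfg.n_sacks):
        sack_mass = float(rng.uniform(lo, hi))
        sampled = sack_mass * float(rng.beta(a_frac, b_frac))
        sorted_mass = sampled * (1.0 - cfg.unsorted_fraction)
        u = rng.random()
        if u < cfg.p_single_white:
            comp = np.array([1.0, 0.0, 0.0, 0.0])
        elif u < cfg.p_single_white + cfg.p_single_black:
            comp = np.array([0.0, 1.0, 0.0, 0.0])
        else:
            comp = rng.dirichlet(alpha)
        sacks.append(
            SackSample(
                sack_id=f"SACK-{i:03d}",
                total_sampled_mass=round(sampled, 6),
                sorted_masses={
                    g: round(float(c * sorted_mass), 6)
                    for g, c in zip(SPECIES_GROUPS, comp)
                },
            )
        )
    return sacks


class DuplicateInjectConfig(BaseModel):
    """Perturbation envelope for injected near-duplicate seizure reports."""

    max_date_jitter_days: int = 5
    max_mass_jitter_frac: float = 0.05
    alt_source: str = "ALT-DB"


def duplicate_injector(
    records: Sequence[SeizureRecord],
    n_dupes: int,
    cfg: DuplicateInjectConfig | None = None,
    seed: int | None = None,
) -> tuple[list[SeizureRecord], dict[str, str]]:
    """Inject near-duplicate reports of existing records.

    Each duplicate jitters the date by up to ``max_date_jitter_days`` and the
    mass by up to ``max_mass_jitter_frac`` (relative), and is attributed to
    an alternate source database.  Returns the corrupted record list (shuffled)
    and the ground-truth map ``duplicate_id -> original_id``.
    """
    from dataclasses import replace
    import datetime as _dt

    cfg = cfg or DuplicateInjectConfig()
    rng = np.random.default_rng(seed)
    pool = [r for r in records if r.mass_known]
    if not pool:
        raise ValueError("no mass-known records to duplicate")
    truth: dict[str, str] = {}
    dupes: list[SeizureRecord] = []
    for k in range(n_dupes):
        orig = pool[int(rng.integers(0, len(pool)))]
        jitter = int(rng.integers(-cfg.max_date_jitter_days, cfg.max_date_jitter_days + 1))
        date = orig.seizure_date.approx() + _dt.timedelta(days=jitter)
        factor = 1.0 + float(rng.uniform(-cfg.max_mass_jitter_frac, cfg.max_mass_jitter_frac))
        masses = {kind: round(kg * factor, 3) for kind, kg in orig.masses.items()}
        dupe_id = f"{orig.record_id}-dup{k}"
        dupes.append(
            replace(
                orig,
                record_id=dupe_id,
                seizure_date=PartialDate(date.year, date.month, date.day),
                masses=masses,
                source_db=cfg.alt_source,
            )
        )
        truth[dupe_id] = orig.record_id
    corrupted = list(records) + dupes
    order = rng.permutation(len(corrupted))
    return [corrupted[i] for i in order], truth
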