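"""Pipeline orchestration: simulate/curate -> stats -> flows -> mni.

A run is described by a single config mapping (JSON or YAML on disk).  Each
stage writes CSV/JSON artifacts into the output directory and the run ends
with a manifest listing every output with a SHA-256 digest, the config
snapshot and the seeds used, so that deterministic stages can be reproduced
byte-for-byte.

Per-stage seeds are derived from the master seed as ``master + stage_offset``
(documented fixed offsets), keeping all derived seeds below 2**31.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import seizure_io, trade_flows, trade_statistics
from .mni_core import ConversionFactor, mni_report
from .synthetic_data import SackSimConfig, SeizureSimConfig, generate_sacks, generate_seizures

__all__ = ["run_pipeline", "load_config", "STAGES", "stage_seed"]

STAGES = ("simulate", "curate", "stats", "flows", "mni")
_STAGE_OFFSETS = {name: i + 1 for i, name in enumerate(STAGES)}
_SEED_MOD = 2**31


def stage_seed(master: int, stage: str) -> int:
    return (int(master) + 1_000_003 * _STAGE_OFFSETS[stage]) % _SEED_MOD


def load_config(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require_inputs(cfg: Mapping[str, Any]) -> None:
    stages = cfg.get("stages", list(STAGES))
    if "curate" in stages and "simulate" not in stages:
        src = cfg.get("curate", {}).get("input")
        if not src or not Path(src).exists():
            raise FileNotFoundError(f"curate stage input not found: {src!r}")
    if "mni" in stages:
        for key in ("sacks", "conversion_factors"):
            src = cfg.get("mni", {}).get(key)
            if src is not None and not Path(src).exists():
                raise FileNotFoundError(f"mni stage input not found: {src!r}")


def _read_sacks_csv(path: Path):
    from .mni_core import SackSample

    frame = pd.read_csv(path)
    sacks = []
    for _, row in frame.iterrows():
        sacks.append(
            SackSample(
                sack_id=str(row["sack_id"]),
                total_sampled_mass=float(row["total_mass_kg"]),
                sorted_masses={
                    "white_bellied": float(row["wb_kg"]),
                    "black_bellied": float(row["bb_kg"]),
                    "smutsia": float(row["smutsia_kg"]),
                    "unidentified": float(row["unid_kg"]),
                },
            )
        )
    return sacks


def write_sacks_csv(sacks, path: Path) -> None:
    rows = [
        {
            "sack_id": s.sack_id,
            "total_mass_kg": s.total_sampled_mass,
            "wb_kg": s.sorted_masses.get("white_bellied", 0.0),
            "bb_kg": s.sorted_masses.get("black_bellied", 0.0),
            "smutsia_kg": s.sorted_masses.get("smutsia", 0.0),
            "unid_kg": s.sorted_masses.get("unidentified", 0.0),
        }
        for s in sacks
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_conversion_factors(path: str | Path) -> dict[str, ConversionFactor]:
    frame = pd.read_csv(path)
    out = {}
    for _, row in frame.iterrows():
        n = row.get("n")
        out[row["group"]] = ConversionFactor(
            group=row["group"],
            cf=float(row["cf_kg"]),
            n_samples=int(n) if pd.notna(n) else None,
        )
    return out


def run_pipeline(config: Mapping[str, Any] | str | Path, out_dir: str | Path) -> dict[str, Any]:
    """Execute the configured stages in order and return the run manifest.

    Missing inputs are reported before any computation starts.  The manifest
    is also written to ``manifest.json`` in the output directory.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _require_inputs(cfg)

    master_seed = int(cfg.get("seed", 0))
    stages = cfg.get("stages", list(STAGES))
    outputs: dict[str, str] = {}
    summary: dict[str, Any] = {}
    records = None
    curated = None

    if "simulate" in stages:
        sim_seed = stage_seed(master_seed, "simulate")
        scfg = SeizureSimConfig(**cfg.get("simulate", {}).get("seizures", {}))
        records = generate_seizures(scfg, seed=sim_seed)
        path = out / "simulated_seizures.csv"
        seizure_io.write_seizures(records, path)
        outputs["simulated_seizures"] = str(path)
        sack_cfg = SackSimConfig(**cfg.get("simulate", {}).get("sacks", {}))
        sacks = generate_sacks(sack_cfg, seed=sim_seed + 1)
        spath = out / "simulated_sacks.csv"
        write_sacks_csv(sacks, spath)
        outputs["simulated_sacks"] = str(spath)
        summary["simulate"] = {"n_seizures": len(records), "n_sacks": len(sacks)}

    if "curate" in stages:
        if records is None:
            records, rejects = seizure_io.read_seizures(cfg["curate"]["input"])
            summary.setdefault("curate", {})["n_rejected_rows"] = len(rejects)
        ccfg = cfg.get("curate", {})
        curated, log = seizure_io.deduplicate(
            records,
            reference_db=ccfg.get("reference", "TRAFFIC"),
            date_window=int(ccfg.get("date_window", 7)),
            mass_rtol=float(ccfg.get("mass_rtol", 0.10)),
        )
        path = out / "curated_seizures.csv"
        seizure_io.write_seizures(curated, path)
        outputs["curated_seizures"] = str(path)
        log_path = out / "merge_log.jsonl"
        seizure_io.write_merge_log(log, log_path)
        outputs["merge_log"] = str(log_path)
        summary.setdefault("curate", {}).update(
            {
                "n_input": len(records),
                "n_curated": len(curated),
                "n_merges": len(log),
                "total_mass_kg": seizure_io.total_mass(curated),
            }
        )
    analysed = curated if curated is not None else records

    if "stats" in stages:
        if analysed is None:
            raise FileNotFoundError("stats stage requires curated or simulated records")
        scfg = cfg.get("stats", {})
        years = tuple(scfg.get("years", (2010, 2020)))
        groups = trade_statistics.records_by_mode(analysed)
        block: dict[str, Any] = {}
        if len(groups) >= 2:
            kw = trade_statistics.kruskal_wallis(groups)
            ranking = trade_statistics.compare_models(analysed, years=years)
            best = trade_statistics.fit_mass_model(analysed, formula=ranking[0][0], years=years)
            block = {
                "kruskal_wallis": {"H": kw.H, "df": kw.df, "n": kw.n, "p": kw.p_value},
                "dunn": [
                    {"a": a, "b": b, "z": z, "p": p} for a, b, z, p in kw.pairwise
                ],
                "model_ranking": [
                    {"formula": f, "aic": v, "k": k} for f, v, k in ranking
                ],
                "best_model": {
                    "formula": best.formula,
                    "r_squared": best.r_squared,
                    "coefficients": {
                        t: {"estimate": e, "se": s, "p": p}
                        for t, (e, s, p) in best.coefficients.items()
                    },
                },
            }
        path = out / "stats.json"
        path.write_text(json.dumps(block, indent=2))
        outputs["stats"] = str(path)
        summary["stats"] = {"n_modes": len(groups)}

    if "flows" in stages:
        if analysed is None:
            raise FileNotFoundError("flows stage requires curated or simulated records")
        profiles = trade_flows.aggregate_roles(analysed)
        role_rows = []
        for p in profiles:
            a, b, c = trade_flows.ternary_coordinates(p)
            role_rows.append(
                {
                    "country": p.country,
                    "interval": p.interval,
                    "n_origin": p.n_origin,
                    "n_transit": p.n_transit,
                    "n_import": p.n_import,
                    "p_origin": a,
                    "p_transit": b,
                    "p_import": c,
                }
            )
        roles_path = out / "country_roles.csv"
        pd.DataFrame(role_rows).to_csv(roles_path, index=False)
        outputs["country_roles"] = str(roles_path)
        edges_path = out / "flow_edges.csv"
        trade_flows.flow_edges(analysed).to_csv(edges_path, index=False)
        outputs["flow_edges"] = str(edges_path)
        dest_path = out / "destinations.csv"
        trade_flows.summarize_destinations(analysed).to_csv(dest_path, index=False)
        outputs["destinations"] = str(dest_path)
        det_path = out / "detection_methods.csv"
        trade_flows.summarize_detection_methods(analysed).to_csv(det_path, index=False)
        outputs["detection_methods"] = str(det_path)
        summary["flows"] = {"n_profiles": len(profiles)}

    if "mni" in stages:
        mcfg = cfg.get("mni", {})
        if mcfg.get("sacks"):
            sacks = _read_sacks_csv(Path(mcfg["sacks"]))
        elif "simulate" in stages:
            sacks = _read_sacks_csv(out / "simulated_sacks.csv")
        else:
            raise FileNotFoundError("mni stage requires a sacks CSV")
        if mcfg.get("conversion_factors"):
            cfs = read_conversion_factors(mcfg["conversion_factors"])
        else:
            from .data import packaged_conversion_factors

            cfs = packaged_conversion_factors()
        m_cs = float(mcfg.get("m_cs", 190_404.0))
        report = mni_report(
            sacks,
            cfs,
            m_cs=m_cs,
            n_boot=int(mcfg.get("n_boot", 1000)),
            seed=stage_seed(master_seed, "mni"),
        )
        path = out / "mni_report.csv"
        report.to_csv(path, index=False)
        outputs["mni_report"] = str(path)
        total = report[report["group"] == "total"].iloc[0]
        summary["mni"] = {
            "m_cs_kg": m_cs,
            "total_mni": int(total["mni"]),
            "total_mni_low": int(total["mni_low"]),
            "total_mni_high": int(total["mni_high"]),
        }

    manifest = {
        "config": cfg,
        "seed": master_seed,
        "stage_seeds": {s: stage_seed(master_seed, s) for s in stages},
        "stages": list(stages),
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "outputs": {k: {"path": v, "sha256": _digest(Path(v))} for k, v in outputs.items()},
        "summary": summary,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
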