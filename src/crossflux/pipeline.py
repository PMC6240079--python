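"""End-to-end pipeline: validate -> harmonize -> derive -> NEP stats -> synthesize.

Stages communicate only via files so every intermediate table is auditable
and each stage can be re-run on its own; identical inputs, config, and seed
produce byte-identical tables and an identical manifest (timings excluded).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .config import Config, default_config
from .decomposition import stratum_decomposition_fluxes
from .harmonize import export_audit, harmonize_table
from .metabolism import nep_analysis
from .records import Ecosystem, FluxClass, read_flux_table, records_to_frame, write_harmonized
from .synthesis import (
    compare_spatial_local,
    driver_interface_tabulation,
    group_summaries,
    sensitivity_band,
)

logger = logging.getLogger("crossflux")

__all__ = ["run_pipeline", "nep_groups"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _config_hash(config: Config) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def nep_groups(records) -> dict[str, list[float]]:
    """NEP samples per ecosystem, in ecosystem enumeration order."""
    groups: dict[str, list[float]] = {}
    for eco in Ecosystem:
        vals = [
            r.value
            for r in records
            if r.flux_class is FluxClass.NEP and r.ecosystem is eco
        ]
        if vals:
            groups[eco.value] = vals
    return groups


def run_pipeline(raw_table, out_dir, config: Config | None = None, strict: bool = False) -> dict:
    """Run every stage on a raw flux table; returns the run manifest.

    Writes, under ``out_dir``: harmonized.csv, audit.csv, derived_fluxes.csv,
    nep_tests.csv, nep_kw.json, stratum_summaries.csv, comparison.csv,
    driver_tabulation.csv, interface_tabulation.csv, sensitivity.csv, and
    manifest.json.
    """
    config = config or default_config()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    raw_table = Path(raw_table)
    manifest: dict = {
        "crossflux_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "band_width_m": config.band_width_m,
        "inputs": {str(raw_table): _sha256(raw_table)},
        "stages": {},
        "outputs": [],
        "incomplete": True,
    }

    def stage(name):
        manifest["stages"][name] = {"started": time.time()}

    def done(name, *outputs):
        manifest["stages"][name]["seconds"] = round(
            time.time() - manifest["stages"][name].pop("started"), 3
        )
        manifest["outputs"].extend(str(o) for o in outputs)

    try:
        stage("validate")
        result = read_flux_table(raw_table, strict=strict)
        if result.rejects:
            logger.warning(
                "validate: %d row(s) rejected: %s", len(result.rejects), result.rejects
            )
        manifest["n_records"] = len(result.records)
        manifest["n_rejected"] = len(result.rejects)
        done("validate")

        stage("harmonize")
        harmonized = harmonize_table(result.records, config)
        hpath = out_dir / "harmonized.csv"
        write_harmonized(harmonized, hpath)
        export_audit(harmonized).to_csv(out_dir / "audit.csv", index=False)
        done("harmonize", hpath, out_dir / "audit.csv")

        stage("derive_decomposition")
        derived = stratum_decomposition_fluxes(harmonized)
        full = harmonized + derived
        dpath = out_dir / "derived_fluxes.csv"
        write_harmonized(derived, dpath)
        done("derive_decomposition", dpath)

        stage("nep_stats")
        groups = nep_groups(harmonized)
        npath, kpath = out_dir / "nep_tests.csv", out_dir / "nep_kw.json"
        if len(groups) >= 2:
            analysis = nep_analysis(groups, alpha=config.alpha)
            pd.DataFrame([vars(r) for r in analysis.per_ecosystem]).to_csv(
                npath, index=False, float_format="%.17g"
            )
            kw = analysis.kruskal
            kpath.write_text(
                json.dumps(
                    {
                        "bartlett_stat": analysis.bartlett.statistic,
                        "bartlett_p": analysis.bartlett.p,
                        "kw_chi2": kw.chi2,
                        "kw_df": kw.df,
                        "kw_n": kw.n_total,
                        "kw_p": kw.p,
                        "letters": kw.letters,
                    },
                    indent=2,
                )
            )
            done("nep_stats", npath, kpath)
        else:
            logger.warning("nep_stats: fewer than 2 NEP groups, stage skipped")
            done("nep_stats")

        stage("synthesize")
        summaries = group_summaries(full, by=("ecosystem", "flux_class"))
        spath = out_dir / "stratum_summaries.csv"
        summaries.to_csv(spath, index=False, float_format="%.17g")
        cpath = out_dir / "comparison.csv"
        compare_spatial_local(full).to_csv(cpath, index=False, float_format="%.17g")
        tab = driver_interface_tabulation(full)
        drpath, ipath = out_dir / "driver_tabulation.csv", out_dir / "interface_tabulation.csv"
        tab.drivers.to_csv(drpath, index=False, float_format="%.17g")
        tab.interfaces.to_csv(ipath, index=False, float_format="%.17g")
        sens = sensitivity_band(
            result.records, config, (config.band_width_m, config.sensitivity_band_width_m)
        )
        sepath = out_dir / "sensitivity.csv"
        sens.paired.to_csv(sepath, index=False, float_format="%.17g")
        done("synthesize", spath, cpath, drpath, ipath, sepath)
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    manifest["incomplete"] = False
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
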