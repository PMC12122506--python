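"""End-to-end orchestration: ingest → dedup → select → describe → signals →
subgroups → sensitivity → time-to-onset, with TSV outputs and a JSON manifest.

The run is deterministic given identical inputs and configuration; every
filtering stage records its input and output counts in the manifest so the
report flow can be audited.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coding import read_coding_table
from .ingest import concat_quarters, deduplicate, assemble, read_quarter, select_primary_suspect
from .report import describe
from .signals import Thresholds, signal_table
from .strata import DEFAULT_AGE_STRATA, SensitivitySpec, StratumSpec, run_sensitivity, run_subgroup, sex_stratum
from .tto import compute_tto, cumulative_incidence, fit_weibull, tto_summary

logger = logging.getLogger("faersig")


@dataclass
class RunConfig:
    """Configuration of one full analysis run (loadable from YAML)."""

    data_dir: str
    quarters: list[str]
    output_dir: str
    target_drug_names: list[str] = field(default_factory=lambda: ["vismodegib", "erivedge"])
    coding_table: str | None = None
    level: Literal["pt", "soc", "both"] = "both"
    top_k: int = 50
    thresholds: Thresholds = field(default_factory=Thresholds)
    run_subgroups: bool = True
    sensitivity_drugs: list[str] = field(
        default_factory=lambda: ["imiquimod", "5-fluorouracil", "mupirocin"]
    )
    tto_allow_imputed: bool = False
    tto_bin_edges: list[float] = field(default_factory=lambda: [0.0, 61.0, 181.0, math.inf])
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if isinstance(self.thresholds, dict):
            self.thresholds = Thresholds(**self.thresholds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _validate(config: RunConfig) -> None:
    if not Path(config.data_dir).is_dir():
        raise FileNotFoundError(f"data directory not found: {config.data_dir}")
    if config.level in ("soc", "both"):
        if not config.coding_table:
            raise ValueError("SOC-level analysis requires a coding table path")
        if not Path(config.coding_table).exists():
            raise FileNotFoundError(f"coding table not found: {config.coding_table}")


def _write_tsv(frame: pd.DataFrame, path: Path) -> str:
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.6g")
    return str(path)


def _descriptives_dict(d) -> dict:
    out = dataclasses.asdict(d)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest (also written to disk)."""
    logging.basicConfig(level=config.verbosity)
    _validate(config)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    coding = read_coding_table(config.coding_table) if config.coding_table else None

    manifest: dict = {
        "tool": {"name": "faersig", "version": __version__},
        "config": {
            **{k: v for k, v in dataclasses.asdict(config).items() if k != "thresholds"},
            "thresholds": dataclasses.asdict(config.thresholds),
        },
        "stages": {},
        "outputs": {},
    }
    stages = manifest["stages"]

    quarters = [read_quarter(config.data_dir, q) for q in config.quarters]
    tables = concat_quarters(quarters)
    stages["ingest"] = {
        "n_demo_rows": len(tables.demo),
        "n_drug_rows": len(tables.drug),
        "n_reac_rows": len(tables.reac),
        "n_ther_rows": len(tables.ther),
        "n_malformed": tables.n_malformed,
    }
    logger.info("ingest: %s demo rows from %d quarter(s)", len(tables.demo), len(quarters))

    demo_dedup = deduplicate(tables.demo)
    stages["dedup"] = {"n_in": len(tables.demo), "n_out": len(demo_dedup),
                       "rule": "max FDA_DT then max PRIMARYID per CASEID"}
    logger.info("dedup: %d -> %d rows", len(tables.demo), len(demo_dedup))

    reports, astats = assemble(demo_dedup, tables.drug, tables.reac, tables.ther)
    stages["assemble"] = dataclasses.asdict(astats)

    target_reports = select_primary_suspect(reports, config.target_drug_names)
    stages["select_primary_suspect"] = {
        "n_in": len(reports), "n_out": len(target_reports),
        "drug_names": list(config.target_drug_names),
    }
    logger.info("select: %d -> %d target reports", len(reports), len(target_reports))
    if not target_reports:
        raise ValueError("no reports with the target drug as primary suspect")

    desc = describe(target_reports)
    desc_path = out_dir / "descriptives.json"
    desc_path.write_text(json.dumps(_descriptives_dict(desc), indent=2, default=str))
    manifest["outputs"]["descriptives"] = str(desc_path)

    levels = ("pt", "soc") if config.level == "both" else (config.level,)
    for level in levels:
        table = signal_table(
            target_reports, config.target_drug_names, reports, level=level,
            coding=coding, k=config.top_k if level == "pt" else None,
            thresholds=config.thresholds,
        )
        manifest["outputs"][f"signals_{level}"] = _write_tsv(
            table, out_dir / f"signals_{level}.tsv"
        )
        stages[f"signals_{level}"] = {
            "n_events": len(table), "n_positive": int(table["sig_combined"].sum()),
        }

    if config.run_subgroups:
        strata: list[StratumSpec] = [sex_stratum("male"), sex_stratum("female"), *DEFAULT_AGE_STRATA]
        sub_manifest = {}
        for spec in strata:
            try:
                table = run_subgroup(
                    target_reports, reports, spec, k=config.top_k,
                    target=config.target_drug_names, thresholds=config.thresholds,
                )
            except ValueError as exc:
                sub_manifest[spec.name] = {"skipped": str(exc)}
                continue
            safe = spec.name.replace("=", "_").replace("<", "lt").replace(">", "gt")
            path = _write_tsv(table, out_dir / f"subgroup_{safe}.tsv")
            sub_manifest[spec.name] = {
                "n_events": len(table),
                "n_positive": int(table["sig_combined"].sum()),
                "path": path,
            }
        stages["subgroups"] = sub_manifest

    if config.sensitivity_drugs:
        table, counts = run_sensitivity(
            target_reports, reports, SensitivitySpec(tuple(config.sensitivity_drugs)),
            k=config.top_k, target=config.target_drug_names, thresholds=config.thresholds,
        )
        manifest["outputs"]["sensitivity"] = _write_tsv(table, out_dir / "sensitivity.tsv")
        stages["sensitivity"] = counts

    sample = compute_tto(
        target_reports, config.target_drug_names,
        allow_imputed_dates=config.tto_allow_imputed,
    )
    tto_stage: dict = {
        "n_onsets": sample.n,
        "n_excluded_missing": sample.n_excluded_missing,
        "n_excluded_negative": sample.n_excluded_negative,
        "n_excluded_partial": sample.n_excluded_partial,
    }
    if sample.n:
        summary = tto_summary(sample, config.tto_bin_edges)
        tto_stage["summary"] = summary
        if sample.n >= 10 and len(set(sample.onsets)) > 1:
            fit = fit_weibull(sample)
            tto_stage["weibull"] = {
                "scale_alpha": fit.scale_alpha, "scale_ci": list(fit.scale_ci),
                "shape_beta": fit.shape_beta, "shape_ci": list(fit.shape_ci),
                "failure_type": fit.failure_type,
            }
        grid = np.arange(0, math.ceil(max(sample.onsets)) + 30, 30, dtype=float)
        cdf = cumulative_incidence(sample, grid)
        cdf_frame = pd.DataFrame({"day": grid, "cumulative_incidence": cdf})
        manifest["outputs"]["cumulative_incidence"] = _write_tsv(
            cdf_frame, out_dir / "cumulative_incidence.tsv"
        )
    stages["tto"] = tto_stage

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest
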