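"""End-to-end orchestration of the four experiments.

Each ``run_experiment_*`` function goes simulate-or-load -> quantify ->
normalize -> statistics -> report, writing diff-able CSV tables plus a
machine-readable JSON summary into the manifest's output directory.
Given the same seed and configuration the outputs are byte-for-byte
identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import comparisons, precision_stats, quantification, synthetic_data
from .errors import MirvarError
from .io_plates import Measurement, read_measurements, write_measurements
from .quantification import STRATEGIES, normalize_table
from .synthetic_data import SyntheticConfig

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """What to run and where: a synthetic preset (or config file) or an
    input measurement table, the seed, and the output directory."""

    out_dir: Path
    preset: str | None = "study"
    config_path: Path | None = None
    input_path: Path | None = None
    seed: int = 0
    stages: list[dict] = field(default_factory=list)

    def config(self) -> SyntheticConfig:
        if self.config_path is not None:
            cfg = SyntheticConfig.from_yaml(self.config_path)
        else:
            cfg = SyntheticConfig.preset(self.preset or "study", seed=self.seed)
        cfg.seed = self.seed
        return cfg

    def record_stage(self, name: str, n_in: int, n_out: int) -> None:
        stamp = datetime.now(timezone.utc).isoformat()
        self.stages.append(
            {"stage": name, "records_in": n_in, "records_out": n_out,
             "timestamp": stamp}
        )
        log.info("stage %-22s in=%-6d out=%d", name, n_in, n_out)

    def write(self) -> Path:
        path = Path(self.out_dir) / "manifest.json"
        payload = {
            "preset": self.preset,
            "config_path": str(self.config_path) if self.config_path else None,
            "input_path": str(self.input_path) if self.input_path else None,
            "seed": self.seed,
            "out_dir": str(self.out_dir),
            "stages": self.stages,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path


def _load_or_generate(
    manifest: RunManifest, generator, experiment_id: str, **kwargs
) -> list[Measurement]:
    if manifest.input_path is not None:
        records = [
            r for r in read_measurements(manifest.input_path)
            if r.meta.experiment_id in ("", experiment_id)
        ]
        manifest.record_stage(f"load:{experiment_id}", 0, len(records))
    else:
        records = generator(manifest.config(), seed=manifest.seed, **kwargs)
        manifest.record_stage(f"simulate:{experiment_id}", 0, len(records))
    if not records:
        raise MirvarError(f"no records for experiment {experiment_id!r}")
    return records


def _normalize_all(
    manifest: RunManifest, records: list[Measurement], stage: str
) -> pd.DataFrame:
    frames = [normalize_table(records, s) for s in STRATEGIES]
    levels = pd.concat(frames, ignore_index=True)
    manifest.record_stage(stage, len(records), len(levels))
    return levels


def _write_report(
    manifest: RunManifest, name: str, tables: dict[str, pd.DataFrame]
) -> dict[str, Path]:
    out = Path(manifest.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    summary: dict[str, object] = {"experiment": name, "seed": manifest.seed}
    for key, table in tables.items():
        path = out / f"{name}_{key}.csv"
        table.to_csv(path, index=False)
        paths[key] = path
        summary[key] = table.to_dict(orient="records")
    (out / f"{name}_summary.json").write_text(json.dumps(summary, indent=2))
    manifest.write()
    return paths


def run_experiment_1(manifest: RunManifest) -> dict[str, Path]:
    """Dual vs prolonged single centrifugation: per-protocol means and
    CVs with protocol t-tests plus the order-of-draw
    check (first 10 vs last 10 tubes)."""
    try:
        records = _load_or_generate(
            manifest, synthetic_data.generate_centrifugation_experiment,
            "centrifugation",
        )
        levels = _normalize_all(manifest, records, "normalize:centrifugation")
        cvs = precision_stats.protocol_cvs(levels)
        tests = comparisons.compare_protocols(levels)
        table1 = cvs.merge(tests[["assay", "strategy", "p_value"]],
                           on=["assay", "strategy"])
        draw = comparisons.order_of_draw_test(levels)
        manifest.record_stage("statistics:centrifugation",
                              len(levels), len(table1) + len(draw))
    except MirvarError as exc:
        raise MirvarError(f"experiment 1 (centrifugation): {exc}") from exc
    return _write_report(
        manifest, "experiment1",
        {"protocol_table": table1, "order_of_draw": draw},
    )


def run_experiments_2_3(manifest: RunManifest) -> dict[str, Path]:
    """Cross-material and cross-method agreement on the patient cohort:
    Spearman correlations for PPP vs standard plasma (single assays) and
    single assays vs TLDA, per assay x strategy."""
    try:
        records = _load_or_generate(
            manifest, synthetic_data.generate_patient_cohort, "cohort"
        )
        levels = _normalize_all(manifest, records, "normalize:cohort")
        qpcr = levels[levels["platform"] == "qPCR"]
        ppp = qpcr[qpcr["material"] == "PPP"]
        std = qpcr[qpcr["material"] == "standard_plasma"]
        tlda = levels[levels["platform"] == "TLDA"]
        materials = comparisons.correlate_tables(ppp, std)
        platforms = comparisons.correlate_tables(ppp, tlda)
        manifest.record_stage("statistics:agreement", len(levels),
                              len(materials) + len(platforms))
    except MirvarError as exc:
        raise MirvarError(f"experiments 2-3 (agreement): {exc}") from exc
    return _write_report(
        manifest, "experiments2_3",
        {"ppp_vs_standard": materials, "single_vs_tlda": platforms},
    )


def run_experiment_4(manifest: RunManifest) -> dict[str, Path]:
    """qPCR vs ddPCR: pooled-sample precision/repeatability per assay x
    platform x strategy plus the cross-platform Spearman
    correlation on the patient cohort."""
    try:
        precision_records = _load_or_generate(
            manifest, synthetic_data.generate_precision_experiment,
            "precision", platform="both",
        )
        plevels = _normalize_all(manifest, precision_records,
                                 "normalize:precision")
        estimates = precision_stats.precision_from_duplicates(plevels)
        table2 = pd.DataFrame(
            [
                {
                    "assay": e.assay, "platform": e.platform,
                    "strategy": e.strategy, "mean": e.grand_mean,
                    "cv_precision": e.cv_inter, "cv_repeatability": e.cv_intra,
                    "n_runs": e.n_runs,
                }
                for e in estimates
            ]
        )
        cohort = _load_or_generate(
            manifest, synthetic_data.generate_patient_cohort, "cohort"
        )
        clevels = _normalize_all(manifest, cohort, "normalize:cohort")
        ppp = clevels[clevels["material"] == "PPP"]
        corr = comparisons.correlate_tables(
            ppp[ppp["platform"] == "qPCR"], ppp[ppp["platform"] == "ddPCR"]
        )
        manifest.record_stage("statistics:precision", len(plevels),
                              len(table2) + len(corr))
    except MirvarError as exc:
        raise MirvarError(f"experiment 4 (qPCR vs ddPCR): {exc}") from exc
    return _write_report(
        manifest, "experiment4",
        {"precision_table": table2, "qpcr_vs_ddpcr": corr},
    )


def attribution_report(manifest: RunManifest) -> dict[str, Path]:
    """Variance attribution: combine the centrifugation experiment's
    whole-procedure CVs with the qPCR repeatability CVs of the precision
    experiment into the preanalytical attribution fractions."""
    try:
        cent = _load_or_generate(
            manifest, synthetic_data.generate_centrifugation_experiment,
            "centrifugation",
        )
        clevels = _normalize_all(manifest, cent, "normalize:centrifugation")
        cvs = precision_stats.protocol_cvs(clevels)
        prec = _load_or_generate(
            manifest, synthetic_data.generate_precision_experiment,
            "precision", platform="qPCR",
        )
        plevels = _normalize_all(manifest, prec, "normalize:precision")
        estimates = {
            (e.assay, e.strategy): e
            for e in precision_stats.precision_from_duplicates(plevels)
            if e.platform == "qPCR"
        }
        rows = []
        for (assay, strategy), grp in cvs.groupby(["assay", "strategy"]):
            key = (assay, strategy)
            if key not in estimates:
                continue
            per_protocol = {r["protocol"]: r["cv"] for _, r in grp.iterrows()}
            if {"dual", "single"} - set(per_protocol):
                continue
            res = precision_stats.attribute_preanalytical(
                cv_single=per_protocol["single"],
                cv_dual=per_protocol["dual"],
                cv_repeatability=estimates[key].cv_intra,
                assay=assay, strategy=strategy,
            )
            rows.append(
                {
                    "assay": assay, "strategy": strategy,
                    "cv_total": res.cv_total,
                    "cv_rt_qpcr": res.cv_rt_qpcr,
                    "fraction_preanalytical": res.fraction_preanalytical,
                    "fraction_rounded": precision_stats.round_half_up(
                        res.fraction_preanalytical
                    ),
                }
            )
        table = pd.DataFrame(rows)
        manifest.record_stage("statistics:attribution", len(cvs), len(table))
    except MirvarError as exc:
        raise MirvarError(f"attribution: {exc}") from exc
    return _write_report(manifest, "attribution", {"attribution": table})


def simulate_to_file(manifest: RunManifest, experiment: str) -> Path:
    """Write one experiment's synthetic measurement table (io schema)."""
    generators = {
        "centrifugation": synthetic_data.generate_centrifugation_experiment,
        "cohort": synthetic_data.generate_patient_cohort,
        "precision": synthetic_data.generate_precision_experiment,
    }
    if experiment not in generators:
        raise ValueError(f"unknown experiment {experiment!r}")
    records = generators[experiment](manifest.config(), seed=manifest.seed)
    out = Path(manifest.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / f"{experiment}_measurements.csv"
    write_measurements(records, path)
    manifest.record_stage(f"simulate:{experiment}", 0, len(records))
    manifest.write()
    return path
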