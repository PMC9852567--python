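"""End-to-end orchestration: simulate -> consensus -> quantify -> calibrate
-> call -> report, with plain-TSV intermediates.

Every stage reads and writes ordinary TSV/JSON files in the output
directory, so any stage can be re-run, diffed, or started from persisted
intermediates (e.g. begin at pre-computed site counts and skip
simulation).  A manifest records every parameter, the seed, and each
stage's outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import __version__
from .classify import (
    CalibrationError,
    as_fraction,
    calibrate_threshold,
    classify,
    training_specificity,
)
from .diagnostics import (
    age_band_fpr,
    compare_groups,
    percent,
    relative_risk,
    roc_auc,
    sens_spec,
    stratified_table,
)
from .panel import (
    Panel,
    SampleMeta,
    default_panel,
    load_panel,
    load_sample_sheet,
    load_site_counts,
    write_panel,
    write_sample_sheet,
    write_site_counts,
)
from .quantify import max_vaf_table, vaf_table_from_counts, write_vaf_table
from .simulate import SimParams, simulate_cohort

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("urivar")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, sample_id: Optional[str] = None):
        where = f"stage {stage}" + (f", sample {sample_id}" if sample_id else "")
        super().__init__(f"{where}: {message}")
        self.stage = stage
        self.sample_id = sample_id


@dataclass
class RunConfig:
    """Declarative configuration for one pipeline run.

    Exactly one of ``threshold`` (a fixed VAF cut-off) or ``calibration``
    (candidate thresholds + target specificity, applied to the training
    cohort) must be set.  Inputs are either simulation parameters or paths
    to a pre-computed sample sheet + site counts.
    """

    out_dir: Union[str, Path]
    panel_path: Optional[Union[str, Path]] = None
    sim_params: Optional[SimParams] = None
    sample_sheet_path: Optional[Union[str, Path]] = None
    site_counts_path: Optional[Union[str, Path]] = None
    threshold: Optional[float] = None
    calibration: Optional[tuple[Sequence[float], float]] = None  # (candidates, target)
    excluded_sites: Sequence[tuple[str, int, str]] = ()
    min_family_size: int = 3
    min_baseq: int = 30
    seed: Optional[int] = None
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.threshold is None) == (self.calibration is None):
            raise ValueError(
                "exactly one of threshold or calibration must be configured"
            )
        have_paths = self.sample_sheet_path is not None and self.site_counts_path is not None
        if self.sim_params is None and not have_paths:
            raise ValueError("provide sim_params or sample_sheet_path + site_counts_path")
        if self.sim_params is not None and have_paths:
            raise ValueError("provide either sim_params or input paths, not both")


def _load_inputs(
    config: RunConfig, panel: Panel
) -> tuple[list[SampleMeta], pd.DataFrame, str]:
    if config.sim_params is not None:
        params = config.sim_params
        if config.seed is not None:
            params = dataclasses.replace(params, seed=config.seed)
        metas, counts, _truth = simulate_cohort(panel, params)
        return metas, counts, "simulated"
    metas = load_sample_sheet(config.sample_sheet_path)
    counts = load_site_counts(config.site_counts_path)
    return metas, counts, "loaded"


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured pipeline end to end; returns the manifest dict."""
    config.validate()
    logging.basicConfig(level=config.log_level, format="%(levelname)s %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "urivar",
        "version": __version__,
        "seed": config.seed if config.seed is not None else (
            config.sim_params.seed if config.sim_params else None
        ),
        "parameters": {
            "min_family_size": config.min_family_size,
            "min_baseq": config.min_baseq,
            "threshold": config.threshold,
            "calibration": (
                {
                    "candidates": [float(c) for c in config.calibration[0]],
                    "target_specificity": config.calibration[1],
                }
                if config.calibration
                else None
            ),
            "excluded_sites": [list(s) for s in config.excluded_sites],
            "sim_params": (
                dataclasses.asdict(config.sim_params) if config.sim_params else None
            ),
        },
        "stages": {},
    }

    def stage(name: str):
        t0 = time.perf_counter()

        def done(outputs: dict):
            dt = time.perf_counter() - t0
            log.info("stage %s done in %.2fs", name, dt)
            manifest["stages"][name] = {"outputs": outputs, "seconds": round(dt, 3)}

        return done

    # 1. panel
    done = stage("panel")
    panel = load_panel(config.panel_path) if config.panel_path else default_panel()
    panel = panel.with_excluded(set(tuple(s) for s in config.excluded_sites))
    panel_out = out / "panel.tsv"
    write_panel(panel, panel_out)
    done({"panel": str(panel_out)})

    # 2. inputs (simulate or load)
    done = stage("inputs")
    try:
        metas, counts, source = _load_inputs(config, panel)
    except Exception as exc:  # noqa: BLE001 - annotate stage
        raise PipelineError("inputs", str(exc)) from exc
    sheet_out = out / "sample_sheet.tsv"
    counts_out = out / "site_counts.tsv"
    write_sample_sheet(metas, sheet_out)
    write_site_counts(counts, counts_out)
    done({"sample_sheet": str(sheet_out), "site_counts": str(counts_out), "source": source})

    # 3. quantify
    done = stage("quantify")
    vaf_table = vaf_table_from_counts(counts, panel)
    vaf_out = out / "vaf_table.tsv"
    write_vaf_table(vaf_table, vaf_out)
    stats = max_vaf_table(vaf_table, panel)
    max_out = out / "max_vaf.tsv"
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "max_vaf": s.max_vaf,
                "argmax": f"{s.argmax[0]}:{s.argmax[1]}:{s.argmax[2]}",
                "n_sites_evaluated": s.n_sites_evaluated,
                "alt_count": s.alt_count,
                "depth": s.depth,
            }
            for s in stats
        ]
    ).to_csv(max_out, sep="\t", index=False, float_format="%.6g")
    done({"vaf_table": str(vaf_out), "max_vaf": str(max_out)})

    # 4. threshold (fixed or calibrated on the training cohort)
    done = stage("threshold")
    meta_by_id = {m.sample_id: m for m in metas}
    if config.calibration is not None:
        training = [
            s
            for s in stats
            if meta_by_id[s.sample_id].cohort == "haematuria_training"
            and not meta_by_id[s.sample_id].bc_status
        ]
        if not training:
            raise PipelineError("threshold", "no haematuria_training samples to calibrate on")
        candidates, target = config.calibration
        try:
            calib = calibrate_threshold(training, list(candidates), target)
        except CalibrationError as exc:
            raise PipelineError("threshold", str(exc)) from exc
        threshold = calib.selected
        calib_report = {
            "candidates": [float(c) for c in calib.candidates],
            "training_specificities": calib.specificities,
            "selected_threshold": float(calib.selected),
            "target_specificity": calib.target_specificity,
            "n_training": len(training),
        }
    else:
        threshold = as_fraction(config.threshold)
        calib_report = {"fixed_threshold": float(threshold)}
    calib_out = out / "calibration.json"
    calib_out.write_text(json.dumps(calib_report, indent=2))
    done({"calibration": str(calib_out), "threshold": float(threshold)})

    # 5. calls
    done = stage("calls")
    calls = [classify(s, threshold) for s in stats]
    calls_out = out / "calls.tsv"
    pd.DataFrame(
        [
            {"sample_id": c.sample_id, "call": "positive" if c.positive else "negative",
             "threshold": float(c.threshold)}
            for c in calls
        ]
    ).to_csv(calls_out, sep="\t", index=False)
    done({"calls": str(calls_out)})

    # 6. report
    done = stage("report")
    outputs = _report(out, panel, metas, vaf_table, stats, calls, threshold)
    done(outputs)

    manifest_out = out / "manifest.json"
    manifest_out.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _report(out, panel, metas, vaf_table, stats, calls, threshold) -> dict:
    meta_by_id = {m.sample_id: m for m in metas}
    metrics: dict = {"threshold": float(threshold)}

    def subset(pred):
        ids = {m.sample_id for m in metas if pred(m)}
        return (
            [c for c in calls if c.sample_id in ids],
            [m for m in metas if m.sample_id in ids],
            [s for s in stats if s.sample_id in ids],
        )

    # incident disease: haematuria test cohort
    inc_calls, inc_metas, inc_stats = subset(lambda m: m.cohort == "haematuria_test")
    if inc_calls and any(m.bc_status for m in inc_metas) and any(
        not m.bc_status for m in inc_metas
    ):
        table, sens, spec = sens_spec(inc_calls, inc_metas)
        roc = roc_auc(
            [s.max_vaf for s in inc_stats],
            [meta_by_id[s.sample_id].bc_status for s in inc_stats],
        )
        roc.points().to_csv(out / "roc_incident.tsv", sep="\t", index=False)
        cmp_groups = compare_groups(
            [s.max_vaf for s in inc_stats if meta_by_id[s.sample_id].bc_status],
            [s.max_vaf for s in inc_stats if not meta_by_id[s.sample_id].bc_status],
        )
        metrics["incident"] = {
            "two_by_two": dataclasses.asdict(table),
            "sensitivity": dataclasses.asdict(sens),
            "specificity": dataclasses.asdict(spec),
            "sensitivity_pct": sens.percent_str(),
            "specificity_pct": spec.percent_str(),
            "auc": roc.auc,
            "median_max_vaf_bc_pct": percent(cmp_groups.median_a, 2),
            "median_max_vaf_non_bc_pct": percent(cmp_groups.median_b, 2),
            "median_comparison_p": cmp_groups.p_value,
        }
        strat = stratified_table(
            vaf_table[vaf_table["sample_id"].isin([m.sample_id for m in inc_metas])],
            inc_metas,
            panel,
            threshold,
        )
        strat.to_csv(out / "stratified_incident.tsv", sep="\t")

    # age-band false-positive rates over all disease-free haematuria samples
    fp_calls, fp_metas, _ = subset(
        lambda m: m.cohort in ("haematuria_training", "haematuria_test")
        and not m.bc_status
    )
    if fp_calls:
        bands = age_band_fpr(fp_calls, fp_metas)
        bands.to_csv(out / "age_band_fpr.tsv", sep="\t", index=False)
        records = bands.to_dict(orient="records")
        for rec in records:  # keep the JSON strict: no bare Infinity tokens
            if not math.isfinite(rec["age_hi"]):
                rec["age_hi"] = None
            if isinstance(rec["fpr"], float) and math.isnan(rec["fpr"]):
                rec["fpr"] = None
        metrics["age_band_fpr"] = records

    # surveillance: recurrence detection + relative risk of future recurrence
    sur_calls, sur_metas, sur_stats = subset(lambda m: m.cohort == "surveillance")
    if sur_calls and any(m.bc_status for m in sur_metas) and any(
        not m.bc_status for m in sur_metas
    ):
        table, sens, spec = sens_spec(sur_calls, sur_metas)
        roc = roc_auc(
            [s.max_vaf for s in sur_stats],
            [meta_by_id[s.sample_id].bc_status for s in sur_stats],
        )
        roc.points().to_csv(out / "roc_surveillance.tsv", sep="\t", index=False)
        metrics["surveillance"] = {
            "two_by_two": dataclasses.asdict(table),
            "sensitivity": dataclasses.asdict(sens),
            "specificity": dataclasses.asdict(spec),
            "sensitivity_pct": sens.percent_str(),
            "specificity_pct": spec.percent_str(),
            "auc": roc.auc,
        }
        pos = {c.sample_id for c in sur_calls if c.positive}
        neg_now = [m for m in sur_metas if not m.bc_status and m.future_recurrence is not None]
        a = sum(1 for m in neg_now if m.sample_id in pos and m.future_recurrence)
        b = sum(1 for m in neg_now if m.sample_id in pos and not m.future_recurrence)
        c_ = sum(1 for m in neg_now if m.sample_id not in pos and m.future_recurrence)
        d = sum(1 for m in neg_now if m.sample_id not in pos and not m.future_recurrence)
        if a + b > 0 and c_ + d > 0 and (a > 0 or c_ > 0):
            rr = relative_risk(a, b, c_, d)
            metrics["future_recurrence"] = {
                "two_by_two": {"a": a, "b": b, "c": c_, "d": d},
                "rr": rr.rr,
                "rr_ci": [rr.lower, rr.upper],
                "method": rr.method,
            }

    metrics_out = out / "metrics.json"
    metrics_out.write_text(json.dumps(metrics, indent=2, default=float))
    outputs = {"metrics": str(metrics_out)}
    return outputs
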