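"""End-to-end pipeline: growth CSV + plates + metadata -> cohort statistics.

Stages: score every plasma growth curve against the plasma-free control
baseline; aggregate ELISA replicates, test samples against background
wells, and quantify competition; join everything into the per-animal
cohort table; run the population mixed models, the between-assay
regressions and the killing-class summary. All outputs are written with a
machine-readable run manifest so a run can be reproduced bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .bka import (
    AssayConfig,
    CurveRole,
    GrowthCurve,
    average_replicates,
    control_baseline,
    score_bka,
    with_class,
)
from .elisa import (
    ElisaPlate,
    WellRole,
    aggregate_replicates,
    compare_to_background,
    competition_reduction,
    fit_standard_curve,
    well_to_index,
)
from .stats import (
    cross_assay_regression,
    killing_class_summary,
    population_mixed_model,
    validate_cohort,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending item."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"[{stage}] {detail}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs, outputs and method flags for one pipeline run."""

    growth_csv: str
    plate_paths: tuple[tuple[str, str], ...]  # (values, layout) pairs
    metadata_csv: str
    outdir: str
    seed: int = 0
    assay: AssayConfig = field(default_factory=AssayConfig)
    use_lrt: bool = False  # likelihood-ratio instead of Wald for the mixed model

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def score_growth_stage(
    curves: list[GrowthCurve], config: AssayConfig
) -> tuple[pd.DataFrame, float]:
    """Score all curves against the control baseline.

    Plasma and heat-inactivated curves are scored per (sample, role),
    technical replicates averaged on the hours scale, and classified
    relative to the mean control crossing time. Returns the per-sample
    results table and the baseline in hours.
    """
    controls = [c for c in curves if c.role is CurveRole.CONTROL]
    if not controls:
        raise PipelineError("bka", "no control growth curves in input")
    baseline = control_baseline(controls, config)
    rows = []
    for role in (CurveRole.PLASMA, CurveRole.HEAT_INACTIVATED):
        by_sample: dict[str, list[GrowthCurve]] = {}
        for c in curves:
            if c.role is role:
                by_sample.setdefault(c.sample_id, []).append(c)
        for sid, group in sorted(by_sample.items()):
            try:
                scored = [score_bka(c, config) for c in group]
                merged = with_class(average_replicates(scored, config), baseline)
            except ValueError as exc:
                raise PipelineError("bka", f"sample {sid!r}: {exc}") from exc
            rows.append(
                {
                    "sample_id": sid,
                    "role": role.value,
                    "grew": merged.grew,
                    "t_threshold_h": merged.t_threshold,
                    "censored": merged.censored,
                    "bka_ln_t": merged.ln_t,
                    "killing_class": merged.killing_class.value,
                }
            )
    return pd.DataFrame(rows), baseline


def elisa_stage(plates: list[ElisaPlate], config: AssayConfig) -> dict:
    """Aggregate samples, run background tests, quantify competition.

    Background testing follows the assay's validation design: the
    maximal-staining sample, the minimal-staining sample and the
    secondary-only wells are each compared against the BSA blank wells at
    the Bonferroni-corrected level for three comparisons.
    """
    per_sample: dict[str, dict] = {}
    bsa_all, sec_all = [], []
    competitions = []
    standards = []
    for plate in plates:
        bsa_all.extend(plate.values(WellRole.BSA_BLANK).tolist())
        sec_all.extend(plate.values(WellRole.SECONDARY_ONLY).tolist())
        for well, info in plate.layout.items():
            if info.role is WellRole.STANDARD:
                r, c = well_to_index(well)
                standards.append((info.concentration, plate.wells[r, c]))
        for sid in plate.sample_ids():
            res = aggregate_replicates(plate, sid)
            per_sample[sid] = {
                "sample_id": sid,
                "mean_a450": res.mean_a450,
                "sd_a450": res.sd_a450,
                "se_a450": res.se_a450,
                "n_replicates": res.n_replicates,
                "sample_wells": plate.values(WellRole.SAMPLE, sid).tolist(),
            }
        comp_by_sample: dict[str, list[float]] = {}
        for well, info in plate.layout.items():
            if info.role is WellRole.COMPETITION:
                r, c = well_to_index(well)
                comp_by_sample.setdefault(info.paired_sample_id, []).append(plate.wells[r, c])
        for sid, vals in comp_by_sample.items():
            if sid not in per_sample:
                raise PipelineError("elisa", f"competition wells reference unknown sample {sid!r}")
            competitions.append(
                {
                    "sample_id": sid,
                    "reduction": competition_reduction(
                        per_sample[sid]["mean_a450"], float(np.mean(vals))
                    ),
                }
            )
    if not per_sample:
        raise PipelineError("elisa", "no sample wells on any plate")
    if not bsa_all:
        raise PipelineError("elisa", "no BSA blank wells on any plate")

    table = pd.DataFrame(
        [{k: v for k, v in d.items() if k != "sample_wells"} for d in per_sample.values()]
    ).sort_values("sample_id", ignore_index=True)

    means = {sid: d["mean_a450"] for sid, d in per_sample.items()}
    max_sid = max(means, key=means.get)
    min_sid = min(means, key=means.get)
    comparisons = {}
    for name, wells in (
        ("max_sample_vs_bsa", per_sample[max_sid]["sample_wells"]),
        ("min_sample_vs_bsa", per_sample[min_sid]["sample_wells"]),
        ("secondary_only_vs_bsa", sec_all),
    ):
        if not wells:
            continue
        p, sig = compare_to_background(wells, bsa_all, alpha=config.bonferroni_alpha)
        comparisons[name] = {"p": p, "significant": sig}

    standard_curve = None
    if standards:
        try:
            standard_curve = fit_standard_curve(standards)
        except ValueError as exc:
            logger.warning("standard-curve fit skipped: %s", exc)
    return {
        "table": table,
        "background_comparisons": comparisons,
        "competition": pd.DataFrame(competitions) if competitions else pd.DataFrame(columns=["sample_id", "reduction"]),
        "standard_curve": standard_curve,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle to ``config.outdir``.

    Deterministic for fixed inputs and seed; nothing is written until all
    stages have succeeded.
    """
    try:
        curves = nio.read_growth_csv(config.growth_csv)
    except (ValueError, FileNotFoundError) as exc:
        raise PipelineError("read_growth", str(exc)) from exc
    if not curves:
        raise PipelineError("read_growth", "no curves in input")
    try:
        plates = [nio.read_plate_csv(v, l) for v, l in config.plate_paths]
        metadata = nio.read_metadata_csv(config.metadata_csv)
    except (ValueError, FileNotFoundError) as exc:
        raise PipelineError("read_inputs", str(exc)) from exc

    bka_table, baseline = score_growth_stage(curves, config.assay)
    elisa_out = elisa_stage(plates, config.assay)

    cohort = metadata.merge(
        elisa_out["table"][["sample_id", "mean_a450"]].rename(columns={"mean_a450": "nab_a450"}),
        on="sample_id",
        how="left",
    ).merge(
        bka_table.loc[bka_table["role"] == "plasma", ["sample_id", "bka_ln_t", "killing_class"]],
        on="sample_id",
        how="left",
    )
    validate_cohort(cohort, censor_time_h=config.assay.censor_time_h)

    stats_out: dict = {"control_baseline_h": baseline}
    try:
        mm_nab = population_mixed_model(cohort, "nab_a450", log_response=True, use_lrt=config.use_lrt)
        mm_bka = population_mixed_model(cohort, "bka_ln_t", log_response=False, use_lrt=config.use_lrt)
        stats_out["mixed_model_nab"] = dataclasses.asdict(mm_nab)
        stats_out["mixed_model_bka"] = dataclasses.asdict(mm_bka)
    except ValueError as exc:
        raise PipelineError("stats", str(exc)) from exc
    regressions = cross_assay_regression(cohort)
    stats_out["regressions"] = {
        name: {"slope": r.slope, "intercept": r.intercept, "r2": r.r2, "p_slope": r.p_slope, "n": r.n}
        for name, r in regressions.items()
    }
    summary = killing_class_summary(cohort)
    comp = elisa_out["competition"]
    stats_out["competition"] = {
        "n_pairs": int(len(comp)),
        "mean_reduction": float(comp["reduction"].mean()) if len(comp) else None,
        "sd_reduction": float(comp["reduction"].std(ddof=1)) if len(comp) > 1 else None,
    }
    stats_out["background_comparisons"] = elisa_out["background_comparisons"]

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(outdir / "cohort.csv", index=False)
    bka_table.to_csv(outdir / "bka_results.csv", index=False)
    elisa_out["table"].to_csv(outdir / "elisa_results.csv", index=False)
    comp.to_csv(outdir / "competition.csv", index=False)
    summary.to_csv(outdir / "killing_summary.csv", index=False)
    (outdir / "stats.json").write_text(json.dumps(stats_out, indent=2, default=float))
    manifest = {
        "config": dataclasses.asdict(config),
        "config_sha256": config.digest(),
        "seed": config.seed,
        "versions": {
            "nabassay": _safe_version("nabassay"),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return {
        "cohort": cohort,
        "bka": bka_table,
        "elisa": elisa_out["table"],
        "competition": comp,
        "killing_summary": summary,
        "stats": stats_out,
        "manifest": manifest,
    }


def _safe_version(name: str) -> str:
    try:
        return _pkg_version(name)
    except Exception:
        return "unknown"
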