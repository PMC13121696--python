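"""End-to-end orchestration: simulate → GFR → outcomes → events → stats → power.

Each stage is a thin driver over the library modules; ``run_pipeline``
executes them in order, writes the six output artifacts below under the
output directory, and returns a :class:`RunManifest` (config hash, seed,
per-stage row counts, output paths).  Reruns with the same config and seed
are bit-identical: floats are serialized at 10 significant digits and the
config hash is taken over the canonical JSON form.

Artifacts::

    cohort_long.csv     one row per (animal_id, group, time_h, analyte, value)
    iohexol_series.csv  per-injection concentration–time samples
    gfr_fits.csv        per-injection PK fit and measured GFR
    outcomes.csv        per-animal exclusion / recovery / slope / urinary indices
    km_curves.csv       Kaplan–Meier step tables per group
    stats.json          group tables, test results and the power curve
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import event_protocol, renal_outcomes, stats_core, trial_power
from .config import EffectConfig, StudyConfig, load_config
from .pk_gfr import IohexolSeries, PKFitError, estimate_gfr
from .renal_outcomes import MissingOutcome
from .synthetic_cohort import (
    AnimalRecord,
    cohort_to_long_frame,
    generate_cohort,
    iohexol_to_frame,
)

__all__ = [
    "RunManifest",
    "run_pipeline",
    "read_cohort_csv",
    "write_frame",
    "gfr_table",
    "outcomes_table",
    "events_analysis",
    "group_statistics",
]

logger = logging.getLogger("crushkit.pipeline")

FLOAT_FORMAT = "%.10g"


@dataclass(frozen=True)
class RunManifest:
    config_hash: str
    seed: int
    version: str
    row_counts: dict[str, int]
    outputs: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def _config_hash(study: StudyConfig, effects: EffectConfig) -> str:
    payload = {
        "study": dataclasses.asdict(study),
        "effects": dataclasses.asdict(effects),
    }
    canonical = json.dumps(payload, sort_keys=True, default=list)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_frame(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_cohort_csv(chem_path: str | Path, iohexol_path: str | Path | None = None):
    """Read the long-format cohort export back into typed frames.

    Returns (long_frame, iohexol_frame-or-None); schema violations raise a
    ValueError naming the missing column.  Extra columns are preserved.
    """
    long_df = pd.read_csv(chem_path)
    required = ["animal_id", "group", "time_h", "analyte", "value"]
    for col in required:
        if col not in long_df.columns:
            raise ValueError(f"cohort CSV is missing required column {col!r}")
    io_df = None
    if iohexol_path is not None:
        io_df = pd.read_csv(iohexol_path)
        for col in (
            "animal_id",
            "injection_time_h",
            "offset_min",
            "concentration_ug_ml",
            "dose_mg",
        ):
            if col not in io_df.columns:
                raise ValueError(f"iohexol CSV is missing required column {col!r}")
    return long_df, io_df


def gfr_table(cohort: list[AnimalRecord]) -> pd.DataFrame:
    """Fit every iohexol series in the cohort; one row per injection."""
    rows = []
    for a in cohort:
        for s in a.iohexol_series:
            try:
                fit = estimate_gfr(s)
                rows.append(
                    dict(
                        animal_id=a.animal_id,
                        group=a.group,
                        injection_time_h=s.injection_time_h,
                        model_order=fit.model_order,
                        auc_mg_min_per_l=fit.auc_mg_min_per_l,
                        gfr_ml_min=fit.gfr_ml_min,
                        converged=fit.converged,
                        fallback_used=fit.fallback_used,
                        rss=fit.rss,
                    )
                )
            except PKFitError as e:
                rows.append(
                    dict(
                        animal_id=a.animal_id,
                        group=a.group,
                        injection_time_h=s.injection_time_h,
                        model_order=np.nan,
                        auc_mg_min_per_l=np.nan,
                        gfr_ml_min=np.nan,
                        converged=False,
                        fallback_used=True,
                        rss=np.nan,
                        error=str(e),
                    )
                )
    return pd.DataFrame(rows)


def outcomes_table(
    cohort: list[AnimalRecord],
    gfr_df: pd.DataFrame,
    study: StudyConfig,
    rule: renal_outcomes.ExclusionRule | None = None,
) -> pd.DataFrame:
    """Per-animal outcomes: exclusion flags, rapid-recovery classification,
    GFR fraction-of-baseline and 24→48 h slope, urinary indices.

    The three iohexol injections (1, 19, 43 h) yield the GFR estimates the
    study reports at ~6, 24 and 48 h; the last two feed the recovery slope.
    """
    renal_outcomes.apply_exclusions(cohort, rule or renal_outcomes.ExclusionRule())
    inj_times = study.iohexol_injection_times_h
    rows = []
    for a in cohort:
        t, cr = a.chem_series("creatinine_mg_dl")
        try:
            rec = renal_outcomes.classify_rapid_recovery(
                t, cr, study.recovery_fraction, study.endpoint_h
            )
            recovery = dict(
                max_creatinine_mg_dl=rec.max_creatinine_mg_dl,
                creatinine_48h_mg_dl=rec.creatinine_48h_mg_dl,
                ratio_to_max=rec.ratio_to_max,
                rapid_recovery=rec.rapid_recovery,
                creatinine_30pct_recovery=rec.creatinine_30pct_recovery,
            )
        except MissingOutcome as e:
            recovery = dict(rapid_recovery=None, missing_reason=str(e))

        sub = gfr_df[gfr_df.animal_id == a.animal_id]
        gfr_by_inj = {
            float(r.injection_time_h): float(r.gfr_ml_min)
            for r in sub.itertuples()
            if np.isfinite(r.gfr_ml_min)
        }
        gfr_first = gfr_by_inj.get(inj_times[0])
        gfr_24 = gfr_by_inj.get(inj_times[-2]) if len(inj_times) >= 2 else None
        gfr_48 = gfr_by_inj.get(inj_times[-1])
        try:
            slope = renal_outcomes.gfr_recovery_slope(gfr_24, gfr_48)
        except MissingOutcome:
            slope = np.nan
        baseline_gfr = a.true_params.get("baseline_gfr_ml_min")
        gfr_frac = (
            gfr_48 / baseline_gfr if gfr_48 is not None and baseline_gfr else np.nan
        )

        u_t = np.array([u.time_h for u in a.urine])
        porph = np.array([u.urine_porphyrin_ug for u in a.urine])
        post = u_t >= 0
        cum_porph = (
            renal_outcomes.cumulative_porphyrin_excretion(u_t[post], porph[post])
            if post.sum() >= 2
            else np.nan
        )
        # fractional excretion of myoglobin at the first post-drug sample
        fe_mb = np.nan
        for s_u, s_c in zip(a.urine, a.chem):
            if s_u.time_h > 0:
                try:
                    fe_mb = renal_outcomes.fractional_excretion_myoglobin(
                        s_u.urine_myoglobin_ng_ml,
                        s_c.plasma_myoglobin_ng_ml,
                        s_u.urine_creatinine_mg_dl,
                        s_c.creatinine_mg_dl,
                    )
                except ValueError:
                    fe_mb = np.nan
                break
        rows.append(
            dict(
                animal_id=a.animal_id,
                group=a.group,
                excluded=a.excluded,
                exclusion_reason=a.exclusion_reason,
                gfr_first_ml_min=gfr_first,
                gfr_24_ml_min=gfr_24,
                gfr_48_ml_min=gfr_48,
                gfr_fraction_of_baseline=gfr_frac,
                gfr_slope_24_48=slope,
                n_interventions=len(a.events),
                cumulative_porphyrin=cum_porph,
                fe_myoglobin_first=fe_mb,
                **recovery,
            )
        )
    return pd.DataFrame(rows)


def events_analysis(
    cohort: list[AnimalRecord], study: StudyConfig
) -> tuple[pd.DataFrame, dict]:
    """Time-to-first-intervention KM curves and log-rank comparisons.

    Returns (km step table, results dict).  Animals with no intervention by
    the endpoint are censored at 48 h.
    """
    times, observed, groups = [], [], []
    for a in cohort:
        if a.excluded:
            continue
        post_events = [e for e in a.events if e.time_h >= 0]
        if post_events:
            times.append(min(e.time_h for e in post_events))
            observed.append(True)
        else:
            times.append(study.endpoint_h)
            observed.append(False)
        groups.append(a.group)

    km_rows = []
    results: dict = {"logrank": {}}
    data_all = event_protocol.SurvivalDataset(
        tuple(times), tuple(observed), tuple(groups)
    )
    for g, curve in event_protocol.km_estimate(data_all).items():
        for t, s, n, d in zip(curve.times, curve.survival, curve.n_at_risk, curve.n_events):
            km_rows.append(dict(group=g, time_h=t, survival=s, n_at_risk=n, n_events=d))

    def _pair(g1: str, g2: str) -> None:
        idx = [i for i, g in enumerate(groups) if g in (g1, g2)]
        if not idx or len({groups[i] for i in idx}) < 2:
            results["logrank"][f"{g1}_vs_{g2}"] = {"skipped": "group absent"}
            return
        sub = event_protocol.SurvivalDataset(
            tuple(times[i] for i in idx),
            tuple(observed[i] for i in idx),
            tuple(groups[i] for i in idx),
        )
        try:
            r = event_protocol.logrank_test(sub)
            results["logrank"][f"{g1}_vs_{g2}"] = dict(
                statistic=r.statistic, df=r.df, p=r.p
            )
        except ValueError as e:
            results["logrank"][f"{g1}_vs_{g2}"] = {"skipped": str(e)}

    _pair("no_impact", "vehicle")
    _pair("vehicle", "cilastatin")

    counts = {
        g: [len([e for e in a.events if e.time_h >= 0]) for a in cohort
            if a.group == g and not a.excluded]
        for g in ("no_impact", "vehicle", "cilastatin")
    }
    results["intervention_counts_median_iqr"] = {
        g: stats_core.median_iqr(v) if v else None for g, v in counts.items()
    }
    for name, (ga, gb) in {
        "impact_vs_no_impact": ("no_impact", "vehicle"),
        "vehicle_vs_cilastatin": ("cilastatin", "vehicle"),
    }.items():
        try:
            results[f"intervention_ratio_{name}"] = event_protocol.intervention_ratio(
                counts[ga], counts[gb]
            )
        except ValueError as e:
            results[f"intervention_ratio_{name}"] = f"skipped: {e}"
    return pd.DataFrame(km_rows), results


def group_statistics(outcomes: pd.DataFrame) -> dict:
    """Recovery 2x2 inference (exact and chi-square) and the Welch test on
    48 h porphyrin excretion, vehicle vs cilastatin."""
    out: dict = {}
    inc = outcomes[~outcomes.excluded & outcomes.rapid_recovery.notna()]
    cil = inc[inc.group == "cilastatin"]
    veh = inc[inc.group == "vehicle"]
    if len(cil) == 0 or len(veh) == 0:
        out["recovery"] = {"skipped": "a comparison group is empty"}
    else:
        a = int(cil.rapid_recovery.sum())
        b = int(len(cil) - a)
        c = int(veh.rapid_recovery.sum())
        d = int(len(veh) - c)
        table = stats_core.ContingencyTable2x2(a, b, c, d)
        rec: dict = {
            "table": [[a, b], [c, d]],
            "proportion_cilastatin": a / len(cil),
            "proportion_vehicle": c / len(veh),
            "fisher_exact_p": stats_core.fisher_exact_2x2(table),
        }
        try:
            chi = stats_core.chi_square_2x2(table)
            rec["chi_square"] = chi.to_record()
        except ValueError as e:
            rec["chi_square"] = {"skipped": str(e)}
        out["recovery"] = rec

    p_cil = cil.cumulative_porphyrin.dropna() if len(cil) else pd.Series(dtype=float)
    p_veh = veh.cumulative_porphyrin.dropna() if len(veh) else pd.Series(dtype=float)
    if len(p_cil) >= 2 and len(p_veh) >= 2:
        summary = stats_core.SummaryStats2(
            float(p_veh.mean()), float(p_veh.std(ddof=1)), len(p_veh),
            float(p_cil.mean()), float(p_cil.std(ddof=1)), len(p_cil),
        )
        out["porphyrin_welch"] = stats_core.welch_t(summary).to_record()
        out["porphyrin_means"] = {
            "vehicle": float(p_veh.mean()),
            "cilastatin": float(p_cil.mean()),
        }
    else:
        out["porphyrin_welch"] = {"skipped": "insufficient porphyrin data"}
    return out


def run_pipeline(
    config_path: str | Path | None = None,
    out_dir: str | Path = "results/pipeline",
    seed: int | None = None,
    study: StudyConfig | None = None,
    effects: EffectConfig | None = None,
    power_reps: int | None = None,
) -> RunManifest:
    """Execute all stages in order and write the six artifacts.

    ``seed`` overrides the config seed; ``power_reps`` overrides the power
    simulation's replicates (the full 500-per-n grid is the default).
    """
    if config_path is not None:
        study, effects = load_config(config_path)
    study = study or StudyConfig()
    effects = effects or EffectConfig()
    if seed is not None:
        study = dataclasses.replace(study, seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    counts: dict[str, int] = {}

    def _stage(name: str, **info) -> None:
        logger.info("stage=%s %s", name, json.dumps(info, default=str))

    cohort = generate_cohort(study, effects)
    long_df = cohort_to_long_frame(cohort)
    io_df = iohexol_to_frame(cohort)
    write_frame(long_df, out / "cohort_long.csv")
    write_frame(io_df, out / "iohexol_series.csv")
    outputs["cohort_long"] = str(out / "cohort_long.csv")
    outputs["iohexol_series"] = str(out / "iohexol_series.csv")
    counts["simulate"] = len(cohort)
    _stage("simulate", animals=len(cohort), seed=study.seed)

    gfr_df = gfr_table(cohort)
    write_frame(gfr_df, out / "gfr_fits.csv")
    outputs["gfr_fits"] = str(out / "gfr_fits.csv")
    counts["gfr"] = len(gfr_df)
    _stage("gfr", fits=len(gfr_df))

    outcomes = outcomes_table(cohort, gfr_df, study)
    write_frame(outcomes, out / "outcomes.csv")
    outputs["outcomes"] = str(out / "outcomes.csv")
    counts["outcomes"] = len(outcomes)
    _stage("outcomes", animals=len(outcomes))

    km_df, event_results = events_analysis(cohort, study)
    write_frame(km_df, out / "km_curves.csv")
    outputs["km_curves"] = str(out / "km_curves.csv")
    counts["events"] = len(km_df)
    _stage("events", km_rows=len(km_df))

    stats_results = group_statistics(outcomes)
    counts["stats"] = len(stats_results)
    _stage("stats", tests=len(stats_results))

    pw_cfg = trial_power.PowerSimConfig(
        p_treat=effects.recovery_probability["cilastatin"],
        p_ctrl=effects.recovery_probability["vehicle"],
        reps_per_n=power_reps or 500,
        seed=study.seed,
    )
    curve = trial_power.power_curve(pw_cfg)
    counts["power"] = len(curve.n_totals)
    _stage("power", minimal_n=curve.minimal_n_total)

    stats_payload = {
        "events": event_results,
        "group_tests": stats_results,
        "power": dataclasses.asdict(curve),
    }
    (out / "stats.json").write_text(json.dumps(stats_payload, indent=2, default=float))
    outputs["stats"] = str(out / "stats.json")

    manifest = RunManifest(
        config_hash=_config_hash(study, effects),
        seed=study.seed,
        version="0.1.0",
        row_counts=counts,
        outputs=outputs,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
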