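"""Study-design and effect-size configuration.

:class:`StudyConfig` encodes the fixed experimental design of the 48 h
porcine crush-injury protocol — group sizes, the blood/urine sampling
schedule, the three iohexol injections with their post-dose sampling
offsets, and the hyperkalemia treatment threshold.  Study time zero is drug
administration (30 min after impact); the baseline draw carries negative
time.

:class:`EffectConfig` holds the generative effect sizes and nuisance
magnitudes used by the synthetic-cohort generator.  The treated/control
rapid-recovery probabilities default to the observed study proportions
(0.571 and 0.111); the remaining magnitudes are physiologically realistic
values for 40 kg swine, documented in the methods note.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["StudyConfig", "EffectConfig", "load_config", "dump_config"]

GROUPS = ("no_impact", "vehicle", "cilastatin")

# OmniPaque 300: 647 mg iohexol (300 mg iodine) per mL; the protocol injects 5 mL
IOHEXOL_MG_PER_ML = 647.0
INJECTION_VOLUME_ML = 5.0


def _check_increasing(name: str, seq) -> None:
    seq = list(seq)
    if any(b <= a for a, b in zip(seq, seq[1:])):
        raise ValueError(f"{name} must be strictly increasing")


@dataclass
class StudyConfig:
    """Experimental design constants (times in hours from drug administration)."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"no_impact": 6, "vehicle": 9, "cilastatin": 21}
    )
    animal_weight_kg: float = 40.0
    chem_times_h: tuple[float, ...] = (-1.5, 0.0, 2.0, 6.0, 12.0, 18.0, 24.0, 48.0)
    iohexol_injection_times_h: tuple[float, ...] = (1.0, 19.0, 43.0)
    iohexol_sample_offsets_min: tuple[float, ...] = (15, 30, 90, 120, 180, 240, 300)
    iohexol_dose_mg: float = INJECTION_VOLUME_ML * IOHEXOL_MG_PER_ML
    k_threshold_mmol_l: float = 5.0
    recovery_fraction: float = 0.70
    impact_time_h: float = -0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"group_sizes: unknown group {g!r}")
            if n < 0 or n != int(n):
                raise ValueError(f"group_sizes[{g!r}] must be a non-negative integer")
        if self.animal_weight_kg <= 0:
            raise ValueError("animal_weight_kg must be > 0")
        if self.iohexol_dose_mg <= 0:
            raise ValueError("iohexol_dose_mg must be > 0")
        if not 0.0 < self.recovery_fraction < 1.0:
            raise ValueError("recovery_fraction must lie in (0, 1)")
        self.chem_times_h = tuple(float(t) for t in self.chem_times_h)
        self.iohexol_injection_times_h = tuple(
            float(t) for t in self.iohexol_injection_times_h
        )
        self.iohexol_sample_offsets_min = tuple(
            float(t) for t in self.iohexol_sample_offsets_min
        )
        _check_increasing("chem_times_h", self.chem_times_h)
        _check_increasing("iohexol_injection_times_h", self.iohexol_injection_times_h)
        _check_increasing(
            "iohexol_sample_offsets_min", self.iohexol_sample_offsets_min
        )

    @property
    def baseline_time_h(self) -> float:
        return self.chem_times_h[0]

    @property
    def endpoint_h(self) -> float:
        return self.chem_times_h[-1]


def _per_group(default: dict[str, float]) -> field:
    return field(default_factory=lambda: dict(default))


@dataclass
class EffectConfig:
    """Generative magnitudes for the synthetic cohort (per-group maps keyed
    by no_impact / vehicle / cilastatin)."""

    baseline_gfr_ml_min_mean: float = 100.0
    baseline_gfr_ml_min_sd: float = 10.0
    # fraction of baseline GFR lost at the injured nadir (impacted groups;
    # non-impacted animals lose half this fraction from anesthesia/immobility)
    injury_gfr_drop_fraction: float = 0.65
    # linear GFR recovery from 24 h for animals on the recovering trajectory
    recovery_rate_per_h: dict[str, float] = _per_group(
        {"no_impact": 2.0, "vehicle": 2.4, "cilastatin": 2.7}
    )
    nonrecovery_rate_fraction: float = 0.10
    recovery_probability: dict[str, float] = _per_group(
        {"no_impact": 0.80, "vehicle": 0.111, "cilastatin": 0.571}
    )
    # creatinine one-compartment mass balance
    creatinine_production_rate_mg_min: float = 1.2
    creatinine_volume_l: float = 24.0
    creatinine_noise_cv: float = 0.03
    # creatine kinase: saturating rise CK(t) = base + max_rise * (1 - e^(-t/tau))
    ck_baseline_iu_l: float = 250.0
    ck_rise_rate: dict[str, float] = _per_group(
        {"no_impact": 8000.0, "vehicle": 17000.0, "cilastatin": 17000.0}
    )
    ck_tau_h: float = 18.0
    ck_noise_cv: float = 0.08
    # potassium: production tracks the CK rise curve, first-order relaxation
    k_baseline_mmol_l: float = 4.0
    k_rise_per_h: dict[str, float] = _per_group(
        {"no_impact": 0.5, "vehicle": 2.0, "cilastatin": 0.7}
    )
    # potassium release saturates faster than CK (cell lysis is immediate)
    k_tau_h: float = 3.0
    k_relaxation_per_h: float = 0.5
    k_noise_sd: float = 0.12
    intervention_k_drop_mmol_l: float = 0.8
    # iohexol assay
    iohexol_noise_cv: float = 0.05
    iohexol_v_central_l: float = 3.0
    iohexol_k12_per_min: float = 0.05
    iohexol_k21_per_min: float = 0.04
    # myoglobin / porphyrin excretion
    plasma_myoglobin_peak_ng_ml: float = 4200.0
    myoglobin_fe_base: float = 0.001
    myoglobin_fe_multiplier: dict[str, float] = _per_group(
        {"no_impact": 1.0, "vehicle": 1.0, "cilastatin": 3.0}
    )
    porphyrin_rate_ug_per_ug_cr_h: float = 1.096
    porphyrin_multiplier: dict[str, float] = _per_group(
        {"no_impact": 0.3, "vehicle": 1.0, "cilastatin": 2.1}
    )
    porphyrin_between_animal_sd_log: float = 0.55
    # urine
    urine_output_baseline_ml_kg_h: float = 3.6
    urine_output_nadir_ml_kg_h: float = 0.5
    cilastatin_first_hour_diuresis_factor: float = 1.67
    urine_creatinine_mg_dl: float = 50.0

    def __post_init__(self) -> None:
        for name in ("recovery_probability",):
            for g, p in getattr(self, name).items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"{name}[{g!r}] must be a probability in [0, 1], got {p}"
                    )
        for name in ("iohexol_noise_cv", "creatinine_noise_cv", "ck_noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.creatinine_volume_l <= 0:
            raise ValueError("creatinine_volume_l must be > 0")
        if self.intervention_k_drop_mmol_l <= 0:
            raise ValueError("intervention_k_drop_mmol_l must be > 0")


def load_config(path: str | Path) -> tuple[StudyConfig, EffectConfig]:
    """Read a YAML or JSON config file with optional ``study`` and
    ``effects`` sections; unspecified fields keep their defaults."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    data = data or {}
    study = StudyConfig(**(data.get("study") or {}))
    effects = EffectConfig(**(data.get("effects") or {}))
    return study, effects


def dump_config(study: StudyConfig, effects: EffectConfig, path: str | Path) -> None:
    path = Path(path)
    payload = {"study": asdict(study), "effects": asdict(effects)}
    # tuples -> lists for clean round-tripping
    payload = json.loads(json.dumps(payload))
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
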