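"""Synthetic multi-generation cohort generator.

Emulates the structure of a Dutch population-based aging cohort: four
10-year birth cohorts ("generations") aged 20-29 / 30-39 / 40-49 / 50-59 at
baseline, measured at five exposure waves spaced 5 years apart, with a
sixth wave carrying the physiological outcome panel. Exposures span four
domains (demographic, lifestyle, environmental, biological); each is either
continuous/ordinal (summarized downstream as AUE/TOE) or binary (percent
summaries). Ground-truth exposure effects on the five outcome indicators
are planted explicitly and recorded, so recovery of the planted predictors
by the downstream random-forest ranking can be tested.

Generative law
--------------
For a continuous exposure with baseline mean m, SD s, per-wave drift d,
generation offset g and within-person correlation rho, participant i's
value at wave w (w = 1..5) is

    x_iw = m + g + d (w - 1) + u_i + e_iw,

with random intercept u_i ~ N(0, rho s^2) and AR(1) wave noise e_iw of
stationary variance (1 - rho) s^2 and lag-1 correlation rho. Binary
exposures follow the same law on a per-person probability scale, clipped to
[0, 1], with independent Bernoulli draws per wave. Indicator latent values
at the outcome wave are linear in the *realized* summarized exposures of
the planted effects, plus sex- and age-dependent intercepts and Gaussian
noise — the simplest law under which parameter recovery has a known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .longitudinal import (
    ExposureDescriptor,
    default_summaries,
    compute_aue,
    compute_toe,
    percent_of_time,
    transitioned_no_to_yes,
)

INDICATOR_COLUMNS = {
    "sbp": "sbp_mmHg",
    "glucose": "glucose_mmol_L",
    "creatinine": "creatinine_mmol_L",
    "fvc": "fvc_L",
    "cognition": "cognition_z",
}

#: Fraction of women; matches the cohort's 53.3%.
P_FEMALE = 0.533

#: Residual SD of each indicator around its latent mean.
DEFAULT_NOISE_SD = {
    "sbp": 12.0,
    "glucose": 1.0,
    "creatinine": 10.0,
    "fvc": 0.45,
    "cognition": 0.9,
}

#: Indicator intercepts: value = base[sex] + age_slope * (age - 46).
#: Chosen so the scored totals sit high for the youngest outcome ages and
#: decline across generations, giving a crude-total gradient like a real
#: aging cohort's.
INDICATOR_BASE = {
    "sbp": {"male": 119.0, "female": 117.0, "age_slope": 0.55},
    "glucose": {"male": 5.2, "female": 5.0, "age_slope": 0.025},
    "creatinine": {"male": 95.0, "female": 71.0, "age_slope": 0.32},
    "fvc": {"male": 4.6, "female": 3.3, "age_slope": -0.030},
    "cognition": {"male": 0.75, "female": 0.85, "age_slope": -0.035},
}

_SUMMARY_REALIZERS = {
    "aue": compute_aue,
    "toe": compute_toe,
    "percent_of_time": percent_of_time,
    "transitioned_no_to_yes": transitioned_no_to_yes,
}


@dataclass(frozen=True)
class GenerationSpec:
    """One 10-year birth cohort stratum."""

    label: str
    n_participants: int
    baseline_age_range: tuple[int, int]
    n_waves: int = 5
    wave_spacing: int = 5

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError(f"{self.label}: n_participants must be >= 1")
        lo, hi = self.baseline_age_range
        if lo > hi:
            raise ValueError(f"{self.label}: baseline_age_range lower must be <= upper")
        if self.wave_spacing <= 0:
            raise ValueError(f"{self.label}: wave_spacing must be positive")


@dataclass(frozen=True)
class ExposureGeneratorSpec:
    """Generative parameters for one exposure.

    ``generation_shift`` gives one additive offset per generation (oldest
    shifts last), recycled as 0 when shorter than the generation list.
    ``level_values``/``level_probabilities`` define ordinal exposures
    (numeric-coded levels); binary exposures use ``baseline_mean`` as the
    wave-1 probability of "yes".
    """

    name: str
    domain: str
    dtype: str  # continuous | binary | ordinal
    baseline_mean: float = 0.0
    baseline_sd: float = 1.0
    level_values: tuple[float, ...] = ()
    level_probabilities: tuple[float, ...] = ()
    per_wave_drift: float = 0.0
    generation_shift: tuple[float, ...] = ()
    waves_measured: tuple[int, ...] = (1, 2, 3, 4, 5)
    within_person_correlation: float = 0.7
    time_varying: bool = True

    def __post_init__(self) -> None:
        if self.baseline_sd < 0:
            raise ValueError(f"{self.name}: baseline_sd must be >= 0")
        if not self.waves_measured:
            raise ValueError(f"{self.name}: waves_measured must be nonempty")
        if not 0.0 <= self.within_person_correlation <= 1.0:
            raise ValueError(f"{self.name}: within_person_correlation must lie in [0, 1]")
        if self.dtype == "ordinal":
            if len(self.level_values) != len(self.level_probabilities):
                raise ValueError(f"{self.name}: level values/probabilities length mismatch")
            if abs(sum(self.level_probabilities) - 1.0) > 1e-9:
                raise ValueError(f"{self.name}: level probabilities must sum to 1")

    def shift_for(self, generation_index: int) -> float:
        if generation_index < len(self.generation_shift):
            return self.generation_shift[generation_index]
        return 0.0


@dataclass(frozen=True)
class EffectSpec:
    """A planted ground-truth effect of one summarized exposure on one indicator."""

    exposure_name: str
    summary_kind: str  # aue | toe | percent_of_time | transitioned_no_to_yes
    target_indicator: str
    coefficient: float

    def __post_init__(self) -> None:
        if self.target_indicator not in INDICATOR_COLUMNS:
            raise ValueError(
                f"effect on {self.exposure_name}: unknown indicator "
                f"{self.target_indicator!r}; must be one of {sorted(INDICATOR_COLUMNS)}"
            )
        if self.summary_kind not in _SUMMARY_REALIZERS:
            raise ValueError(
                f"effect on {self.exposure_name}: unknown summary kind {self.summary_kind!r}"
            )
        if not np.isfinite(self.coefficient):
            raise ValueError(f"effect on {self.exposure_name}: coefficient must be finite")


def indicator_mean(indicator: str, sex: str, age: float) -> float:
    """Deterministic latent mean of an indicator before planted effects and noise."""
    cfg = INDICATOR_BASE[indicator]
    return cfg[sex] + cfg["age_slope"] * (age - 46.0)


def simulate_cohort(
    generations: Sequence[GenerationSpec],
    exposures: Sequence[ExposureGeneratorSpec],
    effects: Sequence[EffectSpec],
    noise_sd_per_indicator: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate the full cohort.

    Returns ``(wave_table, outcome_table, truth_record)``: the long-format
    exposure table (one row per participant per measured wave), the
    outcome-wave table (five indicators + sex + age), and a record of every
    planted effect with the reference value used to center it.
    """
    noise_sd = dict(DEFAULT_NOISE_SD)
    if noise_sd_per_indicator:
        noise_sd.update(noise_sd_per_indicator)
    known = {e.name for e in exposures}
    for eff in effects:
        if eff.exposure_name not in known:
            raise ValueError(
                f"effect references unknown exposure {eff.exposure_name!r}; "
                f"known exposures: {sorted(known)[:5]}..."
            )
    rng = np.random.default_rng(seed)

    frames = []
    outcome_rows = []
    pid_counter = 0
    for g_idx, gen in enumerate(generations):
        n = gen.n_participants
        pids = np.array([f"p{pid_counter + k:05d}" for k in range(n)])
        pid_counter += n
        lo, hi = gen.baseline_age_range
        baseline_age = rng.integers(lo, hi + 1, size=n)
        sex = np.where(rng.random(n) < P_FEMALE, "female", "male")
        waves = np.arange(1, gen.n_waves + 1)

        # exposure trajectories: dict name -> (n, n_waves) with NaN outside
        # the exposure's measured waves
        traj: dict[str, np.ndarray] = {}
        for spec in exposures:
            traj[spec.name] = _simulate_exposure(spec, g_idx, n, waves, sex, rng)
        if "sex_female" in traj:
            # the sex exposure mirrors the outcome-table sex assignment
            female = (sex == "female").astype(float)
            meas = ~np.isnan(traj["sex_female"])
            traj["sex_female"] = np.where(meas, female[:, None], np.nan)

        gen_long = pd.DataFrame(
            {
                "participant_id": np.repeat(pids, waves.size),
                "generation": gen.label,
                "wave": np.tile(waves, n),
                "age_at_wave": (
                    np.repeat(baseline_age, waves.size)
                    + np.tile((waves - 1) * gen.wave_spacing, n)
                ),
            }
        )
        for name, values in traj.items():
            gen_long[name] = values.reshape(-1)
        frames.append(gen_long)

        # outcome wave: baseline + 5 * spacing, jittered 0-3 years within
        # the measurement window
        age_w6 = baseline_age + 5 * gen.wave_spacing + rng.integers(0, 4, size=n)
        latent = {
            ind: np.array([indicator_mean(ind, s, a) for s, a in zip(sex, age_w6)])
            for ind in INDICATOR_COLUMNS
        }
        for eff in effects:
            realized = _realize_summary(traj[eff.exposure_name], waves, eff.summary_kind)
            reference = float(np.nanmean(realized))
            realized = np.where(np.isfinite(realized), realized, reference)
            latent[eff.target_indicator] = latent[eff.target_indicator] + eff.coefficient * (
                realized - reference
            )
        for ind in INDICATOR_COLUMNS:
            if noise_sd[ind] > 0:
                latent[ind] = latent[ind] + rng.normal(0.0, noise_sd[ind], size=n)

        outcome_rows.append(
            pd.DataFrame(
                {
                    "participant_id": pids,
                    "generation": gen.label,
                    "sex": sex,
                    "age_w6": age_w6,
                    **{
                        col: np.maximum(latent[ind], _floor(ind))
                        for ind, col in INDICATOR_COLUMNS.items()
                    },
                }
            )
        )

    wave_table = pd.concat(frames, ignore_index=True)
    outcome_table = pd.concat(outcome_rows, ignore_index=True)
    truth_record = {
        "seed": int(seed),
        "effects": [asdict(e) for e in effects],
        "noise_sd_per_indicator": noise_sd,
    }
    return wave_table, outcome_table, truth_record


def _floor(indicator: str) -> float:
    """Strictly positive floors for physically positive indicators."""
    return {"sbp": 60.0, "glucose": 2.0, "creatinine": 30.0, "fvc": 0.5}.get(
        indicator, -np.inf
    )


def _simulate_exposure(
    spec: ExposureGeneratorSpec,
    g_idx: int,
    n: int,
    waves: np.ndarray,
    sex: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate one exposure's (n, n_waves) trajectory for one generation."""
    nw = waves.size
    rho = spec.within_person_correlation
    shift = spec.shift_for(g_idx)

    if spec.dtype == "binary":
        base_p = spec.baseline_mean + shift
        u_sd = np.sqrt(rho) * spec.baseline_sd
        u = rng.normal(0.0, u_sd, size=n) if u_sd > 0 else np.zeros(n)
        p = base_p + u[:, None] + spec.per_wave_drift * (waves - 1)[None, :]
        p = np.clip(p, 0.0, 1.0)
        values = (rng.random((n, nw)) < p).astype(float)
    elif spec.dtype == "ordinal":
        levels = np.asarray(spec.level_values, dtype=float)
        probs = np.asarray(spec.level_probabilities, dtype=float)
        idx0 = rng.choice(levels.size, size=n, p=probs)
        values = np.repeat(levels[idx0][:, None], nw, axis=1)
        if spec.time_varying and rho < 1.0:
            # occasional band switches: re-draw a wave's level with small prob
            switch = rng.random((n, nw)) < (1.0 - rho) * 0.5
            redraw = rng.choice(levels.size, size=(n, nw), p=probs)
            values = np.where(switch, levels[redraw], values)
    else:
        m = spec.baseline_mean + shift
        u_sd = np.sqrt(rho) * spec.baseline_sd
        e_sd = np.sqrt(max(1.0 - rho, 0.0)) * spec.baseline_sd
        u = rng.normal(0.0, u_sd, size=n) if u_sd > 0 else np.zeros(n)
        e = np.zeros((n, nw))
        if e_sd > 0:
            # stationary AR(1) with lag-1 correlation rho
            innov_sd = e_sd * np.sqrt(max(1.0 - rho**2, 0.0))
            e[:, 0] = rng.normal(0.0, e_sd, size=n)
            for w in range(1, nw):
                e[:, w] = rho * e[:, w - 1] + rng.normal(0.0, innov_sd, size=n)
        values = m + u[:, None] + spec.per_wave_drift * (waves - 1)[None, :] + e

    mask = ~np.isin(waves, spec.waves_measured)
    values[:, mask] = np.nan
    if not spec.time_varying:
        keep = waves == min(spec.waves_measured)
        values[:, ~keep] = np.nan
    return values


def _realize_summary(traj: np.ndarray, waves: np.ndarray, kind: str) -> np.ndarray:
    """Apply a longitudinal summary to each participant's simulated trajectory."""
    func = _SUMMARY_REALIZERS[kind]
    out = np.empty(traj.shape[0])
    for i in range(traj.shape[0]):
        row = pd.Series(traj[i], index=waves).dropna()
        out[i] = func(row) if len(row) else np.nan
    return out


# ---------------------------------------------------------------------------
# Default cohort configuration
# ---------------------------------------------------------------------------

DEFAULT_GENERATIONS = (
    GenerationSpec("1960s", 459, (20, 29)),
    GenerationSpec("1950s", 1155, (30, 39)),
    GenerationSpec("1940s", 872, (40, 49)),
    GenerationSpec("1930s", 329, (50, 59)),
)

# generation-shift tuples run youngest (1960s) -> oldest (1930s)


def default_doetinchem_like_config() -> tuple[
    tuple[GenerationSpec, ...], tuple[ExposureGeneratorSpec, ...], tuple[EffectSpec, ...]
]:
    """Default four-generation, 86-feature cohort configuration.

    Continuous and ordinal time-varying exposures yield AUE + TOE features,
    binary time-varying exposures yield the two percent summaries, and four
    baseline exposures (sex indicator, educational level, nationality,
    single-household) enter once — 31 x 2 + 10 x 2 + 4 = 86 features.
    Means/SDs of the named exposures follow the published cohort
    characteristics (e.g. BMI mean 25.6 SD 3.5 with a +0.6/wave drift,
    diet-quality index mean 66.1 SD 11.8 measured in waves 2-4 only,
    cholesterol-lowering-medication use ~5% of the time rising with
    generation age); the remainder are set to plausible field values.
    Three effects are planted: average BMI on systolic blood pressure,
    percent of time on cholesterol-lowering medication on glucose, and
    average diet quality on cognition.
    """
    c = ExposureGeneratorSpec
    exposures: list[ExposureGeneratorSpec] = [
        # --- demographic ------------------------------------------------
        c("working_hours", "demographic", "continuous", 30.0, 14.0,
          per_wave_drift=-1.0, generation_shift=(6.0, 3.0, -2.0, -8.0)),
        c("household_size", "demographic", "continuous", 2.8, 1.2,
          per_wave_drift=-0.05),
        c("married", "demographic", "binary", 0.72, 0.15, per_wave_drift=0.01),
        c("lives_with_partner", "demographic", "binary", 0.80, 0.15),
        # --- lifestyle --------------------------------------------------
        c("alcohol_glasses_per_week", "lifestyle", "continuous", 7.5, 8.0,
          per_wave_drift=-0.2, generation_shift=(0.5, 0.0, -0.5, -1.0)),
        c("smoking_cigs_per_day", "lifestyle", "continuous", 4.5, 7.0,
          per_wave_drift=-0.4),
        c("packyears", "lifestyle", "continuous", 7.2, 11.5,
          per_wave_drift=0.8, generation_shift=(-3.6, -0.4, 1.1, 3.2)),
        c("years_smoked", "lifestyle", "continuous", 8.0, 10.0, per_wave_drift=0.6),
        c("occupational_activity_score", "lifestyle", "continuous", 2.2, 0.8,
          per_wave_drift=-0.05),
        c("mvpa_hours_per_week", "lifestyle", "continuous", 7.0, 5.0,
          per_wave_drift=-0.1, waves_measured=(2, 3, 4, 5)),
        c("sleep_hours", "lifestyle", "ordinal",
          level_values=(5.0, 6.0, 7.0, 8.0, 9.0),
          level_probabilities=(0.05, 0.20, 0.40, 0.28, 0.07)),
        c("dhd15", "lifestyle", "continuous", 63.7, 11.8, per_wave_drift=1.2,
          generation_shift=(-3.1, -0.4, 1.1, 3.2), waves_measured=(2, 3, 4)),
        c("current_smoker", "lifestyle", "binary", 0.30, 0.18, per_wave_drift=-0.02),
        c("current_alcohol_user", "lifestyle", "binary", 0.80, 0.12, per_wave_drift=-0.01),
        # --- environmental ----------------------------------------------
        c("no2_ugm3", "environmental", "continuous", 30.9, 1.8, per_wave_drift=-1.6,
          generation_shift=(-0.2, 0.1, 0.0, 0.3)),
        c("pm25_ugm3", "environmental", "continuous", 16.5, 1.2, per_wave_drift=-0.4),
        c("pm10_ugm3", "environmental", "continuous", 24.0, 1.6, per_wave_drift=-0.5),
        c("elemental_carbon_ugm3", "environmental", "continuous", 1.4, 0.25,
          per_wave_drift=-0.04),
        c("rail_noise_db", "environmental", "continuous", 48.0, 6.0),
        c("road_traffic_noise_db", "environmental", "continuous", 54.0, 5.0,
          per_wave_drift=0.1),
        c("ndvi_300m", "environmental", "continuous", 0.45, 0.10, per_wave_drift=0.005),
        c("ndvi_1000m", "environmental", "continuous", 0.50, 0.09),
        c("distance_major_road_m", "environmental", "continuous", 350.0, 180.0),
        c("positive_social_experiences", "environmental", "continuous", 14.0, 3.0),
        c("negative_social_experiences", "environmental", "continuous", 5.0, 2.2),
        c("social_support_elderly", "environmental", "continuous", 22.0, 4.5),
        c("loneliness_score", "environmental", "continuous", 2.5, 2.0,
          per_wave_drift=0.05),
        c("damp_stains", "environmental", "binary", 0.18, 0.10, per_wave_drift=-0.01),
        c("mold_growth", "environmental", "binary", 0.10, 0.08),
        c("pets_in_house", "environmental", "binary", 0.55, 0.18),
        c("env_tobacco_smoke", "environmental", "binary", 0.55, 0.20,
          per_wave_drift=-0.05, generation_shift=(0.02, 0.01, 0.0, -0.06)),
        c("gas_cooking", "environmental", "binary", 0.75, 0.12, per_wave_drift=-0.02),
        # --- biological -------------------------------------------------
        c("bmi", "biological", "continuous", 24.4, 3.5, per_wave_drift=0.6,
          generation_shift=(-1.0, -0.2, 0.4, 1.0)),
        c("waist_circumference_cm", "biological", "continuous", 85.0, 11.0,
          per_wave_drift=1.2, generation_shift=(-3.0, -0.5, 1.5, 3.0)),
        c("hip_circumference_cm", "biological", "continuous", 101.0, 8.0,
          per_wave_drift=0.6),
        c("waist_hip_ratio", "biological", "continuous", 0.85, 0.08,
          per_wave_drift=0.006, generation_shift=(-0.02, -0.005, 0.01, 0.02)),
        c("body_weight_kg", "biological", "continuous", 73.0, 12.0, per_wave_drift=1.4),
        c("total_cholesterol_mmol_L", "biological", "continuous", 5.3, 1.0,
          per_wave_drift=0.05, generation_shift=(-0.3, -0.05, 0.15, 0.3)),
        c("hdl_cholesterol_mmol_L", "biological", "continuous", 1.35, 0.35,
          per_wave_drift=0.01),
        c("total_hdl_ratio", "biological", "continuous", 4.1, 1.2, per_wave_drift=0.02),
        c("cholesterol_medication", "biological", "binary", 0.013, 0.09,
          per_wave_drift=0.02, generation_shift=(-0.01, -0.005, 0.01, 0.04)),
        # --- baseline (non-time-varying) --------------------------------
        c("sex_female", "demographic", "binary", P_FEMALE, 0.0,
          waves_measured=(1,), time_varying=False),
        c("educational_level", "demographic", "ordinal",
          level_values=(1.0, 2.0, 3.0, 4.0),
          level_probabilities=(0.14, 0.33, 0.263, 0.267),
          waves_measured=(1,), time_varying=False),
        c("nationality_dutch", "demographic", "binary", 0.95, 0.0,
          waves_measured=(1,), time_varying=False),
        c("single_household_baseline", "demographic", "binary", 0.15, 0.0,
          waves_measured=(1,), time_varying=False),
    ]

    effects = (
        EffectSpec("bmi", "aue", "sbp", 4.0),
        EffectSpec("cholesterol_medication", "percent_of_time", "glucose", 0.08),
        EffectSpec("dhd15", "aue", "cognition", 0.06),
    )
    return DEFAULT_GENERATIONS, tuple(exposures), effects


def expected_aue(
    spec: ExposureGeneratorSpec,
    generations: Sequence[GenerationSpec] = DEFAULT_GENERATIONS,
) -> float:
    """Population-expected AUE of an exposure under the generative law.

    Baseline mean plus drift times the mean wave offset over the measured
    waves, plus the participant-weighted mean generation shift.
    """
    w = np.asarray(spec.waves_measured, dtype=float)
    if spec.dtype == "ordinal":
        base = float(np.dot(spec.level_values, spec.level_probabilities))
    else:
        base = spec.baseline_mean
    base += spec.per_wave_drift * float(np.mean(w - 1))
    ns = np.array([g.n_participants for g in generations], dtype=float)
    shifts = np.array([spec.shift_for(i) for i in range(len(generations))])
    return float(base + np.dot(ns, shifts) / ns.sum())


def descriptors_for(exposures: Sequence[ExposureGeneratorSpec]) -> list[ExposureDescriptor]:
    """Derive summarization descriptors from generator specs."""
    out = []
    for e in exposures:
        out.append(
            ExposureDescriptor(
                name=e.name,
                domain=e.domain,
                dtype=e.dtype,
                waves_measured=e.waves_measured,
                summaries=default_summaries(e.dtype, e.time_varying),
                time_varying=e.time_varying,
            )
        )
    return out


def load_config(path: str | Path) -> tuple[
    tuple[GenerationSpec, ...], tuple[ExposureGeneratorSpec, ...], tuple[EffectSpec, ...]
]:
    """Load a cohort configuration from YAML (or JSON, a YAML subset).

    The file mirrors the three spec types under ``generations``,
    ``exposures`` and ``effects`` keys; list-valued fields are converted to
    the tuples the dataclasses expect.
    """
    import yaml

    d = yaml.safe_load(Path(path).read_text())
    gens = tuple(
        GenerationSpec(
            label=g["label"],
            n_participants=int(g["n_participants"]),
            baseline_age_range=tuple(g["baseline_age_range"]),
            n_waves=int(g.get("n_waves", 5)),
            wave_spacing=int(g.get("wave_spacing", 5)),
        )
        for g in d["generations"]
    )
    tuple_fields = ("level_values", "level_probabilities", "generation_shift", "waves_measured")
    exposures = tuple(
        ExposureGeneratorSpec(
            **{k: tuple(v) if k in tuple_fields else v for k, v in e.items()}
        )
        for e in d["exposures"]
    )
    effects = tuple(EffectSpec(**e) for e in d.get("effects", []))
    return gens, exposures, effects


def write_outputs(
    out_dir: str | Path,
    wave_table: pd.DataFrame,
    outcome_table: pd.DataFrame,
    truth_record: dict,
) -> None:
    """Write waves.csv, outcome.csv and truth.json under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    wave_table.to_csv(out / "waves.csv", index=False, float_format="%.6g")
    outcome_table.to_csv(out / "outcome.csv", index=False, float_format="%.6g")
    (out / "truth.json").write_text(json.dumps(truth_record, indent=2))
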