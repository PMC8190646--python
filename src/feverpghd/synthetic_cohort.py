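"""Synthetic PGHD cohort generator with known ground truth.

Real caregiver-logged fever data are proprietary, so the generator emits
cohorts with the statistical structure the analysis assumes, giving every
downstream stage a testable input with known truth:

* a latent, continuous fever course per child — baseline plus a logistic
  rise to a gamma-distributed peak followed by exponential decay;
* an additive, piecewise-linear antipyretic response kernel per dose
  (zero until a lag, linear descent to a nadir, linear recovery);
* a caregiver dosing policy — dose when the latent temperature crosses the
  caregiver's personal threshold, with a reaction delay; single-ingredient
  caregivers redose the same drug after >= 4 h, combination caregivers
  alternate a second (or third) ingredient at 4-6 h intervals, with the
  probability of being a combination caregiver increasing with the
  temperature at the first dose;
* irregular self-report measurements from a temperature-dependent sampling
  process, plus one reading at every dose, with Gaussian noise rounded to
  0.1 C.

Everything is driven by one :class:`numpy.random.Generator`, so a
(config, seed) pair fully determines every output byte. The emitted
``GroundTruth`` frame carries, per dosing-anchored case, the true group
label, true (noise-free) baseline and the exact latent delta-fever AUC at
the four analysis horizons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .case_builder import build_cases, classify_case, onset_bin
from .episode_builder import from_hours, to_hours
from .io_model import ACE, DEX, IBU, Cohort

STUDY_START = np.datetime64("2015-07-01T00:00")
STUDY_END = np.datetime64("2017-06-24T00:00")

HORIZONS = (6, 8, 10, 12)


@dataclass(frozen=True)
class DrugKernel:
    """Additive antipyretic response: 0 until ``lag_h``, linear descent to
    ``-nadir_drop_c`` at ``nadir_h``, linear recovery to 0 at ``duration_h``.

    The lag/nadir defaults sit on whole hours so the kernel is exactly
    representable on an hourly grid anchored at the dose.
    """

    lag_h: float = 1.0
    nadir_h: float = 2.0
    nadir_drop_c: float = 1.0
    duration_h: float = 6.0

    def __post_init__(self):
        if not (0 <= self.lag_h < self.nadir_h < self.duration_h):
            raise ValueError("need 0 <= lag < nadir < duration")
        if self.nadir_drop_c < 0:
            raise ValueError("nadir_drop_c must be >= 0")

    def __call__(self, u) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        down = (u - self.lag_h) / (self.nadir_h - self.lag_h)
        up = (self.duration_h - u) / (self.duration_h - self.nadir_h)
        return -self.nadir_drop_c * np.clip(np.minimum(down, up), 0.0, 1.0)


def _default_kernels() -> dict[str, DrugKernel]:
    return {
        ACE: DrugKernel(nadir_drop_c=0.9),
        IBU: DrugKernel(nadir_drop_c=1.1),
        DEX: DrugKernel(nadir_drop_c=1.0),
    }


def _default_band_probs() -> dict[str, float]:
    # monotone combination-propensity gradient over onset-temperature bands
    return {"<37": 0.13, "[37,38)": 0.1893, "[38,39)": 0.2381,
            "[39,40)": 0.3448, ">=40": 0.4140}


def _default_single_probs() -> dict[str, float]:
    return {ACE: 0.4008, DEX: 0.3674, IBU: 0.2318}


def _default_pattern_probs() -> dict[str, float]:
    return {"ACE-DEX": 0.5117, "ACE-IBU": 0.4062,
            "IBU-DEX": 0.0601, "ACE-IBU-DEX": 0.0220}


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator (one fever illness per child).

    Defaults emulate the marginal structure of a large caregiver-logged
    pediatric fever cohort: ~50.4% male, age ~ lognormal with mean 835 /
    SD 530 days truncated to [0, 7000], caregiver dosing thresholds
    ~ N(38.3, 0.3) C with a 5.5% share of under-38 dosers, and a
    combination-use gradient rising from ~24% in the [38,39) onset band to
    ~41% at >=40 C.
    """

    n_children: int = 1000
    seed: int = 0
    # demographics
    sex_male_prob: float = 0.5044
    age_lognormal_mu: float = 6.55881     # mean 835.35 d
    age_lognormal_sigma: float = 0.58145  # SD 529.80 d
    age_max_days: float = 7000.0
    weight_noise_sd_kg: float = 1.0
    # latent fever course
    baseline_temp_mean_c: float = 36.8
    baseline_temp_sd_c: float = 0.2
    fever_peak_shape: float = 4.0     # gamma rise above baseline,
    fever_peak_scale: float = 0.58    # mean ~2.3 C
    fever_onset_range_h: tuple[float, float] = (6.0, 18.0)
    fever_rise_h: float = 0.8         # logistic rise time scale
    fever_fall_h: float = 12.0        # exponential decay time constant
    temp_floor_c: float = 35.5
    # drug response
    drug_effect: dict[str, DrugKernel] = field(default_factory=_default_kernels)
    # dosing behaviour
    dosing_threshold_mean_c: float = 38.3
    dosing_threshold_sd_c: float = 0.3
    underthreshold_dosing_prob: float = 0.055
    underthreshold_range_c: tuple[float, float] = (37.0, 38.0)
    dose_delay_mean_h: float = 1.2
    dose_delay_cap_h: float = 3.0
    # under-threshold ("anxious") caregivers react almost immediately, so
    # their first dose is taken close to their personal threshold
    early_doser_delay_mean_h: float = 0.15
    early_doser_delay_cap_h: float = 0.5
    redose_interval_h: float = 4.0
    alternation_interval_h: tuple[float, float] = (4.0, 6.0)
    max_doses: int = 30
    combination_prob_by_band: dict[str, float] = field(
        default_factory=_default_band_probs)
    single_ingredient_probs: dict[str, float] = field(
        default_factory=_default_single_probs)
    combination_pattern_probs: dict[str, float] = field(
        default_factory=_default_pattern_probs)
    # null-calibration mode: one shared dosing policy for everyone and a
    # band-independent combination probability, so group labels are pure
    # relabelings (use with identical kernels)
    exchangeable_dosing: bool = False
    exchangeable_combination_prob: float = 0.5
    # measurement process
    measurement_rate_base_per_h: float = 0.10
    measurement_rate_per_deg: float = 0.8   # extra rate per C above 37.5
    measurement_rate_cap_per_h: float = 3.0
    measurement_rate_pivot_c: float = 37.5
    # post-dose response checks: after each dose the caregiver re-measures
    # at roughly these offsets (each kept with followup_prob, jittered)
    followup_offsets_h: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
    followup_prob: float = 0.85
    followup_jitter_h: float = 0.25
    measurement_noise_sd_c: float = 0.15
    # simulation window
    sim_window_h: float = 96.0
    step_h: float = 1.0 / 12.0  # 5-minute decision grid

    def validate(self) -> None:
        if self.n_children < 1:
            raise ValueError("n_children must be >= 1")
        probs = [self.sex_male_prob, self.underthreshold_dosing_prob,
                 self.exchangeable_combination_prob,
                 *self.combination_prob_by_band.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        for name, v in [("fever_rise_h", self.fever_rise_h),
                        ("fever_fall_h", self.fever_fall_h),
                        ("sim_window_h", self.sim_window_h),
                        ("step_h", self.step_h),
                        ("redose_interval_h", self.redose_interval_h)]:
            if v <= 0:
                raise ValueError(f"{name} must be > 0")
        lo, hi = self.alternation_interval_h
        if not 0 < lo <= hi:
            raise ValueError("alternation_interval_h must be 0 < lo <= hi")
        for table in (self.single_ingredient_probs,
                      self.combination_pattern_probs):
            if abs(sum(table.values()) - 1.0) > 1e-6:
                raise ValueError("ingredient/pattern probabilities must sum to 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "drug_effect" in raw:
            raw["drug_effect"] = {
                k: DrugKernel(**v) for k, v in raw["drug_effect"].items()}
        for key in ("fever_onset_range_h", "alternation_interval_h",
                    "underthreshold_range_c"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def null_config(n_children: int, seed: int = 0, **overrides) -> SimulationConfig:
    """A configuration under which the single/combination null is exactly
    true: identical kernels for all ingredients, one shared dosing policy,
    and a band-independent 50/50 group assignment."""
    kern = DrugKernel(nadir_drop_c=1.0)
    return SimulationConfig(
        n_children=n_children, seed=seed,
        drug_effect={ACE: kern, IBU: kern, DEX: kern},
        exchangeable_dosing=True,
        **overrides)


@dataclass
class FeverCourse:
    """One child's latent course, dosing trace and caregiver parameters."""

    child_id: str
    baseline_c: float
    peak_delta_c: float
    onset_h: float
    rise_h: float
    fall_h: float
    floor_c: float
    threshold_c: float
    kernels: Mapping[str, DrugKernel]
    policy: str = ""                 # intended: "single" | "combination"
    pattern: tuple[str, ...] = ()    # ingredient rotation
    dose_times_h: np.ndarray = field(default_factory=lambda: np.empty(0))
    dose_ingredients: list[str] = field(default_factory=list)

    def untreated(self, t) -> np.ndarray:
        """Latent temperature with no drug on board: baseline + logistic
        rise to the peak, decaying exponentially after onset."""
        t = np.asarray(t, dtype=float)
        rise = 1.0 / (1.0 + np.exp(-(t - self.onset_h) / self.rise_h))
        decay = np.exp(-np.maximum(t - self.onset_h, 0.0) / self.fall_h)
        return self.baseline_c + self.peak_delta_c * rise * decay

    def latent(self, t) -> np.ndarray:
        """Latent temperature including every administered dose's kernel."""
        t = np.asarray(t, dtype=float)
        out = self.untreated(t)
        for td, ing in zip(self.dose_times_h, self.dose_ingredients):
            out = out + self.kernels[ing](t - td)
        return np.maximum(out, self.floor_c)


# ---------------------------------------------------------------------------
# children
# ---------------------------------------------------------------------------

def weight_from_age(age_days) -> np.ndarray:
    """Monotone pediatric weight-for-age curve (kg), birth ~3.3 kg."""
    a = np.asarray(age_days, dtype=float)
    return 3.3 + 6.0 * (1.0 - np.exp(-a / 250.0)) + 1.6 * a / 365.0


def simulate_children(config: SimulationConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Draw child profiles plus each child's illness start time.

    Returns a frame with child_id, sex, age_days, weight_kg, illness_start_h
    (hours on the internal clock) and birth_date.
    """
    n = config.n_children
    ids = np.array([f"C{i:06d}" for i in range(n)])
    sex = np.where(rng.random(n) < config.sex_male_prob, "male", "female")
    age = rng.lognormal(config.age_lognormal_mu, config.age_lognormal_sigma, n)
    over = age > config.age_max_days
    while over.any():  # truncation by resampling (tail mass ~4e-5)
        age[over] = rng.lognormal(config.age_lognormal_mu,
                                  config.age_lognormal_sigma, int(over.sum()))
        over = age > config.age_max_days
    weight = weight_from_age(age) + rng.normal(0.0, config.weight_noise_sd_kg, n)
    weight = np.clip(weight, 2.1, 49.5)

    span_h = float((STUDY_END - STUDY_START) / np.timedelta64(3600, "s"))
    study_start_h = float(to_hours([STUDY_START])[0])
    start_h = (study_start_h
               + np.floor(rng.random(n) * span_h * 60.0) / 60.0)
    birth = from_hours(start_h - age * 24.0).normalize()
    return pd.DataFrame({
        "child_id": ids, "sex": sex, "age_days": age,
        "weight_kg": np.round(weight, 2),
        "illness_start_h": start_h, "birth_date": birth,
    })


# ---------------------------------------------------------------------------
# fever course + dosing
# ---------------------------------------------------------------------------

def _draw_main_threshold(config: SimulationConfig,
                         rng: np.random.Generator) -> float:
    while True:  # N(mean, sd) truncated to >= 38.0
        v = rng.normal(config.dosing_threshold_mean_c,
                       config.dosing_threshold_sd_c)
        if v >= 38.0:
            return float(v)


def _draw_interval(config: SimulationConfig, rng: np.random.Generator,
                   combination: bool) -> float:
    if combination or config.exchangeable_dosing:
        lo, hi = config.alternation_interval_h
        return float(rng.uniform(lo, hi))
    return config.redose_interval_h


def simulate_fever_course(child_id: str, config: SimulationConfig,
                          rng: np.random.Generator) -> FeverCourse:
    """Simulate one child's latent course and the caregiver's dosing trace.

    Doses are emitted whenever the latent temperature is at or above the
    caregiver's threshold, a per-dose reaction delay has elapsed and the
    policy's minimum interval since the previous dose has passed. The
    single/combination decision is made at the first dose as a Bernoulli
    draw whose probability depends on the onset-temperature band (or is
    band-independent under ``exchangeable_dosing``); a combination
    caregiver's second (alternating) dose is scheduled at the drawn
    interval rather than threshold-gated — having committed to alternation,
    the caregiver gives the partner drug once regardless.

    Caregivers are first given a threshold from the >=38 C truncated
    normal; among children whose untreated course reaches that threshold
    (i.e. children who would dose at all), a configured fraction is
    relabelled as under-38 "early dosers" with a low threshold and a short
    reaction delay.
    """
    course = FeverCourse(
        child_id=child_id,
        baseline_c=float(rng.normal(config.baseline_temp_mean_c,
                                    config.baseline_temp_sd_c)),
        peak_delta_c=float(rng.gamma(config.fever_peak_shape,
                                     config.fever_peak_scale)),
        onset_h=float(rng.uniform(*config.fever_onset_range_h)),
        rise_h=config.fever_rise_h,
        fall_h=config.fever_fall_h,
        floor_c=config.temp_floor_c,
        threshold_c=_draw_main_threshold(config, rng),
        kernels=config.drug_effect,
    )
    step = config.step_h
    grid = np.arange(0.0, config.sim_window_h + step / 2, step)
    total = course.untreated(grid)
    n = len(grid)

    delay_mean = config.dose_delay_mean_h
    delay_cap = config.dose_delay_cap_h
    if total.max() < course.threshold_c:
        # never febrile enough for this caregiver: no doses at all
        course.dose_times_h = np.empty(0)
        return course
    if rng.random() < config.underthreshold_dosing_prob:
        course.threshold_c = float(rng.uniform(*config.underthreshold_range_c))
        delay_mean = config.early_doser_delay_mean_h
        delay_cap = config.early_doser_delay_cap_h

    dose_times: list[float] = []
    dose_ings: list[str] = []
    next_allowed = 0.0
    combination = False
    rotation: list[str] = []
    while len(dose_times) < config.max_doses:
        scheduled = (len(dose_times) == 1
                     and (combination or config.exchangeable_dosing))
        if scheduled:
            di = int(np.searchsorted(grid, next_allowed - 1e-9))
            if di >= n:
                break
        else:
            i0 = int(np.searchsorted(grid, next_allowed - 1e-9))
            if i0 >= n:
                break
            febrile = total[i0:] >= course.threshold_c
            if not febrile.any():
                break
            i = i0 + int(np.argmax(febrile))
            delay = min(rng.exponential(delay_mean), delay_cap)
            di = i + int(round(delay / step))
            if di >= n:
                break
        t_dose = float(grid[di])
        if not dose_times:  # policy decision at the first administration
            latent_at_first = float(max(total[di], course.floor_c))
            if config.exchangeable_dosing:
                p_comb = config.exchangeable_combination_prob
            else:
                p_comb = config.combination_prob_by_band[
                    onset_bin(latent_at_first)]
            combination = bool(rng.random() < p_comb)
            if combination:
                keys = list(config.combination_pattern_probs)
                probs = np.array([config.combination_pattern_probs[k]
                                  for k in keys])
                rotation = keys[rng.choice(len(keys), p=probs)].split("-")
            else:
                keys = list(config.single_ingredient_probs)
                probs = np.array([config.single_ingredient_probs[k]
                                  for k in keys])
                rotation = [keys[rng.choice(len(keys), p=probs)]]
            course.policy = "combination" if combination else "single"
            course.pattern = tuple(rotation)
        ing = rotation[len(dose_times) % len(rotation)]
        total[di:] += course.kernels[ing](grid[di:] - t_dose)
        dose_times.append(t_dose)
        dose_ings.append(ing)
        next_allowed = t_dose + _draw_interval(config, rng, combination)

    course.dose_times_h = np.asarray(dose_times)
    course.dose_ingredients = dose_ings
    return course


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

def simulate_measurements(course: FeverCourse, config: SimulationConfig,
                          rng: np.random.Generator
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Sample irregular temperature self-reports from the latent course.

    Event times follow a temperature-dependent sampling process (rate
    ``base + per_deg * max(0, T - pivot)``, capped), plus one reading at
    every dose time and jittered post-dose response checks at the
    configured follow-up offsets. Observed values are latent + Gaussian
    noise, rounded to 0.1 C. Returns (times_h, temps_c) at minute
    resolution.
    """
    step = config.step_h
    grid = np.arange(0.0, config.sim_window_h + step / 2, step)
    latent = course.latent(grid)
    rate = np.minimum(
        config.measurement_rate_base_per_h
        + config.measurement_rate_per_deg
        * np.maximum(latent - config.measurement_rate_pivot_c, 0.0),
        config.measurement_rate_cap_per_h)
    hit = rng.random(len(grid)) < rate * step
    times = grid[hit] + rng.uniform(0.0, step, int(hit.sum()))
    times = np.round(times * 60.0) / 60.0
    times = times[times <= config.sim_window_h]
    if len(course.dose_times_h):
        offs = np.asarray(config.followup_offsets_h)
        fu = (course.dose_times_h[:, None] + offs[None, :]).ravel()
        keep = rng.random(len(fu)) < config.followup_prob
        fu = fu + rng.uniform(-config.followup_jitter_h,
                              config.followup_jitter_h, len(fu))
        fu = np.round(fu[keep] * 60.0) / 60.0
        fu = fu[(fu > 0) & (fu <= config.sim_window_h)]
        times = np.concatenate([times, course.dose_times_h, fu])
    times = np.unique(times)
    if len(times) == 0:
        return times, times
    temps = course.latent(times) + rng.normal(
        0.0, config.measurement_noise_sd_c, len(times))
    temps = np.round(np.clip(temps, 35.0, 42.9), 1)
    return times, temps


# ---------------------------------------------------------------------------
# whole cohort + ground truth
# ---------------------------------------------------------------------------

def _true_case_rows(course: FeverCourse, start_h: float) -> list[dict]:
    """Greedy 72-h windows over the true doses with exact latent AUCs."""
    if not len(course.dose_times_h):
        return []
    cases = build_cases(course.child_id, course.dose_times_h,
                        course.dose_ingredients)
    fine = np.arange(0.0, max(HORIZONS) + 1e-9, 1.0 / 60.0)
    rows = []
    for k, case in enumerate(cases):
        t0 = case.window_start_h
        baseline = float(course.latent(np.array([t0]))[0])
        delta = course.latent(t0 + fine) - baseline
        group, pattern = classify_case(case)
        row = {
            "child_id": course.child_id,
            "case_index": k,
            "case_start_h": start_h + t0,
            "true_baseline_c": baseline,
            "true_band": onset_bin(baseline),
            "true_group": group,
            "true_pattern": pattern,
            "policy": course.policy,
            "n_doses": case.n_doses,
        }
        for h in HORIZONS:
            m = fine <= h + 1e-12
            row[f"true_auc_{h}h"] = float(np.trapezoid(delta[m], fine[m]))
        rows.append(row)
    return rows


def generate_cohort(config: SimulationConfig, with_ground_truth: bool = True
                    ) -> tuple[Cohort, pd.DataFrame]:
    """Generate a full synthetic cohort plus its ground-truth sidecar.

    Returns ``(cohort, ground_truth)`` where the cohort holds the three
    canonical record frames and the ground truth has one row per
    dosing-anchored 72-h case with the true group, true latent baseline and
    exact latent delta-fever AUC at each analysis horizon. Deterministic in
    (config, seed); ``with_ground_truth=False`` skips the sidecar
    quadrature (the record streams are unchanged).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    children = simulate_children(config, rng)

    temp_rows = []
    med_rows = []
    gt_rows = []
    for child in children.itertuples(index=False):
        course = simulate_fever_course(child.child_id, config, rng)
        times, temps = simulate_measurements(course, config, rng)
        start = child.illness_start_h
        if len(times):
            temp_rows.append(pd.DataFrame({
                "child_id": child.child_id,
                "time_h": start + times, "temp_c": temps}))
        if len(course.dose_times_h):
            med_rows.append(pd.DataFrame({
                "child_id": child.child_id,
                "time_h": start + course.dose_times_h,
                "ingredient": course.dose_ingredients}))
        if with_ground_truth:
            gt_rows.extend(_true_case_rows(course, start))

    temps_df = (pd.concat(temp_rows, ignore_index=True) if temp_rows
                else pd.DataFrame(columns=["child_id", "time_h", "temp_c"]))
    meds_df = (pd.concat(med_rows, ignore_index=True) if med_rows
               else pd.DataFrame(
                   columns=["child_id", "time_h", "ingredient"]))

    temperatures = pd.DataFrame({
        "child_id": temps_df["child_id"],
        "time": from_hours(temps_df["time_h"].to_numpy(dtype=float)),
        "temp_c": temps_df["temp_c"].astype(float),
    }).sort_values(["child_id", "time"], kind="stable").reset_index(drop=True)
    antipyretics = pd.DataFrame({
        "child_id": meds_df["child_id"],
        "time": from_hours(meds_df["time_h"].to_numpy(dtype=float)),
        "ingredient": meds_df["ingredient"],
        "dose_mg": np.nan,
    }).sort_values(["child_id", "time"], kind="stable").reset_index(drop=True)

    children_out = children[["child_id", "sex", "birth_date",
                             "weight_kg"]].copy()
    cohort = Cohort(children_out, temperatures, antipyretics)

    ground_truth = pd.DataFrame(gt_rows)
    if len(ground_truth):
        ground_truth["case_start"] = from_hours(
            ground_truth["case_start_h"].to_numpy(dtype=float))
    return cohort, ground_truth


def kernel_integral(kernel: DrugKernel, horizon_h: float) -> float:
    """Exact integral of the dose-response kernel over [0, horizon] (C*h)."""
    if horizon_h <= kernel.lag_h:
        return 0.0
    h = min(horizon_h, kernel.duration_h)
    d = kernel.nadir_drop_c
    if h <= kernel.nadir_h:
        frac = (h - kernel.lag_h) / (kernel.nadir_h - kernel.lag_h)
        return -0.5 * d * frac**2 * (kernel.nadir_h - kernel.lag_h)
    area = -0.5 * d * (kernel.nadir_h - kernel.lag_h)
    rec = kernel.duration_h - kernel.nadir_h
    u = h - kernel.nadir_h
    area += -d * (u - 0.5 * u**2 / rec)
    return area
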