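"""Synthetic two-survey generator with known ground truth.

Builds a population whose latent chronotype has the structure the analysis
battery assumes — a sex-specific exponential age decay, geographic and
settlement gradients, lifestyle covariate effects, a correlated
best-alertness midpoint, and chronotype-linked BMI/HDL in women — and
emits the *raw* instrument files (sleep-timing questionnaire items,
alertness intervals, diary grids, demographics, biomarkers) so that every
pipeline stage can be exercised end to end against a truth table.

Calibration
-----------
The latent chronotype is structural::

    C_i = decay(sex_i, age_i) + sum_j beta_j * (x_ij - mean(x_j)) + delta + eps_i

with ``eps ~ N(0, sigma)``.  ``delta`` and ``sigma`` are solved at
generation time so the population mean and SD of C match the configured
marginal targets, and the drawn noise is residualized against the
structural design and rescaled so the sample moments hit the targets
*exactly* (the empirical-calibration device familiar from
``MASS::mvrnorm(empirical=TRUE)``); covariate effect sizes (hours per
unit) are preserved as configured.  Raw questionnaire items are
constructed by *inverting* the scorer: bed and wake times are placed so
that sleep-debt-corrected scoring returns C_i, then snapped to the minute
grid the CSV format carries.  The truth table records both the pre-rounding
latent value and the exactly scorable post-rounding value.

The best-alertness midpoint is built from the standardized latent
chronotype plus an independent right-skewed (skew-normal) component,
giving the configured Pearson correlation and a slightly asymmetric
marginal whose tails stay on the clock face.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .diary import DIARY_START_H, N_SLOTS, SLOT_H
from .instruments import centre, format_hhmm, uncentre
from .normalization import DEFAULT_CURVES, REFERENCE_AGE, DecayCurve

__all__ = ["GeneratorConfig", "SyntheticSurvey", "generate", "truth_audit"]


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic survey.

    Defaults reproduce the surveyed study conditions: marginal targets for
    the scored chronotype measures, the published decay constants, the
    surveyed country's bounding box, and documented covariate prevalences.
    All values are data and may be loaded from YAML.
    """

    n_subjects: int = 5000
    seed: int = 0

    # demographics
    age_min: float = 18.0
    age_max: float = 85.0
    p_women: float = 0.515
    lon_range: tuple = (12.0, 19.0)
    lat_range: tuple = (48.5, 51.1)
    settlement_log10_mean: float = 3.5
    settlement_log10_sd: float = 1.0
    settlement_log10_range: tuple = (2.0, 6.12)

    # sex-specific decay constants (y0, plateau, k)
    decay_men: tuple = (9.62, 2.829, 0.067)
    decay_women: tuple = (10.69, 2.947, 0.089)

    # covariate prevalences
    p_partner: float = 0.65
    p_children: float = 0.35
    p_dog: float = 0.41
    p_other_pet: float = 0.15
    p_smoking: float = 0.28
    p_alcohol_high: float = 0.15
    p_fruitveg_rarely: float = 0.40
    outdoor_gamma_shape: float = 3.0
    outdoor_gamma_scale: float = 4.0

    # chronotype effects, hours per unit of the covariate
    effects: dict = field(default_factory=lambda: {
        "longitude": -0.05098,
        "latitude": 0.09535,
        "log10_settlement": 0.08,
        "has_children_0_17": -0.25,
        "partner": -0.22,
        "dog_owner": 0.18,
        "outdoor_hours_week": -0.008,
        "smoking": 0.25,
        "alcohol_high": 0.30,
        "fruitveg_rarely": 0.18,
    })

    # marginal calibration targets for the scored instruments; setting the
    # SD target to None disables calibration and uses latent_noise_sd as-is
    target_msfsc_mean: Optional[float] = 3.125
    target_msfsc_sd: Optional[float] = 1.0844
    latent_noise_sd: float = 0.0
    target_bamid_mean: float = 12.109
    target_bamid_sd: float = 3.1410
    bamid_skew: float = 4.0  # skew-normal shape of the instrument-specific part
    target_corr_msfsc_bamid: float = 0.327

    # questionnaire mechanics
    p_alarm_free: float = 0.45
    p_wakes_before_given_alarm: float = 0.20
    sdw_mean: float = 7.1
    sdw_sd: float = 0.6
    debt_halfnormal_scale: float = 0.9
    latency_minutes: tuple = (5, 30)
    wd_values: tuple = (0, 3, 4, 5, 6)
    wd_probs: tuple = (0.08, 0.07, 0.15, 0.60, 0.10)
    alertness_halfwidth: tuple = (1.0, 4.0)

    # diary
    p_free_day: float = 0.32
    p_typical_day: float = 0.85
    diary_mid_noise_sd: float = 0.3

    # biomarkers / BMI (women-specific chronotype links)
    biomarker_fraction: float = 0.22
    hdl_mean_men: float = 1.35
    hdl_mean_women: float = 1.75
    hdl_sd: float = 0.32
    ldl_mean: float = 3.0
    ldl_sd: float = 0.8
    hdl_shift_extreme_women: float = -0.10
    hdl_shift_late_women: float = -0.12
    bmi_mean_men: float = 26.5
    bmi_mean_women: float = 25.0
    bmi_sd: float = 4.0
    bmi_slope_women: float = 0.35

    def __post_init__(self):
        for name in ("target_bamid_sd", "sdw_sd", "hdl_sd",
                     "ldl_sd", "bmi_sd", "settlement_log10_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.target_msfsc_sd is not None and self.target_msfsc_sd <= 0:
            raise ValueError("target_msfsc_sd must be > 0 (or None)")
        if self.latent_noise_sd < 0:
            raise ValueError("latent_noise_sd must be >= 0")
        for name in ("p_women", "p_partner", "p_children", "p_dog", "p_other_pet",
                     "p_smoking", "p_alcohol_high", "p_fruitveg_rarely",
                     "p_alarm_free", "p_wakes_before_given_alarm", "p_free_day",
                     "p_typical_day", "biomarker_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if not abs(self.target_corr_msfsc_bamid) < 1.0:
            raise ValueError("infeasible calibration: |target correlation| must be < 1")
        if abs(sum(self.wd_probs) - 1.0) > 1e-9:
            raise ValueError("wd_probs must sum to 1")

    @property
    def decay_curves(self) -> Mapping[str, DecayCurve]:
        return {
            "men": DecayCurve(*self.decay_men, sex="men"),
            "women": DecayCurve(*self.decay_women, sex="women"),
        }

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("lon_range", "lat_range", "settlement_log10_range", "decay_men",
                    "decay_women", "latency_minutes", "wd_values", "wd_probs",
                    "alertness_halfwidth"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        for key, val in data.items():
            if isinstance(val, tuple):
                data[key] = list(val)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def default_path(cls) -> Path:
        return Path(__file__).parent / "config" / "default.yaml"


FILES = ("mctq", "alertness", "diary", "demographics", "biomarkers", "truth")


@dataclass
class SyntheticSurvey:
    """The emitted file bundle plus the row-aligned truth table."""

    mctq: pd.DataFrame
    alertness: pd.DataFrame
    diary: pd.DataFrame
    demographics: pd.DataFrame
    biomarkers: pd.DataFrame
    truth: pd.DataFrame
    config: Optional[GeneratorConfig] = None

    def write(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in FILES:
            path = outdir / f"{name}.csv"
            getattr(self, name).to_csv(path, index=False)
            paths[name] = path
        if self.config is not None:
            self.config.to_yaml(outdir / "config.yaml")
        return paths

    @classmethod
    def read(cls, indir) -> "SyntheticSurvey":
        indir = Path(indir)
        frames = {name: pd.read_csv(indir / f"{name}.csv") for name in FILES}
        cfg_path = indir / "config.yaml"
        cfg = GeneratorConfig.from_yaml(cfg_path) if cfg_path.exists() else None
        return cls(**frames, config=cfg)


def _residualize(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Least-squares residual of y on the columns of design."""
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def _round_minute(hours: np.ndarray) -> np.ndarray:
    """Snap float clock hours onto the minute grid carried by HH:MM."""
    return np.round(np.asarray(hours) * 60.0) / 60.0


def _hhmm(hours: np.ndarray) -> list:
    return [format_hhmm(h) for h in np.asarray(hours)]


def generate(config: GeneratorConfig, seed: Optional[int] = None) -> SyntheticSurvey:
    """Generate a synthetic survey bundle; deterministic given (config, seed).

    ``seed`` overrides ``config.seed`` when given.  Independent substreams
    drive demographics, questionnaire mechanics, the alertness instrument,
    the diary and the biomarkers, so regenerating one file leaves the
    others unchanged.
    """
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(int(seed))
    rng_demo, rng_latent, rng_mctq, rng_alert, rng_diary, rng_bio = (
        np.random.default_rng(child) for child in ss.spawn(6)
    )
    n = config.n_subjects
    sid = np.arange(1, n + 1)

    # -- demographics and covariates ------------------------------------
    age = rng_demo.uniform(config.age_min, config.age_max, n)
    sex = np.where(rng_demo.random(n) < config.p_women, "women", "men")
    lon = rng_demo.uniform(*config.lon_range, n)
    lat = rng_demo.uniform(*config.lat_range, n)
    log_settle = np.clip(
        rng_demo.normal(config.settlement_log10_mean, config.settlement_log10_sd, n),
        *config.settlement_log10_range,
    )
    settlement = np.round(10.0 ** log_settle).astype(int)
    # density loosely tracks settlement size (persons per km^2)
    density = np.round(10.0 ** (0.6 * log_settle + rng_demo.normal(0.6, 0.2, n)), 1)
    partner = (rng_demo.random(n) < config.p_partner).astype(int)
    children = (rng_demo.random(n) < config.p_children).astype(int)
    pet_u = rng_demo.random(n)
    pet_status = np.where(
        pet_u < config.p_dog, "dog",
        np.where(pet_u < config.p_dog + config.p_other_pet, "other_pet", "none"),
    )
    dog = (pet_status == "dog").astype(int)
    outdoor = rng_demo.gamma(config.outdoor_gamma_shape, config.outdoor_gamma_scale, n)
    smoking = (rng_demo.random(n) < config.p_smoking).astype(int)
    alcohol = (rng_demo.random(n) < config.p_alcohol_high).astype(int)
    fruitveg = (rng_demo.random(n) < config.p_fruitveg_rarely).astype(int)

    # -- latent chronotype, calibrated to the marginal targets ----------
    curves = config.decay_curves
    base = np.where(sex == "women", curves["women"].predict(age), curves["men"].predict(age))
    covariates = {
        "longitude": lon,
        "latitude": lat,
        "log10_settlement": np.log10(settlement),
        "has_children_0_17": children.astype(float),
        "partner": partner.astype(float),
        "dog_owner": dog.astype(float),
        "outdoor_hours_week": outdoor,
        "smoking": smoking.astype(float),
        "alcohol_high": alcohol.astype(float),
        "fruitveg_rarely": fruitveg.astype(float),
    }
    unknown_effects = set(config.effects) - set(covariates)
    if unknown_effects:
        raise ValueError(f"unknown effect covariates: {sorted(unknown_effects)}")
    structural = base.copy()
    for name, beta in config.effects.items():
        x = covariates[name]
        structural = structural + beta * (x - x.mean())
    design = np.column_stack(
        [np.ones(n), base] + [covariates[name] for name in sorted(covariates)]
    )
    if config.target_msfsc_sd is None:
        sigma = config.latent_noise_sd
        delta = (0.0 if config.target_msfsc_mean is None
                 else config.target_msfsc_mean - structural.mean())
        eps = rng_latent.normal(0.0, sigma, n) if sigma > 0 else np.zeros(n)
    else:
        resid_var = config.target_msfsc_sd**2 - structural.var()
        if resid_var <= 0:
            raise ValueError(
                "infeasible calibration: structural variance "
                f"{structural.var():.3f} exceeds target variance "
                f"{config.target_msfsc_sd**2:.3f}"
            )
        sigma = float(np.sqrt(resid_var))
        delta = config.target_msfsc_mean - structural.mean()
        # empirical calibration: make the noise exactly orthogonal to the
        # structural design with exactly the residual SD, so the latent
        # sample mean/SD equal the targets rather than only in expectation
        eps = _residualize(rng_latent.normal(0.0, 1.0, n), design)
        eps *= sigma / eps.std()
    latent = structural + delta + eps

    # -- invert to raw questionnaire items (minute grid) ----------------
    lat_lo, lat_hi = config.latency_minutes
    sd_w = _round_minute(np.clip(rng_mctq.normal(config.sdw_mean, config.sdw_sd, n), 4.5, 10.0))
    debt = _round_minute(np.abs(rng_mctq.normal(0.0, config.debt_halfnormal_scale, n)))
    sd_f = np.minimum(sd_w + debt, 14.0)
    debt = sd_f - sd_w
    wd = rng_mctq.choice(config.wd_values, n, p=config.wd_probs)
    correction = wd * debt / 14.0  # = (SDf - SDweek)/2
    msf = latent + correction
    so_f = _round_minute(uncentre(msf - sd_f / 2.0))
    se_f = _round_minute(so_f + sd_f)
    latency_f = rng_mctq.integers(lat_lo, lat_hi + 1, n) / 60.0
    prep_f = _round_minute(so_f - latency_f)
    msw = msf - correction - rng_mctq.uniform(0.0, 0.5, n)
    so_w = _round_minute(uncentre(msw - sd_w / 2.0))
    se_w = _round_minute(so_w + sd_w)
    latency_w = rng_mctq.integers(lat_lo, lat_hi + 1, n) / 60.0
    prep_w = _round_minute(so_w - latency_w)

    alarm_free = rng_mctq.random(n) < config.p_alarm_free
    wakes_before = np.where(
        alarm_free, rng_mctq.random(n) < config.p_wakes_before_given_alarm, True
    )
    # re-generate the flag for non-alarm users from an independent draw so
    # the two booleans are not perfectly coupled
    wakes_before = np.where(
        ~alarm_free, rng_mctq.random(n) < 0.6, wakes_before
    ).astype(bool)
    eligible = (~alarm_free) | wakes_before

    # exactly scorable truth: re-apply the scoring formulas to the
    # minute-grid items (mirrors instruments.score_mctq, vectorized)
    sd_w_q = (se_w - (prep_w + latency_w)) % 24.0
    sd_f_q = (se_f - (prep_f + latency_f)) % 24.0
    sd_week_q = (wd * sd_w_q + (7 - wd) * sd_f_q) / 7.0
    msf_q = centre((prep_f + latency_f) + sd_f_q / 2.0)
    msfsc_true = np.where(sd_f_q > sd_w_q, msf_q - (sd_f_q - sd_week_q) / 2.0, msf_q)

    mctq = pd.DataFrame({
        "subject_id": sid,
        "wd": wd,
        "work_prep_hhmm": _hhmm(prep_w),
        "work_latency_min": np.round(latency_w * 60).astype(int),
        "work_end_hhmm": _hhmm(se_w),
        "free_prep_hhmm": _hhmm(prep_f),
        "free_latency_min": np.round(latency_f * 60).astype(int),
        "free_end_hhmm": _hhmm(se_f),
        "alarm_free": alarm_free.astype(int),
        "wakes_before_alarm_work": wakes_before.astype(int),
    })

    # -- best-alertness interval ----------------------------------------
    rho = config.target_corr_msfsc_bamid
    latent_sd = latent.std()
    z = (latent - latent.mean()) / latent_sd if latent_sd > 0 else np.zeros(n)
    a = config.bamid_skew
    delta = a / np.sqrt(1.0 + a**2)
    sn_mean = delta * np.sqrt(2.0 / np.pi)
    sn_sd = np.sqrt(1.0 - 2.0 * delta**2 / np.pi)

    def _skew_part(size):
        # standardized skew-normal: Azzalini construction from two normals
        u0 = rng_alert.normal(0.0, 1.0, size)
        u1 = rng_alert.normal(0.0, 1.0, size)
        sn = delta * np.abs(u0) + np.sqrt(1.0 - delta**2) * u1
        return (sn - sn_mean) / sn_sd

    w = _skew_part(n)
    # resample the (very rare) extreme tail so midpoints stay on the clock face
    for _ in range(64):
        b_std = rho * z + np.sqrt(1.0 - rho**2) * w
        bamid_latent = config.target_bamid_mean + config.target_bamid_sd * b_std
        bad = (bamid_latent <= 0.5) | (bamid_latent >= 23.5)
        if not bad.any():
            break
        w[bad] = _skew_part(int(bad.sum()))
    # empirical calibration: exact zero sample correlation with the latent
    # chronotype and exact unit sample SD, so corr(latent, BAmid) and the
    # BAmid marginal moments land on their configured targets
    if w.std() > 0:
        w = _residualize(w, np.column_stack([np.ones(n), z]))
        w /= w.std()
    b_std = rho * z + np.sqrt(1.0 - rho**2) * w
    bamid_latent = np.clip(
        config.target_bamid_mean + config.target_bamid_sd * b_std, 0.25, 23.75
    )
    half = rng_alert.uniform(*config.alertness_halfwidth, n)
    best_start = _round_minute(bamid_latent - half)
    best_end = _round_minute(bamid_latent + half)
    bamid_true = uncentre(centre(best_start + ((best_end - best_start) % 24.0) / 2.0))
    alertness = pd.DataFrame({
        "subject_id": sid,
        "best_start_hhmm": _hhmm(best_start),
        "best_end_hhmm": _hhmm(best_end),
    })

    # -- time-use diary ---------------------------------------------------
    is_free = rng_diary.random(n) < config.p_free_day
    is_typical = rng_diary.random(n) < config.p_typical_day
    diary_mid = np.where(is_free, latent, msw) + rng_diary.normal(
        0.0, config.diary_mid_noise_sd, n
    )
    diary_dur = np.where(is_free, sd_f, sd_w)
    onset_w = (uncentre(diary_mid - diary_dur / 2.0) - DIARY_START_H) % 24.0
    offset_w = onset_w + diary_dur
    mids = 0.25 + SLOT_H * np.arange(N_SLOTS)
    slots = (mids[None, :] >= onset_w[:, None]) & (mids[None, :] < np.minimum(offset_w, 24.0)[:, None])
    diary = pd.DataFrame({"subject_id": sid})
    diary["is_typical_day"] = is_typical.astype(int)
    diary["is_free_day"] = is_free.astype(int)
    diary["version"] = np.where(age < 18, "youth_10_17", "adult")
    slot_df = pd.DataFrame(
        slots.astype(int), columns=[f"s{i:02d}" for i in range(N_SLOTS)]
    )
    diary = pd.concat([diary, slot_df], axis=1)
    diary_censored = slots[:, 0] | slots[:, -1] | ~slots.any(axis=1)

    # -- BMI and biomarkers ----------------------------------------------
    ref30 = float(np.mean([c.predict(REFERENCE_AGE) for c in curves.values()]))
    latent_msfsasc = latent - base + ref30
    women = sex == "women"
    bmi = np.where(women, config.bmi_mean_women, config.bmi_mean_men) + rng_bio.normal(
        0.0, config.bmi_sd, n
    )
    bmi = bmi + np.where(
        women, config.bmi_slope_women * (latent_msfsasc - latent_msfsasc.mean()), 0.0
    )
    bmi = np.clip(bmi, 15.0, 60.0)

    ranks = pd.Series(latent_msfsasc).rank(method="average").to_numpy()
    extreme_early = ranks <= n / 10.0
    extreme_late = ranks > 9.0 * n / 10.0
    hdl = np.where(women, config.hdl_mean_women, config.hdl_mean_men) + rng_bio.normal(
        0.0, config.hdl_sd, n
    )
    hdl = hdl + np.where(
        women & (extreme_early | extreme_late), config.hdl_shift_extreme_women, 0.0
    )
    hdl = hdl + np.where(women & extreme_late, config.hdl_shift_late_women, 0.0)
    hdl = np.clip(hdl, 0.3, None)
    ldl = np.clip(rng_bio.normal(config.ldl_mean, config.ldl_sd, n), 0.5, None)
    has_bio = rng_bio.random(n) < config.biomarker_fraction
    biomarkers = pd.DataFrame({
        "subject_id": sid[has_bio],
        "hdl": np.round(hdl[has_bio], 3),
        "ldl": np.round(ldl[has_bio], 3),
    })

    demographics = pd.DataFrame({
        "subject_id": sid,
        "age": np.round(age, 1),
        "sex": sex,
        "latitude": np.round(lat, 4),
        "longitude": np.round(lon, 4),
        "settlement_size": settlement,
        "population_density": density,
        "partner": partner,
        "has_children_0_17": children,
        "dog_owner": dog,
        "pet_status": pet_status,
        "outdoor_hours_week": np.round(outdoor, 2),
        "smoking_cat": np.where(smoking == 1, "smokers", "non-smokers"),
        "alcohol_cat": np.where(alcohol == 1, "high", "low"),
        "fruitveg_cat": np.where(fruitveg == 1, "rarely", "often"),
        "bmi": np.round(bmi, 2),
    })

    truth = pd.DataFrame({
        "subject_id": sid,
        "latent_msfsc": latent,
        "msfsc_true": msfsc_true,
        "msf_true": msf_q,
        "msw_true": centre((prep_w + latency_w) + sd_w_q / 2.0),
        "latent_bamid": bamid_latent,
        "bamid_true": bamid_true,
        "latent_msfsasc": latent_msfsasc,
        "diary_mid_true": centre(diary_mid),
        "diary_censored": diary_censored.astype(int),
        "eligible": eligible.astype(int),
        "extreme_early_true": extreme_early.astype(int),
        "extreme_late_true": extreme_late.astype(int),
    })

    return SyntheticSurvey(mctq, alertness, diary, demographics, biomarkers, truth,
                           config=config)


def truth_audit(survey: SyntheticSurvey, scored: pd.DataFrame) -> dict:
    """Recovery report of scored values against the generator's truth.

    ``scored`` must carry ``subject_id`` and any of ``msfsc``, ``bamid``,
    ``diary_midsleep``.  Returns per-quantity bias and RMSE plus the diary
    censored fraction; raises when subject ids do not align with the truth
    table.
    """
    truth = survey.truth
    if not set(scored["subject_id"]).issubset(set(truth["subject_id"])):
        raise ValueError("scored table contains subject ids absent from the truth table")
    merged = scored.merge(truth, on="subject_id", how="left", validate="one_to_one")
    report: dict[str, float] = {"n_scored": int(len(merged))}
    pairs = {
        "msfsc": "msfsc_true",
        "bamid": "bamid_true",
        "diary_midsleep": "diary_mid_true",
    }
    for col, true_col in pairs.items():
        if col not in merged:
            continue
        err = (merged[col] - merged[true_col]).dropna()
        if len(err):
            report[f"{col}_bias"] = float(err.mean())
            report[f"{col}_rmse"] = float(np.sqrt((err**2).mean()))
            report[f"{col}_max_abs_err"] = float(err.abs().max())
            report[f"{col}_n"] = int(len(err))
    report["diary_censored_fraction"] = float(truth["diary_censored"].mean())
    return report
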