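"""Synthetic hospital cohort generator.

Produces admissions, timed vital-sign observations, and clinical events with
controllable marginal statistics and score-outcome association, so the whole
pipeline is testable without hospital data.

Design:

* each vital sign has a parametric marginal (truncated normal by default,
  uniform available for calibration tests) with an exact quantile function,
  exposed in :class:`SyntheticTruth` for parameter-recovery oracles;
* each admission carries a latent severity in [0, 1]; the event hazard is a
  calibrated logistic function of severity (so the realised composite
  prevalence matches the configured target in expectation) and vitals are
  shifted toward their abnormal tails by ``effect_size * severity``;
* within event admissions the severity weight ramps up over the stay and the
  event is placed shortly after the last observation, so observations closer
  to the event are more deranged and discrimination decays as the labelling
  horizon T grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm, uniform

from .outcomes import EVENT_TYPES


class CohortError(ValueError):
    pass


@dataclass(frozen=True)
class MarginalSpec:
    """Parametric marginal with an exact quantile function.

    ``severity_gain`` is the signed shift (in standard deviations per unit of
    effective severity) applied to the location parameter: positive pushes
    sick patients up (heart rate), negative pushes them down (SpO2).
    """

    family: str
    params: Mapping[str, float]
    severity_gain: float = 0.0
    resolution: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", dict(self.params))
        if self.family not in ("truncnorm", "uniform"):
            raise CohortError(f"unknown marginal family {self.family!r}")

    def quantile(self) -> Callable[[np.ndarray], np.ndarray]:
        p = self.params
        if self.family == "uniform":
            return uniform(loc=p["low"], scale=p["high"] - p["low"]).ppf
        a = (p["low"] - p["loc"]) / p["scale"]
        b = (p["high"] - p["loc"]) / p["scale"]
        return truncnorm(a, b, loc=p["loc"], scale=p["scale"]).ppf

    def sample_shifted(self, u: np.ndarray, shift: np.ndarray) -> np.ndarray:
        """Inverse-CDF draw with the location shifted per-observation."""
        p = self.params
        if self.family == "uniform":
            return uniform(loc=p["low"], scale=p["high"] - p["low"]).ppf(u) + shift
        loc = p["loc"] + shift
        a = (p["low"] - loc) / p["scale"]
        b = (p["high"] - loc) / p["scale"]
        return truncnorm.ppf(u, a, b, loc=loc, scale=p["scale"])


def default_marginals() -> dict[str, MarginalSpec]:
    """Marginals targeted at a general ward population (median heart rate 82,
    respiratory rate 17, systolic BP 123, temperature 36.3, SpO2 97)."""
    return {
        "heart_rate": MarginalSpec("truncnorm",
                                   {"loc": 82.0, "scale": 16.3, "low": 25.0, "high": 230.0},
                                   severity_gain=2.0),
        "respiratory_rate": MarginalSpec("truncnorm",
                                         {"loc": 17.0, "scale": 1.6, "low": 4.0, "high": 60.0},
                                         severity_gain=4.0),
        "systolic_bp": MarginalSpec("truncnorm",
                                    {"loc": 123.0, "scale": 20.5, "low": 40.0, "high": 270.0},
                                    severity_gain=-1.5),
        "temperature": MarginalSpec("truncnorm",
                                    {"loc": 36.3, "scale": 0.55, "low": 30.0, "high": 43.0},
                                    severity_gain=1.5, resolution=0.1),
        "spo2": MarginalSpec("truncnorm",
                             {"loc": 97.0, "scale": 2.6, "low": 55.0, "high": 100.0},
                             severity_gain=-2.5),
    }


@dataclass(frozen=True)
class CohortConfig:
    n_admissions: int = 2000
    mean_observations: float = 10.0
    obs_interval_hours: float = 4.0
    marginals: Mapping[str, MarginalSpec] = field(default_factory=default_marginals)
    missing_rate: float = 0.01
    implausible_rate: float = 0.0
    effect_size: float = 1.0
    prevalence: float = 0.07
    hazard_slope: float = 6.0
    avpu_base_rate: float = 0.005
    avpu_severity_gain: float = 0.4
    oxygen_base_rate: float = 0.15
    oxygen_severity_gain: float = 0.5
    minor_age_rate: float = 0.01
    palliative_rate: float = 0.005
    heaping: bool = False
    start: str = "2015-01-01"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "marginals", dict(self.marginals))
        for rate in (self.missing_rate, self.implausible_rate,
                     self.minor_age_rate, self.palliative_rate):
            if not 0.0 <= rate <= 1.0:
                raise CohortError("rates must lie in [0, 1]")
        if not 0.0 < self.prevalence < 1.0:
            raise CohortError("prevalence must lie strictly inside (0, 1)")
        if self.n_admissions < 1:
            raise CohortError("n_admissions must be >= 1")


@dataclass(frozen=True)
class SyntheticTruth:
    """Generator-side ground truth for recovery oracles."""

    quantile_functions: Mapping[str, Callable]
    severity: np.ndarray
    event_probability: np.ndarray
    events: pd.DataFrame
    config: CohortConfig


@dataclass(frozen=True)
class CohortTables:
    admissions: pd.DataFrame
    observations: pd.DataFrame
    events: pd.DataFrame
    truth: SyntheticTruth


_IMPLAUSIBLE = {"heart_rate": 999.0, "respiratory_rate": 0.1,
                "systolic_bp": 1000.0, "temperature": 99.0, "spo2": 150.0}


def _calibrate_intercept(severity: np.ndarray, slope: float, target: float) -> float:
    def gap(a: float) -> float:
        return float(expit(a + slope * severity).mean() - target)
    lo, hi = -60.0, 30.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise CohortError("cannot calibrate event hazard to the target prevalence")
    return brentq(gap, lo, hi, xtol=1e-10)


def generate_marginal_sample(variable: str, n: int, config: CohortConfig,
                             seed: int | None = None
                             ) -> tuple[np.ndarray, Callable]:
    """i.i.d. draws from one configured marginal plus its exact quantile fn."""
    if n < 1:
        raise CohortError("n must be >= 1")
    if variable not in config.marginals:
        raise CohortError(f"unknown variable {variable!r}")
    spec = config.marginals[variable]
    rng = np.random.default_rng(config.seed if seed is None else seed)
    q = spec.quantile()
    return q(rng.random(n)), q


def _round_res(values: np.ndarray, resolution: float) -> np.ndarray:
    return np.round(np.round(values / resolution) * resolution, 10)


def generate_cohort(config: CohortConfig, seed: int | None = None) -> CohortTables:
    """Generate (admissions, observations, events) tables plus ground truth."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_adm = config.n_admissions
    adm_ids = np.array([f"adm{i:06d}" for i in range(n_adm)])

    severity = rng.beta(1.5, 4.0, size=n_adm)
    intercept = _calibrate_intercept(severity, config.hazard_slope, config.prevalence)
    p_event = expit(intercept + config.hazard_slope * severity)
    has_event = rng.random(n_adm) < p_event
    event_type = rng.choice(EVENT_TYPES, size=n_adm,
                            p=[0.05, 0.25, 0.70])  # arrest, icu, death

    age = rng.integers(16, 101, size=n_adm).astype(float)
    minors = rng.random(n_adm) < config.minor_age_rate
    age[minors] = rng.integers(1, 16, size=int(minors.sum()))
    specialty = np.where(rng.random(n_adm) < config.palliative_rate,
                         "palliative medicine", "general medicine")

    start = pd.Timestamp(config.start)
    admit_offset_h = rng.uniform(0, 365 * 24, size=n_adm)
    admit_times = (start + pd.to_timedelta(admit_offset_h, unit="h")).round("s")

    n_obs = 1 + rng.poisson(max(config.mean_observations - 1.0, 0.0), size=n_adm)
    total = int(n_obs.sum())
    adm_idx = np.repeat(np.arange(n_adm), n_obs)
    within = np.concatenate([np.arange(k) for k in n_obs])

    gaps = rng.exponential(config.obs_interval_hours, size=total) + 0.5
    obs_offset_h = np.asarray(
        pd.Series(gaps).groupby(adm_idx).cumsum(), dtype=float)
    obs_times = (admit_times[adm_idx]
                 + pd.to_timedelta(obs_offset_h, unit="h")).round("s")

    # severity weight: ramps toward 1 over the stay for event admissions,
    # flat for the rest -- late observations of sick patients are the worst
    denom = np.maximum(n_obs[adm_idx] - 1, 1)
    ramp = 0.3 + 0.7 * (within / denom)
    weight = np.where(has_event[adm_idx], ramp, 0.5)
    sev_t = severity[adm_idx] * weight * config.effect_size

    columns: dict[str, np.ndarray] = {}
    for var, spec in config.marginals.items():
        u = rng.random(total)
        shift = spec.severity_gain * spec.params.get("scale", 1.0) * sev_t
        values = spec.sample_shifted(u, shift)
        values = _round_res(values, spec.resolution)
        if var == "respiratory_rate" and config.heaping:
            even = rng.random(total) < 0.5
            values[even] = np.round(values[even] / 2.0) * 2.0
        columns[var] = values
    columns["diastolic_bp"] = _round_res(
        columns["systolic_bp"] * 0.55 + rng.normal(0.0, 8.0, size=total), 1.0)

    p_not_alert = np.clip(config.avpu_base_rate
                          + config.avpu_severity_gain * sev_t, 0.0, 0.95)
    not_alert = rng.random(total) < p_not_alert
    avpu = np.where(not_alert,
                    rng.choice(["V", "P", "U"], size=total, p=[0.7, 0.2, 0.1]),
                    "A")
    p_oxygen = np.clip(config.oxygen_base_rate
                       + config.oxygen_severity_gain * sev_t, 0.0, 0.95)
    on_oxygen = rng.random(total) < p_oxygen

    obs = pd.DataFrame({
        "admission_id": adm_ids[adm_idx],
        "timestamp": obs_times,
        **{var: columns[var] for var in ("heart_rate", "respiratory_rate",
                                         "systolic_bp", "diastolic_bp",
                                         "temperature", "spo2")},
        "avpu": avpu,
        "on_oxygen": on_oxygen,
    })

    numeric_vars = ("heart_rate", "respiratory_rate", "systolic_bp",
                    "temperature", "spo2")
    for var in numeric_vars:
        if config.implausible_rate > 0:
            bad = rng.random(total) < config.implausible_rate
            obs.loc[bad, var] = _IMPLAUSIBLE[var]
        if config.missing_rate > 0:
            gone = rng.random(total) < config.missing_rate
            obs.loc[gone, var] = np.nan
    if config.missing_rate > 0:
        obs.loc[rng.random(total) < config.missing_rate, "avpu"] = None
        obs["on_oxygen"] = obs["on_oxygen"].astype(object)
        obs.loc[rng.random(total) < config.missing_rate / 2.0, "on_oxygen"] = None

    last_obs = obs.groupby("admission_id", sort=False)["timestamp"].max()
    last_obs = last_obs.reindex(adm_ids).to_numpy()
    # anchor the event shortly after a late observation; with probability 0.3
    # one observation is charted after the event (and so gets excluded from
    # any labelled analysis downstream)
    n_post = np.where(rng.random(n_adm) < 0.3, 1, 0)
    n_post = np.minimum(n_post, n_obs - 1)
    n_post[event_type == "death"] = 0  # nothing is charted after a death
    starts = np.cumsum(n_obs) - n_obs
    anchor_flat = starts + (n_obs - 1 - n_post)
    anchor_offset_h = obs_offset_h[anchor_flat]
    event_gap_h = rng.uniform(1.0, 8.0, size=n_adm)
    event_times = (admit_times
                   + pd.to_timedelta(anchor_offset_h + event_gap_h, unit="h")
                   ).round("s")

    events = pd.DataFrame({
        "admission_id": adm_ids[has_event],
        "event_type": event_type[has_event],
        "timestamp": event_times[has_event],
    })

    stay_pad_h = rng.uniform(6.0, 48.0, size=n_adm)
    discharge = (pd.DatetimeIndex(last_obs)
                 + pd.to_timedelta(stay_pad_h, unit="h")).round("s")
    discharge = discharge.to_numpy()
    has_event_np = np.asarray(has_event)
    discharge[has_event_np] = np.maximum(discharge[has_event_np],
                                         event_times[has_event_np].to_numpy())
    died = has_event & (event_type == "death")
    discharge[died] = event_times[died].to_numpy()

    admissions = pd.DataFrame({
        "admission_id": adm_ids,
        "age": age.astype(int),
        "specialty": specialty,
        "admit_time": admit_times,
        "discharge_time": pd.DatetimeIndex(discharge),
        "discharged_alive": ~died,
    })

    truth = SyntheticTruth(
        quantile_functions={v: s.quantile() for v, s in config.marginals.items()},
        severity=severity, event_probability=p_event,
        events=events.copy(), config=config)
    return CohortTables(admissions=admissions, observations=obs,
                        events=events, truth=truth)
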