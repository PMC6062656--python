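"""Admission filtering, observation validation and mean imputation.

Rules applied before derivation or evaluation:

* admissions: adult (>= 16 years), at least one complete electronically
  recorded vital-sign set, not admitted under palliative medicine, and not
  discharged alive before midnight on the calendar day of admission;
* observation sets: dropped when more than two measurements are missing or
  any present value is physiologically implausible;
* remaining gaps: numeric values replaced by development-population means
  (score-neutral by construction), AVPU by the modal level "A", the oxygen
  flag by False.

The implausibility ranges and the decision to count AVPU / the oxygen flag
in the missing-measurement tally are not fixed by the method description;
the defaults here are deliberately permissive and overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ObservationSet, SCORED_VARIABLES

ADMISSION_COLUMNS = ("admission_id", "age", "specialty",
                     "admit_time", "discharge_time", "discharged_alive")

DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "heart_rate": (10.0, 300.0),
    "respiratory_rate": (1.0, 80.0),
    "systolic_bp": (30.0, 300.0),
    "temperature": (25.0, 45.0),
    "spo2": (10.0, 100.0),
}


@dataclass(frozen=True)
class PlausibilityRanges:
    ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES))

    def __post_init__(self) -> None:
        object.__setattr__(self, "ranges", dict(self.ranges))
        for var, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ValueError(f"{var}: plausibility min must be < max")
        spo2 = self.ranges.get("spo2")
        if spo2 is not None and spo2[1] > 100:
            raise ValueError("spo2 plausibility range cannot exceed 100%")


@dataclass(frozen=True)
class PopulationMeans:
    """Per-variable development-dataset means used for imputation."""

    values: Mapping[str, float]
    avpu_level: str = "A"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", dict(self.values))

    @classmethod
    def from_observations(cls, observations: Iterable[ObservationSet],
                          variables: Sequence[str] = SCORED_VARIABLES
                          ) -> "PopulationMeans":
        sums = {v: 0.0 for v in variables}
        counts = {v: 0 for v in variables}
        for obs in observations:
            for v in variables:
                value = getattr(obs, v)
                if value is not None:
                    sums[v] += float(value)
                    counts[v] += 1
        missing = [v for v in variables if counts[v] == 0]
        if missing:
            raise ValueError(f"no values to average for {missing}")
        return cls({v: sums[v] / counts[v] for v in variables})


@dataclass(frozen=True)
class Verdict:
    keep: bool
    reason: str | None = None
    detail: str | None = None


def validate_observation(obs: ObservationSet,
                         ranges: PlausibilityRanges | None = None,
                         count_categorical: bool = True) -> Verdict:
    """Keep/drop verdict for one observation set.

    Drops when more than two measurements are absent (AVPU and the oxygen
    flag count as measurements when ``count_categorical``), or when any
    present numeric value lies outside its plausibility range.
    """
    ranges = ranges or PlausibilityRanges()
    n_missing = sum(getattr(obs, v) is None for v in SCORED_VARIABLES)
    if count_categorical:
        n_missing += obs.avpu is None
        n_missing += obs.on_oxygen is None
    if n_missing > 2:
        return Verdict(False, "too_many_missing", f"{n_missing} missing")
    for var in SCORED_VARIABLES:
        value = getattr(obs, var)
        if value is None:
            continue
        lo, hi = ranges.ranges[var]
        if not lo <= float(value) <= hi:
            return Verdict(False, "implausible", var)
    return Verdict(True)


def impute(obs: ObservationSet, means: PopulationMeans) -> ObservationSet:
    """Fill missing values with population means (AVPU -> modal level,
    oxygen flag -> False) and record what was imputed."""
    updates: dict = {}
    flags = set(obs.imputed_flags)
    for var in SCORED_VARIABLES:
        if getattr(obs, var) is None:
            if var not in means.values:
                raise ValueError(f"no population mean available for {var}")
            updates[var] = float(means.values[var])
            flags.add(var)
    if obs.avpu is None:
        updates["avpu"] = means.avpu_level
        flags.add("avpu")
    if obs.on_oxygen is None:
        updates["on_oxygen"] = False
        flags.add("on_oxygen")
    if not updates:
        return obs
    return replace(obs, imputed_flags=frozenset(flags), **updates)


def filter_admissions(admissions: pd.DataFrame,
                      observations: pd.DataFrame | Sequence[ObservationSet],
                      min_age: float = 16.0,
                      excluded_specialty: str = "palliative medicine"
                      ) -> tuple[list, dict]:
    """Admission inclusion rules; returns (included ids, per-rule counts).

    An admission must be adult, have at least one complete vital-sign set
    (all scored variables plus AVPU present), not be a palliative-medicine
    admission, and not have been discharged alive before midnight at the end
    of the admission's calendar day.
    """
    missing_cols = [c for c in ADMISSION_COLUMNS if c not in admissions.columns]
    if missing_cols:
        raise ValueError(f"admissions table missing columns {missing_cols}")
    if not isinstance(observations, pd.DataFrame):
        from .io import observations_to_frame
        observations = observations_to_frame(observations)

    complete = np.ones(len(observations), dtype=bool)
    for var in SCORED_VARIABLES:
        complete &= pd.to_numeric(observations[var], errors="coerce").notna().to_numpy()
    complete &= observations["avpu"].notna().to_numpy()
    ids_with_complete = set(observations.loc[complete, "admission_id"])

    age = pd.to_numeric(admissions["age"])
    admit = pd.to_datetime(admissions["admit_time"])
    discharge = pd.to_datetime(admissions["discharge_time"])
    alive = admissions["discharged_alive"].astype(bool)
    specialty = admissions["specialty"].astype(str).str.strip().str.lower()

    fail_age = age < min_age
    fail_complete = ~admissions["admission_id"].isin(ids_with_complete)
    fail_specialty = specialty == excluded_specialty
    midnight_after = admit.dt.normalize() + pd.Timedelta(days=1)
    fail_same_day = alive & (discharge < midnight_after)

    included_mask = ~(fail_age | fail_complete | fail_specialty | fail_same_day)
    counts = {
        "under_min_age": int(fail_age.sum()),
        "no_complete_observation": int(fail_complete.sum()),
        "palliative_specialty": int(fail_specialty.sum()),
        "same_day_alive_discharge": int(fail_same_day.sum()),
        "included": int(included_mask.sum()),
        "total": int(len(admissions)),
    }
    return admissions.loc[included_mask, "admission_id"].tolist(), counts


def preprocess_observations(observations: Sequence[ObservationSet],
                            ranges: PlausibilityRanges | None = None,
                            means: PopulationMeans | None = None,
                            count_categorical: bool = True
                            ) -> tuple[list[ObservationSet], dict]:
    """validate -> impute pipeline over an observation list.

    When ``means`` is None (development mode) they are computed from the
    observations that pass validation; pass development means explicitly for
    a validation dataset.
    """
    ranges = ranges or PlausibilityRanges()
    kept: list[ObservationSet] = []
    report = {"input": len(observations), "kept": 0,
              "dropped_too_many_missing": 0, "dropped_implausible": 0}
    for obs in observations:
        verdict = validate_observation(obs, ranges, count_categorical)
        if verdict.keep:
            kept.append(obs)
        else:
            report[f"dropped_{verdict.reason}"] += 1
    if means is None:
        means = PopulationMeans.from_observations(kept)
    completed = [impute(obs, means) for obs in kept]
    report["kept"] = len(completed)
    report["imputed_values"] = int(sum(len(o.imputed_flags) for o in completed))
    return completed, report
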