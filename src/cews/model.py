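"""Band-based early-warning score (EWS) representation and scoring.

An EWS assigns each vital sign an integer sub-score (0-3) according to which
threshold-delimited band its value falls in, adds a sub-score for the AVPU
consciousness level, and optionally adds a fixed increment when the patient
is on supplemental oxygen.  The aggregate score is the sum.

Band tables store *printed* inclusive endpoints at the variable's charting
resolution (1 unit for most vitals, 0.1 degC for temperature).  Internally a
band ``L..U`` covers the half-open interval ``[L - res/2, U + res/2)`` so
that non-integer inputs from continuous monitors are scored deterministically
(e.g. a heart rate of 104.5 falls in the band above 104) and the bands
partition the whole real line with no gaps or overlaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from functools import cached_property
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

AVPU_LEVELS = ("A", "V", "P", "U")
#: Continuous variables that carry a band table (diastolic BP is recorded
#: but never scored).
SCORED_VARIABLES = (
    "heart_rate",
    "respiratory_rate",
    "systolic_bp",
    "temperature",
    "spo2",
)
ALLOWED_SCORES = (0, 1, 2, 3)

_INF = float("inf")


class EWSError(ValueError):
    """Base error for scoring-system construction and use."""


class MissingValueError(EWSError):
    """A value required for scoring is absent."""


class BandTableError(EWSError):
    """A band table violates the partition / score-pattern contract."""


@dataclass(frozen=True)
class ObservationSet:
    """One timed charting of vital signs for a patient.

    Missing measurements are ``None``.  Raw (pre-validation) rows may carry
    physiologically implausible values; plausibility is enforced by the
    preprocessing step, not here.
    """

    admission_id: str
    timestamp: datetime
    heart_rate: float | None = None
    respiratory_rate: float | None = None
    systolic_bp: float | None = None
    diastolic_bp: float | None = None
    temperature: float | None = None
    spo2: float | None = None
    avpu: str | None = None
    on_oxygen: bool | None = None
    imputed_flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.avpu is not None and self.avpu not in AVPU_LEVELS:
            raise ValueError(f"avpu must be one of {AVPU_LEVELS}, got {self.avpu!r}")
        if not isinstance(self.imputed_flags, frozenset):
            object.__setattr__(self, "imputed_flags", frozenset(self.imputed_flags))


@dataclass(frozen=True)
class ScoreBand:
    """One scored interval, printed-inclusive at the table's resolution."""

    score: int
    lower: float = -_INF
    upper: float = _INF

    def __post_init__(self) -> None:
        if self.score not in ALLOWED_SCORES:
            raise BandTableError(f"score must be in {ALLOWED_SCORES}, got {self.score}")
        # lower == upper is a legal single-value band (printed "92-92" ~ "92")
        if not self.lower <= self.upper:
            raise BandTableError(f"band lower {self.lower} must be <= upper {self.upper}")


@dataclass(frozen=True)
class VariableBandTable:
    """Ordered score bands for one vital sign.

    Invariants checked at construction:

    * bands are contiguous under the half-open convention (adjacent printed
      endpoints differ by exactly one resolution step) and cover the whole
      line on the sides where bands exist;
    * exactly one band carries score 0;
    * sub-scores are non-increasing up to the score-0 band and
      non-decreasing after it.
    """

    variable: str
    bands: tuple[ScoreBand, ...]
    resolution: float = 1.0
    admissible_min: float | None = None
    admissible_max: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", tuple(self.bands))
        if self.resolution <= 0:
            raise BandTableError(f"{self.variable}: resolution must be positive")
        if not self.bands:
            raise BandTableError(f"{self.variable}: no bands")
        bands = self.bands
        if bands[0].lower != -_INF:
            raise BandTableError(f"{self.variable}: first band must be unbounded below")
        if bands[-1].upper != _INF:
            raise BandTableError(f"{self.variable}: last band must be unbounded above")
        tol = 1e-6
        for prev, nxt in zip(bands, bands[1:]):
            if prev.upper == _INF or nxt.lower == -_INF:
                raise BandTableError(
                    f"{self.variable}: only the outermost bands may be unbounded"
                )
            if abs(nxt.lower - (prev.upper + self.resolution)) > tol:
                raise BandTableError(
                    f"{self.variable}: bands {prev.upper} / {nxt.lower} leave a gap "
                    f"or overlap at resolution {self.resolution}"
                )
        scores = [b.score for b in bands]
        if scores.count(0) != 1:
            raise BandTableError(f"{self.variable}: exactly one score-0 band required")
        zero = scores.index(0)
        for i in range(zero):
            if scores[i] < scores[i + 1]:
                raise BandTableError(f"{self.variable}: scores below the score-0 band "
                                     "must be non-increasing")
        for i in range(zero, len(scores) - 1):
            if scores[i] > scores[i + 1]:
                raise BandTableError(f"{self.variable}: scores above the score-0 band "
                                     "must be non-decreasing")
        if self.admissible_min is not None and self.admissible_max is not None:
            if not self.admissible_min < self.admissible_max:
                raise BandTableError(f"{self.variable}: bad admissible range")

    @cached_property
    def _cuts(self) -> np.ndarray:
        # internal half-open boundaries: the printed lower edge of each band
        # shifted down by half a resolution step
        return np.array([b.lower - self.resolution / 2.0 for b in self.bands[1:]])

    @cached_property
    def _scores(self) -> np.ndarray:
        return np.array([b.score for b in self.bands], dtype=np.int64)

    def score_0_band(self) -> ScoreBand:
        return next(b for b in self.bands if b.score == 0)


def sub_score(value: float, table: VariableBandTable) -> int:
    """Sub-score for a single value under ``table``.

    Raises :class:`MissingValueError` on ``None``/NaN and :class:`EWSError`
    for values outside the table's admissible physical range.
    """
    if value is None:
        raise MissingValueError(f"{table.variable}: value is missing")
    value = float(value)
    if not math.isfinite(value):
        raise MissingValueError(f"{table.variable}: value is not finite")
    if table.admissible_min is not None and value < table.admissible_min:
        raise EWSError(f"{table.variable}: {value} below admissible "
                       f"minimum {table.admissible_min}")
    if table.admissible_max is not None and value > table.admissible_max:
        raise EWSError(f"{table.variable}: {value} above admissible "
                       f"maximum {table.admissible_max}")
    idx = int(np.searchsorted(table._cuts, value, side="right"))
    return int(table.bands[idx].score)


@dataclass(frozen=True)
class EWSDefinition:
    """A complete band-based scoring system."""

    name: str
    tables: Mapping[str, VariableBandTable]
    avpu_map: Mapping[str, int]
    oxygen_increment: int = 0
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "tables", dict(self.tables))
        object.__setattr__(self, "avpu_map", dict(self.avpu_map))
        missing = [lvl for lvl in AVPU_LEVELS if lvl not in self.avpu_map]
        if missing:
            raise EWSError(f"{self.name}: avpu_map missing levels {missing}")
        if self.oxygen_increment < 0:
            raise EWSError(f"{self.name}: oxygen_increment must be >= 0")

    def with_oxygen_increment(self, increment: int) -> "EWSDefinition":
        return EWSDefinition(self.name, self.tables, self.avpu_map,
                             oxygen_increment=increment, provenance=self.provenance)


def avpu_sub_score(level: str, definition: EWSDefinition) -> int:
    if level not in definition.avpu_map:
        raise EWSError(f"unknown AVPU level {level!r}")
    return int(definition.avpu_map[level])


def aggregate_score(obs: ObservationSet, definition: EWSDefinition) -> int:
    """Total EWS for one complete observation set.

    Requires every scored variable plus AVPU to be present (impute first);
    ``on_oxygen`` is required only when the definition carries an oxygen
    increment.  Diastolic blood pressure never contributes.
    """
    total = 0
    for var, table in definition.tables.items():
        value = getattr(obs, var)
        if value is None:
            raise MissingValueError(f"required variable {var} is missing")
        total += sub_score(value, table)
    if obs.avpu is None:
        raise MissingValueError("required variable avpu is missing")
    total += avpu_sub_score(obs.avpu, definition)
    if definition.oxygen_increment > 0:
        if obs.on_oxygen is None:
            raise MissingValueError("required variable on_oxygen is missing")
        if obs.on_oxygen:
            total += definition.oxygen_increment
    return total


def aggregate_scores_frame(frame: pd.DataFrame, definition: EWSDefinition) -> np.ndarray:
    """Vectorised :func:`aggregate_score` over a tabular observation frame."""
    n = len(frame)
    total = np.zeros(n, dtype=np.int64)
    for var, table in definition.tables.items():
        values = pd.to_numeric(frame[var], errors="coerce").to_numpy(dtype=float)
        if np.isnan(values).any():
            raise MissingValueError(f"required variable {var} has missing values")
        if table.admissible_min is not None and (values < table.admissible_min).any():
            raise EWSError(f"{var}: values below admissible minimum")
        if table.admissible_max is not None and (values > table.admissible_max).any():
            raise EWSError(f"{var}: values above admissible maximum")
        idx = np.searchsorted(table._cuts, values, side="right")
        total += table._scores[idx]
    avpu = frame["avpu"].map(definition.avpu_map)
    if avpu.isna().any():
        raise MissingValueError("required variable avpu has missing/unknown values")
    total += avpu.to_numpy(dtype=np.int64)
    if definition.oxygen_increment > 0:
        oxy = frame["on_oxygen"]
        if oxy.isna().any():
            raise MissingValueError("required variable on_oxygen has missing values")
        total += oxy.astype(bool).to_numpy() * definition.oxygen_increment
    return total
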