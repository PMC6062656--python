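"""Derive band tables from vital-sign samples via kernel-smoothed centiles.

The procedure: fit an equal-weight Gaussian-mixture CDF to the samples with
bandwidth ``h = 1.06 * sigma_hat * n**(-1/5)``, invert the smoothed CDF at
the requested centiles, round the thresholds to the variable's charting
resolution, and assemble the bands under the scoring module's half-open
boundary convention.

Conventions not fixed by the method description (documented, switchable):

* ``sigma_hat`` uses the n-1 (sample) denominator;
* rounding of inverted centiles is round-half-away-from-zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.special import ndtr

from .model import (
    AVPU_LEVELS,
    EWSDefinition,
    ObservationSet,
    ScoreBand,
    VariableBandTable,
)

DEFAULT_AVPU_MAP = {"A": 0, "V": 3, "P": 3, "U": 3}

_GRID_SIZE = 4096
_GRID_PAD = 4.0  # grid extends this many bandwidths beyond the sample range
# above this sample count the mixture CDF is evaluated from a fine histogram
# (bin width ~ (range/2**14), negligible next to h) instead of per-sample
_EXACT_N_MAX = 20_000
_N_BINS = 16_384


class DerivationError(ValueError):
    """Raised when centile derivation cannot produce a valid band table."""


class ThresholdCollisionError(DerivationError):
    """Rounded centile thresholds are not strictly ordered."""


@dataclass(frozen=True)
class CentileSpec:
    """Which centiles map to which sub-scores for one variable.

    ``lower`` and ``upper`` map centile probabilities to the sub-score of the
    region *below* (resp. *at and above*) the corresponding threshold, e.g.
    the default two-sided map is ``lower={0.01: 3, 0.05: 2, 0.10: 1}``,
    ``upper={0.90: 1, 0.95: 2, 0.99: 3}``.  ``upper=None`` gives a one-sided
    (lower-only) table whose score-0 band extends to +inf.
    """

    variable: str
    lower: Mapping[float, int]
    upper: Mapping[float, int] | None = None
    rounding_resolution: float = 1.0
    admissible_min: float | None = None
    admissible_max: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "lower", dict(self.lower))
        if self.upper is not None:
            object.__setattr__(self, "upper", dict(self.upper))
        if self.rounding_resolution <= 0:
            raise DerivationError(f"{self.variable}: resolution must be positive")
        lo_p = sorted(self.lower)
        if not lo_p or any(not 0 < p < 1 for p in lo_p):
            raise DerivationError(f"{self.variable}: lower centiles must be in (0,1)")
        lo_s = [self.lower[p] for p in lo_p]
        if lo_s != sorted(lo_s, reverse=True) or len(set(lo_s)) != len(lo_s):
            raise DerivationError(
                f"{self.variable}: lower scores must strictly decrease with p")
        if self.upper is not None:
            up_p = sorted(self.upper)
            if any(not 0 < p < 1 for p in up_p):
                raise DerivationError(f"{self.variable}: upper centiles must be in (0,1)")
            if up_p and up_p[0] <= lo_p[-1]:
                raise DerivationError(f"{self.variable}: centiles must be ordered")
            up_s = [self.upper[p] for p in up_p]
            if up_s != sorted(up_s) or len(set(up_s)) != len(up_s):
                raise DerivationError(
                    f"{self.variable}: upper scores must strictly increase with p")

    @property
    def sidedness(self) -> str:
        return "two_sided" if self.upper else "lower_only"


@dataclass(frozen=True)
class SmoothedDistribution:
    """Kernel-smoothed CDF of one vital sign on an evaluation grid."""

    samples_n: int
    sigma_hat: float
    bandwidth_h: float
    grid: np.ndarray
    cdf_values: np.ndarray

    def cdf(self, x) -> np.ndarray:
        """Interpolated CDF value(s); clamps to 0/1 outside the grid."""
        return np.interp(x, self.grid, self.cdf_values, left=0.0, right=1.0)


def bandwidth_from_stats(sigma_hat: float, n: int) -> float:
    """Normal-approximation kernel bandwidth ``1.06 * sigma_hat * n**(-1/5)``."""
    if n < 1:
        raise DerivationError("n must be >= 1")
    if not (math.isfinite(sigma_hat) and sigma_hat > 0):
        raise DerivationError("sigma_hat must be finite and positive "
                              "(constant samples have no bandwidth)")
    return 1.06 * sigma_hat * n ** (-1.0 / 5.0)


def kde_bandwidth(samples: Sequence[float], ddof: int = 1) -> float:
    """Bandwidth for a sample; ``ddof=1`` (sample standard deviation) default."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise DerivationError("need at least 2 samples to estimate sigma_hat")
    if not np.all(np.isfinite(x)):
        raise DerivationError("samples must be finite")
    sigma = float(x.std(ddof=ddof))
    return bandwidth_from_stats(sigma, x.size)


def smoothed_cdf(samples: Sequence[float], bandwidth: float,
                 grid_size: int = _GRID_SIZE) -> SmoothedDistribution:
    """Gaussian-mixture CDF ``P(x) = mean(Phi((x - x_i)/h))`` on a grid.

    The grid spans the sample range padded by four bandwidths either side so
    the tail mass at the extremes is below 1e-4.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise DerivationError("need at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise DerivationError("samples must be finite")
    if not bandwidth > 0:
        raise DerivationError("bandwidth must be positive")
    lo = x.min() - _GRID_PAD * bandwidth
    hi = x.max() + _GRID_PAD * bandwidth
    grid = np.linspace(lo, hi, grid_size)

    if x.size <= _EXACT_N_MAX:
        centers, weights = x, np.full(x.size, 1.0 / x.size)
    else:
        counts, edges = np.histogram(x, bins=_N_BINS)
        mids = 0.5 * (edges[:-1] + edges[1:])
        keep = counts > 0
        centers, weights = mids[keep], counts[keep] / x.size

    cdf = np.empty(grid_size)
    chunk = max(1, int(4e6 // max(1, centers.size)))
    for start in range(0, grid_size, chunk):
        g = grid[start:start + chunk]
        z = (g[:, None] - centers[None, :]) / bandwidth
        cdf[start:start + len(g)] = ndtr(z) @ weights
    cdf = np.maximum.accumulate(cdf)  # guard against fp wiggle
    return SmoothedDistribution(samples_n=int(x.size),
                                sigma_hat=float(x.std(ddof=1)),
                                bandwidth_h=float(bandwidth),
                                grid=grid, cdf_values=cdf)


def invert_centile(dist: SmoothedDistribution, p: float) -> float:
    """Smallest grid value with CDF >= p, refined by local linear interpolation."""
    if not 0 < p < 1:
        raise DerivationError(f"centile probability must be in (0,1), got {p}")
    values = dist.cdf_values
    idx = int(np.searchsorted(values, p, side="left"))
    if idx >= len(values):
        return float(dist.grid[-1])
    if idx == 0:
        return float(dist.grid[0])
    v0, v1 = values[idx - 1], values[idx]
    if v1 <= v0:  # flat stretch: honour "smallest x with P(x) >= p"
        return float(dist.grid[idx])
    frac = (p - v0) / (v1 - v0)
    return float(dist.grid[idx - 1] + frac * (dist.grid[idx] - dist.grid[idx - 1]))


def round_to_resolution(value: float, resolution: float) -> float:
    """Round-half-away-from-zero to a multiple of ``resolution``."""
    q = value / resolution
    r = math.floor(q + 0.5) if q >= 0 else math.ceil(q - 0.5)
    return round(r * resolution, 10)


def derive_band_table(samples: Sequence[float], spec: CentileSpec,
                      sigma_ddof: int = 1) -> VariableBandTable:
    """Full derivation for one variable: KDE -> centiles -> rounded bands."""
    h = kde_bandwidth(samples, ddof=sigma_ddof)
    dist = smoothed_cdf(samples, h)
    return band_table_from_distribution(dist, spec)


def band_table_from_distribution(dist: SmoothedDistribution,
                                 spec: CentileSpec) -> VariableBandTable:
    res = spec.rounding_resolution
    lower_p = sorted(spec.lower)
    upper_p = sorted(spec.upper) if spec.upper else []
    probs = lower_p + upper_p
    raw = [invert_centile(dist, p) for p in probs]
    cuts = [round_to_resolution(t, res) for t in raw]
    for (pa, ca), (pb, cb) in zip(zip(probs, cuts), zip(probs[1:], cuts[1:])):
        if not ca < cb:
            raise ThresholdCollisionError(
                f"{spec.variable}: rounded thresholds collide for centiles "
                f"{pa} -> {ca} and {pb} -> {cb}")
    # region scores from -inf upward: below the smallest lower cut the score
    # is the one mapped to that centile; the region at/above the last lower
    # cut is 0; upper cuts open the ascending upper scores.
    region_scores = ([spec.lower[p] for p in lower_p] + [0]
                     + [spec.upper[p] for p in upper_p])
    bands = []
    for i, score in enumerate(region_scores):
        lower = -math.inf if i == 0 else cuts[i - 1]
        upper = math.inf if i == len(region_scores) - 1 else round(cuts[i] - res, 10)
        bands.append(ScoreBand(score=score, lower=lower, upper=upper))
    return VariableBandTable(variable=spec.variable, bands=tuple(bands),
                             resolution=res,
                             admissible_min=spec.admissible_min,
                             admissible_max=spec.admissible_max)


@dataclass
class DerivationLog:
    """Per-variable diagnostics from :func:`derive_ews`."""

    n: int
    sigma_hat: float
    bandwidth_h: float
    raw_thresholds: dict
    rounded_thresholds: dict


def derive_ews(dataset: Sequence[ObservationSet], specs: Sequence[CentileSpec],
               oxygen_increment: int = 0, name: str = "derived-cews",
               sigma_ddof: int = 1) -> tuple[EWSDefinition, dict]:
    """Derive a complete scoring system from a preprocessed observation table.

    Values that were mean-imputed upstream are excluded from the derivation
    samples (they are artefacts of preprocessing, not measurements).
    Returns the definition and a per-variable :class:`DerivationLog` map.
    """
    dataset = list(dataset)
    if not dataset:
        raise DerivationError("empty dataset")
    tables: dict[str, VariableBandTable] = {}
    logs: dict[str, DerivationLog] = {}
    for spec in specs:
        values = [getattr(o, spec.variable) for o in dataset
                  if getattr(o, spec.variable) is not None
                  and spec.variable not in o.imputed_flags]
        if len(values) < 2:
            raise DerivationError(f"{spec.variable}: not enough samples")
        h = kde_bandwidth(values, ddof=sigma_ddof)
        dist = smoothed_cdf(values, h)
        tables[spec.variable] = band_table_from_distribution(dist, spec)
        probs = sorted(spec.lower) + (sorted(spec.upper) if spec.upper else [])
        raw = {p: invert_centile(dist, p) for p in probs}
        logs[spec.variable] = DerivationLog(
            n=dist.samples_n, sigma_hat=dist.sigma_hat, bandwidth_h=dist.bandwidth_h,
            raw_thresholds=raw,
            rounded_thresholds={p: round_to_resolution(v, spec.rounding_resolution)
                                for p, v in raw.items()})
    definition = EWSDefinition(name=name, tables=tables, avpu_map=DEFAULT_AVPU_MAP,
                               oxygen_increment=oxygen_increment,
                               provenance="derived from data by kernel-smoothed centiles")
    return definition, logs


def default_centile_specs() -> list[CentileSpec]:
    """Default spec set: two-sided 10/5/1 + 90/95/99 centiles for heart rate,
    respiratory rate and systolic BP; one-sided 20/10/2 for SpO2; two-sided
    10/1 + 90/99 at 0.1 degC for temperature."""
    two_sided_lower = {0.10: 1, 0.05: 2, 0.01: 3}
    two_sided_upper = {0.90: 1, 0.95: 2, 0.99: 3}
    return [
        CentileSpec("heart_rate", two_sided_lower, two_sided_upper, 1.0),
        CentileSpec("respiratory_rate", two_sided_lower, two_sided_upper, 1.0),
        CentileSpec("systolic_bp", two_sided_lower, two_sided_upper, 1.0),
        CentileSpec("temperature", {0.10: 1, 0.01: 3}, {0.90: 1, 0.99: 3}, 0.1),
        CentileSpec("spo2", {0.20: 1, 0.10: 2, 0.02: 3}, None, 1.0,
                    admissible_min=0.0, admissible_max=100.0),
    ]
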