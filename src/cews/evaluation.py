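"""Discrimination metrics for integer-valued warning scores.

AUC is computed with the mid-rank tie convention, so it equals the
Mann-Whitney concordance probability and the trapezoidal area under the ROC
curve built over the discrete score support.  The precision-recall area uses
the step-wise average-precision convention (trapezoidal PR interpolation is
known to be optimistic).  Confidence intervals: DeLong for AUC, stratified
bootstrap for AUC-PR (and available as a cross-check for AUC).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .model import EWSDefinition, EWSError, aggregate_scores_frame


class EvaluationError(ValueError):
    pass


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise EvaluationError("scores and labels must be 1-d and aligned")
    if not np.all(np.isfinite(s)):
        raise EvaluationError("scores must be finite")
    return s, y


def roc_auc_score(scores, labels) -> float:
    """Mann-Whitney AUC with mid-rank handling of ties."""
    s, y = _as_arrays(scores, labels)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("need at least one positive and one negative")
    ranks = rankdata(s, method="average")
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_points(scores, labels) -> list[tuple[float, float]]:
    """(FPR, sensitivity) per descending score cutoff, from (0,0) to (1,1)."""
    s, y = _as_arrays(scores, labels)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("need at least one positive and one negative")
    cutoffs = np.unique(s)[::-1]
    points = [(0.0, 0.0)]
    for c in cutoffs:
        pred = s >= c
        tp = int((pred & y).sum())
        fp = int((pred & ~y).sum())
        points.append((fp / n_neg, tp / n_pos))
    return points


def pr_points(scores, labels) -> list[tuple[float, float]]:
    """(sensitivity, PPV) per descending score cutoff."""
    s, y = _as_arrays(scores, labels)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise EvaluationError("need at least one positive")
    points = []
    for c in np.unique(s)[::-1]:
        pred = s >= c
        tp = int((pred & y).sum())
        fp = int((pred & ~y).sum())
        points.append((tp / n_pos, tp / (tp + fp)))
    return points


def average_precision(scores, labels) -> float:
    """Step-wise average precision over the discrete score support."""
    pts = pr_points(scores, labels)
    ap, prev_recall = 0.0, 0.0
    for recall, precision in pts:
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return float(ap)


def delong_auc_variance(scores, labels) -> tuple[float, float]:
    """(AUC, DeLong variance) via the mid-rank formulation."""
    s, y = _as_arrays(scores, labels)
    pos, neg = s[y], s[~y]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise EvaluationError("need at least one positive and one negative")
    tx = rankdata(pos, method="average")
    ty = rankdata(neg, method="average")
    tz = rankdata(np.concatenate([pos, neg]), method="average")
    auc = float((tz[:m].sum() - m * (m + 1) / 2.0) / (m * n))
    v01 = (tz[:m] - tx) / n          # structural components per positive
    v10 = 1.0 - (tz[m:] - ty) / m    # per negative
    s01 = float(v01.var(ddof=1)) if m > 1 else 0.0
    s10 = float(v10.var(ddof=1)) if n > 1 else 0.0
    return auc, s01 / m + s10 / n


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    auc, var = delong_auc_variance(scores, labels)
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


def bootstrap_ci(scores, labels, statistic: Callable, n_boot: int = 2000,
                 seed: int = 0, level: float = 0.95) -> tuple[float, float]:
    """Stratified (per-class) bootstrap percentile interval; seeded."""
    s, y = _as_arrays(scores, labels)
    pos_idx = np.flatnonzero(y)
    neg_idx = np.flatnonzero(~y)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise EvaluationError("need at least one positive and one negative")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        pi = rng.choice(pos_idx, size=len(pos_idx), replace=True)
        ni = rng.choice(neg_idx, size=len(neg_idx), replace=True)
        idx = np.concatenate([pi, ni])
        stats[b] = statistic(s[idx], y[idx])
    lo, hi = np.quantile(stats, [0.5 - level / 2.0, 0.5 + level / 2.0])
    return float(lo), float(hi)


@dataclass(frozen=True)
class EvaluationResult:
    auc: float
    auc_ci: tuple[float, float]
    auc_pr: float
    auc_pr_ci: tuple[float, float]
    roc_points: list
    pr_points: list
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return {"auc": self.auc, "auc_ci": list(self.auc_ci),
                "auc_pr": self.auc_pr, "auc_pr_ci": list(self.auc_pr_ci),
                "n_pos": self.n_pos, "n_neg": self.n_neg}


def evaluate_scores(scores, labels, level: float = 0.95, n_boot: int = 2000,
                    seed: int = 0) -> EvaluationResult:
    """Full metric bundle: AUC (DeLong CI), AUC-PR (bootstrap CI), curves."""
    s, y = _as_arrays(scores, labels)
    return EvaluationResult(
        auc=roc_auc_score(s, y),
        auc_ci=delong_ci(s, y, level),
        auc_pr=average_precision(s, y),
        auc_pr_ci=bootstrap_ci(s, y, average_precision, n_boot=n_boot,
                               seed=seed, level=level),
        roc_points=roc_points(s, y),
        pr_points=pr_points(s, y),
        n_pos=int(y.sum()), n_neg=int((~y).sum()))


@dataclass(frozen=True)
class SubstitutionReport:
    base_name: str
    donor_name: str
    base_auc: float
    substituted_auc: dict
    percentage_change: dict

    def to_dict(self) -> dict:
        return {"base": self.base_name, "donor": self.donor_name,
                "base_auc": self.base_auc,
                "substituted_auc": dict(self.substituted_auc),
                "percentage_change": dict(self.percentage_change)}


def substitution_analysis(base: EWSDefinition, donor: EWSDefinition,
                          observations, labels) -> SubstitutionReport:
    """Swap each variable's band table from ``donor`` into ``base`` in turn
    and report the relative AUC change ``(AUC_i - AUC_base)/AUC_base * 100``.

    ``observations`` is a tabular frame of complete (imputed) observation
    sets aligned with the boolean ``labels``.
    """
    import pandas as pd
    if set(base.tables) != set(donor.tables):
        raise EWSError("base and donor must score the same variable set")
    if not isinstance(observations, pd.DataFrame):
        from .io import observations_to_frame
        observations = observations_to_frame(observations)
    y = np.asarray(labels, dtype=bool)
    base_auc = roc_auc_score(aggregate_scores_frame(observations, base), y)
    sub_auc: dict[str, float] = {}
    pct: dict[str, float] = {}
    for var in base.tables:
        tables = dict(base.tables)
        tables[var] = donor.tables[var]
        hybrid = EWSDefinition(name=f"{base.name}+{donor.name}:{var}",
                               tables=tables, avpu_map=base.avpu_map,
                               oxygen_increment=base.oxygen_increment)
        auc_i = roc_auc_score(aggregate_scores_frame(observations, hybrid), y)
        sub_auc[var] = auc_i
        pct[var] = (auc_i - base_auc) / base_auc * 100.0
    return SubstitutionReport(base_name=base.name, donor_name=donor.name,
                              base_auc=base_auc, substituted_auc=sub_auc,
                              percentage_change=pct)
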