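import math
from dataclasses import replace
from datetime import datetime

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cews.model import (
    AVPU_LEVELS,
    BandTableError,
    EWSDefinition,
    EWSError,
    MissingValueError,
    ObservationSet,
    ScoreBand,
    VariableBandTable,
    aggregate_score,
    aggregate_scores_frame,
    avpu_sub_score,
    sub_score,
)
from cews.io import observations_to_frame

INF = math.inf

# printed band cells (score, lower, upper) transcribed independently of the
# shipped configs, so config drift is caught
MCEWS_CELLS = {
    "heart_rate": [(3, -INF, 42), (2, 43, 49), (1, 50, 53), (0, 54, 104),
                   (1, 105, 112), (2, 113, 127), (3, 128, INF)],
    "respiratory_rate": [(3, -INF, 7), (2, 8, 10), (1, 11, 12), (0, 13, 21),
                         (1, 22, 23), (2, 24, 28), (3, 29, INF)],
    "temperature": [(3, -INF, 35.4), (1, 35.5, 35.9), (0, 36.0, 37.3),
                    (1, 37.4, 38.3), (3, 38.4, INF)],
    "systolic_bp": [(3, -INF, 83), (2, 84, 90), (1, 91, 100), (0, 101, 157),
                    (1, 158, 167), (2, 168, 184), (3, 185, INF)],
    "spo2": [(3, -INF, 84), (2, 85, 90), (1, 91, 93), (0, 94, INF)],
}
CCEWS_CELLS = {
    "heart_rate": [(3, -INF, 50), (2, 51, 58), (1, 59, 63), (0, 64, 104),
                   (1, 105, 112), (2, 113, 127), (3, 128, INF)],
    "respiratory_rate": [(3, -INF, 7), (2, 8, 10), (1, 11, 13), (0, 14, 25),
                         (1, 26, 28), (2, 29, 33), (3, 34, INF)],
    "temperature": [(3, -INF, 35.4), (1, 35.5, 35.9), (0, 36.0, 37.3),
                    (1, 37.4, 38.3), (3, 38.4, INF)],
    "systolic_bp": [(3, -INF, 85), (2, 86, 96), (1, 97, 101), (0, 102, 154),
                    (1, 155, 164), (2, 165, 184), (3, 185, INF)],
    "spo2": [(3, -INF, 84), (2, 85, 90), (1, 91, 93), (0, 94, INF)],
}


def oracle_sub_score(value, table):
    """Brute-force interval membership under the half-open convention."""
    hits = []
    for band in table.bands:
        lo = -INF if band.lower == -INF else band.lower - table.resolution / 2
        hi = INF if band.upper == INF else band.upper + table.resolution / 2
        if lo <= value < hi:
            hits.append(band.score)
    assert len(hits) == 1, f"{value} hit {len(hits)} bands"
    return hits[0]


@pytest.mark.parametrize("system,cells", [("mcews", MCEWS_CELLS),
                                          ("ccews", CCEWS_CELLS)])
def test_shipped_definitions_match_printed_cells(system, cells, request):
    definition = request.getfixturevalue(system)
    for var, expected in cells.items():
        got = [(b.score, b.lower, b.upper) for b in definition.tables[var].bands]
        assert got == pytest.approx(expected), var


@pytest.mark.parametrize("value,expected", [
    (128, 3), (127, 2), (113, 2), (112, 1), (105, 1), (104, 0), (54, 0),
    (53, 1), (50, 1), (49, 2), (43, 2), (42, 3), (0, 3),
])
def test_mcews_heart_rate_cells(mcews, value, expected):
    assert sub_score(value, mcews.tables["heart_rate"]) == expected


def test_mcews_respiratory_rate_examples(mcews):
    table = mcews.tables["respiratory_rate"]
    assert sub_score(17, table) == 0
    assert sub_score(29, table) == 3
    # published table prints overlapping 8-11 / 11-12 cells; under the
    # half-open centile rule RR = 11 receives sub-score 1
    assert sub_score(11, table) == 1
    assert sub_score(10, table) == 2


def test_score_zero_band_scores_zero(mcews, ccews):
    for definition in (mcews, ccews):
        for table in definition.tables.values():
            band = table.score_0_band()
            lo = band.lower if band.lower != -INF else band.upper - 1
            hi = band.upper if band.upper != INF else band.lower + 1
            mid = (lo + hi) / 2
            assert sub_score(mid, table) == 0


@pytest.mark.parametrize("system", ["mcews", "ccews", "news"])
def test_partition_exhaustive_scan(system, request):
    """Every admissible grid value receives exactly one sub-score, and it
    matches the brute-force interval-membership oracle."""
    definition = request.getfixturevalue(system)
    grids = {
        "heart_rate": np.arange(0, 251),
        "respiratory_rate": np.arange(0, 81),
        "systolic_bp": np.arange(0, 301),
        "temperature": np.round(np.arange(250, 451) * 0.1, 1),
        "spo2": np.arange(0, 101),
    }
    for var, grid in grids.items():
        table = definition.tables[var]
        for value in grid:
            assert sub_score(value, table) == oracle_sub_score(value, table)


@pytest.mark.parametrize("system", ["mcews", "ccews", "news"])
def test_monotonicity_away_from_zero_band(system, request):
    definition = request.getfixturevalue(system)
    for var, table in definition.tables.items():
        zero = table.score_0_band()
        anchor = zero.lower if zero.lower != -INF else zero.upper
        grid = np.round(anchor + np.arange(-60, 120) * table.resolution, 10)
        if table.admissible_min is not None:
            grid = grid[grid >= table.admissible_min]
        if table.admissible_max is not None:
            grid = grid[grid <= table.admissible_max]
        scores = np.array([sub_score(v, table) for v in grid])
        pivot = np.searchsorted(grid, anchor)
        below, above = scores[:pivot + 1], scores[pivot:]
        assert np.all(np.diff(below) <= 0)
        assert np.all(np.diff(above) >= 0)


def test_avpu_sub_scores(mcews):
    assert avpu_sub_score("A", mcews) == 0
    for level in ("V", "P", "U"):
        assert avpu_sub_score(level, mcews) == 3
    with pytest.raises(EWSError):
        avpu_sub_score("X", mcews)


def test_aggregate_score_at_medians(mcews, mcews_o2, median_obs):
    assert aggregate_score(median_obs, mcews) == 0
    assert aggregate_score(median_obs, mcews_o2) == 0
    on_o2 = replace(median_obs, on_oxygen=True)
    assert aggregate_score(on_o2, mcews_o2) == 2
    assert aggregate_score(on_o2, mcews) == 0  # no increment configured


def test_aggregate_score_all_extreme(mcews_o2):
    # frozen from the per-variable oracle: 3+3+3+3+3 vitals + 3 AVPU + 2 O2
    obs = ObservationSet("a", datetime(2015, 1, 1), heart_rate=128,
                         respiratory_rate=29, systolic_bp=185,
                         temperature=38.4, spo2=84, avpu="U", on_oxygen=True)
    assert aggregate_score(obs, mcews_o2) == 20


def test_missing_variable_error_names_variable(mcews, median_obs):
    broken = replace(median_obs, respiratory_rate=None)
    with pytest.raises(MissingValueError, match="respiratory_rate"):
        aggregate_score(broken, mcews)
    with pytest.raises(MissingValueError, match="avpu"):
        aggregate_score(replace(median_obs, avpu=None), mcews)


def test_oxygen_flag_required_only_with_increment(mcews, mcews_o2, median_obs):
    no_flag = replace(median_obs, on_oxygen=None)
    assert aggregate_score(no_flag, mcews) == 0
    with pytest.raises(MissingValueError, match="on_oxygen"):
        aggregate_score(no_flag, mcews_o2)


def test_spo2_above_admissible_range_errors(mcews):
    with pytest.raises(EWSError):
        sub_score(150, mcews.tables["spo2"])


def test_non_integer_values_scored_by_half_open_convention(mcews):
    table = mcews.tables["heart_rate"]
    assert sub_score(104.4, table) == 0
    assert sub_score(104.5, table) == 1  # falls in the band above 104
    assert sub_score(42.5, table) == 2


@settings(max_examples=200, deadline=None)
@given(hr=st.integers(20, 240), rr=st.integers(2, 70), sbp=st.integers(40, 280),
       temp=st.integers(300, 430), spo2=st.integers(40, 100),
       avpu=st.sampled_from(AVPU_LEVELS), oxy=st.booleans())
def test_aggregate_additivity_oracle(hr, rr, sbp, temp, spo2, avpu, oxy):
    """aggregate_score equals the independently summed sub-scores."""
    from cews.io import builtin_definition
    definition = builtin_definition("mcews_o2")
    obs = ObservationSet("a", datetime(2015, 1, 1), heart_rate=hr,
                         respiratory_rate=rr, systolic_bp=sbp,
                         temperature=temp / 10.0, spo2=spo2, avpu=avpu,
                         on_oxygen=oxy)
    expected = sum(sub_score(getattr(obs, v), definition.tables[v])
                   for v in definition.tables)
    expected += avpu_sub_score(avpu, definition)
    expected += definition.oxygen_increment if oxy else 0
    assert aggregate_score(obs, definition) == expected


def test_frame_scoring_matches_scalar_path(mcews_o2):
    rng = np.random.default_rng(5)
    observations = [
        ObservationSet(f"a{i}", datetime(2015, 1, 1),
                       heart_rate=int(rng.integers(30, 200)),
                       respiratory_rate=int(rng.integers(4, 50)),
                       systolic_bp=int(rng.integers(50, 250)),
                       temperature=round(float(rng.uniform(33, 41)), 1),
                       spo2=int(rng.integers(60, 101)),
                       avpu=str(rng.choice(AVPU_LEVELS)),
                       on_oxygen=bool(rng.integers(0, 2)))
        for i in range(300)]
    frame = observations_to_frame(observations)
    vectorised = aggregate_scores_frame(frame, mcews_o2)
    scalar = [aggregate_score(o, mcews_o2) for o in observations]
    assert list(vectorised) == scalar


# --- construction invariants -------------------------------------------------

def _bands(*triples):
    return tuple(ScoreBand(score=s, lower=lo, upper=hi) for s, lo, hi in triples)


def test_gap_and_overlap_rejected():
    with pytest.raises(BandTableError):
        VariableBandTable("x", _bands((3, -INF, 50), (0, 45, 100), (3, 101, INF)))
    with pytest.raises(BandTableError):
        VariableBandTable("x", _bands((3, -INF, 50), (0, 55, 100), (3, 101, INF)))


def test_exactly_one_zero_band_required():
    with pytest.raises(BandTableError, match="score-0"):
        VariableBandTable("x", _bands((3, -INF, 50), (1, 51, 100), (3, 101, INF)))
    with pytest.raises(BandTableError, match="score-0"):
        VariableBandTable("x", _bands((0, -INF, 50), (1, 51, 60), (0, 61, 80),
                                      (3, 81, INF)))


def test_score_pattern_must_be_valley_shaped():
    with pytest.raises(BandTableError):
        VariableBandTable("x", _bands((1, -INF, 40), (3, 41, 50), (0, 51, 100),
                                      (3, 101, INF)))


def test_invalid_band_scores_rejected():
    with pytest.raises(BandTableError):
        ScoreBand(score=4, lower=0, upper=10)
    with pytest.raises(BandTableError):
        ScoreBand(score=2, lower=11, upper=10)


def test_avpu_map_must_cover_all_levels(mcews):
    with pytest.raises(EWSError, match="avpu_map"):
        EWSDefinition("bad", mcews.tables, {"A": 0, "V": 3})


def test_observation_rejects_unknown_avpu():
    with pytest.raises(ValueError, match="avpu"):
        ObservationSet("a", datetime(2015, 1, 1), avpu="X")
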