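import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fireconn import (
    ConnectivityDesign,
    ConnectivityParams,
    FireRecord,
    FireSet,
    TrapSite,
    connectivity,
    connectivity_all,
    pairwise_distance_km,
    weight_curve_spatial,
    weight_curve_temporal,
)
from fireconn.errors import ValidationError
from conftest import naive_connectivity


class TestDistance:
    def test_three_four_five(self):
        t = TrapSite("t", 0, 0, 2011)
        assert pairwise_distance_km(t, FireRecord("f", 3000, 4000, 100, 2010)) == 5.0

    def test_identity_and_symmetry(self):
        t = TrapSite("t", 123.0, -456.0, 2011)
        f = FireRecord("f", 123.0, -456.0, 100, 2010)
        assert pairwise_distance_km(t, f) == 0.0

    def test_missing_coordinates_rejected(self):
        t = TrapSite("t", float("nan"), 0, 2011)
        with pytest.raises(ValidationError, match="coordinates"):
            pairwise_distance_km(t, FireRecord("f", 0, 0, 100, 2010))


class TestParams:
    def test_alpha_outside_range_rejected(self):
        with pytest.raises(ValidationError, match="allow_wide"):
            ConnectivityParams(alpha_s=4.5, alpha_t=1.0)
        ConnectivityParams(alpha_s=4.5, alpha_t=1.0, allow_wide=True)

    def test_bad_log_base(self):
        with pytest.raises(ValidationError):
            ConnectivityParams(1.0, 1.0, log_base="2")


class TestConnectivity:
    def test_single_fire_hand_value(self, trap_origin):
        # d=2 km, area 10^4 m2, T=1: exp(-3.4) * ln(1e4) * exp(-1.4)
        fires = FireSet([FireRecord("f", 2000.0, 0.0, 10_000.0, 2010)])
        r = connectivity(trap_origin, fires, ConnectivityParams(1.7, 1.4))
        assert r.st_value == pytest.approx(0.07580, rel=5e-4)
        assert r.n_contributing_fires == 1

    def test_no_decay_collapses_to_log_area_sum(self, trap_origin):
        fires = FireSet(
            [FireRecord("a", 1000, 0, 100, 2010), FireRecord("b", 0, 9000, 1000, 2005)]
        )
        r = connectivity(trap_origin, fires, ConnectivityParams(0.0, 0.0))
        assert r.st_value == pytest.approx(math.log(100) + math.log(1000), rel=1e-12)

    def test_fire_beyond_radius_excluded(self, trap_origin):
        fires = FireSet([FireRecord("far", 25_000.0, 0.0, 1e6, 2010)])
        r = connectivity(trap_origin, fires, ConnectivityParams(0.5, 0.5))
        assert r.st_value == 0.0
        assert r.n_contributing_fires == 0

    def test_truncation_boundary_inclusive(self, trap_origin):
        at_radius = FireSet([FireRecord("edge", 20_000.0, 0.0, 1000.0, 2010)])
        just_out = FireSet([FireRecord("out", 20_000.001, 0.0, 1000.0, 2010)])
        p = ConnectivityParams(0.1, 0.1)
        assert connectivity(trap_origin, at_radius, p).st_value > 0
        assert connectivity(trap_origin, just_out, p).st_value == 0.0

    def test_empty_fireset_warns_and_returns_zero(self, trap_origin, caplog):
        with caplog.at_level("WARNING"):
            r = connectivity(trap_origin, FireSet([]), ConnectivityParams(1, 1))
        assert r.st_value == 0.0 and r.n_contributing_fires == 0
        assert "empty" in caplog.text

    def test_subunit_area_rejected(self, trap_origin):
        fires = FireSet([FireRecord("tiny", 100.0, 0.0, 0.5, 2010)])
        with pytest.raises(ValidationError, match="area_m2 < 1"):
            connectivity(trap_origin, fires, ConnectivityParams(1, 1))

    def test_fire_not_prior_to_sampling_rejected(self, trap_origin):
        fires = FireSet([FireRecord("f", 100.0, 0.0, 500.0, 2011)])
        with pytest.raises(ValidationError, match="prior"):
            connectivity(trap_origin, fires, ConnectivityParams(1, 1))

    def test_log10_rescales_by_ln10(self, trap_origin, small_fires):
        p_e = ConnectivityParams(1.2, 0.8)
        p_10 = ConnectivityParams(1.2, 0.8, log_base="10")
        st_e = connectivity(trap_origin, small_fires, p_e).st_value
        st_10 = connectivity(trap_origin, small_fires, p_10).st_value
        assert st_10 == pytest.approx(st_e / math.log(10), rel=1e-12)

    def test_edge_distance_mode_increases_weight(self, trap_origin):
        fires = FireSet([FireRecord("big", 5000.0, 0.0, 1e6, 2010)])
        centre = ConnectivityParams(1.0, 0.0)
        edge = ConnectivityParams(1.0, 0.0, edge_distance=True)
        assert connectivity(trap_origin, fires, edge).st_value > \
            connectivity(trap_origin, fires, centre).st_value


# -- randomized instances: vectorized design vs the naive double loop --------

_coord = st.floats(-30_000, 30_000, allow_nan=False)
_fire = st.builds(
    FireRecord,
    fire_id=st.uuids().map(str),
    x_m=_coord, y_m=_coord,
    area_m2=st.floats(100, 1e7),
    year=st.integers(1999, 2010),
)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    fires=st.lists(_fire, min_size=0, max_size=100),
    traps=st.lists(st.tuples(_coord, _coord), min_size=1, max_size=21),
    alpha_s=st.floats(0, 4), alpha_t=st.floats(0, 4),
)
def test_vectorized_matches_double_loop_oracle(fires, traps, alpha_s, alpha_t):
    fireset = FireSet(fires)
    sites = [TrapSite(f"T{i}", x, y, 2011) for i, (x, y) in enumerate(traps)]
    results = connectivity_all(sites, fireset, ConnectivityParams(alpha_s, alpha_t))
    for site, res in zip(sites, results):
        expected, n_contrib = naive_connectivity(site, fireset, alpha_s, alpha_t)
        assert res.st_value == pytest.approx(expected, rel=1e-12, abs=1e-300)
        assert res.n_contributing_fires == n_contrib


def test_additivity_over_disjoint_firesets(trap_origin, small_fires):
    p = ConnectivityParams(0.9, 1.3)
    half_a = FireSet(small_fires.records[:2])
    half_b = FireSet(small_fires.records[2:])
    st_union = connectivity(trap_origin, small_fires, p).st_value
    st_split = (
        connectivity(trap_origin, half_a, p).st_value
        + connectivity(trap_origin, half_b, p).st_value
    )
    assert st_union == pytest.approx(st_split, rel=1e-12)


def test_monotone_nonincreasing_in_decay_scales(trap_origin, small_fires):
    alphas = np.linspace(0, 4, 9)
    st_s = [connectivity(trap_origin, small_fires, ConnectivityParams(a, 1.0)).st_value
            for a in alphas]
    st_t = [connectivity(trap_origin, small_fires, ConnectivityParams(1.0, a)).st_value
            for a in alphas]
    assert all(a >= b for a, b in zip(st_s, st_s[1:]))
    assert all(a >= b for a, b in zip(st_t, st_t[1:]))


def test_adding_a_fire_never_decreases_st(trap_origin, small_fires):
    p = ConnectivityParams(1.0, 1.0)
    base = connectivity(trap_origin, small_fires, p).st_value
    more = FireSet(small_fires.records + [FireRecord("extra", 500, 500, 3.0, 2009)])
    assert connectivity(trap_origin, more, p).st_value >= base


class TestWeightCurves:
    def test_spatial_values(self):
        assert weight_curve_spatial(0.0, [0, 1, 5]).tolist() == [1.0, 1.0, 1.0]
        assert weight_curve_spatial(4.0, [2.0])[0] == pytest.approx(3.3546e-4, rel=1e-3)
        assert weight_curve_spatial(1.7, [0.0])[0] == 1.0

    def test_temporal_values(self):
        assert weight_curve_temporal(1.4, [3.0])[0] == pytest.approx(0.01500, rel=1e-3)
        assert weight_curve_temporal(0.0, [0, 7])[1] == 1.0
        assert weight_curve_temporal(1.4, [0.0])[0] == 1.0

    def test_strictly_decreasing_when_decay_positive(self):
        w = weight_curve_spatial(0.3, np.linspace(0, 10, 50))
        assert np.all(np.diff(w) < 0)

    def test_negative_grid_rejected(self):
        with pytest.raises(ValidationError):
            weight_curve_spatial(1.0, [-0.1])
        with pytest.raises(ValidationError):
            weight_curve_temporal(1.0, [-1.0])


def test_design_grid_matches_pointwise(small_fires):
    sites = [TrapSite(f"T{i}", x, y, 2011) for i, (x, y) in
             enumerate([(0, 0), (4000, 4000), (-10_000, 2000)])]
    design = ConnectivityDesign(sites, small_fires)
    a_s = np.array([0.0, 0.7, 2.1])
    a_t = np.array([0.0, 1.4])
    grid = design.st_grid(a_s, a_t)
    for i, s in enumerate(a_s):
        for j, t in enumerate(a_t):
            np.testing.assert_allclose(grid[i, j], design.st(s, t), rtol=1e-12)
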