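"""Cellular-automaton dispersal: kernel math, step dynamics, invariants."""

import numpy as np
import pytest

from spreadca import RasterLayer
from spreadca.ca import (
    STATUS_BARRIER, STATUS_DECOLONIZED, STATUS_OCCUPIED, STATUS_UNSUITABLE,
    CellStateGrid, DispersalParams, SuitabilityStack,
    build_initial_distribution, kernel_prob, ldd_events, percent_colonized,
    run_simulation, sdd_colonization_prob, step_year, update_suitability,
)
from spreadca.errors import AlignmentError, InvalidSpecError, SpreadcaError

from conftest import make_stack


# -- kernel -----------------------------------------------------------------


@pytest.mark.parametrize("d, lam, expected", [
    (0.0, 0.005, 1.0),
    (200.0, 0.005, np.exp(-1.0)),
    (600.0, 0.005, np.exp(-3.0)),
    (100.0, 0.01, np.exp(-1.0)),
])
def test_kernel_closed_form(d, lam, expected):
    assert kernel_prob(d, lam) == pytest.approx(expected, abs=1e-12)


def test_kernel_monotone_and_rejects_negative():
    d = np.linspace(0, 5000, 100)
    k = kernel_prob(d, 0.005)
    assert np.all(np.diff(k) < 0)
    with pytest.raises(ValueError):
        kernel_prob(-1.0, 0.005)


def test_params_invariants_enforced():
    with pytest.raises(InvalidSpecError):
        DispersalParams(sdd_max=700.0, ldd_min=600.0)
    with pytest.raises(InvalidSpecError):
        DispersalParams(ldd_freq=1.5)
    with pytest.raises(InvalidSpecError):
        DispersalParams(maturity_age=0)


# -- SDD probability --------------------------------------------------------


def test_sdd_prob_no_source_in_range(open_state, default_params):
    # nearest source is 4 cells = 800 m away: beyond the 600 m cutoff
    assert sdd_colonization_prob((20, 24), open_state, default_params) == 0.0


def test_sdd_prob_single_source(open_state, default_params):
    assert sdd_colonization_prob((20, 21), open_state, default_params) == \
        pytest.approx(np.exp(-1.0), rel=1e-12)


def test_sdd_prob_two_sources_complement_rule(open_state, default_params):
    open_state.status[20, 22] = STATUS_OCCUPIED
    open_state.age[20, 22] = 1
    # target between them, both at 200 m
    expected = 1.0 - (1.0 - np.exp(-1.0)) ** 2
    assert sdd_colonization_prob((20, 21), open_state, default_params) == \
        pytest.approx(expected, rel=1e-9)
    assert expected == pytest.approx(0.600423, abs=1e-6)


def test_sdd_prob_ignores_immature_sources(open_state, default_params):
    open_state.age[20, 20] = 0
    assert sdd_colonization_prob((20, 21), open_state, default_params) == 0.0


# -- LDD events -------------------------------------------------------------


def test_ldd_freq_zero_never_fires(open_state):
    params = DispersalParams(ldd_freq=0.0)
    rng = np.random.default_rng(0)
    for _ in range(50):
        assert ldd_events(open_state, params, rng) == []


def test_ldd_freq_one_single_source_lands_in_annulus(open_state):
    params = DispersalParams(ldd_freq=1.0, ldd_max=2000.0)
    rng = np.random.default_rng(1)
    hits = 0
    for _ in range(200):
        landings = ldd_events(open_state, params, rng)
        assert len(landings) <= 1  # one source, at most one event
        for r, c in landings:
            d = np.hypot(r - 20, c - 20) * 200.0
            # cell-center distance can differ from the landing point by at
            # most half a cell diagonal (~141 m)
            assert params.ldd_min - 150.0 < d <= params.ldd_max + 150.0
            hits += 1
    assert hits > 150  # 2 km annulus fits inside the 41x41 grid


def test_ldd_event_count_matches_binomial():
    state = CellStateGrid.open_grid(100, 100, 200.0)
    state.status[:, :] = STATUS_OCCUPIED
    state.age[:, :] = 1
    params = DispersalParams(ldd_freq=0.0005, ldd_max=1000.0)
    rng = np.random.default_rng(7)
    n, p = 10_000, params.ldd_freq
    fired = []
    for _ in range(60):
        src = np.flatnonzero(state.mature(1).ravel())
        fired.append((rng.random(src.size) < p).sum())
    mean, sigma = n * p, np.sqrt(n * p * (1 - p))
    assert abs(np.mean(fired) - mean) < 3 * sigma / np.sqrt(len(fired))


# -- annual step ------------------------------------------------------------


def test_step_without_occupied_cells_is_identity(full_suitability):
    state = CellStateGrid.open_grid(20, 20, 200.0)
    before = state.copy()
    step_year(state, full_suitability(20, 20), DispersalParams(),
              np.random.default_rng(0))
    assert np.array_equal(state.status, before.status)
    assert np.array_equal(state.age, before.age)


def test_near_deterministic_kernel_fills_sdd_disk(full_suitability):
    # lambda -> 0 makes D ~ 1 for every cell within 600 m
    params = DispersalParams(lam=1e-9, ldd_freq=0.0)
    within = []
    for rep in range(20):
        state = CellStateGrid.open_grid(15, 15, 200.0)
        state.status[7, 7] = STATUS_OCCUPIED
        state.age[7, 7] = 1
        step_year(state, full_suitability(15, 15), params,
                  np.random.default_rng(rep))
        occ = state.occupied()
        rr, cc = np.meshgrid(np.arange(15), np.arange(15), indexing="ij")
        disk = (np.hypot(rr - 7, cc - 7) * 200.0 <= 600.0)
        within.append(occ[disk].mean())
    assert np.mean(within) >= 0.99


def test_barrier_ring_is_never_crossed(full_suitability):
    # closed barrier ring; ldd_max smaller than the ring outer radius
    n = 31
    state = CellStateGrid.open_grid(n, n, 200.0)
    rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    d = np.hypot(rr - 15, cc - 15) * 200.0
    # inner radius + ldd_max <= outer radius, so no interior source can
    # jump past the band
    ring = (d >= 800.0) & (d <= 2200.0)
    state.status[ring] = STATUS_BARRIER
    state.status[15, 15] = STATUS_OCCUPIED
    state.age[15, 15] = 1
    params = DispersalParams(lam=1e-9, ldd_freq=1.0, ldd_max=1200.0)
    suit = full_suitability(n, n)
    rng = np.random.default_rng(5)
    for _ in range(15):
        step_year(state, suit, params, rng)
    outside = d > 2200.0
    assert not state.occupied()[outside].any()
    assert not (state.status[ring] == STATUS_OCCUPIED).any()


def test_misaligned_suitability_raises(open_state, default_params):
    wrong = RasterLayer(np.ones((41, 41)), cell_size=100.0, origin_y=4100.0)
    with pytest.raises(AlignmentError):
        step_year(open_state, wrong, default_params, np.random.default_rng(0))


# -- initial distribution ---------------------------------------------------


def test_merge_distance_controls_region_count():
    grid = CellStateGrid.open_grid(200, 200, 200.0)
    two_near = np.array([[10_000.0, 20_000.0], [18_000.0, 20_000.0]])   # 8 km
    two_far = np.array([[10_000.0, 20_000.0], [22_000.0, 20_000.0]])    # 12 km
    _, n1 = build_initial_distribution(two_near, grid)
    _, n2 = build_initial_distribution(two_far, grid)
    assert (n1, n2) == (1, 2)


def test_disk_cell_count_matches_brute_force():
    grid = CellStateGrid.open_grid(120, 120, 200.0)
    pt = np.array([[12_040.0, 11_980.0]])
    occ, _ = build_initial_distribution(pt, grid, buffer_radius=5000.0)
    X, Y = occ.cell_centers()
    expected = int((np.hypot(X - pt[0, 0], Y - pt[0, 1]) <= 5000.0).sum())
    assert occ.values.sum() == expected
    assert abs(expected - np.pi * 5000.0**2 / 200.0**2) < 100  # ~1963 cells


def test_initial_distribution_skips_blocked_cells():
    grid = CellStateGrid.open_grid(60, 60, 200.0)
    grid.status[:, :30] = STATUS_BARRIER
    occ, _ = build_initial_distribution(np.array([[6000.0, 6000.0]]), grid,
                                        buffer_radius=2000.0)
    assert occ.values[:, :30].sum() == 0
    assert occ.values.sum() > 0


def test_all_points_outside_grid_raise():
    grid = CellStateGrid.open_grid(10, 10, 200.0)
    with pytest.raises(SpreadcaError, match="outside"):
        build_initial_distribution(np.array([[1e6, 1e6]]), grid)


# -- suitability stack ------------------------------------------------------


def test_update_suitability_decolonizes_below_threshold(full_suitability):
    state = CellStateGrid.open_grid(10, 10, 200.0)
    state.status[2, 2] = STATUS_OCCUPIED
    state.age[2, 2] = 3
    low = RasterLayer(np.zeros((10, 10)), origin_y=2000.0, cell_size=200.0)
    stack = SuitabilityStack([(0, full_suitability(10, 10)), (5, low)])
    update_suitability(state, stack, 5)
    assert state.status[2, 2] == STATUS_DECOLONIZED


def test_stack_layer_switching_and_bounds(full_suitability):
    s0, s1 = full_suitability(5, 5), full_suitability(5, 5)
    stack = SuitabilityStack([(2000, s0), (2020, s1)])
    assert stack.layer_for(2010) is s0
    assert stack.layer_for(2020) is s1
    assert stack.layer_for(2050) is s1
    with pytest.raises(SpreadcaError):
        stack.layer_for(1999)


# -- full simulation --------------------------------------------------------


def _single_point_setup(n=80, cell=200.0):
    init = RasterLayer(np.zeros((n, n), dtype=np.int64), origin_y=n * cell,
                       cell_size=cell)
    init.values[n // 2, n // 2] = 1
    suit = RasterLayer(np.ones((n, n)), origin_y=n * cell, cell_size=cell)
    return init, make_stack(suit)


def test_horizon_zero_returns_initial_state():
    init, stack = _single_point_setup()
    res = run_simulation(init, stack, None, DispersalParams(n_replicates=3),
                         horizon_years=0, master_seed=1)
    for r in range(3):
        assert np.array_equal(res.occupancy[r, 0], init.values > 0)


def test_simulation_is_bit_identical_under_fixed_seed():
    init, stack = _single_point_setup(60)
    params = DispersalParams(n_replicates=2, ldd_freq=0.01, ldd_max=3000.0)
    a = run_simulation(init, stack, None, params, horizon_years=8, master_seed=9)
    b = run_simulation(init, stack, None, params, horizon_years=8, master_seed=9)
    assert np.array_equal(a.occupancy, b.occupancy)
    assert np.array_equal(a.pct_suitable, b.pct_suitable)


def test_sdd_only_reachability_bound():
    init, stack = _single_point_setup(90)
    years = 13
    params = DispersalParams(ldd_freq=0.0, n_replicates=2)
    res = run_simulation(init, stack, None, params, horizon_years=years,
                         master_seed=3)
    X, Y = init.cell_centers()
    cx, cy = X[45, 45], Y[45, 45]
    d = np.hypot(X - cx, Y - cy)
    for r in range(res.n_replicates):
        occupied_d = d[res.occupancy[r, -1]]
        assert occupied_d.max() <= years * 600.0 + 1e-9   # 7.8 km cap


def test_occupied_set_monotone_without_decolonization():
    init, stack = _single_point_setup(50)
    params = DispersalParams(ldd_freq=0.005, ldd_max=2000.0, n_replicates=1)
    res = run_simulation(init, stack, None, params, horizon_years=10,
                         master_seed=11, decolonize=False)
    for t in range(10):
        grew = res.occupancy[0, t] & ~res.occupancy[0, t + 1]
        assert not grew.any()
    assert np.all(np.diff(res.colonized_counts[0]) >= 0)


def test_barrier_and_unsuitable_never_occupied(small_bundle):
    landcover = small_bundle.landcover
    init = RasterLayer(np.zeros(landcover.shape, dtype=np.int64),
                       origin_y=landcover.origin_y, cell_size=landcover.cell_size)
    open_cells = np.argwhere(landcover.values == 0)
    r0, c0 = open_cells[len(open_cells) // 2]
    init.values[r0, c0] = 1
    stack = make_stack(small_bundle.suitability_truth, threshold=0.2)
    params = DispersalParams(ldd_freq=0.01, ldd_max=4000.0, n_replicates=2)
    res = run_simulation(init, stack, landcover, params, horizon_years=12,
                         master_seed=21)
    blocked = np.isin(landcover.values, [1, 2, 3, 4])
    for r in range(res.n_replicates):
        for t in range(res.occupancy.shape[1]):
            assert not res.occupancy[r, t][blocked].any()


def test_percent_colonized_summary():
    init, stack = _single_point_setup(20)
    params = DispersalParams(ldd_freq=0.0, n_replicates=3)
    res = run_simulation(init, stack, None, params, horizon_years=0, master_seed=0)
    # mask covering exactly 2 cells, one of which is occupied
    mask = init.with_values(np.zeros(init.shape, dtype=np.int64))
    mask.values[10, 10] = 1
    mask.values[0, 0] = 1
    out = percent_colonized(res, mask)
    assert out["mean"].iloc[0] == pytest.approx(50.0)
    assert out["ci_high"].iloc[0] - out["ci_low"].iloc[0] == pytest.approx(0.0)
    with pytest.raises(SpreadcaError):
        percent_colonized(res, init.with_values(np.zeros(init.shape, dtype=np.int64)))


def test_strong_barriers_block_line_of_sight(full_suitability):
    # a one-cell-thick wall between source and the far side
    n = 15
    state = CellStateGrid.open_grid(n, n, 200.0)
    state.status[:, 7] = STATUS_BARRIER
    state.status[7, 5] = STATUS_OCCUPIED
    state.age[7, 5] = 1
    params = DispersalParams(lam=1e-9, ldd_freq=0.0)
    suit = full_suitability(n, n)
    rng = np.random.default_rng(2)
    for _ in range(3):
        step_year(state, suit, params, rng, strong_barriers=True)
    assert not state.occupied()[:, 8:].any()  # wall stops every flight path
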