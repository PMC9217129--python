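"""Sliding-window co-localizer classifier and its statistics."""

import numpy as np
import pytest

from cotrack.colocalize import (
    ColocParams,
    bootstrap_ci,
    compare_conditions,
    find_colocalizers,
    is_adjacent,
    pcc_xy,
    windows_of,
)
from cotrack.simulate import SimulationParams, simulate_trajectories, \
    truth_to_tracks
from cotrack.tracks import PARTNER, REFERENCE, Track, TrackSet

from conftest import brownian_xy, make_track


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def _windows_bruteforce(frames, n):
    frames = set(int(f) for f in frames)
    lo, hi = min(frames), max(frames)
    return [s for s in range(lo, hi - n + 2)
            if all(f in frames for f in range(s, s + n))]


def test_windows_gapless_count():
    t = make_track(np.zeros((100, 2)) + np.arange(100)[:, None])
    assert len(windows_of(t, 12)) == 89  # 100 - 12 + 1


def test_windows_below_minimum_length():
    t = make_track(np.random.default_rng(0).normal(size=(11, 2)))
    assert len(windows_of(t, 12)) == 0


@pytest.mark.parametrize("missing", [10, 5, 15])
def test_windows_with_gap_match_enumeration(missing):
    frames = [f for f in range(20) if f != missing]
    t = make_track(np.arange(2 * len(frames)).reshape(-1, 2), frames=frames)
    got = windows_of(t, 12).tolist()
    assert got == _windows_bruteforce(frames, 12)
    if missing == 10:
        assert got == []  # no 12-frame stretch avoids the central gap


def test_windows_step_subsamples_starts():
    t = make_track(np.zeros((30, 2)) + np.arange(30)[:, None])
    all_starts = windows_of(t, 12, step=1)
    stepped = windows_of(t, 12, step=3)
    assert set(stepped) <= set(all_starts)
    assert np.array_equal(stepped, all_starts[::3])


# ---------------------------------------------------------------------------
# PCC
# ---------------------------------------------------------------------------

def test_pcc_identical_windows():
    w = brownian_xy(12, rng=np.random.default_rng(1))
    assert pcc_xy(w, w) == pytest.approx((1.0, 1.0))


def test_pcc_stationary_window_undefined():
    w = brownian_xy(12, rng=np.random.default_rng(2))
    const = np.full((12, 2), 3.0)
    px, py = pcc_xy(w, const)
    assert np.isnan(px) and np.isnan(py)


def test_pcc_perfect_linear_relation():
    ref = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], float)
    par = np.array([[0, 0], [2, 2], [4, 4], [6, 6]], float)
    assert pcc_xy(ref, par) == pytest.approx((1.0, 1.0))


def test_pcc_length_mismatch_rejected():
    with pytest.raises(ValueError):
        pcc_xy(np.zeros((5, 2)), np.zeros((6, 2)))


# ---------------------------------------------------------------------------
# adjacency
# ---------------------------------------------------------------------------

def test_adjacency_cases():
    rng = np.random.default_rng(3)
    a = make_track(brownian_xy(20, rng=rng))
    assert is_adjacent(a, a)

    far = make_track(brownian_xy(20, rng=rng, origin=(30.0, 30.0)),
                     channel=PARTNER)
    assert not is_adjacent(a, far)

    # one partner point exactly on the reference box edge: inclusive
    x0, y0, x1, y1 = a.bounding_box()
    graze = make_track(np.array([[x1, y1], [x1 + 5.0, y1 + 5.0]]),
                       channel=PARTNER)
    assert is_adjacent(a, graze)
    # padding rescues a near miss
    near = make_track(np.array([[x1 + 0.05, y1], [x1 + 5.0, y1 + 5.0]]),
                      channel=PARTNER)
    assert not is_adjacent(a, near)
    assert is_adjacent(a, near, padding=0.1)


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

def _jittered_pair_sets(n_tracks, rng, jitter=0.02):
    refs, partners = [], []
    for i in range(n_tracks):
        xy = brownian_xy(30, rng=rng, origin=rng.uniform(0, 50, 2))
        refs.append(make_track(xy, track_id=i))
        partners.append(make_track(
            xy + rng.normal(0, jitter, xy.shape), track_id=i,
            channel=PARTNER))
    return TrackSet(refs, channel=REFERENCE), TrackSet(partners,
                                                       channel=PARTNER)


def test_jittered_duplicates_are_all_correlated(rng):
    """Partner = reference + 20 nm noise: perfect co-diffusion, 100%."""
    ref, par = _jittered_pair_sets(10, rng)
    res, detail = find_colocalizers(ref, par, ColocParams(), n_bootstrap=200,
                                    rng=rng)
    assert res.n_ref_total == 10
    assert res.percent_correlated == 100.0
    assert len(detail) >= 10


def test_monomer_false_positive_floor():
    """Independent Brownian pairs in a shared region: <=2% correlated."""
    from conftest import independent_pair_floor
    n_corr, n_tot = independent_pair_floor(1200, seed0=7000)
    assert n_tot > 800
    assert n_corr / n_tot <= 0.02


def test_ideal_dimer_fraction_matches_combinatorics():
    """Ideal detection of pure dimers at P_L=0.14.

    The co-localizer fraction among all visible tracks estimates
    F_obs = P_L/(2(1-P_L)) = 0.0814; the reference-denominator percentage
    estimates 100 * 2p/(2-p) = 15.05%.
    """
    tot = np.zeros(3)
    for seed in range(2):
        p = SimulationParams(n_particles=2500, n_frames=100, seed=400 + seed,
                             bleach_probability=0.0,
                             field_size=(900.0, 900.0))
        truth = simulate_trajectories(p)
        ref = truth_to_tracks(truth, REFERENCE)
        par = truth_to_tracks(truth, PARTNER)
        res, _ = find_colocalizers(ref, par, n_bootstrap=0)
        tot += (res.n_ref_correlated, res.n_ref_total, res.n_partner_total)
    f_obs_est = tot[0] / (tot[1] + tot[2] - tot[0])
    percent = 100 * tot[0] / tot[1]
    assert f_obs_est == pytest.approx(0.14 / (2 * 0.86), abs=0.012)
    assert percent == pytest.approx(100 * 2 * 0.14 / (2 - 0.14), abs=2.0)


def test_empty_reference_channel_reported_as_empty():
    par = TrackSet([make_track(brownian_xy(20), channel=PARTNER)],
                   channel=PARTNER)
    res, _ = find_colocalizers(TrackSet([], channel=REFERENCE), par,
                               n_bootstrap=0)
    assert res.n_ref_total == 0
    assert np.isnan(res.percent_correlated)


def test_threshold_monotonicity(rng):
    """Raising T never increases the number of co-localizers."""
    p = SimulationParams(n_particles=800, n_frames=60, seed=5,
                         field_size=(300.0, 300.0), bleach_probability=0.0)
    truth = simulate_trajectories(p)
    ref = truth_to_tracks(truth, REFERENCE)
    par = truth_to_tracks(truth, PARTNER)
    counts = []
    for t in (0.5, 0.7, 0.8, 0.9, 0.99):
        res, _ = find_colocalizers(
            ref, par, ColocParams(pcc_threshold=t), n_bootstrap=0)
        counts.append(res.n_ref_correlated)
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_window_length_monotonicity():
    frames = [f for f in range(40) if f not in (7, 23)]
    t = make_track(np.arange(2 * len(frames)).reshape(-1, 2), frames=frames)
    counts = [len(windows_of(t, n)) for n in (6, 8, 12, 14, 20)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_channel_swap_symmetry():
    """With p1 = p2 the statistic agrees when channels are exchanged."""
    p = SimulationParams(n_particles=2000, n_frames=100, seed=6,
                         bleach_probability=0.0, field_size=(800.0, 800.0))
    truth = simulate_trajectories(p)
    ref = truth_to_tracks(truth, REFERENCE)
    par = truth_to_tracks(truth, PARTNER)
    fwd, _ = find_colocalizers(ref, par, n_bootstrap=0)
    rev, _ = find_colocalizers(par, ref, n_bootstrap=0)
    se = 100 * np.sqrt(0.15 * 0.85 / fwd.n_ref_total)
    assert fwd.percent_correlated == pytest.approx(
        rev.percent_correlated, abs=4 * se)


# ---------------------------------------------------------------------------
# bootstrap and permutation statistics
# ---------------------------------------------------------------------------

def test_bootstrap_degenerate_zero_width(rng):
    assert bootstrap_ci(np.ones(50, bool), 200, rng=rng) == (100.0, 100.0)
    assert bootstrap_ci(np.zeros(50, bool), 200, rng=rng) == (0.0, 0.0)


def test_bootstrap_width_matches_binomial(rng):
    flags = np.zeros(1000, bool)
    flags[:100] = True
    lo, hi = bootstrap_ci(flags, 4000, rng=rng)
    width = hi - lo
    expected = 2 * 1.96 * np.sqrt(0.1 * 0.9 / 1000) * 100  # ~3.7 points
    assert width == pytest.approx(expected, rel=0.2)
    assert lo <= 10.0 <= hi  # point estimate inside the CI


def test_bootstrap_empty_input_rejected(rng):
    with pytest.raises(ValueError):
        bootstrap_ci(np.zeros(0, bool), 200, rng=rng)


def test_permutation_null_is_conservative(rng):
    a = np.array([8.0, 9.0, 10.0, 11.0, 12.0])
    res = compare_conditions(a, a.copy(), n_perm=999, rng=rng)
    assert res.p_permutation >= 0.9
    assert res.mean_difference == 0.0


def test_permutation_complete_separation_hits_floor(rng):
    a = rng.normal(8.0, 1.0, 10)
    b = rng.normal(20.0, 1.0, 10)
    res = compare_conditions(a, b, n_perm=999, rng=rng)
    assert res.p_permutation == pytest.approx(1 / 1000)
    assert res.p_ttest < 1e-6


def test_compare_requires_two_cells(rng):
    with pytest.raises(ValueError):
        compare_conditions([1.0], [2.0, 3.0], n_perm=100, rng=rng)
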