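"""Ground-truth generator: label statistics, Brownian moments, rendering."""

import numpy as np
import pytest

from cotrack.io import MovieStack
from cotrack.simulate import (
    DARK,
    REF_DYE,
    PARTNER_DYE,
    OpticsParams,
    SimulationParams,
    assign_labels,
    ground_truth_to_dataframe,
    render_movie,
    simulate_trajectories,
    truth_to_tracks,
)
from cotrack.tracks import REFERENCE, PARTNER


def test_dimer_label_fraction_half():
    """At p1 = p2 = 0.5 half of all dimers carry at least one of each color."""
    m = 1_000_000
    codes = np.stack(assign_labels(np.full(m, 2), 0.5, 0.5, seed=0))
    both = ((codes == REF_DYE).any(1) & (codes == PARTNER_DYE).any(1)).mean()
    assert both == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / m))


def test_dimer_visible_both_fraction_at_p14():
    """Both-color fraction among visible dimers matches P_L/(2(1-P_L))."""
    m = 1_000_000
    codes = np.stack(assign_labels(np.full(m, 2), 0.14, 0.14, seed=1))
    has_r = (codes == REF_DYE).any(1)
    has_p = (codes == PARTNER_DYE).any(1)
    frac = (has_r & has_p).sum() / (has_r | has_p).sum()
    expected = 0.14 / (2 * 0.86)
    assert frac == pytest.approx(expected, abs=3 * np.sqrt(expected / m / 0.48))


def test_assign_labels_invalid_probability():
    with pytest.raises(ValueError):
        assign_labels([2], 0.8, 0.4, seed=0)
    with pytest.raises(ValueError):
        assign_labels([2], -0.1, 0.1, seed=0)


def test_frozen_dynamics_at_zero_diffusion():
    p = SimulationParams(diffusion_coefficient=0.0, n_particles=5,
                         n_frames=20, seed=3)
    truth = simulate_trajectories(p)
    assert np.allclose(truth.positions, truth.positions[:, :1, :])
    assert np.allclose(truth.positions_partner, truth.positions)


def test_brownian_step_variance():
    """Per-axis mean squared frame-to-frame step equals 2 D dt."""
    d, dt = 0.18, 0.06
    p = SimulationParams(diffusion_coefficient=d, frame_interval=dt,
                         n_particles=200, n_frames=101, seed=4,
                         field_size=(2000.0, 2000.0), bleach_probability=0.0)
    truth = simulate_trajectories(p)
    steps = np.diff(truth.positions, axis=1)
    expected = 2 * d * dt
    n = steps.size
    se = expected * np.sqrt(2.0 / n)
    assert steps.var() == pytest.approx(expected, abs=4 * se)


def test_boundaries_contain_particles():
    for boundary in ("reflecting", "periodic"):
        p = SimulationParams(diffusion_coefficient=0.5, n_particles=50,
                             n_frames=200, field_size=(3.0, 2.0),
                             boundary=boundary, seed=5)
        truth = simulate_trajectories(p)
        assert truth.positions[..., 0].min() >= 0
        assert truth.positions[..., 0].max() <= 3.0
        assert truth.positions[..., 1].min() >= 0
        assert truth.positions[..., 1].max() <= 2.0


def test_empty_roi_mask_rejected():
    with pytest.raises(ValueError):
        SimulationParams(roi_mask=np.zeros((10, 10), bool))


def test_roi_mask_confines_particles():
    mask = np.zeros((20, 20), bool)
    mask[:, 8:12] = True  # vertical tubule strip
    p = SimulationParams(n_particles=30, n_frames=50, roi_mask=mask,
                         field_size=(10.0, 10.0), seed=6)
    truth = simulate_trajectories(p)
    cols = (truth.positions[..., 0] / 10.0 * 20).astype(int)
    assert ((cols >= 8) & (cols < 12)).all()


def test_identical_seeds_bit_identical():
    p1 = SimulationParams(seed=7, n_particles=20, n_frames=30)
    p2 = SimulationParams(seed=7, n_particles=20, n_frames=30)
    t1, t2 = simulate_trajectories(p1), simulate_trajectories(p2)
    assert np.array_equal(t1.positions, t2.positions)
    assert all(np.array_equal(a, b) for a, b in zip(t1.labels, t2.labels))
    t3 = simulate_trajectories(SimulationParams(seed=8, n_particles=20,
                                                n_frames=30))
    assert not np.array_equal(t1.positions, t3.positions)


def test_bleaching_is_absorbing():
    p = SimulationParams(n_particles=50, n_frames=60,
                         bleach_probability=0.2, seed=9, p1=0.5, p2=0.5)
    truth = simulate_trajectories(p)
    for i in range(truth.n_particles):
        states = truth.dye_state_matrix(i)
        for row in states:
            lit = row != DARK
            if lit.any():
                # once dark, never lit again
                last_lit = np.nonzero(lit)[0][-1]
                assert lit[: last_lit + 1].all()


def test_render_background_only():
    p = SimulationParams(n_particles=0, n_frames=3, seed=10,
                         field_size=(3.0, 3.0))
    truth = simulate_trajectories(p)
    opt = OpticsParams(background_level=80.0)
    movie = render_movie(truth, opt)
    assert isinstance(movie, MovieStack)
    assert movie.data.shape[:2] == (3, 2)
    assert movie.data.mean() == pytest.approx(80.0, abs=1.0)


def test_render_centroid_matches_truth():
    """Noiseless rendering: intensity centroid within 0.1 px of the truth."""
    from cotrack.simulate import SimulationGroundTruth
    p = SimulationParams(n_particles=1, n_frames=1, seed=11,
                         oligomer_size_distribution={1: 1.0},
                         p1=1.0, p2=0.0, bleach_probability=0.0,
                         field_size=(4.0, 4.0))
    pos = np.array([[[2.131, 1.874]]])  # mid-field, off pixel centres
    truth = SimulationGroundTruth(
        params=p, sizes=np.array([1]), labels=[np.array([1])],
        bleach_frames=[np.array([10**9])], positions=pos,
        positions_partner=pos)
    opt = OpticsParams(background_level=5.0)
    movie = render_movie(truth, opt, noise=False)
    img = movie.data[0, 0].astype(float) - 5.0
    yy, xx = np.mgrid[0: img.shape[0], 0: img.shape[1]]
    cx = (img * xx).sum() / img.sum()
    cy = (img * yy).sum() / img.sum()
    tx, ty = truth.positions[0, 0] / opt.pixel_size
    assert abs(cx - tx) < 0.1 and abs(cy - ty) < 0.1


def test_render_linearity_in_photons():
    p = SimulationParams(n_particles=1, n_frames=1, seed=12,
                         oligomer_size_distribution={1: 1.0},
                         p1=1.0, p2=0.0, bleach_probability=0.0,
                         field_size=(4.0, 4.0))
    truth = simulate_trajectories(p)
    lo = render_movie(truth, OpticsParams(
        photons_per_fluor_per_frame=500.0, background_level=0.0),
        noise=False)
    hi = render_movie(truth, OpticsParams(
        photons_per_fluor_per_frame=1000.0, background_level=0.0),
        noise=False)
    s_lo = lo.data[0, 0].astype(float).sum()
    s_hi = hi.data[0, 0].astype(float).sum()
    assert s_hi == pytest.approx(2 * s_lo, rel=0.05)


def test_truth_to_tracks_visibility_and_channels():
    p = SimulationParams(n_particles=300, n_frames=40, seed=13,
                         bleach_probability=0.0)
    truth = simulate_trajectories(p)
    ref = truth_to_tracks(truth, REFERENCE, localization_sigma=0.0)
    par = truth_to_tracks(truth, PARTNER, localization_sigma=0.0)
    n_ref_true = sum(1 for lab in truth.labels if (lab == REF_DYE).any())
    n_par_true = sum(1 for lab in truth.labels if (lab == PARTNER_DYE).any())
    assert len(ref) == n_ref_true
    assert len(par) == n_par_true
    # partner tracks sample the offset positions, not the reference grid
    df = ground_truth_to_dataframe(truth)
    assert set(df.columns) >= {"particle_id", "frame", "x_um", "y_um"}
    assert len(df) == 300 * 40
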