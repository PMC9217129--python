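"""LoG detection and LAP linking against constructed and simulated truth."""

import numpy as np
import pandas as pd
import pytest

from cotrack.simulate import (OpticsParams, SimulationParams, render_movie,
                              simulate_trajectories)
from cotrack.simulate import _render_emitters
from cotrack.tracking import TrackingParams, detect_spots, link_spots
from cotrack.tracks import REFERENCE


def _spot_frame(positions_px, photons=1000.0, shape=(64, 64), background=50.0,
                sigma=1.3, noise_seed=None):
    img = np.full(shape, background)
    _render_emitters(img, np.asarray(positions_px, float),
                     np.full(len(positions_px), photons), sigma)
    if noise_seed is not None:
        rng = np.random.default_rng(noise_seed)
        img = rng.poisson(img).astype(float)
    return img


# pixel-unit parameters: pixel_size=1 so distances are in pixels
PX_PARAMS = TrackingParams(spot_radius=1.84, quality_threshold=10.0,
                           max_link_distance=9.0, max_gap_frames=2,
                           max_gap_distance=14.0)


def test_empty_frame_yields_no_spots():
    spots = detect_spots(np.zeros((2, 32, 32)), PX_PARAMS, pixel_size=1.0)
    assert len(spots) == 0


def test_single_spot_subpixel_accuracy():
    """One Gaussian spot at SNR ~10 localizes to within 0.2 px."""
    img = _spot_frame([(20.30, 31.70)], noise_seed=7)
    spots = detect_spots(img[None], PX_PARAMS, pixel_size=1.0)
    assert len(spots) == 1
    err = np.hypot(spots.x.iloc[0] - 20.30, spots.y.iloc[0] - 31.70)
    assert err < 0.2


def test_two_spots_ten_px_apart():
    img = _spot_frame([(20.0, 20.0), (30.0, 20.0)], noise_seed=8)
    spots = detect_spots(img[None], PX_PARAMS, pixel_size=1.0)
    assert len(spots) == 2


def _spot_table(tracks_px):
    """Build a detection table from {track: [(frame, x, y), ...]}."""
    rows = [(f, x, y, 50.0, 100.0) for pts in tracks_px for f, x, y in pts]
    df = pd.DataFrame(rows, columns=["frame", "x", "y", "quality",
                                     "intensity"])
    df["channel"] = 0
    return df


def test_single_stationary_track():
    pts = [[(f, 10.0, 10.0) for f in range(100)]]
    ts = link_spots(_spot_table(pts), PX_PARAMS)
    assert len(ts) == 1
    assert ts[0].n_points == 100


def test_two_parallel_tracks_no_switches():
    rng = np.random.default_rng(9)
    sep = 3 * PX_PARAMS.max_link_distance
    a = [(f, 10.0 + rng.normal(0, 1.5), 10.0 + rng.normal(0, 1.5))
         for f in range(30)]
    b = [(f, 10.0 + rng.normal(0, 1.5), 10.0 + sep + rng.normal(0, 1.5))
         for f in range(30)]
    ts = link_spots(_spot_table([a, b]), PX_PARAMS)
    assert len(ts) == 2
    for t in ts:
        # each track stays on one side: no identity switches
        assert (t.xy[:, 1] < 10 + sep / 2).all() or \
               (t.xy[:, 1] > 10 + sep / 2).all()
        assert t.n_points == 30


def test_gap_closing_bridges_missing_detection():
    pts = [[(f, 10.0, 10.0) for f in range(30) if f != 10]]
    ts = link_spots(_spot_table(pts), PX_PARAMS)
    assert len(ts) == 1
    assert ts[0].n_points == 29
    assert ts[0].span == 30
    assert ts[0].has_gaps


def test_gap_longer_than_limit_splits_track():
    pts = [[(f, 10.0, 10.0) for f in range(30) if not 10 <= f < 14]]
    ts = link_spots(_spot_table(pts), TrackingParams(
        spot_radius=1.84, max_link_distance=9.0, max_gap_frames=2,
        max_gap_distance=14.0))
    assert len(ts) == 2


def test_linking_permutation_invariant(rng):
    pts = []
    for i in range(5):
        x0, y0 = rng.uniform(5, 55, 2)
        pts.append([(f, x0 + rng.normal(0, 1.0), y0 + rng.normal(0, 1.0))
                    for f in range(20)])
    df = _spot_table(pts)
    shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
    ts_a = link_spots(df, PX_PARAMS)
    ts_b = link_spots(shuffled, PX_PARAMS)
    key = lambda ts: sorted(
        (tuple(t.frames), tuple(map(tuple, np.round(t.xy, 9)))) for t in ts
    )
    assert key(ts_a) == key(ts_b)


def test_no_two_tracks_share_a_spot(rng):
    pts = []
    for i in range(8):
        x0, y0 = rng.uniform(5, 55, 2)
        pts.append([(f, x0 + rng.normal(0, 2.0), y0 + rng.normal(0, 2.0))
                    for f in range(15)])
    ts = link_spots(_spot_table(pts), PX_PARAMS)
    seen = set()
    for t in ts:
        for f, (x, y) in zip(t.frames, t.xy):
            assert (f, x, y) not in seen
            seen.add((f, x, y))


def test_simulated_movie_recovery():
    """>=90% of particles recovered as single tracks, <=5% identity switches.

    Moderate density (0.026 spots/um^2), D = 0.18 um^2/s, 60 ms frames —
    the regime the linker defaults are designed for.
    """
    n_rec = n_parts = switches = links = 0
    for seed in (11, 12, 13):
        p = SimulationParams(n_particles=20, n_frames=50, seed=seed,
                             bleach_probability=0.0,
                             oligomer_size_distribution={1: 1.0},
                             p1=1.0, p2=0.0, field_size=(28.0, 28.0))
        truth = simulate_trajectories(p)
        movie = render_movie(truth, OpticsParams())
        spots = detect_spots(movie, TrackingParams(), channel=0)
        ts = link_spots(spots, TrackingParams())
        cover: dict[int, int] = {}
        for t in ts:
            ids = np.array([
                int(np.argmin(np.hypot(truth.positions[:, f, 0] - x,
                                       truth.positions[:, f, 1] - y)))
                for f, (x, y) in zip(t.frames, t.xy)
            ])
            switches += int((np.diff(ids) != 0).sum())
            links += ids.size - 1
            maj = np.bincount(ids).argmax()
            cover[maj] = max(cover.get(maj, 0), int((ids == maj).sum()))
        n_rec += sum(1 for i in range(20) if cover.get(i, 0) >= 0.9 * 50)
        n_parts += 20
    assert n_rec / n_parts >= 0.90
    assert switches / links <= 0.05
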