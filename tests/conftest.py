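import numpy as np
import pytest

from cotrack.tracks import Track, REFERENCE


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_track(xy, frames=None, track_id=0, channel=REFERENCE) -> Track:
    """Build a Track from an (n, 2) array (frames default to 0..n-1)."""
    xy = np.asarray(xy, dtype=float)
    if frames is None:
        frames = np.arange(len(xy))
    return Track(track_id=track_id, frames=np.asarray(frames), xy=xy,
                 channel=channel)


def brownian_xy(n_steps, d=0.18, dt=0.06, rng=None, origin=(0.0, 0.0)):
    """Unconstrained 2-D Brownian positions, n_steps points."""
    rng = rng or np.random.default_rng(0)
    steps = rng.normal(0.0, np.sqrt(2 * d * dt), (n_steps - 1, 2))
    return np.vstack([[origin], steps]).cumsum(axis=0) + 0.0


def independent_pair_floor(n_pairs, coloc_params=None, roi=5.0, seed0=0,
                           bleach=0.01, loc_sigma=0.02):
    """Monte-Carlo false-positive oracle: independent Brownian pairs.

    Each pair is one reference and one partner monomer diffusing
    independently in a shared square region of side ``roi`` um, with
    photobleaching-limited track durations.  Returns (n_classified
    correlated, n eligible reference tracks).
    """
    from cotrack.colocalize import ColocParams, find_colocalizers
    from cotrack.simulate import SimulationParams, simulate_trajectories
    from cotrack.tracks import PARTNER, REFERENCE, TrackSet

    params = coloc_params or ColocParams()
    corr = tot = 0
    for s in range(n_pairs):
        p = SimulationParams(
            oligomer_size_distribution={1: 1.0}, n_particles=2,
            n_frames=100, seed=seed0 + s, field_size=(roi, roi),
            p1=1.0, p2=0.0, bleach_probability=0.0)
        truth = simulate_trajectories(p)
        rng = np.random.default_rng(seed0 + s + 1_000_000)
        lives = np.clip(rng.geometric(bleach, 2), 2, 100)
        ref = Track(0, np.arange(lives[0]),
                    truth.positions[0, : lives[0]]
                    + rng.normal(0, loc_sigma, (lives[0], 2)), REFERENCE)
        par = Track(0, np.arange(lives[1]),
                    truth.positions_partner[1, : lives[1]]
                    + rng.normal(0, loc_sigma, (lives[1], 2)), PARTNER)
        res, _ = find_colocalizers(
            TrackSet([ref], channel=REFERENCE),
            TrackSet([par], channel=PARTNER), params, n_bootstrap=0)
        corr += res.n_ref_correlated
        tot += res.n_ref_total
    return corr, tot
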