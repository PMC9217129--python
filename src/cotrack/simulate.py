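"""Ground-truth simulator for two-color single-molecule tracking.

The generator emulates the experiment end to end: oligomers of known size
diffuse in 2-D (Brownian motion at D of order 0.05-0.5 um^2/s), each
protomer is stochastically labeled with a reference dye, a partner dye, or
nothing (per-protomer probabilities ``p1``/``p2``, ~0.14 each under
saturating labeling), fluorophores photobleach irreversibly, and the two
channels are imaged sequentially within each 60 ms combined frame so the
partner channel samples positions a configurable offset later.  Movies are
rendered with integrated Gaussian point-spread functions, Poisson photon
noise, constant background, and Gaussian read noise.

Every stage downstream of raw data (detection, linking, colocalization,
stoichiometry, diffusion) can therefore be tested against exact ground
truth: true particle identities, dye states, and trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import erf

from .io import AcquisitionParams, MovieStack
from .tracks import Track, TrackSet, REFERENCE, PARTNER

__all__ = [
    "SimulationParams",
    "OpticsParams",
    "SimulationGroundTruth",
    "assign_labels",
    "simulate_trajectories",
    "render_movie",
    "truth_to_tracks",
    "ground_truth_to_dataframe",
]

DARK, REF_DYE, PARTNER_DYE = 0, 1, 2


@dataclass
class SimulationParams:
    """Physical conditions of a simulated single-molecule movie.

    Defaults reproduce the imaging conditions of the assay this package
    models: 0.06 s combined frame time, ~100 frames per cell, labeling
    probability ~0.14 per protomer per color, and diffusion at
    0.18 um^2/s (the unstressed-receptor estimate).  The oligomer size
    distribution defaults to pure dimers, the resting state of the
    receptor.
    """

    diffusion_coefficient: float = 0.18  # um^2 / s
    oligomer_size_distribution: dict[int, float] = field(
        default_factory=lambda: {2: 1.0}
    )
    p1: float = 0.14
    p2: float = 0.14
    bleach_probability: float = 0.01  # per fluorophore per combined frame
    n_frames: int = 100
    frame_interval: float = 0.06  # s
    field_size: tuple[float, float] = (20.0, 20.0)  # um
    n_particles: int = 60
    boundary: str = "reflecting"  # or "periodic"
    roi_mask: Optional[np.ndarray] = None  # binary; True = accessible
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.p1 >= 0 and self.p2 >= 0 and self.p1 + self.p2 <= 1 + 1e-12):
            raise ValueError("need p1 >= 0, p2 >= 0, p1 + p2 <= 1")
        total = sum(self.oligomer_size_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("oligomer size fractions must sum to 1")
        if any(s < 1 for s in self.oligomer_size_distribution):
            raise ValueError("oligomer sizes must be >= 1 protomer")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.boundary not in ("reflecting", "periodic"):
            raise ValueError("boundary must be 'reflecting' or 'periodic'")
        if self.roi_mask is not None:
            self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
            if not self.roi_mask.any():
                raise ValueError("roi_mask has no accessible pixels")


@dataclass
class OpticsParams:
    """Camera and point-spread-function model for movie rendering.

    ``channel_time_offset`` is the lag between the reference and partner
    exposures within one combined frame (sequential acquisition); the
    default half-frame 0.03 s matches a 60 ms combined frame split between
    two channels.
    """

    pixel_size: float = 0.065  # um / pixel (100x objective, 6.5 um sensor px)
    psf_sigma: float = 1.3  # pixels
    photons_per_fluor_per_frame: float = 1000.0
    background_level: float = 50.0  # counts
    read_noise_sd: float = 2.0  # counts
    channel_time_offset: float = 0.03  # s

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.psf_sigma <= 0:
            raise ValueError("pixel_size and psf_sigma must be positive")
        if self.photons_per_fluor_per_frame < 0:
            raise ValueError("photon count must be >= 0")


@dataclass
class SimulationGroundTruth:
    """Exact state of every simulated particle.

    ``labels[i]`` gives the dye carried by each protomer of particle ``i``
    (0 dark, 1 reference, 2 partner); ``bleach_frames[i]`` the number of
    frames each fluorophore stays lit (bleaching is absorbing: a dye that
    has bleached never re-lights).  ``positions`` holds reference-channel
    sampling positions, ``positions_partner`` the same trajectories
    sampled ``channel_time_offset`` later within each combined frame.
    All positions in micrometres.
    """

    params: SimulationParams
    sizes: np.ndarray  # (n_particles,)
    labels: list[np.ndarray]
    bleach_frames: list[np.ndarray]
    positions: np.ndarray  # (n_particles, n_frames, 2)
    positions_partner: np.ndarray  # (n_particles, n_frames, 2)
    channel_time_offset: float = 0.03

    @property
    def n_particles(self) -> int:
        return int(self.sizes.size)

    def n_lit(self, particle: int, channel_code: int, frame: int) -> int:
        """Number of unbleached fluorophores of one color on a particle."""
        lab = self.labels[particle]
        bf = self.bleach_frames[particle]
        return int(np.sum((lab == channel_code) & (bf > frame)))

    def visible(self, particle: int, channel_code: int, frame: int) -> bool:
        return self.n_lit(particle, channel_code, frame) > 0

    def lit_matrix(self, channel_code: int) -> np.ndarray:
        """(n_particles, n_frames) count of unbleached fluors per color."""
        out = np.zeros((self.n_particles, self.params.n_frames), dtype=int)
        frames = np.arange(self.params.n_frames)
        for i in range(self.n_particles):
            sel = self.labels[i] == channel_code
            if sel.any():
                out[i] = (self.bleach_frames[i][sel][:, None]
                          > frames[None, :]).sum(axis=0)
        return out

    def dye_state_matrix(self, particle: int) -> np.ndarray:
        """(n_protomers, n_frames) dye-state codes, dark after bleaching."""
        lab = self.labels[particle][:, None]
        bf = self.bleach_frames[particle][:, None]
        frames = np.arange(self.params.n_frames)[None, :]
        return np.where(bf > frames, lab, DARK)


def assign_labels(sizes, p1: float, p2: float, seed=0) -> list[np.ndarray]:
    """Independently assign each protomer a dye state.

    Each protomer carries a reference dye with probability ``p1``, a
    partner dye with ``p2``, and is otherwise dark (unlabeled, pre-bleached
    or otherwise undetectable).  ``seed`` may also be a Generator.

    Returns one int array of dye codes per particle.
    """
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1 and p1 + p2 <= 1 + 1e-12):
        raise ValueError("need 0 <= p1, p2 and p1 + p2 <= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sizes = np.asarray(sizes, dtype=int)
    total = int(sizes.sum())
    u = rng.random(total)
    codes = np.where(u < p1, REF_DYE, np.where(u < p1 + p2, PARTNER_DYE, DARK))
    return list(np.split(codes, np.cumsum(sizes)[:-1]))


def _apply_boundary(pos: np.ndarray, field: tuple[float, float],
                    boundary: str) -> np.ndarray:
    out = pos.copy()
    for ax, L in enumerate(field):
        if boundary == "periodic":
            out[:, ax] = np.mod(out[:, ax], L)
        else:  # reflecting: fold onto the triangle wave of period 2L
            m = np.mod(out[:, ax], 2 * L)
            out[:, ax] = L - np.abs(m - L)
    return out


def _mask_lookup(mask: np.ndarray, pos: np.ndarray,
                 field: tuple[float, float]) -> np.ndarray:
    """True where positions fall on accessible mask pixels."""
    h, w = mask.shape
    col = np.clip((pos[:, 0] / field[0] * w).astype(int), 0, w - 1)
    row = np.clip((pos[:, 1] / field[1] * h).astype(int), 0, h - 1)
    return mask[row, col]


def simulate_trajectories(params: SimulationParams,
                          channel_time_offset: float = 0.03
                          ) -> SimulationGroundTruth:
    """Simulate labeled oligomers diffusing through the acquisition.

    All protomers of one oligomer share one Brownian trajectory (they are
    rigidly bound on the timescale of a movie).  Per-axis displacement over
    time tau has standard deviation sqrt(2 D tau); the partner channel is
    sampled ``channel_time_offset`` seconds after the reference channel
    within each combined frame, as sequential two-channel acquisition does.
    Reproducible: identical params (incl. seed) give identical output.
    """
    rng = np.random.default_rng(params.seed)
    sizes_avail = np.array(sorted(params.oligomer_size_distribution), dtype=int)
    probs = np.array([params.oligomer_size_distribution[s] for s in sizes_avail])
    sizes = rng.choice(sizes_avail, size=params.n_particles, p=probs)

    labels = assign_labels(sizes, params.p1, params.p2, rng)
    bleach_frames = []
    for lab in labels:
        if params.bleach_probability > 0:
            bf = rng.geometric(params.bleach_probability, size=lab.size)
        else:
            bf = np.full(lab.size, np.iinfo(np.int64).max)
        bleach_frames.append(np.asarray(bf, dtype=np.int64))

    n, F = params.n_particles, params.n_frames
    D, dt = params.diffusion_coefficient, params.frame_interval
    delta = float(np.clip(channel_time_offset, 0.0, dt))
    fx, fy = params.field_size

    start = rng.random((n, 2)) * np.array([fx, fy])
    if params.roi_mask is not None:
        # rejection-sample starts onto the accessible region
        for _ in range(1000):
            bad = ~_mask_lookup(params.roi_mask, start, params.field_size)
            if not bad.any():
                break
            start[bad] = rng.random((int(bad.sum()), 2)) * np.array([fx, fy])

    pos_ref = np.empty((n, F, 2))
    pos_par = np.empty((n, F, 2))
    cur = start
    sd_a = np.sqrt(2 * D * delta)  # ref -> partner within a frame
    sd_b = np.sqrt(2 * D * (dt - delta))  # partner -> next ref
    for f in range(F):
        pos_ref[:, f] = cur
        step = rng.normal(0.0, sd_a, (n, 2)) if sd_a > 0 else 0.0
        nxt = _apply_boundary(cur + step, params.field_size, params.boundary)
        if params.roi_mask is not None:
            ok = _mask_lookup(params.roi_mask, nxt, params.field_size)
            nxt[~ok] = cur[~ok]
        pos_par[:, f] = nxt
        cur = nxt
        step = rng.normal(0.0, sd_b, (n, 2)) if sd_b > 0 else 0.0
        nxt = _apply_boundary(cur + step, params.field_size, params.boundary)
        if params.roi_mask is not None:
            ok = _mask_lookup(params.roi_mask, nxt, params.field_size)
            nxt[~ok] = cur[~ok]
        cur = nxt

    return SimulationGroundTruth(
        params=params, sizes=sizes, labels=labels,
        bleach_frames=bleach_frames, positions=pos_ref,
        positions_partner=pos_par, channel_time_offset=delta,
    )


def _render_emitters(img: np.ndarray, xy_px: np.ndarray,
                     photons: np.ndarray, sigma: float) -> None:
    """Accumulate integrated-Gaussian spots into ``img`` (in place).

    Pixel i is centred at integer coordinate i; the photon count of each
    emitter is integrated over pixel boundaries with the error function.
    """
    h, w = img.shape
    r = int(np.ceil(4 * sigma))
    s2 = sigma * np.sqrt(2.0)
    for (x, y), ph in zip(xy_px, photons):
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = max(cx - r, 0), min(cx + r + 1, w)
        y0, y1 = max(cy - r, 0), min(cy + r + 1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1)
        ys = np.arange(y0, y1)
        gx = 0.5 * (erf((xs + 0.5 - x) / s2) - erf((xs - 0.5 - x) / s2))
        gy = 0.5 * (erf((ys + 0.5 - y) / s2) - erf((ys - 0.5 - y) / s2))
        img[y0:y1, x0:x1] += ph * np.outer(gy, gx)


def render_movie(truth: SimulationGroundTruth, optics: OpticsParams,
                 noise: bool = True, seed: Optional[int] = None) -> MovieStack:
    """Render ground truth into a two-channel camera movie.

    Each unbleached fluorophore contributes an integrated 2-D Gaussian of
    width ``psf_sigma`` at its trajectory position (the partner channel at
    the within-frame time offset).  With ``noise=True`` the expected image
    is Poisson-sampled (photon shot noise on signal + background) and
    Gaussian read noise is added; output is integer camera counts.
    """
    p = truth.params
    ps = optics.pixel_size
    w = max(int(round(p.field_size[0] / ps)), 1)
    h = max(int(round(p.field_size[1] / ps)), 1)
    rng = np.random.default_rng(p.seed + 1 if seed is None else seed)

    data = np.zeros((p.n_frames, 2, h, w), dtype=np.uint16)
    lit_counts = {code: truth.lit_matrix(code)
                  for code in (REF_DYE, PARTNER_DYE)}
    img = np.empty((h, w), dtype=np.float64)  # per-frame work buffer
    for f in range(p.n_frames):
        for c, (code, posarr) in enumerate(
            [(REF_DYE, truth.positions), (PARTNER_DYE, truth.positions_partner)]
        ):
            img[:] = optics.background_level
            n_lit = lit_counts[code][:, f]
            lit = np.nonzero(n_lit)[0]
            if lit.size:
                _render_emitters(
                    img, posarr[lit, f] / ps,
                    n_lit[lit] * optics.photons_per_fluor_per_frame,
                    optics.psf_sigma,
                )
            if noise:
                frame = rng.poisson(img).astype(np.float64)
                frame += rng.normal(0.0, optics.read_noise_sd, frame.shape)
            else:
                frame = img
            data[f, c] = np.clip(np.round(frame), 0, 65535).astype(np.uint16)
    acq = AcquisitionParams(
        combined_frame_time=p.frame_interval,
        exposure_per_channel=min(0.025, p.frame_interval / 2),
        n_frames=p.n_frames, pixel_size=ps,
    )
    return MovieStack(data=data, acquisition=acq)


def truth_to_tracks(truth: SimulationGroundTruth, channel: str,
                    localization_sigma: float = 0.02,
                    min_points: int = 2, seed: Optional[int] = None
                    ) -> TrackSet:
    """Idealized detection: ground-truth trajectories as a per-channel TrackSet.

    A particle appears in a channel while it carries at least one
    unbleached dye of that color; positions get iid Gaussian localization
    error of ``localization_sigma`` um.  This bypasses rendering/detection
    and is the oracle for testing the colocalization stage in isolation.
    """
    code = REF_DYE if channel == REFERENCE else PARTNER_DYE
    posarr = truth.positions if channel == REFERENCE else truth.positions_partner
    rng = np.random.default_rng(
        truth.params.seed + 2 + (0 if channel == REFERENCE else 1)
        if seed is None else seed
    )
    tracks = []
    tid = 0
    for i in range(truth.n_particles):
        lab = truth.labels[i]
        bf = truth.bleach_frames[i]
        lit_until = bf[lab == code]
        if lit_until.size == 0:
            continue
        n_vis = int(min(int(lit_until.max()), truth.params.n_frames))
        if n_vis < min_points:
            continue
        frames = np.arange(n_vis)
        xy = posarr[i, :n_vis] + rng.normal(0, localization_sigma, (n_vis, 2))
        tracks.append(Track(track_id=tid, frames=frames, xy=xy, channel=channel))
        tid += 1
    return TrackSet(tracks=tracks, channel=channel)


def ground_truth_to_dataframe(truth: SimulationGroundTruth) -> pd.DataFrame:
    """Tabular export: particle_id, frame, x_um, y_um, per-channel visibility."""
    rows = []
    for i in range(truth.n_particles):
        for f in range(truth.params.n_frames):
            rows.append(
                (i, int(truth.sizes[i]), f,
                 truth.positions[i, f, 0], truth.positions[i, f, 1],
                 truth.visible(i, REF_DYE, f), truth.visible(i, PARTNER_DYE, f))
            )
    return pd.DataFrame(
        rows, columns=["particle_id", "oligomer_size", "frame",
                       "x_um", "y_um", "visible_reference", "visible_partner"],
    )
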