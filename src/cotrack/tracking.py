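"""Spot detection and trajectory linking.

Detection uses a scale-normalized Laplacian-of-Gaussian (LoG) filter tuned
to the expected spot radius: diffraction-limited single molecules appear as
local maxima of the (sign-flipped) LoG response, refined to sub-pixel
precision with a local quadratic fit.  Quality is the raw LoG response at
the maximum; thresholds are therefore not numerically transferable from
other software that normalizes quality differently.

Linking solves frame-to-frame correspondence as a rectangular linear
assignment problem (LAP) with squared-displacement costs and birth/death
alternatives, followed by a second assignment over track-segment ends and
starts that closes short gaps — the standard two-pass LAP tracking scheme
for Brownian single particles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .io import MovieStack
from .tracks import Track, TrackSet, REFERENCE, PARTNER

__all__ = ["TrackingParams", "detect_spots", "link_spots", "track_movie"]

_BIG = 1e12


@dataclass
class TrackingParams:
    """Detector and linker settings.

    Defaults are physically motivated by the imaging regime this package
    targets: spot radius ~0.25 um (diffraction limit), maximum link
    distance 0.6 um (~4 sigma of the per-frame Brownian step at
    D = 0.18 um^2/s and 60 ms frames, so genuine steps are essentially
    never refused), and up to 2 closable gap frames.
    """

    spot_radius: float = 0.25  # um; LoG scale
    quality_threshold: float = 10.0  # LoG response units (counts)
    max_link_distance: float = 0.6  # um
    max_gap_frames: int = 2
    max_gap_distance: float = 0.9  # um

    def __post_init__(self) -> None:
        if min(self.spot_radius, self.max_link_distance,
               self.max_gap_distance) <= 0:
            raise ValueError("radii and distances must be positive")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")


def _log_response(img: np.ndarray, sigma: float) -> np.ndarray:
    """Scale-normalized, sign-flipped LoG response (bright blobs positive)."""
    return -sigma ** 2 * ndimage.gaussian_laplace(img.astype(float), sigma)


def _quadratic_offset(fm: float, f0: float, fp: float) -> float:
    """Sub-pixel peak offset from three samples of a 1-D quadratic."""
    denom = fm - 2.0 * f0 + fp
    if denom >= 0:  # not a maximum; stay on the pixel
        return 0.0
    return float(np.clip(0.5 * (fm - fp) / denom, -0.5, 0.5))


def detect_spots(movie, params: TrackingParams, channel: int = 0,
                 pixel_size: float | None = None) -> pd.DataFrame:
    """Detect sub-pixel spot positions in every frame of one channel.

    ``movie`` is a MovieStack (channel selected by index) or a (T, H, W)
    array with an explicit ``pixel_size``.  Returns a table with columns
    frame, x, y (um), quality (LoG response at the maximum), intensity
    (raw counts at the peak pixel), channel.
    """
    if isinstance(movie, MovieStack):
        stack = movie.channel(channel)
        ps = movie.acquisition.pixel_size
    else:
        stack = np.asarray(movie)
        if pixel_size is None:
            raise ValueError("pixel_size is required for raw arrays")
        ps = pixel_size
    sigma = params.spot_radius / ps / np.sqrt(2.0)  # LoG scale for radius r

    rows = []
    for f, img in enumerate(stack):
        resp = _log_response(img, sigma)
        peak = (resp == ndimage.maximum_filter(resp, size=3)) & \
               (resp > params.quality_threshold)
        peak[0, :] = peak[-1, :] = False
        peak[:, 0] = peak[:, -1] = False
        for r, c in zip(*np.nonzero(peak)):
            dx = _quadratic_offset(resp[r, c - 1], resp[r, c], resp[r, c + 1])
            dy = _quadratic_offset(resp[r - 1, c], resp[r, c], resp[r + 1, c])
            rows.append((f, (c + dx) * ps, (r + dy) * ps,
                         float(resp[r, c]), float(img[r, c])))
    df = pd.DataFrame(rows, columns=["frame", "x", "y", "quality", "intensity"])
    df["channel"] = channel
    return df


def _lap_link(cost: np.ndarray, alt_cost: float) -> list[tuple[int, int]]:
    """Solve one rectangular LAP with birth/death alternatives.

    ``cost`` is (n1, n2) with np.inf where a link is disallowed.  Returns
    the accepted (i, j) links of the augmented-square formulation in which
    every unlinked object pays ``alt_cost``.
    """
    n1, n2 = cost.shape
    blocked = ~np.isfinite(cost)
    c = np.where(blocked, _BIG, cost)
    full = np.full((n1 + n2, n1 + n2), _BIG)
    full[:n1, :n2] = c
    full[:n1, n2:] = np.where(np.eye(n1, dtype=bool), alt_cost, _BIG)
    full[n1:, :n2] = np.where(np.eye(n2, dtype=bool), alt_cost, _BIG)
    # auxiliary block: feasibility complement, free where a link is allowed
    full[n1:, n2:] = np.where(blocked.T, _BIG, 0.0)
    rows, cols = linear_sum_assignment(full)
    return [(int(r), int(cc)) for r, cc in zip(rows, cols)
            if r < n1 and cc < n2 and not blocked[r, cc]]


def link_spots(spots: pd.DataFrame, params: TrackingParams,
               channel: str = REFERENCE) -> TrackSet:
    """Link a single channel's spots into trajectories with gap closing.

    Pass 1 links spots of consecutive frames minimizing total squared
    displacement subject to ``max_link_distance`` (unlinked spots open or
    close track segments).  Pass 2 joins segment ends to segment starts
    within ``max_gap_frames`` missing frames and ``max_gap_distance``.
    Only tracks with >= 2 points are returned.  The result is independent
    of the input row order (spots are canonically sorted first).
    """
    if len(spots) == 0:
        return TrackSet(tracks=[], channel=channel)
    df = spots.sort_values(["frame", "x", "y"], kind="mergesort")
    frames = df["frame"].to_numpy(dtype=int)
    xy = df[["x", "y"]].to_numpy(dtype=float)

    segments: list[dict] = []  # {"frames": [...], "xy": [...]}
    open_segs: dict[int, tuple[int, np.ndarray]] = {}  # seg idx -> (last frame, pos)

    for f in np.unique(frames):
        idx = np.nonzero(frames == f)[0]
        cur_xy = xy[idx]
        prev = [(s, pos) for s, (lf, pos) in open_segs.items() if lf == f - 1]
        links: dict[int, int] = {}
        if prev and len(idx):
            ppos = np.array([p for _, p in prev])
            d2 = ((ppos[:, None, :] - cur_xy[None, :, :]) ** 2).sum(-1)
            cost = np.where(d2 <= params.max_link_distance ** 2, d2, np.inf)
            for i, j in _lap_link(cost, params.max_link_distance ** 2):
                links[j] = prev[i][0]
        for j, row in enumerate(idx):
            if j in links:
                s = links[j]
                segments[s]["frames"].append(int(f))
                segments[s]["xy"].append(xy[row])
            else:
                s = len(segments)
                segments.append({"frames": [int(f)], "xy": [xy[row]]})
            open_segs[s] = (int(f), xy[row])

    # gap closing: assign segment ends to later segment starts
    n_seg = len(segments)
    if n_seg > 1 and params.max_gap_frames > 0:
        ends = np.array([(s["frames"][-1], *s["xy"][-1]) for s in segments])
        starts = np.array([(s["frames"][0], *s["xy"][0]) for s in segments])
        dt = starts[None, :, 0] - ends[:, None, 0]
        d2 = ((ends[:, None, 1:] - starts[None, :, 1:]) ** 2).sum(-1)
        ok = (dt >= 2) & (dt <= params.max_gap_frames + 1) & \
             (d2 <= params.max_gap_distance ** 2)
        if ok.any():
            cost = np.where(ok, d2, np.inf)
            nxt: dict[int, int] = dict(
                _lap_link(cost, params.max_gap_distance ** 2)
            )
            merged_into = set(nxt.values())
            chains = []
            for s in range(n_seg):
                if s in merged_into:
                    continue
                chain = [s]
                while chain[-1] in nxt:
                    chain.append(nxt[chain[-1]])
                chains.append(chain)
            new_segments = []
            for chain in chains:
                seg = {"frames": [], "xy": []}
                for s in chain:
                    seg["frames"].extend(segments[s]["frames"])
                    seg["xy"].extend(segments[s]["xy"])
                new_segments.append(seg)
            segments = new_segments

    tracks = []
    tid = 0
    segments.sort(key=lambda s: (s["frames"][0], s["xy"][0][0], s["xy"][0][1]))
    for seg in segments:
        if len(seg["frames"]) < 2:
            continue
        tracks.append(Track(track_id=tid, frames=np.array(seg["frames"]),
                            xy=np.array(seg["xy"]), channel=channel))
        tid += 1
    return TrackSet(tracks=tracks, channel=channel)


def track_movie(movie: MovieStack, params: TrackingParams
                ) -> tuple[TrackSet, TrackSet]:
    """Detect and link both channels of a movie.

    Returns (reference TrackSet, partner TrackSet) for channels 0 and 1.
    """
    out = []
    for c, name in enumerate([REFERENCE, PARTNER]):
        spots = detect_spots(movie, params, channel=c)
        ts = link_spots(spots, params, channel=name)
        ts.pixel_size = movie.acquisition.pixel_size
        out.append(ts)
    return out[0], out[1]
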