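"""Apparent diffusion coefficients from single-particle tracks via MSD.

Each trajectory is broken into consecutive non-overlapping 5-frame
segments; within a segment, squared displacements from the segment's first
point are taken at lags 1-4 and averaged across segments to give the
track's MSD curve.  The curve is fitted to the 2-D Brownian law
<r^2> = 4 D t by least squares through the origin, and tracks followed for
fewer than 15 frames are excluded (too little data for a stable segment
average).

The through-origin fit means localization noise (which adds a constant
4*sigma_loc^2 offset to the MSD) inflates the fitted D rather than being
absorbed by an intercept; ``fit_diffusion(..., through_origin=False)``
exposes the free-intercept alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .tracks import Track, TrackSet

__all__ = ["MsdResult", "TrackTooShortError", "compute_msd", "fit_diffusion",
           "fit_ensemble"]


class TrackTooShortError(ValueError):
    """Track does not meet the minimum-length filter for MSD analysis."""


@dataclass
class MsdResult:
    """Per-track MSD curve and fit."""

    lags: np.ndarray  # s, strictly increasing
    msd: np.ndarray  # um^2 at each lag
    n_segments: int
    track_id: int = -1
    d_fit: Optional[float] = None  # um^2/s, filled by fit_diffusion


def compute_msd(track: Track, frame_interval: float,
                segment_length: int = 5,
                min_track_length: int = 15) -> MsdResult:
    """Segment-averaged MSD of one trajectory.

    The track is partitioned into consecutive non-overlapping
    ``segment_length``-frame segments (within gapless stretches only);
    each segment contributes squared displacements from its first point at
    lags 1..segment_length-1, and segments are averaged.  Tracks with
    fewer than ``min_track_length`` points are excluded by raising
    :class:`TrackTooShortError` — the caller decides how to report that.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    if track.n_points < min_track_length:
        raise TrackTooShortError(
            f"track {track.track_id}: {track.n_points} frames < "
            f"{min_track_length}"
        )
    n_lags = segment_length - 1
    acc = np.zeros(n_lags)
    n_segments = 0
    # gapless runs: split where consecutive frames are not adjacent
    breaks = np.nonzero(np.diff(track.frames) != 1)[0] + 1
    for run in np.split(np.arange(track.n_points), breaks):
        n_seg = run.size // segment_length
        for s in range(n_seg):
            seg = track.xy[run[s * segment_length:(s + 1) * segment_length]]
            acc += ((seg[1:] - seg[0]) ** 2).sum(axis=1)
            n_segments += 1
    if n_segments == 0:
        raise TrackTooShortError(
            f"track {track.track_id}: no gapless {segment_length}-frame "
            f"segment"
        )
    lags = np.arange(1, segment_length) * frame_interval
    return MsdResult(lags=lags, msd=acc / n_segments,
                     n_segments=n_segments, track_id=track.track_id)


def fit_diffusion(msd: MsdResult, through_origin: bool = True) -> float:
    """Fit <r^2> = 4 D t and return D in um^2/s (clipped at 0).

    Through-origin least squares gives D = sum(t*m) / (4 sum(t^2)); with
    ``through_origin=False`` an ordinary linear fit is used and D is the
    slope / 4 (the intercept then absorbs static localization error).
    """
    t, m = np.asarray(msd.lags, float), np.asarray(msd.msd, float)
    if t.size < 2:
        raise ValueError("need at least 2 lag points")
    if through_origin:
        denom = (t * t).sum()
        slope = (t * m).sum() / denom if denom > 0 else 0.0
    else:
        slope = np.polyfit(t, m, 1)[0]
    d = max(float(slope) / 4.0, 0.0)
    msd.d_fit = d
    return d


def fit_ensemble(tracks: TrackSet, frame_interval: float,
                 segment_length: int = 5, min_track_length: int = 15,
                 through_origin: bool = True) -> pd.DataFrame:
    """Per-track D table for a TrackSet; short tracks are counted, not fitted.

    Returns a DataFrame with columns track_id, d_fit, n_segments,
    n_points, excluded.
    """
    rows = []
    for t in tracks:
        try:
            res = compute_msd(t, frame_interval, segment_length,
                              min_track_length)
        except TrackTooShortError:
            rows.append((t.track_id, np.nan, 0, t.n_points, True))
            continue
        d = fit_diffusion(res, through_origin=through_origin)
        rows.append((t.track_id, d, res.n_segments, t.n_points, False))
    return pd.DataFrame(
        rows, columns=["track_id", "d_fit", "n_segments", "n_points",
                       "excluded"],
    )
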