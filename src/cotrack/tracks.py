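"""Trajectory containers shared across the pipeline.

A :class:`Track` is an ordered sequence of sub-pixel localizations of one
diffusing particle, indexed by acquisition frame.  Frames may be missing in
the middle of a track (gap-closed links); downstream code that needs gapless
data (sliding-window correlation, MSD segments) is responsible for selecting
gap-free stretches.  Coordinates are stored in physical units (micrometres),
with the pixel size recorded on the :class:`TrackSet` when known.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

REFERENCE = "reference"
PARTNER = "partner"

__all__ = ["Track", "TrackSet", "REFERENCE", "PARTNER"]


@dataclass
class Track:
    """One linked single-particle trajectory.

    Parameters
    ----------
    track_id:
        Identifier unique within a channel.
    frames:
        Strictly increasing integer frame indices (0-based).
    xy:
        ``(n, 2)`` array of (x, y) positions in micrometres, one row per
        entry of ``frames``.
    channel:
        Which acquisition channel the track belongs to
        (``"reference"``/``"partner"`` or any label).
    """

    track_id: int
    frames: np.ndarray
    xy: np.ndarray
    channel: str = REFERENCE

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.frames.ndim != 1:
            raise ValueError("frames must be 1-D")
        if self.xy.shape != (self.frames.size, 2):
            raise ValueError(
                f"xy shape {self.xy.shape} does not match {self.frames.size} frames"
            )
        if self.frames.size and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")

    def __len__(self) -> int:
        return int(self.frames.size)

    @property
    def n_points(self) -> int:
        return int(self.frames.size)

    @property
    def start_frame(self) -> int:
        return int(self.frames[0])

    @property
    def end_frame(self) -> int:
        return int(self.frames[-1])

    @property
    def span(self) -> int:
        """Number of frames from first to last detection, inclusive."""
        return self.end_frame - self.start_frame + 1

    @property
    def has_gaps(self) -> bool:
        return self.span != self.n_points

    def bounding_box(self) -> tuple[float, float, float, float]:
        """Axis-aligned bounding rectangle ``(xmin, ymin, xmax, ymax)`` in um."""
        return (
            float(self.xy[:, 0].min()),
            float(self.xy[:, 1].min()),
            float(self.xy[:, 0].max()),
            float(self.xy[:, 1].max()),
        )

    def positions_on_grid(self, first_frame: int, last_frame: int) -> np.ndarray:
        """Positions on a dense frame grid, NaN where the track has no point.

        Returns an ``(last_frame - first_frame + 1, 2)`` array.
        """
        length = last_frame - first_frame + 1
        out = np.full((length, 2), np.nan)
        sel = (self.frames >= first_frame) & (self.frames <= last_frame)
        out[self.frames[sel] - first_frame] = self.xy[sel]
        return out


@dataclass
class TrackSet:
    """All tracks from one channel of one movie/cell."""

    tracks: list[Track] = field(default_factory=list)
    channel: Optional[str] = None
    pixel_size: Optional[float] = None  # um per pixel, if known
    units: str = "um"

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    def __getitem__(self, i: int) -> Track:
        return self.tracks[i]

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table with columns particle, frame, x, y, channel."""
        if not self.tracks:
            return pd.DataFrame(columns=["particle", "frame", "x", "y", "channel"])
        parts = [
            pd.DataFrame(
                {
                    "particle": t.track_id,
                    "frame": t.frames,
                    "x": t.xy[:, 0],
                    "y": t.xy[:, 1],
                    "channel": t.channel,
                }
            )
            for t in self.tracks
        ]
        return pd.concat(parts, ignore_index=True)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        channel: Optional[str] = None,
        pixel_size: Optional[float] = None,
    ) -> "TrackSet":
        """Build a TrackSet from a (particle, frame, x, y) table."""
        tracks: list[Track] = []
        if len(df):
            for pid, grp in df.groupby("particle", sort=True):
                grp = grp.sort_values("frame")
                chan = channel
                if chan is None and "channel" in grp.columns:
                    chan = str(grp["channel"].iloc[0])
                tracks.append(
                    Track(
                        track_id=int(pid),
                        frames=grp["frame"].to_numpy(),
                        xy=grp[["x", "y"]].to_numpy(),
                        channel=chan or REFERENCE,
                    )
                )
        return cls(tracks=tracks, channel=channel, pixel_size=pixel_size)
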