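"""Readers and writers for the pipeline's standard artifacts.

* Dual-channel movies as multi-page TIFF stacks with channel-interleaved
  pages (reference frame, partner frame, reference frame, ...), the layout
  produced by sequential two-channel acquisition on a single camera.
* Per-channel track files in the TrackMate v7 XML dialect (spots keyed by
  ID with FRAME/POSITION_X/POSITION_Y, edges defining track membership) or
  as plain long-format CSV tables.
* A JSON analysis configuration holding the sliding-window parameters and
  the folder-per-condition layout of a batch run.

Frame indices are 0-based throughout (TrackMate's FRAME attribute is also
0-based and is used verbatim).  Coordinates are stored in micrometres; the
pixel size is recorded so pixel-unit files can be converted on read.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .tracks import Track, TrackSet, REFERENCE

__all__ = [
    "MovieStack",
    "AcquisitionParams",
    "AnalysisConfig",
    "FormatError",
    "read_movie",
    "write_movie",
    "read_trackmate_xml",
    "write_trackmate_xml",
    "read_tracks_csv",
    "write_tracks_csv",
    "read_config",
]


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


@dataclass
class AcquisitionParams:
    """Timing and geometry of sequential two-channel acquisition.

    The default 60 ms combined frame time splits into a 25 ms exposure per
    channel plus channel-switching overhead; ~100 combined frames per cell
    keeps the movie short enough to avoid extensive photobleaching.
    """

    combined_frame_time: float = 0.06  # s
    exposure_per_channel: float = 0.025  # s
    n_frames: int = 100
    pixel_size: float = 0.065  # um / pixel

    def __post_init__(self) -> None:
        if self.combined_frame_time < 2 * self.exposure_per_channel:
            raise ValueError(
                "combined_frame_time must cover two channel exposures"
            )
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class MovieStack:
    """Two-channel time-lapse intensity data.

    ``data`` has shape (n_frames, n_channels, height, width); channel 0 is
    the reference (JF549-like) channel, channel 1 the partner (JF646-like)
    channel.
    """

    data: np.ndarray
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("movie data must be (time, channel, row, col)")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def channel(self, c: int) -> np.ndarray:
        """(time, row, col) stack of one channel."""
        return self.data[:, c]


def write_movie(path, movie: MovieStack) -> None:
    """Write a MovieStack as a channel-interleaved multi-page TIFF."""
    t, c, h, w = movie.data.shape
    pages = movie.data.reshape(t * c, h, w)
    tifffile.imwrite(str(path), pages, metadata={"axes": "QYX"})


def read_movie(path, acquisition: Optional[AcquisitionParams] = None,
               n_channels: int = 2) -> MovieStack:
    """Read a channel-interleaved multi-page TIFF as a MovieStack.

    An explicit (T, C, Y, X) stack is accepted as-is; a flat page stack is
    de-interleaved into ``n_channels`` channels and must have a page count
    divisible by ``n_channels``.
    """
    data = tifffile.imread(str(path))
    if data.ndim == 4:
        pass
    elif data.ndim == 3:
        pages = data.shape[0]
        if pages % n_channels != 0:
            raise FormatError(
                f"{path}: {pages} pages cannot be de-interleaved into "
                f"{n_channels} channels"
            )
        data = data.reshape(pages // n_channels, n_channels, *data.shape[1:])
    else:
        raise FormatError(f"{path}: expected a 3-D or 4-D TIFF stack")
    acq = acquisition or AcquisitionParams(n_frames=data.shape[0])
    acq.n_frames = data.shape[0]
    return MovieStack(data=data, acquisition=acq)


# ---------------------------------------------------------------------------
# TrackMate-dialect XML
# ---------------------------------------------------------------------------

def write_trackmate_xml(path, trackset: TrackSet,
                        spatial_units: str = "um") -> None:
    """Write a TrackSet in the TrackMate v7 Model dialect.

    Spots are stored per frame with unique integer IDs; each track is a
    chain of edges between consecutive spots (gaps appear as edges that
    skip frames, as TrackMate's gap-closing produces).
    """
    root = ET.Element("TrackMate", version="7.0.0")
    model = ET.SubElement(root, "Model", spatialunits=spatial_units,
                          timeunits="frame")
    allspots = ET.SubElement(model, "AllSpots")
    alltracks = ET.SubElement(model, "AllTracks")
    filtered = ET.SubElement(model, "FilteredTracks")

    frames: dict[int, ET.Element] = {}
    spot_id = 0
    for track in trackset:
        ids = []
        for f, (x, y) in zip(track.frames, track.xy):
            f = int(f)
            if f not in frames:
                frames[f] = ET.SubElement(allspots, "SpotsInFrame",
                                          frame=str(f))
            ET.SubElement(
                frames[f], "Spot",
                ID=str(spot_id), name=f"ID{spot_id}",
                QUALITY="1.0", FRAME=str(f),
                POSITION_X=repr(float(x)), POSITION_Y=repr(float(y)),
                POSITION_Z="0.0", POSITION_T=repr(float(f)),
                RADIUS="0.25", VISIBILITY="1",
            )
            ids.append(spot_id)
            spot_id += 1
        tr = ET.SubElement(
            alltracks, "Track",
            TRACK_ID=str(track.track_id), name=f"Track_{track.track_id}",
            NUMBER_SPOTS=str(len(ids)),
        )
        for a, b in zip(ids[:-1], ids[1:]):
            ET.SubElement(tr, "Edge", SPOT_SOURCE_ID=str(a),
                          SPOT_TARGET_ID=str(b), LINK_COST="0.0")
        ET.SubElement(filtered, "TrackID", TRACK_ID=str(track.track_id))

    nspots = str(spot_id)
    allspots.set("nspots", nspots)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(str(path), xml_declaration=True, encoding="unicode")


def read_trackmate_xml(path, channel: Optional[str] = None,
                       pixel_size: Optional[float] = None) -> TrackSet:
    """Parse a TrackMate v7 XML file into a TrackSet.

    One Track per <Track> element; spot membership comes from the edge
    list; frames ascend and gaps are preserved.  Coordinates are kept in
    the file's spatial units.
    """
    root = ET.parse(str(path)).getroot()
    model = root.find("Model")
    if model is None:
        raise FormatError(f"{path}: no <Model> element (not TrackMate XML?)")

    spots: dict[int, tuple[int, float, float]] = {}
    allspots = model.find("AllSpots")
    if allspots is not None:
        for sif in allspots.findall("SpotsInFrame"):
            for spot in sif.findall("Spot"):
                sid = int(spot.get("ID"))
                spots[sid] = (
                    int(float(spot.get("FRAME"))),
                    float(spot.get("POSITION_X")),
                    float(spot.get("POSITION_Y")),
                )

    tracks: list[Track] = []
    alltracks = model.find("AllTracks")
    if alltracks is not None:
        for tr in alltracks.findall("Track"):
            tid = int(tr.get("TRACK_ID"))
            members: set[int] = set()
            for edge in tr.findall("Edge"):
                members.add(int(edge.get("SPOT_SOURCE_ID")))
                members.add(int(edge.get("SPOT_TARGET_ID")))
            missing = members - spots.keys()
            if missing:
                raise FormatError(
                    f"{path}: track {tid} references missing spot IDs "
                    f"{sorted(missing)}"
                )
            rows = sorted(spots[m] for m in members)
            frames = np.array([r[0] for r in rows])
            xy = np.array([[r[1], r[2]] for r in rows])
            tracks.append(Track(track_id=tid, frames=frames, xy=xy,
                                channel=channel or REFERENCE))
    units = model.get("spatialunits", "um")
    return TrackSet(tracks=tracks, channel=channel, pixel_size=pixel_size,
                    units=units)


# ---------------------------------------------------------------------------
# CSV track tables (interchange format, e.g. for state-array diffusion tools)
# ---------------------------------------------------------------------------

def write_tracks_csv(path, trackset: TrackSet) -> None:
    """Long-format CSV with columns particle, frame, x, y, channel (um)."""
    trackset.to_dataframe().to_csv(path, index=False)


def read_tracks_csv(path, channel: Optional[str] = None) -> TrackSet:
    df = pd.read_csv(path)
    required = {"particle", "frame", "x", "y"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: track CSV needs columns {sorted(required)}"
        )
    return TrackSet.from_dataframe(df, channel=channel)


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "window_length", "pcc_threshold", "window_step", "adjacency_padding",
    "conditions", "tracking", "seed", "n_bootstrap", "n_permutation",
    "reference_channel", "pixel_size",
}

_TRACKING_KEYS = {
    "spot_radius", "quality_threshold", "max_link_distance",
    "max_gap_frames", "max_gap_distance",
}


@dataclass
class AnalysisConfig:
    """Batch-analysis settings: sliding-window parameters and input layout.

    ``window_length`` (N) and ``pcc_threshold`` (T) are the two parameters
    that tune the sensitivity of the co-localizer classifier; everything
    else is plumbing (folders per condition, tracking parameters, seeds
    and resampling iteration counts).
    """

    window_length: int = 12
    pcc_threshold: float = 0.8
    window_step: int = 1
    adjacency_padding: float = 0.0
    conditions: dict[str, str] = field(default_factory=dict)
    tracking: dict = field(default_factory=dict)
    seed: int = 0
    n_bootstrap: int = 10_000
    n_permutation: int = 10_000
    reference_channel: str = REFERENCE
    pixel_size: float = 0.065

    def __post_init__(self) -> None:
        if self.window_length < 3:
            raise ValueError("window_length (N) must be >= 3")
        if not -1.0 <= self.pcc_threshold <= 1.0:
            raise ValueError("pcc_threshold (T) must lie in [-1, 1]")
        if self.window_step < 1:
            raise ValueError("window_step must be >= 1")
        unknown = set(self.tracking) - _TRACKING_KEYS
        if unknown:
            raise ValueError(f"unknown tracking keys: {sorted(unknown)}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def read_config(path) -> AnalysisConfig:
    """Load and validate a JSON analysis configuration.

    Missing keys take the documented defaults (N=12, step=1, 10,000
    bootstrap and permutation iterations); unknown keys are rejected so a
    typo cannot silently disable a setting.
    """
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config must be a JSON object")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**raw)
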