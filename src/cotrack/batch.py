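"""Folder-per-condition batch analysis.

Each condition points at a folder; each cell is one movie file (detection
and tracking are run first) or one pair of per-channel track files
(``<cell>_reference.xml|csv`` + ``<cell>_partner.xml|csv``).  The batch
runner computes per-cell co-localization results, per-condition summaries
with cell-level bootstrap CIs, and all pairwise permutation/t-test
comparisons.  All randomness derives from the single config seed through
per-task streams, so identical config + inputs reproduce the report
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .colocalize import (ColocParams, compare_conditions, find_colocalizers)
from .io import (AnalysisConfig, read_movie, read_trackmate_xml,
                 read_tracks_csv)
from .tracking import TrackingParams, track_movie
from .tracks import PARTNER, REFERENCE, TrackSet

__all__ = ["BatchReport", "run_batch"]

_MOVIE_SUFFIXES = {".tif", ".tiff"}
_TRACK_SUFFIXES = {".xml", ".csv"}


@dataclass
class BatchReport:
    """Everything one batch run produced."""

    cells: pd.DataFrame  # one row per cell
    condition_summaries: pd.DataFrame
    comparisons: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(out / "per_cell.csv", index=False,
                          float_format="%.6f")
        self.condition_summaries.to_csv(out / "condition_summaries.csv",
                                        index=False, float_format="%.6f")
        self.comparisons.to_csv(out / "comparisons.csv", index=False,
                                float_format="%.6g")
        with open(out / "summary.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2, sort_keys=True)
        with open(out / "log.txt", "w") as fh:
            for line in self.warnings:
                fh.write(line + "\n")


def _collect_cells(folder: Path) -> list[tuple[str, dict]]:
    """Group a condition folder into per-cell inputs.

    Returns (cell_id, spec) where spec is {"movie": path} or
    {"reference": path, "partner": path}.  Mixing movies and track files
    in one folder is a configuration error.
    """
    movies = sorted(p for p in folder.iterdir()
                    if p.suffix.lower() in _MOVIE_SUFFIXES)
    trackfiles = sorted(p for p in folder.iterdir()
                        if p.suffix.lower() in _TRACK_SUFFIXES)
    if movies and trackfiles:
        raise ValueError(
            f"{folder}: contains both movies and track files; one input "
            f"type per folder"
        )
    if movies:
        return [(p.stem, {"movie": p}) for p in movies]
    cells: dict[str, dict] = {}
    for p in trackfiles:
        stem = p.stem
        for suffix, chan in (("_reference", REFERENCE), ("_partner", PARTNER)):
            if stem.endswith(suffix):
                cells.setdefault(stem[: -len(suffix)], {})[chan] = p
                break
        else:
            raise ValueError(
                f"{p}: track files must end in _reference or _partner"
            )
    if not cells:
        raise ValueError(f"{folder}: no movies or track files found")
    for cid, spec in cells.items():
        if set(spec) != {REFERENCE, PARTNER}:
            raise ValueError(
                f"{folder}/{cid}: need both _reference and _partner files"
            )
    return sorted(cells.items())


def _load_trackset(path: Path, channel: str) -> TrackSet:
    if path.suffix.lower() == ".xml":
        return read_trackmate_xml(path, channel=channel)
    return read_tracks_csv(path, channel=channel)


def run_batch(config: AnalysisConfig) -> BatchReport:
    """Run the full per-condition analysis described by ``config``.

    Per-cell identity is one movie (or track-file pair).  Cells with zero
    eligible reference tracks are reported but excluded from condition
    means and comparisons.
    """
    if not config.conditions:
        raise ValueError("config.conditions is empty")
    coloc_params = ColocParams(
        window_length=config.window_length,
        window_step=config.window_step,
        pcc_threshold=config.pcc_threshold,
        adjacency_padding=config.adjacency_padding,
    )
    tracking_params = TrackingParams(**config.tracking)
    warnings: list[str] = []
    rows = []

    for ci, (cond, folder) in enumerate(sorted(config.conditions.items())):
        folder = Path(folder)
        if not folder.is_dir():
            raise ValueError(f"condition {cond}: folder {folder} not found")
        for cj, (cell_id, spec) in enumerate(_collect_cells(folder)):
            rng = np.random.default_rng([config.seed, ci, cj])
            try:
                if "movie" in spec:
                    movie = read_movie(spec["movie"])
                    movie.acquisition.pixel_size = config.pixel_size
                    ref, par = track_movie(movie, tracking_params)
                else:
                    ref = _load_trackset(spec[REFERENCE], REFERENCE)
                    par = _load_trackset(spec[PARTNER], PARTNER)
            except Exception as exc:  # unreadable input: log and skip
                warnings.append(f"SKIP {cond}/{cell_id}: {exc}")
                continue
            res, _ = find_colocalizers(
                ref, par, coloc_params, n_bootstrap=config.n_bootstrap,
                rng=rng, cell_id=cell_id,
            )
            rows.append({
                "condition": cond, "cell_id": cell_id,
                "n_total": res.n_ref_total,
                "n_corr": res.n_ref_correlated,
                "percent": res.percent_correlated,
                "ci_low": res.ci95[0], "ci_high": res.ci95[1],
                "f_obs": res.f_obs,
            })
            warnings.append(f"OK   {cond}/{cell_id}: "
                            f"{res.n_ref_correlated}/{res.n_ref_total}")

    cells = pd.DataFrame(rows)
    summaries, comparisons = _aggregate(cells, config)
    meta = {
        "seed": config.seed,
        "version": __version__,
        "config_hash": hashlib.sha256(
            config.to_json().encode()).hexdigest()[:16],
        "n_cells": int(len(cells)),
        "n_warnings": sum(1 for w in warnings if w.startswith("SKIP")),
    }
    return BatchReport(cells=cells, condition_summaries=summaries,
                       comparisons=comparisons, metadata=meta,
                       warnings=warnings)


def _aggregate(cells: pd.DataFrame, config: AnalysisConfig
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Condition summaries (cell-level bootstrap CI) and pairwise tests."""
    sum_rows, cmp_rows = [], []
    conds = sorted(config.conditions)
    usable: dict[str, np.ndarray] = {}
    for k, cond in enumerate(conds):
        sub = cells[(cells["condition"] == cond) & (cells["n_total"] > 0)] \
            if len(cells) else cells
        pct = sub["percent"].to_numpy() if len(sub) else np.zeros(0)
        usable[cond] = pct
        rng = np.random.default_rng([config.seed, 10_000, k])
        if pct.size:
            boots = pct[rng.integers(0, pct.size,
                                     (config.n_bootstrap, pct.size))].mean(1)
            lo, hi = np.percentile(boots, [2.5, 97.5])
            sum_rows.append((cond, pct.size, pct.mean(), lo, hi))
        else:
            sum_rows.append((cond, 0, np.nan, np.nan, np.nan))
    for i, ca in enumerate(conds):
        for j in range(i + 1, len(conds)):
            cb = conds[j]
            a, b = usable[ca], usable[cb]
            if a.size >= 2 and b.size >= 2:
                rng = np.random.default_rng([config.seed, 20_000, i, j])
                cmp_ = compare_conditions(a, b, n_perm=config.n_permutation,
                                          rng=rng, name_a=ca, name_b=cb)
                cmp_rows.append((ca, cb, cmp_.mean_a, cmp_.mean_b,
                                 cmp_.mean_difference, cmp_.p_permutation,
                                 cmp_.p_ttest))
            else:
                cmp_rows.append((ca, cb, np.nan, np.nan, np.nan,
                                 np.nan, np.nan))
    summaries = pd.DataFrame(
        sum_rows, columns=["condition", "n_cells", "mean_percent",
                           "ci_low", "ci_high"])
    comparisons = pd.DataFrame(
        cmp_rows, columns=["condition_a", "condition_b", "mean_a", "mean_b",
                           "mean_difference", "p_permutation", "p_ttest"])
    return summaries, comparisons
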