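"""Sliding-window correlation analysis of two-color trajectory pairs.

Two molecules bound in one complex diffuse together, so their trajectories
are near-identical up to localization noise; two independent molecules
merely wander.  The classifier slides a window of N frames along every
pair of spatially adjacent reference/partner tracks and computes Pearson
correlation coefficients (PCC) separately for the x- and y-coordinate
sequences inside the window.  A reference-channel track is a
*co-localizer* when all of the following hold for at least one partner
track:

1. the pair shares at least one window of N consecutive frames in which
   both tracks have a position in every frame;
2. at least one such window has PCC > T on both axes;
3. the tracks at least partially overlap in space (bounding-box
   adjacency).

The per-cell statistic is

    % correlated trajectories = 100 * n_ref_corr / n_ref_total,

where n_ref_total counts reference-channel tracks spanning at least N
frames.  Because reference-only clusters enter that denominator while
partner-only clusters do not, this percentage is *not* the model quantity
F_obs (fraction of all visible clusters carrying both colors); the result
object exposes both, and the stoichiometry inversion consumes F_obs.

Windowing makes the comparison robust to unequal track durations and to
trajectories crossing: only N-frame stretches where both particles were
continuously followed are ever compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .tracks import Track, TrackSet

__all__ = [
    "ColocParams",
    "WindowCorrelation",
    "CellColocResult",
    "ConditionComparison",
    "windows_of",
    "pcc_xy",
    "is_adjacent",
    "find_colocalizers",
    "calibrate_threshold",
    "bootstrap_ci",
    "compare_conditions",
]


@dataclass
class ColocParams:
    """Sensitivity parameters of the co-localizer classifier.

    ``window_length`` (N) and ``pcc_threshold`` (T) are the only two knobs
    that tune sensitivity; 12 (or 14) frames and a threshold around 0.8
    separate co-diffusing pairs from the correlation floor of independent
    Brownian walkers.
    """

    window_length: int = 12
    window_step: int = 1
    pcc_threshold: float = 0.8
    adjacency_padding: float = 0.0  # um

    def __post_init__(self) -> None:
        if self.window_length < 3:
            raise ValueError("window_length (N) must be >= 3")
        if not -1.0 <= self.pcc_threshold <= 1.0:
            raise ValueError("pcc_threshold (T) must lie in [-1, 1]")
        if self.window_step < 1:
            raise ValueError("window_step must be >= 1")


@dataclass
class WindowCorrelation:
    """PCC of one track pair in one fully-defined window."""

    ref_track_id: int
    partner_track_id: int
    window_start: int  # absolute frame index
    pcc_x: float  # NaN when undefined (zero variance)
    pcc_y: float


@dataclass
class CellColocResult:
    """Per-cell co-localization outcome.

    ``percent_correlated`` is the plotted statistic (reference-channel
    denominator).  ``f_obs`` estimates the fraction of *visible* clusters
    (either color) that co-localize — the quantity the stoichiometry model
    inverts — as n_corr / (n_ref + n_partner - n_corr), counting each
    correlated pair once.
    """

    n_ref_total: int
    n_ref_correlated: int
    n_partner_total: int = 0
    percent_correlated: float = np.nan
    ci95: tuple[float, float] = (np.nan, np.nan)
    flags: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    cell_id: str = ""

    @property
    def f_obs(self) -> float:
        denom = self.n_ref_total + self.n_partner_total - self.n_ref_correlated
        return self.n_ref_correlated / denom if denom > 0 else np.nan


@dataclass
class ConditionComparison:
    """Pairwise comparison of per-cell percentages between two conditions."""

    name_a: str
    name_b: str
    mean_a: float
    mean_b: float
    mean_difference: float
    p_permutation: float
    p_ttest: float
    n_cells_a: int
    n_cells_b: int


def windows_of(track: Track, window_length: int, step: int = 1) -> np.ndarray:
    """Start frames of every fully-defined window of a track.

    A window is fully defined when the track has a position in each of the
    ``window_length`` consecutive frames.  Tracks spanning fewer frames
    than the window yield no windows.  Returns absolute frame indices.
    """
    n = window_length
    if track.span < n:
        return np.zeros(0, dtype=int)
    present = np.zeros(track.span, dtype=bool)
    present[track.frames - track.start_frame] = True
    full = sliding_window_view(present, n).all(axis=1)
    starts = np.nonzero(full)[0]
    if step > 1:
        starts = starts[starts % step == 0]
    return starts + track.start_frame


def pcc_xy(ref_window: np.ndarray, partner_window: np.ndarray
           ) -> tuple[float, float]:
    """Pearson correlations of the x- and y-coordinate sequences.

    Inputs are (N, 2) position arrays covering the same frames.  An axis
    with zero variance in either track makes that axis's PCC undefined
    (NaN) — a stationary spot carries no co-diffusion evidence.
    """
    a = np.asarray(ref_window, float)
    b = np.asarray(partner_window, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 2:
        raise ValueError("windows must be equal-shape (N, 2) arrays")
    out = []
    for ax in (0, 1):
        x, y = a[:, ax], b[:, ax]
        sx, sy = x.std(), y.std()
        if sx == 0.0 or sy == 0.0:
            out.append(np.nan)
        else:
            out.append(float(np.corrcoef(x, y)[0, 1]))
    return out[0], out[1]


def is_adjacent(ref: Track, partner: Track, padding: float = 0.0) -> bool:
    """Spatial-overlap gate: do the tracks' bounding boxes touch?

    True iff at least one partner point lies inside the reference track's
    bounding rectangle expanded by ``padding`` (inclusive), or vice versa
    (symmetrized).
    """
    for a, b in ((ref, partner), (partner, ref)):
        x0, y0, x1, y1 = a.bounding_box()
        inside = (
            (b.xy[:, 0] >= x0 - padding) & (b.xy[:, 0] <= x1 + padding)
            & (b.xy[:, 1] >= y0 - padding) & (b.xy[:, 1] <= y1 + padding)
        )
        if inside.any():
            return True
    return False


def _sliding_pcc_grid(a: np.ndarray, b: np.ndarray, n: int, step: int
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Window PCCs for two NaN-padded position grids of equal length.

    Returns (relative start indices, pcc_x, pcc_y) for every fully-defined
    window; undefined (zero-variance) axes give NaN.
    """
    L = a.shape[0]
    if L < n:
        return np.zeros(0, int), np.zeros(0), np.zeros(0)
    valid = np.isfinite(a[:, 0]) & np.isfinite(b[:, 0])
    full = sliding_window_view(valid, n).all(axis=1)
    starts = np.nonzero(full)[0]
    starts = starts[starts % step == 0] if step > 1 else starts
    if starts.size == 0:
        return starts, np.zeros(0), np.zeros(0)
    pcc = np.empty((2, starts.size))
    a0 = np.nan_to_num(a)
    b0 = np.nan_to_num(b)
    for axi in (0, 1):
        wa = sliding_window_view(a0[:, axi], n)[starts]
        wb = sliding_window_view(b0[:, axi], n)[starts]
        wa = wa - wa.mean(axis=1, keepdims=True)
        wb = wb - wb.mean(axis=1, keepdims=True)
        va = (wa * wa).sum(axis=1)
        vb = (wb * wb).sum(axis=1)
        cov = (wa * wb).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov / np.sqrt(va * vb)
        r[(va == 0) | (vb == 0)] = np.nan
        pcc[axi] = r
    return starts, pcc[0], pcc[1]


def find_colocalizers(
    ref_tracks: TrackSet,
    partner_tracks: TrackSet,
    params: Optional[ColocParams] = None,
    n_bootstrap: int = 10_000,
    rng: Optional[np.random.Generator] = None,
    record_windows: bool = False,
    cell_id: str = "",
) -> tuple[CellColocResult, list[WindowCorrelation]]:
    """Classify every eligible reference track as co-localizer or not.

    A reference track counts (at most once) as a co-localizer when some
    adjacent partner track shares at least one fully-defined window with
    PCC > T on both axes.  Eligible tracks span >= N frames.  The 95% CI
    on the percentage is a percentile bootstrap over per-track flags.

    With ``record_windows=True`` every evaluated window's PCC pair is
    returned (can be large); otherwise the list holds only the windows
    that triggered a classification.
    """
    params = params or ColocParams()
    rng = rng or np.random.default_rng(0)
    n, step, T = params.window_length, params.window_step, params.pcc_threshold

    eligible = [t for t in ref_tracks if t.span >= n]
    partner_eligible = [t for t in partner_tracks if t.span >= n]
    flags = np.zeros(len(eligible), dtype=bool)
    detail: list[WindowCorrelation] = []

    # bounding-box intersection is necessary for adjacency: cheap prefilter
    pboxes = np.array([t.bounding_box() for t in partner_eligible]) \
        if partner_eligible else np.zeros((0, 4))
    pad = params.adjacency_padding

    for i, rt in enumerate(eligible):
        if windows_of(rt, n, step).size == 0:
            continue
        x0, y0, x1, y1 = rt.bounding_box()
        cand = np.nonzero(
            (pboxes[:, 0] <= x1 + pad) & (pboxes[:, 2] >= x0 - pad)
            & (pboxes[:, 1] <= y1 + pad) & (pboxes[:, 3] >= y0 - pad)
        )[0] if len(partner_eligible) else []
        for ci_ in cand:
            pt = partner_eligible[int(ci_)]
            if not is_adjacent(rt, pt, pad):
                continue
            f0 = max(rt.start_frame, pt.start_frame)
            f1 = min(rt.end_frame, pt.end_frame)
            if f1 - f0 + 1 < n:
                continue
            a = rt.positions_on_grid(f0, f1)
            b = pt.positions_on_grid(f0, f1)
            starts, px, py = _sliding_pcc_grid(a, b, n, step)
            hit = (px > T) & (py > T)  # NaN (undefined) never passes
            if record_windows:
                detail.extend(
                    WindowCorrelation(rt.track_id, pt.track_id,
                                      int(s + f0), float(x), float(y))
                    for s, x, y in zip(starts, px, py)
                )
            elif hit.any():
                k = int(np.argmax(hit))
                detail.append(
                    WindowCorrelation(rt.track_id, pt.track_id,
                                      int(starts[k] + f0),
                                      float(px[k]), float(py[k]))
                )
            if hit.any():
                flags[i] = True
                if not record_windows:
                    break
        # with record_windows we keep scanning to log all pairs

    n_total = len(eligible)
    n_corr = int(flags.sum())
    if n_total > 0:
        percent = 100.0 * n_corr / n_total
        ci = bootstrap_ci(flags, n_boot=n_bootstrap, rng=rng) \
            if n_bootstrap else (np.nan, np.nan)
    else:
        percent, ci = np.nan, (np.nan, np.nan)
    result = CellColocResult(
        n_ref_total=n_total, n_ref_correlated=n_corr,
        n_partner_total=len(partner_eligible),
        percent_correlated=percent, ci95=ci, flags=flags, cell_id=cell_id,
    )
    return result, detail


def calibrate_threshold(
    dimer_cells: Sequence[tuple[TrackSet, TrackSet]],
    monomer_cells: Sequence[tuple[TrackSet, TrackSet]],
    grid: Sequence[float] = (0.7, 0.75, 0.8, 0.85, 0.9, 0.95),
    params: Optional[ColocParams] = None,
) -> tuple[float, np.ndarray]:
    """Pick the PCC threshold maximizing dimer-minus-monomer separation.

    The threshold T is an empirical operating point; this reproduces the
    tuning procedure on simulated (or measured) constitutive dimer and
    monomer control cells, each given as (reference, partner) TrackSet
    pairs.  Returns the winning T (smallest T on the plateau of maximal
    separation, to minimize attenuation of true co-localizers) and the
    (T, dimer %, monomer %) table.
    """
    base = params or ColocParams()
    rows = []
    for t in grid:
        p = ColocParams(window_length=base.window_length,
                        window_step=base.window_step, pcc_threshold=t,
                        adjacency_padding=base.adjacency_padding)
        means = []
        for cells in (dimer_cells, monomer_cells):
            nc = nt = 0
            for ref, par in cells:
                res, _ = find_colocalizers(ref, par, p, n_bootstrap=0)
                nc += res.n_ref_correlated
                nt += res.n_ref_total
            means.append(100.0 * nc / nt if nt else np.nan)
        rows.append((t, means[0], means[1]))
    table = np.array(rows)
    sep = table[:, 1] - table[:, 2]
    best = sep.max()
    winner = float(table[np.nonzero(sep >= best - 0.5)[0][0], 0])
    return winner, table


def bootstrap_ci(flags: Sequence[bool], n_boot: int = 10_000,
                 level: float = 95.0,
                 rng: Optional[np.random.Generator] = None
                 ) -> tuple[float, float]:
    """Percentile-bootstrap CI of the per-cell percentage.

    Resamples the per-track co-localizer flags with replacement.
    """
    flags = np.asarray(flags, dtype=float)
    if flags.size == 0:
        raise ValueError("cannot bootstrap an empty flag list")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = rng or np.random.default_rng(0)
    idx = rng.integers(0, flags.size, size=(n_boot, flags.size))
    percents = 100.0 * flags[idx].mean(axis=1)
    alpha = (100.0 - level) / 2.0
    lo, hi = np.percentile(percents, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


def compare_conditions(cells_a: Sequence[float], cells_b: Sequence[float],
                       n_perm: int = 10_000,
                       rng: Optional[np.random.Generator] = None,
                       name_a: str = "A", name_b: str = "B"
                       ) -> ConditionComparison:
    """Two-sided tests on per-cell percentages of two conditions.

    The approximate permutation test shuffles cell labels ``n_perm`` times;
    p = (1 + #{|mean diff permuted| >= |observed|}) / (n_perm + 1), so the
    smallest attainable p is 1/(n_perm + 1).  A two-sample two-tailed
    t-test is reported alongside.
    """
    a = np.asarray(cells_a, float)
    b = np.asarray(cells_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 cells per condition")
    rng = rng or np.random.default_rng(0)
    obs = a.mean() - b.mean()
    pool = np.concatenate([a, b])
    count = 0
    chunk = max(1, min(n_perm, 200_000 // max(pool.size, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm = rng.permuted(np.tile(pool, (m, 1)), axis=1)
        diffs = perm[:, : a.size].mean(axis=1) - perm[:, a.size:].mean(axis=1)
        count += int(np.sum(np.abs(diffs) >= np.abs(obs)))
        done += m
    p_perm = (1 + count) / (n_perm + 1)
    p_t = float(stats.ttest_ind(a, b).pvalue)
    return ConditionComparison(
        name_a=name_a, name_b=name_b,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        mean_difference=float(obs),
        p_permutation=float(p_perm), p_ttest=p_t,
        n_cells_a=int(a.size), n_cells_b=int(b.size),
    )
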