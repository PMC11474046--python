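"""Growth-rate estimation and cell-cycle alignment.

The quantities computed here follow the standard single-cell timelapse
conventions for rod-shaped bacteria:

* the **average growth rate** of a cell cycle, ``lambda = ln(A_d/A_b) / dt``,
  where ``A_b`` and ``A_d`` are the cell areas at birth and division and
  ``dt`` the interdivision time (min);
* the **instantaneous relative growth rate**,
  ``r_i = (A_{i+1} - A_i) / (A_i * frame_interval)`` (min^-1), computed on
  areas smoothed with a centred sliding-average window;
* an **exponential-fit residual score** quantifying how far a trajectory
  departs from single-exponential growth;
* per-cell curves resampled onto **cell-cycle units** (0 at birth, 1 at
  division) and population summaries (bootstrap mean curve, tempogram,
  grouping by G1 duration).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .lineage import BirthDefinition, CellTrack

__all__ = [
    "AlignedPopulation",
    "GrowthProfile",
    "align_cell_cycle",
    "average_growth_rate",
    "bin_by_g1",
    "bin_by_quantiles",
    "compute_profile",
    "exp_fit_residuals",
    "instantaneous_growth_rate",
    "population_mean_curve",
    "smooth_area",
    "tempogram",
]


def smooth_area(areas: Sequence[float], window: int = 12) -> np.ndarray:
    """Centred sliding-average smoothing with symmetric shrinkage at the edges.

    Interior points average over ``2*(window//2) + 1`` frames; near the
    boundaries the half-width shrinks to what is available on both sides, so
    the first and last points are returned unchanged.  Output length equals
    input length.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    a = np.asarray(areas, dtype=float)
    if a.ndim != 1 or len(a) < 2:
        raise ValueError("need a 1-D series with at least 2 frames")
    n = len(a)
    h = window // 2
    idx = np.arange(n)
    k = np.minimum(np.minimum(idx, n - 1 - idx), h)
    csum = np.concatenate([[0.0], np.cumsum(a)])
    lo = idx - k
    hi = idx + k
    return (csum[hi + 1] - csum[lo]) / (2 * k + 1)


def instantaneous_growth_rate(smoothed: Sequence[float], frame_interval: float) -> np.ndarray:
    """Per-step relative growth rate in min^-1.

    ``r_i = (A_{i+1} - A_i) / (A_i * frame_interval)``, normalising the
    absolute increment by the area of the first frame of each pair.
    """
    a = np.asarray(smoothed, dtype=float)
    if len(a) < 2:
        raise ValueError("need at least 2 frames")
    if np.any(a <= 0):
        raise ValueError("areas must be positive")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    return np.diff(a) / (a[:-1] * frame_interval)


def average_growth_rate(A_b: float, A_d: float, dt: float) -> float:
    """Whole-cycle growth rate ``ln(A_d / A_b) / dt`` (min^-1)."""
    if A_b <= 0 or A_d <= 0 or dt <= 0:
        raise ValueError("A_b, A_d and dt must all be positive")
    return float(np.log(A_d / A_b) / dt)


def exp_fit_residuals(areas: Sequence[float], times: Sequence[float]) -> float:
    """Mean area-normalised absolute residual to the best single-exponential fit.

    A first-degree polynomial is fit to ln(area) versus time; the residual at
    each frame is ``area - exp(fit)`` and the score is the mean of
    ``|residual| / area``.  Exponential trajectories score 0.
    """
    a = np.asarray(areas, dtype=float)
    t = np.asarray(times, dtype=float)
    if len(a) < 3:
        raise ValueError("need at least 3 frames")
    if np.any(a <= 0):
        raise ValueError("areas must be positive")
    if np.ptp(t) == 0:
        raise ValueError("degenerate time axis")
    slope, intercept = np.polyfit(t, np.log(a), 1)
    fit = np.exp(intercept + slope * t)
    return float(np.mean(np.abs(a - fit) / a))


def align_cell_cycle(
    inst_rate: Sequence[float],
    step_times: Sequence[float],
    t_birth: float,
    t_division: float,
    n_bins: int = 30,
) -> np.ndarray:
    """Bin per-step rates onto normalised cell-cycle units in [0, 1].

    ``step_times`` are the midpoint times of the inter-frame steps.  Each
    step maps to ``(t_mid - t_birth) / (t_division - t_birth)`` and rates are
    averaged within ``n_bins`` equal-width bins; empty bins are NaN.
    """
    if t_division <= t_birth:
        raise ValueError("zero-length cell cycle")
    r = np.asarray(inst_rate, dtype=float)
    t = np.asarray(step_times, dtype=float)
    if len(r) != len(t):
        raise ValueError("inst_rate and step_times must have equal length")
    cc = (t - t_birth) / (t_division - t_birth)
    keep = (cc >= 0.0) & (cc <= 1.0)
    cc, r = cc[keep], r[keep]
    bins = np.minimum((cc * n_bins).astype(int), n_bins - 1)
    out = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = bins == b
        if np.any(sel):
            out[b] = r[sel].mean()
    return out


@dataclass
class GrowthProfile:
    """Per-cell derived growth quantities under one birth definition."""

    cell_id: str
    smoothed_area: np.ndarray        # full-track smoothed areas
    inst_rate: np.ndarray            # per-step rates on the full track
    step_times: np.ndarray           # midpoint times of the steps (min)
    avg_rate: float | None           # ln(A_d/A_b)/dt for the active cycle
    residual_score: float | None
    cc_units: np.ndarray             # cc position of each in-cycle step
    aligned: np.ndarray              # (n_bins,) binned rate, NaN where empty
    interdivision_min: float | None
    birth_definition: BirthDefinition | None


def compute_profile(
    track: CellTrack,
    smooth_window: int = 12,
    n_bins: int = 30,
) -> GrowthProfile:
    """Smooth, differentiate and align one track (birth already assigned).

    Smoothing and instantaneous rates are computed over the cell's full mask
    trajectory; average rate, residuals and cell-cycle alignment are
    restricted to the active cycle window set by ``assign_birth``.
    """
    smoothed = smooth_area(track.areas, smooth_window)
    interval = float(np.median(np.diff(track.times)))
    inst = instantaneous_growth_rate(smoothed, interval)
    step_times = 0.5 * (track.times[:-1] + track.times[1:])

    avg = resid = None
    aligned = np.full(n_bins, np.nan)
    cc = np.array([])
    if not track.incomplete and track.active_birth_frame is not None:
        t_birth = track.time_at(track.active_birth_frame)
        t_div = t_birth + float(track.interdivision_min)
        if track.A_b and track.A_d and track.interdivision_min:
            avg = average_growth_rate(track.A_b, track.A_d, track.interdivision_min)
        in_cycle = (track.times >= t_birth) & (track.times <= t_div)
        if np.count_nonzero(in_cycle) >= 3:
            resid = exp_fit_residuals(track.areas[in_cycle], track.times[in_cycle])
        aligned = align_cell_cycle(inst, step_times, t_birth, t_div, n_bins)
        cc = (step_times - t_birth) / (t_div - t_birth)
        cc = cc[(cc >= 0) & (cc <= 1)]

    return GrowthProfile(
        cell_id=track.cell_id,
        smoothed_area=smoothed,
        inst_rate=inst,
        step_times=step_times,
        avg_rate=avg,
        residual_score=resid,
        cc_units=cc,
        aligned=aligned,
        interdivision_min=track.interdivision_min,
        birth_definition=track.birth_definition,
    )


@dataclass
class AlignedPopulation:
    """Binned population mean growth-rate curve with bootstrap confidence band."""

    bin_centers: np.ndarray
    mean_rate: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    boot_se: np.ndarray
    n_cells: int
    n_contributing: np.ndarray       # cells contributing per bin
    tempogram: np.ndarray | None = None
    sort_key: np.ndarray | None = None


def population_mean_curve(
    aligned_vectors: Sequence[np.ndarray],
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> AlignedPopulation:
    """Per-bin mean over cells with a percentile bootstrap CI of the mean.

    Cells (not bins) are resampled, preserving within-cell correlation
    across the cycle.  Bins with fewer than two contributing cells get NaN
    confidence limits.
    """
    mat = np.asarray(aligned_vectors, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("need aligned vectors from at least 2 cells")
    n_cells, n_bins = mat.shape
    contributing = np.sum(~np.isnan(mat), axis=0)
    mean = np.full(n_bins, np.nan)
    ok = contributing > 0
    with np.errstate(invalid="ignore"):
        mean[ok] = np.nanmean(mat[:, ok], axis=0)

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, n_bins))
    for b in range(n_boot):
        idx = rng.integers(0, n_cells, n_cells)
        with np.errstate(invalid="ignore"):
            boot[b] = np.nanmean(mat[idx], axis=0)
    lo = np.nanpercentile(boot, 100 * alpha / 2, axis=0)
    hi = np.nanpercentile(boot, 100 * (1 - alpha / 2), axis=0)
    se = np.nanstd(boot, axis=0, ddof=1)
    thin = contributing < 2
    lo[thin] = hi[thin] = se[thin] = np.nan

    centers = (np.arange(n_bins) + 0.5) / n_bins
    return AlignedPopulation(
        bin_centers=centers,
        mean_rate=mean,
        ci_low=lo,
        ci_high=hi,
        boot_se=se,
        n_cells=n_cells,
        n_contributing=contributing,
    )


def tempogram(
    aligned_vectors: Sequence[np.ndarray],
    interdivision_times: Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Cells-by-bins rate matrix with rows sorted by ascending interdivision time.

    Returns ``(matrix, order)`` where ``order`` indexes the input cells from
    shortest (top row) to longest (bottom row) interdivision time.
    """
    mat = np.asarray(aligned_vectors, dtype=float)
    dt = np.asarray(interdivision_times, dtype=float)
    if mat.shape[0] != len(dt):
        raise ValueError("one interdivision time per cell required")
    order = np.argsort(dt, kind="stable")
    return mat[order], order


def bin_by_g1(
    durations: Sequence[float],
    edges: Sequence[tuple[float, float]],
) -> tuple[list[list[int]], list[int]]:
    """Assign cells to G1-duration intervals ``[lo, hi)`` (last interval ``[lo, hi]``).

    Returns ``(groups, excluded)`` as lists of indices into ``durations``.
    Overlapping intervals raise ValueError; cells falling in no interval are
    excluded.
    """
    iv = sorted((float(lo), float(hi)) for lo, hi in edges)
    for (lo1, hi1), (lo2, _) in zip(iv, iv[1:]):
        if lo2 < hi1:
            raise ValueError(f"overlapping intervals ({lo1}, {hi1}) and starting at {lo2}")
    order = {tuple(e): i for i, e in enumerate((float(lo), float(hi)) for lo, hi in edges)}
    groups: list[list[int]] = [[] for _ in edges]
    excluded: list[int] = []
    last = iv[-1]
    for i, d in enumerate(durations):
        d = float(d)
        for e in iv:
            lo, hi = e
            if (lo <= d < hi) or (e == last and d == hi):
                groups[order[e]].append(i)
                break
        else:
            excluded.append(i)
    return groups, excluded


def bin_by_quantiles(durations: Sequence[float], n_groups: int = 3) -> list[list[int]]:
    """Rank-split cells into ``n_groups`` near-equal groups by G1 duration."""
    d = np.asarray(durations, dtype=float)
    order = np.argsort(d, kind="stable")
    return [list(chunk) for chunk in np.array_split(order, n_groups)]
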