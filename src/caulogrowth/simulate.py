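"""Ground-truthed synthetic timelapse generator.

Emulates the statistical structure of soft-agarose timelapse data on an
asymmetrically dividing bacterium:

* each division produces a smaller motile (swarmer-like) and a larger
  sessile (stalked-like) daughter, with a configurable birth-area split;
* every cell experiences a G1-coupled growth-rate dip: the relative growth
  rate declines linearly from its baseline at birth to a trough at the end
  of G1, then recovers linearly to baseline;
* G1 durations are gamma-distributed with a type-specific mean (long for
  swarmer-like, short for stalked-like progenies);
* cytokinesis (mask split) precedes visible daughter separation by a
  truncated-normal offset, so the two birth definitions disagree;
* phase-derived areas are sampled every 1.5 min with multiplicative
  lognormal measurement noise, fluorescence every 3 min.

Everything is reproducible from a single integer seed, and every cell's
generative truth is recorded so each downstream stage can be tested by
parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .foci import FociTrack, Focus

__all__ = [
    "CellGeometry",
    "RenderParams",
    "SimParams",
    "TrueCell",
    "growth_rate_profile",
    "rate_time_integral",
    "render_cell_frame",
    "render_frame",
    "rod_length",
    "simulate_foci_track",
    "simulate_lineage",
    "truth_table",
]

_EPS = 1e-9


@dataclass(frozen=True)
class SimParams:
    """Generative parameters; defaults are the nutrient-replete study conditions."""

    baseline_rate: float = 0.006          # mu0, relative growth rate (min^-1)
    dip_depth: float = 0.4                # d in [0, 1): trough is mu0 * (1 - d)
    recovery_width: float = 30.0          # w (min): trough -> baseline ramp
    trough_offset: float = 0.0            # min, trough position relative to G1 end
    g1_mean_swarmer: float = 40.0         # mean G1* duration (min)
    g1_mean_stalked: float = 12.0
    g1_dispersion: float = 0.5            # CV of the gamma G1 distribution
    division_ratio: float = 0.45          # swarmer birth-area fraction s
    sep_offset_mean: float = 18.0         # cytokinesis -> separation delay (min)
    sep_offset_sd: float = 5.0
    frame_interval_phase: float = 1.5     # min
    frame_interval_fluor: float = 3.0     # min
    area_noise_cv: float = 0.005          # multiplicative per-frame area noise
    rate_cv: float = 0.10                 # cell-to-cell baseline-rate CV
    interdivision_mean: float = 120.0     # min
    interdivision_sd: float = 15.0
    founder_area: float = 1.8             # um^2
    cell_width: float = 0.7               # um, rod width for geometry
    stalk_visibility: float = 0.9         # P(stalk visible) on stalked progenies
    swarmer_motion_um: float = 3.0        # mean net swim-away displacement
    focus_initial_sep: float = 0.5        # um between foci when duplication is called
    focus_seg_speed: float = 0.15         # um/min origin segregation speed
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dip_depth < 1:
            raise ValueError("dip_depth must be in [0, 1)")
        if not 0 < self.division_ratio < 1:
            raise ValueError("division_ratio must be in (0, 1)")
        for name in ("recovery_width", "frame_interval_phase", "frame_interval_fluor",
                     "interdivision_mean", "founder_area", "cell_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrueCell:
    """Ground-truth record for one simulated cell."""

    cell_id: str
    progeny_type: str                 # swarmer | stalked
    generation: int
    birth_area_true: float            # um^2 at cytokinesis birth
    g1_duration_true: float           # min, from cytokinesis birth
    birth_time_cyto: float
    birth_time_sep: float
    division_time: float              # own cytokinesis completion
    mother_id: str | None
    sister_id: str | None
    baseline_rate_cell: float         # this cell's mu0 (min^-1)
    sep_offset_own: float             # delay between own cyto birth and separation
    frame_times: np.ndarray = field(default_factory=lambda: np.array([]))
    areas_true: np.ndarray = field(default_factory=lambda: np.array([]))
    rate_trajectory_true: np.ndarray = field(default_factory=lambda: np.array([]))
    has_daughters: bool = False

    def __post_init__(self) -> None:
        if not self.birth_time_cyto <= self.birth_time_sep:
            raise ValueError(f"{self.cell_id}: separation precedes cytokinesis")
        if self.g1_duration_true < 0:
            raise ValueError(f"{self.cell_id}: negative G1 duration")

    def area_true_at(self, t: float, params: SimParams) -> float:
        """Noiseless area at absolute time ``t`` (within this cell's lifetime)."""
        return float(
            self.birth_area_true
            * np.exp(
                rate_time_integral(
                    t - self.birth_time_cyto,
                    self.baseline_rate_cell,
                    params.dip_depth,
                    max(self.g1_duration_true + params.trough_offset, 0.0),
                    params.recovery_width,
                )
            )
        )


def growth_rate_profile(t, params: SimParams, g1_duration: float) -> np.ndarray | float:
    """Piecewise-linear relative growth rate at time(s) ``t`` since cytokinesis birth.

    Declines from ``mu0`` at t=0 to ``mu0 * (1 - dip_depth)`` at the trough
    (G1 end plus ``trough_offset``), rises linearly back to ``mu0`` over
    ``recovery_width`` minutes, and is constant thereafter.  With zero dip
    depth or zero G1 the profile is flat at ``mu0``.
    """
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("t must be >= 0")
    out = _profile(arr, params.baseline_rate, params.dip_depth,
                   max(g1_duration + params.trough_offset, 0.0), params.recovery_width)
    return float(out) if np.isscalar(t) else out


def _profile(t: np.ndarray, mu0: float, d: float, trough: float, w: float) -> np.ndarray:
    if d == 0 or trough <= 0:
        return np.full_like(t, mu0, dtype=float)
    rate = np.full_like(t, mu0, dtype=float)
    falling = t < trough
    rate[falling] = mu0 * (1 - d * t[falling] / trough)
    rising = (t >= trough) & (t < trough + w)
    rate[rising] = mu0 * (1 - d + d * (t[rising] - trough) / w)
    return rate


def rate_time_integral(t, mu0: float, d: float, trough: float, w: float) -> np.ndarray | float:
    """Exact integral of the piecewise-linear profile from 0 to ``t`` (unitless)."""
    tt = np.asarray(t, dtype=float)
    if d == 0 or trough <= 0:
        out = mu0 * tt
        return float(out) if np.isscalar(t) else out
    u1 = np.clip(tt, 0.0, trough)
    integral = mu0 * u1 - 0.5 * mu0 * d * u1**2 / trough
    u2 = np.clip(tt - trough, 0.0, w)
    integral = integral + mu0 * (1 - d) * u2 + 0.5 * mu0 * d * u2**2 / w
    u3 = np.maximum(tt - trough - w, 0.0)
    integral = integral + mu0 * u3
    return float(integral) if np.isscalar(t) else integral


def rod_length(area: float, width: float) -> float:
    """Pole-to-pole length of a stadium-shaped rod of the given area and width."""
    length = (area - np.pi * width**2 / 4) / width + width
    return float(max(length, width))


def _first_frame(t: float, interval: float) -> int:
    return int(np.ceil(t / interval - _EPS))


def simulate_lineage(
    params: SimParams,
    n_generations: int,
    n_founders: int = 1,
) -> tuple[list[TrueCell], pd.DataFrame]:
    """Simulate founder lineages and emit the observed tracked-area table.

    Founders are stalked-like cells born at t = 0.  Every cell divides once
    at a drawn interdivision time; cells of the final generation are
    tracked until their division but leave no daughters (and therefore
    cannot be curated as complete cycles).  Returns the per-cell ground
    truth and a track table in the standard CSV dialect, deterministic
    under ``params.seed``.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    rng = np.random.default_rng(params.seed)
    dtp = params.frame_interval_phase
    truth: list[TrueCell] = []
    rows: list[dict] = []

    queue: list[dict] = []
    for i in range(n_founders):
        queue.append(
            dict(
                cell_id=f"F{i:03d}",
                progeny_type="stalked",
                generation=0,
                birth_area=params.founder_area,
                birth_cyto=0.0,
                birth_sep=0.0,
                sep_offset=0.0,
                mother_id=None,
                sister_id=None,
                base_pos=rng.uniform(15.0, 85.0, size=2),
            )
        )

    while queue:
        spec = queue.pop(0)
        mu0 = params.baseline_rate
        if params.rate_cv > 0:
            mu0 *= float(rng.lognormal(0.0, params.rate_cv))
        g1_mean = (
            params.g1_mean_swarmer
            if spec["progeny_type"] == "swarmer"
            else params.g1_mean_stalked
        )
        if params.g1_dispersion > 0:
            shape = 1.0 / params.g1_dispersion**2
            g1 = float(rng.gamma(shape, g1_mean / shape))
        else:
            g1 = g1_mean
        dt_div = max(
            float(rng.normal(params.interdivision_mean, params.interdivision_sd)),
            params.interdivision_mean / 3.0,
        )
        birth_cyto = spec["birth_cyto"]
        division = birth_cyto + dt_div
        trough = max(g1 + params.trough_offset, 0.0)

        f0 = _first_frame(birth_cyto, dtp)
        f1 = _first_frame(division, dtp) - 1
        frames = np.arange(f0, f1 + 1)
        times = frames * dtp
        rel = times - birth_cyto
        areas_true = spec["birth_area"] * np.exp(
            rate_time_integral(rel, mu0, params.dip_depth, trough, params.recovery_width)
        )
        rates_true = _profile(rel, mu0, params.dip_depth, trough, params.recovery_width)
        if params.area_noise_cv > 0:
            observed = areas_true * rng.lognormal(0.0, params.area_noise_cv, size=len(frames))
        else:
            observed = areas_true.copy()

        f_sep = min(max(_first_frame(spec["birth_sep"], dtp), f0), f1)
        theta = rng.uniform(0.0, np.pi)
        axis = np.array([np.cos(theta), np.sin(theta)])

        centroids = np.tile(spec["base_pos"], (len(frames), 1)).astype(float)
        if spec["progeny_type"] == "swarmer":
            travel = max(float(rng.normal(params.swarmer_motion_um, 1.0)), 0.0)
            direction = rng.uniform(0.0, 2 * np.pi)
            vec = travel * np.array([np.cos(direction), np.sin(direction)])
            ramp = np.clip((frames - f_sep) / 2.0, 0.0, 1.0)
            centroids = centroids + ramp[:, None] * vec[None, :]
        else:
            centroids = centroids + rng.normal(0.0, 0.02, size=centroids.shape)

        lengths = np.array([rod_length(a, params.cell_width) for a in observed])
        pole1 = centroids - 0.5 * lengths[:, None] * axis[None, :]
        pole2 = centroids + 0.5 * lengths[:, None] * axis[None, :]
        has_stalk = (
            spec["progeny_type"] == "stalked" and rng.random() < params.stalk_visibility
        )

        cell = TrueCell(
            cell_id=spec["cell_id"],
            progeny_type=spec["progeny_type"],
            generation=spec["generation"],
            birth_area_true=spec["birth_area"],
            g1_duration_true=g1,
            birth_time_cyto=birth_cyto,
            birth_time_sep=spec["birth_sep"],
            division_time=division,
            mother_id=spec["mother_id"],
            sister_id=spec["sister_id"],
            baseline_rate_cell=mu0,
            sep_offset_own=spec["sep_offset"],
            frame_times=times,
            areas_true=areas_true,
            rate_trajectory_true=rates_true,
        )

        for i, f in enumerate(frames):
            rows.append(
                dict(
                    cell_id=spec["cell_id"],
                    frame=int(f),
                    time_min=float(times[i]),
                    area_um2=float(observed[i]),
                    centroid_x_um=float(centroids[i, 0]),
                    centroid_y_um=float(centroids[i, 1]),
                    pole1_x=float(pole1[i, 0]),
                    pole1_y=float(pole1[i, 1]),
                    pole2_x=float(pole2[i, 0]),
                    pole2_y=float(pole2[i, 1]),
                    mother_id=spec["mother_id"] or "",
                    has_stalk=int(has_stalk),
                    sep_event=int(f == f_sep),
                    cyto_event=int(f == f0),
                )
            )

        if spec["generation"] < n_generations:
            cell.has_daughters = True
            offset = max(float(rng.normal(params.sep_offset_mean, params.sep_offset_sd)), 0.0)
            a_div = cell.area_true_at(division, params)
            sw_id = spec["cell_id"] + ".S"
            st_id = spec["cell_id"] + ".T"
            sep_dir = axis * rod_length(a_div, params.cell_width) / 4.0
            common = dict(
                generation=spec["generation"] + 1,
                birth_cyto=division,
                birth_sep=division + offset,
                sep_offset=offset,
                mother_id=spec["cell_id"],
            )
            queue.append(
                dict(
                    cell_id=sw_id,
                    progeny_type="swarmer",
                    birth_area=params.division_ratio * a_div,
                    sister_id=st_id,
                    base_pos=spec["base_pos"] - sep_dir,
                    **common,
                )
            )
            queue.append(
                dict(
                    cell_id=st_id,
                    progeny_type="stalked",
                    birth_area=(1 - params.division_ratio) * a_div,
                    sister_id=sw_id,
                    base_pos=spec["base_pos"] + sep_dir,
                    **common,
                )
            )
        truth.append(cell)

    table = pd.DataFrame(rows)
    return truth, table


def truth_table(truth: Sequence[TrueCell]) -> pd.DataFrame:
    """Flatten ground-truth records (scalars only) for CSV export."""
    return pd.DataFrame(
        [
            dict(
                cell_id=c.cell_id,
                progeny_type=c.progeny_type,
                generation=c.generation,
                mother_id=c.mother_id or "",
                sister_id=c.sister_id or "",
                birth_area_true=c.birth_area_true,
                g1_duration_true=c.g1_duration_true,
                birth_time_cyto=c.birth_time_cyto,
                birth_time_sep=c.birth_time_sep,
                division_time=c.division_time,
                baseline_rate_cell=c.baseline_rate_cell,
                sep_offset_own=c.sep_offset_own,
                has_daughters=int(c.has_daughters),
            )
            for c in truth
        ]
    )


def simulate_foci_track(
    cell: TrueCell,
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> FociTrack:
    """Replication-marker focus observations for one cell on the fluorescence grid.

    One polar focus at every fluorescence frame before the end of G1, two
    foci afterwards: the duplicated focus starts ``focus_initial_sep`` um
    from its sibling and segregates towards the far pole at
    ``focus_seg_speed`` um/min.  A G1 longer than the interdivision time
    yields a single focus at every frame.
    """
    dtf = params.frame_interval_fluor
    f0 = _first_frame(cell.birth_time_cyto, dtf)
    f1 = _first_frame(cell.division_time, dtf) - 1
    times = np.arange(f0, f1 + 1) * dtf
    g1_end = cell.birth_time_cyto + cell.g1_duration_true
    counts = np.where(times < g1_end - _EPS, 1, 2)
    foci: list[list[Focus]] = []
    for t, count in zip(times, counts):
        length = rod_length(cell.area_true_at(float(t), params), params.cell_width)
        jitter = 0.0 if rng is None else float(rng.normal(0.0, 0.01))
        first = Focus(cell.cell_id, None, np.nan, np.nan,
                      float(np.clip(0.08 + jitter, 0.0, 1.0)), 1.0)
        if count == 1:
            foci.append([first])
        else:
            travelled = params.focus_initial_sep + params.focus_seg_speed * max(
                float(t) - g1_end, 0.0
            )
            frac = float(np.clip(0.08 + travelled / length, 0.0, 0.92))
            second = Focus(cell.cell_id, None, np.nan, np.nan, frac, 1.0)
            foci.append([first, second])
    return FociTrack(cell_id=cell.cell_id, times=times, counts=counts, foci=foci)


@dataclass(frozen=True)
class RenderParams:
    """Parameters for rasterising synthetic fluorescence frames and label masks."""

    pixel_size: float = 0.065         # um / px
    psf_sigma: float = 1.3            # px
    background_level: float = 200.0   # counts
    focus_amplitude: float = 300.0    # counts at the Gaussian peak
    noise_model: str = "poisson"      # poisson | gaussian | none
    image_shape: tuple[int, int] = (64, 64)

    def __post_init__(self) -> None:
        if self.psf_sigma <= 0 or self.focus_amplitude <= 0:
            raise ValueError("psf_sigma and focus_amplitude must be positive")
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


@dataclass(frozen=True)
class CellGeometry:
    """Rod-shaped cell footprint in pixel coordinates: segment poles + radius."""

    label: int
    pole1: tuple[float, float]        # (row, col) px
    pole2: tuple[float, float]
    radius: float                     # px


def render_frame(
    cells: Sequence[CellGeometry],
    foci: Sequence[tuple[float, float, float]],
    render: RenderParams,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterise one synthetic fluorescence frame and its uint16 label mask.

    Cells become stadium-shaped (rectangle plus semicircular caps) label
    regions; each focus ``(row, col, amplitude)`` adds an isotropic Gaussian
    of sd ``psf_sigma`` on top of the flat background, and the configured
    noise model is applied.  A focus outside the image raises ValueError.
    """
    h, w = render.image_shape
    mask = np.zeros((h, w), dtype=np.uint16)
    rr, cc = np.mgrid[0:h, 0:w]
    for cell in cells:
        p1 = np.asarray(cell.pole1, dtype=float)
        p2 = np.asarray(cell.pole2, dtype=float)
        seg = p2 - p1
        seg_len2 = float(seg @ seg)
        d = np.stack([rr - p1[0], cc - p1[1]], axis=-1)
        if seg_len2 == 0:
            dist = np.linalg.norm(d, axis=-1)
        else:
            t = np.clip((d @ seg) / seg_len2, 0.0, 1.0)
            proj = p1[None, None, :] + t[..., None] * seg[None, None, :]
            dist = np.linalg.norm(np.stack([rr, cc], axis=-1) - proj, axis=-1)
        mask[dist <= cell.radius] = cell.label

    image = np.full((h, w), float(render.background_level))
    sigma = render.psf_sigma
    win = int(np.ceil(4 * sigma))
    for row, col, amp in foci:
        if not (0 <= row < h and 0 <= col < w):
            raise ValueError(f"focus ({row}, {col}) outside image {render.image_shape}")
        r0, c0 = int(round(row)), int(round(col))
        rlo, rhi = max(0, r0 - win), min(h, r0 + win + 1)
        clo, chi = max(0, c0 - win), min(w, c0 + win + 1)
        sub_r, sub_c = np.mgrid[rlo:rhi, clo:chi]
        image[rlo:rhi, clo:chi] += amp * np.exp(
            -((sub_r - row) ** 2 + (sub_c - col) ** 2) / (2 * sigma**2)
        )

    if render.noise_model != "none":
        if rng is None:
            rng = np.random.default_rng(0)
        if render.noise_model == "poisson":
            image = rng.poisson(np.clip(image, 0, None)).astype(float)
        else:
            image = image + rng.normal(0.0, np.sqrt(render.background_level), image.shape)
    return image, mask


def render_cell_frame(
    cell: TrueCell,
    t: float,
    foci_axis_fracs: Sequence[float],
    params: SimParams,
    render: RenderParams,
    rng: np.random.Generator | None = None,
    label: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one cell, horizontally centred, with foci at given axis fractions.

    Convenience wrapper used for round-trip tests of the detector: returns
    ``(image, mask, true_positions)`` where positions are (row, col) px.
    """
    length_px = rod_length(cell.area_true_at(t, params), params.cell_width) / render.pixel_size
    radius_px = 0.5 * params.cell_width / render.pixel_size
    # grow the canvas if the cell outgrows the configured crop
    h = max(render.image_shape[0], int(np.ceil(2 * radius_px)) + 12)
    w = max(render.image_shape[1], int(np.ceil(length_px)) + 12)
    if (h, w) != render.image_shape:
        render = replace(render, image_shape=(h, w))
    row = h / 2.0
    p1 = (row, w / 2.0 - length_px / 2.0)
    p2 = (row, w / 2.0 + length_px / 2.0)
    geom = CellGeometry(label=label, pole1=p1, pole2=p2, radius=radius_px)
    positions = np.array(
        [[row, p1[1] + frac * (p2[1] - p1[1])] for frac in foci_axis_fracs]
    )
    foci = [(float(r), float(c), render.focus_amplitude) for r, c in positions]
    image, mask = render_frame([geom], foci, render, rng)
    return image, mask, positions
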