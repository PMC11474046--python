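"""Trajectory-quality curation with full rejection logging.

Reproduces the standard filters used on tracked single-cell growth data:
cycles that are too short to be real, implausibly small area gain over a
cycle, instantaneous rates outside what accurate segmentation can produce,
broken mother/daughter linkage, unclassifiable progeny identity, and (for
strain comparisons) cells born too late on the pad.  Boundary values are
retained: all comparisons are strict, exactly as the thresholds are
printed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .growth import GrowthProfile, compute_profile
from .lineage import BirthDefinition, CellTrack, assign_birth

__all__ = ["CurationConfig", "CurationReport", "apply_filters", "demo_tracks"]

log = logging.getLogger(__name__)

#: reason codes, in the order the rules are evaluated
REASONS = (
    "incomplete_lineage",
    "short_cycle",
    "small_area_increase",
    "rate_above_max",
    "rate_below_min",
    "uncertain_type",
    "late_birth",
    "manual_exclusion",
)


@dataclass(frozen=True)
class CurationConfig:
    min_duration: float = 30.0            # min; reject dt < this
    min_area_increase: float = 0.61       # um^2; reject (A_d - A_b) < this
    rate_upper: float = 0.015             # min^-1; reject any smoothed rate > this
    rate_lower: float = -0.0025           # min^-1; reject any smoothed rate < this
    max_birth_time: float | None = None   # min; 60 for strain comparisons
    require_complete_lineage: bool = True
    drop_uncertain: bool = True
    manual_exclusions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.rate_lower < 0 < self.rate_upper:
            raise ValueError("rate bounds must straddle zero")
        if self.min_duration <= 0:
            raise ValueError("min_duration must be positive")


@dataclass
class CurationReport:
    retained: list[str]
    rejected: dict[str, list[str]]        # cell_id -> reason codes

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(cell_id=c, decision="retained", reasons="") for c in self.retained]
        rows += [
            dict(cell_id=c, decision="rejected", reasons=";".join(r))
            for c, r in sorted(self.rejected.items())
        ]
        return pd.DataFrame(rows, columns=["cell_id", "decision", "reasons"])


def apply_filters(
    tracks: Mapping[str, CellTrack],
    profiles: Mapping[str, GrowthProfile],
    config: CurationConfig = CurationConfig(),
) -> tuple[CurationReport, dict[str, CellTrack]]:
    """Partition tracks into retained and rejected sets with per-rule reason codes.

    ``tracks`` must have an active birth definition assigned and
    ``profiles`` must hold the matching smoothed instantaneous-rate series
    (the rate bounds are evaluated on the smoothed series).  A cell may
    carry several reason codes.  Missing profiles raise KeyError naming the
    track.
    """
    retained: list[str] = []
    rejected: dict[str, list[str]] = {}
    for cid in sorted(tracks):
        track = tracks[cid]
        if cid not in profiles:
            raise KeyError(f"no growth profile for track {cid!r}")
        profile = profiles[cid]
        codes: list[str] = []

        missing_links = track.mother_id is None or not track.daughter_ids
        if config.require_complete_lineage and (track.incomplete or missing_links):
            codes.append("incomplete_lineage")
        dt = track.interdivision_min
        if dt is not None and dt < config.min_duration:
            codes.append("short_cycle")
        if (
            track.A_b is not None
            and track.A_d is not None
            and (track.A_d - track.A_b) < config.min_area_increase
        ):
            codes.append("small_area_increase")
        rates = np.asarray(profile.inst_rate, dtype=float)
        if rates.size and np.any(rates > config.rate_upper):
            codes.append("rate_above_max")
        if rates.size and np.any(rates < config.rate_lower):
            codes.append("rate_below_min")
        if config.drop_uncertain and track.progeny_type == "uncertain":
            codes.append("uncertain_type")
        if (
            config.max_birth_time is not None
            and track.active_birth_frame is not None
            and track.time_at(track.active_birth_frame) > config.max_birth_time
        ):
            codes.append("late_birth")
        if cid in config.manual_exclusions:
            codes.append("manual_exclusion")

        if codes:
            rejected[cid] = codes
            log.info("curation: rejected %s (%s)", cid, ";".join(codes))
        else:
            retained.append(cid)

    report = CurationReport(retained=retained, rejected=rejected)
    return report, {cid: tracks[cid] for cid in retained}


def _make_track(
    cell_id: str,
    areas: np.ndarray,
    frame_interval: float = 1.5,
    complete: bool = True,
) -> CellTrack:
    n = len(areas)
    frames = np.arange(n)
    track = CellTrack(
        cell_id=cell_id,
        frames=frames,
        times=frames * frame_interval,
        areas=areas,
        centroids=np.zeros((n, 2)),
        poles=np.zeros((n, 2, 2)),
        mother_id="M0" if complete else None,
        cyto_event_frame=0,
        progeny_type="stalked",
    )
    if complete:
        track.daughter_ids = [cell_id + ".S", cell_id + ".T"]
        track.division_frame_cyto = n
        # mother outline at the division frame, extrapolated geometrically
        track.division_area_cyto = float(areas[-1] * areas[-1] / areas[-2])
    return track


def demo_tracks() -> tuple[dict[str, CellTrack], dict[str, GrowthProfile]]:
    """Six hand-built tracks, one violating each quality rule plus one clean.

    Synthetic demonstration fixture: a clean exponential cycle, a too-short
    cycle, a near-flat cycle with tiny area gain, a segmentation-jump
    artefact (rate spike above the upper bound), a mask-loss artefact (rate
    drop below the lower bound), and a cycle with no tracked daughters.
    Returns tracks with the cytokinesis birth definition assigned and the
    matching growth profiles.
    """
    dt = 1.5

    def exp_areas(a0: float, mu: float, n: int) -> np.ndarray:
        return a0 * np.exp(mu * np.arange(n) * dt)

    areas_clean = exp_areas(1.0, 0.006, 80)
    areas_short = exp_areas(2.2, 0.014, 15)          # 21 min cycle, all else in range
    areas_flat = exp_areas(1.0, 0.003, 80)           # gains only ~0.43 um^2
    areas_spike = exp_areas(1.0, 0.006, 80)
    areas_spike[40:] *= 1.5                          # segmentation merge artefact
    areas_drop = exp_areas(1.2, 0.006, 80)
    areas_drop[40:] *= 0.8                           # partial mask loss

    tracks = {
        "clean": _make_track("clean", areas_clean),
        "short": _make_track("short", areas_short),
        "flat": _make_track("flat", areas_flat),
        "spike": _make_track("spike", areas_spike),
        "drop": _make_track("drop", areas_drop),
        "no_daughter": _make_track("no_daughter", areas_clean.copy(), complete=False),
    }
    profiles = {}
    for cid, tr in tracks.items():
        assign_birth(tr, BirthDefinition.CYTOKINESIS)
        profiles[cid] = compute_profile(tr)
    return tracks, profiles
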