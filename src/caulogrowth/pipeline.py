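"""High-level orchestration: track table -> curated, aligned population results.

These helpers glue the modules together the way the command-line interface
uses them: assign the configured birth definition, classify progenies,
compute growth profiles, curate, and summarise the retained population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import growth, lineage
from .config import PipelineConfig
from .curation import CurationReport, apply_filters
from .growth import AlignedPopulation, GrowthProfile
from .lineage import BirthDefinition, CellTrack

__all__ = ["AnalysisResult", "analyze_tracks", "metrics_frame", "population_frame"]


@dataclass
class AnalysisResult:
    tracks: dict[str, CellTrack]
    profiles: dict[str, GrowthProfile]
    report: CurationReport
    retained: dict[str, CellTrack]
    population: AlignedPopulation | None
    by_type: dict[str, AlignedPopulation]


def analyze_tracks(
    tracks: Mapping[str, CellTrack],
    config: PipelineConfig = PipelineConfig(),
) -> AnalysisResult:
    """Run birth assignment, typing, profiling, curation and population alignment."""
    ana = config.analysis
    definition = BirthDefinition(ana.birth_definition)
    tracks = dict(tracks)
    lineage.classify_all(tracks, motion_threshold=ana.motion_threshold)
    profiles: dict[str, GrowthProfile] = {}
    for cid in sorted(tracks):
        lineage.assign_birth(tracks[cid], definition)
        profiles[cid] = growth.compute_profile(
            tracks[cid], smooth_window=ana.smooth_window, n_bins=ana.n_bins
        )
    report, retained = apply_filters(tracks, profiles, config.curation.to_config())

    def _curve(ids: list[str]) -> AlignedPopulation | None:
        vectors = [profiles[c].aligned for c in ids if not np.all(np.isnan(profiles[c].aligned))]
        if len(vectors) < 2:
            return None
        pop = growth.population_mean_curve(
            vectors, n_boot=ana.n_boot, alpha=ana.alpha, seed=config.seed
        )
        dts = [profiles[c].interdivision_min for c in ids if not np.all(np.isnan(profiles[c].aligned))]
        pop.tempogram, order = growth.tempogram(vectors, dts)
        pop.sort_key = np.asarray(dts, dtype=float)[order]
        return pop

    retained_ids = sorted(retained)
    population = _curve(retained_ids)
    by_type = {}
    for ptype in ("swarmer", "stalked"):
        ids = [c for c in retained_ids if tracks[c].progeny_type == ptype]
        pop = _curve(ids)
        if pop is not None:
            by_type[ptype] = pop
    return AnalysisResult(
        tracks=tracks,
        profiles=profiles,
        report=report,
        retained=retained,
        population=population,
        by_type=by_type,
    )


def metrics_frame(result: AnalysisResult) -> pd.DataFrame:
    """Per-cell metrics table for the analysed lineage."""
    rows = []
    for cid in sorted(result.tracks):
        tr = result.tracks[cid]
        pr = result.profiles[cid]
        rows.append(
            dict(
                cell_id=cid,
                progeny_type=tr.progeny_type,
                retained=int(cid in result.retained),
                birth_definition=tr.birth_definition.value if tr.birth_definition else "",
                A_b=tr.A_b,
                A_d=tr.A_d,
                interdivision_min=tr.interdivision_min,
                avg_rate=pr.avg_rate,
                residual_score=pr.residual_score,
                reasons=";".join(result.report.rejected.get(cid, [])),
            )
        )
    return pd.DataFrame(rows)


def population_frame(pop: AlignedPopulation) -> pd.DataFrame:
    """Aligned-population curve as a tidy table."""
    return pd.DataFrame(
        dict(
            cc_unit=pop.bin_centers,
            mean_rate=pop.mean_rate,
            ci_low=pop.ci_low,
            ci_high=pop.ci_high,
            boot_se=pop.boot_se,
            n_contributing=pop.n_contributing,
        )
    )
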