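import numpy as np
import pytest

import caulogrowth as cg
from caulogrowth.growth import compute_profile
from caulogrowth.lineage import (
    BirthDefinition,
    CellTrack,
    assign_birth,
    classify_all,
    link_generations,
)


@pytest.fixture(scope="session")
def sim_small():
    """Small realistic lineage: 4 founders, 3 generations, default conditions."""
    params = cg.SimParams(seed=42)
    truth, table = cg.simulate_lineage(params, 3, 4)
    return params, truth, table


@pytest.fixture(scope="session")
def sim_clean():
    """Noise-free lineage with deterministic per-cell rates and on-grid event times."""
    params = cg.SimParams(
        seed=8,
        area_noise_cv=0.0,
        rate_cv=0.0,
        interdivision_sd=0.0,
        sep_offset_sd=0.0,
    )
    truth, table = cg.simulate_lineage(params, 2, 3)
    return params, truth, table


@pytest.fixture(scope="session")
def linked_small(sim_small):
    params, truth, table = sim_small
    tracks = link_generations(table.to_dict("records"))
    classify_all(tracks)
    for cid in sorted(tracks):
        assign_birth(tracks[cid], BirthDefinition.CYTOKINESIS)
    profiles = {cid: compute_profile(tracks[cid]) for cid in sorted(tracks)}
    truth_map = {c.cell_id: c for c in truth}
    return params, truth_map, tracks, profiles


def make_exponential_track(
    cell_id="c",
    a0=1.0,
    mu=0.006,
    n=80,
    frame_interval=1.5,
    complete=True,
    mother_id="M",
):
    """Noise-free exponential CellTrack with division bookkeeping filled in."""
    frames = np.arange(n)
    times = frames * frame_interval
    areas = a0 * np.exp(mu * times)
    track = CellTrack(
        cell_id=cell_id,
        frames=frames,
        times=times,
        areas=areas,
        centroids=np.zeros((n, 2)),
        poles=np.zeros((n, 2, 2)),
        mother_id=mother_id,
        cyto_event_frame=0,
        progeny_type="stalked",
    )
    if complete:
        track.daughter_ids = [cell_id + ".S", cell_id + ".T"]
        track.division_frame_cyto = n
        track.division_area_cyto = float(a0 * np.exp(mu * n * frame_interval))
    return track
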