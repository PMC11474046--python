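"""Tracked-cell data model: mother/daughter linkage, birth definitions, progeny typing.

A *Caulobacter*-style asymmetric division produces a small motile swarmer
cell and a larger stalked cell.  Two conventions exist for when a progeny
is "born":

``separation``
    the frame at which the two daughters become visibly separate objects
    (the classical definition on soft-agarose timelapse data, where the
    swarmer daughter swims away from its sibling);

``cytokinesis``
    the earlier frame at which the late predivisional mother is first
    segmented into two label regions, i.e. near the completion of
    cytokinesis, when the daughter compartments already have separate
    cytoplasms.  Quantities computed under this convention conventionally
    carry an asterisk (G1 duration*, growth rate*, ...).

Both conventions are carried by every :class:`CellTrack`, and
:func:`assign_birth` activates one of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "BirthDefinition",
    "CellTrack",
    "LinkError",
    "assign_birth",
    "classify_progeny",
    "link_generations",
]


class LinkError(ValueError):
    """Raised when per-frame records cannot be assembled into a consistent lineage."""


class BirthDefinition(str, Enum):
    """Which event defines the start of a progeny cell cycle."""

    SEPARATION = "separation"
    CYTOKINESIS = "cytokinesis"


@dataclass
class CellTrack:
    """One cell's trajectory from its appearance as a mask to its own division.

    Frames are 0-based indices on the global acquisition grid; ``times`` are
    the corresponding acquisition times in minutes.  Pole positions are the
    two endpoints of the cell's long axis, in micrometres.
    """

    cell_id: str
    frames: np.ndarray            # (n,) int, strictly increasing
    times: np.ndarray             # (n,) min
    areas: np.ndarray             # (n,) um^2
    centroids: np.ndarray         # (n, 2) um  (x, y)
    poles: np.ndarray             # (n, 2, 2) um  [:, pole, (x, y)]
    mother_id: str | None = None
    has_stalk: bool = False
    cyto_event_frame: int | None = None   # first frame this cell exists as its own mask
    sep_event_frame: int | None = None    # frame assigned as the separation birth
    daughter_ids: list[str] = field(default_factory=list)
    sister_id: str | None = None
    progeny_type: str = "uncertain"       # swarmer | stalked | uncertain

    # division bookkeeping, filled in by link_generations from the daughters
    division_frame_cyto: int | None = None   # daughters' first frame
    division_frame_sep: int | None = None    # daughters' separation frame
    division_area_cyto: float | None = None  # summed daughter area at division_frame_cyto
    division_area_sep: float | None = None   # summed daughter area at division_frame_sep

    # active-birth quantities, filled in by assign_birth
    birth_definition: BirthDefinition | None = None
    active_birth_frame: int | None = None
    active_division_frame: int | None = None
    A_b: float | None = None
    A_d: float | None = None
    interdivision_min: float | None = None
    incomplete: bool = False
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.poles = np.asarray(self.poles, dtype=float)
        if self.frames.ndim != 1 or len(self.frames) == 0:
            raise ValueError(f"{self.cell_id}: empty track")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError(f"{self.cell_id}: frames must be strictly increasing")
        if np.any(self.areas <= 0):
            raise ValueError(f"{self.cell_id}: areas must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def birth_frame_cyto(self) -> int | None:
        return self.cyto_event_frame if self.cyto_event_frame is not None else int(self.frames[0])

    @property
    def birth_frame_sep(self) -> int | None:
        return self.sep_event_frame

    def frame_index(self, frame: int) -> int:
        """Position of a global frame number within this track's arrays."""
        idx = np.searchsorted(self.frames, frame)
        if idx >= len(self.frames) or self.frames[idx] != frame:
            raise KeyError(f"{self.cell_id}: frame {frame} not in track")
        return int(idx)

    def area_at(self, frame: int) -> float:
        return float(self.areas[self.frame_index(frame)])

    def time_at(self, frame: int) -> float:
        return float(self.times[self.frame_index(frame)])


def link_generations(records: Iterable[Mapping]) -> dict[str, CellTrack]:
    """Assemble per-frame records into linked :class:`CellTrack` objects.

    Each record needs the keys of the track-table dialect (see
    :mod:`caulogrowth.io`).  Exactly two daughters are allowed per division;
    more raise :class:`LinkError` listing the offending ids.  Orphan tracks
    (no mother present in the table) are retained and flagged ``"orphan"``.
    """
    by_cell: dict[str, list[Mapping]] = {}
    seen: set[tuple[str, int]] = set()
    for rec in records:
        key = (str(rec["cell_id"]), int(rec["frame"]))
        if key in seen:
            raise LinkError(f"duplicated (cell_id, frame) = {key}")
        seen.add(key)
        by_cell.setdefault(key[0], []).append(rec)

    tracks: dict[str, CellTrack] = {}
    for cid in sorted(by_cell):
        rows = sorted(by_cell[cid], key=lambda r: int(r["frame"]))
        frames = np.array([int(r["frame"]) for r in rows])
        mother = rows[0].get("mother_id")
        mother_id = None if mother in (None, "", "none", "None") or (
            isinstance(mother, float) and np.isnan(mother)
        ) else str(mother)
        sep_frames = [int(r["frame"]) for r in rows if int(r.get("sep_event", 0) or 0) == 1]
        cyto_frames = [int(r["frame"]) for r in rows if int(r.get("cyto_event", 0) or 0) == 1]
        tracks[cid] = CellTrack(
            cell_id=cid,
            frames=frames,
            times=np.array([float(r["time_min"]) for r in rows]),
            areas=np.array([float(r["area_um2"]) for r in rows]),
            centroids=np.array([[float(r["centroid_x_um"]), float(r["centroid_y_um"])] for r in rows]),
            poles=np.array(
                [
                    [
                        [float(r["pole1_x"]), float(r["pole1_y"])],
                        [float(r["pole2_x"]), float(r["pole2_y"])],
                    ]
                    for r in rows
                ]
            ),
            mother_id=mother_id,
            has_stalk=bool(int(rows[0].get("has_stalk", 0) or 0)),
            cyto_event_frame=cyto_frames[0] if cyto_frames else int(frames[0]),
            sep_event_frame=sep_frames[0] if sep_frames else None,
        )

    daughters: dict[str, list[str]] = {}
    for cid, tr in tracks.items():
        if tr.mother_id is None:
            tr.flags.append("orphan")
        elif tr.mother_id not in tracks:
            tr.flags.append("orphan")
        else:
            daughters.setdefault(tr.mother_id, []).append(cid)

    for mid, kids in daughters.items():
        if len(kids) > 2:
            raise LinkError(f"mother {mid} has {len(kids)} daughters: {sorted(kids)}")
        mother = tracks[mid]
        mother.daughter_ids = sorted(kids)
        if len(kids) == 2:
            a, b = mother.daughter_ids
            tracks[a].sister_id = b
            tracks[b].sister_id = a
            fcyto = min(tracks[a].birth_frame_cyto, tracks[b].birth_frame_cyto)
            mother.division_frame_cyto = fcyto
            try:
                mother.division_area_cyto = tracks[a].area_at(fcyto) + tracks[b].area_at(fcyto)
            except KeyError:
                mother.flags.append("cyto_area_unavailable")
            sep_frames = [tracks[k].sep_event_frame for k in (a, b)]
            if all(f is not None for f in sep_frames):
                fsep = int(min(sep_frames))  # type: ignore[arg-type]
                mother.division_frame_sep = fsep
                try:
                    mother.division_area_sep = tracks[a].area_at(fsep) + tracks[b].area_at(fsep)
                except KeyError:
                    mother.flags.append("sep_area_unavailable")
        else:
            mother.flags.append("single_daughter")

    return tracks


def assign_birth(track: CellTrack, definition: BirthDefinition) -> CellTrack:
    """Activate one birth definition on a track, setting A_b, A_d and the interdivision time.

    The birth and division events are the same kind of event one generation
    apart, so both are measured the same way: A_b is the track's own area at
    its birth-event frame, A_d the summed area of its two daughters at their
    birth-event frame (the outline of the just-divided mother), and the
    interdivision time runs between those two frames.  Under ``separation``
    the events are the assigned separation frames; under ``cytokinesis``
    they are the frames at which the mask first splits.  Missing events mark
    the track incomplete instead of raising.
    """
    definition = BirthDefinition(definition)
    track.birth_definition = definition
    track.incomplete = False
    track.active_birth_frame = None
    track.active_division_frame = None
    track.A_b = track.A_d = track.interdivision_min = None

    if definition is BirthDefinition.CYTOKINESIS:
        birth = track.birth_frame_cyto
        division = track.division_frame_cyto
        division_area = track.division_area_cyto
    else:
        birth = track.birth_frame_sep
        division = track.division_frame_sep
        division_area = track.division_area_sep
    if birth is None or division is None or division_area is None:
        track.incomplete = True
        track.flags.append("missing_event")
        return track
    try:
        track.A_b = track.area_at(int(birth))
    except KeyError:
        track.incomplete = True
        track.flags.append("birth_outside_track")
        return track
    track.active_birth_frame = int(birth)
    track.active_division_frame = int(division)
    track.A_d = float(division_area)
    dt_frames = division - birth

    if dt_frames <= 0:
        track.incomplete = True
        track.flags.append("nonpositive_cycle")
        return track
    interval = float(np.median(np.diff(track.times) / np.diff(track.frames)))
    track.interdivision_min = float(dt_frames) * interval
    return track


def _net_displacement(track: CellTrack, start_frame: int, n_after: int) -> float | None:
    """Net centroid displacement (um) over ``n_after`` frames following ``start_frame``."""
    try:
        i0 = track.frame_index(start_frame)
    except KeyError:
        return None
    i1 = min(i0 + n_after, track.n_frames - 1)
    if i1 <= i0:
        return None
    return float(np.linalg.norm(track.centroids[i1] - track.centroids[i0]))


def classify_progeny(
    track: CellTrack,
    sister: CellTrack | None,
    motion_threshold: float = 1.0,
    n_motion_frames: int = 3,
) -> str:
    """Rule-based swarmer/stalked call for one progeny.

    ``stalked`` if the cell has a visible stalk, or if its sister moved more
    than ``motion_threshold`` um net after separation (the swarmer swims off,
    identifying the stayer as stalked).  ``swarmer`` if the cell itself moved
    beyond the threshold and carries no stalk.  Anything else is
    ``uncertain`` (dropped downstream).  On immobilised preparations where
    nothing moves, the stalk flag alone decides.
    """
    if track.has_stalk:
        track.progeny_type = "stalked"
        return "stalked"

    sep = track.sep_event_frame
    own = _net_displacement(track, sep, n_motion_frames) if sep is not None else None
    sis = None
    if sister is not None and sister.sep_event_frame is not None:
        sis = _net_displacement(sister, sister.sep_event_frame, n_motion_frames)

    if sis is not None and sis > motion_threshold:
        track.progeny_type = "stalked"
    elif own is not None and own > motion_threshold:
        track.progeny_type = "swarmer"
    else:
        track.progeny_type = "uncertain"
    return track.progeny_type


def classify_all(
    tracks: Mapping[str, CellTrack],
    motion_threshold: float = 1.0,
    n_motion_frames: int = 3,
) -> None:
    """Classify every track in a linked lineage in place."""
    for cid in sorted(tracks):
        tr = tracks[cid]
        sister = tracks.get(tr.sister_id) if tr.sister_id else None
        classify_progeny(tr, sister, motion_threshold, n_motion_frames)
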