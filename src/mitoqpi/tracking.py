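"""Cell tracking, specific growth rates, cytokinesis and lineage analysis.

Regions from consecutive frames are linked by greedy nearest-centroid
assignment under a maximum displacement.  A division is recorded when one
region is replaced by two nearby regions whose masses sum to the parent's
mass (within tolerance); the parent track ends and two daughter tracks
begin, forming a lineage.  The specific growth rate of a track is the slope
of a least-squares linear fit to mass versus time, divided by the track's
mean mass — the mass-normalized growth rate in 1/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, InsufficientDataError, InvalidParameterError
from .qpi import LabelMap, MassMap, OpticalConstants

__all__ = [
    "CellTrack",
    "LineageRecord",
    "track_cells",
    "specific_growth_rate",
    "cytokinesis_fraction",
    "normalize_daughter_masses",
    "build_lineages",
]

FATE_DIVIDED = "divided"
FATE_LEFT_FRAME = "left_frame"
FATE_CENSORED = "censored"


@dataclass
class CellTrack:
    """One cell's time-indexed observations.

    ``fate`` is ``"divided"`` (track ends at a detected division),
    ``"left_frame"`` (track ends mid-movie near the image border) or
    ``"censored"`` (track ends without division anywhere else, including at
    the end of the movie).  ``division_time`` is the absolute time (h) of
    the first daughter frame when fate is ``"divided"``.
    Fluorescence summaries are filled in per channel by the pipeline as
    ``intensities[channel][i]`` aligned with ``times``.
    """

    track_id: int
    times: list[float] = field(default_factory=list)
    labels: list[int] = field(default_factory=list)
    centroids: list[tuple[float, float]] = field(default_factory=list)
    masses: list[float] = field(default_factory=list)
    frame_indices: list[int] = field(default_factory=list)
    intensities: dict[str, list[float]] = field(default_factory=dict)
    fate: str = FATE_CENSORED
    division_time: float | None = None
    parent_id: int | None = None
    daughter_ids: tuple[int, int] | None = None

    def append(
        self, frame: int, time: float, label: int, centroid: tuple[float, float], mass: float
    ) -> None:
        if self.times and time <= self.times[-1]:
            raise InputError("track frame times must be strictly increasing")
        self.frame_indices.append(frame)
        self.times.append(time)
        self.labels.append(label)
        self.centroids.append(centroid)
        self.masses.append(mass)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def start_time(self) -> float:
        return self.times[0]

    @property
    def duration(self) -> float:
        """Observed time span (h), birth/appearance to last frame."""
        return self.times[-1] - self.times[0]

    @property
    def division_age(self) -> float | None:
        """Time from first observation to division (h), if the cell divided."""
        if self.division_time is None:
            return None
        return self.division_time - self.times[0]


@dataclass
class LineageRecord:
    """A parent track linked to its two daughters, with punctae inheritance flags."""

    parent: CellTrack
    daughters: tuple[CellTrack, CellTrack]
    inheritance: tuple[bool, bool] = (False, False)


def track_cells(
    frames: list[tuple[LabelMap, MassMap]],
    max_displacement: float = 20.0,
    optical: OpticalConstants = OpticalConstants(),
    division_mass_tolerance: float = 0.2,
) -> list[CellTrack]:
    """Link segmented regions across frames into single-cell tracks.

    Parameters
    ----------
    frames : per-frame ``(LabelMap, MassMap)`` pairs in time order; frame
        times are taken from the mass maps.
    max_displacement : maximum centroid displacement per frame, um.
    optical : supplies the pixel size for the um -> px conversion.
    division_mass_tolerance : relative tolerance on (daughter mass sum) vs
        parent mass when detecting a division.
    """
    if len(frames) < 2:
        raise InsufficientDataError("tracking requires at least 2 frames")
    shape = frames[0][0].values.shape
    for lm, mm in frames:
        if lm.values.shape != shape or np.shape(mm.values) != shape:
            raise InputError("all frames must share one grid shape")
    if max_displacement <= 0:
        raise InvalidParameterError("max_displacement must be positive")

    maxdisp_px = max_displacement / optical.pixel_size

    tracks: list[CellTrack] = []
    next_id = 0

    def new_track(frame_i, time, reg, parent_id=None) -> CellTrack:
        nonlocal next_id
        tr = CellTrack(track_id=next_id, parent_id=parent_id)
        next_id += 1
        tr.append(frame_i, time, int(reg.label), (reg.row, reg.col), float(reg.mass_pg))
        tracks.append(tr)
        return tr

    lm0, mm0 = frames[0]
    active: dict[int, CellTrack] = {}
    for reg in lm0.regions.itertuples():
        tr = new_track(0, mm0.frame_time, reg)
        active[tr.track_id] = tr

    resume_window = 8  # frames an interrupted track stays eligible for re-linking
    recently_ended: list[CellTrack] = []

    for fi in range(1, len(frames)):
        lm, mm = frames[fi]
        t = mm.frame_time
        regs = list(lm.regions.itertuples())
        recently_ended = [
            tr for tr in recently_ended if fi - tr.frame_indices[-1] <= resume_window
        ]

        # greedy nearest-centroid assignment under maxdisp
        pairs = []
        track_list = list(active.values())
        for ti, tr in enumerate(track_list):
            r0, c0 = tr.centroids[-1]
            for ri, reg in enumerate(regs):
                d = np.hypot(reg.row - r0, reg.col - c0)
                if d <= maxdisp_px:
                    pairs.append((d, ti, ri))
        pairs.sort(key=lambda p: p[0])
        track_match: dict[int, int] = {}
        region_match: dict[int, int] = {}
        for d, ti, ri in pairs:
            if ti in track_match or ri in region_match:
                continue
            track_match[ti] = ri
            region_match[ri] = ti

        def try_resume(reg) -> bool:
            """Re-link a region to a track that ended a few frames ago.

            Transient region merges (touching cells segmented as one blob)
            end tracks; when the blob splits again the original tracks are
            resumed instead of being mistaken for a division.
            """
            best = None
            for tr in recently_ended:
                gap = fi - tr.frame_indices[-1]
                if gap < 1 or gap > resume_window:
                    continue
                r0, c0 = tr.centroids[-1]
                d = np.hypot(reg.row - r0, reg.col - c0)
                if d > maxdisp_px * gap:
                    continue
                if abs(reg.mass_pg - tr.masses[-1]) > 0.3 * tr.masses[-1]:
                    continue
                if best is None or d < best[0]:
                    best = (d, tr)
            if best is None:
                return False
            tr = best[1]
            tr.append(fi, t, int(reg.label), (reg.row, reg.col), float(reg.mass_pg))
            active[tr.track_id] = tr
            recently_ended.remove(tr)
            return True

        # unmatched regions: first try to resume recently interrupted tracks
        new_regions = []
        for ri in range(len(regs)):
            if ri in region_match:
                continue
            if not try_resume(regs[ri]):
                new_regions.append(ri)

        # division: a remaining new region next to a track whose matched
        # region's mass dropped to ~half, with the two masses summing to the
        # parent's previous mass within tolerance
        divisions: list[tuple[int, int, int]] = []  # (ti, ri_matched, ri_new)
        used_new: set[int] = set()
        lo, hi = 0.5 - division_mass_tolerance, 0.5 + division_mass_tolerance
        for ri in new_regions:
            reg = regs[ri]
            best = None
            for ti, tr in enumerate(track_list):
                if ti not in track_match or tr.n_frames < 3:
                    continue
                r0, c0 = tr.centroids[-1]
                d = np.hypot(reg.row - r0, reg.col - c0)
                if d > maxdisp_px:
                    continue
                sib = regs[track_match[ti]]
                parent_mass = tr.masses[-1]
                total = reg.mass_pg + sib.mass_pg
                if abs(total - parent_mass) > division_mass_tolerance * parent_mass:
                    continue
                # both daughters must look like halves, not a merge/split artifact
                if not (lo <= reg.mass_pg / parent_mass <= hi
                        and lo <= sib.mass_pg / parent_mass <= hi):
                    continue
                if best is None or d < best[0]:
                    best = (d, ti)
            if best is not None and best[1] not in {ti for ti, _, _ in divisions}:
                divisions.append((best[1], track_match[best[1]], ri))
                used_new.add(ri)

        ended: list[CellTrack] = []
        for ti, tr in enumerate(track_list):
            if tr.track_id not in active:
                continue  # already resumed this frame
            if any(div_ti == ti for div_ti, _, _ in divisions):
                div = next(dv for dv in divisions if dv[0] == ti)
                tr.fate = FATE_DIVIDED
                tr.division_time = t
                d1 = new_track(fi, t, regs[div[1]], parent_id=tr.track_id)
                d2 = new_track(fi, t, regs[div[2]], parent_id=tr.track_id)
                tr.daughter_ids = (d1.track_id, d2.track_id)
                del active[tr.track_id]
                active[d1.track_id] = d1
                active[d2.track_id] = d2
            elif ti in track_match:
                reg = regs[track_match[ti]]
                ratio = reg.mass_pg / tr.masses[-1]
                if ratio < 0.6 or ratio > 1.5:
                    # abrupt mass halving (missed division / segmentation
                    # failure) or jump (merge with a neighbor): end the track
                    # rather than corrupt its growth fit
                    tr.fate = FATE_CENSORED
                    del active[tr.track_id]
                    recently_ended.append(tr)
                    if not try_resume(reg):
                        nt = new_track(fi, t, reg)
                        active[nt.track_id] = nt
                else:
                    tr.append(fi, t, int(reg.label), (reg.row, reg.col), float(reg.mass_pg))
            else:
                ended.append(tr)

        for tr in ended:
            r0, c0 = tr.centroids[-1]
            near_border = (
                min(r0, shape[0] - 1 - r0, c0, shape[1] - 1 - c0) <= maxdisp_px
            )
            tr.fate = FATE_LEFT_FRAME if near_border else FATE_CENSORED
            del active[tr.track_id]
            if not near_border:
                recently_ended.append(tr)

        for ri in new_regions:
            if ri not in used_new:
                tr = new_track(fi, t, regs[ri])
                active[tr.track_id] = tr

    # tracks alive at the last frame remain censored (default fate)
    return tracks


def specific_growth_rate(track: CellTrack) -> float:
    """Least-squares slope of mass vs time divided by the track's mean mass (1/h)."""
    if track.n_frames < 3:
        raise InsufficientDataError(
            f"track {track.track_id} has {track.n_frames} frames; need >= 3"
        )
    t = np.asarray(track.times)
    m = np.asarray(track.masses)
    slope = np.polyfit(t, m, 1)[0]
    return float(slope / m.mean())


def cytokinesis_fraction(
    tracks: list[CellTrack],
    max_doubling: float = 40.0,
    min_observation: float = 30.0,
) -> float:
    """Percent of evaluable cells that divide within the expected doubling time.

    A track enters the denominator if it divided, or was observed for at
    least ``min_observation`` hours; tracks leaving the field earlier are
    omitted.  The numerator counts tracks whose division occurred less than
    ``max_doubling`` hours after first observation.
    """
    denom = [
        tr
        for tr in tracks
        if tr.fate == FATE_DIVIDED or tr.duration >= min_observation
    ]
    if not denom:
        raise InsufficientDataError("no evaluable tracks for cytokinesis fraction")
    num = sum(
        1
        for tr in denom
        if tr.division_age is not None and tr.division_age < max_doubling
    )
    return 100.0 * num / len(denom)


def normalize_daughter_masses(
    lineage: LineageRecord,
) -> tuple[np.ndarray, np.ndarray]:
    """Each daughter's mass series divided by its mass at birth (first frame)."""
    out = []
    for d in lineage.daughters:
        if d.n_frames == 0:
            raise InputError("daughter track is empty")
        m = np.asarray(d.masses, dtype=float)
        if m[0] <= 0:
            raise InputError(f"daughter track {d.track_id} has non-positive birth mass")
        out.append(m / m[0])
    return out[0], out[1]


def build_lineages(
    tracks: list[CellTrack],
    punctae_frames: dict[int, list[bool]] | None = None,
    inheritance_window: int = 3,
) -> list[LineageRecord]:
    """Assemble parent/daughter lineage records from tracked divisions.

    ``punctae_frames`` maps track_id to a per-frame donor-punctae detection
    flag; a daughter is marked as inheriting if punctae are detected in any
    of its first ``inheritance_window`` frames.
    """
    by_id = {tr.track_id: tr for tr in tracks}
    records = []
    for tr in tracks:
        if tr.daughter_ids is None:
            continue
        daughters = (by_id[tr.daughter_ids[0]], by_id[tr.daughter_ids[1]])
        inh = [False, False]
        if punctae_frames is not None:
            for i, d in enumerate(daughters):
                flags = punctae_frames.get(d.track_id, [])
                inh[i] = any(flags[:inheritance_window])
        records.append(LineageRecord(parent=tr, daughters=daughters, inheritance=(inh[0], inh[1])))
    return records
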