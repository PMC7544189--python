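"""Linking of per-frame protrusion instances into tracks and event calling.

Four fundamental events are read off each track relative to the recording
window: *formation* (de novo appearance), *elimination* (complete
disappearance), *lability* (appearance and disappearance within the
recording) and *motility* (partial extension or retraction of a persisting
protrusion). Formation, elimination and lability are mutually exclusive per
track; motility is an independent flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from protrudyn.errors import ClassificationError, InternalError
from protrudyn.protdetect import ProtrusionInstance

__all__ = [
    "ProtrusionTrack",
    "EventLog",
    "link_tracks",
    "classify_track",
    "aggregate_events",
]

CATEGORIES = ("stable", "formed", "eliminated", "labile")


@dataclass
class ProtrusionTrack:
    """One protrusion followed over time."""

    track_id: int
    instances: dict[int, ProtrusionInstance] = field(default_factory=dict)
    lengths_um: dict[int, float] = field(default_factory=dict)  # incl. bridged
    base_positions_um: dict[int, float] = field(default_factory=dict)
    category: str | None = None
    motile: bool | None = None
    n_extensions: int = 0
    n_retractions: int = 0

    @property
    def first_frame(self) -> int:
        return min(self.lengths_um)

    @property
    def last_frame(self) -> int:
        return max(self.lengths_um)

    def length_series(self) -> tuple[np.ndarray, np.ndarray]:
        """(frames, lengths) over the contiguous track span."""
        frames = np.array(sorted(self.lengths_um))
        return frames, np.array([self.lengths_um[f] for f in frames])

    def mean_length_um(self) -> float:
        return float(np.mean(list(self.lengths_um.values())))


@dataclass
class EventLog:
    """Per-segment event counts over one recording."""

    n0: int  # protrusions present at frame 0
    n_end: int  # protrusions present at the last frame
    formed: int
    eliminated: int
    labile: int
    motile: int
    recording_duration_min: float

    def __post_init__(self) -> None:
        for name in ("n0", "n_end", "formed", "eliminated", "labile", "motile"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_end != self.n0 - self.eliminated + self.formed:
            raise InternalError(
                "event bookkeeping violated N_end = N0 - E + F: "
                f"{self.n_end} != {self.n0} - {self.eliminated} + {self.formed}"
            )


def link_tracks(
    instances_per_frame: list[list[ProtrusionInstance]],
    linkage_radius_um: float = 1.0,
    max_gap_frames: int = 1,
) -> list[ProtrusionTrack]:
    """Greedy nearest-base linking with gap closing.

    Frame by frame, each instance is matched to the open track whose last
    base position (along the shaft centerline) is nearest, provided the
    distance is within ``linkage_radius_um``; matches are assigned greedily
    in order of increasing distance, with ties broken by (track id, instance
    id) so linking is deterministic. Unmatched instances start new tracks. A
    track unmatched for more than ``max_gap_frames`` consecutive frames is
    terminated; shorter dropouts are bridged by linear interpolation of the
    length series so every track spans a contiguous frame range.
    """
    tracks: list[ProtrusionTrack] = []
    open_tracks: list[ProtrusionTrack] = []
    next_id = 0
    for frame, instances in enumerate(instances_per_frame):
        # candidate (distance, track, instance) pairs within the radius
        pairs = []
        for track in open_tracks:
            pos = track.base_positions_um[track.last_frame]
            for inst in instances:
                d = abs(inst.base_position_um - pos)
                if d <= linkage_radius_um:
                    pairs.append((d, track.track_id, inst.instance_id, track, inst))
        pairs.sort(key=lambda p: (p[0], p[1], p[2]))
        matched_tracks: set[int] = set()
        matched_instances: set[int] = set()
        for d, tid, iid, track, inst in pairs:
            if tid in matched_tracks or iid in matched_instances:
                continue
            matched_tracks.add(tid)
            matched_instances.add(iid)
            track.instances[frame] = inst
            track.lengths_um[frame] = inst.length_um
            track.base_positions_um[frame] = inst.base_position_um
        for inst in instances:
            if inst.instance_id in matched_instances:
                continue
            track = ProtrusionTrack(track_id=next_id)
            next_id += 1
            track.instances[frame] = inst
            track.lengths_um[frame] = inst.length_um
            track.base_positions_um[frame] = inst.base_position_um
            open_tracks.append(track)
        # close tracks that exceeded the gap allowance
        still_open = []
        for track in open_tracks:
            if frame - track.last_frame > max_gap_frames:
                tracks.append(track)
            else:
                still_open.append(track)
        open_tracks = still_open
    tracks.extend(open_tracks)
    for track in tracks:
        _bridge_gaps(track)
    tracks.sort(key=lambda t: t.track_id)
    return tracks


def _bridge_gaps(track: ProtrusionTrack) -> None:
    """Fill missing frames inside the span by linear interpolation."""
    frames = sorted(track.lengths_um)
    for a, b in zip(frames[:-1], frames[1:]):
        for f in range(a + 1, b):
            w = (f - a) / (b - a)
            track.lengths_um[f] = (1 - w) * track.lengths_um[a] + w * track.lengths_um[b]
            track.base_positions_um[f] = (
                (1 - w) * track.base_positions_um[a] + w * track.base_positions_um[b]
            )


def classify_track(
    track: ProtrusionTrack,
    n_frames: int,
    motility_threshold_um: float = 0.25,
) -> ProtrusionTrack:
    """Assign the event category and the motility flag.

    * present at frame 0 and the last frame → ``stable``
    * absent at 0, present at the last frame → ``formed``
    * present at 0, absent at the last frame → ``eliminated``
    * absent at both → ``labile``

    Independently, the track is *motile* if any consecutive-frame length
    change of at least ``motility_threshold_um`` occurs while the protrusion
    persists (its appearance and disappearance do not count). The numbers of
    such extensions and retractions are recorded.
    """
    if not track.lengths_um:
        raise ClassificationError(f"track {track.track_id} has no instances")
    at_start = track.first_frame == 0
    at_end = track.last_frame == n_frames - 1
    if at_start and at_end:
        track.category = "stable"
    elif at_end:
        track.category = "formed"
    elif at_start:
        track.category = "eliminated"
    else:
        track.category = "labile"
    frames, lengths = track.length_series()
    deltas = np.diff(lengths)
    track.n_extensions = int(np.sum(deltas >= motility_threshold_um))
    track.n_retractions = int(np.sum(deltas <= -motility_threshold_um))
    track.motile = (track.n_extensions + track.n_retractions) > 0
    return track


def aggregate_events(
    tracks: list[ProtrusionTrack],
    n_frames: int,
    frame_interval_s: float = 5.0,
) -> EventLog:
    """Count N0, N_end, F, E, L and M over classified tracks.

    The conservation identity ``N_end = N0 - E + F`` is asserted; a violation
    indicates a linking or classification bug.
    """
    for track in tracks:
        if track.category is None:
            raise ClassificationError(
                f"track {track.track_id} has not been classified"
            )
    n0 = sum(t.first_frame == 0 for t in tracks)
    n_end = sum(t.last_frame == n_frames - 1 for t in tracks)
    counts = {c: sum(t.category == c for t in tracks) for c in CATEGORIES}
    return EventLog(
        n0=n0,
        n_end=n_end,
        formed=counts["formed"],
        eliminated=counts["eliminated"],
        labile=counts["labile"],
        motile=sum(bool(t.motile) for t in tracks),
        recording_duration_min=(n_frames - 1) * frame_interval_s / 60.0,
    )
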