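"""Synthetic dendrite-segment time-lapses with known ground truth.

Real recordings of this kind image a membrane-labelled dendrite segment every
few seconds for several minutes; protrusions appear, disappear, flicker in
and out, and partially extend or retract. The simulator draws a stochastic
event schedule for a population of protrusions on a straight horizontal
shaft, then renders each frame as a microscopy-like image: binary geometry
convolved with a Gaussian point-spread function, scaled to a signal level
over a background, with Poisson shot noise and Gaussian read noise.

Because the schedule is known exactly, the rendered stacks provide ground
truth for validating detection, tracking, event classification and the
derived dynamics metrics.

Modelling choices (the data this emulates, and what it does not):

* protrusions are straight segments normal to a straight shaft — only length
  and presence are quantified downstream, not curvature;
* formation and lability events arrive as homogeneous Poisson processes;
* motility is a bounded random walk on length with a fixed step;
* rendering is 2-D (post-projection); no z-stack or 3-D PSF is simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from protrudyn.errors import ConfigurationError, RenderingError
from protrudyn.imgpipe import TimelapseStack
from protrudyn.protrack import EventLog
from protrudyn.dynmetrics import DynamicsMetrics, compute_metrics

__all__ = [
    "SimulationConfig",
    "TrackTruth",
    "SimulationTruth",
    "sample_schedule",
    "render_timelapse",
    "simulate",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Geometry, acquisition, event rates and noise of one simulation.

    Defaults follow the acquisition conditions the pipeline targets: one
    frame every 5 s for 10 min (121 frames), 0.06 µm/px, a ~70 µm dendrite
    segment, and protrusions gated to 0.4–10 µm. Event-rate defaults describe
    a moderately dynamic segment (a handful of formations/eliminations and a
    couple of labile protrusions over 10 min, about half of the persisting
    protrusions motile).
    """

    # geometry, µm
    segment_length_um: float = 70.0
    shaft_width_um: float = 1.5
    protrusion_width_um: float = 0.3
    protrusion_length_range_um: tuple[float, float] = (0.4, 10.0)
    length_sampling_range_um: tuple[float, float] = (1.0, 4.0)
    min_base_spacing_um: float = 2.0
    margin_um: float = 1.0
    fov_shape: tuple[int, int] | None = None  # (ny, nx) px; auto when None

    # acquisition
    pixel_size_um: float = 0.06
    frame_interval_s: float = 5.0
    n_frames: int = 121

    # event schedule
    n_initial_protrusions: int = 15
    formation_rate_per_min: float = 0.3
    formation_count: int | None = None  # exact override of the Poisson draw
    elimination_count: int = 2
    lability_rate_per_min: float = 0.2
    lability_count: int | None = None  # exact override of the Poisson draw
    labile_lifetime_range_min: tuple[float, float] = (1.0, 3.0)
    motility_fraction: float = 0.5
    motility_step_um: float = 0.5
    motility_move_prob: float = 0.15  # per frame interval, for motile tracks
    min_visible_frames: int = 6  # shortest lifetime an event leaves visible

    # optics and noise
    psf_sigma_um: float = 0.15
    background_level: float = 20.0
    signal_level: float = 200.0
    shot_noise: bool = True
    read_noise_sigma: float = 2.0

    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "segment_length_um",
            "shaft_width_um",
            "protrusion_width_um",
            "pixel_size_um",
            "frame_interval_s",
            "min_base_spacing_um",
            "motility_step_um",
            "psf_sigma_um",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.n_frames < 2:
            raise ConfigurationError("n_frames must be >= 2")
        lo, hi = self.protrusion_length_range_um
        if not (0 < lo < hi):
            raise ConfigurationError("protrusion_length_range_um must be 0 < lo < hi")
        slo, shi = self.length_sampling_range_um
        if not (lo <= slo <= shi <= hi):
            raise ConfigurationError(
                "length_sampling_range_um must lie within protrusion_length_range_um"
            )
        llo, lhi = self.labile_lifetime_range_min
        if not (0 < llo <= lhi):
            raise ConfigurationError("labile_lifetime_range_min must be 0 < lo <= hi")
        if lhi >= self.duration_min:
            raise ConfigurationError(
                "labile lifetimes must be shorter than the recording"
            )
        if not 0 <= self.motility_fraction <= 1:
            raise ConfigurationError("motility_fraction must be in [0, 1]")
        if self.elimination_count > self.n_initial_protrusions:
            raise ConfigurationError(
                "cannot eliminate more protrusions than initially present"
            )
        for name in ("formation_rate_per_min", "lability_rate_per_min"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")

    @property
    def duration_min(self) -> float:
        return (self.n_frames - 1) * self.frame_interval_s / 60.0


@dataclass
class TrackTruth:
    """Ground truth for one simulated protrusion."""

    track_id: int
    birth_frame: int
    death_frame: int | None  # first absent frame; None if alive at the end
    base_position_um: float  # along the shaft, from its left end
    side: int  # +1 below the shaft, -1 above
    motile: bool
    lengths_um: np.ndarray  # per frame, NaN when absent

    def alive(self, frame: int) -> bool:
        return self.birth_frame <= frame and (
            self.death_frame is None or frame < self.death_frame
        )

    def last_live_span(self) -> int:
        """Number of frames the protrusion is present."""
        return int(np.count_nonzero(~np.isnan(self.lengths_um)))


@dataclass
class SimulationTruth:
    """Complete ground truth of one simulated recording."""

    config: SimulationConfig
    tracks: list[TrackTruth] = field(default_factory=list)

    def event_log(self) -> EventLog:
        """The true event counts implied by the schedule."""
        n_frames = self.config.n_frames
        n0 = sum(t.birth_frame == 0 for t in self.tracks)
        n_end = sum(t.alive(n_frames - 1) for t in self.tracks)
        formed = sum(
            t.birth_frame > 0 and t.death_frame is None for t in self.tracks
        )
        eliminated = sum(
            t.birth_frame == 0 and t.death_frame is not None for t in self.tracks
        )
        labile = sum(
            t.birth_frame > 0 and t.death_frame is not None for t in self.tracks
        )
        return EventLog(
            n0=n0,
            n_end=n_end,
            formed=formed,
            eliminated=eliminated,
            labile=labile,
            motile=sum(t.motile for t in self.tracks),
            recording_duration_min=self.config.duration_min,
        )

    def metrics(self) -> DynamicsMetrics:
        """The true per-segment dynamics metrics."""
        return compute_metrics(self.event_log(), self.config.segment_length_um)


def sample_schedule(config: SimulationConfig, seed: int | None = None) -> SimulationTruth:
    """Draw a stochastic event schedule from the configured rates.

    Initial protrusions are present at frame 0; ``elimination_count`` of them
    disappear at a uniform frame. Formation and lability events arrive as
    homogeneous Poisson processes over the recording (counts overridable for
    exact parameter-recovery experiments), with labile lifetimes uniform in
    ``labile_lifetime_range_min``. A configured fraction of the persisting
    protrusions performs a bounded ±``motility_step_um`` random walk on
    length. Deterministic for a fixed ``(config, seed)``.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    n_frames = config.n_frames
    last = n_frames - 1
    frames_per_min = 60.0 / config.frame_interval_s

    n_formed = (
        config.formation_count
        if config.formation_count is not None
        else int(rng.poisson(config.formation_rate_per_min * config.duration_min))
    )
    n_labile = (
        config.lability_count
        if config.lability_count is not None
        else int(rng.poisson(config.lability_rate_per_min * config.duration_min))
    )
    n_tracks = config.n_initial_protrusions + n_formed + n_labile

    positions = _base_positions(config, n_tracks, rng)
    sides = rng.choice([-1, 1], size=n_tracks)

    tracks: list[TrackTruth] = []
    tid = 0
    eliminated_ids = set(
        rng.choice(config.n_initial_protrusions, size=config.elimination_count, replace=False)
        if config.elimination_count
        else []
    )
    # events leave at least min_visible_frames of presence: a protrusion
    # living a single frame interval is not observable as a protrusion
    vis = min(config.min_visible_frames, last)
    for i in range(config.n_initial_protrusions):
        death = int(rng.integers(vis, n_frames)) if i in eliminated_ids else None
        tracks.append(_make_track(tid, 0, death, positions[tid], sides[tid], config, rng))
        tid += 1
    for _ in range(n_formed):
        birth = int(rng.integers(1, n_frames - vis + 1))
        tracks.append(_make_track(tid, birth, None, positions[tid], sides[tid], config, rng))
        tid += 1
    for _ in range(n_labile):
        llo, lhi = config.labile_lifetime_range_min
        lifetime = max(1, int(round(rng.uniform(llo, lhi) * frames_per_min)))
        lifetime = min(lifetime, last - 1)
        birth = int(rng.integers(1, last - lifetime + 1))
        tracks.append(
            _make_track(tid, birth, birth + lifetime, positions[tid], sides[tid], config, rng)
        )
        tid += 1

    # motility: a fraction of the protrusions persisting to the end
    persisting = [t for t in tracks if t.death_frame is None and t.last_live_span() >= 2]
    n_motile = int(round(config.motility_fraction * len(persisting)))
    if n_motile:
        chosen = rng.choice(len(persisting), size=n_motile, replace=False)
        for j in chosen:
            _apply_motility(persisting[j], config, rng)
    return SimulationTruth(config=config, tracks=tracks)


def _make_track(tid, birth, death, position, side, config, rng) -> TrackTruth:
    lengths = np.full(config.n_frames, np.nan)
    slo, shi = config.length_sampling_range_um
    length = float(rng.uniform(slo, shi))
    end = config.n_frames if death is None else death
    lengths[birth:end] = length
    return TrackTruth(
        track_id=tid,
        birth_frame=birth,
        death_frame=death,
        base_position_um=position,
        side=int(side),
        motile=False,
        lengths_um=lengths,
    )


def _base_positions(config: SimulationConfig, n: int, rng) -> np.ndarray:
    """Shuffled grid positions with guaranteed minimum spacing."""
    spacing = config.min_base_spacing_um
    usable = config.segment_length_um - 2 * spacing
    n_slots = int(usable // spacing) + 1
    if n_slots < n:
        raise ConfigurationError(
            f"segment too short for {n} protrusions at "
            f"{spacing} µm minimum spacing ({n_slots} slots)"
        )
    slots = spacing + np.arange(n_slots) * spacing
    # jitter kept small enough that adjacent bases stay > 0.7 * spacing
    # apart, preserving the separation the linker relies on
    jitter = rng.uniform(-0.15, 0.15, size=n_slots) * spacing
    chosen = rng.choice(n_slots, size=n, replace=False)
    return (slots + jitter)[chosen]


def _apply_motility(track: TrackTruth, config: SimulationConfig, rng) -> None:
    """Bounded random walk on length for one persisting track.

    The walk reflects at the configured sampling band, not at the full
    admissible length range: a partial retraction that carried the length to
    the detection gate would be indistinguishable from an elimination, so
    motile protrusions stay within the band the initial lengths are drawn
    from.
    """
    lo, hi = config.length_sampling_range_um
    live = np.flatnonzero(~np.isnan(track.lengths_um))
    length = track.lengths_um[live[0]]
    moves = rng.random(live.size - 1) < config.motility_move_prob
    if not moves.any():  # a motile track must move at least once
        moves[rng.integers(0, moves.size)] = True
    signs = rng.choice([-1.0, 1.0], size=live.size - 1)
    for k, frame in enumerate(live[1:]):
        if moves[k]:
            step = signs[k] * config.motility_step_um
            if not lo <= length + step <= hi:
                step = -step  # reflect at the length bounds
            length = float(np.clip(length + step, lo, hi))
        track.lengths_um[frame] = length
    track.motile = True


# ---------------------------------------------------------------------------
# rendering


def render_timelapse(truth: SimulationTruth, config: SimulationConfig | None = None) -> TimelapseStack:
    """Render the schedule to a noisy, calibrated (t, y, x) stack.

    Each frame draws the shaft as a horizontal ribbon and every live
    protrusion as a line of its true length normal to the shaft, convolves
    with a Gaussian PSF, rescales so that the noiseless peak equals
    ``signal_level`` over ``background_level``, and adds Poisson shot noise
    plus Gaussian read noise. The noise stream is independent of the schedule
    stream but derived from the same seed.
    """
    if config is None:
        config = truth.config
    px = config.pixel_size_um
    ny, nx = _canvas_shape(truth, config)
    margin_px = int(round(config.margin_um / px))
    cy = ny // 2
    shaft_half = max(1, int(round(config.shaft_width_um / (2 * px))))
    half_w = max(0, int(round(config.protrusion_width_um / (2 * px))))
    x0 = margin_px
    x1 = x0 + int(round(config.segment_length_um / px))
    if x1 > nx:
        raise RenderingError("segment does not fit the field of view")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    psf_sigma_px = config.psf_sigma_um / px
    frames = np.empty((config.n_frames, ny, nx))
    for t in range(config.n_frames):
        geom = np.zeros((ny, nx), dtype=float)
        geom[cy - shaft_half : cy + shaft_half + 1, x0:x1] = 1.0
        for track in truth.tracks:
            if not track.alive(t):
                continue
            _draw_protrusion(geom, track, t, config, cy, shaft_half, half_w, x0)
        blurred = ndi.gaussian_filter(geom, sigma=psf_sigma_px, mode="constant")
        peak = blurred.max()
        if peak > 0:
            blurred /= peak
        frame = config.background_level + config.signal_level * blurred
        if config.shot_noise:
            frame = rng.poisson(frame).astype(float)
        if config.read_noise_sigma > 0:
            frame = frame + rng.normal(0.0, config.read_noise_sigma, size=frame.shape)
        frames[t] = np.clip(frame, 0.0, None)
    return TimelapseStack(
        data=frames, pixel_size=px, frame_interval=config.frame_interval_s
    )


def _canvas_shape(truth: SimulationTruth, config: SimulationConfig) -> tuple[int, int]:
    if config.fov_shape is not None:
        return config.fov_shape
    px = config.pixel_size_um
    max_len = config.length_sampling_range_um[1]
    for track in truth.tracks:
        finite = track.lengths_um[~np.isnan(track.lengths_um)]
        if finite.size:
            max_len = max(max_len, float(finite.max()))
    half = max_len + config.shaft_width_um / 2 + 3 * config.psf_sigma_um + config.margin_um
    ny = 2 * int(math.ceil(half / px)) + 1
    nx = int(round(config.segment_length_um / px)) + 2 * int(round(config.margin_um / px))
    return ny, nx


def _draw_protrusion(geom, track, t, config, cy, shaft_half, half_w, x0) -> None:
    px = config.pixel_size_um
    length_px = int(round(track.lengths_um[t] / px))
    bx = x0 + int(round(track.base_position_um / px))
    edge = cy + track.side * shaft_half
    tip = edge + track.side * length_px
    if not (0 <= tip < geom.shape[0]) or not (0 <= bx < geom.shape[1]):
        raise RenderingError(
            f"track {track.track_id} leaves the field of view at frame {t}"
        )
    y_lo, y_hi = sorted((edge, tip))
    geom[y_lo : y_hi + 1, max(0, bx - half_w) : bx + half_w + 1] = 1.0


def simulate(
    config: SimulationConfig, seed: int | None = None
) -> tuple[TimelapseStack, SimulationTruth]:
    """Sample a schedule and render it; the composition of the two stages."""
    if seed is not None:
        config = replace(config, seed=int(seed))
    truth = sample_schedule(config, config.seed)
    stack = render_timelapse(truth, config)
    return stack, truth
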