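"""Synthetic time-lapse stacks and optical-trap bead traces with known ground truth.

The generators emulate the statistical structure the downstream estimators
assume — a lamellipodial leading edge undergoing sawtooth protrusion/retraction
cycles with retrograde-moving internal texture and a vertical lift during
retraction, thin elongating filopodial rods, and trapped-bead traces with
nanopositioner feedback recentering — so that every analysis stage can be
validated by parameter recovery without any experimental recording.

Scene model for the lamellipodium stack (per frame, per imaged height H):

* **bulk** — the thick cell body / proximal lamellipodium at height 0. Always
  visible (its contrast attenuates but never vanishes with defocus), carrying
  dark texture dips that translate rearward at the retrograde rate during
  retraction; these produce the sloped dark kymograph streaks.
* **sheet band** — a thin phase-object strip behind the rim at the edge's
  current height ``h_e(t)``. Its intensity equalises with the background when
  the imaging plane matches its height and deviates increasingly with
  defocus; this is what the defocus-based height analysis counts.
* **rim** — a dense, always-visible strip at the very leading edge, also at
  ``h_e(t)``. It keeps the edge trackable in the height-0 plane at every
  cycle phase; its outer boundary is the ground-truth edge position.

All three layers vary only along the protrusion axis (columns), so frames are
rendered as 1-D profiles broadcast across rows, plus i.i.d. Gaussian pixel
noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "MotilityParams",
    "ImagingConfig",
    "ImageStackSequence",
    "BeadEvent",
    "BeadSimConfig",
    "BeadTrace",
    "FilopodiumGroundTruth",
    "generate_lamellipodium_stack",
    "generate_bead_trace",
    "generate_filopodium_tracks",
    "trapezoid_lift",
]

# Rendering constants (intensity units relative to background; px = pixel).
BULK_CONTRAST = 80.0
BAND_CONTRAST = 60.0
RIM_CONTRAST = 120.0  # actin-dense edge bundle: brightest structure in phase contrast
RIM_WIDTH_UM = 0.2
BAND_WIDTH_UM = 1.0
BASE_FRACTION = 0.30  # cell occupies ~1/3 of the field so the plane median is background
TEXTURE_DEPTH = 0.5
TEXTURE_SIGMA_UM = 0.15
TEXTURE_SPACING_UM = 1.2
ATTENUATION_PER_UM = 0.05  # mild contrast loss ~ 1/(1 + a*|defocus|); the thick
# bulk stays well above background across the whole height range
BAND_DEFOCUS_SCALE_UM = 1.0  # band contrast ~ 1 - exp(-|defocus|/scale)


def trapezoid_lift(peak_um: float = 5.0) -> Callable[[float, float], float]:
    """Vertical lift of the leading edge during retraction.

    Returns ``h(phase, retraction_start_phase)``: zero throughout protrusion,
    rising over the first part of the retraction, holding a plateau at
    ``peak_um`` near the end of the retraction (where lamellipodia reach their
    maximal height) and returning to zero at the cycle boundary.
    """

    def lift(phase: float, phi_r: float) -> float:
        if phase < phi_r or phi_r >= 1.0:
            return 0.0
        u = (phase - phi_r) / (1.0 - phi_r)  # position within the retraction
        if u < 0.2:
            return 0.0
        if u < 0.5:
            return peak_um * (u - 0.2) / 0.3
        if u < 0.9:
            return peak_um
        return peak_um * (1.0 - u) / 0.1

    return lift


@dataclass
class MotilityParams:
    """Ground-truth parameters of the sawtooth protrusion/retraction cycle.

    ``protrude_rate_um_s`` may be left ``None``; it is then derived so one
    full protrusion plus one retraction lasts exactly ``period_s``.
    """

    period_s: float = 86.5
    persistence_um: float = 1.48
    retro_rate_um_s: float = 0.08
    protrude_rate_um_s: float | None = None
    lift_profile: Callable[[float, float], float] | None = field(
        default_factory=trapezoid_lift
    )
    n_cycles: int = 5
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period_s <= 0:
            raise ValueError("period_s must be positive")
        if self.persistence_um <= 0:
            raise ValueError("persistence_um must be positive")
        if self.retro_rate_um_s < 0:
            raise ValueError("retro_rate_um_s must be non-negative")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.retro_rate_um_s > 0:
            t_r = self.persistence_um / self.retro_rate_um_s
            if t_r >= self.period_s:
                raise ValueError(
                    "retraction alone would exceed the period; "
                    "increase period_s or retro_rate_um_s"
                )
            derived = self.persistence_um / (self.period_s - t_r)
        else:
            derived = self.persistence_um / self.period_s
        if self.protrude_rate_um_s is None:
            self.protrude_rate_um_s = derived
        elif not np.isclose(self.protrude_rate_um_s, derived, rtol=1e-6):
            raise ValueError(
                f"protrude_rate_um_s={self.protrude_rate_um_s} inconsistent with "
                f"period/persistence/retro rate (expected {derived:.6g})"
            )

    @property
    def protrusion_time_s(self) -> float:
        return self.persistence_um / self.protrude_rate_um_s

    def edge_position(self, t_s: float) -> float:
        """Analytic sawtooth edge excursion (μm, 0 at each cycle minimum)."""
        tau = t_s % self.period_s
        tp = self.protrusion_time_s
        if tau <= tp:
            return self.protrude_rate_um_s * tau
        return self.persistence_um - self.retro_rate_um_s * (tau - tp)

    def edge_height(self, t_s: float) -> float:
        """True vertical position (μm) of the edge at time ``t_s``."""
        if self.lift_profile is None:
            return 0.0
        phase = (t_s % self.period_s) / self.period_s
        phi_r = self.protrusion_time_s / self.period_s
        return float(self.lift_profile(phase, phi_r))

    def texture_shift(self, t_s: float) -> float:
        """Cumulative rearward translation (μm) of internal features.

        Features move rearward at the retrograde rate during retraction and
        stand still during protrusion.
        """
        k, tau = divmod(t_s, self.period_s)
        tp = self.protrusion_time_s
        within = 0.0 if tau <= tp else self.retro_rate_um_s * (tau - tp)
        return k * self.persistence_um + within


@dataclass
class ImagingConfig:
    """Acquisition geometry of the phase-contrast Z-stack movie."""

    pixel_um: float = 0.1
    frame_interval_s: float = 5.0
    heights_um: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
    image_shape: tuple[int, int] = (80, 160)
    background_level: float = 100.0
    defocus_blur_per_um: float = 0.3  # Gaussian sigma in px per μm of defocus

    def __post_init__(self) -> None:
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be positive")
        if not 1.0 <= self.frame_interval_s <= 10.0:
            raise ValueError("frame_interval_s must lie in [1, 10] s")
        if len(self.heights_um) == 0:
            raise ValueError("heights_um must not be empty")
        if 0.0 not in self.heights_um:
            raise ValueError("heights_um must include the coverslip plane (0)")

    @property
    def width_um(self) -> float:
        return self.image_shape[1] * self.pixel_um


@dataclass
class ImageStackSequence:
    """Time-ordered per-height image planes plus optional ground truth.

    ``frames[t][h]`` is the plane imaged at ``config.heights_um[h]`` at frame
    ``t``; all planes share ``config.image_shape``.
    """

    frames: list[dict[float, np.ndarray]]
    config: ImagingConfig
    ground_truth: "StackGroundTruth | None" = None

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.config.frame_interval_s

    def planes_at(self, height_um: float) -> np.ndarray:
        """(T, rows, cols) movie for a single height."""
        return np.stack([f[height_um] for f in self.frames])


@dataclass
class StackGroundTruth:
    params: MotilityParams
    base_um: float
    true_edge_um: np.ndarray  # outer edge position along the axis, per frame
    true_height_um: np.ndarray  # vertical edge position, per frame


def _interval_coverage(lo: float, hi: float, n: int, pixel: float) -> np.ndarray:
    """Fraction of each pixel [j*p, (j+1)*p) covered by the interval [lo, hi)."""
    j = np.arange(n)
    left = j * pixel
    right = left + pixel
    return np.clip(
        (np.minimum(right, hi) - np.maximum(left, lo)) / pixel, 0.0, 1.0
    )


class _Texture:
    """Smooth dark dips at random positions, evaluated on a moving coordinate."""

    def __init__(self, rng: np.random.Generator, domain_um: float) -> None:
        n = max(3, int(domain_um / TEXTURE_SPACING_UM))
        self.centers = np.sort(rng.uniform(0.0, domain_um, size=n))

    def __call__(self, x_um: np.ndarray) -> np.ndarray:
        out = np.zeros_like(x_um)
        for c in self.centers:
            out += np.exp(-0.5 * ((x_um - c) / TEXTURE_SIGMA_UM) ** 2)
        return np.clip(out, 0.0, 1.0)


def generate_lamellipodium_stack(
    params: MotilityParams, config: ImagingConfig
) -> ImageStackSequence:
    """Render the synthetic protrusion/retraction movie.

    Returns a stack whose height-0 plane shows a bright cell with a crisp
    leading edge following the analytic sawtooth, rearward-moving dark texture
    during retraction, and whose off-height planes show only defocused
    (blurred, attenuated) signal; the thin edge band equalises with the
    background in the plane matching its current height.
    """
    rng = np.random.default_rng(params.seed)
    rows, cols = config.image_shape
    pixel = config.pixel_um

    # Edge base: leave room on the cell side and beyond the maximal excursion.
    margin_um = 2.0
    base = BASE_FRACTION * config.width_um + rng.uniform(0.0, pixel)
    if base + params.persistence_um + margin_um >= config.width_um:
        raise ValueError(
            "persistence_um too large for the field of view "
            f"({params.persistence_um} μm vs width {config.width_um} μm)"
        )

    n_frames = int(np.ceil(params.n_cycles * params.period_s / config.frame_interval_s))
    total_shift = params.n_cycles * params.persistence_um
    texture = _Texture(rng, config.width_um + total_shift + 2.0)

    x = (np.arange(cols) + 0.5) * pixel
    frames: list[dict[float, np.ndarray]] = []
    true_edge = np.empty(n_frames)
    true_height = np.empty(n_frames)

    for ti in range(n_frames):
        t = ti * config.frame_interval_s
        edge = base + params.edge_position(t)
        h_e = params.edge_height(t)
        shift = params.texture_shift(t)
        true_edge[ti] = edge
        true_height[ti] = h_e

        bulk_hi = edge - RIM_WIDTH_UM - BAND_WIDTH_UM
        bulk_cov = _interval_coverage(-1.0, bulk_hi, cols, pixel)
        band_cov = _interval_coverage(bulk_hi, edge - RIM_WIDTH_UM, cols, pixel)
        rim_cov = _interval_coverage(edge - RIM_WIDTH_UM, edge, cols, pixel)
        dips = texture(x + shift)

        plane_set: dict[float, np.ndarray] = {}
        for H in config.heights_um:
            d_bulk = abs(H)  # bulk sits at height 0
            d_edge = abs(H - h_e)  # rim and band at the edge height
            bulk_dev = (
                BULK_CONTRAST
                / (1.0 + ATTENUATION_PER_UM * d_bulk)
                * bulk_cov
                * (1.0 - TEXTURE_DEPTH * dips)
            )
            band_dev = (
                BAND_CONTRAST
                * (1.0 - np.exp(-d_edge / BAND_DEFOCUS_SCALE_UM))
                * band_cov
            )
            # Dense rim: defocus blurs it but does not bleach its halo contrast.
            rim_dev = RIM_CONTRAST * rim_cov

            sig_bulk = config.defocus_blur_per_um * d_bulk
            sig_edge = config.defocus_blur_per_um * d_edge
            if sig_bulk > 0:
                bulk_dev = gaussian_filter1d(bulk_dev, sig_bulk)
            if sig_edge > 0:
                band_dev = gaussian_filter1d(band_dev, sig_edge)
                rim_dev = gaussian_filter1d(rim_dev, sig_edge)

            profile = config.background_level + bulk_dev + band_dev + rim_dev
            plane = np.broadcast_to(profile, (rows, cols)).copy()
            if params.noise_sd > 0:
                plane += rng.normal(0.0, params.noise_sd, size=(rows, cols))
            plane_set[H] = plane
        frames.append(plane_set)

    gt = StackGroundTruth(
        params=params, base_um=base, true_edge_um=true_edge, true_height_um=true_height
    )
    return ImageStackSequence(frames=frames, config=config, ground_truth=gt)


# ---------------------------------------------------------------------------
# Optical-trap bead traces


_DIRECTIONS = {
    "+x": np.array([1.0, 0.0, 0.0]),
    "-x": np.array([-1.0, 0.0, 0.0]),
    "+y": np.array([0.0, 1.0, 0.0]),
    "-y": np.array([0.0, -1.0, 0.0]),
    "+z": np.array([0.0, 0.0, 1.0]),
    "-z": np.array([0.0, 0.0, -1.0]),
}


@dataclass
class BeadEvent:
    """One push/retraction episode driving the bead at constant speed."""

    start_s: float
    direction: str
    speed_nm_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"direction must be one of {sorted(_DIRECTIONS)}")
        if self.speed_nm_s < 0:
            raise ValueError("speed_nm_s must be non-negative")
        if self.duration_s < 0:
            raise ValueError("duration_s must be non-negative")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    @property
    def vector(self) -> np.ndarray:
        return _DIRECTIONS[self.direction]


@dataclass
class BeadSimConfig:
    """Trap, feedback and sampling parameters for the bead-trace simulation.

    Default stiffness is the experimental trap calibration
    (k_xy = 0.10, k_z = 0.08 pN/nm); the lateral feedback threshold defaults
    to the 200 nm linear range of the position detector. Thermal noise
    defaults to the equipartition scale sqrt(kB*T/k_xy) ≈ 6 nm.
    """

    stiffness_pn_nm: tuple[float, float] = (0.10, 0.08)
    feedback_threshold_nm: float = 200.0
    thermal_sd_nm: float = 6.0
    event_schedule: Sequence[BeadEvent] = ()
    sample_rate_hz: float = 20.0
    duration_s: float | None = None
    relax_tau_s: float = 0.25  # trap pulls the bead back once the obstacle leaves
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.stiffness_pn_nm) <= 0:
            raise ValueError("stiffness components must be positive")
        if self.feedback_threshold_nm <= 0:
            raise ValueError("feedback_threshold_nm must be positive")
        if self.thermal_sd_nm < 0:
            raise ValueError("thermal_sd_nm must be non-negative")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        self.event_schedule = [
            ev if isinstance(ev, BeadEvent) else BeadEvent(**ev)
            for ev in self.event_schedule
        ]
        events = sorted(self.event_schedule, key=lambda e: e.start_s)
        for a, b in zip(events, events[1:]):
            if b.start_s < a.end_s:
                raise ValueError("events must not overlap")
        if self.duration_s is None:
            last = max((e.end_s for e in events), default=5.0)
            self.duration_s = last + 5.0


@dataclass
class BeadTrace:
    """Synchronized QPD bead position, stage position and ground-truth force."""

    t_s: np.ndarray
    qpd_xyz_nm: np.ndarray  # (n, 3), bead position relative to trap centre
    stage_xy_nm: np.ndarray  # (n, 2), nanopositioner position
    config: BeadSimConfig
    ground_truth_force_pn: np.ndarray | None = None  # (n, 3)


def generate_bead_trace(config: BeadSimConfig) -> BeadTrace:
    """Simulate a trapped-bead recording with nanopositioner feedback.

    Between events the bead fluctuates about the trap centre; during an event
    it is driven at the scheduled speed. Whenever the recorded lateral
    displacement r = sqrt(x²+y²) exceeded the feedback threshold at the
    previous sample, the stage jumps so the bead returns to the trap centre
    (the axial direction is never recentered). The ground-truth force is
    stiffness × noiseless deflection.
    """
    rng = np.random.default_rng(config.seed)
    dt = 1.0 / config.sample_rate_hz
    n = int(np.round(config.duration_s * config.sample_rate_hz)) + 1
    t = np.arange(n) * dt

    velocity = np.zeros((n, 3))
    for ev in config.event_schedule:
        active = (t > ev.start_s) & (t <= ev.end_s + 0.5 * dt)
        velocity[active] += ev.speed_nm_s * ev.vector

    qpd_true = np.zeros((n, 3))
    qpd = np.zeros((n, 3))
    stage = np.zeros((n, 2))
    noise = (
        rng.normal(0.0, config.thermal_sd_nm, size=(n, 3))
        if config.thermal_sd_nm > 0
        else np.zeros((n, 3))
    )

    push = np.zeros(3)  # cumulative driven path of the obstacle
    offset = np.zeros(2)  # lateral recentering accumulated by the stage
    thr = config.feedback_threshold_nm
    decay = np.exp(-dt / config.relax_tau_s) if config.relax_tau_s > 0 else 0.0
    for i in range(n):
        if i > 0:
            driven = np.any(velocity[i] != 0)
            if driven:
                push += velocity[i] * dt
            else:
                # Obstacle gone: the trap relaxes the bead toward its centre
                # (deflection -> 0; the accumulated stage offset stays).
                push[:2] = offset + (push[:2] - offset) * decay
                push[2] *= decay
            # Recenter iff the *recorded* lateral excursion crossed the
            # threshold at the previous sample.
            if np.hypot(qpd[i - 1, 0], qpd[i - 1, 1]) > thr:
                offset = push[:2].copy()
        qpd_true[i, :2] = push[:2] - offset
        qpd_true[i, 2] = push[2]
        qpd[i] = qpd_true[i] + noise[i]
        stage[i] = -offset

    kxy, kz = config.stiffness_pn_nm
    gt_force = qpd_true * np.array([kxy, kxy, kz])
    return BeadTrace(
        t_s=t,
        qpd_xyz_nm=qpd,
        stage_xy_nm=stage,
        config=config,
        ground_truth_force_pn=gt_force,
    )


# ---------------------------------------------------------------------------
# Filopodia


@dataclass
class FilopodiumGroundTruth:
    """True geometry of one synthetic filopodium."""

    base_px: tuple[float, float]  # (row, col)
    angle_rad: float
    start_len_um: float
    rate_um_s: float
    max_len_um: float

    def length_at(self, t_s: float) -> float:
        return min(self.start_len_um + self.rate_um_s * t_s, self.max_len_um)

    def tip_at(self, t_s: float, pixel_um: float) -> tuple[float, float]:
        l_px = self.length_at(t_s) / pixel_um
        return (
            self.base_px[0] + l_px * np.sin(self.angle_rad),
            self.base_px[1] + l_px * np.cos(self.angle_rad),
        )


def _rod_image(
    shape: tuple[int, int],
    base: tuple[float, float],
    tip: tuple[float, float],
    amplitude: float,
    width_px: float = 1.0,
) -> np.ndarray:
    """Coverage-antialiased straight rod from base to tip (row, col coords)."""
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    b = np.asarray(base)
    v = np.asarray(tip) - b
    L2 = float(v @ v)
    if L2 == 0:
        d = np.hypot(rr - b[0], cc - b[1])
    else:
        s = np.clip(((rr - b[0]) * v[0] + (cc - b[1]) * v[1]) / L2, 0.0, 1.0)
        pr = b[0] + s * v[0]
        pc = b[1] + s * v[1]
        d = np.hypot(rr - pr, cc - pc)
    return amplitude * np.clip(width_px / 2 + 0.5 - d, 0.0, 1.0)


def generate_filopodium_tracks(
    n: int,
    rate_um_s: float,
    max_len_um: float,
    frame_interval_s: float,
    seed: int,
    *,
    start_len_um: float = 0.5,
    pixel_um: float = 0.1,
    image_shape: tuple[int, int] = (128, 128),
    amplitude: float = 60.0,
    background_level: float = 100.0,
    noise_sd: float = 2.0,
    n_frames: int | None = None,
    angles_rad: Sequence[float] | None = None,
    bases_px: Sequence[tuple[float, float]] | None = None,
) -> tuple[list[FilopodiumGroundTruth], np.ndarray]:
    """Render thin rods elongating from fixed bases at ``rate_um_s``.

    Returns the ground truths and a (T, rows, cols) height-0 image sequence.
    Rods grow linearly until ``max_len_um`` and then stop.
    """
    if rate_um_s < 0:
        raise ValueError("rate_um_s must be non-negative")
    if max_len_um <= 0:
        raise ValueError("max_len_um must be positive")
    if n < 1:
        raise ValueError("need at least one filopodium")
    rng = np.random.default_rng(seed)
    rows, cols = image_shape

    if n_frames is None:
        if rate_um_s > 0:
            grow_t = (max_len_um - start_len_um) / rate_um_s
            n_frames = int(np.ceil(grow_t / frame_interval_s)) + 4
        else:
            n_frames = 10

    # Default layout: bases on a small circle around the image centre, rods
    # radiating outward with angular jitter — distinct filopodia that never
    # merge, as around a growth-cone periphery. Explicit bases/angles allow
    # crossing-rod fixtures.
    hub = 6.0
    if bases_px is None:
        reach = hub + max_len_um / pixel_um + 6
        if reach > min(rows, cols) / 2:
            raise ValueError(
                f"max_len_um={max_len_um} does not fit in image_shape={image_shape}"
            )
    truths: list[FilopodiumGroundTruth] = []
    for i in range(n):
        theta = 2 * np.pi * i / n + rng.uniform(-0.2, 0.2)
        if angles_rad is not None:
            ang = float(angles_rad[i])
        else:
            ang = theta + rng.uniform(-0.2, 0.2)
        if bases_px is not None:
            base = tuple(map(float, bases_px[i]))
        else:
            base = (
                rows / 2 + hub * np.sin(theta),
                cols / 2 + hub * np.cos(theta),
            )
        truths.append(
            FilopodiumGroundTruth(
                base_px=base,
                angle_rad=ang,
                start_len_um=start_len_um,
                rate_um_s=rate_um_s,
                max_len_um=max_len_um,
            )
        )

    movie = np.empty((n_frames, rows, cols))
    for ti in range(n_frames):
        t = ti * frame_interval_s
        frame = np.full((rows, cols), background_level, dtype=float)
        for gt in truths:
            frame += _rod_image(image_shape, gt.base_px, gt.tip_at(t, pixel_um), amplitude)
        if noise_sd > 0:
            frame += rng.normal(0.0, noise_sd, size=(rows, cols))
        movie[ti] = frame
    return truths, movie
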