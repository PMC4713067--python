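"""Kymograph-based quantification of lamellipodial protrusion/retraction.

The pipeline is: difference-of-Gaussians (DoG) edge extraction on the
height-0 planes, leading-edge tracking along a sampling line, kymograph
construction, and the three cycle metrics — period ``T`` of the
protrusion/retraction cycle, persistence length ``dl`` (maximal excursion per
cycle before retraction starts) and retrograde flow rate ``dx/dt`` measured
from the slope of the dark streaks that retrograde-moving features leave in
the kymograph.

Positions are reported in μm, times in s, rates in μm/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from .synthetic import ImageStackSequence

__all__ = [
    "SamplingLine",
    "EdgeProfile",
    "Kymograph",
    "CycleMetrics",
    "NoCyclesError",
    "extract_edges",
    "dog_response",
    "track_leading_edge",
    "build_kymograph",
    "measure_period",
    "measure_persistence",
    "measure_retrograde_flow",
    "retraction_windows",
    "default_sampling_line",
    "analyze_stack",
]


class NoCyclesError(RuntimeError):
    """Raised when fewer than two protrusion/retraction cycles are detectable."""


@dataclass
class SamplingLine:
    """Line along which the kymograph is sampled.

    Endpoints are 0-based pixel coordinates ``(x=column, y=row)``. The first
    endpoint declares the cell-body side; "outermost" edge positions are
    measured away from it.
    """

    start_xy: tuple[float, float]
    end_xy: tuple[float, float]

    def __post_init__(self) -> None:
        if self.length_px < 20:
            raise ValueError("sampling line must be at least 20 px long")

    @property
    def length_px(self) -> float:
        dx = self.end_xy[0] - self.start_xy[0]
        dy = self.end_xy[1] - self.start_xy[1]
        return float(np.hypot(dx, dy))

    def sample_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) float coordinates at 1-px spacing along the line."""
        n = int(np.floor(self.length_px)) + 1
        s = np.arange(n) / max(n - 1, 1)
        cols = self.start_xy[0] + s * (self.end_xy[0] - self.start_xy[0])
        rows = self.start_xy[1] + s * (self.end_xy[1] - self.start_xy[1])
        return rows, cols

    def validate_inside(self, shape: tuple[int, int]) -> None:
        r, c = shape
        for x, y in (self.start_xy, self.end_xy):
            if not (0 <= x <= c - 1 and 0 <= y <= r - 1):
                raise ValueError(f"line endpoint {(x, y)} outside image {shape}")


@dataclass
class EdgeProfile:
    """Per-frame leading-edge position along a sampling line."""

    positions_um: np.ndarray
    times_s: np.ndarray
    interpolated: np.ndarray = field(default=None)  # bool mask of gap frames
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.interpolated is None:
            self.interpolated = np.zeros(len(self.positions_um), dtype=bool)

    @property
    def dt_s(self) -> float:
        return float(self.times_s[1] - self.times_s[0])


@dataclass
class Kymograph:
    """Space-time intensity matrix ``data[position_along_line, frame]``."""

    data: np.ndarray
    spatial_step_um: float
    time_step_s: float


@dataclass
class CycleMetrics:
    period_s: float
    persistence_um: float
    retro_rate_um_s: float
    n_cycles: int


def dog_response(frame: np.ndarray, sigma_small: float = 1.0, sigma_large: float = 3.0) -> np.ndarray:
    """Band-pass difference-of-Gaussians response of one image plane."""
    if sigma_small >= sigma_large:
        raise ValueError("sigma_small must be < sigma_large")
    f = np.asarray(frame, dtype=float)
    return ndimage.gaussian_filter(f, sigma_small) - ndimage.gaussian_filter(f, sigma_large)


def extract_edges(
    frame: np.ndarray,
    sigma_small: float = 1.0,
    sigma_large: float = 3.0,
    k: float = 2.0,
) -> np.ndarray:
    """Binary edge map: |DoG response| above ``k`` standard deviations.

    A constant image yields an empty map (zero response, zero threshold).
    """
    r = dog_response(frame, sigma_small, sigma_large)
    sd = r.std()
    if sd == 0:
        return np.zeros_like(r, dtype=bool)
    return np.abs(r) > k * sd


def _edge_position_on_line(
    response: np.ndarray, k: float = 2.0, support_px: int = 3
) -> float | None:
    """Outermost zero-crossing of the DoG response sampled along a line.

    An intensity edge produces a positive and a negative DoG lobe; the
    boundary is the sign change between them. A crossing is only accepted if
    both flanking lobes are significant (≥ k·sd on the approaching side,
    ≥ k·sd/2 on the far side, with opposite signs), which rejects sign flips
    in flat noise. The returned position (px from the line start, sub-pixel
    by linear interpolation) is the accepted crossing farthest from the
    cell-body end.
    """
    sd = response.std()
    if sd == 0:
        return None
    thr = k * sd
    sign = np.sign(response)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    best = None
    for i in idx:
        left = response[max(0, i - support_px) : i + 1]
        right = response[i + 1 : i + 1 + support_px]
        if len(right) == 0:
            continue
        descending = left.max() >= thr and right.min() <= -0.5 * thr
        ascending = left.min() <= -thr and right.max() >= 0.5 * thr
        if not (descending or ascending):
            continue
        denom = response[i] - response[i + 1]
        frac = response[i] / denom if denom != 0 else 0.5
        best = i + frac
    return best


def track_leading_edge(
    stack: ImageStackSequence,
    line: SamplingLine,
    *,
    sigma_small: float = 1.0,
    sigma_large: float = 3.0,
    k: float = 2.0,
) -> EdgeProfile:
    """Track the leading-edge position along ``line`` in the height-0 movie.

    Frames where no edge crosses the line are filled by linear interpolation
    and flagged; more than 10% such frames adds a warning, and an edge found
    in no frame at all is an error.
    """
    cfg = stack.config
    line.validate_inside(cfg.image_shape)
    rows, cols = line.sample_coords()
    positions = np.full(stack.n_frames, np.nan)
    for ti, frame_set in enumerate(stack.frames):
        resp = ndimage.map_coordinates(
            dog_response(frame_set[0.0], sigma_small, sigma_large),
            np.vstack([rows, cols]),
            order=1,
            mode="nearest",
        )
        pos = _edge_position_on_line(resp, k=k)
        if pos is not None:
            positions[ti] = pos * cfg.pixel_um

    warnings: list[str] = []
    missing = np.isnan(positions)
    if missing.all():
        raise RuntimeError("no edge detected in any frame along the line")
    if missing.any():
        good = np.nonzero(~missing)[0]
        positions = np.interp(np.arange(len(positions)), good, positions[good])
        frac = missing.mean()
        if frac > 0.10:
            warnings.append(f"{frac:.0%} of frames had no edge on the line; interpolated")
    return EdgeProfile(
        positions_um=positions,
        times_s=stack.times_s,
        interpolated=missing,
        warnings=warnings,
    )


def build_kymograph(stack: ImageStackSequence, line: SamplingLine) -> Kymograph:
    """Bilinear intensity samples of each height-0 frame along ``line``."""
    cfg = stack.config
    line.validate_inside(cfg.image_shape)
    rows, cols = line.sample_coords()
    coords = np.vstack([rows, cols])
    data = np.column_stack(
        [
            ndimage.map_coordinates(f[0.0], coords, order=1, mode="nearest")
            for f in stack.frames
        ]
    )
    return Kymograph(
        data=data, spatial_step_um=cfg.pixel_um, time_step_s=cfg.frame_interval_s
    )


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")[: len(x)]


def _cycle_minima(
    profile: EdgeProfile, smooth_window: int = 3, min_period_s: float = 20.0
) -> np.ndarray:
    sm = _smooth(profile.positions_um, smooth_window)
    dist = max(1, int(np.ceil(min_period_s / profile.dt_s)))
    minima, _ = find_peaks(-sm, distance=dist)
    return minima


def measure_period(
    profile: EdgeProfile, *, smooth_window: int = 3, min_period_s: float = 20.0
) -> tuple[float, np.ndarray]:
    """Mean protrusion/retraction period T and the per-cycle intervals (s).

    Cycles are delimited by successive local minima of the smoothed profile.
    """
    minima = _cycle_minima(profile, smooth_window, min_period_s)
    if len(minima) < 2:
        raise NoCyclesError("no cycles: fewer than 2 profile minima detected")
    intervals = np.diff(profile.times_s[minima])
    return float(intervals.mean()), intervals


def measure_persistence(
    profile: EdgeProfile, *, smooth_window: int = 3, min_period_s: float = 20.0
) -> tuple[float, np.ndarray]:
    """Mean persistence length dl and the per-cycle values (μm).

    Per cycle: maximal edge position within the cycle minus the position at
    the cycle-start minimum.
    """
    minima = _cycle_minima(profile, smooth_window, min_period_s)
    if len(minima) < 2:
        raise NoCyclesError("no cycles: fewer than 2 profile minima detected")
    pos = profile.positions_um
    per_cycle = []
    for a, b in zip(minima[:-1], minima[1:]):
        # Smoothing can shift the minimum index by a frame; take the raw
        # minimum in its immediate neighbourhood as the cycle-start position.
        start = pos[max(0, a - 1) : a + 2].min()
        per_cycle.append(pos[a : b + 1].max() - start)
    per_cycle = np.asarray(per_cycle)
    return float(per_cycle.mean()), per_cycle


def retraction_windows(
    profile: EdgeProfile, *, min_frames: int = 2
) -> list[tuple[float, float]]:
    """Time intervals (s) in which the leading edge is clearly retracting.

    A frame belongs to a retraction when the centered time-derivative of the
    edge position is below half the 10th-percentile (i.e. strongly negative)
    velocity; this excludes the diluted transition frames at the cycle's
    maximum and minimum, whose derivative mixes protrusion and retraction.
    Maximal runs of at least ``min_frames`` frames become windows.
    """
    v = np.gradient(profile.positions_um, profile.times_s)
    neg = v[v < 0]
    if len(neg) == 0:
        raise NoCyclesError("profile never retracts")
    thr = 0.5 * np.percentile(v, 10)
    if thr >= 0:
        raise NoCyclesError("profile never retracts")
    mask = v <= thr
    out = []
    i = 0
    while i < len(mask):
        if mask[i]:
            j = i
            while j + 1 < len(mask) and mask[j + 1]:
                j += 1
            if j - i + 1 >= min_frames:
                out.append((float(profile.times_s[i]), float(profile.times_s[j])))
            i = j + 1
        else:
            i += 1
    if not out:
        raise NoCyclesError("no retraction window of sufficient length")
    return out


def _shear_score(sub: np.ndarray, shifts_px: np.ndarray) -> float:
    """Alignment score of a kymograph window sheared by per-column shifts.

    Columns are resampled along position with the given shifts; when the
    shear matches the streak slope the features align and the variance of the
    time-averaged profile is maximal. Rows that would sample outside the
    window under the largest shift are dropped.
    """
    n_pos, n_t = sub.shape
    lo = int(np.ceil(max(0.0, -float(np.min(shifts_px)))))
    hi = n_pos - int(np.ceil(max(0.0, float(np.max(shifts_px)))))
    if hi - lo < 4:
        return -np.inf
    p = np.arange(lo, hi, dtype=float)
    acc = np.zeros(hi - lo)
    for j in range(n_t):
        acc += ndimage.map_coordinates(sub[:, j], [p + shifts_px[j]], order=1)
    return float(np.var(acc / n_t))


def measure_retrograde_flow(
    kymo: Kymograph,
    windows: list[tuple[float, float]],
    *,
    max_rate_um_s: float = 0.25,
    step_um_s: float = 0.0025,
    min_contrast: float = 1e-6,
) -> tuple[float, list[float]]:
    """Retrograde flow rate dx/dt from streak slopes within retraction windows.

    For each window the streak orientation is found by exhaustively scanning
    candidate rates: each column is sheared by rate·Δt and the variance of the
    time-averaged profile is scored; the best rate is refined by a parabolic
    fit around the grid optimum. Windows without contrast structure are
    skipped. Returns the mean |rate| and the per-window rates (μm/s).
    """
    dt = kymo.time_step_s
    dx = kymo.spatial_step_um
    rates: list[float] = []
    grid = np.arange(-max_rate_um_s, max_rate_um_s + step_um_s / 2, step_um_s)
    for t0, t1 in windows:
        j0 = int(np.round(t0 / dt))
        j1 = int(np.round(t1 / dt))
        if j1 <= j0 or j0 < 0 or j1 >= kymo.data.shape[1]:
            continue
        sub = kymo.data[:, j0 : j1 + 1]
        if sub.std() <= min_contrast * max(1.0, np.abs(sub).max()):
            continue
        tt = (np.arange(sub.shape[1]) * dt) / dx  # px shift per unit rate
        scores = np.array([_shear_score(sub, v * tt) for v in grid])
        if not np.isfinite(scores).any():
            continue
        b = int(np.argmax(scores))
        best = grid[b]
        if 0 < b < len(grid) - 1 and np.isfinite(scores[b - 1 : b + 2]).all():
            y0, y1, y2 = scores[b - 1 : b + 2]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                best = grid[b] + 0.5 * step_um_s * (y0 - y2) / denom
        rates.append(abs(float(best)))
    if not rates:
        raise RuntimeError("no kymograph window with usable contrast structure")
    return float(np.mean(rates)), rates


def default_sampling_line(stack: ImageStackSequence) -> SamplingLine:
    """Automatic line placement: through the cell centroid, across the front.

    The height-0 first frame is segmented by its DoG-supported intensity
    (pixels well above the median), the blob's elongation axis is found from
    image moments, and the line runs through the centroid along the normal to
    that axis — i.e. perpendicular to the mean edge orientation — with its
    first endpoint on the cell-body side.
    """
    from skimage.measure import regionprops, label

    frame = stack.frames[0][0.0]
    med = np.median(frame)
    mask = frame > med + 3.0 * 1.4826 * np.median(np.abs(frame - med))
    lab = label(mask)
    if lab.max() == 0:
        raise RuntimeError("no cell found in the first frame")
    props = max(regionprops(lab), key=lambda p: p.area)
    cy, cx = props.centroid
    # Normal to the blob's major axis = protrusion direction.
    theta = props.orientation  # angle of major axis w.r.t. row axis
    nx, ny = np.cos(theta), np.sin(theta)
    rows, cols = stack.config.image_shape

    def clip_endpoint(sign: float) -> tuple[float, float]:
        tmax = np.inf
        for bound, c0, d in ((cols - 1, cx, sign * nx), (rows - 1, cy, sign * ny)):
            if d > 0:
                tmax = min(tmax, (bound - c0) / d)
            elif d < 0:
                tmax = min(tmax, -c0 / d)
        return (cx + sign * nx * tmax, cy + sign * ny * tmax)

    e1 = clip_endpoint(-1.0)
    e2 = clip_endpoint(1.0)

    def coverage(pt: tuple[float, float]) -> float:
        n = 20
        s = np.linspace(0, 1, n)
        xs = cx + s * (pt[0] - cx)
        ys = cy + s * (pt[1] - cy)
        return float(
            mask[np.clip(ys.astype(int), 0, rows - 1), np.clip(xs.astype(int), 0, cols - 1)].mean()
        )

    if coverage(e1) >= coverage(e2):
        return SamplingLine(start_xy=e1, end_xy=e2)
    return SamplingLine(start_xy=e2, end_xy=e1)


def analyze_stack(
    stack: ImageStackSequence,
    line: SamplingLine | None = None,
    *,
    sigma_small: float = 1.0,
    sigma_large: float = 3.0,
    k: float = 2.0,
    smooth_window: int = 3,
    min_period_s: float = 20.0,
) -> tuple[CycleMetrics, EdgeProfile, Kymograph]:
    """Full Algorithm-I run on one stack: track, kymograph, three metrics."""
    if line is None:
        line = default_sampling_line(stack)
    profile = track_leading_edge(
        stack, line, sigma_small=sigma_small, sigma_large=sigma_large, k=k
    )
    kymo = build_kymograph(stack, line)
    period, intervals = measure_period(
        profile, smooth_window=smooth_window, min_period_s=min_period_s
    )
    persistence, _ = measure_persistence(
        profile, smooth_window=smooth_window, min_period_s=min_period_s
    )
    windows = retraction_windows(profile)
    rate, _ = measure_retrograde_flow(kymo, windows)
    metrics = CycleMetrics(
        period_s=period,
        persistence_um=persistence,
        retro_rate_um_s=rate,
        n_cycles=len(intervals),
    )
    return metrics, profile, kymo
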