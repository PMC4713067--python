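"""Filopodium tip tracking and length/growth-rate measurement.

Filopodia appear as thin bright ridges in the height-0 movie. Tips are
followed frame to frame: the movie is thresholded at half the ridge
amplitude, skeletonized, and each tip is advanced to the skeleton endpoint
nearest its previous position, then refined to the sub-pixel half-maximum
crossing along the ridge axis. Lengths are straight base-to-tip distances by
default (an arc-length mode is available for curved ridges).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

__all__ = [
    "FilopodiumTrack",
    "track_tips",
    "max_length",
    "protrusion_rate_filo",
    "tracks_from_tip_coordinates",
]


@dataclass
class FilopodiumTrack:
    """Per-frame tip positions of one filopodium.

    Coordinates are (row, col) pixels; lengths in μm. A truncated track (tip
    lost) simply ends early; ``truncated`` records whether that happened.
    """

    tip_px: np.ndarray  # (n, 2) float
    base_px: tuple[float, float]
    times_s: np.ndarray
    pixel_um: float
    truncated: bool = False
    arc_lengths_um: np.ndarray | None = None

    @property
    def lengths_um(self) -> np.ndarray:
        if self.arc_lengths_um is not None:
            return self.arc_lengths_um
        d = self.tip_px - np.asarray(self.base_px)
        return np.hypot(d[:, 0], d[:, 1]) * self.pixel_um


def _skeleton_endpoints(skel: np.ndarray) -> np.ndarray:
    """(k, 2) row/col coordinates of skeleton pixels with exactly 1 neighbour."""
    neigh = ndimage.convolve(skel.astype(int), np.ones((3, 3), int), mode="constant")
    ends = skel & (neigh == 2)  # itself + one neighbour
    return np.argwhere(ends)


def _refine_tip(
    frame: np.ndarray,
    base: np.ndarray,
    tip: np.ndarray,
    background: float,
    amplitude: float,
) -> np.ndarray:
    """Sub-pixel tip: half-maximum crossing along the base→tip ray."""
    v = tip - base
    n = np.linalg.norm(v)
    if n == 0:
        return tip.astype(float)
    u = v / n
    half = background + amplitude / 2.0
    # March outward from just inside the endpoint until intensity < half.
    ss = np.arange(max(0.0, n - 3.0), n + 4.0, 0.25)
    pts = base + ss[:, None] * u
    vals = ndimage.map_coordinates(frame, pts.T, order=1, mode="nearest")
    below = np.nonzero(vals < half)[0]
    if len(below) == 0 or below[0] == 0:
        return tip.astype(float)
    j = below[0]
    # Linear interpolation of the crossing between samples j-1 and j.
    f = (vals[j - 1] - half) / (vals[j - 1] - vals[j])
    s_star = ss[j - 1] + f * (ss[j] - ss[j - 1])
    return base + s_star * u


def track_tips(
    frames: np.ndarray,
    seeds_px: list[tuple[float, float]],
    *,
    pixel_um: float = 0.1,
    frame_interval_s: float = 1.0,
    bases_px: list[tuple[float, float]] | None = None,
    search_radius_px: float = 10.0,
    refine: bool = True,
) -> list[FilopodiumTrack]:
    """Follow each seeded tip through a (T, rows, cols) height-0 movie.

    Per frame the tip moves to the nearest ridge-skeleton endpoint within the
    search radius; losing the endpoint truncates the track. When ``bases_px``
    is omitted, each base is taken as the skeleton point of the first frame
    farthest from the seed within its connected ridge.
    """
    frames = np.asarray(frames, dtype=float)
    n_t = len(frames)
    times = np.arange(n_t) * frame_interval_s

    masks = []
    amps = []
    bgs = []
    for f in frames:
        bg = np.median(f)
        amp = np.percentile(f, 99.9) - bg
        masks.append(f > bg + amp / 2.0)
        amps.append(amp)
        bgs.append(bg)

    if bases_px is None:
        lab, _ = ndimage.label(masks[0], structure=np.ones((3, 3), int))
        skel0 = skeletonize(masks[0])
        bases_px = []
        for seed in seeds_px:
            sr, sc = int(round(seed[0])), int(round(seed[1]))
            comp = lab[np.clip(sr, 0, lab.shape[0] - 1), np.clip(sc, 0, lab.shape[1] - 1)]
            pts = np.argwhere(skel0 & (lab == comp))
            if len(pts) == 0:
                bases_px.append((float(seed[0]), float(seed[1])))
                continue
            d = np.hypot(pts[:, 0] - seed[0], pts[:, 1] - seed[1])
            bases_px.append(tuple(pts[int(np.argmax(d))].astype(float)))

    endpoints = [_skeleton_endpoints(skeletonize(m)) for m in masks]

    tracks: list[FilopodiumTrack] = []
    for seed, base in zip(seeds_px, bases_px):
        base_arr = np.asarray(base, dtype=float)
        prev = np.asarray(seed, dtype=float)
        tip_list: list[np.ndarray] = []
        truncated = False
        for ti in range(n_t):
            ends = endpoints[ti]
            if len(ends) == 0:
                truncated = True
                break
            d = np.hypot(ends[:, 0] - prev[0], ends[:, 1] - prev[1])
            j = int(np.argmin(d))
            if d[j] > search_radius_px:
                truncated = True
                break
            tip = ends[j].astype(float)
            if refine:
                tip = _refine_tip(frames[ti], base_arr, tip, bgs[ti], amps[ti])
            tip_list.append(tip)
            prev = tip
        if not tip_list:
            continue
        tracks.append(
            FilopodiumTrack(
                tip_px=np.vstack(tip_list),
                base_px=tuple(base_arr),
                times_s=times[: len(tip_list)],
                pixel_um=pixel_um,
                truncated=truncated,
            )
        )
    return tracks


def tracks_from_tip_coordinates(
    tips_px: np.ndarray,
    base_px: tuple[float, float],
    *,
    pixel_um: float,
    frame_interval_s: float,
) -> FilopodiumTrack:
    """Manual mode: build a track from externally clicked tip coordinates."""
    tips_px = np.asarray(tips_px, dtype=float)
    return FilopodiumTrack(
        tip_px=tips_px,
        base_px=base_px,
        times_s=np.arange(len(tips_px)) * frame_interval_s,
        pixel_um=pixel_um,
    )


def max_length(track: FilopodiumTrack) -> float:
    """Maximum base-to-tip length (μm) over the track."""
    if len(track.tip_px) == 0:
        raise ValueError("empty track")
    return float(track.lengths_um.max())


def protrusion_rate_filo(
    track: FilopodiumTrack,
    *,
    min_rate_um_s: float = 0.01,
    min_frames: int = 3,
) -> float:
    """Filopodium growth rate (μm/s): LS slope of length vs time while growing.

    The growth phase is the longest run of frames whose smoothed length
    increases at ≥ ``min_rate_um_s``; a pause or shrink phase is excluded
    from the fit. Raises if no growth phase of at least ``min_frames`` frames
    exists.
    """
    lengths = track.lengths_um
    t = track.times_s
    if len(lengths) < min_frames:
        raise RuntimeError("no growth phase: track too short")
    dt = float(t[1] - t[0])
    sm = np.convolve(np.pad(lengths, 1, mode="edge"), np.ones(3) / 3, mode="valid")
    v = np.gradient(sm, dt)
    ok = v >= min_rate_um_s
    best = None
    i = 0
    while i < len(ok):
        if ok[i]:
            j = i
            while j + 1 < len(ok) and ok[j + 1]:
                j += 1
            if best is None or (j - i) > (best[1] - best[0]):
                best = (i, j)
            i = j + 1
        else:
            i += 1
    if best is None or best[1] - best[0] + 1 < min_frames:
        raise RuntimeError("no growth phase detected")
    i0, i1 = best
    # Drop the smoothed corner frames at the run ends (onset / plateau).
    if (i1 - i0 + 1) >= min_frames + 2:
        i0 += 1
        i1 -= 1
    return float(np.polyfit(t[i0 : i1 + 1], lengths[i0 : i1 + 1], 1)[0])
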