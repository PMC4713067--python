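"""Defocus-based vertical-motion analysis of the lamellipodium.

A pixel of a thin phase object is taken to be *in focus* at a given Z-plane
when its intensity equalises (within a tolerance) with that plane's
background intensity, computed as the median of the plane. Counting in-focus
pixels per height and normalising by the total across heights yields the
fractional-height series, whose per-frame peak tracks the vertical position
of the lamellipodium — lamellipodia lift up around maximal retraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .synthetic import ImageStackSequence

__all__ = [
    "FractionalHeightSeries",
    "background_intensity",
    "robust_tolerance",
    "in_focus_mask",
    "lamellipodium_roi",
    "height0_roi",
    "fractional_height_series",
    "max_height_trace",
    "cycle_max_heights",
]


def background_intensity(plane: np.ndarray) -> float:
    """Background of one plane: the exact median of its pixel intensities."""
    plane = np.asarray(plane)
    if plane.size == 0:
        raise ValueError("empty plane")
    return float(np.median(plane))


def robust_tolerance(plane: np.ndarray, k: float = 1.5) -> float:
    """Default in-focus tolerance: ``k`` × robust sd (1.4826·MAD) of the plane."""
    med = np.median(plane)
    return float(k * 1.4826 * np.median(np.abs(plane - med)))


def in_focus_mask(
    plane: np.ndarray,
    background: float,
    tol: float,
    roi: np.ndarray | None = None,
    gradient_tol: float | None = None,
) -> np.ndarray:
    """Pixels whose intensity equalises with the background, within the ROI.

    With ``gradient_tol`` set, pixels sitting on an intensity gradient larger
    than that value (per px, after light smoothing) are excluded: a pixel on
    the flank of a defocus halo crosses the background level without being in
    focus, whereas a genuinely in-focus phase-object region is flat at the
    background level.
    """
    if tol < 0:
        raise ValueError("tol must be non-negative")
    plane = np.asarray(plane, dtype=float)
    mask = np.abs(plane - background) <= tol
    if gradient_tol is not None:
        sm = ndimage.gaussian_filter(plane, 1.0)
        gy, gx = np.gradient(sm)
        mask &= np.hypot(gy, gx) <= gradient_tol
    if roi is not None:
        mask &= roi.astype(bool)
    return mask


def lamellipodium_roi(
    frame_planes: dict[float, np.ndarray],
    *,
    tol: float | None = None,
    factor: float = 3.0,
    margin_px: int = 0,
) -> np.ndarray:
    """Cell-region mask for one frame, built from the full height set.

    A pixel belongs to the lamellipodium if, at any imaged height, its
    deviation from that plane's background exceeds ``factor`` × the in-focus
    tolerance: cell material is visible (defocused) at the planes away from
    its own height, whereas true background matches the median everywhere.
    An optional dilation margin widens the mask.
    """
    roi = None
    for h, plane in frame_planes.items():
        bg = background_intensity(plane)
        t = robust_tolerance(plane) if tol is None else tol
        dev = np.abs(np.asarray(plane, dtype=float) - bg) > factor * t
        roi = dev if roi is None else (roi | dev)
    if margin_px > 0:
        roi = ndimage.binary_dilation(roi, iterations=margin_px)
    return roi


def height0_roi(
    plane0: np.ndarray, *, tol: float | None = None, factor: float = 3.0, margin_px: int = 3
) -> np.ndarray:
    """Dilated height-0 segmentation (alternative ROI for real recordings)."""
    bg = background_intensity(plane0)
    t = robust_tolerance(plane0) if tol is None else tol
    roi = np.abs(np.asarray(plane0, dtype=float) - bg) > factor * t
    if margin_px > 0:
        roi = ndimage.binary_dilation(roi, iterations=margin_px)
    return roi


@dataclass
class FractionalHeightSeries:
    """Fraction of in-focus pixels per height and frame.

    ``fractions[h, t]`` sums to 1 over heights whenever any pixel was in
    focus at frame ``t``; frames with no in-focus pixel at any height are
    emitted as all-zero columns and flagged, keeping the time axis aligned.
    """

    fractions: np.ndarray  # (n_heights, n_frames)
    heights_um: np.ndarray
    times_s: np.ndarray
    flagged: np.ndarray = field(default=None)  # zero-total columns

    def __post_init__(self) -> None:
        if self.flagged is None:
            self.flagged = ~self.fractions.any(axis=0)


def fractional_height_series(
    stack: ImageStackSequence,
    *,
    tol: float | None = None,
    roi: np.ndarray | list[np.ndarray] | None = None,
    roi_margin_px: int = 0,
    min_focus_fraction: float = 0.01,
) -> FractionalHeightSeries:
    """Per-frame fraction of in-focus pixels at each imaged height.

    ``tol`` defaults to the per-plane robust tolerance; ``roi`` may be a
    single mask, a per-frame list, or ``None`` to derive one per frame with
    :func:`lamellipodium_roi`. Frames whose total in-focus population across
    all heights is below ``min_focus_fraction`` of the ROI (including zero —
    e.g. when the edge sits between two imaged heights) are emitted as
    all-zero columns and flagged rather than normalised from a handful of
    noise pixels.
    """
    heights = list(stack.config.heights_um)
    if len(heights) < 2:
        raise ValueError("need at least 2 heights")
    n_t = stack.n_frames
    counts = np.zeros((len(heights), n_t))
    floors = np.zeros(n_t)
    for ti, frame_planes in enumerate(stack.frames):
        if roi is None:
            frame_roi = lamellipodium_roi(frame_planes, tol=tol, margin_px=roi_margin_px)
        elif isinstance(roi, list):
            frame_roi = roi[ti]
        else:
            frame_roi = roi
        floors[ti] = max(1.0, min_focus_fraction * float(np.sum(frame_roi)))
        for hi, h in enumerate(heights):
            plane = frame_planes[h]
            bg = background_intensity(plane)
            t = robust_tolerance(plane) if tol is None else tol
            counts[hi, ti] = in_focus_mask(
                plane, bg, t, frame_roi, gradient_tol=0.5 * t
            ).sum()
    totals = counts.sum(axis=0)
    fractions = np.zeros_like(counts)
    ok = totals >= floors
    fractions[:, ok] = counts[:, ok] / totals[ok]
    return FractionalHeightSeries(
        fractions=fractions,
        heights_um=np.asarray(heights, dtype=float),
        times_s=stack.times_s,
        flagged=~ok,
    )


def max_height_trace(
    series: FractionalHeightSeries, threshold: float = 0.1
) -> np.ndarray:
    """Per-frame reached height: highest h with fraction(h, t) ≥ threshold.

    Flagged (all-zero) frames yield NaN.
    """
    n_t = series.fractions.shape[1]
    out = np.full(n_t, np.nan)
    order = np.argsort(series.heights_um)[::-1]
    for t in range(n_t):
        if series.flagged[t]:
            continue
        for hi in order:
            if series.fractions[hi, t] >= threshold:
                out[t] = series.heights_um[hi]
                break
    return out


def cycle_max_heights(
    series: FractionalHeightSeries,
    cycle_bounds_s: list[tuple[float, float]],
    threshold: float = 0.1,
) -> np.ndarray:
    """Maximal reached height (μm) within each cycle time window."""
    trace = max_height_trace(series, threshold)
    out = []
    for t0, t1 in cycle_bounds_s:
        sel = (series.times_s >= t0) & (series.times_s <= t1)
        vals = trace[sel]
        vals = vals[~np.isnan(vals)]
        out.append(float(vals.max()) if len(vals) else np.nan)
    return np.asarray(out)
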