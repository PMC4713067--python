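"""Optical-trap force analysis: forces, feedback compensation, event typing.

Force components follow Hooke's law for the calibrated trap,
``F = k × deflection`` with separate lateral and axial stiffness. Lateral
bead excursions beyond the detector's linear range trigger nanopositioner
recentering; the compensated trajectory splices the recorded stage motion
back into the bead path so protrusion can be followed beyond the trap range.
Force episodes are classified into the four stereotyped behaviours —
vertical push (VP), vertical retraction (VR), lateral push (LP) and lateral
retraction (LR) — by the dominant axis and by whether the bead moves away
from or toward the cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic import BeadTrace

__all__ = [
    "ForceTrace",
    "ForceEvent",
    "ProtrusionRateResult",
    "displacement_to_force",
    "compensate_feedback",
    "force_trace",
    "detect_events",
    "classify_event",
    "max_event_force",
    "protrusion_rate",
]


def displacement_to_force(
    deflection_nm: np.ndarray, stiffness_pn_nm: tuple[float, float]
) -> np.ndarray:
    """(F_x, F_y, F_z) in pN from bead deflection (nm): F = k · displacement."""
    kxy, kz = stiffness_pn_nm
    if kxy <= 0 or kz <= 0:
        raise ValueError("stiffness components must be positive")
    d = np.asarray(deflection_nm, dtype=float)
    return d * np.array([kxy, kxy, kz])


def compensate_feedback(trace: BeadTrace) -> tuple[np.ndarray, list[str]]:
    """Feedback-corrected lateral bead path (nm).

    ``compensated(t) = qpd_xy(t) + (stage reference − stage_xy(t))`` with the
    first sample's stage position as reference, so every recentering jump is
    undone; with a stationary stage the compensated path equals the raw QPD
    signal exactly. Stage jumps not preceded by a lateral threshold crossing
    are flagged as inconsistencies.
    """
    qpd = trace.qpd_xyz_nm[:, :2]
    stage = trace.stage_xy_nm
    comp = qpd + (stage[0] - stage)

    flags: list[str] = []
    thr = trace.config.feedback_threshold_nm
    jumps = np.nonzero(np.any(np.abs(np.diff(stage, axis=0)) > 1e-9, axis=1))[0] + 1
    r = np.hypot(trace.qpd_xyz_nm[:, 0], trace.qpd_xyz_nm[:, 1])
    for j in jumps:
        if r[j - 1] <= thr:
            flags.append(
                f"stage jump at sample {j} without threshold crossing "
                f"(r={r[j - 1]:.1f} nm <= {thr:.0f} nm)"
            )
    return comp, flags


@dataclass
class ForceTrace:
    """Three-component force time course plus the compensated lateral path."""

    t_s: np.ndarray
    force_pn: np.ndarray  # (n, 3): F_x, F_y, F_z = k × raw QPD deflection
    compensated_xy_nm: np.ndarray  # (n, 2)
    stiffness_pn_nm: tuple[float, float]
    flags: list[str] = field(default_factory=list)

    @property
    def lateral_pn(self) -> np.ndarray:
        return np.hypot(self.force_pn[:, 0], self.force_pn[:, 1])

    @property
    def axial_pn(self) -> np.ndarray:
        return np.abs(self.force_pn[:, 2])


def force_trace(trace: BeadTrace) -> ForceTrace:
    """Convert a bead recording into forces and the compensated lateral path."""
    comp, flags = compensate_feedback(trace)
    force = displacement_to_force(trace.qpd_xyz_nm, trace.config.stiffness_pn_nm)
    return ForceTrace(
        t_s=trace.t_s,
        force_pn=force,
        compensated_xy_nm=comp,
        stiffness_pn_nm=trace.config.stiffness_pn_nm,
        flags=flags,
    )


@dataclass
class ForceEvent:
    window_s: tuple[float, float]
    behaviour: str  # VP, VR, LP or LR
    max_force_pn: float


def detect_events(
    ft: ForceTrace,
    *,
    floor_pn: float = 1.0,
    min_duration_s: float = 2.0,
    merge_gap_s: float = 1.0,
) -> list[tuple[float, float]]:
    """Maximal intervals where |F| stays at/above the detection floor.

    Intervals separated by gaps shorter than ``merge_gap_s`` are merged, and
    only intervals lasting at least ``min_duration_s`` are kept.
    """
    mag = np.linalg.norm(ft.force_pn, axis=1)
    above = mag >= floor_pn
    if not above.any():
        return []
    dt = float(ft.t_s[1] - ft.t_s[0]) if len(ft.t_s) > 1 else 1.0
    edges = np.diff(above.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0])
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above) - 1)
    intervals = list(zip(starts, ends))
    merged: list[list[int]] = []
    for s, e in intervals:
        if merged and (s - merged[-1][1]) * dt < merge_gap_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        if (e - s) * dt >= min_duration_s:
            out.append((float(ft.t_s[s]), float(ft.t_s[e])))
    return out


def _window_slice(ft: ForceTrace, window_s: tuple[float, float]) -> slice:
    i0 = int(np.searchsorted(ft.t_s, window_s[0]))
    i1 = int(np.searchsorted(ft.t_s, window_s[1], side="right"))
    return slice(i0, i1)


def classify_event(
    ft: ForceTrace,
    window_s: tuple[float, float],
    away_vector: tuple[float, float, float] = (1.0, 0.0, 0.0),
    *,
    floor_pn: float = 1.0,
) -> str | None:
    """Assign one of VP/VR/LP/LR to a force episode, or None below the floor.

    The axis is vertical when the peak |F_z| exceeds the peak lateral force
    magnitude. The sense is *push* when the dominant deflection moves the
    bead away from the cell: the away-from-cell unit vector is supplied per
    recording (for the axial component, up = push). The rule depends only on
    directions, so it is invariant to overall force scaling.
    """
    away = np.asarray(away_vector, dtype=float)
    nrm = np.linalg.norm(away)
    if nrm == 0:
        raise ValueError("away_vector must be non-zero")
    away = away / nrm
    sl = _window_slice(ft, window_s)
    if sl.stop - sl.start < 2:
        return None
    fz = ft.force_pn[sl, 2]
    flat = ft.lateral_pn[sl]
    peak_z = np.abs(fz).max()
    peak_lat = flat.max()
    if max(peak_z, peak_lat) < floor_pn:
        return None
    if peak_z > peak_lat:
        sign = np.sign(fz[np.argmax(np.abs(fz))])
        az = away[2] if away[2] != 0 else 1.0  # default: up = away = push
        return "VP" if sign * az > 0 else "VR"
    # Lateral: net compensated displacement over the episode vs away direction.
    comp = ft.compensated_xy_nm[sl]
    disp = comp[np.argmax(flat)] - comp[0]
    lat_away = away[:2]
    if np.linalg.norm(lat_away) == 0:
        raise ValueError("away_vector has no lateral component for a lateral event")
    return "LP" if float(disp @ lat_away) > 0 else "LR"


def max_event_force(
    ft: ForceTrace, window_s: tuple[float, float], behaviour: str
) -> float:
    """Peak force (pN) of the behaviour-relevant component within the window.

    |F_z| for vertical events (VP/VR); sqrt(F_x²+F_y²) for lateral (LP/LR).
    """
    sl = _window_slice(ft, window_s)
    if behaviour in ("VP", "VR"):
        return float(ft.axial_pn[sl].max())
    if behaviour in ("LP", "LR"):
        return float(ft.lateral_pn[sl].max())
    raise ValueError(f"unknown behaviour {behaviour!r}")


def analyze_events(
    ft: ForceTrace,
    away_vector: tuple[float, float, float] = (1.0, 0.0, 0.0),
    *,
    floor_pn: float = 1.0,
    min_duration_s: float = 2.0,
    merge_gap_s: float = 1.0,
) -> list[ForceEvent]:
    """Detect, classify and measure all force episodes in a trace."""
    events = []
    for win in detect_events(
        ft, floor_pn=floor_pn, min_duration_s=min_duration_s, merge_gap_s=merge_gap_s
    ):
        behaviour = classify_event(ft, win, away_vector, floor_pn=floor_pn)
        if behaviour is None:
            continue
        events.append(
            ForceEvent(
                window_s=win,
                behaviour=behaviour,
                max_force_pn=max_event_force(ft, win, behaviour),
            )
        )
    return events


@dataclass
class ProtrusionRateResult:
    rate_nm_s: float
    n_used: int
    excluded: list[int] = field(default_factory=list)


def _scalar_displacement(path: np.ndarray) -> np.ndarray:
    """Project a lateral path onto its own net direction of motion (nm)."""
    path = np.asarray(path, dtype=float)
    if path.ndim == 1:
        return path - path[0]
    d = path - path[0]
    net = d[-1]
    n = np.linalg.norm(net)
    if n == 0:
        return np.zeros(len(path))
    return d @ (net / n)


def _smooth_velocity(s: np.ndarray, dt: float) -> np.ndarray:
    """Velocity of a 0.5 s boxcar-smoothed displacement series."""
    win = max(1, int(round(0.5 / dt)))
    sm = np.convolve(
        np.pad(s, win, mode="edge"), np.ones(2 * win + 1) / (2 * win + 1), mode="valid"
    )
    return np.gradient(sm[: len(s)], dt)


def _rising_phase(
    s: np.ndarray, dt: float, min_rate_nm_s: float, min_duration_s: float
) -> tuple[int, int] | None:
    """Longest run of sustained positive slope ≥ min_rate; None if too short."""
    v = _smooth_velocity(s, dt)
    ok = v >= min_rate_nm_s
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
    if best is None or (best[1] - best[0]) * dt < min_duration_s:
        return None
    return best


def protrusion_rate(
    paths: list[np.ndarray],
    dt_s: float,
    *,
    min_rate_nm_s: float = 5.0,
    min_duration_s: float = 2.0,
    max_lag_s: float | None = None,
) -> ProtrusionRateResult:
    """Lamellipodial protrusion rate from averaged compensated bead paths.

    Each path (a compensated lateral trajectory, (n,2) or already scalar) is
    reduced to its displacement along its net direction of motion; paths with
    a detected rising phase are aligned to the first one by maximizing the
    cross-correlation of their velocity profiles over integer-sample lags,
    averaged, and the least-squares slope of the averaged rising phase is the
    protrusion rate in nm/s. Paths without a rising phase are excluded.
    """
    if len(paths) < 2:
        raise ValueError("need at least 2 traces")
    scalars = [_scalar_displacement(p) for p in paths]
    rising = [_rising_phase(s, dt_s, min_rate_nm_s, min_duration_s) for s in scalars]
    excluded = [i for i, r in enumerate(rising) if r is None]
    used = [i for i, r in enumerate(rising) if r is not None]
    if not used:
        raise RuntimeError("no trace has a detectable rising phase")

    ref_i = used[0]
    ref_start = rising[ref_i][0]
    max_lag = int(round((max_lag_s if max_lag_s is not None else 2.0) / dt_s))
    lags = {ref_i: 0}
    ref_v = _smooth_velocity(scalars[ref_i], dt_s)
    for i in used[1:]:
        coarse = rising[i][0] - ref_start  # align rising-phase onsets
        v = _smooth_velocity(scalars[i], dt_s)
        best_score, best_lag = -np.inf, coarse
        for lag in range(coarse - max_lag, coarse + max_lag + 1):
            lo = max(0, lag)
            hi = min(len(v), len(ref_v) + lag)
            if hi - lo < 4:
                continue
            a = v[lo:hi]
            b = ref_v[lo - lag : hi - lag]
            score = float(np.dot(a - a.mean(), b - b.mean()))
            if score > best_score:
                best_score, best_lag = score, lag
        lags[i] = best_lag

    # Average over the reference-frame samples where all used traces overlap.
    lo_ref = max(0, max(-lags[i] for i in used))
    hi_ref = min(len(scalars[i]) - lags[i] for i in used)
    if hi_ref - lo_ref < 4:
        raise RuntimeError("aligned traces have no usable overlap")
    avg = np.mean(
        [scalars[i][lo_ref + lags[i] : hi_ref + lags[i]] for i in used], axis=0
    )

    phase = _rising_phase(avg, dt_s, min_rate_nm_s, min_duration_s)
    if phase is None:
        raise RuntimeError("averaged trace has no rising phase")
    i0, i1 = phase
    # Trim the smoothed ramp corners so the fit sees only the linear interior.
    edge = max(1, int(round(0.5 / dt_s)))
    if (i1 - i0) > 4 * edge:
        i0 += edge
        i1 -= edge
    tt = np.arange(i0, i1 + 1) * dt_s
    slope = float(np.polyfit(tt, avg[i0 : i1 + 1], 1)[0])
    return ProtrusionRateResult(rate_nm_s=slope, n_used=len(used), excluded=excluded)
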