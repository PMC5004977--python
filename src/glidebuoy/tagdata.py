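"""Processing of raw tag records into filtered 5-s glide segments.

The pipeline mirrors standard biologging practice for stroke-and-glide
analysis: pitch and roll from the low-passed (gravitational) component of
the whale-frame accelerometer, glide detection from the high-passed
dorso-ventral axis against a per-deployment stroke threshold, dive-phase
segmentation (descent / bottom / ascent), speed either from a calibrated
propeller channel or from vertical rate divided by sin(pitch), and
extraction of non-adjacent 5-s glide segments with pitch-steepness and
roll-stability filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats

from .errors import ConfigurationError, InsufficientDataError
from .seawater import DensityProfile

__all__ = [
    "TagRecord",
    "DivePhases",
    "GlideSegment",
    "SpeedCalibration",
    "SegmentFilters",
    "SEGMENT_COLUMNS",
    "compute_pitch_roll",
    "detect_glides",
    "calibrate_speed",
    "speed_from_depth_pitch",
    "segment_dives",
    "extract_glide_segments",
    "roll_circular_variance",
    "downsample_mean",
]

logger = logging.getLogger(__name__)

GRAVITY = 9.8
SEGMENT_COLUMNS = [
    "individual_id",
    "dive_id",
    "phase",
    "v",
    "a",
    "sigma_a",
    "d",
    "p",
    "rho_sw",
    "roll_circvar",
]


@dataclass
class TagRecord:
    """One individual's tag record with whale-frame acceleration.

    ``time`` indexes the accelerometer channel; depth is stored on the
    same regular timeline (records with a slower depth channel are
    interpolated onto it at load time).
    """

    individual_id: str
    sample_rate: float
    time: np.ndarray
    depth: np.ndarray
    accel: np.ndarray  # (n, 3): longitudinal, lateral, dorso-ventral
    propeller_rate: Optional[np.ndarray] = None
    location_tag: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise ValueError("accel must have shape (n, 3)")
        if not (len(self.time) == len(self.depth) == len(self.accel)):
            raise ValueError("channel lengths differ")
        if len(self.time) > 1:
            dt = np.diff(self.time)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-3, atol=1e-6):
                raise ValueError("time must be strictly increasing and regular")
        if np.any(self.depth < -1.0):
            raise ValueError("depth below -1 m (surface sensor-noise bound)")
        if np.any(np.abs(self.accel) >= 40.0):
            raise ValueError("acceleration magnitude >= 40 m s^-2")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass
class DivePhases:
    """Phase boundaries of one dive (times in record seconds)."""

    dive_id: int
    start: float
    end: float
    descent_end: float
    ascent_start: float
    max_depth: float

    def phase_of(self, t: float) -> Optional[str]:
        if not (self.start <= t <= self.end):
            return None
        if t < self.descent_end:
            return "descent"
        if t > self.ascent_start:
            return "ascent"
        return "bottom"


@dataclass(frozen=True)
class GlideSegment:
    """One 5-s glide observation (row schema of the segment table)."""

    individual_id: str
    dive_id: int
    phase: str
    v: float
    a: float
    sigma_a: float
    d: float
    p: float
    rho_sw: float
    roll_circvar: float


@dataclass(frozen=True)
class SpeedCalibration:
    """Linear propeller-rate -> speed calibration."""

    slope: float
    intercept: float
    r_squared: float
    resolution: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValueError("r_squared outside [0, 1]")

    def speed(self, propeller_rate) -> np.ndarray:
        return self.slope * np.asarray(propeller_rate, dtype=float) + self.intercept


def downsample_mean(x: np.ndarray, factor: int) -> np.ndarray:
    """Mean-decimate a series (DTAG-style 50 -> 5 Hz downsampling)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    x = np.asarray(x, dtype=float)
    n = (len(x) // factor) * factor
    if x.ndim == 1:
        return x[:n].reshape(-1, factor).mean(axis=1)
    return x[:n].reshape(-1, factor, x.shape[1]).mean(axis=1)


def compute_pitch_roll(
    accel: np.ndarray,
    sample_rate: float,
    smoothing_window: float = 3.0,
    pitch_axis: str = "longitudinal",
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pitch and roll time series (rad) from whale-frame acceleration.

    A moving-average low-pass estimates the gravitational component,
    which is normalized to |g| = 9.8.  Pitch is the arcsine of the
    normalized component on the pitch axis (negative = downward); roll
    comes from the lateral and dorso-ventral axes via arctangent.
    ``pitch_axis`` selects the longitudinal (surge) axis — standard
    gravity geometry — or ``"dorso_ventral"`` for tags where that axis
    carries sin(pitch).

    Returns (pitch, roll, reliable): ``reliable`` flags samples whose
    gravity-estimate magnitude is within 30% of 9.8 m s^-2.
    """
    accel = np.asarray(accel, dtype=float)
    if smoothing_window < 2.0 / sample_rate:
        raise ValueError("smoothing_window must cover at least 2 samples")
    win = max(int(round(smoothing_window * sample_rate)), 2)
    grav = ndimage.uniform_filter1d(accel, size=win, axis=0, mode="nearest")
    norm = np.linalg.norm(grav, axis=1)
    reliable = np.abs(norm - GRAVITY) <= 0.3 * GRAVITY
    safe_norm = np.where(norm > 0, norm, 1.0)
    unit = grav / safe_norm[:, None]
    axis = {"longitudinal": 0, "dorso_ventral": 2}[pitch_axis]
    pitch = np.arcsin(np.clip(unit[:, axis], -1.0, 1.0))
    roll = np.arctan2(-unit[:, 1], unit[:, 2])
    return pitch, roll, reliable


def detect_glides(
    accel_dv: np.ndarray,
    sample_rate: float,
    highpass_cutoff: float = 0.2,
    stroke_threshold: float = 0.3,
    closing_window: float = 1.0,
) -> List[Tuple[float, float]]:
    """Glide intervals (s) from the dorso-ventral accelerometer axis.

    The signal is high-pass filtered (zero-phase 2nd-order Butterworth at
    ``highpass_cutoff``) to remove gravitational components; its absolute
    value is closed morphologically over ``closing_window`` seconds to
    form a stroking envelope, which is compared with ``stroke_threshold``.
    Glides are the maximal intervals where the envelope stays below
    threshold; together with stroking intervals they tile the record.
    """
    if not (0.05 <= highpass_cutoff <= 1.0):
        raise ValueError("highpass_cutoff outside [0.05, 1] Hz")
    if not (0.0 < stroke_threshold <= 2.0):
        raise ValueError("stroke_threshold outside (0, 2] m s^-2")
    x = np.asarray(accel_dv, dtype=float)
    min_len = int(np.ceil(5.0 * sample_rate / highpass_cutoff))
    if len(x) < min_len:
        raise InsufficientDataError(
            f"series shorter than 5x the filter impulse-response scale ({min_len} samples)"
        )
    sos = signal.butter(2, highpass_cutoff, btype="highpass", fs=sample_rate, output="sos")
    hp = signal.sosfiltfilt(sos, x)
    size = max(int(round(closing_window * sample_rate)), 1)
    envelope = ndimage.grey_closing(np.abs(hp), size=size, mode="nearest")
    stroking = envelope > stroke_threshold
    glide_mask = ~stroking
    edges = np.diff(glide_mask.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0] + 1)
    if glide_mask[0]:
        starts.insert(0, 0)
    if glide_mask[-1]:
        ends.append(len(x))
    return [(s / sample_rate, e / sample_rate) for s, e in zip(starts, ends)]


def speed_from_depth_pitch(depth_rate, pitch, min_abs_sin: float = 0.5):
    """Speed through the water from vertical rate and pitch.

    v = |depth_rate / sin(pitch)|; raises when |sin(pitch)| falls below
    ``min_abs_sin`` (sin 30 deg by default, the segment filter bound),
    where the geometry is unreliable.
    """
    dr = np.asarray(depth_rate, dtype=float)
    sinp = np.sin(np.asarray(pitch, dtype=float))
    if np.any(np.abs(sinp) < min_abs_sin - 1e-12):
        raise ValueError("|sin(pitch)| below the filter bound")
    out = np.abs(dr / sinp)
    return float(out) if out.ndim == 0 else out


def roll_circular_variance(roll: np.ndarray) -> float:
    """Circular variance 1 - |mean unit vector| of roll angles, in [0, 1]."""
    roll = np.asarray(roll, dtype=float)
    if roll.size < 2:
        raise ValueError("need at least 2 samples")
    return float(1.0 - np.abs(np.mean(np.exp(1j * roll))))


def calibrate_speed(
    propeller_rate: np.ndarray,
    depth: np.ndarray,
    pitch: np.ndarray,
    sample_rate: float,
    window: float = 5.0,
    min_abs_sin_pitch: float = 0.9,
) -> SpeedCalibration:
    """Propeller calibration by regression against depth-rate speed.

    The record is split into consecutive ``window``-second blocks; in
    blocks whose mean |sin(pitch)| exceeds ``min_abs_sin_pitch`` the
    reference speed is |mean vertical rate| / |mean sin(pitch)| and an
    ordinary least-squares line of reference speed on rotation rate is
    fitted (the predictive direction, since the line is then applied to
    rotation data).  Resolution is the speed increment of one rotation
    per window.
    """
    depth = np.asarray(depth, dtype=float)
    n_win = int(len(depth) // (window * sample_rate))
    rates, speeds = [], []
    block = int(window * sample_rate)
    sinp = np.sin(np.asarray(pitch, dtype=float))
    for i in range(n_win):
        sl = slice(i * block, (i + 1) * block)
        mean_sin = np.mean(sinp[sl])
        if np.abs(mean_sin) <= min_abs_sin_pitch:
            continue
        rates.append(np.mean(propeller_rate[sl]))
        rate_of_depth = (depth[sl][-1] - depth[sl][0]) / ((block - 1) / sample_rate)
        speeds.append(np.abs(rate_of_depth / mean_sin))
    if len(rates) < 10:
        raise InsufficientDataError(
            f"only {len(rates)} qualifying windows (need >= 10)"
        )
    fit = stats.linregress(np.asarray(rates), np.asarray(speeds))
    return SpeedCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        resolution=float(fit.slope / window),
    )


def _smooth(x: np.ndarray, sample_rate: float, seconds: float) -> np.ndarray:
    win = max(int(round(seconds * sample_rate)), 1)
    return ndimage.uniform_filter1d(np.asarray(x, dtype=float), size=win, mode="nearest")


def segment_dives(
    depth: np.ndarray,
    sample_rate: float,
    pitch: Optional[np.ndarray] = None,
    dive_threshold: float = 20.0,
    bottom_fraction: float = 0.75,
    pitch_smooth: float = 5.0,
) -> List[DivePhases]:
    """Split a depth record into dives with descent/bottom/ascent phases.

    A dive is an excursion deeper than ``dive_threshold``.  Descent runs
    from the start of the dive until smoothed pitch first becomes
    non-negative or depth first exceeds ``bottom_fraction`` x max depth,
    whichever happens first; the ascent boundary is found symmetrically
    from the end of the dive.  Without a pitch channel only the depth
    criterion applies.
    """
    depth = np.asarray(depth, dtype=float)
    deep = depth > dive_threshold
    if not np.any(deep):
        return []
    sm_pitch = None
    if pitch is not None:
        sm_pitch = _smooth(pitch, sample_rate, pitch_smooth)
    edges = np.diff(deep.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0] + 1)
    if deep[0]:
        starts.insert(0, 0)
    if deep[-1]:
        ends.append(len(depth))
    dives: List[DivePhases] = []
    for dive_id, (s, e) in enumerate(zip(starts, ends)):
        d_seg = depth[s:e]
        max_depth = float(np.max(d_seg))
        depth_cond = d_seg >= bottom_fraction * max_depth
        if sm_pitch is not None:
            p_seg = sm_pitch[s:e]
            desc_cond = (p_seg >= 0.0) | depth_cond
            asc_cond = (p_seg <= 0.0) | depth_cond
        else:
            desc_cond = depth_cond
            asc_cond = depth_cond
        desc_idx = int(np.argmax(desc_cond)) if np.any(desc_cond) else len(d_seg) - 1
        asc_idx = int(len(d_seg) - 1 - np.argmax(asc_cond[::-1])) if np.any(asc_cond) else 0
        if asc_idx < desc_idx:  # degenerate: meet at the deepest point
            desc_idx = asc_idx = int(np.argmax(d_seg))
        dives.append(
            DivePhases(
                dive_id=dive_id,
                start=s / sample_rate,
                end=(e - 1) / sample_rate,
                descent_end=(s + desc_idx) / sample_rate,
                ascent_start=(s + asc_idx) / sample_rate,
                max_depth=max_depth,
            )
        )
    return dives


@dataclass(frozen=True)
class SegmentFilters:
    """Filters applied to candidate 5-s glide segments."""

    window: float = 5.0
    min_pitch_deg: float = 30.0
    max_roll_circvar: float = 0.1
    smoothing_window: float = 3.0
    pitch_axis: str = "longitudinal"
    depth_rate_smooth: float = 1.0


def _alternate_windows(t0: float, t1: float, window: float) -> List[Tuple[float, float]]:
    """Keep windows 1, 3, 5, ... of the 5-s partition of [t0, t1]."""
    n_full = int(np.floor((t1 - t0) / window + 1e-9))
    return [
        (t0 + k * window, t0 + (k + 1) * window) for k in range(n_full) if k % 2 == 0
    ]


def extract_glide_segments(
    record: TagRecord,
    glide_intervals: Sequence[Tuple[float, float]],
    phases: Iterable[DivePhases],
    density_profile: DensityProfile,
    filters: SegmentFilters = SegmentFilters(),
    speed_calibration: Optional[SpeedCalibration] = None,
) -> pd.DataFrame:
    """Extract the table of filtered 5-s glide segments from one record.

    Each glide is partitioned into consecutive ``window``-second windows
    from its start; alternate windows (1st, 3rd, ...) are kept to reduce
    autocorrelation and trailing partial windows are discarded.  Per kept
    window, acceleration ``a`` is the OLS slope of speed versus time,
    ``sigma_a`` the RMS of the fit residuals, and ``v``, ``d``, ``p`` are
    window means.  Windows are dropped unless they fall entirely within a
    descent or ascent phase, are steeper than ``min_pitch_deg``, have
    roll circular variance below ``max_roll_circvar`` and a reliable
    gravity estimate.  Speed comes from the calibrated propeller channel
    when present, otherwise from vertical rate / sin(pitch).
    """
    fs = record.sample_rate
    pitch, roll, reliable = compute_pitch_roll(
        record.accel, fs, filters.smoothing_window, filters.pitch_axis
    )
    if record.propeller_rate is not None:
        if speed_calibration is None:
            raise ConfigurationError(
                "record has a propeller channel but no speed calibration was given"
            )
        speed = speed_calibration.speed(record.propeller_rate)
    else:
        depth_rate = _smooth(
            np.gradient(record.depth) * fs, fs, filters.depth_rate_smooth
        )
        sinp = np.sin(pitch)
        safe = np.where(np.abs(sinp) > 0.05, sinp, np.nan)
        speed = np.abs(depth_rate / safe)

    phase_list = list(phases)
    min_sin = np.sin(np.deg2rad(filters.min_pitch_deg))
    t_start = record.time[0]
    counts = {"candidate": 0, "phase": 0, "pitch": 0, "roll": 0, "gravity": 0, "speed": 0}
    rows = []
    for g0, g1 in glide_intervals:
        for w0, w1 in _alternate_windows(g0, g1, filters.window):
            counts["candidate"] += 1
            i0 = int(round((w0 - t_start) * fs))
            i1 = int(round((w1 - t_start) * fs))
            if i0 < 0 or i1 > len(record.time):
                continue
            mid = 0.5 * (w0 + w1)
            phase = None
            dive_id = None
            for dp in phase_list:
                ph = dp.phase_of(mid)
                if ph is not None and dp.start <= w0 and w1 <= dp.end:
                    phase, dive_id = ph, dp.dive_id
                    break
            if phase not in ("descent", "ascent"):
                counts["phase"] += 1
                continue
            p_mean = float(np.mean(pitch[i0:i1]))
            if np.abs(np.sin(p_mean)) < min_sin:
                counts["pitch"] += 1
                continue
            rcv = roll_circular_variance(roll[i0:i1])
            if rcv >= filters.max_roll_circvar:
                counts["roll"] += 1
                continue
            if not np.all(reliable[i0:i1]):
                counts["gravity"] += 1
                continue
            v_win = speed[i0:i1]
            t_win = record.time[i0:i1]
            if np.any(~np.isfinite(v_win)) or np.mean(v_win) <= 0:
                counts["speed"] += 1
                continue
            slope, intercept = np.polyfit(t_win - t_win[0], v_win, 1)
            resid = v_win - (intercept + slope * (t_win - t_win[0]))
            d_mean = float(np.mean(record.depth[i0:i1]))
            rows.append(
                GlideSegment(
                    individual_id=record.individual_id,
                    dive_id=int(dive_id),
                    phase=phase,
                    v=float(np.mean(v_win)),
                    a=float(slope),
                    sigma_a=float(np.sqrt(np.mean(resid**2))),
                    d=d_mean,
                    p=p_mean,
                    rho_sw=float(density_profile(d_mean)),
                    roll_circvar=float(rcv),
                )
            )
    logger.info(
        "extract_glide_segments[%s]: %d candidate windows, kept %d (dropped: %s)",
        record.individual_id,
        counts["candidate"],
        len(rows),
        {k: v for k, v in counts.items() if k != "candidate"},
    )
    return pd.DataFrame([r.__dict__ for r in rows], columns=SEGMENT_COLUMNS)
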