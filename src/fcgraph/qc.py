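"""Temporal cleaning and motion scrubbing at the ROI level.

Implements the quality-control stage of a resting-state pipeline once ROI
time series have been extracted: initial-volume discard, polynomial
detrending plus zero-phase band-pass filtering, framewise displacement (FD)
and DVARS computation, and frame censoring ("scrubbing").

FD follows the Power convention: the sum of absolute framewise changes of
the three translations (mm) plus the three rotations converted to mm of arc
on a sphere of configurable radius (default 50 mm).  DVARS is the
root-mean-square frame-to-frame signal change across ROIs expressed as a
fraction of the grand-mean signal, so the conventional 0.05 threshold reads
"5% of mean signal".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .timeseries import RoiTimeSeries

DEFAULT_FD_THRESHOLD_MM = 0.8
DEFAULT_DVARS_THRESHOLD = 0.05
DEFAULT_HEAD_RADIUS_MM = 50.0
DEFAULT_MIN_FRAMES = 100
DEFAULT_BAND_HZ = (0.009, 0.1)
DEFAULT_N_DISCARD = 5


@dataclass
class QcReport:
    """Per-frame motion/QC summary for one subject-session.

    ``fd`` and ``dvars`` are defined as 0 at the first frame.  ``keep`` is
    the censoring mask (True = frame survives).  ``excluded`` flags a subject
    whose surviving frame count fell below the configured minimum — a soft
    exclusion signal, distinct from hard validation errors.
    """

    fd: np.ndarray
    dvars: np.ndarray
    keep: np.ndarray
    fd_threshold: float = DEFAULT_FD_THRESHOLD_MM
    dvars_threshold: float = DEFAULT_DVARS_THRESHOLD
    min_frames: int = DEFAULT_MIN_FRAMES
    subject: str = "sub"
    session: str = "1"

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, float)
        self.dvars = np.asarray(self.dvars, float)
        self.keep = np.asarray(self.keep, bool)
        if not (len(self.fd) == len(self.dvars) == len(self.keep)):
            raise ValueError("fd, dvars and keep must have equal length")

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    @property
    def excluded(self) -> bool:
        return self.n_kept < self.min_frames

    @property
    def mean_abs_displacement(self) -> float:
        """Mean FD over frames 2..T (mm)."""
        return float(self.fd[1:].mean()) if len(self.fd) > 1 else 0.0

    @property
    def max_abs_displacement(self) -> float:
        return float(self.fd.max()) if len(self.fd) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(len(self.fd)),
            "fd_mm": self.fd,
            "dvars": self.dvars,
            "keep": self.keep.astype(int),
        })

    def summary(self) -> dict:
        return {
            "subject": self.subject,
            "session": self.session,
            "n_frames": int(len(self.fd)),
            "n_kept": self.n_kept,
            "excluded": bool(self.excluded),
            "mean_abs_displacement_mm": self.mean_abs_displacement,
            "max_abs_displacement_mm": self.max_abs_displacement,
            "fd_threshold": self.fd_threshold,
            "dvars_threshold": self.dvars_threshold,
        }


def discard_initial_volumes(ts: RoiTimeSeries, n_discard: int = DEFAULT_N_DISCARD,
                            motion: np.ndarray | None = None):
    """Drop the first ``n_discard`` frames of each acquisition run.

    Scanner signal needs several TRs to reach steady state, so the leading
    volumes of every run are conventionally discarded.  If ``motion`` is
    given the same frames are dropped from the motion trace and the pair is
    returned; otherwise only the trimmed series is returned.
    """
    if n_discard < 0:
        raise ValueError("n_discard must be >= 0")
    if any(n_discard >= r for r in ts.run_lengths):
        raise ValueError(
            f"n_discard={n_discard} >= frames in a run {ts.run_lengths}")
    keep = np.ones(ts.n_frames, bool)
    start = 0
    new_runs = []
    for rl in ts.run_lengths:
        keep[start:start + n_discard] = False
        new_runs.append(rl - n_discard)
        start += rl
    out = ts.with_data(ts.data[keep], run_lengths=tuple(new_runs))
    if motion is not None:
        motion = np.asarray(motion, float)
        if motion.shape[0] != ts.n_frames:
            raise ValueError("motion trace frame count mismatch")
        return out, motion[keep]
    return out


def _detrend_poly(x: np.ndarray, order: int = 2) -> np.ndarray:
    """Remove polynomial trends up to ``order`` (including the mean)."""
    n = x.shape[0]
    t = np.linspace(-1.0, 1.0, n)
    basis = np.vander(t, order + 1, increasing=True)  # [1, t, t^2, ...]
    coef, *_ = np.linalg.lstsq(basis, x, rcond=None)
    return x - basis @ coef


def bandpass_detrend(ts: RoiTimeSeries, low_hz: float = DEFAULT_BAND_HZ[0],
                     high_hz: float = DEFAULT_BAND_HZ[1],
                     detrend_order: int = 2,
                     method: str = "fft") -> RoiTimeSeries:
    """Polynomial detrend (orders 1 and 2) then zero-phase band-pass.

    ``method="fft"`` applies an ideal spectral mask retaining frequency bins
    with low_hz <= |f| <= high_hz (sharp band edges); ``method="butter"``
    uses a 4th-order Butterworth applied forward-backward (``filtfilt``).
    Output length equals input length in either case.
    """
    nyquist = 1.0 / (2.0 * ts.tr)
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyquist:g} Hz at TR={ts.tr:g}s)")
    x = _detrend_poly(ts.data, detrend_order)
    if method == "fft":
        n = x.shape[0]
        freqs = np.fft.rfftfreq(n, d=ts.tr)
        mask = (freqs >= low_hz) & (freqs <= high_hz)
        spec = np.fft.rfft(x, axis=0)
        spec[~mask] = 0.0
        filtered = np.fft.irfft(spec, n=n, axis=0)
    elif method == "butter":
        sos = sps.butter(4, [low_hz, high_hz], btype="bandpass",
                         fs=1.0 / ts.tr, output="sos")
        filtered = sps.sosfiltfilt(sos, x, axis=0)
    else:
        raise ValueError(f"unknown filter method {method!r}")
    return ts.with_data(filtered, run_lengths=ts.run_lengths)


def compute_fd(motion: np.ndarray,
               head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM,
               rotations_in_degrees: bool = False) -> np.ndarray:
    """Framewise displacement (mm) from a frames x 6 motion trace.

    FD(t) = sum_i |d trans_i(t)| + r * sum_i |d rot_i(t)|, with rotations in
    radians converted to arc length on a ``head_radius_mm`` sphere.
    FD at the first frame is defined as 0.
    """
    motion = np.asarray(motion, float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion trace must be frames x 6")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    rot = motion[:, 3:]
    if rotations_in_degrees:
        rot = np.deg2rad(rot)
    d_trans = np.abs(np.diff(motion[:, :3], axis=0)).sum(axis=1)
    d_rot = np.abs(np.diff(rot, axis=0)).sum(axis=1)
    fd = np.zeros(motion.shape[0])
    fd[1:] = d_trans + head_radius_mm * d_rot
    return fd


def compute_dvars(ts: RoiTimeSeries, divisor: float | None = None) -> np.ndarray:
    """DVARS: RMS across ROIs of the frame-to-frame signal change.

    The raw RMS is divided by ``divisor`` (default: the grand mean of the
    series) so the result is a fractional signal change and the conventional
    0.05 threshold applies.  A detrended/zero-mean series has no meaningful
    grand mean; pass the pre-filter grand mean explicitly in that case.
    """
    if ts.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if divisor is None:
        divisor = float(ts.data.mean())
    if divisor <= 0:
        raise ValueError(
            "grand-mean divisor must be positive; the signal must be "
            "mean-scaled positive or the divisor overridden")
    rms = np.sqrt(np.mean(np.diff(ts.data, axis=0) ** 2, axis=1))
    dvars = np.zeros(ts.n_frames)
    dvars[1:] = rms / divisor
    return dvars


def make_qc_report(ts: RoiTimeSeries, motion: np.ndarray,
                   fd_threshold: float = DEFAULT_FD_THRESHOLD_MM,
                   dvars_threshold: float = DEFAULT_DVARS_THRESHOLD,
                   head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM,
                   min_frames: int = DEFAULT_MIN_FRAMES,
                   flag_rule: str = "union",
                   rotations_in_degrees: bool = False,
                   dvars_divisor: float | None = None) -> QcReport:
    """Compute FD + DVARS and the censoring mask for one subject-session.

    ``flag_rule="union"`` censors a frame when either metric exceeds its
    threshold (the conservative convention); ``"intersection"`` requires
    both.
    """
    fd = compute_fd(motion, head_radius_mm, rotations_in_degrees)
    dvars = compute_dvars(ts, divisor=dvars_divisor)
    fd_bad = fd > fd_threshold
    dv_bad = dvars > dvars_threshold
    if flag_rule == "union":
        bad = fd_bad | dv_bad
    elif flag_rule == "intersection":
        bad = fd_bad & dv_bad
    else:
        raise ValueError("flag_rule must be 'union' or 'intersection'")
    return QcReport(fd=fd, dvars=dvars, keep=~bad,
                    fd_threshold=fd_threshold, dvars_threshold=dvars_threshold,
                    min_frames=min_frames, subject=ts.subject,
                    session=ts.session)


def interpolate_censored(ts: RoiTimeSeries, keep: np.ndarray) -> RoiTimeSeries:
    """Replace censored frames by linear interpolation over kept frames.

    Temporal filtering before censoring would otherwise smear the
    high-amplitude artifact of a flagged frame into its neighbours; the
    interpolated values are placeholders that are themselves removed when
    the mask is finally applied.  Leading/trailing censored frames take the
    nearest kept value.
    """
    keep = np.asarray(keep, bool)
    if len(keep) != ts.n_frames:
        raise ValueError("mask length must match frame count")
    if keep.all():
        return ts
    if not keep.any():
        raise ValueError("cannot interpolate: no kept frames")
    idx = np.arange(ts.n_frames)
    data = ts.data.copy()
    for j in range(ts.n_rois):
        data[~keep, j] = np.interp(idx[~keep], idx[keep], data[keep, j])
    return ts.with_data(data, run_lengths=ts.run_lengths)


def scrub(ts: RoiTimeSeries, qc: QcReport) -> tuple[RoiTimeSeries, QcReport]:
    """Remove censored frames from the series.

    Returns the surviving-frame series and a report restricted to the kept
    frames (so scrubbing is idempotent: re-deriving a mask from the output
    removes nothing).  Check ``qc.excluded`` before using the output in
    group statistics.
    """
    if len(qc.keep) != ts.n_frames:
        raise ValueError("QC report frame count does not match series")
    kept = ts.data[qc.keep]
    # run structure no longer meaningful after censoring
    out = ts.with_data(kept)
    out_qc = QcReport(fd=qc.fd[qc.keep], dvars=qc.dvars[qc.keep],
                      keep=np.ones(out.n_frames, bool),
                      fd_threshold=qc.fd_threshold,
                      dvars_threshold=qc.dvars_threshold,
                      min_frames=qc.min_frames, subject=qc.subject,
                      session=qc.session)
    return out, out_qc
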