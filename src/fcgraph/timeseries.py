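"""ROI time-series container shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class RoiTimeSeries:
    """A frames x ROIs signal matrix for one subject-session.

    Attributes
    ----------
    data : ndarray, shape (n_frames, n_rois)
        ROI-mean BOLD signal per frame.
    tr : float
        Repetition time in seconds.
    subject, session : str
        Identifiers; ``session`` is conventionally "1" (pre) or "2" (post).
    roi_names : tuple of str
        Column names; must match the partition used downstream.
    run_lengths : tuple of int
        Frame counts of the concatenated acquisition runs; sums to n_frames.
        Volume discard operates per run.
    """

    data: np.ndarray
    tr: float
    subject: str = "sub"
    session: str = "1"
    roi_names: tuple[str, ...] = ()
    run_lengths: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (frames x ROIs)")
        if not self.roi_names:
            self.roi_names = tuple(f"ROI_{i + 1:03d}" for i in range(self.data.shape[1]))
        if len(self.roi_names) != self.data.shape[1]:
            raise ValueError("roi_names length must match data width")
        if not self.run_lengths:
            self.run_lengths = (self.data.shape[0],)
        if sum(self.run_lengths) != self.data.shape[0]:
            raise ValueError("run_lengths must sum to the frame count")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray,
                  run_lengths: tuple[int, ...] | None = None) -> "RoiTimeSeries":
        """Copy with replaced signal (same metadata)."""
        return replace(self, data=np.asarray(data, float),
                       run_lengths=run_lengths or (np.asarray(data).shape[0],))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.data, columns=list(self.roi_names)).to_csv(
            path, sep="\t", index=False, float_format="%.8g")

    @classmethod
    def from_tsv(cls, path: str | Path, tr: float, subject: str = "sub",
                 session: str = "1",
                 run_lengths: tuple[int, ...] = ()) -> "RoiTimeSeries":
        df = pd.read_csv(path, sep="\t")
        return cls(df.to_numpy(float), tr=tr, subject=subject, session=session,
                   roi_names=tuple(df.columns), run_lengths=run_lengths)


def write_motion(path: str | Path, motion: np.ndarray) -> None:
    """Write a frames x 6 motion trace (3 translations mm, 3 rotations rad)."""
    motion = np.asarray(motion, float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion trace must be frames x 6")
    np.savetxt(path, motion, fmt="%.10g")


def read_motion(path: str | Path) -> np.ndarray:
    motion = np.loadtxt(path, ndmin=2)
    if motion.shape[1] != 6:
        raise ValueError(f"motion file {path} has {motion.shape[1]} columns, expected 6")
    if not np.all(np.isfinite(motion)):
        raise ValueError(f"motion file {path} contains non-finite values")
    return motion
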