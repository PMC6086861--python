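"""Functional-connectivity matrices and network-block summaries.

A subject-session connectome is the ROI x ROI matrix of Fisher r-to-z
transformed Pearson correlations between ROI time series.  Block summaries
average z over all ROI pairs within (intra) or between (inter) the eight
systems of the partition, giving 8 intra + 28 inter = 36 outcome values per
connectome.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .partition import NetworkPartition
from .timeseries import RoiTimeSeries

#: correlations are clipped to +/-(1 - R_CLIP) before atanh so z stays finite
R_CLIP = 1e-7


def fisher_z(r):
    """Fisher r-to-z transform, z = atanh(r).

    Accepts scalars or arrays.  |r| within 1e-7 of 1 is clipped so the
    transform stays finite; |r| > 1 raises.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    clipped = np.clip(r, -(1 - R_CLIP), 1 - R_CLIP)
    out = np.arctanh(clipped)
    return float(out) if out.ndim == 0 else out


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z FC matrix with zero diagonal."""

    values: np.ndarray
    roi_names: tuple[str, ...] = ()
    subject: str = "sub"
    session: str = "1"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("connectivity matrix contains non-finite values")
        if np.max(np.abs(v - v.T)) > 1e-12:
            raise ValueError("connectivity matrix must be symmetric (tol 1e-12)")
        if np.any(np.diag(v) != 0):
            raise ValueError("connectivity matrix diagonal must be zero")
        if not self.roi_names:
            self.roi_names = tuple(f"ROI_{i + 1:03d}" for i in range(v.shape[0]))
        if len(self.roi_names) != v.shape[0]:
            raise ValueError("roi_names length must match matrix dimension")
        self.values = v

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=list(self.roi_names),
                     columns=list(self.roi_names)).to_csv(
            path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, subject: str = "sub",
                 session: str = "1") -> "ConnectivityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(float), roi_names=tuple(df.columns),
                   subject=subject, session=session)


def fc_matrix(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation between every ROI pair, Fisher z-transformed.

    Computed on the frames present in ``ts`` (scrub before calling to use
    kept frames only).  A zero-variance ROI is an error naming the ROI:
    its correlations are undefined.
    """
    if ts.n_frames < 2:
        raise ValueError("need at least 2 frames for correlation")
    dead = np.flatnonzero(np.ptp(ts.data, axis=0) == 0)
    if dead.size:
        names = [ts.roi_names[i] for i in dead]
        raise ValueError(f"zero-variance ROI(s): {names}")
    r = np.corrcoef(ts.data, rowvar=False)
    # numerical safety: corrcoef can exceed 1 by epsilon
    np.clip(r, -1.0, 1.0, out=r)
    z = fisher_z(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return ConnectivityMatrix(z, roi_names=ts.roi_names,
                              subject=ts.subject, session=ts.session)


@dataclass
class BlockFcTable:
    """Mean Fisher-z per system pair (8x8 symmetric; 36 unique cells)."""

    table: pd.DataFrame  # systems x systems, NaN where undefined
    n_pairs: pd.DataFrame
    subject: str = "sub"
    session: str = "1"

    @property
    def systems(self) -> tuple[str, ...]:
        return tuple(self.table.index)

    def value(self, a: str, b: str) -> float:
        return float(self.table.loc[a, b])

    def to_long(self) -> pd.DataFrame:
        """Long format: one row per unique (ordered) system pair."""
        systems = list(self.table.index)
        rows = []
        for i, a in enumerate(systems):
            for b in systems[i:]:
                rows.append({"system_a": a, "system_b": b,
                             "mean_z": self.table.loc[a, b],
                             "n_pairs": int(self.n_pairs.loc[a, b])})
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False, float_format="%.10g")


def block_summary(fc: ConnectivityMatrix,
                  partition: NetworkPartition) -> BlockFcTable:
    """Average z over ROI pairs of each system block.

    Intra-system cells average the off-diagonal pairs within the system
    (undefined — NaN — for a system with fewer than 2 ROIs); inter-system
    cells average all cross-system pairs.  Both positive and negative z
    contribute: the positive-only rule applies to graph construction, not to
    block summaries.
    """
    if partition.n_rois != fc.n_rois:
        raise ValueError(
            f"partition has {partition.n_rois} ROIs, matrix has {fc.n_rois}")
    systems = list(partition.systems)
    k = len(systems)
    means = np.full((k, k), np.nan)
    counts = np.zeros((k, k), dtype=int)
    idx = {s: partition.indices(s) for s in systems}
    v = fc.values
    for i, a in enumerate(systems):
        ia = idx[a]
        for j in range(i, k):
            b = systems[j]
            ib = idx[b]
            if i == j:
                if len(ia) < 2:
                    continue
                sub = v[np.ix_(ia, ia)]
                iu = np.triu_indices(len(ia), k=1)
                vals = sub[iu]
            else:
                if len(ia) == 0 or len(ib) == 0:
                    continue
                vals = v[np.ix_(ia, ib)].ravel()
            means[i, j] = means[j, i] = vals.mean()
            counts[i, j] = counts[j, i] = vals.size
    return BlockFcTable(
        table=pd.DataFrame(means, index=systems, columns=systems),
        n_pairs=pd.DataFrame(counts, index=systems, columns=systems),
        subject=fc.subject, session=fc.session)
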