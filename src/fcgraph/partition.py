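"""ROI-to-system partition defining the block structure of the connectome.

The whole-brain parcellation groups regions of interest (ROIs) into seven
intrinsic connectivity networks (ICNs) plus a subcortical system, giving an
8x8 block structure over the ROI-by-ROI connectivity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical system labels: 7 cortical ICNs + subcortical.
SYSTEMS: tuple[str, ...] = (
    "SVN", "DAN", "DMN", "ECN", "SMN", "Visual", "Limbic", "Subcortical",
)

# Default ROI allocation for the 141-region layout: 111 cortical regions
# spread over the 7 ICNs plus 30 subcortical regions.  The per-system counts
# are a synthetic stand-in layout; real atlases carry their own partition file.
_DEFAULT_COUNTS_141 = {
    "SVN": 16, "DAN": 15, "DMN": 24, "ECN": 18,
    "SMN": 15, "Visual": 14, "Limbic": 9, "Subcortical": 30,
}


@dataclass(frozen=True)
class NetworkPartition:
    """Assignment of each ROI to exactly one system label.

    Parameters
    ----------
    roi_names : list of str
        One name per ROI, in matrix/time-series column order.
    labels : list of str
        System label per ROI; same length as ``roi_names``.
    """

    roi_names: tuple[str, ...]
    labels: tuple[str, ...]
    systems: tuple[str, ...] = field(default=SYSTEMS)

    def __post_init__(self) -> None:
        if len(self.roi_names) != len(self.labels):
            raise ValueError("roi_names and labels must have equal length")
        unknown = set(self.labels) - set(self.systems)
        if unknown:
            raise ValueError(f"labels not in declared systems: {sorted(unknown)}")
        if len(set(self.roi_names)) != len(self.roi_names):
            raise ValueError("duplicate ROI names in partition")

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    def indices(self, system: str) -> np.ndarray:
        """Integer ROI indices belonging to ``system``."""
        lab = np.asarray(self.labels)
        return np.flatnonzero(lab == system)

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "roi_index": np.arange(self.n_rois),
            "roi_name": list(self.roi_names),
            "system": list(self.labels),
        })

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NetworkPartition":
        df = pd.read_csv(path, sep="\t")
        required = {"roi_index", "roi_name", "system"}
        if not required.issubset(df.columns):
            raise ValueError(f"partition file must have columns {sorted(required)}")
        df = df.sort_values("roi_index")
        systems = tuple(dict.fromkeys(df["system"]))  # preserve order
        base = tuple(s for s in SYSTEMS if s in systems)
        extra = tuple(s for s in systems if s not in SYSTEMS)
        return cls(tuple(df["roi_name"].astype(str)), tuple(df["system"]),
                   systems=base + extra)


def default_partition(roi_count: int = 141) -> NetworkPartition:
    """Build the default partition for ``roi_count`` ROIs.

    For 141 ROIs this is the stand-in 111-cortical + 30-subcortical layout.
    For other counts each system receives a share proportional to that layout
    (every system gets at least 2 ROIs so intra-system blocks are defined),
    which keeps reduced-scale simulations structurally faithful.
    """
    if roi_count < 2 * len(SYSTEMS):
        raise ValueError(f"roi_count must be >= {2 * len(SYSTEMS)} so every "
                         "system has at least 2 ROIs")
    if roi_count == 141:
        counts = dict(_DEFAULT_COUNTS_141)
    else:
        weights = np.array([_DEFAULT_COUNTS_141[s] for s in SYSTEMS], float)
        raw = weights / weights.sum() * (roi_count - 2 * len(SYSTEMS))
        extra = np.floor(raw).astype(int)
        # distribute the remainder by largest fractional part, ties by order
        rem = roi_count - 2 * len(SYSTEMS) - extra.sum()
        order = np.argsort(-(raw - extra), kind="stable")
        for i in order[:rem]:
            extra[i] += 1
        counts = {s: 2 + int(e) for s, e in zip(SYSTEMS, extra)}
    names, labels = [], []
    for sys_name in SYSTEMS:
        for k in range(counts[sys_name]):
            names.append(f"{sys_name}_{k + 1:02d}")
            labels.append(sys_name)
    return NetworkPartition(tuple(names), tuple(labels))
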