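"""Breast-density volumetrics: fibroglandular volume fraction and Volpara
density grades.

FGV is the percentage of fibroglandular voxels over fibroglandular-plus-fat
voxels summed across all slices; background never enters the ratio.  VDG
grades follow the BIRADS 4th-edition-style percent-dense-volume cut-offs
with lower-inclusive boundaries: grade 1 for PDV < 4.5, 2 for
4.5 <= PDV < 7.5, 3 for 7.5 <= PDV < 15.5, 4 for PDV >= 15.5.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import PairedTestResult, wilcoxon_signed_rank

__all__ = ["SegmentedVolume", "DensityResult", "compute_fgv", "classify_vdg",
           "fgv_paired_change", "LABEL_BACKGROUND", "LABEL_FAT", "LABEL_FG"]

LABEL_BACKGROUND, LABEL_FAT, LABEL_FG = 0, 1, 2
VDG_CUTOFFS = (4.5, 7.5, 15.5)


@dataclass
class SegmentedVolume:
    """Per-voxel labels over slices: 0 background, 1 fat, 2 fibroglandular."""

    labels: np.ndarray  # (n_slices, H, W) integer
    voxel_volume_mm3: float | None = None  # optional anisotropy weighting hook

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a (slices, H, W) array")
        bad = set(np.unique(self.labels)) - {LABEL_BACKGROUND, LABEL_FAT, LABEL_FG}
        if bad:
            raise ValueError(f"labels must be in {{0,1,2}}; found {sorted(bad)}")

    def counts(self) -> dict:
        vals, n = np.unique(self.labels, return_counts=True)
        c = dict(zip(vals.tolist(), n.tolist()))
        return {
            "background": c.get(LABEL_BACKGROUND, 0),
            "fat": c.get(LABEL_FAT, 0),
            "fibroglandular": c.get(LABEL_FG, 0),
        }


@dataclass(frozen=True)
class DensityResult:
    fgv_percent: float
    pdv_percent: float | None = None
    vdg: int | None = None


def compute_fgv(volume: SegmentedVolume) -> float:
    """100 * n_fibroglandular / (n_fibroglandular + n_fat) over all slices."""
    c = volume.counts()
    denom = c["fibroglandular"] + c["fat"]
    if denom == 0:
        raise ValueError("FGV undefined: no fibroglandular or fat voxels")
    return 100.0 * c["fibroglandular"] / denom


def classify_vdg(pdv_percent: float) -> int:
    """Volpara density grade 1-4 from percent dense volume (lower-inclusive)."""
    if not 0.0 <= pdv_percent <= 100.0:
        raise ValueError("PDV must lie in [0, 100]")
    # bisect_right makes each cutoff belong to the higher grade (lower-inclusive)
    return 1 + bisect_right(VDG_CUTOFFS, pdv_percent)


def fgv_paired_change(frame: pd.DataFrame) -> PairedTestResult:
    """Wilcoxon matched-pairs signed-rank test on post - baseline FGV.

    ``frame`` columns: participant, timepoint ('baseline'/'post'), value.
    Unpaired participants are dropped with a warning.
    """
    wide = frame.pivot_table(index="participant", columns="timepoint",
                             values="value")
    if not {"baseline", "post"}.issubset(wide.columns):
        raise ValueError("frame needs baseline and post timepoints")
    unpaired = wide.index[wide[["baseline", "post"]].isna().any(axis=1)]
    if len(unpaired):
        warnings.warn(f"dropping unpaired participants: {list(unpaired)}",
                      stacklevel=2)
        wide = wide.dropna(subset=["baseline", "post"])
    return wilcoxon_signed_rank((wide["post"] - wide["baseline"]).to_numpy())
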