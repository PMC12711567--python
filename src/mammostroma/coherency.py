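"""Structure-tensor coherency of fibre images.

For a region R the structure tensor is the region average

    J = [[<Ix*Ix>, <Ix*Iy>],
         [<Ix*Iy>, <Iy*Iy>]]

of products of image gradients, computed by centred finite differences
after Gaussian pre-smoothing at scale ``sigma``.  Coherency is the
eigenvalue anisotropy C = (l_max - l_min) / (l_max + l_min) in [0, 1]
(1 = perfectly aligned texture, 0 = isotropic); the dominant angle is the
orientation of the structures (the minor eigenvector of J, i.e. the
direction along which intensity varies least), in degrees in [0, 180)
measured from the image x (column) axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .stats import PairedTestResult, wilcoxon_signed_rank

__all__ = ["CoherencyResult", "region_coherency", "lobule_average",
           "coherency_change_test"]


@dataclass(frozen=True)
class CoherencyResult:
    coherency: float                 # in [0, 1]
    dominant_angle_deg: float        # in [0, 180); NaN when coherency == 0
    region: tuple[int, int, int, int]  # row0, col0, row1, col1 (exclusive)
    n_pixels: int


def _smoothed_gradients(image: np.ndarray, sigma: float):
    img = gaussian_filter(np.asarray(image, float), sigma, mode="nearest")
    gy, gx = np.gradient(img)       # d/drow, d/dcol
    return gx, gy


def region_coherency(image, region=None, sigma: float = 2.0) -> CoherencyResult:
    """Coherency and dominant orientation over a rectangular region.

    ``region`` is (row0, col0, row1, col1) with exclusive upper bounds;
    ``None`` uses the whole image.  Regions smaller than 3x3 are rejected.
    A zero-gradient (constant) region returns coherency 0 by convention,
    with an undefined (NaN) angle.
    """
    image = np.asarray(image, float)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    h, w = image.shape
    if region is None:
        region = (0, 0, h, w)
    r0, c0, r1, c1 = region
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError("region out of image bounds")
    if r1 - r0 < 3 or c1 - c0 < 3:
        raise ValueError("region must be at least 3x3")

    gx, gy = _smoothed_gradients(image, sigma)
    gx = gx[r0:r1, c0:c1]
    gy = gy[r0:r1, c0:c1]
    jxx = float(np.mean(gx * gx))
    jyy = float(np.mean(gy * gy))
    jxy = float(np.mean(gx * gy))

    trace = jxx + jyy
    n_px = (r1 - r0) * (c1 - c0)
    if trace == 0.0:
        return CoherencyResult(0.0, float("nan"), (r0, c0, r1, c1), n_px)
    spread = math.hypot(jxx - jyy, 2.0 * jxy)
    coh = spread / trace
    # gradient-dominant direction; structures run perpendicular to it
    grad_angle = 0.5 * math.atan2(2.0 * jxy, jxx - jyy)
    angle = (math.degrees(grad_angle) + 90.0) % 180.0
    return CoherencyResult(min(coh, 1.0), angle, (r0, c0, r1, c1), n_px)


def lobule_average(frame: pd.DataFrame, min_lobules: int = 3) -> pd.DataFrame:
    """Two-level averaging: regions within lobule, then lobules within
    participant/timepoint.

    ``frame`` columns: participant, timepoint, lobule, coherency.  Returns a
    paired long table (participant, timepoint, value).  Fewer than
    ``min_lobules`` lobules for a participant/timepoint triggers a warning,
    not an error; empty input is an error.
    """
    required = {"participant", "timepoint", "lobule", "coherency"}
    if frame.empty:
        raise ValueError("no coherency measurements to average")
    if not required.issubset(frame.columns):
        raise ValueError(f"frame must have columns {sorted(required)}")
    per_lobule = (
        frame.groupby(["participant", "timepoint", "lobule"])["coherency"]
        .mean()
        .reset_index()
    )
    out = []
    for (part, tp), grp in per_lobule.groupby(["participant", "timepoint"]):
        if len(grp) < min_lobules:
            warnings.warn(
                f"{part}/{tp}: only {len(grp)} lobules (>= {min_lobules} recommended)",
                stacklevel=2,
            )
        out.append({"participant": part, "timepoint": tp,
                    "value": float(grp["coherency"].mean()),
                    "n_lobules": len(grp)})
    return pd.DataFrame(out)


def coherency_change_test(paired: pd.DataFrame) -> PairedTestResult:
    """Two-sided Wilcoxon matched-pairs test on post - baseline coherency."""
    wide = paired.pivot_table(index="participant", columns="timepoint",
                              values="value").dropna()
    if not {"baseline", "post"}.issubset(wide.columns):
        raise ValueError("paired frame needs baseline and post timepoints")
    diffs = (wide["post"] - wide["baseline"]).to_numpy()
    return wilcoxon_signed_rank(diffs)
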