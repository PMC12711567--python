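"""Pericellular ECM quantification in multiplexed tissue images.

The analysis mirrors a single-cell neighbourhood pipeline for imaging mass
cytometry: hot pixels are removed with a neighbourhood-max rule, channels
are min-max normalised, tissue and void regions are masked, per-cell mean
intensities are extracted from a segmentation label mask, epithelial cells
are gated on E-cadherin and split into marker-high cells (above a
threshold) and an equal count of the lowest-expressing cells, and the mean
ECM intensity is measured in a disc of fixed physical radius around each
classified cell after removing every pixel that belongs to any segmented
cell or to void.  Participant-level condition means feed a within-subject
repeated-measures ANOVA with Sidak-adjusted contrasts.

Pericellular means are reported on the hot-pixel-filtered raw intensity
scale: min-max normalisation rescales each channel by its own image
maximum, which is convenient for thresholding but destroys comparability
of enrichment magnitudes across images, so normalised channels are used
only for tissue masking and marker classification (an option flips this).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_multiotsu
from skimage.morphology import closing, disk

from .stats import AnovaResult, rm_anova

__all__ = [
    "MultiplexImage",
    "ImcConfig",
    "filter_hot_pixels",
    "normalize_channels",
    "compute_tissue_mask",
    "extract_cell_intensities",
    "classify_marker_classes",
    "pericellular_intensity",
    "class_positive_fraction",
    "compare_classes",
    "analyze_scene",
]


@dataclass
class MultiplexImage:
    """Channel stack (C, H, W) with names and physical pixel size."""

    channels: np.ndarray
    channel_names: tuple[str, ...]
    pixel_size_um: float = 1.0

    def __post_init__(self):
        self.channels = np.asarray(self.channels, float)
        self.channel_names = tuple(self.channel_names)
        if self.channels.ndim != 3:
            raise ValueError("channels must be (C, H, W)")
        if self.channels.shape[0] != len(self.channel_names):
            raise ValueError("channel count does not match name count")
        if self.channels.size == 0:
            raise ValueError("empty image")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    def channel(self, name: str) -> np.ndarray:
        return self.channels[self.channel_names.index(name)]


@dataclass
class ImcConfig:
    """Analysis knobs; defaults follow the standard neighbourhood protocol."""

    hot_pixel_threshold: float = 50.0
    tissue_channels: tuple[str, ...] = ("DNA", "ECAD")
    radius_um: float = 10.0
    min_valid_fraction: float = 0.1
    marker_channel: str = "SOX9"
    high_strategy: str = "quantile"        # manual_threshold | quantile | fixed_value
    high_param: float = 0.8                # quantile q, or the threshold itself
    epithelial_channel: str = "ECAD"
    epithelial_threshold: float = 0.5      # on normalised means
    ki67_channel: str = "KI67"
    ki67_threshold: float = 0.5
    ecm_channels: tuple[str, ...] = ("COL6", "COL1", "FN1")
    tissue_threshold: float | str = 0.1    # fixed value on summed normalised, or "otsu"
    closing_radius: int = 2
    exclude_index_cell: bool = True
    pericell_on_normalized: bool = False

    def validate(self, pixel_size_um: float = 1.0) -> None:
        if self.hot_pixel_threshold < 0:
            raise ValueError("hot_pixel_threshold must be nonnegative")
        if self.radius_um / pixel_size_um < 1:
            raise ValueError("radius must span at least one pixel")
        if not 0 < self.min_valid_fraction <= 1:
            raise ValueError("min_valid_fraction must lie in (0, 1]")
        if self.high_strategy not in ("manual_threshold", "quantile", "fixed_value"):
            raise ValueError(f"unknown high_strategy {self.high_strategy!r}")


# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------

_NEIGHBOUR_FOOTPRINT = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], bool)


def filter_hot_pixels(image: MultiplexImage, threshold: float = 50.0) -> MultiplexImage:
    """Replace pixels exceeding their 8-neighbour maximum by more than
    ``threshold`` with that maximum; everything else is untouched.

    Idempotent: a replaced pixel equals its neighbourhood max, so it can
    never be flagged again.  Borders use odd (mirror) reflection so a pixel
    is never its own neighbour.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    out = image.channels.copy()
    for c in range(out.shape[0]):
        nmax = ndi.maximum_filter(out[c], footprint=_NEIGHBOUR_FOOTPRINT,
                                  mode="mirror")
        hot = out[c] - nmax > threshold
        out[c][hot] = nmax[hot]
    return MultiplexImage(out, image.channel_names, image.pixel_size_um)


def normalize_channels(image: MultiplexImage) -> MultiplexImage:
    """Per-channel min-max scaling to [0, 1]; constant channels become zero."""
    out = np.empty_like(image.channels)
    for c, ch in enumerate(image.channels):
        lo, hi = ch.min(), ch.max()
        out[c] = (ch - lo) / (hi - lo) if hi > lo else 0.0
    return MultiplexImage(out, image.channel_names, image.pixel_size_um)


def compute_tissue_mask(image: MultiplexImage, config: ImcConfig,
                        labels: np.ndarray | None = None) -> np.ndarray:
    """Boolean tissue mask (True = tissue) from the summed normalised
    tissue channels.

    The threshold is either a fixed value on the summed normalised signal
    (default 0.1 — void is zero-signal by construction in this pipeline's
    inputs) or ``"otsu"``, the lower threshold of a three-class multi-Otsu
    split (void / stroma / cells).  A morphological closing fills small
    gaps, and labelled cell pixels are always tissue.
    """
    missing = [n for n in config.tissue_channels if n not in image.channel_names]
    if missing:
        raise ValueError(f"tissue channels not in image: {missing}")
    total = sum(normalize_channels(image).channel(n) for n in config.tissue_channels)
    if total.max() == 0:
        tissue = np.zeros(total.shape, bool)
    elif config.tissue_threshold == "otsu":
        try:
            t = threshold_multiotsu(total, classes=3)[0]
        except ValueError:  # fewer than 3 grey levels
            t = total.max() / 2.0
        tissue = total > t
    else:
        tissue = total > float(config.tissue_threshold)
    if config.closing_radius > 0:
        tissue = closing(tissue, disk(config.closing_radius))
    if labels is not None:
        tissue = tissue | (labels > 0)
    return tissue


# --------------------------------------------------------------------------
# single-cell measurements
# --------------------------------------------------------------------------

def extract_cell_intensities(image: MultiplexImage, labels: np.ndarray) -> pd.DataFrame:
    """One row per nonzero label: centroid, area and per-channel mean."""
    labels = np.asarray(labels)
    if labels.shape != image.channels.shape[1:]:
        raise ValueError("label mask shape does not match image")
    if labels.min() < 0:
        raise ValueError("labels must be nonnegative integers")
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        cols = ["label", "centroid_row", "centroid_col", "area_px",
                *image.channel_names]
        return pd.DataFrame(columns=cols)
    centroids = ndi.center_of_mass(np.ones_like(labels, float), labels, ids)
    areas = ndi.sum_labels(np.ones_like(labels, float), labels, ids)
    data = {
        "label": ids.astype(int),
        "centroid_row": [c[0] for c in centroids],
        "centroid_col": [c[1] for c in centroids],
        "area_px": areas.astype(int),
    }
    for c, name in enumerate(image.channel_names):
        data[name] = ndi.mean(image.channels[c], labels, ids)
    return pd.DataFrame(data)


def classify_marker_classes(cells: pd.DataFrame, config: ImcConfig,
                            manual_threshold: float | None = None) -> pd.DataFrame:
    """Gate epithelial cells, then split into marker-high and the matched
    count of lowest-expressing cells.

    ``high`` are epithelial cells whose marker mean exceeds a threshold
    chosen per ``config.high_strategy``; ``low`` are the k lowest-expressing
    epithelial cells with k = |high|, so |low| = |high| on every image.
    Classes are disjoint; an image where they would overlap
    (2|high| > n_epithelial) is an error.  No high cells yields empty
    classes with a warning.
    """
    cells = cells.copy()
    marker = config.marker_channel
    if marker not in cells.columns:
        raise ValueError(f"marker column {marker!r} missing")
    cells["epithelial"] = cells[config.epithelial_channel] > config.epithelial_threshold
    cells["marker_class"] = "unassigned"
    epi = cells.index[cells["epithelial"]]
    if len(epi) == 0:
        warnings.warn("no epithelial cells; classes empty", stacklevel=2)
        return cells

    values = cells.loc[epi, marker]
    if config.high_strategy == "quantile":
        threshold = float(values.quantile(config.high_param))
    elif config.high_strategy == "fixed_value":
        threshold = float(config.high_param)
    else:  # manual_threshold: per-image analyst value
        if manual_threshold is None:
            raise ValueError("manual_threshold strategy needs a per-image value")
        threshold = float(manual_threshold)

    high = values.index[values > threshold]
    k = len(high)
    if k == 0:
        warnings.warn("no marker-high cells above threshold; classes empty",
                      stacklevel=2)
        return cells
    if 2 * k > len(epi):
        raise ValueError(
            f"{k} high cells but only {len(epi)} epithelial cells: "
            "high and low classes would overlap"
        )
    low = values.sort_values(kind="stable").index[:k]
    cells.loc[high, "marker_class"] = "high"
    cells.loc[low, "marker_class"] = "low"
    return cells


def _disc_window(shape, cy, cx, radius):
    """Local window bounds and the in-window disc membership mask."""
    h, w = shape
    r = int(math.ceil(radius))
    r0, r1 = max(0, int(math.floor(cy)) - r), min(h, int(math.ceil(cy)) + r + 1)
    c0, c1 = max(0, int(math.floor(cx)) - r), min(w, int(math.ceil(cx)) + r + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius * radius
    return (slice(r0, r1), slice(c0, c1)), inside


def pericellular_intensity(image: MultiplexImage, labels: np.ndarray,
                           void_mask: np.ndarray, cells: pd.DataFrame,
                           config: ImcConfig) -> pd.DataFrame:
    """Mean ECM intensity in a disc of ``radius_um`` around each classified
    cell, excluding every segmented-cell pixel and void.

    Disc membership is centre-to-centroid Euclidean distance <= radius in
    pixels.  ``valid_pixel_fraction`` is the retained share of in-image
    disc pixels; cells below ``min_valid_fraction`` keep NaN means and are
    flagged ``pericell_dropped``.  By default the index cell's own pixels
    are excluded too (pericellular means extracellular); setting
    ``config.exclude_index_cell = False`` keeps only neighbours excluded.
    """
    config.validate(image.pixel_size_um)
    radius_px = config.radius_um / image.pixel_size_um
    cells = cells.copy()
    channels = [c for c in config.ecm_channels if c in image.channel_names]
    for ch in channels:
        cells[f"pericell_{ch}"] = np.nan
    cells["valid_pixel_fraction"] = np.nan
    cells["pericell_dropped"] = False

    classified = cells.index[cells.get("marker_class", "unassigned")
                             .isin(["high", "low"])]
    if len(classified) == 0:
        return cells

    forbidden = (np.asarray(labels) > 0) | np.asarray(void_mask, bool)
    for i in classified:
        cy, cx = cells.at[i, "centroid_row"], cells.at[i, "centroid_col"]
        win, disc = _disc_window(forbidden.shape, cy, cx, radius_px)
        bad = forbidden[win]
        if not config.exclude_index_cell:
            bad = bad & (labels[win] != cells.at[i, "label"])
        valid = disc & ~bad
        n_disc = int(disc.sum())
        frac = valid.sum() / n_disc if n_disc else 0.0
        cells.at[i, "valid_pixel_fraction"] = frac
        if frac < config.min_valid_fraction:
            cells.at[i, "pericell_dropped"] = True
            continue
        for ch in channels:
            cells.at[i, f"pericell_{ch}"] = float(image.channel(ch)[win][valid].mean())
    return cells


def class_positive_fraction(cells: pd.DataFrame, channel: str, threshold: float,
                            marker_class: str) -> float:
    """Fraction of a marker class whose channel mean exceeds ``threshold``."""
    members = cells[cells["marker_class"] == marker_class]
    if members.empty:
        raise ValueError(f"class {marker_class!r} is empty")
    return float((members[channel] > threshold).mean())


def compare_classes(frame: pd.DataFrame) -> AnovaResult:
    """RM-ANOVA over participant-level condition means followed by
    Sidak-adjusted pairwise contrasts.

    ``frame`` columns: participant, condition (e.g. high_baseline,
    low_post), value — one summary value per participant and condition.
    """
    return rm_anova(frame, subject="participant", condition="condition",
                    value="value")


# --------------------------------------------------------------------------
# per-scene driver
# --------------------------------------------------------------------------

def analyze_scene(image: MultiplexImage, labels: np.ndarray,
                  config: ImcConfig | None = None,
                  manual_threshold: float | None = None):
    """Full single-image pipeline.

    Returns (cell table, tissue mask).  Order: hot-pixel filtering,
    normalisation, tissue masking, intensity extraction, epithelial gating
    and marker classification (on normalised means), pericellular
    quantification (raw scale unless configured otherwise).
    """
    config = config or ImcConfig()
    config.validate(image.pixel_size_um)
    filtered = filter_hot_pixels(image, config.hot_pixel_threshold)
    normed = normalize_channels(filtered)
    tissue = compute_tissue_mask(normed, config, labels)
    cells = extract_cell_intensities(normed, labels)
    if cells.empty:
        return cells, tissue
    cells = classify_marker_classes(cells, config, manual_threshold)
    source = normed if config.pericell_on_normalized else filtered
    cells = pericellular_intensity(source, labels, ~tissue, cells, config)
    # keep raw per-cell channel means alongside the normalised ones
    raw = extract_cell_intensities(filtered, labels)
    for name in image.channel_names:
        cells[f"raw_{name}"] = raw[name].to_numpy()
    return cells, tissue
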