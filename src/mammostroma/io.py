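"""Readers and writers for the pipeline's on-disk formats.

Multichannel scenes are stored as a (C, H, W) TIFF plus a panel CSV
(columns: channel, name), a 16-bit label-mask TIFF and a ground-truth CSV.
Force curves are one CSV per curve (columns declare units, e.g.
``indentation_m,force_n`` or ``indentation_nm,force_nn``) plus a metadata
JSON.  Fibre images are 16-bit grayscale TIFFs, volumes are multi-page
label TIFFs, tabular data are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .afm import ForceCurve
from .density import SegmentedVolume
from .pericell import MultiplexImage
from .synth import MultiplexScene

_UNIT_SCALE = {"m": 1.0, "mm": 1e-3, "um": 1e-6, "nm": 1e-9,
               "n": 1.0, "mn": 1e-3, "un": 1e-6, "nn": 1e-9, "pn": 1e-12}


# ---------------------------------------------------------------- scenes ---

def write_scene(scene: MultiplexScene, outdir, name: str) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    img = outdir / f"{name}_img.tiff"
    tifffile.imwrite(img, scene.channels.astype(np.float32))
    panel = outdir / f"{name}_panel.csv"
    pd.DataFrame({"channel": range(len(scene.channel_names)),
                  "name": scene.channel_names}).to_csv(panel, index=False)
    mask = outdir / f"{name}_mask.tiff"
    tifffile.imwrite(mask, scene.label_mask.astype(np.uint16))
    void = outdir / f"{name}_void.tiff"
    tifffile.imwrite(void, scene.void_mask.astype(np.uint8))
    gt = outdir / f"{name}_truth.csv"
    scene.ground_truth.to_csv(gt, index=False)
    return [img, panel, mask, void, gt]


def read_multiplex(image_path, panel_path, pixel_size_um: float = 1.0) -> MultiplexImage:
    stack = tifffile.imread(image_path).astype(float)
    panel = pd.read_csv(panel_path)
    names = tuple(panel.sort_values("channel")["name"])
    return MultiplexImage(stack, names, pixel_size_um)


def read_label_mask(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int64)


# ---------------------------------------------------------------- curves ---

def write_curves(curves, outdir, metadata: dict | None = None) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for curve in curves:
        p = outdir / f"curve_{curve.curve_id}.csv"
        pd.DataFrame({"indentation_m": curve.indentation_m,
                      "force_n": curve.force_n}).to_csv(p, index=False)
        paths.append(p)
    meta = dict(metadata or {})
    meta.setdefault("probe_radius_m", curves[0].probe_radius_m if curves else None)
    mp = outdir / "metadata.json"
    mp.write_text(json.dumps(meta, indent=2, sort_keys=True))
    paths.append(mp)
    return paths


def _column_unit(col: str) -> float:
    unit = col.rsplit("_", 1)[-1].lower()
    if unit not in _UNIT_SCALE:
        raise ValueError(f"column {col!r} does not declare a recognised unit")
    return _UNIT_SCALE[unit]


def read_curves(indir, probe_radius_m: float | None = None) -> list[ForceCurve]:
    """Read every curve_*.csv in a directory, converting declared units to SI."""
    indir = Path(indir)
    meta_path = indir / "metadata.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    radius = probe_radius_m or meta.get("probe_radius_m") or 2.5e-6
    curves = []
    for p in sorted(indir.glob("curve_*.csv")):
        df = pd.read_csv(p)
        icol = next(c for c in df.columns if c.lower().startswith("indentation"))
        fcol = next(c for c in df.columns if c.lower().startswith("force"))
        curves.append(ForceCurve(
            indentation_m=df[icol].to_numpy() * _column_unit(icol),
            force_n=df[fcol].to_numpy() * _column_unit(fcol),
            probe_radius_m=radius,
            curve_id=p.stem.removeprefix("curve_"),
        ))
    return curves


# ------------------------------------------------------- images & volumes ---

def write_gray16(image: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    scaled = np.clip(image, 0.0, 1.0)
    tifffile.imwrite(path, (scaled * 65535).round().astype(np.uint16))
    return path


def read_gray(path) -> np.ndarray:
    img = tifffile.imread(path).astype(float)
    return img / 65535.0 if img.max() > 1 else img


def write_volume(volume: SegmentedVolume, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, volume.labels.astype(np.uint8))
    return path


def read_volume(path) -> SegmentedVolume:
    return SegmentedVolume(labels=tifffile.imread(path).astype(np.uint8))


# ----------------------------------------------------------------- tables ---

def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))
    return path


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.DataFrame):
        return x.to_dict(orient="records")
    raise TypeError(f"not JSON serialisable: {type(x)}")
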