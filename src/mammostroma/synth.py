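"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its spec (the seed is part of the
spec), so identical specs yield bit-identical artifacts.  Every generator
also returns enough ground truth to compute the downstream expected value
in closed form, which is what the test suite and the acceptance checks
lean on.

The multiplexed-scene generator emulates imaging-mass-cytometry-like data:
two classes of disc-shaped epithelial cells on a stained stromal
background, an extracellular-matrix channel multiplicatively enriched in a
fixed annulus around class-A cells, a rectangular zero-signal void region,
Gaussian noise and optional hot pixels.  The force-curve generator draws
from the spherical Hertz forward model; the fibre generator superposes
sinusoidal gratings with a controllable angular dispersion; the volume and
assay generators place exact label counts and paired participant effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SceneSpec",
    "MultiplexScene",
    "CurveSpec",
    "FibreSpec",
    "VolumeSpec",
    "AssaySpec",
    "gen_multiplex_scene",
    "gen_force_curves",
    "gen_fibre_image",
    "gen_label_volume",
    "gen_assay_tables",
    "DEFAULT_CHANNELS",
    "ECM_CHANNELS",
]

DEFAULT_CHANNELS = ("DNA", "ECAD", "SOX9", "KI67", "COL6", "COL1", "FN1")
ECM_CHANNELS = ("COL6", "COL1", "FN1")

#: raw intensity written into hot pixels; far above any tissue signal so the
#: neighbourhood-max rule always detects them at the default threshold of 50.
HOT_PIXEL_VALUE = 1000.0


# --------------------------------------------------------------------------
# multiplexed scenes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic multiplexed scene.

    Class A stands in for marker-high epithelial cells (e.g. SOX9-high),
    class B for the remaining epithelium.  The ECM channels carry
    ``ecm_baseline`` everywhere in tissue and ``ecm_enrichment_factor *
    ecm_baseline`` inside the annulus from each class-A cell boundary out
    to ``enrichment_annulus_um`` beyond it, before noise.  Cells never
    overlap; by default their centres are kept two annuli apart so that a
    measurement disc around one cell cannot touch another cell's enriched
    zone, which keeps the expected pericellular means closed-form.
    """

    image_size_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = 1.0
    n_cells_per_class: tuple[int, int] = (12, 12)
    cell_radius_px: int = 4
    marker_mean_high: float = 0.8
    marker_mean_low: float = 0.1
    ecm_baseline: float = 0.2
    ecm_enrichment_factor: float = 2.0
    enrichment_annulus_um: float = 10.0
    void_fraction: float = 0.15
    noise_sd: float = 0.02
    hot_pixel_count: int = 0
    seed: int = 0
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    # geometry / staining levels with no counterpart in the source assay;
    # chosen so every downstream expectation is analytic
    min_separation_px: float | None = None
    ki67_positive_fraction: tuple[float, float] = (0.4, 0.1)
    tissue_background: float = 0.3
    cell_dna: float = 0.9
    cell_ecad: float = 0.8
    ki67_positive_level: float = 0.8
    ki67_negative_level: float = 0.05

    def validate(self) -> None:
        h, w = self.image_size_px
        if h < 8 or w < 8:
            raise ValueError("image_size_px must be at least 8x8")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if any(n < 0 for n in self.n_cells_per_class):
            raise ValueError("n_cells_per_class must be nonnegative")
        if self.cell_radius_px < 1:
            raise ValueError("cell_radius_px must be a positive integer")
        if not 0 <= self.void_fraction < 1:
            raise ValueError("void_fraction must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.ecm_baseline < 0:
            raise ValueError("ecm_baseline must be nonnegative")
        if self.ecm_enrichment_factor < 1:
            raise ValueError("ecm_enrichment_factor must be >= 1")
        if self.enrichment_annulus_um <= 0:
            raise ValueError("enrichment_annulus_um must be positive")
        if self.hot_pixel_count < 0:
            raise ValueError("hot_pixel_count must be nonnegative")

    @property
    def annulus_outer_px(self) -> float:
        """Outer annulus radius from the cell centre, in pixels."""
        return self.cell_radius_px + self.enrichment_annulus_um / self.pixel_size_um

    @property
    def separation_px(self) -> float:
        if self.min_separation_px is not None:
            return float(self.min_separation_px)
        return 2.0 * self.annulus_outer_px


@dataclass
class MultiplexScene:
    """A generated scene: channel stack plus masks and ground truth."""

    channels: np.ndarray          # (C, H, W) float64, raw intensities
    channel_names: tuple[str, ...]
    pixel_size_um: float
    label_mask: np.ndarray        # (H, W) uint16, 0 = background
    void_mask: np.ndarray         # (H, W) bool, True = void
    ground_truth: pd.DataFrame    # label, cell_class, row, col, ki67_positive,
                                  # expected pericellular mean per ECM channel
    spec: SceneSpec = field(repr=False, default=None)

    def channel(self, name: str) -> np.ndarray:
        return self.channels[self.channel_names.index(name)]


def _disc_offsets(radius: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(math.floor(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy * dy + dx * dx <= radius * radius
    return dy[keep], dx[keep]


def _place_centres(rng, spec: SceneSpec, void_box):
    """Dart-throwing placement honouring void clearance and min separation."""
    h, w = spec.image_size_px
    n_total = sum(spec.n_cells_per_class)
    r = spec.cell_radius_px
    sep2 = spec.separation_px ** 2
    v0, v1, vh, vw = void_box
    centres: list[tuple[int, int]] = []
    attempts = 0
    max_attempts = 2000 * max(n_total, 1)
    while len(centres) < n_total:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"infeasible packing: placed {len(centres)} of {n_total} cells "
                f"with separation {spec.separation_px:.1f}px in {h}x{w} image"
            )
        cy = int(rng.integers(r, h - r))
        cx = int(rng.integers(r, w - r))
        # the full cell disc must clear the void rectangle
        if (v0 - r <= cy <= v0 + vh - 1 + r) and (v1 - r <= cx <= v1 + vw - 1 + r):
            continue
        if any((cy - y) ** 2 + (cx - x) ** 2 < sep2 for y, x in centres):
            continue
        centres.append((cy, cx))
    return centres


def gen_multiplex_scene(spec: SceneSpec) -> MultiplexScene:
    """Generate a multiplexed scene with closed-form ground truth.

    Raises ``ValueError`` on invalid specs or when the requested cells do
    not fit without violating the separation constraint.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size_px
    names = tuple(spec.channels)
    idx = {n: i for i, n in enumerate(names)}

    # void rectangle with area as close to void_fraction * H * W as integers allow
    if spec.void_fraction > 0:
        vh = max(1, round(math.sqrt(spec.void_fraction) * h))
        vw = max(1, round(spec.void_fraction * h * w / vh))
        vh, vw = min(vh, h), min(vw, w)
        v0 = int(rng.integers(0, h - vh + 1))
        v1 = int(rng.integers(0, w - vw + 1))
    else:
        vh = vw = v0 = v1 = 0
    void = np.zeros((h, w), bool)
    if vh and vw:
        void[v0 : v0 + vh, v1 : v1 + vw] = True
    tissue = ~void

    centres = _place_centres(rng, spec, (v0, v1, vh, vw))
    n_a, n_b = spec.n_cells_per_class

    labels = np.zeros((h, w), np.uint16)
    dy, dx = _disc_offsets(spec.cell_radius_px)
    for lab, (cy, cx) in enumerate(centres, start=1):
        labels[cy + dy, cx + dx] = lab
    cell_any = labels > 0

    stack = np.zeros((len(names), h, w))
    bg = {
        "DNA": spec.tissue_background,
        "ECAD": spec.tissue_background,
        "SOX9": 0.02,
        "KI67": 0.02,
    }
    for n in names:
        stack[idx[n]][tissue] = bg.get(n, spec.ecm_baseline if n in ECM_CHANNELS else 0.02)

    # enriched annulus: union over class-A cells, tissue pixels outside every cell
    if n_a and any(n in idx for n in ECM_CHANNELS):
        rr, cc = np.mgrid[0:h, 0:w]
        enriched = np.zeros((h, w), bool)
        outer2 = spec.annulus_outer_px ** 2
        for cy, cx in centres[:n_a]:
            enriched |= (rr - cy) ** 2 + (cc - cx) ** 2 <= outer2
        enriched &= tissue & ~cell_any
        for n in ECM_CHANNELS:
            if n in idx:
                stack[idx[n]][enriched] = spec.ecm_enrichment_factor * spec.ecm_baseline

    # per-cell staining
    ki67_pos = np.zeros(len(centres), bool)
    for cls, (lo, hi_n) in enumerate(((0, n_a), (n_a, n_a + n_b))):
        members = np.arange(lo, hi_n)
        k = round(spec.ki67_positive_fraction[cls] * len(members))
        if k:
            ki67_pos[rng.choice(members, size=k, replace=False)] = True
    marker_levels = [spec.marker_mean_high] * n_a + [spec.marker_mean_low] * n_b
    for i, (cy, cx) in enumerate(centres):
        sel = (cy + dy, cx + dx)
        if "DNA" in idx:
            stack[idx["DNA"]][sel] = spec.cell_dna
        if "ECAD" in idx:
            stack[idx["ECAD"]][sel] = spec.cell_ecad
        if "SOX9" in idx:
            stack[idx["SOX9"]][sel] = marker_levels[i]
        if "KI67" in idx:
            stack[idx["KI67"]][sel] = (
                spec.ki67_positive_level if ki67_pos[i] else spec.ki67_negative_level
            )

    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=stack.shape)
        noise[:, void] = 0.0          # void carries zero signal in all channels
        stack = np.clip(stack + noise, 0.0, None)

    if spec.hot_pixel_count:
        ty, tx = np.nonzero(tissue)
        pick = rng.integers(0, len(ty), size=spec.hot_pixel_count)
        ch = rng.integers(0, len(names), size=spec.hot_pixel_count)
        stack[ch, ty[pick], tx[pick]] = HOT_PIXEL_VALUE

    gt = pd.DataFrame(
        {
            "label": np.arange(1, len(centres) + 1, dtype=int),
            "cell_class": ["A"] * n_a + ["B"] * n_b,
            "row": [c[0] for c in centres],
            "col": [c[1] for c in centres],
            "ki67_positive": ki67_pos,
        }
    )
    for n in ECM_CHANNELS:
        if n in idx:
            expected = np.where(
                gt["cell_class"] == "A",
                spec.ecm_enrichment_factor * spec.ecm_baseline,
                spec.ecm_baseline,
            )
            gt[f"expected_pericellular_{n}"] = expected

    return MultiplexScene(
        channels=stack,
        channel_names=names,
        pixel_size_um=spec.pixel_size_um,
        label_mask=labels,
        void_mask=void,
        ground_truth=gt,
        spec=spec,
    )


# --------------------------------------------------------------------------
# AFM force curves
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CurveSpec:
    """Parameters for Hertz-model force curves.

    Defaults mirror a colloidal-probe indentation protocol: a spherical
    probe of 5 um diameter (R = 2.5 um) driven 50 nm into the sample.  A
    fifth of each curve is a flat pre-contact segment so baseline
    estimation is well-posed.  ``corrupted_fraction`` of the curves get a
    linear drift, an adhesion dip of random sign and a ripple large enough
    that a Hertz fit cannot reach r^2 = 0.9 on the fit window.
    """

    n_curves: int = 100
    true_modulus_pa: float | tuple[float, ...] = 5000.0
    probe_radius_m: float = 2.5e-6
    max_indentation_m: float = 5.0e-8
    samples_per_curve: int = 200
    noise_sd_n: float = 8.0e-13
    corrupted_fraction: float = 0.0
    pre_contact_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_curves < 1:
            raise ValueError("n_curves must be positive")
        if self.samples_per_curve < 4:
            raise ValueError("samples_per_curve must be at least 4")
        if self.probe_radius_m <= 0 or self.max_indentation_m <= 0:
            raise ValueError("probe radius and max indentation must be positive")
        if not 0 <= self.corrupted_fraction < 1:
            raise ValueError("corrupted_fraction must lie in [0, 1)")
        if self.noise_sd_n < 0:
            raise ValueError("noise_sd_n must be nonnegative")
        moduli = np.atleast_1d(np.asarray(self.true_modulus_pa, float))
        if np.any(moduli <= 0):
            raise ValueError("true_modulus_pa must be positive")
        if len(moduli) not in (1, self.n_curves):
            raise ValueError("true_modulus_pa must be scalar or one per curve")


def gen_force_curves(spec: CurveSpec):
    """Return (curves, ground_truth) for a :class:`CurveSpec`.

    ``curves`` is a list of :class:`mammostroma.afm.ForceCurve`;
    ``ground_truth`` a DataFrame with the true modulus and corruption flag
    per curve.  Clean noiseless curves satisfy the Hertz forward model
    exactly on the contact segment.
    """
    from .afm import ForceCurve, hertz_force

    spec.validate()
    moduli = np.broadcast_to(
        np.atleast_1d(np.asarray(spec.true_modulus_pa, float)), (spec.n_curves,)
    )
    n_corrupt = round(spec.corrupted_fraction * spec.n_curves)
    root = np.random.SeedSequence(spec.seed)
    order_rng = np.random.default_rng(root.spawn(1)[0])
    corrupt = np.zeros(spec.n_curves, bool)
    if n_corrupt:
        corrupt[order_rng.choice(spec.n_curves, size=n_corrupt, replace=False)] = True

    n_pre = max(1, round(spec.pre_contact_fraction * spec.samples_per_curve))
    n_post = spec.samples_per_curve - n_pre
    delta = np.concatenate(
        [
            np.linspace(-0.25 * spec.max_indentation_m, 0.0, n_pre, endpoint=False),
            np.linspace(0.0, spec.max_indentation_m, n_post),
        ]
    )
    contact = np.clip(delta, 0.0, None)

    curves = []
    streams = root.spawn(spec.n_curves + 1)[1:]
    for i in range(spec.n_curves):
        rng = np.random.default_rng(streams[i])
        force = hertz_force(contact, moduli[i], spec.probe_radius_m)
        fmax = force[-1]
        if corrupt[i]:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            drift = 0.6 * fmax * (delta - delta[0]) / (delta[-1] - delta[0])
            dip = -0.8 * fmax * np.exp(
                -((delta - 0.1 * spec.max_indentation_m) ** 2)
                / (2 * (0.08 * spec.max_indentation_m) ** 2)
            )
            ripple = 0.35 * fmax * np.sin(
                8 * np.pi * delta / spec.max_indentation_m + rng.uniform(0, 2 * np.pi)
            )
            force = force + drift + sign * dip + ripple
        if spec.noise_sd_n > 0:
            force = force + rng.normal(0.0, spec.noise_sd_n, size=force.shape)
        curves.append(
            ForceCurve(
                indentation_m=delta.copy(),
                force_n=force,
                probe_radius_m=spec.probe_radius_m,
                curve_id=i,
            )
        )
    gt = pd.DataFrame(
        {
            "curve_id": np.arange(spec.n_curves),
            "true_modulus_pa": moduli,
            "corrupted": corrupt,
        }
    )
    return curves, gt


# --------------------------------------------------------------------------
# oriented fibre images
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FibreSpec:
    """Striped texture with controllable orientation dispersion.

    ``dispersion`` is the angular SD (radians) of the grating orientations
    superposed; 0 gives a single perfectly periodic grating along
    ``dominant_angle_deg``.  ``signal_amplitude`` 0 with ``noise_sd`` > 0
    yields pure white noise (isotropic limit).
    """

    image_size_px: tuple[int, int] = (256, 256)
    dominant_angle_deg: float = 30.0
    dispersion: float = 0.0
    spatial_period_px: float = 8.0
    noise_sd: float = 0.0
    signal_amplitude: float = 0.45
    n_gratings: int = 24
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.dominant_angle_deg < 180:
            raise ValueError("dominant_angle_deg must lie in [0, 180)")
        if self.dispersion < 0 or self.noise_sd < 0 or self.signal_amplitude < 0:
            raise ValueError("dispersion, noise_sd, signal_amplitude must be >= 0")
        if self.spatial_period_px <= 0:
            raise ValueError("spatial_period_px must be positive")


def gen_fibre_image(spec: FibreSpec) -> np.ndarray:
    """Grayscale float image in [0, 1] with the requested texture."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size_px
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    img = np.full((h, w), 0.5)
    if spec.signal_amplitude > 0:
        k = 1 if spec.dispersion == 0 else spec.n_gratings
        angles = np.deg2rad(spec.dominant_angle_deg) + (
            spec.dispersion * rng.standard_normal(k) if spec.dispersion else np.zeros(k)
        )
        phases = rng.uniform(0, 2 * np.pi, size=k)
        acc = np.zeros((h, w))
        for a, ph in zip(angles, phases):
            # stripes run along direction a; intensity varies along its normal
            nx, ny = -math.sin(a), math.cos(a)
            acc += np.sin(2 * np.pi * (xx * nx + yy * ny) / spec.spatial_period_px + ph)
        # unit-RMS signal scaled to the requested amplitude
        acc /= math.sqrt(k / 2.0)
        img = img + spec.signal_amplitude * acc / 2.0
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


# --------------------------------------------------------------------------
# labelled volumes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VolumeSpec:
    """Label volume with exact voxel counts (0 bg, 1 fat, 2 fibroglandular)."""

    n_slices: int = 8
    slice_size_px: tuple[int, int] = (32, 32)
    n_fg_voxels: int = 300
    n_fat_voxels: int = 700
    seed: int = 0

    def validate(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be positive")
        if self.n_fg_voxels < 0 or self.n_fat_voxels < 0:
            raise ValueError("voxel counts must be nonnegative")
        total = self.n_slices * self.slice_size_px[0] * self.slice_size_px[1]
        if self.n_fg_voxels + self.n_fat_voxels > total:
            raise ValueError("requested voxels exceed volume size")


def gen_label_volume(spec: VolumeSpec):
    """Return a :class:`mammostroma.density.SegmentedVolume` with exact counts."""
    from .density import SegmentedVolume

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.slice_size_px
    total = spec.n_slices * h * w
    flat = np.zeros(total, np.uint8)
    pos = rng.permutation(total)
    flat[pos[: spec.n_fg_voxels]] = 2
    flat[pos[spec.n_fg_voxels : spec.n_fg_voxels + spec.n_fat_voxels]] = 1
    return SegmentedVolume(labels=flat.reshape(spec.n_slices, h, w))


# --------------------------------------------------------------------------
# paired assay tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AssaySpec:
    """Paired pre/post measurements with subject effects and optional ties."""

    n_participants: int = 19
    baseline_mean: float = 0.29
    post_mean: float = 0.16
    between_subject_sd: float = 0.10
    within_subject_sd: float = 0.05
    tie_quantization: float = 0.0
    metric: str = "value"
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        if self.between_subject_sd < 0 or self.within_subject_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.tie_quantization < 0:
            raise ValueError("tie_quantization must be nonnegative")


def gen_assay_tables(spec: AssaySpec) -> pd.DataFrame:
    """Long paired table: participant, timepoint in {baseline, post}, value."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    subj = rng.normal(0.0, spec.between_subject_sd, size=spec.n_participants)
    rows = []
    for tp, mean in (("baseline", spec.baseline_mean), ("post", spec.post_mean)):
        vals = mean + subj + rng.normal(0.0, spec.within_subject_sd, spec.n_participants)
        if spec.tie_quantization > 0:
            vals = np.round(vals / spec.tie_quantization) * spec.tie_quantization
        for i, v in enumerate(vals):
            rows.append({"participant": f"P{i + 1:02d}", "timepoint": tp,
                         "metric": spec.metric, "value": float(v)})
    return pd.DataFrame(rows)


def with_seed(spec, seed: int):
    """Copy a spec with a different seed (specs are frozen dataclasses)."""
    return replace(spec, seed=seed)
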