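# Methods

`mammostroma` re-implements, as tested reusable code, the quantification
procedures behind a set of paired (baseline vs post-treatment) breast-tissue
readouts: pericellular extracellular-matrix (ECM) intensity around
marker-classified epithelial cells in multiplexed images, tissue stiffness
from AFM force curves under the spherical Hertz contact model, collagen
fibre coherency from structure tensors, fibroglandular volume fractions
from annotated MRI-like label volumes, and the shared assay/statistics
arithmetic (mammosphere-forming efficiency, colony metrics, lobule
morphometry, Wilcoxon signed-rank, Sidak-adjusted repeated-measures ANOVA).
Every stage can be exercised on synthetic data with known ground truth;
this note records the models, the defaults and why, and what the synthetic
conditions do and do not establish about real tissue data.

## Pericellular ECM quantification (`pericell`)

Pipeline per image: hot-pixel removal, per-channel min-max normalisation,
tissue/void masking, per-cell intensity extraction from a supplied 16-bit
segmentation label mask, epithelial gating, marker classification, and
pericellular measurement.

- **Hot pixels.** A pixel whose value exceeds the maximum of its 8
  neighbours by more than a threshold (default 50, the convention used by
  steinbock-style IMC preprocessing) is replaced by that neighbourhood
  maximum. The rule is idempotent; borders use odd (mirror) reflection so a
  pixel never counts as its own neighbour.
- **Tissue mask.** Void is detected on the summed min-max-normalised
  tissue channels (default DNA + E-cadherin). The default threshold is a
  fixed 0.1: void regions are zero-signal while stained stroma is not, and
  a plain two-class Otsu on these images splits cells from everything else,
  wrongly sending stained stroma to void. A three-class multi-Otsu option
  (`tissue_threshold="otsu"`) is provided for images without a reliable
  zero floor. A closing (disk radius 2) fills small gaps; labelled cell
  pixels are always tissue.
- **Classification.** Epithelial cells are gated on E-cadherin mean above
  a fixed normalised threshold (default 0.5). A quantile-of-all-cells gate
  was considered and rejected: in a field of view that is entirely
  epithelial it misclassifies half the cells by construction. Marker-high
  cells (default marker SOX9) are epithelial cells above a threshold from
  one of three strategies — per-image manual value, fixed value, or a
  quantile of the epithelial marker means (default, q = 0.8, mirroring the
  reported equivalence of analyst thresholds to a fixed top-20% gate).
  The matched-count contract is enforced exactly: the k lowest-expressing
  epithelial cells are the marker-low class, k = |high|, and an image where
  the classes would overlap is an error.
- **Pericellular means.** A disc of fixed physical radius (default 10 µm)
  is taken around each classified cell's centroid (membership by
  centre-to-centroid Euclidean distance); pixels belonging to *any*
  labelled cell — including the index cell, since "pericellular" means
  extracellular; `exclude_index_cell=False` restricts exclusion to
  neighbours — or to void are removed, and the mean of each ECM channel is
  computed over the rest. The disc radius is never shrunk; masking
  preserves the stated radius and is deterministic. Cells retaining fewer
  than `min_valid_fraction` (default 0.1) of their disc pixels are flagged
  and excluded from downstream statistics, so near-empty ROIs cannot
  produce unstable means.
- **Scale.** Pericellular means are reported on the hot-pixel-filtered
  *raw* intensity scale. Min-max normalisation divides each channel by its
  own image maximum, which destroys cross-image comparability of
  enrichment magnitudes; normalised channels are used only for masking and
  thresholding. `pericell_on_normalized=True` flips this.
- **Statistics.** Participant-level condition means (not pooled cells —
  pooling would pseudoreplicate) enter a within-subject one-way
  repeated-measures ANOVA (subject × condition sum-of-squares
  decomposition, F on (k−1, (k−1)(n−1)) df) followed by paired-t pairwise
  contrasts with Sidak adjustment p_adj = 1 − (1 − p)^m.

## AFM stiffness (`afm`)

The contact model is the spherical-indenter Hertz relation in the
reduced-modulus convention, F(δ) = (4/3)·E_r·√R·δ^{3/2}, with probe radius
R (default 2.5 µm, a 5-µm colloidal probe) and indentation δ (default
protocol depth 50 nm). No Poisson-ratio assumption is made; E_r is
reported as a reduced modulus.

- **Fitting.** The baseline is the mean force over the first 10% of
  samples, assumed pre-contact. E_r and a contact offset are estimated by
  nonlinear least squares restricted to samples whose baseline-corrected
  force lies between 25% and 75% of maximum force (both ends inclusive);
  r² is the coefficient of determination on that window. Initialisation is
  deterministic: the contact offset starts at the first sample exceeding
  5% of F_max and E_r from the closed form at maximum indentation.
- **Window selection at low SNR.** F_max and window membership are
  evaluated on a Savitzky–Golay-smoothed copy (21-sample window, quadratic)
  of the force. Selecting on the raw signal couples window membership to
  the noise and biases the modulus downward by ~15% at SNR 20; with
  smoothed selection the median bias is about −1% (the regression itself
  always uses raw samples).
- **QC.** Exactly two stages in order: drop fits with r² < 0.95, then drop
  moduli outside mean ± 2 sample SD (ddof = 1; boundary inclusive, so a
  zero-SD population survives intact) of the stage-1 survivors. The trim is
  applied within each sample/timepoint population in the pipeline; where
  the trimming population should differ, call `qc_filter` on the grouping
  of your choice.
- **Comparison.** Per-sample two-sided two-sample t-test between baseline
  and post moduli; pooled variance by default (Student), Welch behind a
  flag.

## Fibre coherency (`coherency`)

For a rectangular region the structure tensor J averages products of image
gradients (centred finite differences after Gaussian pre-smoothing, default
σ = 2 px, a typical local-window scale for orientation analysis).
Coherency C = (λ_max − λ_min)/(λ_max + λ_min) ∈ [0, 1]; a zero-gradient
region is defined as C = 0 with an undefined angle. The dominant angle is
the structure orientation (minor eigenvector of J), degrees in [0, 180)
from the image x (column) axis. Aggregation follows the two-level scheme:
mean over regions within a lobule, then mean over lobules per participant
and timepoint, warning (not failing) below three lobules; paired change is
tested with the two-sided Wilcoxon matched-pairs test.

## Density volumetrics (`density`)

FGV = 100 × n_fibroglandular / (n_fibroglandular + n_fat) over all slices;
background voxels never enter the ratio, and voxel counts are unweighted
(a `voxel_volume_mm3` hook exists for anisotropic acquisitions). Volpara
density grades use lower-inclusive percent-dense-volume cut-offs 4.5, 7.5
and 15.5 exactly as printed.

## Shared statistics (`stats`)

- **Wilcoxon signed-rank** (two-sided, paired): zero differences dropped
  (Wilcoxon's original rule, matching the common R default rather than
  Pratt's method). With no tied magnitudes and n ≤ 25, the exact null
  distribution of W (sum of positive ranks) is computed by the standard
  count-convolution recursion — equivalent to full 2^n enumeration, which
  the tests verify — and p = min(1, 2·min(P(W ≤ w), P(W ≥ w))). With ties
  (or n > 25) a normal approximation with tie-corrected variance
  n(n+1)(2n+1)/24 − Σ(t³−t)/48 is used, with no continuity correction;
  this matches scipy's tie-corrected approximation to 1e-12.
- **MFE** = 100 × spheres (diameter ≥ 50 µm, inclusive) / cells seeded;
  **colonies** are clusters of ≥ 50 cells (inclusive), with type
  proportions as percentages of typed colonies.
- **Reporting fractions** round half-away-from-zero (via decimal
  arithmetic, so 41.25 → 41.3), the convention that reproduces the
  printed percentages from the printed counts.

## Synthetic data (`synth`)

Generators are pure functions of their spec (the seed is a field), so
identical specs give bit-identical artifacts, and each carries ground truth
sufficient to compute every downstream expected value in closed form.

- **Scenes** (default 256² px at 1 µm/px, 12 + 12 cells): disc-shaped
  cells (radius 4 px) of two classes; SOX9 level 0.8 (class A) vs 0.1
  (class B); all cells E-cadherin-positive; ECM channels at baseline 0.2
  in tissue and factor × baseline (default 2.0) in the annulus from each
  class-A boundary out 10 µm — a sharp multiplicative annulus rather than
  a smooth kernel, so the expected pericellular mean is exactly
  factor × baseline; a rectangular zero-signal void region (fraction
  0.15); Gaussian noise (σ = 0.02, clipped at 0, void kept at exactly
  zero); optional hot pixels written at intensity 1000. Cell centres keep a
  default minimum separation of two annulus radii, chosen a priori so one
  cell's measurement disc can never touch another cell's enriched zone —
  the geometric condition for the closed-form expectation, not a tuned
  value.
- **Force curves** (default 200 samples, 20% pre-contact at zero force so
  the baseline estimate is well-posed): the Hertz forward model plus
  Gaussian force noise, default σ = 0.8 pN — sub-piconewton force noise
  typical of a well-calibrated instrument, chosen so that clean curves at
  the softest moduli of interest (~1–2 kPa) both pass the r² ≥ 0.95 gate
  (r² ≈ 0.98 at 2 kPa) and keep per-curve modulus scatter under 5%.
  Corrupted curves (an exact rounded fraction, flagged in ground truth)
  add a linear drift, an adhesion dip of random sign and a ripple sized so
  a Hertz fit cannot reach r² = 0.9.
- **Fibre images**: superposed sinusoidal gratings whose orientations are
  normal around the dominant angle with SD `dispersion` (radians);
  dispersion 0 is a single perfectly periodic grating, and
  `signal_amplitude = 0` with noise gives the isotropic white-noise limit.
- **Volumes** place exact fat/fibroglandular voxel counts at random
  positions; **assay tables** draw subject effects (between-SD 0.10) plus
  within-subject noise (SD 0.05) around designed baseline/post means
  (defaults 0.29 → 0.16, a realistic mammosphere-efficiency scale), with
  optional quantisation to force ties.

What passing on these conditions does *not* show: the generators have no
isotope spillover or ablation artefacts, no realistic cell shapes or
spatially varying stroma, no viscoelastic or adhesive contact physics, no
birefringence optics, and no scanner physics or annotation noise. They
validate the estimators and their contracts, not instrument models.

## Pipeline (`pipeline`, `mammostroma` CLI)

One YAML config with per-stage blocks drives everything; validation
collects the complete list of violations. All randomness flows from one
root seed via fixed per-stage offsets. The demonstration run uses 4 IMC
participants × 2 timepoints (enrichment 2.0 → 1.4), 3 AFM samples × 2
timepoints × 60 curves (4 kPa → 2 kPa, 5% corrupted), 4 coherency
participants × 3 lobules × 4 regions (dispersion 0.15 → 0.6), 6 FGV
participants (post fibroglandular count scaled 0.7×) and a 19-participant
assay table — sizes chosen to mirror the small paired-cohort design while
completing in seconds. Stages are independent given the seed, each
regenerating its own inputs; the run report lists every output file with a
SHA-256 hash, and re-running an identical config is byte-stable for all
outputs (wall times live only in the report). The `simulate` subcommand
writes one example of every artifact in its file format (TIFF + panel CSV,
per-curve CSVs + metadata JSON, label stacks, tables) and the other
subcommands consume those formats, so the file-based route and the
in-memory route are both exercised.

## Known limitations

- The 2-SD modulus trim assumes a roughly unimodal surviving population;
  on strongly bimodal populations it keeps both modes.
- The exact Wilcoxon path requires untied magnitudes; heavily quantised
  data always take the tie-corrected normal path, which is approximate for
  very small n.
- The RM-ANOVA is the classical univariate decomposition without
  sphericity correction; with k = 4 conditions and small n, a
  Greenhouse–Geisser correction would be more conservative.
- Coherency depends on the smoothing scale σ; values are comparable only
  at a fixed σ (default 2 px).
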