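# Methods

`smfish3d` quantifies single-molecule RNA FISH (smFISH) signals in
multi-channel 3D fluorescence stacks of whole-mount brain tissue. The
pipeline has two parallel branches per image — semantic segmentation of
marked neurons from a membrane-marker channel, and single-molecule spot
detection in the smFISH channel — whose intersection yields per-cell and
per-neuron transcript counts, followed by a quality-control battery. A
synthetic-stack simulator with exact ground truth makes every stage testable
without microscope data. This note records the models, the parameters that
matter, and the design choices made where the design was genuinely open.

## Conventions

Stacks are held in memory as `(channel, z, y, x)` float arrays with physical
voxel sizes `(dz, dy, dx)` in µm, regardless of on-disk layout. Voxel indices
are 0-based and the physical coordinate of the center of voxel `i` along an
axis of pitch `s` is `(i + 0.5)·s`; a physical point maps back to its
containing voxel by `floor(coord / s)`. Default voxel sizes (dz = 0.2 µm,
dy = dx = 0.05 µm) are configuration values describing a typical
high-resolution confocal acquisition, not measured constants; they are read
from OME-TIFF metadata whenever present.

## Spot model and detection

A diffraction-limited spot is modeled as an anisotropic 3D Gaussian with
lateral symmetry:

    I(x,y,z) = b + A·exp(−((x−x₀)² + (y−y₀)²)/(2σ_xy²) − (z−z₀)²/(2σ_z²))

with default widths σ_xy = 120 nm and σ_z = 400 nm, the values measured for
the Airyscan-class acquisitions this pipeline targets. The widths are
interpreted as the Gaussian **σ** parameters, not FWHM — a deliberate and
documented reading, since "spot size" is ambiguous; if your instrument
reports FWHM, divide by 2.355 before configuring.

Detection proceeds in three stages:

1. **Global threshold.** A voxel must reach intensity `T` to seed a
   candidate. `T` can be absolute or expressed as a multiple of the robust
   noise SD (1.4826·MAD) above the channel median (`threshold_mode: mad`),
   which transfers across batches with different backgrounds. The threshold
   is empirical by nature; detected counts fall monotonically as `T` rises,
   and the pipeline's overlay images exist to tune it visually.
2. **Local maxima.** Candidates are voxels that are strict maxima of their
   26-neighborhood. On an exactly flat plateau that is itself a local
   maximum, the lexicographically smallest `(z, y, x)` voxel is kept — an
   arbitrary but deterministic tie-break that only matters on integer data.
3. **Gaussian fitting.** Bounded least squares (`scipy.optimize.least_squares`,
   TRF) over a window of ±2σ per axis around the candidate, fitting
   `(x₀, y₀, z₀, A, b)` with σ fixed to the configured PSF (`fixed_sigma`),
   or additionally σ_xy and σ_z for PSF estimation (`free_sigma`).
   Initialization: the candidate voxel center, `b₀` = window median,
   `A₀` = peak − `b₀`.

The ±2σ window (rather than a wider one) is deliberate: with well-separated
molecules the ±2σ region contains essentially all of a spot's information,
while a wider window lets a bright neighbor inside it capture the fit — on
simulated 80-spot cells, recovery rose from 303/320 planted spots at ±3σ to
318/320 at ±2σ, at 6× less cost. The window is a parameter
(`fit_window_sigmas`).

A fit is rejected when the window holds fewer than 10 voxels, the amplitude
is non-positive, the center converges onto the window boundary, or the
residual RMS exceeds `residual_factor` (default 10) times the robust
(MAD-based) noise estimated from the fit residuals. These rejection rules
are this package's own; additionally, the composed detector drops fits whose
amplitude does not clear the same margin above the fitted background as the
detection threshold clears above the image median — this suppresses fits to
noise fluctuations whose peak voxel crossed `T`, because fitting averages the
noise and leaves such fits with amplitudes far below the margin. Duplicate
fits closer than one anisotropically scaled σ
(√((Δx²+Δy²)/σ_xy² + Δz²/σ_z²) < 1) are merged greedily by descending
amplitude.

Integrated intensity is reported in closed form, `A·(2π)^{3/2}·σ_xy²·σ_z`
(intensity·µm³), rather than by summing voxels; the two agree within 1% for
σ ≥ 2 voxels.

**PSF estimation** refits ≥ 3 user-picked (or ground-truth) locations with
free σ and takes the medians; picks whose fitted amplitude is within 3× the
residual noise are discarded as unusable size references.

## Segmentation

The membrane marker labels the plasma membrane and intracellular secretory
components, so marker intensity varies strongly through the cytoplasm and
plain thresholding fails. Segmentation is instead per-pixel classification
(cell vs background) by a small encoder–decoder CNN over **2.5D slab
inputs**: for each Z-slice, three aligned planes — the slice itself, a
maximum-intensity projection (MIP) of the slices within `w` above it, and a
MIP of the slices within `w` below (default w = 0.4 µm, i.e.
`floor(w/dz) = 2` neighbors per side at dz = 0.2 µm). At the stack boundary
an empty neighbor set degrades to a copy of the current slice. This gives a
2D network three-dimensional context at 2D cost.

Before slab construction the marker volume is normalized by **percentile
histogram stretching**: the 2nd and 98th percentile intensities of the whole
stack are mapped to 0 and 1 with clipping. The marker histogram is bimodal
(background near zero, signal well above), so this yields comparable
contrast across acquisitions with very different absolute brightness.
Normalization is per-stack, not per-slice, so genuine Z-intensity trends
remain visible to QC. Percentiles use linear interpolation between order
statistics. Whether normalization precedes slab MIPs is an open choice; this
implementation normalizes first.

The network is a compact U-Net-style model — `depth` pooling levels
(default 2), base 8 channels doubling per level, one 3×3 conv + ReLU per
block, skip concatenations, softmax over {background, cell} — implemented
directly in numpy (im2col convolutions, Adam, class-weighted cross-entropy).
A from-scratch numpy implementation keeps training bit-for-bit reproducible
given the seed and trains in about a minute on one CPU at the default
250 iterations of 4 random 64×64 crops; the segmentation task after
normalization is high-contrast, so a small model suffices. Training
augmentations: random brightness factors {0.5, 0.75, 1.0, 1.25, 2.0}
(masks untouched) and random swapping of the above/below MIP planes. Class
weights are inverse class frequencies, since foreground is rare. When at
least two annotated stacks are provided, the last is held out and its
foreground IoU is stored on the model.

At inference the network is evaluated on both orderings of the above/below
planes and averaged, making predictions exactly symmetric under Z reversal
of the stack — the symmetry the slab construction itself has. Per-slice
probability maps are stacked, thresholded at 0.5, and 26-connected 3D
components of at least 1 µm³ become the cell mask. Touching neurons
typically merge into one label — the mask outlines the contiguous cluster,
which is expected for this cell type; the pipeline does not attempt instance
separation. Nuclei are recovered by Otsu thresholding of the nuclear-stain
channel restricted to the cell mask (components ≥ 0.5 µm³), and are
contained in the cell mask by construction.

## Quantification

A spot belongs to the region whose label sits at the voxel containing its
fitted center (floor convention at the mask grid — no sub-voxel mask
interpolation); background-voxel spots are flagged extracellular and excluded.
Because one mask label can cover several contiguous neurons, per-neuron
values divide each label's total by `neurons_per_label`, which defaults to
the number of nucleus components inside the label when a nuclear channel
exists and to 1 (with a logged warning) otherwise. Group comparisons use
Welch's unpaired two-tailed t-test (unequal variances, Welch–Satterthwaite
degrees of freedom), implemented from the closed form and cross-checked in
the tests against an independent reference implementation. No
multiple-testing correction is applied across pairwise comparisons by
default; a Holm adjustment is available.

## Quality control

Three per-image checks, all pure functions of spot tables and masks:

* **Intensity histogram / unimodality.** Each mRNA is tiled by a similar
  number of probes, so integrated intensities should form one mode.
  Histograms share bin edges (pooled 1st–99th percentile range, 30 bins);
  the flag counts peaks of the 3-bin moving-average-smoothed histogram with
  prominence ≥ 25% of the tallest bin — a transparent heuristic, not a dip
  test.
* **Intensity-vs-Z screen.** Pearson correlation between integrated
  intensity and z; pass ⇔ p ≥ α (default 0.05). Pearson was chosen over
  rank correlation for its standard p-value; the choice is configurable. On
  simulated attenuation-free images the pass rate is the nominal ~95%, and
  the acceptance bar is ≥ 80%, the fraction reported for real acquisitions
  with adequate working distance. Fewer than 3 spots yields a null result.
* **Diameter consistency.** Equivalent diameters d = (6V/π)^(1/3) of mask
  labels, with an outlier flag beyond a 2× fold change from the batch median
  *diameter* (a doubled volume is only a 1.26× diameter change and is not
  flagged).

## Synthetic data

The simulator renders 3-channel stacks (marker, smFISH, nuclear) over a
32×256×256 voxel canvas (6.4×12.8×12.8 µm): ellipsoidal cells of radius
2.5 ± 0.2 µm (axis ratios ≤ 1.5, equal-volume normalization) placed adjacent
so clusters are contiguous; a bright membrane shell (~12% of the radius)
over an interior whose intensity is modulated by a smooth multiplicative
lognormal texture (log-SD 0.4), giving the bimodal marker histogram the
normalization assumes; nuclei as concentric regions at half the cell radius.
Per-cell spot counts are fixed (default 80, the expression-peak scenario; 30
for the trough) or Poisson. Spot amplitudes are lognormal with 10% CV —
narrow, because each molecule binds a similar number of probes — with
default mean 500 over a background of 100, and optional exponential depth
attenuation. Noise is Poisson shot noise on (signal×gain)/gain plus Gaussian
read noise (SD 5); the defaults give a peak-amplitude SNR of ~45, and the
PSF-recovery studies run at SNR 8, the detector's nominal working point.

Planted spots are kept at least 3 anisotropically scaled σ apart
(√((Δxy/σ_xy)² + (Δz/σ_z)²) ≥ 3): two equal Gaussians merge into a single
maximum at exactly 2σ separation, so 3σ guarantees each planted molecule is
individually resolvable and ground-truth counts are unambiguous. Setting the
separation to 0 is an explicit stress-test mode in which merged pairs make
recall comparisons ill-defined.

What the simulator does **not** emulate: real PSF structure (Airy rings,
spherical aberration, depth-dependent blur), photobleaching, autofluorescent
debris, tissue scattering, irregular cell shapes, transcription-site foci
containing many molecules, and annotation noise in training masks (simulated
masks are exact). Passing tests therefore demonstrate correctness of the
algorithms under the stated model, not performance on any particular
microscope's data; on real stacks the detection threshold and PSF widths
must be set from the data, which is exactly what the threshold-sweep
overlays and the PSF-estimation routine are for.

## Orchestration

The pipeline runner tracks each stage (segment, detect, quantify per image;
aggregate QC/plots per run) in a JSON manifest keyed by parameter hashes and
input-file content hashes. A stage re-runs only if its parameters, inputs,
or outputs changed, so re-running with the same configuration recomputes
nothing, and changing only the detection threshold re-runs detection and
downstream stages while reusing segmentation outputs byte-for-byte. One
detection threshold applies to all images in a run, matching the
one-threshold-per-batch practice. Failures in one image are recorded in the
manifest (with traceback) without stopping the others. Two complete runs
with the same configuration, inputs and seed produce identical CSV outputs.

## Problem sizes used in the checks

The test suite and the acceptance script train on 10 simulated annotated
stacks (250 iterations, ~1–2 min on one CPU), analyze 4-cell stacks of
32×256×256 voxels end to end, refit 50 isolated spots at SNR 8 for PSF
recovery, and screen 200 simulated spot tables (50 spots each) for the
Z-correlation pass rate. These sizes were chosen as the smallest at which
every estimate is stable; all scale linearly if increased.

## Known limitations

* Semantic, not instance, segmentation: touching cells share a label, and
  per-neuron counts depend on the nucleus count inside each label.
* The detector assumes isolated diffraction-limited emitters; bright
  multi-molecule foci are fitted as single spots.
* The unimodality flag is a heuristic (smoothed-histogram peak counting).
* The numpy CNN is deliberately small; very low-contrast markers may need a
  larger `depth`/`base_channels` (at correspondingly longer training).
* OME-TIFF is the only supported stack format; proprietary vendor formats
  must be converted upstream.
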