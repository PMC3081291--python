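# Methods

This note documents the models, parameter choices and numerical conventions
behind each pipeline stage, what the synthetic phantoms do and do not
emulate, and the known limitations.

## The ganglion phantom

No raw imaging data exists for the biological system this pipeline targets,
so every stage is developed and validated against a generative phantom whose
*spatial and statistical* structure matches what the analysis assumes.

**Geometry.** A rectangular raster (default 24×24 pixels at 50 µm — nine
serial sections through a ~0.8 mm ganglion cross-section) carries one region
label per pixel: a circular ganglion disc split by the horizontal line
through its center into an anterior and a posterior half-disc, an optional
concentric neuropil disc, an optional blood-sinus annulus between two radii
(inner ≥ disc radius), and background. Labeling is purely deterministic;
a requested region that captures zero pixel centers is an error naming the
region, except a zero-width annulus (inner == outer), which is legal and
empty.

**Spectra.** Each non-background pixel of each section receives one spectrum
on a shared m/z axis (default 8,000 points over 2,000–20,000 Th):

* Peaks are Gaussian in m/z with σ = m/z ∕ (2.355 R) at constant nominal
  resolving power R — R = 500 for the linear-mode protein profile, 10,000
  for the reflector/SIMS lipid profile. Real TOF peak shapes are asymmetric;
  a Gaussian is sufficient for every property tested here.
* Peak amplitudes are log-normal, parameterized by mean and CV so that
  intensities stay positive and the configured mean is the true expectation
  (verified by Monte-Carlo in the tests). A per-peak `anterior_bias` g
  multiplies the expectation by g^(s−1) in section s, emulating expression
  fading from the anterior lesion face; a `conditions` gate restricts peaks
  (e.g. the m/z 2475 regeneration marker) to the regenerating condition.
* The baseline is b₀·exp(−m/z ∕ τ) (default b₀ = 5 counts, τ = 2,000 Th for
  the protein profile; none for lipids), noise is additive Gaussian
  truncated at zero (default SD 2 counts), 2% of pixels are hot spots whose
  entire spectrum is multiplied by 5 (a matrix crystal hit directly by the
  laser), and 5% are pure-noise pixels carrying baseline + noise only (e.g.
  matrix-only spots). These two artifact classes are exactly what TIC
  normalization with a noise cutoff exists to handle.
* All randomness flows from a single integer seed through per-section
  `SeedSequence` substreams: identical specs give bit-identical datasets.

The default protein phantom has partly disjoint anterior and posterior peak
panels (five shared, three anterior-only, three posterior-only peptide
peaks, amplitudes 400–1,000 counts, CV 0.25–0.3) so that the two half-discs
are separable but correlated; the sinus phantom adds an annulus whose
five-peak panel is fully disjoint from the core's. Amplitudes and panel
sizes are a design choice — the source study reports no quantitative effect
sizes for its ganglia — scaled so that per-pixel signal dominates baseline
about 10:1, a realistic regime for dried-droplet MALDI tissue imaging.

**What the phantom does not emulate:** desorption/ionization physics,
isotope envelopes, peak-shape asymmetry and drift, detector saturation,
spatial autocorrelation of biological expression, or section-to-section
registration error. Passing tests therefore demonstrate correctness of the
*computations* under the stated statistical assumptions, not robustness to
every artifact of real acquisitions.

## Normalization with noise-spectrum exclusion

TIC normalization rescales each retained spectrum so all spectra share one
total ion count (default target: the mean TIC of retained spectra, which
preserves the count scale; unit TIC is available). Its known failure mode is
inflating pure-noise spectra, so spectra with

  Ymean < threshold_factor × Ymax

are excluded, where Ymean is the spectrum's mean intensity over its n points
and Ymax is, by convention, the dataset-wide maximum single intensity ("the
maximum of the y-axis"; a per-spectrum scope is available). The vendor-style
rule this mirrors is stated ambiguously in the literature — read verbatim it
scales *only* the below-cutoff spectra, which defeats the cutoff's stated
purpose. The default semantics here follow the purpose (below-cutoff spectra
are excluded from scaling); `literal_text_mode=True` implements the verbatim
reading. Both are tested.

Because Ymean of even a strong spectrum is orders of magnitude below the
single tallest data point in a dataset, useful dataset-scope threshold
factors are small. The default is 3·10⁻⁴, which on the default phantom
places the cutoff (~2.7 counts) in the wide gap between the Ymean of
pure-noise pixels (~0.9) and tissue pixels (≥4). No threshold value is
reported for the original analysis; this default is the package's choice and
is a config parameter everywhere it is used.

Zero-TIC spectra are always excluded and never divided. Excluded spectra are
kept unscaled by default (or zeroed via `excluded_policy`), and the
exclusion flags feed `bin_to_matrix(include=...)` so segmentation operates
on retained spectra only.

## Binning, resampling, peak picking

* Binning uses half-open bins [left, right), first left edge at the axis
  minimum, with exactly enough bins to hold the axis maximum — so binning
  conserves counts exactly (each row of the feature matrix sums to the
  spectrum's TIC). Default bin width 9 Th gives ~2,000 bins over the protein
  range.
* Resampling is linear interpolation onto a common ascending axis, clamped
  to zero outside a spectrum's support; it exists because continuous-mode
  export and binning require a shared axis.
* Peak picking estimates noise as 1.4826 × MAD of the first-difference
  signal (restricted to strictly positive sample pairs, since zero-clipped
  samples deflate the MAD), detects candidates on a lightly
  Savitzky–Golay-smoothed copy (window 7, order 2 — isolated noise spikes do
  not survive smoothing) as local maxima with topographic prominence ≥
  S/N-threshold × noise, then measures on the raw signal: apex by a local
  three-point parabola, area by the trapezoid over the peak's support
  (walking downhill through plateaus to the surrounding minima). Prominence
  rather than absolute height keeps slowly varying baselines from promoting
  noise.

## Segmentation

The pixels × bins matrix is column-mean-centered and decomposed by SVD.
Components are signed deterministically (largest-magnitude loading element
positive); requesting more components than the numerical rank truncates with
a flag. The number of components passed to clustering defaults to the
smallest k explaining ≥ 70% of variance, capped at 20 — the source
convention states no k; on the phantoms one component usually suffices
because the planted contrast dominates.

Clustering is agglomerative on the PCA scores, Euclidean metric, Ward
linkage by default (average and complete available); the original report
names neither the linkage nor whether clustering ran on scores or raw
spectra, so these are explicit config choices. The merge tree keeps
per-branch spectrum counts and branch distances, exports to a Newick-style
serialization, and is cut either into k clusters or at a distance threshold
(exactly one criterion). Cut labels are renumbered by first-leaf index so
cluster ids are deterministic, and the fixed eight-color palette makes
branch colors reproducible across runs. Ties during agglomeration are
resolved by scipy's linkage implementation; the test-suite oracle comparison
uses continuous random data, where ties have probability zero.

Reconstruction paints each pixel of each section with its branch id;
pixels without a retained spectrum are marked −1 (sections may legitimately
carry different pixel counts). Recovery of planted structure is scored by
the adjusted Rand index against the phantom's ground-truth labels: ≥ 0.9
required, ≈ 1.0 observed at default noise for both the anterior/posterior
and the annulus/core contrast.

## Ion images

An ion image sums, per pixel, the intensities within [center − tol,
center + tol] (inclusive ends; asymmetric windows available). `mc` is the
raw maximum pixel count — the amplitude of the [0, mc] color scale — and
`tc` the sum over all pixels; no smoothing or interpolation is applied, and
mc/tc scale exactly linearly with the data. Default tolerance is 0.5% of the
center m/z in the protein range and 0.05 Th in the lipid range. Missing
pixels render as zero and are flagged. Adjacent tiles of equal height
concatenate end-to-end with per-tile mc/tc preserved in metadata.

## Mass calculation

Atomic masses are embedded constants, stored to six decimals: monoisotopic
(most-abundant isotope) masses from the IUPAC/AME tables — with ⁷Li for
lithium and ²H available as an isotope tag — and IUPAC standard atomic
weights for average mode; the electron mass (5.49·10⁻⁴ Da, CODATA) is
subtracted or added per charge. Electron correction is ON by default, since
the quantities of interest are ion m/z values, with a toggle because
printed values in the literature mix conventions. Adducts are element
deltas: [M+H]+, [M−H]−, [M+Li]+, [M+Na]+, [M+K]+, [M+H−H₂O]+ and
preformed cations (the formula already lists the cation's atoms).

Peptide masses are the sum of residue compositions plus water; residue
masses are derived from elemental composition at call time, never stored
per-residue, so they stay consistent with the atomic table. The m/z 2475
regeneration marker is treated as an opaque planted value throughout: its
published N-terminal sequence describes only a fragment of the parent
intermediate-filament protein, so no mass computation is attached to it.

Verification is dual-route: the implementation's values are cross-checked in
the tests against pyteomics' independent mass tables, and the printed
assignments (385.29, 354.29, 281.2, 283.2, 184.1, 369.32) are reproduced at
the precision each was printed with (the AEA value was truncated, not
rounded; the cholesterol fragment value is ~0.03 below the exact fragment
mass, consistent with SIMS calibration at that mass).

## Isotope-dilution quantification

The relative level of an analyte is (analyte peak area / internal-standard
peak area) × spiked amount (default 4 µg/mL, the study's spike), which is
invariant to any common scale factor. Areas are trapezoidal integrals over
the configured window after subtracting a linear baseline drawn between the
window endpoints; each endpoint's value is the median of the outermost three
window points, so a single noisy edge sample cannot tilt the baseline.
Analyte and standard windows must not overlap. A non-positive standard area
is an error (failed internal standard), and a failed replicate flags its
time point rather than silently dropping it; replicate spread is reported as
the sample standard deviation.

The synthetic dilution series plants a known area ratio by scaling the
analyte amplitude with the σ-ratio of the two peaks, and the time-course
generator follows a gamma-shaped release pulse (t/t_peak)·exp(1 − t/t_peak)
over 0–240 min at six sampling times with three replicates (CV 10%) —
defaults peak at 15 min, matching release within minutes; a one-hour peak
models the slower profile. Recovery requirements: exact ratio within 3%
noiseless, median relative error < 5% over 100 seeds at analyte-apex S/N 20,
and the argmax of the recovered course at the planted peak time.

**Marker presence.** "Present in regenerating, absent in control" becomes an
explicit rule: a marker is present in a region when ≥ 25% of its pixels show
a picked peak with S/N ≥ 3 inside the window (defaults exposed in config;
`min_fraction=0` is a documented degenerate boundary that always returns
present). On the phantoms at a ±5 Th window this yields ~96% qualifying
anterior pixels in the regenerating condition versus ~5% in the control.

## imzML I/O

Only continuous-mode imzML (one shared m/z axis) is read and written —
segmentation requires a common axis anyway, and heterogeneous-axis datasets
must be resampled first. m/z is stored float64, intensities float32; the
section index rides in the third (z) position coordinate; pixel coordinates
are 1-based in the file and 0-based in memory, converted only at the I/O
boundary. The file pair's UUID is derived from the dataset content
(SHA-1 → UUID), and the embedded run id is normalized to the file stem, so
writing the same dataset twice yields byte-identical files and
write→read→write is stable. Reading verifies the XML/binary UUID pair and
rejects processed-mode files with an actionable message. Grid dimensions
recovered from a file are the acquisition bounding box (imzML stores pixel
counts, not the original scan frame).

## Problem sizes and determinism

The default phantom produces 1,872 spectra of 8,000 points (≈ 1,800 tissue
pixels across nine sections) and a 1,783 × 2,001 feature matrix after
exclusion — sized so the full simulate → normalize → segment chain completes
in seconds while preserving the acquisition geometry (50 µm raster, nine
sections). The lipid preset defaults to a 64×64 raster, a down-scaled
stand-in for a 256×256 field of view; the full raster is one override away.
Every stochastic stage takes an explicit integer seed and identical
config + seed reproduce byte-identical numeric outputs, which the pipeline
records as a resolved-config snapshot sufficient to re-run.

## Known limitations

* The Ymean/Ymax threshold factor has no published reference value; the
  default suits the phantom's noise model and must be re-tuned for real
  acquisitions.
* Baseline handling is limited to the exponential phantom baseline and the
  local linear baseline inside integration windows; no general baseline
  subtraction or recalibration/alignment across sections is provided (axes
  are shared by construction here).
* Cluster-count selection is manual (default 2); no significance testing of
  cluster separation is attempted.
* Absolute quantification (calibration curves) and MS/MS confirmation are
  out of scope; the dilution pipeline reports relative levels in spike
  units.
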