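# Methods

This note documents the models behind `slimcluster`, the defaults and why
they were chosen, what the synthetic data do and do not emulate, and the
numerical decisions a maintainer should know about.

## Imaging model and units

All simulation and analysis share one forward model: a fluorescence image
is camera offset + Gaussian-PSF-blurred photon flux, with Poisson shot
noise and Gaussian read noise. Conventions: lengths in nm (80 nm/pixel),
times in ms (5 ms/frame), diffusion coefficients in µm²/s, intensities in
camera counts.

Defaults (`SimParams`): PSF sigma 230 nm; cell diameter 5 µm, nucleus
2 µm; photobleach constant t_b = 40 ms; single-fluorophore brightness
I_GFP = 5000 counts. The camera offset (100 counts) and read noise sd
(10 counts) are free parameters of the simulator — no camera noise spec
exists for the imaging conditions the defaults describe — set once to give
single-molecule SNR comparable to in-vivo Slimfield data; EMCCD gain is
fixed at 1 (the multiplication register is not modeled).

## Synthetic data: what it emulates, what it does not

`generate_cell_stack` renders the diffuse pool as a compartment-uniform
density — the chord-length projection of a uniform sphere — convolved with
the PSF, rather than thousands of explicit fast diffusers. Above the
resolution limit the two are equivalent and the density form matches the
CoPro forward model exactly. Foci are Gaussian spots whose fluorophores
bleach in discrete steps with exponential lifetimes (mean t_b); the pool
bleaches with the same constant in expectation. Photon conservation holds
exactly with noise off: summed frame intensity equals (expected pool +
actual unbleached focus content) × I_GFP.

Diffusion is simulated as per-frame Gaussian steps (per-axis sd
√(2DΔt)) with radial reflection at compartment boundaries. Trans-nuclear
foci follow a straight crossing path *in the focal plane* with an
exponential pause (default mean 10 ms) at the envelope; out-of-plane
crossings are not generated because a 2D analysis cannot observe them —
a 3D radial crossing places the envelope pause strictly inside the
*projected* nuclear boundary. The crossing time carries a random sub-frame
phase so dwell sampling is not locked to the frame grid.

Not emulated: optical aberrations and z-dependent PSF shape, EMCCD gain
statistics, cell-to-cell variability in brightness and autofluorescence
structure, chromatin-like motion of bound foci, and cell crowding
(one cell per field). Passing tests therefore demonstrate correctness of
the estimators under the stated model, not robustness to every real-data
pathology.

The toy genome plants concrete instances of an IUPAC pattern into random
sequence, a chosen fraction within 500 bp upstream of annotated genes.
3D coordinates come from a self-avoiding random walk (one locus per 500 bp,
100 nm segments) confined to the nuclear sphere. The 100 nm default makes
chromosomes span the nucleus, as consensus 3D chromosome models do; it is
a geometric stand-in, not chromatin physics.

## Segmentation

The compartment threshold is iterated: Otsu initializes a mask, then the
threshold is re-set to 0.3 × the mean background-corrected intensity
inside the current mask until stable; the largest connected component is
kept and its sub-pixel boundary extracted by marching squares at the
converged level. Background is the modal pixel value (camera offset).
On simulated uniform spheres of radius 25 px the median boundary error is
~0.23 px, within the half-pixel figure the 0.3 threshold is known for.

Boundary smoothing is a periodic penalized spline of radius versus polar
angle about the centroid (cells and nuclei are star-shaped), minimizing
p·Σ(r−s)² + (1−p)·∫s″², with p = 0.9992 by default and p = 1
interpolating. Periodicity is enforced by fitting on data extended one
angular period to each side.

## Focus detection and linking

Candidates are seeded on a difference-of-Gaussians band-pass, thresholded
at 5 robust standard deviations (median + 5·MAD·1.4826) above the band
median — a scale-free criterion that behaves identically on sparse and
crowded frames. Each candidate is refined by iterative Gaussian masking
with two safeguards for crowded scenes: the mask window is ±2σ, and the
centroid may not wander more than 2σ from its seed (plain centroid
iteration otherwise migrates along merged-intensity ridges onto the
brightest neighbor and all candidates collapse together).

The characteristic intensity is the background-corrected sum in a
5 px-radius ROI, divided by the enclosed-energy fraction
1 − exp(−r²/2σ²) of the nominal PSF: a σ = 230 nm (2.9 px) spot puts only
~78% of its flux inside a 5 px disk, and without the correction every
stoichiometry would be ~30% low. The correction deliberately uses the
nominal PSF width, not the fitted width — merged multi-emitter blobs fit
wide and would otherwise blow the correction up. Local background comes
from a 5–8 px annulus median, refined by the free offset of the radial
Gaussian fit (the annulus itself sits in the spot tail at this PSF size).
Acceptance requires SNR = (ROI sum / ROI pixels) / (annulus sd) > 0.4.

Linking is greedy nearest-neighbor between consecutive frames only (no
gap closing), with a displacement gate of one PSF width and factor-2
gates on brightness and sigma ratios; ambiguities resolve by minimal
displacement, and a canonical within-frame sort makes the result
invariant to detection order. Measured performance on the default
simulator: localization RMSE ≈ 29 nm for S = 7 foci (nominal precision
40 nm), recall > 90% for S ≥ 3.

## Stoichiometry

I_GFP is the mode (Silverman-KDE argmax) of all positive focus
intensities over time, cross-checked against the fundamental of the
pairwise-distance power spectrum (warning if they disagree by > 30%).
Track stoichiometry corrects each intensity by exp(+t/t_b) — the exact
inverse of exponential bleaching — and divides the corrected-trace mean
(Î₀; first-point and exponential-intercept estimators are provided as
options) by I_GFP. Tracks starting after 70 frames of illumination are
excluded: by then the bleach correction amplifies noise by e^8.75 and the
estimate is worthless.

### Periodicity

The histogram (0.2-molecule bins) of all pairwise stoichiometry
differences is detrended with a 3-molecule Gaussian and Fourier
transformed; the candidate periodicity is the strongest peak with period
in [2, 12] molecules. The band cap matters: near span/2 the detrend
leaks envelope structure that mimics long periods. Significance is
calibrated by Monte Carlo, the only approach we found that controls false
positives across distribution shapes: 40 surrogate samples are drawn by
variance-corrected smoothed bootstrap (kernel bandwidth 2× Silverman,
shrunk to preserve the sample variance, reflected at the sample range to
preserve sharp distribution edges — whose spectral ringing is the
dominant false-positive mechanism), and the observed peak must exceed
twice the largest surrogate maximum. Genuine combs exceed the surrogate
ceiling by 1–2 orders of magnitude; uniform, normal and gamma nulls sit
below ~1.4×.

### Pool quantification (CoPro)

The image is decomposed by non-negative least squares into three basis
images — PSF-convolved uniform nuclear sphere, uniform cytoplasmic shell,
and constant background — using radii from the segmented boundaries;
amplitudes divided by I_GFP give copy numbers. A nucleus/cytoplasm basis
correlation > 0.999 raises a singular-design error. Depth-of-field
correction (dividing by the compartment volume fraction within the focal
slab) is available but off by default: the simulator renders full-volume
projections, and analysis and simulation must share one forward model for
recovery to be meaningful. Recovery on simulated cells is within 10%
given correct boundaries; segmentation radius bias (~0.5–0.8 px on the
nucleus) adds a comparable error on fully segmented inputs.

## Mobility

MSD uses the standard time-averaged estimator (all start points per lag).
D is slope/4 of a line through the first four MSD points, intercept free
by default (fixing it to 4σ² is an option; free is safer when the true
precision differs from the nominal 40 nm).

The CDF mixture fit follows the empirical CDF of first-step r² at all
observed points with uniform weights. Model selection (1 → 2 → 3
components) accepts an extra component only if (i) it lowers a
binomial-weighted reduced χ² — residuals scaled by √(F(1−F)/n), so χ² ≈ 1
for an adequate model — by more than 10%, and (ii) the component is
identifiable: every weight ≥ 8% and successive D ratios ≥ 2.5. Without
the identifiability guard, single-population data sprouted a spurious
component in ~37% of runs; with it, the spurious rate is ≤ 5–10% and the
two-component operating point (20%/80%, D = 0.15/1.5 µm²/s, σ = 40 nm)
is recovered with the immobile fraction unbiased to ~2 percentage points
(single-run sampling sd ~6 points at n = 1000 — medians over replicates
are reported wherever a stable number is needed). Note the localization
term is part of the data: σ = 40 nm at Δt = 5 ms adds σ²/Δt = 0.32 µm²/s
to every apparent D, which is why recovered D values exceed the
generating ones while fractions are unaffected.

The Gamma mixture over per-track D uses the density
(m/D_i)^m x^(m−1) e^(−mx/D_i)/(m−1)! with m = 4 (the number of MSD points
behind each D estimate), fitted by least squares to the D histogram; at
m = 1 it reduces to an exponential. The anomalous fit
MSD = 4σ² + 4Kτ^α (τ ≤ 30 ms) is initialized from a log–log line after
subtracting 4σ²; the Brownian restriction (α = 1) is always co-fitted
through the same origin-constrained closed form, and its χ² reported.

## Kinetics

The trans-nuclear transformation interpolates the crossing linearly on
the signed radial distance between the first straddling pair of points,
takes the tangent from the boundary-spline derivative, and rotates so x′
is tangential and the nucleus interior is y′ < 0; the transformation is
rigid. Dwells are contiguous runs with |y′| ≤ 20 nm (envelope band 40 nm
by default — the band is a declared choice, the envelope being 30–40 nm
wide). Because durations are frame-quantized (10 ms mean vs 5 ms frames),
the exponential constant uses the geometric-sampling MLE
τ = Δt / ln(n̄/(n̄−1)), which removes the discretization bias; recovery is
within 20% at ~150 crossings.

FRAP fits C(t) = C(0)(1 − exp(−t/t_R)) by nonlinear least squares with
data-driven initialization; monotonically decreasing input is rejected.
An optional exp(+t/t_b) pre-correction covers stroboscopic acquisitions
(timestamps are taken as given). Both the slow nuclear-foci regime
(t_R ≈ 133 s, 10 log-spaced points to 1000 s) and the fast pool regime
(t_R ≈ 3 s) are recovered within 15% at realistic noise.

## Genome binding models

`scan_sites` matches any IUPAC pattern on both strands with overlaps
(regex lookahead), deduplicated by (chromosome, start, strand), and flags
sites within 500 bp upstream of an annotated gene start on the matching
strand. The target-pattern sequence itself is an input, not a constant —
published promoter-site counts for specific factors are treated as data.
Binding models: monomer (one molecule per promoter site, remainder on
random non-promoter sites), DNA cluster (⌊total/u⌋ clusters of u = 7 on
random promoter sites; remainder molecules dropped with a log note),
nuclear-envelope variants (uniform on the envelope sphere), and a 75/25
NE-cluster/DNA-cluster per-cell mixture. bp → 3D mapping interpolates
linearly between the two nearest modeled loci on the same chromosome.
Rendering projects a uniformly random 3D rotation of the configuration
through the PSF and noise model; model comparison is R² = 1 − SS_res/SS_tot
between Silverman-KDE densities of simulated and reference stoichiometries
on a shared grid.

The end-to-end discrimination suite (cluster-generated reference vs
cluster and monomer model fits) runs at scaled-down molecule counts
(14 DNA + 14 NE molecules per cell, 25 cells per sample, toy genome of
3 × 40 kb): with a 230 nm-sigma PSF in a 2 µm nucleus, a full
~190-molecule load merges into one or two blobs per cell and no
distribution statistic can rank the models at desk scale. At the scaled
counts the cluster model wins the R² ordering in ≥ 95% of replicates.

## Geometry and colocalization

Cluster diameter: d = p_foci − p_GFP − √(4DΔt), where widths are 2× the
fitted Gaussian sigma (p_GFP = 460 nm) and √(4DΔt) is the in-plane
diffusion length during one exposure; subtracting the *area* 4DΔt is
dimensionally inconsistent and kept only behind `blur="area"` for
comparison. Non-positive diameters return an "unresolvable" result, not
an exception. This linear width subtraction is a heuristic — true PSF
broadening combines closer to quadrature — so sub-PSF diameters carry
order-of-magnitude, not nanometer, meaning. The packing law d ∝ S^a is
fitted on log–log axes (a = 1/3 ideal sphere, 1 rotating rod, 0 fixed
anchor). The overlap integral ν = exp(−Δr²/2(σ₁²+σ₂²)) is computed only
for pairs within 5 px; ν > 0.75 flags colocalization (both configurable).
Heat maps accumulate bilinear point splats (weight-conserving) under a
Gaussian blur: 1000 px grid with 15 px sigma for focus maps, 20 nm pixels
with 40 nm sigma for STORM-style maps.

## Determinism and problem sizes

Every stochastic routine takes a seed or Generator; fixed seeds give
byte-identical outputs, which the pipeline manifest exploits for
checksum-verified reruns. Test and acceptance problem sizes (20-seed
segmentation and FRAP medians, 15 × 1000 displacements, 50-replicate
discrimination at 25 cells/sample, 10 kb scanner-oracle sequences) were
chosen as the smallest sizes at which the estimators' sampling noise is
comfortably below the tolerances being checked; the full suite runs in
about two minutes on one CPU.

## Known limitations

- The detector is single-emitter: merged foci are measured as one focus
  with summed stoichiometry (as in the experimental method), not
  resolved by multi-emitter fitting.
- No z information: classification, dwell analysis and binding-model
  rendering all work in 2D projection.
- CoPro assumes spherical compartments and uniform pools; it has no
  depth sectioning unless configured, and inherits segmentation radius
  bias.
- The cluster-diameter estimator's linear width subtraction is biased
  low for diameters below the PSF scale.
- The smoothing-spline boundary assumes star-shaped compartments.
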