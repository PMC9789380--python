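# Methods

This note documents the models and procedures implemented in `ciliaxis`,
the parameter choices that matter, what the synthetic scenes do and do not
emulate, and the numerical decisions taken where the underlying methods
left the design open.

## Coordinate and data conventions

All volumes are (z, y, x) scalar fields with per-axis physical spacing in
µm; indices are 0-based and physical coordinates refer to voxel centers.
Photon-count fields are integer and non-negative. Volumes are read and
written as OME-TIFF with spacing taken from metadata; a missing spacing is
a hard error (a JSON sidecar `<file>.tif.json` with `spacing_um` is the
only fallback). Masks resample with nearest-neighbor interpolation,
intensities with linear interpolation; resampling preserves the physical
extent to within one voxel per axis and integrated intensity of smooth
fields to well under 1%.

## Segmentation

Otsu's threshold is computed from a 256-bin histogram over the observed
range; data with at most 256 distinct values are handled exactly, with the
distinct values as candidate thresholds, so the threshold provably
maximizes between-class variance (the test suite checks this against an
exhaustive search and against scikit-image's implementation). The
*restricted* variant computes the threshold only from values at or below a
percentile (90th by default) — this keeps rare bright outliers from
inflating the threshold — and the threshold is then applied to all voxels.
Morphological operations use Euclidean balls specified in µm; closing pads
the volume by the element radius first, because scipy's erosion otherwise
eats valid foreground at the array faces. Defaults: closing radius 0.4 µm
and minimum object size 0.05 µm³ for cilia/axons, 0.5 µm³ for nuclei.

The cell-body layer is the largest connected component of the dilated
nucleus mask (1.5 µm dilation by default; ties break deterministically to
the lowest label). Nucleus centers come from erosion, a Euclidean distance
transform, and a per-component threshold at 0.5 × the component's maximum
distance; this splits nuclei overlapping by up to roughly a third of their
radius when the erosion radius is of order one voxel–one µm.

Cilia trajectory analysis operates on maximum-intensity z projections. The
2D structure tensor uses Gaussian-derivative gradients (σ = 2 px) smoothed
with a Gaussian analysis window (σ = 20 px); per-pixel orientation is
½·atan2(2Jxy, Jyy − Jxx) and the histogram (180 bins over (−90°, 90°]) is
weighted by tensor energy (trace), with coherence available as an
alternative. A single Gaussian (center, width, amplitude, offset) is
fitted after unwrapping the bins around the circular mean direction;
needle-like histograms that defeat least squares fall back to circular
moments. The result is flagged *low confidence* when the circular
concentration |Σw·e^{2iθ}|/Σw falls below 0.3 (near-flat histogram — note
that white noise under a 20 px window yields a lumpy, not flat, histogram,
which the concentration criterion handles where an amplitude/offset
comparison does not), when the fitted width exceeds 60°, or when the
amplitude does not clear half the offset.

## Skeletons, distances, contacts

Central axes come from 3D topological thinning. Thinning of symmetric
tubes with even voxel thickness can collapse partially or entirely (a
parity artifact of the sub-iteration scheme), so each mask component whose
thinned skeleton is missing, fragmented, or spans less than half the
component's extent falls back to an EDT-penalized geodesic centerline: the
shortest path between the component's farthest voxel pair under edge
weights step/(1 + mean EDT)², which hugs the medial axis. Connected
components define instances.

Distances are encoded by sampling the Euclidean distance transform of the
target (axon skeleton, synaptophysin mask, nuclei) at every cilium
skeleton voxel; the per-cilium minimum feeds classification. The EDT is
exact, so these distances equal an exhaustive all-pairs scan. The contact
cutoff is 2 µm, **inclusive**; the puncta–axon association cutoff is 1 µm,
inclusive. Cilia are excluded when any skeleton voxel lies within one
voxel of a volume face, or when the nucleus nearest their base (the
geodesic endpoint closest to any nucleus centroid) lies outside the layer
mask.

**Length estimator.** The raw sum of 26-connectivity step lengths along a
digital path overestimates oblique straight runs by up to ~8% (lattice
effect), and thinning retracts tube ends by a variable 0.2–1 µm. The
estimator therefore (i) takes the longest geodesic path through the
instance, (ii) smooths it with a 5-point moving average (endpoints
pinned), and (iii) when the source mask is available, extends each end
along its local tangent to the mask boundary and subtracts the tube radius
(median EDT along the path interior). The radius subtraction makes the
correction valid for both skeleton types: thinning-retracted ends receive
a net positive extension, tip-to-tip centerlines a net trim. On planted
straight tubes of 3–12 µm (radius 0.25 µm) this recovers ≥ 95% of lengths
within max(5%, 2 voxels). Through the full noisy segmentation pipeline the
estimate acquires a small negative bias (≈ −0.3 µm) because thresholding
erodes the blurred tube caps; this is a segmentation property, not an
estimator property, and is visible in the pipeline tests.

The ciliary receptor fraction divides the integrated receptor intensity
inside the 1-voxel-dilated cilia mask by the integrated intensity over all
voxels with at least 20 counts. No size filter is applied to extra-ciliary
signal.

## Puncta

The detector computes the scale-normalized response −σ²∇²(G_σ ∗ I) with
σ = 0.2 µm by default (a diffraction-limited punctum at the sampled grid)
and takes 26-neighborhood local maxima above 5 × the robust noise SD of
the response (1.4826 × MAD). Centroids are refined by center of mass of
the positive response in a 3³ neighborhood. Detection is invariant under
global intensity scaling when the threshold scales along. Radial counts
are inclusive at each radius.

## Trace, FRET and FLIM analytics

ΔF/F₀ subtracts a scalar background, takes F₀ as the mean over a baseline
frame window (e.g. the 10 frames before photostimulation, or the first 5
frames before ligand application), and is invariant under joint rescaling
of F and background. The low-pass filter zeroes Fourier components
strictly above the cutoff; DC is preserved exactly and the operation is
idempotent. Response metrics are the maximum (photostimulation) or mean
(ligand stimulation) ΔF/F₀ over the stimulus window.

Hill fits estimate log₁₀EC₅₀ (bounded), slope, top and optionally fixed
bottom by least squares; kinetics fits are single exponentials
A(1 − e^{−t/τ}) + C (on) or A e^{−t/τ} + C (off), with a warning when the
trace spans less than 3τ.

FRET ratios are computed per frame from z-projected donor/sensitized
stacks: rolling-ball background flattening of the donor (radius 50 px by
default) for mask creation, Otsu threshold, subtraction of the mean of a
caller-supplied acellular region from both channels, then
Σ(sensitized)/Σ(donor) within the mask (summed intensities; identical to
means for a shared mask). Optional frame-pair temporal averaging and 1 Hz
low-pass; ΔR/R₀ uses the early-frame baseline. Frames with an empty mask
are flagged and carry NaN.

The two-component decay fit holds the donor lifetimes fixed at 1.3 ns
(quenched) and 2.7 ns (unquenched) and solves the two amplitudes by
non-negative least squares; the quenched fraction is a_q/(a_q + a_u) and
the mean lifetime its amplitude-weighted average. This is a tail fit: no
instrument-response deconvolution is attempted, a deliberate
simplification of reconvolution fitting.

Per-cilium lifetime summaries discard voxels with fewer than 50 photons,
fit a three-parameter alpha distribution by maximum likelihood
(`scipy.stats.alpha.fit`), and report the analytic density maximizer
loc + scale·(√(a² + 8) − a)/4 (cross-checked against a numerical maximizer
in the tests). All-equal inputs short-circuit to that value; fewer than 10
usable voxels is an error, as is a fitted mode outside the observed range.

## Ratiometric mapping

The flat-field estimate follows the projection sequence: per channel, mean
projection through y to an x–z plane, max-normalization, averaging across
channels, a 2D Gaussian (σ = 2 px), mean through x, max-normalization.
One numerical addition: before smoothing, the plane is padded along z with
a per-column log-linear extrapolation and cropped afterwards. Plain
padding biases a monotone (attenuating) profile at both volume faces —
reflection lowers the bright face, which the final max-normalization then
propagates to every entry — and the log-linear pad removes this bias for
exponential-like profiles. Marker channels are corrected; the DNA channel
is not.

Ratios are computed only where the DNA signal reaches the
90th-percentile-restricted Otsu threshold; other voxels are invalid and
excluded from summaries. The KDE mode uses a Gaussian kernel with Scott's
rule (overridable); for samples above 50 000 values the density is
evaluated by convolving a fine histogram (≥ 8192 bins) with the kernel —
indistinguishable from the exact KDE at these bandwidths, and orders of
magnitude faster on million-voxel fields. Percent change is reported
relative to the reference (control) mode: round(100·(new − ref)/ref). The
conventions in published figure legends are not fully consistent on this
point; the control-denominator convention is fixed here.

## Estimation statistics

The effect size is mean(b) − mean(a) with a percentile bootstrap CI (5000
resamples, within-group resampling, 95% by default; percentile rather than
BCa, overridable in principle via the recorded bootstrap draws). The
permutation test is two-sided on the absolute mean difference; when the
number of distinct assignments is at most `n_perm` the null is enumerated
exhaustively (p = k/total, including the observed arrangement), otherwise
Monte Carlo with the +1 correction, so p is never exactly zero.
Comparisons carry a 1e−12 slack so floating-point ties match enumeration.
Calibration, measured by the test suite: 95% CI coverage ≈ 94–95% at
n = 50 per group (percentile bootstrap slightly undercovers at this n),
permutation type-I error ≈ 5% at nominal 5%.

## Synthetic scenes: what they emulate, and what they do not

**Contact scenes** (default 0.189 µm isotropic, 64×256×256) place 20
cilium–axon pairs in a 4×5 grid of cells with alternating z levels, so
each pair's planted minimum axis-to-axis distance (drawn at least 0.5 µm
clear of the 2 µm cutoff; 35% of cilia contacting by default) is also the
global minimum over all axons. Cilia are gently curved tubes (radius
0.25 µm, lengths ~5–8.5 µm) launched bidirectionally from nucleus
surfaces; any distal bend points away from the paired axon so the planted
distance is attained on the straight segment. Axons run through the cell
with Gaussian varicosity bumps (0.45 µm radius, 2 µm spacing) and bend
away from the cilium outside the contact window. The nucleus channel adds
filler nuclei along each row plus bridge chains between rows so the
band reads as one connected layer under a 1.5 µm dilation; optional stray
nuclei near the top face stay disconnected and are marked out-of-layer.
Channels are blurred with an anisotropic Gaussian PSF (σ 0.1 µm lateral,
0.3 µm axial), then carry Poisson noise plus Gaussian read noise (σ 1.5)
over a low background (2) at amplitude 500 — the contrast of
deconvolution-processed confocal data, which is the regime in which a
global Otsu threshold is meaningful. Truth records actual polyline arc
lengths, planted distances, contact labels, nucleus ownership, puncta
coordinates/associations, and the noise-free rasters.

**Ratiometric scenes** (0.15 µm isotropic) place ~190 nuclei (radius
1.8 µm) on a jittered xy lattice inset one radius from the faces, with z
positions assigned by Latin-hypercube stratification over the extended
depth — both choices exist to make the structure density uniform in z,
since any density taper would confound the flat-field estimate.
Per-nucleus log-ratios are assigned antithetically in z order (marginal
exactly lognormal around a planted density maximizer, default 1.10, σ =
0.25) and multiplied by per-voxel lognormal jitter (σ = 0.10), so the
voxelwise ratio distribution is exactly lognormal with a closed-form
mode. Spheres compose additively (overlaps stack in both channels
consistently). The marker channel is attenuated by exp(−z/8 µm). Known
limitation: additive noise convolution shifts the measured KDE mode up by
a few percent, more so at lower absolute marker intensity, so percent
changes between conditions of very different brightness are compressed by
roughly 3–6 percentage points relative to the planted change.

**FLIM scenes** draw per-voxel lifetimes from an alpha distribution
(default shape 3, loc 1.2 ns, scale 2 ns, mode ≈ 1.76 ns — between the
quenched and unquenched donor lifetimes) or a two-population 1.3/2.7 ns
mixture; 30% of voxels receive photon counts below 50 and adversarial
lifetimes to exercise the count filter.

**Traces** are built from the constants the measurements target: τ_on =
0.19 s, τ_off = 8.46 s, EC₅₀ 84 nM (plasma-membrane sensor, top 0.80) and
28 nM (cilia-targeted sensor, top 0.40 — the up-to-40% per-cilium
response scale), peak ΔF/F₀ 0.15 for optogenetic and mean 0.08 for
chemogenetic stimulation, with optional additive trace noise and
multiplicative dose-response noise.

None of the generators model realistic optics (Airyscan PSFs, spherical
aberration), chromatic shifts, sample drift, or biological variability in
structure shape beyond what is listed; passing tests demonstrate that the
estimators recover what was planted under these conditions, not that the
pipeline is robust to every failure mode of real microscopy data.

## Problem sizes

The default scenes are sized so the full test suite runs in a few minutes
on a single CPU: contact scenes 64×256×256 voxels, ratiometric scenes
48×192×192, FLIM scenes ~150k voxels (≥ 10⁵ usable), 500 bootstrap
coverage replicates and 2000 permutation null simulations. The
acceptance script (`scripts/acceptance.py`) re-runs all of the above in
roughly half a minute.
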