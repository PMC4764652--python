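# Methods

This note documents the models behind each analysis stage, the synthetic
world the generators state, the numerical choices that were genuinely open,
and what a green test does and does not establish.

## SAXD reduction and fibril strain

**Geometry.** Pixels map to scattering coordinates with the exact
flat-detector relations `q = (4 pi / lambda) sin(arctan(r p / L) / 2)` and
azimuth `chi` measured counter-clockwise from the tensile loading axis,
wrapped to [-180, 180). Wavelength is accepted in Angstrom and converted
internally; all `q` are nm^-1, all `D` nm. Defaults mirror the experiment
this package models: lambda = 0.8857 A, L = 1.034 m. Pixel size and beam
center are required inputs (they are instrument properties, not physics);
the generator default is a 384 x 384 detector with 57 um pixels and a
centered beam. We deliberately did not default to the 172 um pixels of a
large-area hybrid photon counter: at this camera length the third-order
collagen ring then sits at only ~24 px radius, and the pixelated sampling
interacts with the narrowing azimuthal envelope to bias sub-pixel peak-shift
recovery by several percent. At 57 um (ring radius ~72 px) the bias is below
0.1% and purely statistical errors dominate.

**Reduction.** Radial profiles average pixel intensities over a 20-degree
total sector about the loading axis, pooling the mirror sector at +180
(meridional patterns are centrosymmetric), on a uniform q grid; the reported
q of each bin is the mean q of its contributing pixels, which is sub-bin
accurate, and empty bins are flagged and excluded. The third-order peak is
fitted as `A exp(-(q - q0)^2 / 2w^2) + m q + b` with a deterministic,
derivative-free start (argmax for q0, window/10 for w, endpoints for the
background) inside a window of q0 +/- 5 peak widths; fit failure, a
non-positive amplitude or a center escaping the window return
`converged = False`, never an exception. `D = 6 pi / q0`; fibril strain is
the percent increase of D relative to the first converged zero-load frame.
Non-converged frames propagate as missing values rather than being dropped,
so frame indices stay aligned with the mechanical record.

## Azimuthal orientation

The total azimuthal profile is taken in a band q0 +/- 2w; the mineral
background is the pointwise arithmetic mean of two flanking bands of the
same width placed with a half-band guard gap ([q0-5w, q0-3w] and
[q0+3w, q0+5w]). Keeping the flanking bands close limits the bias a curved
(non-linear in q) diffuse background leaves in a two-band average; with the
generator's exponential background the residual is ~1% of the peak. The
collagen profile (difference; negative values retained) is fitted to a
Gaussian **without a baseline term** — an added baseline systematically
narrows the fitted peak, so it exists only behind `with_baseline=True` for
sensitivity analysis. The profile is circularly re-centred on its argmax
before fitting, so peaks near the fold boundary (chi ~ +/-90) are handled
seamlessly. The reorientation result reports both the slope of FWHM percent
change per percent tissue strain (`rate`, the headline quantity) and the raw
slope in degrees (`rate_deg`).

Residual background plus the baseline-free fit leave a known ~1.5% low bias
on recovered FWHM at the default noise level; this is a property of the
method, not a bug, and sits well inside the 2% recovery band the tests
enforce.

## Mechanics

Tissue strain is the percent change of optical-marker separation; stress is
load over the load-bearing area `A (1 - porosity)` — the standard
effective-area porosity correction, chosen because the source experiment
names "porosity-corrected stress" without a formula. The elastic region is
detected with the >10% slope-reduction rule: baseline slope over the first
n0 = 5 frames, running n0-frame windows scanned forward. Because a window
localizes the kink only to its own length and can dip on noise alone, a
trigger is refined by a **global two-segment least-squares breakpoint** and
kept only if the post-breakpoint slope is below 90% of the pre-breakpoint
slope (a sustained drop). For noiseless bilinear data this recovers the kink
frame exactly; a 5% slope change never yields. Yield stress/strain are the
measured values at the detected region end. All moduli and the strain ratio
are free-intercept least-squares slopes over the elastic region (a forced
zero intercept would bias noisy series), restricted to frames with converged
fibril strain for the fibril-level quantities; maximal fibril strain is
taken over the full test. For exactly linear data the identity
`d eps_F / d eps_T = E_T / E_f` holds to machine precision and is tested.

## BMDD

Gray-to-calcium conversion is the affine map through the carbon (0 wt%) and
aluminium anchors; the aluminium-anchor calcium value defaults to 39.86 wt%
(pure hydroxyapatite) because the source text names the reference materials
but not the numeric transfer — it is a single documented config value, as is
the conventional 0.17 wt% histogram bin. Ca_mean is the count-weighted mean
of bin centers. FWHM is the distance between the half-maximum crossings of
the histogram's highest peak, linearly interpolated — no Gaussian assumption,
since real BMDDs are asymmetric. Peak height and crossings are read from a
5-bin boxcar-smoothed copy of the histogram: the raw maximum of a noisy
histogram is biased high, which made the width come out ~5% low; the
smoothing widens a realistic BMDD by well under 1%. Counts and Ca_mean are
always computed from the raw histogram. Single-bin distributions set a
degeneracy flag and report the bin width.

## Morphometry

The mesh-era counting procedure (split a surface mesh into loose parts,
drop components under 1% of total size, separate canals manually) is
re-expressed in the voxel domain: threshold segmentation, 26-connected
components, the 1% rule applied to pore-volume fraction, and canal/cavity
separation by the square root of the leading-to-middle eigenvalue ratio of
the component's voxel covariance (>= 3 means canal). The bone mask is the
largest connected foreground component with interior pores filled; exterior
background is any non-foreground component touching a lateral face, and the
medullary cavity is the component containing the shaft axis (volume center),
falling back to the largest interior component — the center rule matters
because a thick canal can out-volume a narrow medullary canal. Components
touching only the axial faces are kept (canals run the full shaft).
Densities are per mm^3 of cortical tissue volume = bone-mask volume
(pore space included, medullary excluded).

## The synthetic world

Presets state the published group values as ground truth: strain
partitioning 0.57 (WT) / 1.18 (osteoporotic), maximal fibril strain 0.30 /
0.63%, yield stress 28.2 / 16.2 MPa, Ca_mean 30.32 / 28.44 / 27.06 wt% and
BMDD FWHM 3.80 / 4.63 / 6.43 wt% for the WT, periosteal and halo regions,
cortical porosity 2% / 30%, cavity volume fraction 0.025, cohort sizes
n = 4 / 6. Values the source does not print were fixed once at realistic
levels and documented here:

- **Tissue moduli** 7.0 / 3.5 GPa: give yield strains of 0.40 / 0.46%
  (similar between groups, as reported), a ~50% modulus reduction, and
  imply fibril moduli of 12.3 / 3.0 GPa — a ~76% reduction, consistent with
  the reported "~79%".
- **Orientation** FWHM0 30 / 45 degrees; reorientation rates -12 / -6
  percent per percent strain, reproducing order-10% FWHM reductions at ~1%
  strain and the slower reorientation of the osteoporotic group.
- **Noise**: Poisson photon noise with 1e4 expected counts at the ring peak
  plus unit-level additive detector noise; mechanical records use 0.06 N
  load noise (~1% of WT yield load) and 0.2 um marker jitter; qBSE images
  are 16-bit with 200-gray-level noise (~0.15 wt%); CT volumes are 8-bit
  with 8-gray-level noise against a 140-level tissue/void contrast.
- **Microstructure**: lacunar densities 15,000 / 8,000 mm^-3 and canal
  densities 800 / 350 mm^-3 (reduced in the osteoporotic preset, as
  reported; no numbers are printed). Lacunae are ellipsoids with semi-axes
  U(3,6) x U(3,6) x U(4,9) um; canals are full-length z-parallel cylinders
  whose radius is **sized from the porosity budget**
  (porosity x volume - lacunae - cavities), giving ~5 um WT canals and
  ~35 um osteoporotic ones — the latter are outside the typical vascular
  range and are the geometric price of stating 30% porosity with only 0.025
  cavity fraction on the same reference volume; cavities are unions of
  three overlapping spheres strung along z (resorption cavities run along
  the shaft), sized above the 1% classification threshold with elongation
  below the canal cutoff. Placement is rejection sampling in physical
  (micrometre) coordinates with exact per-sphere clearances and a 3.5 um
  margin so 26-connectivity never merges components, capped at 10^4 retries
  per component (deterministic given the seed); the same seed therefore
  yields the same physical microstructure at any voxel size, which the
  scale-invariance test exercises. Cavity placement stops at the target
  minus half a typical blob, making the volume-fraction quantization error
  symmetric (about +/-8%) rather than a systematic overshoot.

**What the generators do not emulate:** detector point-spread, polarization
or absorption corrections; WAXD/mineral-crystallite signals; post-yield
plasticity beyond a single reduced slope; electron-backscatter physics
beyond the affine gray map; osteocyte biology (lacunae are geometric);
canal networks (canals are disjoint straight cylinders); between-animal
biological variability (per-sample scatter comes from measurement noise
only, so cohort standard deviations are smaller than the published ones —
recovery of group *means* is the validated claim, and significance tests on
synthetic cohorts overstate real power). A green recovery test therefore
establishes that the estimators are unbiased at realistic noise, not that
they would be robust to artifacts the generators do not produce.

## Determinism and seeds

Every generator draws from `numpy.random.default_rng(seed)`; identical
(preset, geometry, seed) gives bit-identical arrays and files. Pipeline
stages derive sub-seeds with a crc32-keyed `SeedSequence`, stable across
processes and below 2^31.

## Known limitations

- The orientation analysis assumes a single Gaussian orientation population
  per frame; no pole-figure or multi-component reconstruction.
- The elastic-region rule assumes one monotone slope change; multi-stage
  yielding would be localized at the first sustained drop only.
- Canal/cavity separation by elongation needs the volume to be at least
  ~6 canal radii long; on very short stacks thick canals classify as
  cavities (the acceptance-scale volumes respect this).
- BMDD FWHM carries the +/-1% bias of histogram smoothing and bin width;
  at the conventional 0.17 wt% bin this is negligible against the 3.8-6.4
  wt% widths analyzed here.
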