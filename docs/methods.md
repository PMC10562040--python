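# Methods

This note documents the models behind `spectral_spr`, the choices that were
genuinely open, and what the synthetic study does and does not demonstrate.

## Problem

Proton treatment planning converts CT numbers to proton stopping-power
ratios (SPR); SPR errors translate directly into range errors of 1–3 mm.
Spectral CT offers virtual-monoenergetic (VM) images at many energies, and
a pair of VM images constrains electron density far better than one kVp
image.  The package implements a segmentation-based workflow: determine,
per tissue, the VM energy pair that predicts SPR best on a calibration
phantom; segment a patient-like volume into tissue regions; convert each
region with its own optimal pair; and quantify the dose/range consequences
against the conventional single-energy (SECT) calibration with a
simplified analytic proton dose engine.

## Reference stopping powers (tissue_library)

Reference SPR is the Bethe ratio

SPR = RED · [ln(2 m_e c² β² / (I (1−β²))) − β²] / [ln(2 m_e c² β² / (I_w (1−β²))) − β²]

evaluated at a proton kinetic energy of 100 MeV (mid-range clinical;
moving anywhere in 80–120 MeV changes any library tissue's SPR by <0.2% of
its default value, which the suite asserts).  Tissue I-values come from
Bragg additivity over elemental values; no shell, density-effect or Barkas
terms are included, since they nearly cancel in the ratio.

Two consistency conventions matter:

- **Condensed-phase I adjustment.**  Additivity over gas-phase elemental
  I-values yields water I ≈ 69 eV rather than the accepted 75 eV, which
  would make water's own SPR 1.011.  All elemental I-values are therefore
  scaled by a single factor (≈1.087) so that water additivity reproduces
  I_w = 75 eV exactly and water's SPR is identically 1 — the anchor every
  CT calibration assumes.
- **Fixture self-consistency.**  The vendor's insert compositions and
  electron densities are not publicly deposited.  The bundled library
  (`data/gammex1467_inserts_synthetic.csv`, labelled synthetic) carries
  package-constructed epoxy-style compositions, and the reference relative
  electron density (RED) of each insert is *derived* as the published
  reference SPR divided by the composition's Bethe factor.  The library is
  then exactly self-consistent under the Bethe formula: recomputing SPR
  from composition and RED reproduces the published per-insert values.

One inconsistency cannot be removed: the published LN-300 triple
(reference SPR 0.2800, 120 kVp CT number −702.66, near-zero spectral
residual) is not simultaneously attainable by any single composition under
a Bethe + photoelectric/coherent/Compton model — matching SPR and HU
forces a Bethe factor ≈0.97, which puts the polyline conversion ≈+2.8%
above the Bethe reference for both lung foams (the published table itself
shows +2.09% for LN-450).  The fixture matches the HU anchors exactly and
accepts the lung residual.

## Synthetic VM scanner (vm_forward_model)

Per-electron attenuation is modeled as

σ(Z, E) = A_ph · Z^4.62 · E⁻³ + A_coh · Z^2.86 · E⁻² + σ_KN(E),

weighted by electron fractions and normalized to water (so water is 0 HU
at every energy by construction).  The 120 kVp SECT image is a three-point
spectrum average at 50/70/90 keV.  The committed constants
(A_ph = 0.411345, A_coh = 6×10⁻⁴ ≈ 7% coherent share of the water cross
section at 70 keV, weights 0.3326/0.3827/0.2847) together with two fixture
composition parameters (lung Mg filler 31.92%, blood Ca 1.856%) were
solved once so the simulated SECT numbers of the four anchor inserts match
881.44 / 106.44 / 45.61 / −702.66 HU within ±2 HU; they are not free knobs.

Noise is additive Gaussian per voxel.  One noise field is shared across
all VM energies: every VM image is synthesized from the same spectral
acquisition, so their noise is strongly correlated, and with the 5-keV
pairs' mixing weights |c_e| ≈ 5–10 an independent-noise model would
amplify 10 HU of noise into ~14% voxel SPR noise — an artifact no real VM
stack exhibits.  The SECT volume is a separate acquisition and gets its
own independent field.  What this generator does **not** emulate: beam
hardening, scatter, reconstruction correlations between neighboring
voxels, partial-volume edges, and metal artifacts.  Passing tests
therefore demonstrate algorithmic correctness and model-consistent
parameter recovery, not robustness to real scanner physics.

The default phantom is a four-region thorax (soft body ellipse / lung /
spine / 12 mm-radius tumor at the anterior lung edge) on a 96×96×48 grid
at 2 mm; geometry was chosen so a +45° field crosses the full lung
thickness while a −45° field sees soft tissue only, and both target WEPL
intervals fall inside the dose engine's 70–230 MeV band.

## Energy-pair calibration (spectral_calibration)

RED = c_e(HU₁/1000+1) + (1−c_e)(HU₂/1000+1), with one global c_e per pair
fitted by closed-form least squares over all 14 inserts (per-tissue
residual evaluation, per the workflow's single-fit reading).  RED→SPR uses
the four-branch polyline in SPR/RED with breakpoints 0.9/1.035/1.4/2.0;
the curve is deliberately discontinuous at 0.9 (1 → 1.028) and is *not* 1
at RED = 1 (it evaluates to 1.00726 there).  REDs outside (0, 2] — noisy
voxels — are clamped to the branch ends with a warning rather than
rejected.  The optimal pair per tissue minimizes the absolute percent SPR
residual over all C(15,2)=105 pairs; ties break lexicographically.
Percent deviations are reported rounded half-away-from-zero to 2 decimals.

The SECT baseline is a group-wise (lung/soft/bone) piecewise-linear
least-squares HU→SPR curve joined continuously between group spans, with
flat extrapolation — a documented stand-in for a scanner-specific
stoichiometric calibration, which the source workflow names but does not
specify.

On noiseless model-consistent data the calibration recovers each tissue's
RED to <0.1% for at least one pair (asserted).  On the synthetic library
the surviving SPR residuals are dominated by polyline-vs-Bethe mismatch of
the epoxy-style compositions, not by fitting error; the reported group
RMSEs are therefore the package's own numbers and are not tuned toward any
published set.

## Segmentation and SPR maps (segmentation_spr)

Threshold segmentation assigns HU ∈ (t_k, t_{k+1}] to class k+1; default
cuts are −950 HU (air) plus midpoints of adjacent anchor CT numbers.
Regions are matched to library tissues by closest mean CT number on the
SECT image (the anchors are 120 kVp-style numbers; a 70 keV option
exists), ties toward the lower anchor.  Conversion is voxelwise with the
region's pair and c_e; unlabeled voxels and voxels below −950 HU get air
SPR 0.001.  An optional connected-component minimum-size filter exists and
is off by default.  For a homogeneous region the voxel path reproduces the
tissue-level scalar pipeline bit-for-bit (asserted to 1e-9).

## Analytic dose engine (proton_dose)

- Range–energy: R₀ = 0.0022·E^1.77 cm (76.3 mm at 100 MeV); straggling
  σ = 0.012·R₀^0.935 cm.  Pristine curves are dE/dz of the range–energy
  relation convolved numerically with the straggling Gaussian, peak
  normalized, and truncated to zero beyond R₀+3σ.
- WEPL: voxel-exact Siddon traversal; depth-dose profiles measure depth
  from the grid entry face.
- SOBP: nonnegative least squares flattens the stacked curves over the
  target WEPL interval (±3% typical; a warning reports worse).  The energy
  ladder starts at the range of the *proximal* interval edge — shallower
  peaks would let the fit grow an uncontrolled spike outside the flattened
  region — and runs in 1 MeV steps to the distal edge.
- Beams: parallel (no divergence), gantry rotation in the axial plane via
  linear-interpolation resampling into the beam frame (cumulative-sum WEPL
  along the beam axis), couch fixed at 0°, circular aperture of PTV radius
  + 5 mm with a 5 mm Gaussian lateral penumbra.  Plans are made once (on
  the spectral map by default) and reused unchanged on the second map, so
  dose differences reflect only the SPR maps.
- Dose: summed fields scaled so the PTV-mean RBE-weighted dose equals the
  prescription (60 Gy in 30 fractions), constant RBE 1.1.
- R90: distal depth of first crossing below 90% of the profile maximum,
  linearly interpolated; range tables report difference (spectral − SECT)
  and percent deviation at 2 decimals.

The engine reproduces comparison arithmetic and qualitative range
behavior; absolute published ranges depend on a proprietary beam model and
patient anatomy and are out of reach by design (no spot optimization,
nuclear halo, or Monte Carlo).

## Evaluation (evaluation, pipeline, CLI)

Gamma is global (ΔD as a percentage of the reference maximum), 10%
low-dose cutoff, exhaustive search within 3×DTA — exact at desk scale and
verified against a brute-force oracle.  Relative dose difference is
voxelwise above the cutoff, with extremes reported for the PTV sphere and
for the proximal third of each beam path.  The pipeline
(simulate→calibrate→segment→map→dose→evaluate) is deterministic from one
seed; reports (LUT, residual surface, SECT nodes, RMSE, ranges, γ,
provenance with config hash) are byte-identical across reruns.
`scripts/acceptance.py` re-runs the published-arithmetic checks and the
full synthetic study at the default 96×96×48 / 2 mm problem size (the
whole script completes in well under a minute).

## Known limitations

- The attenuation model is a two-coefficient power-law decomposition; it
  is calibrated to four HU anchors, and other inserts' simulated CT
  numbers are model extrapolations.
- Epoxy-style surrogate compositions make the polyline conversion a
  biased SPR estimator (up to ~1% soft tissue, ~2.8% lung); this mirrors
  the real limitation of plastic surrogates but means the synthetic
  spectral-vs-SECT contrast is driven by that bias, not by scanner noise.
- The SECT baseline is idealized (fitted directly to reference SPRs), so
  it is more accurate here than a real stoichiometric calibration; range
  differences between the two routes are correspondingly conservative.
- Lateral heterogeneity scattering, nuclear buildup and divergence are
  not modeled; entrance-region dose differences are smaller than a full
  pencil-beam engine would show.
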