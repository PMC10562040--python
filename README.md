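# spectral-spr

Per-tissue optimal virtual-monoenergetic (VM) energy pairs for proton
stopping-power-ratio (SPR) prediction from spectral CT, segmentation-based
SPR maps, and an analytic proton dose engine that quantifies the dose and
range consequences against the conventional single-energy-CT (SECT)
calibration.

## Who this is for

Medical physicists and method developers studying CT-to-SPR conversion for
proton therapy.  Proton range scales directly with SPR accuracy: the
classical single-energy stoichiometric calibration carries ±1–2% SPR
uncertainty (1–3 mm of range), while a pair of VM images from a spectral
scan constrains relative electron density (RED) much more tightly.  The
package implements the full segmentation-based workflow at desk scale,
with a synthetic VM scanner standing in for acquisition hardware, so every
step is reproducible from a single seed.

## The model

**Calibration.**  For an energy pair (E₁, E₂) the electron density is

  RED = c_e·(HU₁/1000 + 1) + (1 − c_e)·(HU₂/1000 + 1),

with one scalar weight c_e fitted per pair by closed-form least squares
against the reference REDs of 14 Gammex 1467 tissue surrogates.  RED
converts to SPR through a four-branch polyline in SPR/RED (breakpoints at
RED 0.9, 1.035, 1.4, 2.0).  Reference SPRs come from the Bethe formula

  SPR = RED · [ln(2m_ec²β²/(I(1−β²))) − β²] / [ln(2m_ec²β²/(I_w(1−β²))) − β²]

at 100 MeV with Bragg-additivity I-values (I_w = 75 eV).  For each tissue,
the pair minimizing the absolute percent SPR residual over all
C(15,2) = 105 pairs of the 70–140 keV / 5 keV grid enters a lookup table.

**Conversion.**  A CT volume is threshold-segmented into tissue regions;
each region is matched to the lookup table by closest mean CT number and
converted voxelwise with its own optimal pair, versus the SECT baseline's
single piecewise-linear HU→SPR curve.

**Dose.**  A simplified analytic engine (power-law range–energy
R₀ = 0.0022·E^1.77 cm, Gaussian range straggling, Siddon WEPL ray tracing,
NNLS-weighted spread-out Bragg peaks, parallel beams, RBE 1.1) computes
dose on both SPR maps under identical plans and reports R90 ranges,
relative dose differences and 3D γ pass rates.

## Worked example

```python
from spectral_spr.pipeline import PipelineConfig, run_pipeline

res = run_pipeline(PipelineConfig(seed=1))
print(res.lut.to_frame().head(5).to_string(index=False))
print(res.ranges.to_string(index=False))
for crit, g in res.gamma.items():
    print(f"gamma {crit[0]:.0f}%/{crit[1]:.0f}mm pass rate: {g.pass_rate:.2f}%")
```

prints (seed 1, default 96×96×48 grid at 2 mm, 10 HU noise):

```
          tissue  e1_kev  e2_kev       c_e  residual_pct  mean_hu_anchor
HE Cortical Bone    70.0    75.0 -4.739461     -0.388047     1475.562269
       50% CaCO3   135.0   140.0 -9.620873     -0.094526      881.440003
       30% CaCO3   135.0   140.0 -9.620873     -0.447560      474.682287
   HE Inner Bone    70.0    75.0 -4.739461      0.223809      317.822118
    HE Blood 100   135.0   140.0 -9.620873     -0.919760      108.162496

      beam  range_spectral_mm  range_sect_mm  deviation_pct  difference_mm
gantry_-45         166.975946     164.529194           1.49           2.45
gantry_+45         131.301470     131.129773           0.13           0.17
gamma 2%/2mm pass rate: 97.88%
gamma 1%/1mm pass rate: 96.22%
```

Reading the numbers: each row of the lookup table is one insert's best
energy pair with its fitted mixing weight and the surviving percent SPR
residual (negative = polyline prediction below the Bethe reference); the
`mean_hu_anchor` column is the simulated 120 kVp CT number used to match
segmented regions to inserts (the four anchor tissues reproduce the
printed 881.44 / 106.44 / 45.61 / −702.66 values within ±2 HU).  The range
table compares R90 — the distal depth where the central-axis dose first
falls to 90% of its maximum — between the spectral and SECT SPR maps under
the same plan: here the soft-tissue field shifts by 2.45 mm (1.49%) while
the lung-crossing field agrees within 0.2 mm, and the γ pass rate drops as
the criterion tightens from 2%/2 mm to 1%/1 mm.

The same pipeline is available from the shell:

```
spectral-spr all --seed 1 --outdir out/
```

writes the lookup table, residual surface, SECT calibration nodes,
group-RMSE table, range comparison, γ/dose-difference report and a
provenance JSON (config hash, versions, seed) to `out/`.

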