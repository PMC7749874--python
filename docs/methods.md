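# Methods

This note documents the models behind `oemdose`: what is computed, under
which assumptions, with which defaults, and where the synthetic study
deliberately departs from clinical reality.

## OEM characterization from dose-rate profiles

A volume scan delivers one 360° rotation (nominal `T_1rot` = 500 ms) plus a
start-up overhead (~25 ms of output not used for reconstruction; measured
total output runs ~525 ms). With organ-effective modulation (OEM) on, the
tube output dips over a gantry arc. Three numbers characterize the dip,
all computed from an ON/OFF profile pair on a common time grid (the OFF
profile is linearly resampled onto the ON grid):

* **Modulation window.** The dip support is detected where the ON/OFF
  ratio falls below `1 − threshold` (default 1 %) of the local pre/post-dip
  peak ratio, searched within ±50 ms of each provisional edge — the
  peak-relative rule makes detection robust to the start-up ramp. No
  qualifying sample yields a zero-length window. `θ = 360 · T_drr / T_1rot`.
* **DM_Max** is `100·(1 − min ratio)` inside one rotation; **DM_Total** is
  `100·(1 − ∫ON/∫OFF)` with trapezoid quadrature over exactly one rotation
  starting after the start-up overhead. Quadrature on a sampled grid limits
  round-trip accuracy to ~5·10⁻⁴ % at 0.1 ms spacing (the dip edges are
  discontinuous), which is why round-trip tests assert 10⁻³ %, not machine
  precision.

Windows are only detectable when the dip depth at the arc edge exceeds the
1 % threshold; at low currents (small DM_Max) the angle becomes
unmeasurable, mirroring the practice of excluding ≤ 100 mA profiles from
angle estimation.

## The calibrated OEM model

* **Console current.** The embedded requested→displayed current table is
  interpolated piecewise-linearly and rounded half-up to integer mA
  (half-up reproduces every printed protocol value, e.g. 115 → 106.5 → 107).
  Below the smallest anchor the mapping is the identity; above 500 mA the
  last ratio (0.85) is extrapolated with a runtime warning — behaviour
  there is unmeasured.
* **Modulation rates.** Plateau values 63.5 % / 16.0 % at ≥ 200 mA; zero at
  ≤ 80 mA; between, both plateau values are scaled by the current-reduction
  ratio the console table implies, normalized to its plateau-onset ratio
  (15 % at 200 mA). The measured plateau values override the table's 15 %
  at and above onset: the table drives only the displayed current and the
  ramp shape.
* **Dip shape.** The scanner reveals only the dip's extremum (DM_Max) and
  rotation integral (DM_Total); the shape is closed with a raised-cosine
  taper `w(u) = cos^p(πu/2)` on the arc, the exponent solved by bisection
  (quadrature residual < 10⁻⁸) so the integral constraint holds. Two exact
  checkpoints anchor the solver: a required mean of 2/π gives p = 1, and
  0.5 gives p = 2. The *built* profile additionally raises the taper onto
  a small relative floor at the arc edges (5 % of full depth, exponent
  re-solved so DM_Total is still exact). Rationale: measured dips switch on
  steeply, and a taper that decays to zero depth at the edges would make
  the 1 %-threshold window systematically ~6° narrow — with the floor the
  edge depth (3.2 % of output at plateau) crosses the threshold within one
  sample. The floor is capped at half the required mean so nearly
  rectangular dips stay feasible. Front mode centres the dip at gantry 0°
  (anterior, 12 o'clock), back mode at 180°; the dip is assumed symmetric
  about its centre. Angle convention everywhere: φ = 0° anterior,
  increasing clockwise viewed from the couch foot; patient axes +x left,
  +y posterior, +z cranial.

## Beam model

* **Spectrum.** Kramers-type bremsstrahlung `N(E) ∝ (kV − E)/E` on 0.5 keV
  bins, hardened by aluminum filtration, plus tungsten K fluorescence above
  the 69.5 keV K edge (Kα1 59.32, Kα2 57.98, Kβ1 67.24, Kβ2 67.42 keV; the
  Kβ2 constant follows the source characterization this package reproduces
  — the literature value is ≈ 69.1 keV — and is overridable). The line
  fraction grows as `0.3·(kV/69.5 − 1)^1.5` of pre-filtration fluence. This
  is deliberately semi-empirical: the only verifiable beam property is its
  quality, so the total filtration is *calibrated* by bisection until the
  computed HVL matches the measured one (4.76 mm Al at 80 kV, 6.03 at
  100 kV, tolerance 0.005 mm). All kerma-weighted quantities use
  `Σ w_i E_i (μ_en/ρ)_air`.
* **Effective energy** inverts the aluminum attenuation table (log-log) at
  `ln 2 / HVL`; the embedded tables are standard NIST-compilation values on
  the 10–150 keV grid, giving 41.1 keV and 46.4 keV for the two calibrated
  beams.
* **Bowtie.** A lateral free-in-air kerma profile (measured, or the
  synthetic Gaussian-shaped stand-in falling to 30 % at 180 mm) is inverted
  position-by-position into equivalent aluminum thickness at fan angle
  `atan(x/SID)`, then symmetrized and forced monotone in |angle|.
  Source-to-isocenter distance is not published; default 600 mm,
  configurable, as is the 320 mm field of view.

## Materials and interaction channels

Each material (air, water, ICRU-44 soft tissue, PMMA, cortical bone,
aluminum) carries tabulated total `μ/ρ` (coherent included) and `μ_en/ρ`,
log-log interpolated. Free paths and every attenuation quantity use the
table total, so beam transmission is exact by construction. The *split*
into channels is semi-empirical: incoherent scattering is free-electron
Klein–Nishina times electron density, and the photoelectric/coherent
remainder is apportioned by fitting `A·E⁻³ + B·E⁻²` shapes — this only
decides how often an interaction absorbs locally versus scatters, a
percent-level effect on dose at CT energies. Voxels are classed by density:
< 0.05 air, < 0.95 lung-like (ICRU soft-tissue coefficients — fetal lungs
are fluid-filled), ≤ 1.1 water (the HU→density line is anchored on water,
so a 0 HU voxel must attenuate as water), ≤ 1.25 PMMA-like, above that
bone.

## Monte Carlo transport

Photons are tracked by Woodcock (delta) tracking against an
energy-dependent majorant — expectation-identical to surface-to-surface
voxel marching, with exact total attenuation, and it vectorizes over whole
photon batches in numpy. Physics: photoelectric events absorb locally;
Compton scattering samples the free-electron Klein–Nishina distribution
exactly (1/ε proposal with rejection; electron binding neglected, a
few-percent effect below ~30 keV); coherent events pass straight through by
default (forward delta-scattering, keeping the attenuation exact) or
deflect via a form-factor-free Thomson kernel when `rayleigh=True`.
Electron energy deposits at the interaction site (kerma approximation,
standard for CT energies where electron ranges are sub-voxel); photons
terminate below 5 keV or on leaving the grid. Cross-sections are looked up
on a 0.5 keV grid.

The source rotates uniformly over 360° (start-up output is excluded from
dose scoring); fan and cone angles are uniform over the field of view and
beam width; the bowtie transmission and the OEM relative output `r(φ)`
enter as statistical weights rather than rejection, keeping variance
predictable. Wide-volume scans are independent sequential rotations at
couch offsets; overlap arises purely geometrically.

**Normalization.** Absolute dose anchors to the measured free-in-air kerma
per 100 mAs (11.17 mGy at 80 kV, 19.08/19.11 at 100 kV — always config
inputs, never recomputed). The simulated kerma per source photon is
tallied with a track-length estimator over a 15 mm scoring sphere at the
isocenter, importance-sampled within the sphere's angular window (~0.15 %
SE) and computed with a fixed internal seed: it is a calibration constant,
identical for every scan sharing a spectrum, so it cancels exactly in
mode-to-mode dose ratios. Per-position mAs is requested current × rotation
time; the OEM reduction is carried entirely by the angular weights.

**Uncertainty and comparisons.** Runs are split into batches (default 10)
with independent substreams; organ means and effective doses carry batch
standard errors. `run_study` runs the off/front/back modes on *common
random numbers* (identical photon histories, only source weights differ):
single-mode estimates remain unbiased while mode differences become
paired, which is what makes 3-SE significance of the small posterior-mode
effects attainable at a few hundred thousand photons.

## Phantoms: what the generator emulates, and what it does not

The pregnant-abdomen phantom is a labelled geometric composite, not
anatomy. It encodes exactly the features that drive the directional
dosimetry: an elliptical water-equivalent torso whose Ramanujan perimeter
matches the abdominal circumference (default 95 cm, the study population
mean; aspect ratio 1.3); a 2 cm carbon-fibre-equivalent couch slab
(density 0.24 g/cm³, absorbing ≈ 10 % of an 80 kV beam) behind the
posterior surface; a fetus at 32 gestational weeks with its head (with
skull shell and brain) central and inferior — in the pelvic cavity — and
its thoraco-abdominal ellipsoid pressed against the anterior wall; fetal
organs (lungs, breasts, stomach, colon, gonads, three marrow sites,
remainder) as ellipsoids inside the trunk; maternal liver, kidneys, colon,
uterus (a band surrounding the fetal envelope) and bladder placed away
from the anterior wall. The seed jitters organ centres by millimetres;
generation is bit-for-bit reproducible per seed. PMMA voxels are written
at 190 HU, the value consistent with ρ = 1.19 under the two-point line
(real PMMA images nearer 120 HU; transport uses density, so only the
label, not the dose, would change).

Consequently, passing the directional contracts (front mode spares the
fetus more than back mode; maternal reductions stay small) demonstrates
the *mechanism* on a geometry faithful to the described fetal pose — it
does not reproduce per-patient clinical values, which depend on individual
anatomy, multi-rotation protocols and image-based organ delineation that
the synthetic phantom does not model.

## Dose reporting

`D_T,R` defaults to the full-mask mean (deterministic); a three-ROI
emulation (spheres at the organ's z-tertile centroids) mimics manual
scoring and is reported as a diagnostic alternative. Organs wholly outside
the scanned z-range return an explicit excluded-organ marker, never a
number. Red marrow is a site-weighted average over the labelled marrow
sites; the default skull/spine/pelvis weights (0.27/0.40/0.33) derive from
reference-person marrow-distribution data, are external to any measurement
here, and are fully overridable, with strict or renormalizing handling of
missing sites. Effective dose uses the embedded ICRP 103 tissue weights
(sum exactly 1; `W_R = 1` for photons, mGy ↔ mSv 1:1); tissues without a
labelled organ contribute zero with a coverage warning. ED for a named
individual exceeds the reference-person definition of ED; every report
carries that caveat. Mode comparisons report both absolute (mGy/mSv) and
recomputed percentage reductions, positive = dose saved.

## Problem sizes and numerical defaults

Test and acceptance runs use sizes chosen to exercise every contract at
full statistical strength on a single core: 10⁶ photons for the
primary-transmission oracle, 10⁵ for Klein–Nishina moments, 5·10⁵ per mode
for the cylinder rotation-integral ratio (0.84 ± 3 SE), and 4·10⁵ photons
per mode at 5 mm voxels for the pregnant-phantom study; profile round
trips sample at 0.1 ms. Key tolerances: taper-solver residual 10⁻⁸; HVL
calibration 0.005 mm; window detection threshold 1 %; density cutoff for
dose reporting 0.01 g/cm³ (near-vacuum voxels carry no meaningful dose).

## Known limitations

No electron transport, anode heel effect, off-focal radiation, or helical
trajectories; no detector or reconstruction simulation (noise is evaluated
on supplied ROI statistics); Compton binding and Doppler broadening
neglected; the coherent channel's angular model, when enabled, omits form
factors; the spectrum model is calibrated to beam quality only, not to a
measured spectral shape; and the phantom is schematic, as above. The
136.5° angle outlier a scan ending mid-modulation can produce is a
documented failure mode of random-start volume scans, not something the
model reproduces.
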