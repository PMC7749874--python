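# oemdose

Organ-effective modulation (OEM) characterization and voxel Monte Carlo CT
dosimetry, built for medical physicists evaluating dose-sparing scan
techniques in fetal CT.

OEM is a CT scanning feature that throttles the X-ray tube output over a
fixed gantry arc so that superficial organs on one side of the patient —
here, a fetus pressed against the anterior abdominal wall — receive less
dose. This package implements the complete evaluation chain for that
technique:

1. **Characterization** of OEM from isocenter dose-rate profiles measured
   with the feature off and on:

   - modulation angle  `θ = 360 · T_drr / T_1rot`, where `T_drr` is the
     dose-rate reduction time and `T_1rot` the rotation time;
   - maximum modulation rate  `DM_Max = [1 − DR_ON^min / DR_OFF] · 100` (%);
   - total modulation rate  `DM_Total = [1 − D_ON^tot / D_OFF^tot] · 100` (%),
     integrated over exactly one rotation;
   - noise change  `n = [SD_ON / SD_OFF − 1] · 100` (%) from supplied ROI
     statistics.

2. **A calibrated OEM model**: the console tube-current table
   (e.g. 220 mA → 187 mA with OEM on), the current dependence of the
   modulation rates (plateau 63.5 % / 16.0 % at ≥ 200 mA, zero at ≤ 80 mA),
   and a smooth angular output dip `r(φ)` over a 160° arc whose extremum and
   rotation integral reproduce `DM_Max` and `DM_Total` exactly.

3. **A beam model** calibrated to measured beam quality: a semi-empirical
   bremsstrahlung + tungsten-K-line spectrum whose aluminum filtration is
   solved so the computed half-value layer matches the measured one
   (4.76 mm Al at 80 kV, 6.03 mm Al at 100 kV), plus a virtual bowtie
   filter inverted from a lateral free-in-air kerma profile.

4. **Synthetic voxel phantoms**: the 32-cm PMMA QA cylinder and a
   parametric pregnant-abdomen phantom (elliptical torso sized by
   abdominal circumference, couch slab, fetus with its head central in the
   pelvic cavity and thorax against the anterior wall, labelled fetal and
   maternal organs), with the two-point CT-number conversion
   `ρ = (HU + 1000)/1000`.

5. **Monte Carlo photon transport** (Woodcock tracking, exact Klein–Nishina
   Compton sampling, kerma approximation) of the rotating, bowtie-filtered,
   OEM-modulated source, normalized to the measured free-in-air kerma per
   100 mAs.

6. **Dose reporting**: per-organ mean absorbed dose `D_T,R` (mGy),
   site-weighted red-marrow dose, effective dose
   `ED = Σ_T W_T Σ_R W_R D_T,R` (mSv, ICRP 103 weights, `W_R = 1`), and
   off/front/back mode comparisons with Monte Carlo uncertainties.

## Worked example

Characterize a synthesized plateau-current profile pair:

```python
from oemdose import build_angular_profile, synthesize_profile, analyze_pair

prof = build_angular_profile("front", 300)          # 300 mA: plateau modulation
on  = synthesize_profile(500.0, 10.0, prof, dt_ms=0.1)
off = synthesize_profile(500.0, 10.0, None, dt_ms=0.1)
metrics, window = analyze_pair(on, off)
print(f"T_drr  = {window.t_drr_ms:.1f} ms")
print(f"theta  = {metrics.theta_deg:.1f} deg")
print(f"DM_Max = {metrics.dm_max_pct:.1f} %")
print(f"DM_Total = {metrics.dm_total_pct:.1f} %")
```

```
T_drr  = 222.2 ms
theta  = 160.0 deg
DM_Max = 63.5 %
DM_Total = 16.0 %
```

A 222.2 ms dose-rate reduction in a 500 ms rotation is a 160° gantry arc;
at its deepest the tube output drops by 63.5 %, and integrated over the
rotation the scan delivers 16 % less output than with OEM off.

Run a full study on the synthetic pregnant phantom (80 kV, 220 mA, one
160-mm volume rotation):

```python
from oemdose.pipeline import (RunConfig, PhantomConfig, ProtocolConfig,
                              MCConfig, run_study)

cfg = RunConfig(
    phantom=PhantomConfig(abdominal_circumference_cm=95, voxel_size_mm=5.0, seed=3),
    protocol=ProtocolConfig(tube_voltage_kV=80.0, currents_mA=(220.0,),
                            airkerma_mGy_per_100mAs=11.17),
    mc=MCConfig(n_photons=400_000, seed=801, batches=8),
)
bundle = run_study(cfg)
for mode in ("off", "front", "back"):
    r = bundle.fetal_reports[mode]
    print(f"fetal ED {mode:>5}: {r.effective_dose_mSv:.2f} "
          f"+/- {r.effective_dose_se_mSv:.2f} mSv")
```

```
fetal ED   off: 4.05 +/- 0.09 mSv
fetal ED front: 2.58 +/- 0.06 mSv
fetal ED  back: 3.89 +/- 0.09 mSv
```

Anterior (front) modulation spares the anteriorly positioned fetus far more
(1.46 mSv, 36 %) than posterior modulation does (0.15 mSv, 4 %), while the
maternal abdominal organs — deeper and surrounding the isocenter — see only
small reductions. The uncertainties are per-batch Monte Carlo standard
errors; all three modes share photon histories, so mode differences are
resolved much more precisely than the individual values.

The same chain is scriptable from the shell:

```bash
oemdose beam-calibrate --kv 80 --hvl 4.76
oemdose phantom --kind pregnant --out scratch/case1
oemdose simulate --config study.yaml
```

Note on ED: effective dose is defined for a reference person; evaluating it
per individual (one fetus, one patient) goes beyond that definition, and
every report carries this caveat.

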