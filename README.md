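# vegtherm

Vegetation cover pulls land surface temperature (LST) in two directions at
once: it cools by dissipating absorbed energy through latent and sensible
heat, and it warms by darkening the surface (lower albedo, more absorbed
shortwave). `vegtherm` implements an observation-style attribution pipeline
that isolates the *net* effect from satellite-like gridded data, aimed at
land-surface and remote-sensing scientists who want to study — or stress-test
— this biophysical feedback without multi-terabyte satellite archives. A
synthetic scene generator with planted ground truth makes every stage of the
pipeline verifiable end to end.

## The method

The core temperature statistic is the **diurnal warming rate** d(LST)/dt:
the daily median of finite-difference rates between time-adjacent valid
15-min LST samples in the 07:00–11:00 local-solar window (K/h). It
integrates the near-linear rising limb of the diurnal cycle, tolerates
cloud gaps, and tracks the diurnal temperature range DTR =
LST(13:30) − LST(06:00).

Three assessments build on it:

1. **Space-for-time conditioning.** Pixels with near-identical long-term
   soil moisture (±0.0025 m³/m³) and shortwave radiation (±1.25 W/m²) are
   binned; within each bin

   E[dLST/dt] = β₀ + β_FVC·E[FVC] + ε

   estimates the effect of fraction of vegetation cover. A significant
   (p < 0.05) negative β_FVC is a cooling effect, positive is warming,
   insignificant is neutral; effects are reported per 0.1 FVC. A seasonal
   variant adds seasonal-mean θ and R_S as controls, and interannual
   DTR-on-FVC regressions test whether the spatial relations hold in time.

2. **Mechanisms.** Energy-dissipation efficiency β_Eff is the negated slope
   of d(LST)/dt versus concurrent LST, made unitless by the force-restore
   factor 32.5; albedo sensitivity β_α,FVC is the within-bin slope of mean
   albedo on FVC. Dryland (<500 mm/yr) vs humid contrasts carry percentile
   bootstrap 95% CIs.

3. **Tropical ΔLST accounting.** Per pixel, 19-year annual LST is regressed
   on NDVI with precipitation and radiation controls (significant linear
   trends removed from LST and NDVI first). ΔLST = β_NDVI × 0.01 × mean NDVI
   is the LST change a 1% relative greening would cause, and

   reduction = 100 · (mean ΔLST|humid − mean ΔLST|all) / (mean ΔLST|humid)

   quantifies how much drylands reduce the domain-wide mean cooling.

## Worked example

```bash
python examples/04_mechanisms.py
```

```
k = 0.05/h -> beta_eff = 1.6250 (32.5 k = 1.6250)
k = 0.10/h -> beta_eff = 3.2498 (32.5 k = 3.2500)
k = 0.20/h -> beta_eff = 6.4986 (32.5 k = 6.5000)

albedo sensitivity per 0.1 FVC: dryland -0.0253, humid -0.0124
dryland/humid ratio: 2.04 (95% CI 1.95-2.15, significant vs 1: True)
implied absorbed-shortwave increase for a 0.1 FVC dryland greening at R_S = 400 W/m2: 10.1 W/m2
```

The first block fits the dissipation regression on noise-free
exponential-relaxation LST series: the recovered unitless efficiency equals
32.5·k up to the (tiny) finite-difference tanh correction, confirming both
the estimator and its normalization. The second block recovers the planted
dryland/humid albedo-sensitivity contrast: dryland greening darkens the
surface about twice as fast (−0.025 vs −0.012 albedo per 0.1 FVC), which at
R_S = 400 W/m² adds roughly 10 W/m² of absorbed shortwave.

The other examples walk the remaining stages: scene generation (`01`),
warming-rate statistics (`02`), effect classification along the rainfall
gradient (`03`), and the tropical ΔLST / dryland-reduction accounting
(`05`). Each prints the numbers it computes and a line on what they mean.

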