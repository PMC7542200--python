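# myotorque

Subject-specific muscle torque models from diffusion-tensor-derived
muscle architecture, validated against (simulated) isokinetic
dynamometry.

## The problem

Musculoskeletal models predict joint torques by summing the moments of
Hill-type musculotendon actuators, each parameterised by four
force-generating properties: maximum isometric force `Fmax`, optimal
fibre length `Lf`, pennation angle `θ` and tendon slack length `Lts`.
In practice these properties are usually taken from *generic* anatomical
datasets — often elderly cadaveric material — rather than measured in the
individual being modelled. Diffusion tensor imaging (DTI) of skeletal
muscle makes in-vivo, subject-specific architecture measurable: fibre
tractography yields fascicle lengths and pennation angles, and volumetric
segmentation yields muscle volumes. The question this package addresses
at desk scale is: **how much accuracy does subject-specific architecture
buy over generic (elderly or young, raw or operating-range-optimised)
architecture when predicting maximal isokinetic joint torques?**

Because real MR and dynamometer data are not consumed here, every input
is generated synthetically with known ground truth, which turns the
question into a set of testable closure and ordering properties.

## The model

The pipeline mirrors a subject-specific modelling workflow:

1. **Tractography** (`dti_tractography`): deterministic streamline
   tracking over tensor volumes (1 mm steps, stop when FA ≤ 0.5, turn
   angle > 30°, or the tract exceeds the muscle belly length), followed
   by anatomically constrained clipping at the muscle boundary. Outputs
   fascicle length `Lf′`, pennation `θ` and volume `Vm`.
2. **Architecture** (`architecture`): optimal fibre length
   `Lf = Lf′ · 2.7 µm / Ls` (sarcomere normalisation), physiological
   cross-sectional area `PCSA = Vm · cos θ / Lf`, maximum force
   `Fmax = PCSA · σ` with specific tension `σ = 0.3 N/mm²`, tendon slack
   length from a bounded 1-D optimisation placing the normalised fibre
   length at 1.0 at the mid operating range, and generic-model machinery:
   mass scaling `Fmax,scaled = Fmax,generic · (M_subject/M_generic)^(2/3)`
   and operating-range optimisation of generic `Lf`/`Lts`.
3. **Limb model** (`limb_model`): a planar sagittal lower limb (pelvis,
   thigh, shank, foot; hip/knee/ankle hinges) with 12 musculotendon
   actuators across 6 functional groups, via-point and wrap-cylinder
   paths, tendon-excursion moment arms `r = −dL/dq`, and rigid-tendon
   Hill force `F = Fmax (a·fl(l̃)·fv(ṽ) + fp(l̃)) cos θ(l̃)`.
4. **Isokinetic simulation** (`isokinetic_sim`): at each sampled posture
   of a torque trace, static optimization resolves muscle redundancy by
   minimising `Σ a²` subject to matching the measured torque with
   activations in [0, 1] and no reserve actuators — an exactly solvable
   diagonal quadratic program. Agreement is scored as
   `RMSE = sqrt(mean((Te − Tp)²))`, reported in Nm, as % of peak `Te`,
   and per kg body mass.
5. **Cohort statistics** (`cohort_stats`): the five-variant experiment
   (SS subject-specific; GE/GY generic elderly/young; GE_O/GY_O their
   operating-range-optimised versions, all sharing the subject's own limb
   geometry) with one-way ANOVA + Tukey HSD on RMSE by variant, linear
   regression of RMSE on maximal isometric torque, and Spearman rank
   correlation of predicted vs measured maximal torques.
6. **Synthetic data** (`synth_cohort`): tensor-volume muscle phantoms
   with analytic fibre fields, virtual cohorts drawn around generic
   architecture templates, and emulated maximal isokinetic dynamometer
   traces (the joint sweeps its range at constant velocity; torque is the
   limb's maximal agonist capacity plus multiplicative noise).

## Worked example

```python
from myotorque.cohort_stats import ExperimentConfig, run_experiment, summarize_report

result = run_experiment(ExperimentConfig())   # 10 subjects, seed 42
print(summarize_report(result))
```

prints (excerpt):

```
RMSE (% of max Te), mean +/- SE per model variant

ankle_plantarflexion
  GE     51.45 +/-  6.25
  GE_O   27.31 +/-  2.08
  GY     15.69 +/-  4.21
  GY_O    4.05 +/-  1.30
  SS      1.78 +/-  0.13
  ANOVA F(4,45) = 32.74, p = 8.42e-13
...
  GE    knee_extension  rho = 0.636
  GY    knee_extension  rho = 0.382
  SS    knee_extension  rho = 0.952
```

Reading: subject-specific (SS) models reproduce the measured torque
traces to within a couple of percent (limited only by the 3% simulated
dynamometer noise), while models built from elderly generic architecture
(GE) err by 24–51% of peak torque depending on the movement;
operating-range optimisation (GE_O) recovers part of that error, young
generic data (GY/GY_O) most of it. The variant effect is highly
significant at every movement, and the SS models also rank subjects by
strength far better than any generic variant (Spearman ρ ≈ 0.9–0.95 vs
≤ 0.75) — the qualitative pattern expected when generic donor anatomy
differs systematically from the modelled cohort.

The same pipeline is scriptable from the shell:

```bash
myotorque synth cohort --n 10 --population young --seed 42 --out work/
myotorque synth phantom --shape unipennate --pennation 20 --out work/vol.nii.gz
myotorque track --tensors work/vol.nii.gz --mask work/vol_mask.nii.gz --out work/tracts/
myotorque experiment --seed 42 --out work/results/
```

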