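# Methods

This note documents the models, parameter choices and limitations behind
`myotorque`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is asserted that the code
does not itself measure.

## Muscle phantoms and tractography

A phantom muscle is a slab of parallel fibres rendered as a voxel grid of
prolate diffusion tensors. The slab is bounded by two planes
perpendicular to the **fibre** direction separated by the true fascicle
length, with lateral faces parallel to the fibres; this makes every
interior fibre chord exactly `fibre_length_true` long, so mean tract
length, pennation (angle between tract chord and the line of action) and
voxel-counted volume all have exact analytic targets. A
line-of-action-aligned box would clip obliquely running fibres at its
ends and bias the mean tract length downward. Bipennate phantoms are two
such slabs mirrored about the septum plane containing the line of
action; fibres meeting the septum are clipped there, so only fusiform
and unipennate phantoms are used for quantitative recovery checks.
Recovery phantoms deliberately use a line of action tilted off the grid
axes so that no slab face is grid-aligned: voxel-centre counting of a
tilted face is unbiased, whereas an axis-aligned face can be mis-placed
by up to half a voxel coherently across the whole face.

Tensor eigenvalues are chosen prolate (`λ2 = λ3`) with the requested
fractional anisotropy by solving `FA = (1 − r)/sqrt(1 + 2r²)` for the
eigenvalue ratio `r`; the principal diffusivity is 1.7·10⁻³ mm²/s
(FA is scale-free, so this only sets a realistic magnitude).

Tracking is fixed-step Euler integration of the principal eigenvector
field with nearest-neighbour tensor lookup, bidirectional from each
seed, sign-aligning each step with the previous direction. Defaults:
1 mm step, stop when FA ≤ 0.5 or the inter-segment angle exceeds 30°,
with the per-muscle maximum tract length set from the belly length (a
fascicle cannot exceed the muscle belly) shared across both tracking
directions. Seeds are drawn by uniform rejection sampling inside the
mask from an explicit RNG seed, so tracking is bit-reproducible. The
anatomically constrained post-pass keeps, per tract, the contiguous
in-mask run containing the seed and discards tracts shorter than
`min_tract_length` (default 5 steps, suppressing boundary fragments).

Known bias: because a step is only taken when its endpoint's voxel still
passes the FA criterion, tracts systematically stop up to one step plus
one voxel short of each boundary. On 50 mm phantoms at 1 mm voxels the
mean recovered fascicle length runs ≈ 4% short; pennation and volume are
recovered to numerical precision. This one-voxel-scale bias is inherent
to discrete stopping criteria and is documented rather than corrected.

## Architecture

Raw fascicle length is normalised to optimal fibre length via the
sarcomere ratio `Lf = Lf′ · 2.7/Ls` (`Ls` in µm); PCSA is
`Vm cos θ / Lf`; maximum isometric force is PCSA times a specific
tension of 0.3 N/mm². Every stored `MTUArchitecture` enforces both
identities to 1e-9 relative, so inconsistent tables fail fast. Muscles
with broad origins are flagged with `n_actuators` (3 for gluteus
maximus, 2 for adductor magnus) and their force is divided equally
across actuators; since the desk-scale limb gives the sub-actuators
identical paths, the equal split is torque-equivalent to a single
actuator carrying the full force, and the model stores it that way.

Tendon slack length is estimated by bounded scalar minimisation: choose
`Lts` so the rigid-tendon normalised fibre length equals 1.0 at the
mid operating range, with a quadratic penalty on excursions outside
[0.5, 1.5] across the range. For a constant-moment-arm joint this
reduces to the closed form `Lts = L_mid − Lf cos θ`, which the tests
verify against an exhaustive 0.01 mm grid.

Generic-variant machinery: generic maximum forces are scaled to a
subject by `(M_subject/M_generic)^(2/3)` with reference masses 75.3 kg
(elderly-derived reference model) and 71.9 kg (young dataset mean); the
unoptimised GE/GY variants keep the table's forces unscaled (a config
flag can scale them too). Operating-range optimisation maps a generic
muscle's `(Lf, Lts)` onto a target geometry by least-squares matching of
the normalised fibre-length trajectory over sampled poses at matched
relative joint angles; a uniform scaling of the length range has the
exact similarity solution `(s·Lf, s·Lts)`, which the tests check. When a
scaled force is imposed on an optimised variant, the stored volume is
recomputed as the volume implied by the new force and fibre length so
the PCSA identity keeps holding; it is an effective volume.

## Limb model

The limb is a planar sagittal chain — pelvis (root), thigh, shank, foot —
with hinge joints at hip, knee and ankle, one degree of freedom each,
extension-positive angles (plantarflexion plays the role of extension at
the ankle). Purely sagittal single-DOF trials make a 3-D joint model
unnecessary. Segment masses come from volume × density (1062 kg/m³ limb
segments, 1013 kg/m³ pelvis); inertia uses a volume-matched cylinder
stand-in and is not used by the static analyses.

Twelve MTUs cover six functional groups (plantarflexors soleus +
gastrocnemius, dorsiflexors tibialis anterior + extensor digitorum,
knee extensors vasti + rectus femoris, knee flexors hamstrings +
gastrocnemius, hip extensors gluteus maximus + adductor magnus +
hamstrings, hip flexors iliopsoas + rectus femoris), standing in for a
full ~92-actuator lower limb at desk scale. Paths are polylines of
segment-fixed points; an optional per-joint wrap cylinder (axis = hinge
axis) replaces a straight segment by the tangent–arc–tangent geodesic
when the straight line would cut the cylinder — when both tangents are
engaged the moment arm equals the cylinder radius, which the tests use
as a closed-form oracle. Moment arms are tendon-excursion derivatives
`r = −dL/dq` by central differences (0.01° step); the work–excursion
identity `∫ r dq = −ΔL` holds over every muscle × joint ROM to well
under 0.5%.

Hill curves (dimensionless, all configurable): active force–length is a
Gaussian of width 0.45 in normalised length; passive force is
`((l̃ − 1)/0.7)⁴` above optimal length (unit normalised force at
l̃ = 1.7, matching the standard reference-model default); force–velocity
is a Hill hyperbola with shape parameter 0.25, zero force at the maximum
shortening velocity of 10 optimal lengths/s, and an eccentric branch
rising to a 1.5 plateau. The tendon is rigid (standard for static
optimization): fibre length follows constant-thickness pennation
geometry `w = Lf sin θ₀`, and fibre velocity is the along-fibre
component of the MTU rate.

## Isokinetic simulation

The measured torque is imposed directly as a net-joint-torque equality
constraint rather than as an equivalent external force at a limb site
(the two are mechanically identical for a single-hinge trial, and the
site lever arms are a dynamometer-rig detail the synthetic protocol does
not model). At fixed posture and joint rate, tendon force is affine in
activation, so minimising `Σ a²` under the torque equality and box
constraints is a diagonal QP solved exactly: the KKT solution is
`aᵢ = clip(λ gᵢ, 0, 1)` over the demand-sign gains, with `λ` found by
sorting saturation breakpoints. No iterative solver, no tolerance
tuning; torque residual tolerance 1e-8. When demand exceeds capacity,
every positive-gain actuator saturates at 1, the step is flagged
infeasible, and the reconstructed torque equals the capacity — the
"model cannot produce enough force" outcome. Antagonists contribute only
passive force (their activations are optimally zero under this
objective). Gravity is ignored: the emulated traces are maximal capacity
curves and the comparison is capacity vs demand. Traces are simulated at
their own samples with no resampling or filtering.

RMSE is reported three ways: absolute (Nm), % of the peak measured
torque, and normalised by body mass (Nm/kg).

## Synthetic cohort: what it emulates and what it does not

Virtual subjects are drawn around a generic architecture template with
independent multiplicative lognormal factors (unit mean) on muscle
volume, optimal fibre length and pennation — positive-valued anatomy
with between-subject coefficients of variation of 10%, 7% and 15% by
default, magnitudes chosen to match typical reported between-subject
variability. Body mass is normal around the template's donor mass (SD
9 kg); limb geometry scales isotropically with the cube root of the mass
ratio against a 75.3 kg reference. Dynamometer noise is multiplicative
Gaussian with 3% SD (no published measurement-error model to copy; 3% is
a realistic repeatability figure for maximal isokinetic efforts). An
emulated trace sweeps the joint's range at constant angular velocity
(default 60°/s, exposed as a parameter since the study protocol's
velocities are not fixed by the synthetic setting) and records the
maximal agonist capacity at each posture — maximal-effort trials compare
capacity to demand, so gravity-free, antagonist-coactivation-free
capacity curves are the appropriate idealisation.

The packaged generic tables are **synthetic stand-ins** (flagged in the
CSV filenames): 12 representative muscles whose elderly-vs-young
contrasts follow the expected pattern — the elderly table has smaller
volumes and maximum forces, shorter fibres (most strongly distally) and
smaller pennation. Elderly donor mass is 82.7 kg, young 71.9 kg. Tendon
slack lengths for generic tables are not shipped: they are derived at
runtime on the reference geometry scaled to the **donor** body mass,
where the generic fibre lengths are internally consistent. Applying
those slack lengths to a smaller subject's geometry puts the generic
fibres off-optimal — precisely the mechanism by which unoptimised
generic architecture degrades, and what the operating-range-optimised
variants repair.

What passing tests therefore show: the pipeline is internally consistent
(zero-noise closure to machine precision), its solver and geometry
engines match independent oracles, and the expected qualitative ordering
of model variants emerges from the stated donor/subject mismatches.
What they do not show: anything about real MR artefacts (registration,
denoising, partial-volume effects), real muscle path complexity
(3-D wrapping, broad attachments), antagonist co-activation, or the
actual magnitudes of human subject-specific vs generic errors — the
synthetic cohort's SS model is exactly right by construction, whereas a
real SS model carries measurement error.

In the cohort experiment the SS variant uses the subject's true
architecture directly; the DTI measurement chain is validated separately
on phantoms rather than run per virtual subject, so SS accuracy is
bounded by torque noise alone.

## Statistics

ANOVA is the classical between/within decomposition with subjects as
independent observations per variant; Tukey HSD adjusted p values come
from the studentized-range distribution (and can be skipped in
simulation loops that only need the omnibus F). Regression is ordinary
least squares with adjusted `R² = 1 − (1 − R²)(n − 1)/(n − 2)` and a
two-sided slope test. Spearman's ρ uses average ranks for ties, with an
exact permutation p for n ≤ 8 and the t approximation otherwise; a
constant input yields ρ = NaN with p = 1 rather than an error, which a
zero-noise cohort makes reachable. Both omnibus tests hold their nominal
5% size within ±2% over 1000 seeded null replicates.

## Numerical choices and degenerate inputs

- Degrees at every interface, radians internally; mm and N internally,
  Nm for torques (moment arms converted mm → m at the torque step).
- Angle-keyed caching of segment transforms makes repeated
  moment-arm/length queries at shared postures cheap; the cache is
  cleared beyond 4096 entries.
- Zero tensors have FA 0 by convention; slightly negative eigenvalues
  are clamped with a warning.
- The rigid-tendon fibre projection is floored at 1 µm so forces stay
  defined for pathologically short MTUs.
- An empty constrained tract set warns rather than raises; summarising
  zero tracts raises.
- Problem sizes: cohorts of 10 subjects, 40-sample traces, 500 seeds per
  phantom in tests and the acceptance script; tract counts and cohort
  sizes are parameters, and the defaults keep a full experiment in the
  tens of seconds on one CPU.

## Known limitations

- Planar geometry with single-cylinder wraps; no 3-D wrapping surfaces,
  no broad attachments, no ISB axis construction from landmarks.
- Rigid tendon only in the default analyses (a compliant-tendon
  equilibrium solve is out of scope here).
- Constant pennation within the architecture stage; length-dependent
  pennation lives only in the limb model's constant-thickness geometry.
- The one-voxel tract-termination bias described above.
- Generic tables are constructed stand-ins, not published datasets;
  absolute RMSE magnitudes depend on the chosen contrasts and should be
  read as qualitative orderings, not as reproductions of human values.
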