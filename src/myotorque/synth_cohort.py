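"""Synthetic inputs with known ground truth for the whole pipeline.

Three generators:

* **Muscle phantoms** — parametric muscles rendered as diffusion-tensor
  volumes with an analytic fibre field (fusiform, unipennate or bipennate),
  so tractography can be validated against exact fibre length, pennation
  and volume.  Pennate phantoms are fibre-aligned slabs (a box bounded by
  planes perpendicular to the fibre direction), which makes every interior
  fibre chord exactly ``fibre_length_true`` long.
* **Virtual cohorts** — subjects drawn around a generic architecture
  template with multiplicative lognormal between-subject variation on
  volume, fibre length and pennation, and normal variation in body mass.
* **Dynamometer traces** — emulated maximal isokinetic repetitions: the
  joint sweeps its range at constant angular velocity and the recorded
  torque is the limb's maximal agonist capacity (full activation,
  force-length-velocity applied, antagonists passive) times multiplicative
  measurement noise.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .architecture import MTUArchitecture, estimate_tendon_slack
from .dti_tractography import TensorVolume
from .isokinetic_sim import TorqueTrace
from .limb_model import (
    DEFAULT_JOINT_ROM,
    LimbModel,
    MOVEMENTS,
    build_default_geometry,
    build_limb,
    movement_sign,
)

__all__ = [
    "MuscleSpec",
    "VirtualSubject",
    "CohortConfig",
    "GenericDataset",
    "make_tensor_volume",
    "sample_cohort",
    "generate_dynamometer_trace",
    "load_generic_dataset",
    "generic_slack_and_ranges",
    "DONOR_MASS",
    "SCALING_REFERENCE_MASS",
    "build_true_limb",
    "cohort_to_csv",
]

#: typical principal diffusivity of muscle tissue, mm^2/s (FA is scale-free)
_LAMBDA1 = 1.7e-3


@dataclass
class MuscleSpec:
    """Parametric phantom definition with exact architecture ground truth."""

    name: str
    shape: str                      # fusiform | unipennate | bipennate
    belly_length: float             # mm
    volume_true: float              # mm^3
    fibre_length_true: float        # mm
    pennation_true: float           # degrees
    line_of_action: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    fa_inside: float = 0.7
    fa_outside: float = 0.1

    def __post_init__(self) -> None:
        if self.shape not in ("fusiform", "unipennate", "bipennate"):
            raise ValueError(f"unknown muscle shape {self.shape!r}")
        if self.fibre_length_true > self.belly_length:
            raise ValueError("muscle fascicle length cannot exceed muscle length")
        if not 0 <= self.pennation_true <= 45:
            raise ValueError("pennation must lie in [0, 45] degrees")
        if self.shape == "fusiform" and self.pennation_true != 0:
            raise ValueError("fusiform muscles have zero pennation")
        if not (0 < self.fa_inside <= 1 and 0 <= self.fa_outside < 1):
            raise ValueError("FA values out of range")
        if self.fa_inside <= self.fa_outside:
            raise ValueError("fa_inside must exceed fa_outside")
        self.line_of_action = np.asarray(self.line_of_action, dtype=float)
        self.line_of_action = self.line_of_action / np.linalg.norm(self.line_of_action)


def _fa_eigenvalues(fa: float) -> tuple[float, float]:
    """(lambda1, lambda23) of a prolate tensor with the requested FA."""
    if fa == 0:
        return _LAMBDA1, _LAMBDA1
    den = 1.0 - 2.0 * fa * fa
    if abs(den) < 1e-12:
        r = 0.25
    else:
        r = (1.0 - fa * np.sqrt(3.0 - 2.0 * fa * fa)) / den
    return _LAMBDA1, float(r) * _LAMBDA1


def _prolate_tensor(direction: np.ndarray, fa: float) -> np.ndarray:
    l1, l2 = _fa_eigenvalues(fa)
    d = direction / np.linalg.norm(direction)
    return l2 * np.eye(3) + (l1 - l2) * np.outer(d, d)


def _orthonormal_frame(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(w @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(w, helper)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return u, v


def analytic_fibre_direction(spec: MuscleSpec, point_local: np.ndarray | None = None,
                             compartment: int = 0) -> np.ndarray:
    """The phantom's exact fibre direction (unit vector)."""
    w = spec.line_of_action
    u, _ = _orthonormal_frame(w)
    th = np.radians(spec.pennation_true)
    if spec.shape == "fusiform":
        return w
    s = 1.0 if compartment >= 0 else -1.0
    return np.cos(th) * w + s * np.sin(th) * u


def make_tensor_volume(spec: MuscleSpec, voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
                       rng_seed: int = 0,
                       volume_shape: tuple[int, int, int] | None = None
                       ) -> tuple[TensorVolume, np.ndarray]:
    """Render a muscle phantom as a tensor volume plus binary mask.

    Inside the mask the tensor's principal eigenvector equals the analytic
    fibre field and the fractional anisotropy equals ``fa_inside``;
    outside, FA equals ``fa_outside``.  The grid is auto-sized to the
    muscle with at least one voxel of background margin unless
    ``volume_shape`` is given.
    """
    if any(v <= 0 for v in voxel_size):
        raise ValueError("voxel sizes must be positive")
    rng = np.random.default_rng(rng_seed)  # reserved for optional jitter; keeps API seeded
    del rng

    lf = spec.fibre_length_true
    half_w = 0.5 * np.sqrt(spec.volume_true / lf)
    # fibre-aligned frames: lateral faces parallel to the fibres so every
    # interior chord spans the full fibre length
    frames = []
    if spec.shape == "bipennate":
        for comp in (+1, -1):
            f = analytic_fibre_direction(spec, compartment=comp)
            e1, e2 = _orthonormal_frame(f)
            frames.append((f, e1, e2))
    else:
        f = analytic_fibre_direction(spec, compartment=+1)
        e1, e2 = _orthonormal_frame(f)
        frames.append((f, e1, e2))

    # bounding box of the slab(s) in world coordinates
    corners = []
    for f, e1, e2 in frames:
        for a in (0.0, lf):
            for b in (-half_w, half_w):
                for c in (-half_w, half_w):
                    corners.append(a * f + b * e1 + c * e2)
    corners = np.asarray(corners)
    vox = np.asarray(voxel_size)
    margin = 2.0 * vox
    lo = corners.min(axis=0) - margin
    hi = corners.max(axis=0) + margin
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / vox[i])) for i in range(3))
    if volume_shape is not None:
        if any(volume_shape[i] < shape[i] for i in range(3)):
            raise ValueError("muscle does not fit inside the requested volume")
        shape = tuple(volume_shape)
    origin = tuple(lo)

    # voxel-centre coordinates relative to the muscle origin
    axes = [lo[i] + (np.arange(shape[i]) + 0.5) * vox[i] for i in range(3)]
    xg, yg, zg = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([xg, yg, zg], axis=-1)

    grid = np.empty(shape + (3, 3))
    grid[...] = _prolate_tensor(spec.line_of_action, spec.fa_outside)

    def slab_mask(f, e1, e2):
        cf = pts @ f
        return ((cf >= 0) & (cf <= lf)
                & (np.abs(pts @ e1) <= half_w) & (np.abs(pts @ e2) <= half_w))

    if spec.shape == "bipennate":
        # two compartments mirrored about the central septum (the plane
        # containing the line of action); each is a fibre-aligned slab
        u_mirror, _ = _orthonormal_frame(spec.line_of_action)
        side = pts @ u_mirror
        pos = slab_mask(*frames[0]) & (side >= 0)
        neg = slab_mask(*frames[1]) & (side < 0)
        mask = pos | neg
        grid[pos] = _prolate_tensor(frames[0][0], spec.fa_inside)
        grid[neg] = _prolate_tensor(frames[1][0], spec.fa_inside)
    else:
        f = frames[0][0]
        mask = slab_mask(*frames[0])
        grid[mask] = _prolate_tensor(f, spec.fa_inside)

    vol = TensorVolume(grid=grid, spacing=tuple(vox), origin=origin)
    return vol, mask


# --- generic datasets -------------------------------------------------------

@dataclass
class GenericDataset:
    """A generic architecture table (elderly or young donors)."""

    source_label: str               # "GE" or "GY"
    source_body_mass: float         # kg, mean donor body mass
    table: dict[str, MTUArchitecture]

    def __post_init__(self) -> None:
        if self.source_label not in ("GE", "GY"):
            raise ValueError("source_label must be GE or GY")
        if self.source_body_mass <= 0:
            raise ValueError("source body mass must be positive")


#: mean donor body masses (kg): elderly cadaveric set and young in-vivo set
DONOR_MASS = {"GE": 82.7, "GY": 71.9}
#: reference-model masses (kg) used by the 2/3-power Fmax scaling
SCALING_REFERENCE_MASS = {"GE": 75.3, "GY": 71.9}

_DATA_FILES = {"GE": "generic_elderly_synthetic.csv", "GY": "generic_young_synthetic.csv"}


def load_generic_dataset(label: str) -> GenericDataset:
    """Load a packaged generic architecture template (synthetic stand-in).

    The shipped tables are desk-scale stand-ins for the published elderly
    cadaveric and young in-vivo architecture datasets: the elderly table
    has lower volumes and maximum forces, shorter fibres (most strongly in
    the distal functional groups) and smaller pennation angles than the
    young table.
    """
    if label not in _DATA_FILES:
        raise ValueError("label must be GE or GY")
    with resources.files("myotorque.data").joinpath(_DATA_FILES[label]).open() as fh:
        df = pd.read_csv(fh, comment="#")
    table = {
        row.muscle: MTUArchitecture.from_measurements(
            muscle=row.muscle, Vm=row.Vm_mm3,
            Lf_raw=row.Lf_mm * row.Ls_um / 2.7, Ls=row.Ls_um,
            pennation=row.pennation_deg, n_actuators=int(row.n_actuators))
        for row in df.itertuples()
    }
    return GenericDataset(source_label=label, source_body_mass=DONOR_MASS[label], table=table)


_slack_cache: dict[str, tuple[dict, dict]] = {}


def generic_slack_and_ranges(dataset: GenericDataset):
    """Tendon slack lengths and MTU operating ranges of a generic dataset.

    Both are derived on the reference limb geometry scaled to the donor
    body mass, which is where the generic fibre lengths are internally
    consistent; applying the resulting slack lengths to a differently
    sized subject reproduces the off-optimal operating points that make
    unoptimised generic models inaccurate.
    """
    key = dataset.source_label
    if key in _slack_cache:
        return _slack_cache[key]
    from .limb_model import geometry_scale_for_mass
    geo = build_default_geometry(geometry_scale_for_mass(dataset.source_body_mass))
    archs: dict[str, MTUArchitecture] = {}
    ranges: dict[str, tuple[float, float]] = {}
    for name, arch in dataset.table.items():
        lo, hi = geo.mtu_length_range(name)
        lengths = np.linspace(lo, hi, 21)
        lts = estimate_tendon_slack(lengths, arch.Lf, arch.pennation)
        archs[name] = MTUArchitecture(**{**arch.__dict__, "Lts": lts})
        ranges[name] = (lo, hi)
    _slack_cache[key] = (archs, ranges)
    return archs, ranges


# --- virtual cohorts --------------------------------------------------------

@dataclass
class VirtualSubject:
    subject_id: str
    body_mass: float                                # kg
    sex: str
    segment_volumes: dict[str, float]               # m^3
    muscles: dict[str, MTUArchitecture]             # ground-truth architecture
    joint_rom: dict[tuple[str, str], tuple[float, float]]

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValueError("body mass must be positive")
        for rom in self.joint_rom.values():
            if rom[0] >= rom[1]:
                raise ValueError("ROM min must be below max")


@dataclass
class CohortConfig:
    """Cohort size, population and between-subject variation settings."""

    n_subjects: int = 10
    population: str = "young"           # selects the architecture template
    rng_seed: int = 42
    noise_sd_volume: float = 0.10       # relative SD of muscle volume
    noise_sd_fibre: float = 0.07        # relative SD of optimal fibre length
    noise_sd_pennation: float = 0.15    # relative SD of pennation angle
    torque_noise_sd: float = 0.03       # relative SD of dynamometer torque
    mass_sd_kg: float = 9.0             # between-subject body-mass SD

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("a cohort needs at least 2 subjects")
        if self.population not in ("young", "elderly"):
            raise ValueError("population must be young or elderly")
        for f in ("noise_sd_volume", "noise_sd_fibre", "noise_sd_pennation",
                  "torque_noise_sd", "mass_sd_kg"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative factor with unit mean and relative SD ~ cv."""
    if cv == 0:
        return np.ones(size) if size else 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def sample_cohort(config: CohortConfig, template: GenericDataset | None = None) -> list[VirtualSubject]:
    """Draw a cohort of virtual subjects around an architecture template.

    Muscle volume, optimal fibre length and pennation get independent
    multiplicative lognormal factors per subject and muscle; body mass is
    normal around the template's source mass.  Deterministic for a fixed
    ``config.rng_seed``.
    """
    if template is None:
        template = load_generic_dataset("GY" if config.population == "young" else "GE")
    rng = np.random.default_rng(config.rng_seed)
    from .limb_model import _DEMO_VOLUMES, REFERENCE_GEOMETRY_MASS

    subjects = []
    for i in range(config.n_subjects):
        mass = float(rng.normal(template.source_body_mass, config.mass_sd_kg))
        mass = max(mass, 0.5 * template.source_body_mass)
        muscles = {}
        for name, arch in template.table.items():
            vm = arch.Vm * _lognormal_factor(rng, config.noise_sd_volume)
            lf = arch.Lf * _lognormal_factor(rng, config.noise_sd_fibre)
            th = min(arch.pennation * _lognormal_factor(rng, config.noise_sd_pennation), 89.0)
            muscles[name] = MTUArchitecture.from_measurements(
                muscle=name, Vm=vm, Lf_raw=lf * arch.Ls / 2.7, Ls=arch.Ls,
                pennation=th, n_actuators=arch.n_actuators,
                specific_tension=arch.specific_tension)
        vol_scale = mass / REFERENCE_GEOMETRY_MASS
        seg_vols = {k: v * vol_scale for k, v in _DEMO_VOLUMES.items()}
        rom = {(j, d): DEFAULT_JOINT_ROM[j] for j, d, _ in MOVEMENTS}
        subjects.append(VirtualSubject(
            subject_id=f"S{i + 1:02d}", body_mass=mass,
            sex="F" if i % 2 else "M",
            segment_volumes=seg_vols, muscles=muscles, joint_rom=rom))
    return subjects


def build_true_limb(subject: VirtualSubject) -> LimbModel:
    """The subject's ground-truth limb model (true architecture + geometry)."""
    return build_limb(subject.muscles, subject.body_mass)


def generate_dynamometer_trace(subject: VirtualSubject, limb: LimbModel, joint: str,
                               direction: str, angular_velocity: float = 60.0,
                               n_samples: int = 50, torque_noise_sd: float = 0.0,
                               rng: np.random.Generator | int | None = None) -> TorqueTrace:
    """Emulate one maximal isokinetic repetition.

    The joint angle sweeps the subject's range of motion at constant
    angular velocity while the recorded torque is the limb's maximal
    agonist torque capacity at each posture (all agonists at full
    activation with the force-length-velocity scaling of the ongoing
    concentric movement, antagonists passive), perturbed by multiplicative
    Gaussian noise.  Plays the role of the measured trace Te.
    """
    rom = subject.joint_rom[(joint, direction)]
    if rom[1] - rom[0] <= 0:
        raise ValueError("zero-length range of motion")
    if angular_velocity <= 0:
        raise ValueError("angular velocity must be positive")
    sign = movement_sign(joint, direction)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    start, end = (rom[0], rom[1]) if sign > 0 else (rom[1], rom[0])
    duration = abs(end - start) / angular_velocity
    t = np.linspace(0.0, duration, n_samples)
    angle = np.linspace(start, end, n_samples)
    qdot = np.full(n_samples, sign * angular_velocity)
    torque = np.array([
        limb.joint_torque_capacity(joint, direction, float(q), float(v)) * sign
        for q, v in zip(angle, qdot)
    ])
    if torque_noise_sd > 0:
        torque = torque * (1.0 + rng.normal(0.0, torque_noise_sd, size=n_samples))
    return TorqueTrace(time=t, angle=angle, angular_velocity=qdot, torque=torque,
                       joint=joint, direction=direction,
                       subject_id=subject.subject_id, body_mass=subject.body_mass)


def cohort_to_csv(subjects: list[VirtualSubject], path: str) -> None:
    """One row per subject x muscle: the cohort architecture table."""
    rows = []
    for s in subjects:
        for name, arch in s.muscles.items():
            rows.append({
                "subject_id": s.subject_id, "muscle": name,
                "body_mass_kg": s.body_mass, "Vm_mm3": arch.Vm,
                "Lf_raw_mm": arch.Lf_raw, "Ls_um": arch.Ls,
                "Lf_mm": arch.Lf, "pennation_deg": arch.pennation,
                "PCSA_mm2": arch.PCSA, "Fmax_N": arch.Fmax,
            })
    pd.DataFrame(rows).to_csv(path, index=False)
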