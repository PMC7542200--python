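"""Planar hinge-joint lower-limb model with Hill-type musculotendon actuators.

The limb is a sagittal-plane kinematic chain (pelvis - thigh - shank -
foot) articulated by three hinge joints (hip, knee, ankle) whose axes are
normal to the sagittal plane.  Musculotendon paths are polylines of
attachment and via points expressed in segment-local millimetre
coordinates; an optional wrap cylinder per joint replaces a straight
segment by the tangent-arc-tangent geodesic when the straight line would
cut through the cylinder.

Sign conventions: one degree of freedom per joint, extension torque
positive (at the ankle, plantarflexion plays the role of extension),
angles in degrees at the interface and radians internally.  MTU lengths
and moment arms are in mm; forces in N; joint torques in Nm.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .architecture import MTUArchitecture

__all__ = [
    "Segment",
    "HingeJoint",
    "MTUPath",
    "WrapCylinder",
    "HillCurves",
    "HillMTU",
    "LimbGeometry",
    "LimbModel",
    "segment_mass_props",
    "hill_force",
    "build_default_geometry",
    "build_limb",
    "TRIAL_POSTURE",
    "DENSITY_LIMB",
    "DENSITY_PELVIS",
    "DEFAULT_JOINT_ROM",
    "MOVEMENTS",
]

#: segment tissue densities, kg/m^3
DENSITY_LIMB = 1062.0
DENSITY_PELVIS = 1013.0

#: posture (deg) of the joints not being tested during an isokinetic trial
TRIAL_POSTURE = {"hip": -45.0, "knee": -45.0, "ankle": 0.0}

#: default hinge ranges of motion, deg, extension positive
DEFAULT_JOINT_ROM = {"hip": (-70.0, 5.0), "knee": (-85.0, -5.0), "ankle": (-15.0, 25.0)}

#: the six movements of the dynamometer protocol: (joint, direction, sign)
MOVEMENTS = (
    ("ankle", "plantarflexion", +1),
    ("ankle", "dorsiflexion", -1),
    ("knee", "extension", +1),
    ("knee", "flexion", -1),
    ("hip", "extension", +1),
    ("hip", "flexion", -1),
)


_DIRECTION_SIGN = {"extension": +1, "plantarflexion": +1,
                   "flexion": -1, "dorsiflexion": -1}


def movement_sign(joint: str, direction: str) -> int:
    """Sign of a movement direction in the extension-positive convention."""
    try:
        return _DIRECTION_SIGN[direction]
    except KeyError:
        raise ValueError(f"unknown movement direction {direction!r}") from None


@dataclass
class Segment:
    name: str
    volume: float                   # m^3
    density: float                  # kg/m^3
    parent_joint: str | None = None  # None for the root segment

    @property
    def mass(self) -> float:
        return self.volume * self.density


@dataclass
class HingeJoint:
    name: str
    parent: str                     # parent segment name
    child: str
    location: np.ndarray            # joint centre in parent-local mm
    rom: tuple[float, float]        # degrees, min < max
    sign: int = 1                   # maps the extension-positive angle onto the +y rotation

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, dtype=float)
        if self.rom[0] >= self.rom[1]:
            raise ValueError(f"joint {self.name}: ROM min must be below max")


@dataclass
class WrapCylinder:
    """A wrap cylinder at a joint (axis = hinge axis), for one MTU path."""

    joint: str
    radius: float                   # mm
    wrap_sign: int = 1              # +1 wraps counter-clockwise in the x-z plane


@dataclass
class MTUPath:
    """Ordered attachment points: (segment name, local point mm)."""

    points: list[tuple[str, np.ndarray]]
    wraps: list[WrapCylinder] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("an MTU path needs at least two points")
        self.points = [(seg, np.asarray(p, dtype=float)) for seg, p in self.points]


@dataclass
class HillCurves:
    """Normalised Hill curve constants (dimensionless unless noted)."""

    fl_width: float = 0.45      # Gaussian width of the active force-length curve
    fp_strain: float = 0.7      # normalised passive force reaches 1 at l = 1 + fp_strain
    fp_exponent: float = 4.0
    fv_shape: float = 0.25      # Hill a_f parameter
    fv_ecc_plateau: float = 1.5
    vmax: float = 10.0          # optimal fibre lengths per second

    def fl_active(self, ltilde: float) -> float:
        return math.exp(-(((ltilde - 1.0) / self.fl_width) ** 2))

    def fp_passive(self, ltilde: float) -> float:
        if ltilde <= 1.0:
            return 0.0
        return ((ltilde - 1.0) / self.fp_strain) ** self.fp_exponent

    def fv(self, vtilde: float) -> float:
        """Force-velocity scaling; vtilde < 0 is shortening (concentric)."""
        if vtilde <= -1.0:
            return 0.0
        if vtilde <= 0.0:
            return (1.0 + vtilde) / (1.0 - vtilde / self.fv_shape)
        # eccentric branch: rises from 1 towards the plateau
        b = self.fv_shape / 7.56
        return (self.fv_ecc_plateau * vtilde + b) / (vtilde + b)


@dataclass
class HillMTU:
    architecture: MTUArchitecture
    curves: HillCurves = field(default_factory=HillCurves)


def hill_force(mtu: HillMTU, activation: float, mtu_length: float,
               mtu_velocity: float = 0.0) -> float:
    """Tendon force of a rigid-tendon Hill-type MTU.

    Fibre length follows constant-thickness pennation geometry
    (w = Lf sin(theta0) fixed); the force is
    F = Fmax (a fl(l) fv(v) + fp(l)) cos(theta(l)).
    """
    if not 0.0 <= activation <= 1.0:
        raise ValueError("activation must lie in [0, 1]")
    active, passive = hill_force_components(mtu, mtu_length, mtu_velocity)
    return active * activation + passive


def hill_force_components(mtu: HillMTU, mtu_length: float,
                          mtu_velocity: float = 0.0) -> tuple[float, float]:
    """(active gain, passive force): tendon force is affine in activation."""
    arch = mtu.architecture
    if arch.Lts is None:
        raise ValueError(f"{arch.muscle}: tendon slack length not set")
    w = arch.Lf * math.sin(math.radians(arch.pennation))
    proj = mtu_length - arch.Lts
    if proj < 1e-6:
        proj = 1e-6  # fibre cannot project to non-positive length under rigid tendon
    lf_mm = math.hypot(w, proj)
    ltilde = lf_mm / arch.Lf
    cos_pen = proj / lf_mm
    # fibre velocity: the along-fibre component of the MTU rate
    vtilde = (mtu_velocity * cos_pen) / (arch.Lf * mtu.curves.vmax)
    active = arch.Fmax * mtu.curves.fl_active(ltilde) * mtu.curves.fv(vtilde) * cos_pen
    passive = arch.Fmax * mtu.curves.fp_passive(ltilde) * cos_pen
    return active, passive


def segment_mass_props(volume: float, density: float) -> dict:
    """Mass, COM and transverse inertia of a volume-matched cylinder stand-in.

    The cylinder has aspect ratio length = 6 r; COM at mid-length along the
    segment's long (-z) axis.
    """
    if volume <= 0:
        raise ValueError("volume must be positive")
    if density <= 0:
        raise ValueError("density must be positive")
    mass = volume * density
    r = (volume / (6.0 * math.pi)) ** (1.0 / 3.0)
    length = 6.0 * r
    inertia = mass * (3 * r * r + length * length) / 12.0
    return {"mass": mass, "com": (0.0, 0.0, -length / 2.0 * 1000.0),
            "inertia_transverse": inertia, "radius_m": r, "length_m": length}


def _rot_y(angle_rad: float) -> np.ndarray:
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


class LimbGeometry:
    """Kinematic chain + MTU paths; architecture-independent geometry engine."""

    def __init__(self, segments: list[Segment], joints: list[HingeJoint],
                 paths: dict[str, MTUPath]):
        self.segments = {s.name: s for s in segments}
        self.joints = {j.name: j for j in joints}
        self.paths = dict(paths)
        self._children = {j.parent: j for j in joints}
        self._cache: dict[tuple, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
        # chain order from the root
        root = next(s.name for s in segments if s.parent_joint is None)
        self._order = [root]
        while self._order[-1] in self._children:
            self._order.append(self._children[self._order[-1]].child)

    # -- kinematics --------------------------------------------------------

    def _angles_key(self, angles: dict[str, float]) -> tuple:
        return tuple(round(float(angles.get(j, 0.0)), 9) for j in self.joints)

    def segment_transforms(self, angles: dict[str, float]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """World (R, t) per segment for joint angles in degrees."""
        key = self._angles_key(angles)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        transforms: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        transforms[self._order[0]] = (np.eye(3), np.zeros(3))
        for seg_name in self._order[1:]:
            joint = self.joints[self.segments[seg_name].parent_joint]
            r_p, t_p = transforms[joint.parent]
            q = math.radians(float(angles.get(joint.name, 0.0))) * joint.sign
            r = r_p @ _rot_y(q)
            t = r_p @ joint.location + t_p
            transforms[seg_name] = (r, t)
        if len(self._cache) > 4096:
            self._cache.clear()
        self._cache[key] = transforms
        return transforms

    def world_points(self, mtu: str, angles: dict[str, float]) -> np.ndarray:
        tf = self.segment_transforms(angles)
        pts = [tf[seg][0] @ p + tf[seg][1] for seg, p in self.paths[mtu].points]
        return np.asarray(pts)

    def joint_centre(self, joint: str, angles: dict[str, float]) -> np.ndarray:
        j = self.joints[joint]
        r_p, t_p = self.segment_transforms(angles)[j.parent]
        return r_p @ j.location + t_p

    def spanned_joints(self, mtu: str) -> list[str]:
        """Joints between the first and last segment of the path's chain."""
        segs = [seg for seg, _ in self.paths[mtu].points]
        idx = [self._order.index(s) for s in segs]
        lo, hi = min(idx), max(idx)
        return [self.segments[self._order[i]].parent_joint for i in range(lo + 1, hi + 1)]

    # -- lengths and moment arms -------------------------------------------

    def mtu_length(self, mtu: str, angles: dict[str, float]) -> float:
        """Path length (mm): straight segments, wrap arcs where engaged."""
        pts = self.world_points(mtu, angles)
        path = self.paths[mtu]
        total = 0.0
        for a, b in zip(pts[:-1], pts[1:]):
            seg_len = None
            for wrap in path.wraps:
                centre = self.joint_centre(wrap.joint, angles)
                wrapped = _wrap_length_2d(a, b, centre, wrap.radius, wrap.wrap_sign)
                if wrapped is not None:
                    seg_len = wrapped
                    break
            total += seg_len if seg_len is not None else float(np.linalg.norm(b - a))
        return total

    def moment_arm(self, mtu: str, joint: str, angles: dict[str, float],
                   step_deg: float = 0.01) -> float:
        """Tendon-excursion moment arm r = -dL/dq (mm per radian).

        Positive for extensor action under the extension-positive angle
        convention.  Returns 0 with a warning-free no-op if the path does
        not cross the joint.
        """
        if joint not in self.spanned_joints(mtu):
            return 0.0
        q0 = float(angles.get(joint, 0.0))
        up = dict(angles); up[joint] = q0 + step_deg
        dn = dict(angles); dn[joint] = q0 - step_deg
        dq = math.radians(2 * step_deg)
        return -(self.mtu_length(mtu, up) - self.mtu_length(mtu, dn)) / dq

    def mtu_length_range(self, mtu: str, posture: dict[str, float] | None = None,
                         n_grid: int = 9) -> tuple[float, float]:
        """MTU length extremes over the spanned joints' ROM (grid sweep)."""
        posture = dict(TRIAL_POSTURE if posture is None else posture)
        spanned = self.spanned_joints(mtu)
        grids = [np.linspace(*self.joints[j].rom, n_grid) for j in spanned]
        lengths = []
        for combo in np.stack(np.meshgrid(*grids), axis=-1).reshape(-1, len(spanned)):
            ang = dict(posture)
            for j, q in zip(spanned, combo):
                ang[j] = float(q)
            lengths.append(self.mtu_length(mtu, ang))
        return float(min(lengths)), float(max(lengths))


def _wrap_length_2d(p1: np.ndarray, p2: np.ndarray, centre: np.ndarray,
                    radius: float, wrap_sign: int) -> float | None:
    """Tangent-arc-tangent length in the x-z plane, or None if not engaged."""
    a = np.array([p1[0] - centre[0], p1[2] - centre[2]])
    b = np.array([p2[0] - centre[0], p2[2] - centre[2]])
    d1, d2 = np.linalg.norm(a), np.linalg.norm(b)
    if d1 <= radius or d2 <= radius:
        return None  # attachment inside the cylinder: treat as straight
    # distance of the straight segment from the centre
    ab = b - a
    tpar = -float(a @ ab) / float(ab @ ab)
    closest = a + np.clip(tpar, 0.0, 1.0) * ab
    if np.linalg.norm(closest) >= radius or not 0.0 < tpar < 1.0:
        return None
    # tangent lengths and wrapped arc
    lt1 = math.sqrt(d1 * d1 - radius * radius)
    lt2 = math.sqrt(d2 * d2 - radius * radius)
    ang1 = math.atan2(a[1], a[0])
    ang2 = math.atan2(b[1], b[0])
    off1 = math.acos(radius / d1)
    off2 = math.acos(radius / d2)
    t1 = ang1 + wrap_sign * off1
    t2 = ang2 - wrap_sign * off2
    arc = (t2 - t1) * wrap_sign
    arc = arc % (2.0 * math.pi)
    return lt1 + lt2 + radius * arc


class LimbModel:
    """Geometry plus per-MTU Hill actuators; supports torque-level queries."""

    def __init__(self, geometry: LimbGeometry, mtus: dict[str, HillMTU],
                 body_mass: float | None = None):
        missing = set(mtus) - set(geometry.paths)
        if missing:
            raise ValueError(f"no path for MTUs: {sorted(missing)}")
        self.geometry = geometry
        self.mtus = dict(mtus)
        self.body_mass = body_mass

    def muscles_crossing(self, joint: str) -> list[str]:
        return [m for m in self.mtus if joint in self.geometry.spanned_joints(m)]

    def torque_terms(self, joint: str, q: float, qdot: float = 0.0,
                     posture: dict[str, float] | None = None):
        """Per-MTU (name, active gain Nm, passive Nm) about a joint.

        The torque contribution of MTU i is affine in its activation:
        tau_i = gain_i * a_i + passive_i, with gain_i = A_i r_i and A_i the
        Hill active force at full activation for the posture and the
        fibre velocity implied by the joint rate.
        """
        angles = dict(TRIAL_POSTURE if posture is None else posture)
        angles[joint] = q
        qdot_rad = math.radians(qdot)
        terms = []
        for name in self.muscles_crossing(joint):
            r = self.geometry.moment_arm(name, joint, angles)   # mm/rad
            length = self.geometry.mtu_length(name, angles)
            velocity = -r * qdot_rad                            # mm/s, dL/dt
            active, passive = hill_force_components(self.mtus[name], length, velocity)
            terms.append((name, active * r / 1000.0, passive * r / 1000.0))
        return terms

    def joint_torque_capacity(self, joint: str, direction: str, q: float,
                              qdot: float = 0.0,
                              posture: dict[str, float] | None = None) -> float:
        """Maximum achievable torque in a direction: agonists fully active,
        antagonists passive-only.  Signed in the joint convention."""
        sign = movement_sign(joint, direction)
        terms = self.torque_terms(joint, q, qdot, posture)
        if not terms:
            raise ValueError(f"no MTU crosses joint {joint!r}")
        return sum(g for _, g, _ in terms if g * sign > 0) + sum(p for _, _, p in terms)

    # -- serialisation ------------------------------------------------------

    def to_json(self) -> str:
        geo = self.geometry
        payload = {
            "body_mass": self.body_mass,
            "segments": [asdict(s) for s in geo.segments.values()],
            "joints": [
                {"name": j.name, "parent": j.parent, "child": j.child,
                 "location": j.location.tolist(), "rom": list(j.rom), "sign": j.sign}
                for j in geo.joints.values()
            ],
            "paths": {
                name: {
                    "points": [[seg, p.tolist()] for seg, p in path.points],
                    "wraps": [asdict(w) for w in path.wraps],
                }
                for name, path in geo.paths.items()
            },
            "mtus": {
                name: {"architecture": asdict(m.architecture), "curves": asdict(m.curves)}
                for name, m in self.mtus.items()
            },
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LimbModel":
        payload = json.loads(text)
        segments = [Segment(**s) for s in payload["segments"]]
        joints = [HingeJoint(name=j["name"], parent=j["parent"], child=j["child"],
                             location=np.asarray(j["location"]), rom=tuple(j["rom"]),
                             sign=j["sign"]) for j in payload["joints"]]
        paths = {
            name: MTUPath(points=[(seg, np.asarray(p)) for seg, p in spec["points"]],
                          wraps=[WrapCylinder(**w) for w in spec["wraps"]])
            for name, spec in payload["paths"].items()
        }
        mtus = {
            name: HillMTU(architecture=MTUArchitecture(**spec["architecture"]),
                          curves=HillCurves(**spec["curves"]))
            for name, spec in payload["mtus"].items()
        }
        return cls(LimbGeometry(segments, joints, paths), mtus,
                   body_mass=payload.get("body_mass"))


# --- default desk-scale limb ------------------------------------------------

#: reference body mass (kg) at which the default geometry has scale 1
REFERENCE_GEOMETRY_MASS = 75.3

# segment-local attachment coordinates (mm) for the 12-MTU demo limb:
# 6 functional groups (plantarflexors, dorsiflexors, knee
# extensors/flexors, hip extensors/flexors); x anterior, z up,
# each segment frame rooted at its proximal joint.
_DEMO_PATHS: dict[str, list[tuple[str, tuple[float, float, float]]]] = {
    "soleus":            [("shank", (-25, 0, -100)), ("foot", (-45, 0, -30))],
    "gastrocnemius":     [("thigh", (-30, 0, -400)), ("foot", (-45, 0, -30))],
    "tibialis_anterior": [("shank", (20, 0, -150)), ("shank", (30, 0, -385)), ("foot", (55, 0, -25))],
    "ext_digitorum":     [("shank", (25, 0, -120)), ("shank", (33, 0, -385)), ("foot", (105, 0, -30))],
    "vastus_lateralis":  [("thigh", (10, 0, -150)), ("thigh", (45, 0, -400)), ("shank", (40, 0, -60))],
    "vastus_medialis":   [("thigh", (5, 0, -200)), ("thigh", (45, 0, -400)), ("shank", (40, 0, -60))],
    "rectus_femoris":    [("pelvis", (40, 0, 20)), ("thigh", (45, 0, -400)), ("shank", (40, 0, -60))],
    "biceps_femoris":    [("pelvis", (-70, 0, 0)), ("shank", (-25, 0, -40))],
    "semitendinosus":    [("pelvis", (-65, 0, -5)), ("shank", (-20, 0, -70))],
    "gluteus_maximus":   [("pelvis", (-80, 0, 90)), ("thigh", (-35, 0, -120))],
    "iliopsoas":         [("pelvis", (25, 0, 140)), ("pelvis", (35, 0, -10)), ("thigh", (8, 0, -55))],
    "adductor_magnus":   [("pelvis", (-55, 0, -25)), ("thigh", (-12, 0, -250))],
}

#: reference segment volumes (m^3) at scale 1
_DEMO_VOLUMES = {"pelvis": 9.0e-3, "thigh": 7.5e-3, "shank": 3.5e-3, "foot": 0.9e-3}


def build_default_geometry(scale: float = 1.0,
                           joint_rom: dict[str, tuple[float, float]] | None = None) -> LimbGeometry:
    """The 12-MTU sagittal demo limb, isotropically scaled.

    ``scale`` multiplies every linear dimension (volumes scale by its
    cube); body-size scaling uses the 1/3 power of the body-mass ratio
    against the 75.3 kg reference.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    rom = dict(DEFAULT_JOINT_ROM if joint_rom is None else joint_rom)
    segments = [
        Segment("pelvis", _DEMO_VOLUMES["pelvis"] * scale**3, DENSITY_PELVIS, None),
        Segment("thigh", _DEMO_VOLUMES["thigh"] * scale**3, DENSITY_LIMB, "hip"),
        Segment("shank", _DEMO_VOLUMES["shank"] * scale**3, DENSITY_LIMB, "knee"),
        Segment("foot", _DEMO_VOLUMES["foot"] * scale**3, DENSITY_LIMB, "ankle"),
    ]
    joints = [
        HingeJoint("hip", "pelvis", "thigh", np.array([0.0, 0.0, 0.0]), rom["hip"], sign=+1),
        HingeJoint("knee", "thigh", "shank", np.array([0.0, 0.0, -420.0]) * scale, rom["knee"], sign=-1),
        HingeJoint("ankle", "shank", "foot", np.array([0.0, 0.0, -400.0]) * scale, rom["ankle"], sign=+1),
    ]
    paths = {
        name: MTUPath(points=[(seg, np.asarray(p, dtype=float) * scale) for seg, p in pts])
        for name, pts in _DEMO_PATHS.items()
    }
    return LimbGeometry(segments, joints, paths)


def geometry_scale_for_mass(body_mass: float) -> float:
    return (body_mass / REFERENCE_GEOMETRY_MASS) ** (1.0 / 3.0)


def build_limb(architectures: dict[str, MTUArchitecture], body_mass: float,
               curves: HillCurves | None = None,
               geometry: LimbGeometry | None = None) -> LimbModel:
    """Assemble a LimbModel from an architecture set on (scaled) demo geometry.

    Any MTU without a tendon slack length gets one estimated on this
    geometry (normalised fibre length 1 at the mid operating range).
    """
    from .architecture import estimate_tendon_slack

    if geometry is None:
        geometry = build_default_geometry(geometry_scale_for_mass(body_mass))
    curves = curves or HillCurves()
    mtus: dict[str, HillMTU] = {}
    for name, arch in architectures.items():
        if arch.Lts is None:
            lo, hi = geometry.mtu_length_range(name)
            lengths = np.linspace(lo, hi, 21)
            lts = estimate_tendon_slack(lengths, arch.Lf, arch.pennation)
            arch = MTUArchitecture(**{**asdict(arch), "Lts": lts})
        mtus[name] = HillMTU(architecture=arch, curves=curves)
    return LimbModel(geometry, mtus, body_mass=body_mass)
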