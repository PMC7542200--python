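"""Hill-model force-generating properties from measured muscle anatomy.

Converts raw measurements (volume, DTI fascicle length, sarcomere length,
pennation) into the four parameters a Hill-type musculotendon actuator
needs: optimal fibre length, maximum isometric force (via physiological
cross-sectional area and specific tension), pennation angle and tendon
slack length.  Also covers the generic-model machinery: body-mass scaling
of generic maximum forces, operating-range optimisation of generic
fibre/tendon lengths onto a target geometry, and equal splitting of a
muscle's force across multiple actuators.

Units: lengths mm, sarcomere length um, volume mm^3, area mm^2, force N,
angles degrees at the interface (radians internally), specific tension
N/mm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

__all__ = [
    "OPTIMAL_SARCOMERE_UM",
    "DEFAULT_SPECIFIC_TENSION",
    "MTUArchitecture",
    "ScalingContext",
    "optimal_fibre_length",
    "pcsa",
    "fmax_from_pcsa",
    "scale_generic_fmax",
    "estimate_tendon_slack",
    "optimize_generic_operating_range",
    "split_fmax",
    "build_variant",
    "VARIANTS",
]

#: generic optimal sarcomere length used to normalise measured fascicles
OPTIMAL_SARCOMERE_UM = 2.7
#: isometric stress of skeletal muscle, N/mm^2
DEFAULT_SPECIFIC_TENSION = 0.3

VARIANTS = ("SS", "GE", "GE_O", "GY", "GY_O")


def optimal_fibre_length(Lf_raw: float, Ls: float) -> float:
    """Optimal fibre length: raw length normalised to a 2.7 um sarcomere.

    Lf = Lf' * 2.7 / Ls, with Lf' the measured (raw) fascicle length in mm
    and Ls the muscle's sarcomere length in um.
    """
    if Lf_raw <= 0 or Ls <= 0:
        raise ValueError("fibre and sarcomere lengths must be positive")
    return Lf_raw * OPTIMAL_SARCOMERE_UM / Ls


def pcsa(Vm: float, pennation: float, Lf: float) -> float:
    """Physiological cross-sectional area: PCSA = Vm * cos(theta) / Lf."""
    if Vm <= 0 or Lf <= 0:
        raise ValueError("volume and fibre length must be positive")
    if not 0 <= pennation < 90:
        raise ValueError("pennation must lie in [0, 90) degrees")
    return Vm * np.cos(np.radians(pennation)) / Lf


def fmax_from_pcsa(PCSA: float, specific_tension: float = DEFAULT_SPECIFIC_TENSION) -> float:
    """Maximum isometric force from PCSA and specific tension."""
    if specific_tension <= 0:
        raise ValueError("specific tension must be positive")
    if PCSA < 0:
        raise ValueError("PCSA must be non-negative")
    return PCSA * specific_tension


@dataclass
class ScalingContext:
    """Body masses for generic maximum-force scaling."""

    M_subject: float
    M_generic: float  # 75.3 kg for the elderly-derived reference, 71.9 kg young

    def __post_init__(self) -> None:
        if self.M_subject <= 0 or self.M_generic <= 0:
            raise ValueError("body masses must be positive")


def scale_generic_fmax(Fmax_generic: float, ctx: ScalingContext) -> float:
    """Scale a generic Fmax to a subject by the 2/3 power of the mass ratio."""
    return Fmax_generic * (ctx.M_subject / ctx.M_generic) ** (2.0 / 3.0)


def split_fmax(Fmax: float, n_actuators: int) -> list[float]:
    """Equally divide a muscle's Fmax over its actuators (broad-origin muscles)."""
    if n_actuators < 1:
        raise ValueError("n_actuators must be at least 1")
    return [Fmax / n_actuators] * n_actuators


@dataclass
class MTUArchitecture:
    """Force-generating properties of one musculotendon unit.

    The stored fields satisfy PCSA = Vm cos(theta) / Lf and
    Fmax = PCSA * sigma; use :meth:`from_measurements` to populate them
    consistently from raw measurements.
    """

    muscle: str
    Vm: float               # mm^3
    Lf_raw: float           # mm (raw DTI fascicle length, Lf')
    Ls: float               # um (sarcomere length)
    Lf: float               # mm (optimal fibre length)
    pennation: float        # degrees
    PCSA: float             # mm^2
    Fmax: float             # N
    Lts: float | None = None  # mm; geometry-dependent, filled by slack estimation
    n_actuators: int = 1
    specific_tension: float = DEFAULT_SPECIFIC_TENSION

    def __post_init__(self) -> None:
        for name in ("Vm", "Lf_raw", "Ls", "Lf", "PCSA", "Fmax"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive for {self.muscle}")
        if not 0 <= self.pennation < 90:
            raise ValueError("pennation must lie in [0, 90) degrees")
        if self.Lts is not None and self.Lts <= 0:
            raise ValueError("tendon slack length must be positive")
        expect_pcsa = pcsa(self.Vm, self.pennation, self.Lf)
        if abs(self.PCSA - expect_pcsa) > 1e-9 * expect_pcsa:
            raise ValueError(f"PCSA inconsistent with Vm cos(theta)/Lf for {self.muscle}")
        expect_fmax = self.PCSA * self.specific_tension
        if abs(self.Fmax - expect_fmax) > 1e-9 * expect_fmax:
            raise ValueError(f"Fmax inconsistent with PCSA * sigma for {self.muscle}")

    @classmethod
    def from_measurements(cls, muscle: str, Vm: float, Lf_raw: float, Ls: float,
                          pennation: float, n_actuators: int = 1,
                          specific_tension: float = DEFAULT_SPECIFIC_TENSION,
                          Lts: float | None = None) -> "MTUArchitecture":
        Lf = optimal_fibre_length(Lf_raw, Ls)
        area = pcsa(Vm, pennation, Lf)
        return cls(muscle=muscle, Vm=Vm, Lf_raw=Lf_raw, Ls=Ls, Lf=Lf,
                   pennation=pennation, PCSA=area,
                   Fmax=fmax_from_pcsa(area, specific_tension),
                   Lts=Lts, n_actuators=n_actuators,
                   specific_tension=specific_tension)

    def with_fmax(self, Fmax: float, Lf: float | None = None,
                  Lts: float | None = None) -> "MTUArchitecture":
        """Return a copy with a prescribed Fmax (and optionally new Lf/Lts).

        The stored volume is recomputed as the volume implied by the new
        force and fibre length so the PCSA identity keeps holding.
        """
        Lf = self.Lf if Lf is None else Lf
        area = Fmax / self.specific_tension
        vm = area * Lf / np.cos(np.radians(self.pennation))
        return replace(self, Vm=vm, Lf=Lf, Lf_raw=Lf * self.Ls / OPTIMAL_SARCOMERE_UM,
                       PCSA=area, Fmax=Fmax, Lts=self.Lts if Lts is None else Lts)


def _norm_fibre_length(L_mtu: np.ndarray, Lts: float, Lf: float, pennation: float) -> np.ndarray:
    """Rigid-tendon normalised fibre length with constant-thickness pennation."""
    w = Lf * np.sin(np.radians(pennation))
    proj = np.maximum(np.asarray(L_mtu) - Lts, 1e-9)
    return np.sqrt(w * w + proj * proj) / Lf


def estimate_tendon_slack(mtu_lengths: Sequence[float] | Callable[[float], float],
                          Lf: float, pennation: float,
                          rom: tuple[float, float] | None = None,
                          n_samples: int = 21) -> float:
    """Estimate tendon slack length from MTU lengths over the joint range.

    Picks the Lts that places the rigid-tendon normalised fibre length at
    the mid-range posture at 1.0 (the optimum of the force-length curve),
    penalising excursions of the normalised length outside [0.5, 1.5]
    across the range.  Deterministic bounded scalar minimisation.
    """
    if callable(mtu_lengths):
        if rom is None:
            raise ValueError("rom required when mtu_lengths is a callable")
        qs = np.linspace(rom[0], rom[1], n_samples)
        lengths = np.array([mtu_lengths(q) for q in qs])
    else:
        lengths = np.asarray(mtu_lengths, dtype=float)
    if len(lengths) == 0:
        raise ValueError("need at least one MTU length sample")
    l_min, l_max = float(lengths.min()), float(lengths.max())
    l_mid = 0.5 * (l_min + l_max)
    cos_pen = np.cos(np.radians(pennation))
    if Lf * cos_pen >= l_mid:
        raise ValueError("no feasible tendon slack length: fibre longer than the MTU")

    def cost(lts: float) -> float:
        ltilde = _norm_fibre_length(lengths, lts, Lf, pennation)
        mid = _norm_fibre_length(np.array([l_mid]), lts, Lf, pennation)[0]
        band = np.clip(ltilde - 1.5, 0, None) + np.clip(0.5 - ltilde, 0, None)
        return (mid - 1.0) ** 2 + float(np.sum(band**2))

    hi = l_mid - Lf * cos_pen * 1e-3
    res = minimize_scalar(cost, bounds=(max(1e-6, l_min - 2 * Lf), hi),
                          method="bounded", options={"xatol": 1e-7})
    return float(res.x)


def optimize_generic_operating_range(reference: MTUArchitecture,
                                     reference_range: tuple[float, float],
                                     target_range: tuple[float, float],
                                     n_poses: int = 11) -> tuple[float, float]:
    """Map a generic MTU's (Lf, Lts) onto a target geometry.

    Finds the fibre and tendon slack lengths that make the normalised
    fibre-length trajectory over the target MTU length range reproduce the
    reference trajectory at matched relative postures (least squares over
    sampled poses).  Used to build the optimised generic variants so the
    MTUs operate on the correct part of their force-length curve.
    """
    if reference.Lts is None:
        raise ValueError("reference architecture needs a tendon slack length")
    ref_lo, ref_hi = reference_range
    tgt_lo, tgt_hi = target_range
    if not (ref_hi > ref_lo and tgt_hi > tgt_lo):
        raise ValueError("MTU length ranges must be non-degenerate")
    rel = np.linspace(0.0, 1.0, n_poses)
    ref_lengths = ref_lo + rel * (ref_hi - ref_lo)
    tgt_lengths = tgt_lo + rel * (tgt_hi - tgt_lo)
    ref_traj = _norm_fibre_length(ref_lengths, reference.Lts, reference.Lf, reference.pennation)

    scale = (tgt_hi - tgt_lo) / (ref_hi - ref_lo)
    lf0 = reference.Lf * scale
    lts0 = 0.5 * (tgt_lo + tgt_hi) - (0.5 * (ref_lo + ref_hi) - reference.Lts) * scale

    def residuals(x: np.ndarray) -> np.ndarray:
        lf, lts = x
        return _norm_fibre_length(tgt_lengths, lts, lf, reference.pennation) - ref_traj

    res = least_squares(residuals, x0=[lf0, max(lts0, 1e-3)],
                        bounds=([1e-3, 1e-6], [np.inf, tgt_hi]),
                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
    lf_opt, lts_opt = res.x
    return float(lf_opt), float(lts_opt)


def build_variant(subject_arch: dict[str, MTUArchitecture], variant: str,
                  generic: "dict[str, MTUArchitecture] | None" = None,
                  ctx: ScalingContext | None = None,
                  reference_ranges: dict[str, tuple[float, float]] | None = None,
                  target_ranges: dict[str, tuple[float, float]] | None = None,
                  scale_all_generic: bool = False) -> dict[str, MTUArchitecture]:
    """Assemble the per-muscle architecture set for one model variant.

    SS returns the subject's own measured properties.  GE/GY return the
    generic table's properties unchanged (their Fmax is not mass-scaled
    unless ``scale_all_generic``).  GE_O/GY_O keep the generic pennation,
    optimise Lf/Lts onto the subject's MTU operating ranges, and scale
    Fmax by the 2/3 power of the body-mass ratio.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if variant == "SS":
        return dict(subject_arch)
    if generic is None:
        raise ValueError("generic table required for generic variants")
    missing = set(subject_arch) - set(generic)
    if missing:
        raise KeyError(f"generic table missing muscles: {sorted(missing)}")

    out: dict[str, MTUArchitecture] = {}
    for name in subject_arch:
        g = generic[name]
        if variant in ("GE", "GY"):
            if scale_all_generic:
                if ctx is None:
                    raise ValueError("scaling context required to scale generic Fmax")
                out[name] = g.with_fmax(scale_generic_fmax(g.Fmax, ctx))
            else:
                out[name] = replace(g)
        else:  # optimised variants
            if ctx is None or reference_ranges is None or target_ranges is None:
                raise ValueError("optimised variants need ctx and MTU length ranges")
            lf_opt, lts_opt = optimize_generic_operating_range(
                g, reference_ranges[name], target_ranges[name])
            fmax = scale_generic_fmax(g.Fmax, ctx)
            out[name] = g.with_fmax(fmax, Lf=lf_opt, Lts=lts_opt)
    return out
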