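"""Isokinetic trial simulation by per-posture static optimization.

At each sampled posture of a torque trace the muscle redundancy is
resolved by minimising the sum of squared activations subject to the net
joint torque matching the measured torque, with activations bounded in
[0, 1] and no reserve actuators.  Because tendon force is affine in
activation under the rigid-tendon Hill model at a fixed posture and joint
rate, each step is an equality-constrained diagonal quadratic program with
box constraints whose exact solution is obtained in closed form (sorting
the saturation breakpoints); when the demanded torque exceeds the model's
capacity every positive-gain actuator saturates at 1 and the achieved
torque equals the capacity.

Predicted torque is reconstructed by multiplying the solved muscle forces
by their moment arms and summing, and agreement with the measured trace
is scored as RMSE (absolute Nm, % of peak measured torque, and Nm per kg
body mass).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .limb_model import LimbModel, movement_sign

__all__ = [
    "TorqueTrace",
    "ActivationSolution",
    "SimResult",
    "solve_activation_qp",
    "static_optimization_step",
    "simulate_trial",
    "rmse",
    "max_isokinetic_torque",
]

TORQUE_TOL = 1e-8


@dataclass
class TorqueTrace:
    """One isokinetic repetition: sampled (time, angle, velocity, torque).

    Torque is stored as a positive effort in the direction of the
    movement; ``joint``/``direction`` give the movement, ``subject_id``
    and ``body_mass`` identify the subject.
    """

    time: np.ndarray          # s, strictly increasing
    angle: np.ndarray         # deg, joint convention (extension positive)
    angular_velocity: np.ndarray  # deg/s, signed in the joint convention
    torque: np.ndarray        # Nm, positive in the movement direction
    joint: str
    direction: str
    subject_id: str = ""
    body_mass: float = 0.0

    def __post_init__(self) -> None:
        for name in ("time", "angle", "angular_velocity", "torque"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.time)
        if n == 0:
            raise ValueError("trace must have at least one sample")
        if any(len(getattr(self, f)) != n for f in ("angle", "angular_velocity", "torque")):
            raise ValueError("trace fields must share one length")
        if n > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("trace time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)

    def to_csv(self, path: str) -> None:
        pd.DataFrame({
            "time_s": self.time, "angle_deg": self.angle,
            "ang_vel_deg_s": self.angular_velocity, "torque_Nm": self.torque,
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str, joint: str, direction: str,
                 subject_id: str = "", body_mass: float = 0.0) -> "TorqueTrace":
        df = pd.read_csv(path)
        return cls(time=df["time_s"].to_numpy(), angle=df["angle_deg"].to_numpy(),
                   angular_velocity=df["ang_vel_deg_s"].to_numpy(),
                   torque=df["torque_Nm"].to_numpy(), joint=joint,
                   direction=direction, subject_id=subject_id, body_mass=body_mass)


@dataclass
class ActivationSolution:
    activations: dict[str, float]
    objective: float          # sum of squared activations
    feasible: bool
    achieved_torque: float    # Nm, signed joint convention


@dataclass
class SimResult:
    trace: TorqueTrace
    Tp: np.ndarray            # predicted torque, positive in the movement direction
    feasible: np.ndarray
    RMSE_abs: float
    RMSE_pct: float
    RMSE_norm_bw: float
    solutions: list[ActivationSolution] = field(default_factory=list)


def solve_activation_qp(gains: np.ndarray, net_torque: float,
                        torque_tol: float = TORQUE_TOL) -> tuple[np.ndarray, bool]:
    """Exact minimiser of sum(a^2) s.t. gains . a = net_torque, 0 <= a <= 1.

    The KKT solution is a_i = clip(lam * g_i, 0, 1) for the active-sign
    gains; lam is found exactly by sorting the saturation breakpoints of
    the piecewise-linear achieved-torque function.  Returns (activations,
    feasible); when |net_torque| exceeds the one-sided capacity all
    same-sign actuators saturate at 1 (the failed-optimization case) and
    feasible is False.
    """
    gains = np.asarray(gains, dtype=float)
    a = np.zeros_like(gains)
    if abs(net_torque) <= torque_tol:
        return a, True
    sign = 1.0 if net_torque > 0 else -1.0
    idx = np.flatnonzero(gains * sign > 0)
    if idx.size == 0:
        return a, False
    g = gains[idx] * sign
    tau = net_torque * sign
    capacity = g.sum()
    if tau > capacity + torque_tol:
        a[idx] = 1.0
        return a, False
    # achieved(lam) = sum_i g_i min(1, lam g_i) is piecewise linear and
    # increasing; breakpoints at lam = 1/g_i
    order = np.argsort(-g)              # largest gain saturates first
    g_sorted = g[order]
    sat_cum = np.concatenate([[0.0], np.cumsum(g_sorted)])
    sq_cum = np.concatenate([[0.0], np.cumsum(g_sorted**2)])
    lam = None
    for k in range(len(g_sorted) + 1):
        # first k actuators saturated: achieved = sat_cum[k] + lam * (sq_rest)
        sq_rest = sq_cum[-1] - sq_cum[k]
        if sq_rest <= 0:
            lam = np.inf
            cand = np.inf
        else:
            cand = (tau - sat_cum[k]) / sq_rest
        lo = 1.0 / g_sorted[k - 1] if k > 0 else 0.0
        hi = 1.0 / g_sorted[k] if k < len(g_sorted) else np.inf
        if lo - 1e-15 <= cand <= hi + 1e-15:
            lam = cand
            break
    if lam is None:                      # numerical fallback: full saturation
        a[idx] = 1.0
        return a, False
    a[idx] = np.clip(lam * g, 0.0, 1.0)
    return a, True


def static_optimization_step(model: LimbModel, q: float, qdot: float, Te: float,
                             joint: str, direction: str,
                             posture: dict[str, float] | None = None) -> ActivationSolution:
    """Solve one static-optimization posture for a demanded torque.

    ``Te`` is the measured torque, positive in the movement direction;
    the equality constraint is imposed on the net joint torque (for a
    single-hinge trial this is mechanically identical to applying the
    measured torque as an external load).  Passive muscle contributions
    enter the constraint; antagonists end up at zero activation under the
    squared-activation objective.
    """
    if not np.isfinite(Te):
        raise ValueError("demanded torque must be finite")
    sign = movement_sign(joint, direction)
    terms = model.torque_terms(joint, q, qdot * sign, posture)
    if not terms:
        raise ValueError(f"no MTU crosses joint {joint!r}")
    names = [t[0] for t in terms]
    gains = np.array([t[1] for t in terms])
    passive = sum(t[2] for t in terms)
    net = Te * sign - passive
    a, feasible = solve_activation_qp(gains, net)
    achieved = float(gains @ a + passive)
    return ActivationSolution(
        activations=dict(zip(names, a.tolist())),
        objective=float(a @ a),
        feasible=feasible,
        achieved_torque=achieved,
    )


def simulate_trial(model: LimbModel, te_trace: TorqueTrace,
                   posture: dict[str, float] | None = None,
                   keep_solutions: bool = False) -> SimResult:
    """Simulate a full isokinetic repetition against a measured trace.

    Runs static optimization at every sample of the trace; the predicted
    torque equals the demand when feasible and the model's capacity when
    the MTUs saturate.  Aggregates the RMSE triple.
    """
    if te_trace.joint not in model.geometry.joints:
        raise ValueError(f"model has no joint {te_trace.joint!r}")
    sign = movement_sign(te_trace.joint, te_trace.direction)
    tp = np.empty(len(te_trace))
    feas = np.empty(len(te_trace), dtype=bool)
    solutions: list[ActivationSolution] = []
    for i in range(len(te_trace)):
        sol = static_optimization_step(
            model, float(te_trace.angle[i]),
            float(abs(te_trace.angular_velocity[i])),
            float(te_trace.torque[i]), te_trace.joint, te_trace.direction, posture)
        tp[i] = sol.achieved_torque * sign
        feas[i] = sol.feasible
        if keep_solutions:
            solutions.append(sol)
    r_abs, r_pct, r_bw = rmse(te_trace.torque, tp, body_mass=te_trace.body_mass or None)
    return SimResult(trace=te_trace, Tp=tp, feasible=feas,
                     RMSE_abs=r_abs, RMSE_pct=r_pct, RMSE_norm_bw=r_bw,
                     solutions=solutions)


def rmse(Te: np.ndarray, Tp: np.ndarray,
         body_mass: float | None = None) -> tuple[float, float, float]:
    """RMSE of predicted vs measured torque.

    Returns (RMSE in Nm, RMSE as % of peak |Te|, RMSE per kg body mass;
    nan when body mass is unknown).
    """
    Te = np.asarray(Te, dtype=float)
    Tp = np.asarray(Tp, dtype=float)
    if Te.shape != Tp.shape:
        raise ValueError("Te and Tp must have equal length")
    if Te.size == 0:
        raise ValueError("need at least one sample")
    r = float(np.sqrt(np.mean((Te - Tp) ** 2)))
    peak = float(np.max(np.abs(Te)))
    pct = 100.0 * r / peak if peak > 0 else np.nan
    bw = r / body_mass if body_mass else np.nan
    return r, pct, bw


def max_isokinetic_torque(obj: "SimResult | TorqueTrace") -> float:
    """Peak torque over the isokinetic phase (of Tp for a SimResult)."""
    series = obj.Tp if isinstance(obj, SimResult) else obj.torque
    if len(series) == 0:
        raise ValueError("empty torque series")
    return float(np.max(series))
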