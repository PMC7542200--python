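"""Cohort-level experiment driver and validation statistics.

Runs the five-variant comparison (subject-specific SS; generic elderly GE
and its operating-range-optimised GE_O; generic young GY and GY_O) over a
virtual cohort and six isokinetic movements, then applies the validation
statistics: one-way ANOVA with Tukey HSD on RMSE by model variant, linear
regression of RMSE on maximal isometric torque, and Spearman rank
correlation of predicted vs measured maximal isokinetic torques.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .architecture import ScalingContext, build_variant, VARIANTS
from .isokinetic_sim import max_isokinetic_torque, simulate_trial
from .limb_model import MOVEMENTS, build_limb
from .synth_cohort import (
    CohortConfig,
    build_true_limb,
    generate_dynamometer_trace,
    generic_slack_and_ranges,
    load_generic_dataset,
    sample_cohort,
    SCALING_REFERENCE_MASS,
)

__all__ = [
    "AnovaResult",
    "RegressionResult",
    "ExperimentConfig",
    "ExperimentResult",
    "one_way_anova",
    "regress_rmse_on_tmax",
    "spearman_rho",
    "run_experiment",
    "summarize_report",
]


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    tukey: pd.DataFrame     # pairwise: group_a, group_b, difference, q, p_adj


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    adj_r2: float
    p_slope: float
    n: int


def one_way_anova(groups: list[np.ndarray],
                  labels: list[str] | None = None,
                  compute_tukey: bool = True) -> AnovaResult:
    """Classical one-way ANOVA with Tukey HSD post hoc comparisons.

    Subjects are treated as independent observations per group; Tukey
    adjusted p values come from the studentized-range distribution
    (skipped when ``compute_tukey`` is False, e.g. in simulation loops
    that only need the omnibus F test).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need at least 2 groups with at least 2 observations each")
    labels = labels or [f"g{i}" for i in range(len(groups))]

    k = len(groups)
    n_total = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n_total - k
    ms_within = ss_within / df_w
    if ms_within == 0:
        F = 0.0 if ss_between == 0 else np.inf
        p = 1.0 if ss_between == 0 else 0.0
    else:
        F = (ss_between / df_b) / ms_within
        p = float(stats.f.sf(F, df_b, df_w))

    rows = []
    for i in range(k if compute_tukey else 0):
        for j in range(i + 1, k):
            diff = groups[i].mean() - groups[j].mean()
            se = math.sqrt(ms_within / 2 * (1 / len(groups[i]) + 1 / len(groups[j]))) \
                if ms_within > 0 else 0.0
            q = abs(diff) / se if se > 0 else (0.0 if diff == 0 else np.inf)
            p_adj = float(stats.studentized_range.sf(q, k, df_w)) if np.isfinite(q) else 0.0
            if q == 0.0:
                p_adj = 1.0
            rows.append({"group_a": labels[i], "group_b": labels[j],
                         "difference": diff, "q": q, "p_adj": p_adj})
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w, p=p,
                       tukey=pd.DataFrame(rows))


def regress_rmse_on_tmax(pairs: "np.ndarray | list[tuple[float, float]]") -> RegressionResult:
    """OLS of RMSE on maximal isometric torque, with adjusted R^2."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (Tmax, RMSE) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    res = stats.linregress(x, y)
    n = len(x)
    r2 = res.rvalue**2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            adj_r2=float(adj), p_slope=float(res.pvalue), n=n)


def spearman_rho(predicted: np.ndarray, measured: np.ndarray,
                 exact_max_n: int = 8) -> tuple[float, float]:
    """Spearman rank correlation with ties handled by average ranks.

    The p value is an exact permutation test for n <= ``exact_max_n`` and
    the t approximation otherwise.
    """
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if predicted.shape != measured.shape or predicted.ndim != 1:
        raise ValueError("predicted and measured must be equal-length 1D arrays")
    if len(predicted) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(predicted) == 0 or np.ptp(measured) == 0:
        return float("nan"), 1.0    # ranks undefined for a constant input
    rho, p_t = stats.spearmanr(predicted, measured)
    n = len(predicted)
    if n <= exact_max_n:
        rp = stats.rankdata(predicted)
        rm = stats.rankdata(measured)
        obs = abs(np.corrcoef(rp, rm)[0, 1])
        count = 0
        total = 0
        for perm in permutations(rm):
            r = abs(np.corrcoef(rp, np.asarray(perm))[0, 1])
            count += r >= obs - 1e-12
            total += 1
        return float(rho), count / total
    return float(rho), float(p_t)


@dataclass
class ExperimentConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    variants: tuple[str, ...] = VARIANTS
    angular_velocity: float = 60.0      # deg/s
    n_samples: int = 40                 # samples per isokinetic repetition
    scale_all_generic: bool = False     # also mass-scale GE/GY Fmax


@dataclass
class ExperimentResult:
    table: pd.DataFrame                             # subject x variant x movement rows
    anova: dict[str, AnovaResult]                   # per movement
    regressions: dict[tuple[str, str], RegressionResult]  # (variant, movement)
    spearman: pd.DataFrame                          # variant x movement rho, p


def run_experiment(config: ExperimentConfig | None = None) -> ExperimentResult:
    """The full cohort experiment.

    For every subject, builds the five model variants on the subject's own
    (shared) limb geometry, simulates all six isokinetic movements against
    the subject's emulated dynamometer traces, and aggregates the RMSE
    table, per-movement ANOVA, RMSE-vs-Tmax regressions and the Spearman
    table of predicted vs measured maximal torques.  Fully seeded.
    """
    config = config or ExperimentConfig()
    subjects = sample_cohort(config.cohort)
    rng = np.random.default_rng(config.cohort.rng_seed + 1)

    ge = load_generic_dataset("GE")
    gy = load_generic_dataset("GY")
    generic_arch = {"GE": generic_slack_and_ranges(ge)[0], "GY": generic_slack_and_ranges(gy)[0]}
    generic_ranges = {"GE": generic_slack_and_ranges(ge)[1], "GY": generic_slack_and_ranges(gy)[1]}

    rows = []
    for subject in subjects:
        true_limb = build_true_limb(subject)
        geometry = true_limb.geometry
        target_ranges = {m: geometry.mtu_length_range(m) for m in subject.muscles}

        # measured data: isokinetic traces and isometric maxima per movement
        traces = {}
        tmax_iso = {}
        for joint, direction, sign in MOVEMENTS:
            traces[(joint, direction)] = generate_dynamometer_trace(
                subject, true_limb, joint, direction,
                angular_velocity=config.angular_velocity,
                n_samples=config.n_samples,
                torque_noise_sd=config.cohort.torque_noise_sd, rng=rng)
            rom = subject.joint_rom[(joint, direction)]
            sweep = [true_limb.joint_torque_capacity(joint, direction, q, 0.0) * sign
                     for q in np.linspace(rom[0], rom[1], 11)]
            noise = 1.0 + (rng.normal(0.0, config.cohort.torque_noise_sd)
                           if config.cohort.torque_noise_sd > 0 else 0.0)
            tmax_iso[(joint, direction)] = max(sweep) * noise

        subj_arch = {m: true_limb.mtus[m].architecture for m in subject.muscles}
        for variant in config.variants:
            source = variant[:2] if variant != "SS" else None
            if variant == "SS":
                arch = build_variant(subj_arch, "SS")
            else:
                ctx = ScalingContext(subject.body_mass, SCALING_REFERENCE_MASS[source])
                arch = build_variant(
                    subj_arch, variant, generic=generic_arch[source], ctx=ctx,
                    reference_ranges=generic_ranges[source],
                    target_ranges=target_ranges,
                    scale_all_generic=config.scale_all_generic)
            model = build_limb(arch, subject.body_mass, geometry=geometry)
            for joint, direction, _ in MOVEMENTS:
                trace = traces[(joint, direction)]
                sim = simulate_trial(model, trace)
                rows.append({
                    "subject_id": subject.subject_id, "variant": variant,
                    "joint": joint, "direction": direction,
                    "movement": f"{joint}_{direction}",
                    "RMSE_abs": sim.RMSE_abs, "RMSE_pct": sim.RMSE_pct,
                    "RMSE_norm_bw": sim.RMSE_norm_bw,
                    "Tmax_measured": max_isokinetic_torque(trace),
                    "Tmax_predicted": max_isokinetic_torque(sim),
                    "Tmax_isometric": tmax_iso[(joint, direction)],
                    "frac_feasible": float(np.mean(sim.feasible)),
                })
    table = pd.DataFrame(rows)

    anova = {}
    if len(config.variants) >= 2:
        for movement, sub in table.groupby("movement"):
            groups = [sub.loc[sub.variant == v, "RMSE_pct"].to_numpy() for v in config.variants]
            anova[movement] = one_way_anova(groups, labels=list(config.variants))

    regressions = {}
    for (variant, movement), sub in table.groupby(["variant", "movement"]):
        pairs = np.column_stack([sub["Tmax_isometric"], sub["RMSE_pct"]])
        try:
            regressions[(variant, movement)] = regress_rmse_on_tmax(pairs)
        except ValueError:
            continue

    sp_rows = []
    for (variant, movement), sub in table.groupby(["variant", "movement"]):
        if len(sub) < 3:
            continue
        rho, p = spearman_rho(sub["Tmax_predicted"].to_numpy(),
                              sub["Tmax_measured"].to_numpy())
        sp_rows.append({"variant": variant, "movement": movement, "rho": rho, "p": p})
    spearman = pd.DataFrame(sp_rows)

    return ExperimentResult(table=table, anova=anova, regressions=regressions,
                            spearman=spearman)


def summarize_report(result: ExperimentResult) -> str:
    """Plain-text report: mean +/- SE RMSE per variant per movement."""
    lines = ["RMSE (% of max Te), mean +/- SE per model variant", ""]
    for movement, sub in result.table.groupby("movement"):
        lines.append(movement)
        for variant, vs in sub.groupby("variant"):
            vals = vs["RMSE_pct"]
            lines.append(f"  {variant:5s} {vals.mean():6.2f} +/- {vals.sem():5.2f}")
        a = result.anova.get(movement)
        if a is not None:
            lines.append(f"  ANOVA F({a.df_between},{a.df_within}) = {a.F:.2f}, p = {a.p:.3g}")
        lines.append("")
    lines.append("Spearman rho, predicted vs measured max isokinetic torque")
    for _, r in result.spearman.iterrows():
        lines.append(f"  {r.variant:5s} {r.movement:22s} rho = {r.rho:6.3f}  p = {r.p:.3g}")
    return "\n".join(lines)
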