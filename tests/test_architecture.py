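"""Force-generating property formulas, slack estimation and variants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myotorque.architecture import (
    MTUArchitecture,
    ScalingContext,
    build_variant,
    estimate_tendon_slack,
    fmax_from_pcsa,
    optimal_fibre_length,
    optimize_generic_operating_range,
    pcsa,
    scale_generic_fmax,
    split_fmax,
)


class TestFormulas:
    @pytest.mark.parametrize("lf_raw, ls, expected", [
        (54.0, 2.7, 54.0),        # identity at the generic sarcomere length
        (54.0, 3.0, 48.6),
        (100.0, 2.16, 125.0),
    ])
    def test_optimal_fibre_length(self, lf_raw, ls, expected):
        assert optimal_fibre_length(lf_raw, ls) == pytest.approx(expected, abs=1e-3)

    @pytest.mark.parametrize("vm, theta, lf, expected", [
        (1000.0, 0.0, 10.0, 100.0),
        (27000.0, 60.0, 135.0, 100.0),
    ])
    def test_pcsa(self, vm, theta, lf, expected):
        assert pcsa(vm, theta, lf) == pytest.approx(expected, abs=1e-3)

    def test_pcsa_vanishes_toward_90_degrees(self):
        assert pcsa(1000.0, 89.999, 10.0) < 1e-2
        with pytest.raises(ValueError):
            pcsa(1000.0, 90.0, 10.0)

    def test_fmax(self):
        assert fmax_from_pcsa(100.0, 0.3) == pytest.approx(30.0, abs=1e-3)
        assert fmax_from_pcsa(57.0, 1.0) == pytest.approx(57.0)
        assert fmax_from_pcsa(0.0) == 0.0

    @pytest.mark.parametrize("ms, mg, factor", [
        (75.3, 75.3, 1.0),
        (8.0, 1.0, 4.0),          # 8^(2/3) = 4
    ])
    def test_mass_scaling(self, ms, mg, factor):
        ctx = ScalingContext(M_subject=ms, M_generic=mg)
        assert scale_generic_fmax(100.0, ctx) == pytest.approx(100.0 * factor, abs=1e-3)

    @given(st.floats(1.0, 200.0), st.floats(1.0, 200.0))
    @settings(derandomize=True, max_examples=50)
    def test_mass_scaling_homogeneous_degree_two_thirds(self, m, k):
        base = scale_generic_fmax(50.0, ScalingContext(m, 70.0))
        scaled = scale_generic_fmax(50.0, ScalingContext(m * k, 70.0))
        assert scaled == pytest.approx(base * k ** (2 / 3), rel=1e-9)

    @given(st.floats(10.0, 80.0), st.floats(5.0, 85.0), st.floats(20.0, 200.0))
    @settings(derandomize=True, max_examples=50)
    def test_pcsa_decreasing_in_pennation_and_fibre_length(self, theta, dtheta, lf):
        theta2 = min(theta + dtheta * 0.1, 89.0)
        assert pcsa(1e5, theta2, lf) < pcsa(1e5, theta, lf) or theta2 == theta
        assert pcsa(1e5, theta, lf * 1.1) < pcsa(1e5, theta, lf)

    def test_split_fmax(self):
        assert split_fmax(90.0, 3) == [30.0, 30.0, 30.0]
        assert split_fmax(80.0, 2) == [40.0, 40.0]
        assert sum(split_fmax(77.7, 5)) == pytest.approx(77.7)
        with pytest.raises(ValueError):
            split_fmax(10.0, 0)


class TestMTUArchitecture:
    def test_consistency_enforced(self):
        arch = MTUArchitecture.from_measurements("m", Vm=1000.0, Lf_raw=10.0,
                                                 Ls=2.7, pennation=0.0)
        assert arch.PCSA == pytest.approx(100.0)
        assert arch.Fmax == pytest.approx(30.0)
        with pytest.raises(ValueError):
            MTUArchitecture(muscle="m", Vm=1000.0, Lf_raw=10.0, Ls=2.7, Lf=10.0,
                            pennation=0.0, PCSA=55.0, Fmax=30.0)


class TestTendonSlack:
    def test_constant_moment_arm_closed_form(self):
        lengths = np.linspace(290.0, 310.0, 21)     # mid 300
        lts = estimate_tendon_slack(lengths, Lf=45.0, pennation=0.0)
        assert lts == pytest.approx(300.0 - 45.0, abs=1e-3)

    def test_pennation_geometry(self):
        lengths = np.linspace(290.0, 310.0, 21)
        lts = estimate_tendon_slack(lengths, Lf=45.0, pennation=30.0)
        assert lts == pytest.approx(300.0 - 45.0 * np.cos(np.radians(30.0)), abs=1e-3)

    def test_degenerate_point_rom(self):
        lts = estimate_tendon_slack([300.0], Lf=45.0, pennation=0.0)
        assert lts == pytest.approx(255.0, abs=1e-3)

    def test_infeasible_fibre_longer_than_mtu(self):
        with pytest.raises(ValueError):
            estimate_tendon_slack([50.0, 60.0], Lf=80.0, pennation=0.0)

    def test_matches_grid_oracle_on_random_geometries(self):
        # independent oracle: exhaustive 0.01 mm grid over the stated objective
        rng = np.random.default_rng(12345)
        for _ in range(10):
            lf = rng.uniform(30.0, 120.0)
            theta = rng.uniform(0.0, 30.0)
            mid = rng.uniform(1.5, 4.0) * lf
            half = rng.uniform(0.05, 0.3) * lf
            lengths = np.linspace(mid - half, mid + half, 21)
            got = estimate_tendon_slack(lengths, lf, theta)

            w = lf * np.sin(np.radians(theta))
            grid = np.arange(1e-3, mid, 0.01)
            l_mid = 0.5 * (lengths.min() + lengths.max())

            def cost(lts):
                proj = np.maximum(lengths[None, :] - lts[:, None], 1e-9)
                ltil = np.sqrt(w**2 + proj**2) / lf
                pmid = np.maximum(l_mid - lts, 1e-9)
                mid_l = np.sqrt(w**2 + pmid**2) / lf
                band = np.clip(ltil - 1.5, 0, None) + np.clip(0.5 - ltil, 0, None)
                return (mid_l - 1.0) ** 2 + (band**2).sum(axis=1)

            best = grid[np.argmin(cost(grid))]
            assert abs(got - best) <= 0.011


class TestOperatingRangeOptimization:
    def _ref(self):
        arch = MTUArchitecture.from_measurements("m", Vm=2e5, Lf_raw=60.0, Ls=2.7,
                                                 pennation=15.0)
        arch = MTUArchitecture(**{**arch.__dict__, "Lts": 250.0})
        return arch

    def test_identity_mapping(self):
        ref = self._ref()
        lf, lts = optimize_generic_operating_range(ref, (290.0, 320.0), (290.0, 320.0))
        assert lf == pytest.approx(ref.Lf, rel=1e-6)
        assert lts == pytest.approx(ref.Lts, rel=1e-6)

    def test_similarity_scaling(self):
        ref = self._ref()
        tgt = (290.0 * 1.1, 320.0 * 1.1)
        lf, lts = optimize_generic_operating_range(ref, (290.0, 320.0), tgt)
        assert lf == pytest.approx(ref.Lf * 1.1, abs=1e-6 * ref.Lf)
        assert lts == pytest.approx(ref.Lts * 1.1, abs=1e-6 * ref.Lts)

    def test_trajectory_reproduced(self):
        from myotorque.architecture import _norm_fibre_length
        ref = self._ref()
        ref_range, tgt_range = (290.0, 320.0), (275.0, 331.0)
        lf, lts = optimize_generic_operating_range(ref, ref_range, tgt_range)
        rel = np.linspace(0, 1, 25)
        ref_traj = _norm_fibre_length(ref_range[0] + rel * np.ptp(ref_range),
                                      ref.Lts, ref.Lf, ref.pennation)
        tgt_traj = _norm_fibre_length(tgt_range[0] + rel * np.ptp(tgt_range),
                                      lts, lf, ref.pennation)
        assert np.sqrt(np.mean((ref_traj - tgt_traj) ** 2)) < 1e-3


class TestBuildVariant:
    def test_ss_is_the_subject_architecture(self):
        arch = MTUArchitecture.from_measurements("m", Vm=1e5, Lf_raw=50.0, Ls=2.7,
                                                 pennation=10.0)
        out = build_variant({"m": arch}, "SS")
        assert out["m"] is arch or out["m"] == arch

    def test_generic_fmax_not_scaled_but_optimised_is(self):
        g = MTUArchitecture.from_measurements("m", Vm=1e5, Lf_raw=50.0, Ls=2.7,
                                              pennation=10.0)
        g = MTUArchitecture(**{**g.__dict__, "Lts": 250.0})
        subj = {"m": g}
        ctx = ScalingContext(M_subject=60.0, M_generic=75.3)
        ge = build_variant(subj, "GE", generic={"m": g}, ctx=ctx)
        assert ge["m"].Fmax == pytest.approx(g.Fmax)
        geo = build_variant(subj, "GE_O", generic={"m": g}, ctx=ctx,
                            reference_ranges={"m": (290.0, 320.0)},
                            target_ranges={"m": (290.0, 320.0)})
        assert geo["m"].Fmax == pytest.approx(g.Fmax * (60.0 / 75.3) ** (2 / 3), rel=1e-9)
        # identity ranges: Lf/Lts pass through the optimisation unchanged
        assert geo["m"].Lf == pytest.approx(g.Lf, rel=1e-6)
        assert geo["m"].Lts == pytest.approx(g.Lts, rel=1e-6)

    def test_missing_muscle_is_an_error(self):
        arch = MTUArchitecture.from_measurements("m", Vm=1e5, Lf_raw=50.0, Ls=2.7,
                                                 pennation=10.0)
        with pytest.raises(KeyError):
            build_variant({"m": arch}, "GE", generic={})
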