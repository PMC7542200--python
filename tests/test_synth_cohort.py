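"""Phantom fields, cohort sampling and emulated dynamometer traces."""

import numpy as np
import pytest

from myotorque.dti_tractography import compute_fa
from myotorque.limb_model import build_limb
from myotorque.synth_cohort import (
    CohortConfig,
    MuscleSpec,
    analytic_fibre_direction,
    build_true_limb,
    cohort_to_csv,
    generate_dynamometer_trace,
    load_generic_dataset,
    make_tensor_volume,
    sample_cohort,
)

from conftest import make_phantom, zero_noise_cohort
from test_limb_model import toy_arch


def principal_direction(tensor):
    vals, vecs = np.linalg.eigh(tensor)
    return vecs[:, 2]


class TestPhantoms:
    def test_fusiform_eigenvectors_parallel_to_line_of_action(self):
        spec, vol, mask = make_phantom(0)
        vecs = np.array([principal_direction(t) for t in vol.grid[mask][::50]])
        cos = np.abs(vecs @ spec.line_of_action)
        assert np.all(cos > 1.0 - 1e-9)

    @pytest.mark.parametrize("theta", [10.0, 20.0])
    def test_unipennate_eigenvector_angle(self, theta):
        spec, vol, mask = make_phantom(theta)
        vecs = np.array([principal_direction(t) for t in vol.grid[mask][::50]])
        ang = np.degrees(np.arccos(np.clip(np.abs(vecs @ spec.line_of_action), 0, 1)))
        assert np.allclose(ang, theta, atol=1e-6)

    def test_inside_fa_matches_request(self):
        spec, vol, mask = make_phantom(20, fa_inside=0.7)
        idx = np.argwhere(mask)[0]
        assert compute_fa(vol.grid[tuple(idx)]) == pytest.approx(0.70, abs=1e-6)
        out = np.argwhere(~mask)[0]
        assert compute_fa(vol.grid[tuple(out)]) == pytest.approx(spec.fa_outside, abs=1e-6)

    def test_bipennate_has_two_mirrored_compartments(self):
        spec = MuscleSpec(name="bp", shape="bipennate", belly_length=60.0,
                          volume_true=40000.0, fibre_length_true=45.0,
                          pennation_true=20.0)
        vol, mask = make_tensor_volume(spec, (1.0, 1.0, 1.0), rng_seed=1)
        loa = spec.line_of_action
        angles = []
        for t in vol.grid[mask][::100]:
            v = principal_direction(t)
            angles.append(np.degrees(np.arccos(abs(float(v @ loa)))))
        assert np.allclose(angles, 20.0, atol=1e-6)
        # both fibre orientations present
        dots = np.array([principal_direction(t) @ analytic_fibre_direction(spec, compartment=+1)
                         for t in vol.grid[mask][::100]])
        assert (np.abs(dots) > 1 - 1e-9).any() and (np.abs(dots) < 1 - 1e-3).any()

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            MuscleSpec(name="bad", shape="fusiform", belly_length=40.0,
                       volume_true=1e4, fibre_length_true=50.0, pennation_true=0.0)
        with pytest.raises(ValueError):
            MuscleSpec(name="bad", shape="unipennate", belly_length=60.0,
                       volume_true=1e4, fibre_length_true=50.0, pennation_true=20.0,
                       fa_inside=0.3, fa_outside=0.5)

    def test_explicit_volume_too_small_rejected(self):
        spec = MuscleSpec(name="m", shape="fusiform", belly_length=60.0,
                          volume_true=4e4, fibre_length_true=50.0, pennation_true=0.0)
        with pytest.raises(ValueError):
            make_tensor_volume(spec, (1.0, 1.0, 1.0), volume_shape=(5, 5, 5))
        with pytest.raises(ValueError):
            make_tensor_volume(spec, (0.0, 1.0, 1.0))


class TestGenericDatasets:
    def test_elderly_weaker_shorter_less_pennate_than_young(self):
        ge = load_generic_dataset("GE").table
        gy = load_generic_dataset("GY").table
        assert set(ge) == set(gy)
        for name in ge:
            assert ge[name].Fmax < gy[name].Fmax
            assert ge[name].Vm < gy[name].Vm
            assert ge[name].Lf < gy[name].Lf
            assert ge[name].pennation < gy[name].pennation

    def test_broad_origin_muscles_are_multi_actuator(self):
        gy = load_generic_dataset("GY").table
        assert gy["gluteus_maximus"].n_actuators == 3
        assert gy["adductor_magnus"].n_actuators == 2


class TestCohortSampling:
    def test_zero_noise_reproduces_template(self):
        template = load_generic_dataset("GY")
        subjects = sample_cohort(zero_noise_cohort(n=3))
        for s in subjects:
            assert s.body_mass == pytest.approx(template.source_body_mass)
            for name, arch in s.muscles.items():
                assert arch.Vm == pytest.approx(template.table[name].Vm, rel=1e-12)
                assert arch.Lf == pytest.approx(template.table[name].Lf, rel=1e-12)

    def test_seed_determinism(self):
        cfg = CohortConfig(n_subjects=4, rng_seed=9)
        a = sample_cohort(cfg)
        b = sample_cohort(cfg)
        for sa, sb in zip(a, b):
            assert sa.body_mass == sb.body_mass
            for name in sa.muscles:
                assert sa.muscles[name] == sb.muscles[name]

    def test_sample_mean_near_template(self):
        # law-of-large-numbers check on the multiplicative noise model
        template = load_generic_dataset("GY")
        cfg = CohortConfig(n_subjects=200, rng_seed=1, noise_sd_volume=0.1,
                           noise_sd_fibre=0.0, noise_sd_pennation=0.0,
                           torque_noise_sd=0.0, mass_sd_kg=0.0)
        subjects = sample_cohort(cfg)
        vm = np.array([s.muscles["soleus"].Vm for s in subjects])
        se = vm.std(ddof=1) / np.sqrt(len(vm))
        assert abs(vm.mean() - template.table["soleus"].Vm) < 3 * se

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_subjects=1)

    def test_cohort_csv_roundtrip(self, tmp_path):
        import pandas as pd
        subjects = sample_cohort(CohortConfig(n_subjects=2, rng_seed=3))
        path = tmp_path / "cohort.csv"
        cohort_to_csv(subjects, str(path))
        df = pd.read_csv(path)
        assert len(df) == 2 * len(subjects[0].muscles)
        row = df[(df.subject_id == "S01") & (df.muscle == "soleus")].iloc[0]
        assert row.Vm_mm3 == pytest.approx(subjects[0].muscles["soleus"].Vm)


@pytest.fixture(scope="module")
def subject_and_limb():
    subject = sample_cohort(zero_noise_cohort(n=2))[0]
    return subject, build_true_limb(subject)


class TestDynamometerTraces:
    def test_angle_sweeps_rom_at_constant_velocity(self, subject_and_limb):
        subject, limb = subject_and_limb
        trace = generate_dynamometer_trace(subject, limb, "knee", "extension",
                                           angular_velocity=60.0, n_samples=30)
        rom = subject.joint_rom[("knee", "extension")]
        assert trace.angle[0] == rom[0] and trace.angle[-1] == rom[1]
        assert np.allclose(np.diff(trace.angle) / np.diff(trace.time), 60.0)

    def test_doubling_fmax_doubles_noiseless_trace(self, subject_and_limb):
        subject, limb = subject_and_limb
        t1 = generate_dynamometer_trace(subject, limb, "ankle", "plantarflexion",
                                        n_samples=10)
        doubled = {n: m.architecture.with_fmax(2 * m.architecture.Fmax)
                   for n, m in limb.mtus.items()}
        limb2 = build_limb(doubled, subject.body_mass, geometry=limb.geometry)
        t2 = generate_dynamometer_trace(subject, limb2, "ankle", "plantarflexion",
                                        n_samples=10)
        assert np.allclose(t2.torque, 2 * t1.torque, rtol=1e-9)

    def test_noise_seed_determinism(self, subject_and_limb):
        subject, limb = subject_and_limb
        t1 = generate_dynamometer_trace(subject, limb, "hip", "flexion",
                                        n_samples=10, torque_noise_sd=0.05, rng=4)
        t2 = generate_dynamometer_trace(subject, limb, "hip", "flexion",
                                        n_samples=10, torque_noise_sd=0.05, rng=4)
        assert np.array_equal(t1.torque, t2.torque)

    def test_single_muscle_hand_value(self):
        # Fmax 100 N at ~50 mm constant moment arm, isometric near-optimal:
        # noiseless torque approaches F * r = 5 Nm
        from test_isokinetic_sim import single_muscle_model
        model = single_muscle_model()
        cap = model.joint_torque_capacity("j", "extension", 0.0, 0.0, posture={"j": 0.0})
        assert cap == pytest.approx(5.0, rel=1e-3)
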