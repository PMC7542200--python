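"""Shared fixtures: expensive cohort experiments and phantoms run once."""

import numpy as np
import pytest

from myotorque.cohort_stats import ExperimentConfig, run_experiment
from myotorque.synth_cohort import CohortConfig, MuscleSpec, make_tensor_volume


def zero_noise_cohort(n=10, seed=42):
    return CohortConfig(n_subjects=n, rng_seed=seed, noise_sd_volume=0.0,
                        noise_sd_fibre=0.0, noise_sd_pennation=0.0,
                        torque_noise_sd=0.0, mass_sd_kg=0.0)


@pytest.fixture(scope="session")
def zero_noise_experiment():
    """SS-only experiment on a 10-subject zero-noise cohort (closure)."""
    config = ExperimentConfig(cohort=zero_noise_cohort(), variants=("SS",))
    return run_experiment(config)


@pytest.fixture(scope="session")
def arch_noise_experiment():
    """All five variants on a cohort with 5% architecture noise."""
    cohort = CohortConfig(n_subjects=10, rng_seed=42, noise_sd_volume=0.05,
                          noise_sd_fibre=0.05, noise_sd_pennation=0.05)
    return run_experiment(ExperimentConfig(cohort=cohort))


@pytest.fixture(scope="session")
def default_experiment():
    """The default seeded experiment (n=10, default noise, all variants)."""
    return run_experiment(ExperimentConfig())


def make_phantom(pennation, fibre_length=50.0, volume=40000.0, belly_length=60.0,
                 voxel=1.0, fa_inside=0.7, fa_outside=0.1, seed=7):
    """A recovery phantom with a slightly off-axis line of action (so no
    slab face is grid-aligned and voxel counting is unbiased)."""
    shape = "fusiform" if pennation == 0 else "unipennate"
    spec = MuscleSpec(name=f"phantom_{pennation}", shape=shape,
                      belly_length=belly_length, volume_true=volume,
                      fibre_length_true=fibre_length, pennation_true=float(pennation),
                      line_of_action=np.array([0.22, 0.13, 1.0]),
                      fa_inside=fa_inside, fa_outside=fa_outside)
    vol, mask = make_tensor_volume(spec, (voxel, voxel, voxel), rng_seed=seed)
    return spec, vol, mask


@pytest.fixture(scope="session")
def recovery_phantoms():
    """Phantoms spanning pennation 0-30 degrees, tracked at 500 seeds."""
    from myotorque.dti_tractography import (
        TractographyParams, constrain_tracts, summarize_architecture, track_fibres,
    )

    results = {}
    for theta in (0, 10, 20, 30):
        spec, vol, mask = make_phantom(theta)
        params = TractographyParams(max_tract_length=spec.belly_length,
                                    n_seeds=500, rng_seed=7)
        raw = track_fibres(vol, mask, params)
        kept = constrain_tracts(raw, mask, vol, params.min_tract_length)
        summary = summarize_architecture(kept, spec.line_of_action, mask, vol.spacing)
        results[theta] = (spec, vol, mask, kept, summary)
    return results
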