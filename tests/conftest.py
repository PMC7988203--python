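import warnings

import numpy as np
import pytest

from vvrkit import CohortSpec, REFERENCE, generate_cohort, simulate

warnings.filterwarnings("ignore", message=".*poorly conditioned.*")


@pytest.fixture(scope="session")
def reference_trace():
    """Deterministic (noise-free) reference simulation, 30 s."""
    return simulate(REFERENCE.with_(sigma_T=0.0), duration=30.0)


@pytest.fixture(scope="session")
def noisy_trace():
    """Reference simulation with per-cycle threshold noise, 60 s."""
    return simulate(REFERENCE.with_(seed=7), duration=60.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-episode cohort used by the end-to-end tests."""
    spec = CohortSpec(n_vvr=3, n_normal=3, seed=42)
    return spec, generate_cohort(spec)


def make_beats(rng, n=30):
    """Random but valid beat series for property tests."""
    from vvrkit import BeatSeries

    isi = rng.uniform(0.12, 0.3, n - 1)
    times = np.concatenate([[0.0], np.cumsum(isi)])
    sbp = 120 + rng.normal(0, 5, n)
    dbp = sbp - rng.uniform(20, 40, n)
    return BeatSeries(peak_times=times, sbp=sbp, dbp=dbp)
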