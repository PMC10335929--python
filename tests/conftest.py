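import pytest

from phasekit.simdata import SimConfig, simulate_panel
from phasekit.workflows import run_phasing_experiment


@pytest.fixture(scope="session")
def small_panel():
    """A small genealogy panel reused by read-only tests."""
    cfg = SimConfig(n_founders=40, n_samples=120, n_sites=1000, seed=11)
    truth, genotypes, records = simulate_panel(cfg)
    return cfg, truth, genotypes, records


@pytest.fixture(scope="session")
def experiment_cache():
    """Phasing experiments keyed by (n_samples, n_sites, seed).

    The large-cohort runs are shared across the accuracy, monotonicity and
    confidence-filtering acceptance tests so each (n, seed) is phased once.
    """
    cache = {}

    def get(n_samples, n_sites, seed):
        key = (n_samples, n_sites, seed)
        if key not in cache:
            cache[key] = run_phasing_experiment(n_samples, n_sites, seed)
        return cache[key]

    return get
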