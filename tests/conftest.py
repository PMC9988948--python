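import pytest

from refqual.pipeline import score_cohort
from refqual.simulate import SimulationParams, simulate_cohort, worked_micro_cohort

#: One seed for every session-scoped simulated cohort.
SIM_SEED = 1234


@pytest.fixture(scope="session")
def micro(tmp_path_factory):
    """The deterministic 3-species golden cohort, generated and scored once."""
    outdir = tmp_path_factory.mktemp("micro")
    cohort = worked_micro_cohort(outdir)
    result = score_cohort(cohort.manifest_path)
    return cohort, result


@pytest.fixture(scope="session")
def sim_small(tmp_path_factory):
    """A cheap 8-species cohort for structural/round-trip tests."""
    outdir = tmp_path_factory.mktemp("sim_small")
    params = SimulationParams(n_species=8, n_samples_per_species=3, seed=SIM_SEED)
    cohort = simulate_cohort(params, outdir)
    result = score_cohort(cohort.manifest_path)
    return cohort, result


@pytest.fixture(scope="session")
def sim50(tmp_path_factory):
    """The full-scale synthetic cohort (50 species x 10 samples)."""
    outdir = tmp_path_factory.mktemp("sim50")
    params = SimulationParams(n_species=50, n_samples_per_species=10, seed=SIM_SEED)
    cohort = simulate_cohort(params, outdir)
    result = score_cohort(cohort.manifest_path)
    return cohort, result
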