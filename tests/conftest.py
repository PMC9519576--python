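import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mitosleep.sleep_metrics import phenotype_table
from mitosleep.synthetic_data import (
    SimScenario,
    assemble_simulated,
    published_calibration,
    simulate_experiment,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def small_scenario(**overrides) -> SimScenario:
    """A reduced experiment for fast tests: 4 lines, 2 blocks, 1 day."""
    kw = dict(
        n_lines_per_panel=4,
        n_per_sex_line=4,
        n_blocks=2,
        days=1,
        death_prob=0.0,
    )
    kw.update(overrides)
    return SimScenario(**kw)


@pytest.fixture(scope="session")
def calibrated_experiment():
    """Full-size calibrated experiment (480 flies, 3 days), simulated once."""
    scenario = published_calibration()
    records, meta, truth = simulate_experiment(scenario, seed=1)
    series = assemble_simulated(records, meta, scenario)
    pheno, qc_log = phenotype_table(series)
    return {
        "scenario": scenario,
        "records": records,
        "meta": meta,
        "truth": truth,
        "series": series,
        "phenotypes": pheno,
        "qc_log": qc_log,
    }


@pytest.fixture(scope="session")
def small_experiment():
    scenario = small_scenario()
    records, meta, truth = simulate_experiment(scenario, seed=3)
    series = assemble_simulated(records, meta, scenario)
    return scenario, records, meta, truth, series
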