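import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from plexquant.ingest import DEFAULT_CHANNEL_MAP, PSMTable, assign_uniqueness, filter_psms
from plexquant.simulate import SimulationConfig, generate_experiment

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_psm_table(rows, pool_id="pool1", channel_map=None):
    """Build a small in-memory PSM table from (seq, proteins, i127, i128, i129, i130) tuples."""
    df = pd.DataFrame(
        [
            {
                "spectrum_id": f"{pool_id}_s{i}",
                "peptide_sequence": seq,
                "protein_ids": tuple(prots),
                "ion_score": 50.0,
                "qvalue": 0.001,
                "intensity_127": i127,
                "intensity_128": i128,
                "intensity_129": i129,
                "intensity_130": i130,
            }
            for i, (seq, prots, i127, i128, i129, i130) in enumerate(rows)
        ]
    )
    return PSMTable(df=df, pool_id=pool_id, channel_map=channel_map or dict(DEFAULT_CHANNEL_MAP))


@pytest.fixture(scope="session")
def default_experiment():
    """One noisy synthetic experiment at the benchmark conditions."""
    return generate_experiment(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def noise_free_experiment():
    """Noise-free experiment: fold changes propagate exactly."""
    cfg = SimulationConfig(cv_reporter=0.0, seed=5)
    return generate_experiment(cfg)


@pytest.fixture(scope="session")
def prepared_noise_free(noise_free_experiment):
    tables, annotation, truth = noise_free_experiment
    tables = assign_uniqueness([filter_psms(t) for t in tables])
    return tables, annotation, truth
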