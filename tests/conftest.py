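import numpy as np
import pytest

from plvcpm.synthetic import PlantedModel, cohort_z_scores, gen_cohort, gen_connectomes
from plvcpm.validation import Dataset


def planted_dataset(
    n_hc=75,
    n_mdd=45,
    effect_size=0.1,
    noise_sd=0.05,
    n_pos=33,
    n_neg=5,
    seed=0,
) -> tuple[Dataset, PlantedModel]:
    """Cohort + connectomes with a planted edge-score signal, as a Dataset."""
    cohort = gen_cohort(n_hc, n_mdd, seed=seed)
    model = PlantedModel.random(
        n_pos=n_pos, n_neg=n_neg, effect_size=effect_size, noise_sd=noise_sd, seed=seed + 1
    )
    connectomes = gen_connectomes(cohort, model, seed=seed + 2)
    ds = Dataset(
        edges=np.vstack([c.edge_vector() for c in connectomes]),
        z_scores=cohort_z_scores(cohort),
        groups=np.array([s.group for s in cohort]),
        subject_ids=[s.subject_id for s in cohort],
    )
    return ds, model


@pytest.fixture(scope="session")
def signal_dataset():
    """Strong planted signal, N=120 (reused read-only across tests)."""
    return planted_dataset(effect_size=0.1, noise_sd=0.05, seed=11)


@pytest.fixture(scope="session")
def null_dataset():
    """No planted signal, N=120."""
    return planted_dataset(effect_size=0.0, noise_sd=0.05, seed=13)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
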