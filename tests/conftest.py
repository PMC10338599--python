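import numpy as np
import pytest

from plcalds import CohortConfig, generate_cohort
from plcalds.dictionary import DictionaryTensor


def random_dictionary_3d(F, S, A, seed=0):
    rng = np.random.default_rng(seed)
    templates = rng.dirichlet(np.ones(F) * 0.5, size=(S, A)).transpose(2, 0, 1)
    return DictionaryTensor(templates=templates,
                            symptom_names=[f"s{i}" for i in range(S)])


def random_dictionary_4d(F, M, S, A, seed=0):
    rng = np.random.default_rng(seed)
    templates = rng.dirichlet(np.ones(F) * 0.5, size=(M, S, A)).transpose(3, 0, 1, 2)
    return DictionaryTensor(templates=templates,
                            symptom_names=[f"s{i}" for i in range(S)],
                            season_names=("spring", "summer", "autumn", "winter"))


def random_activations(S, A, T, seed=0, M=None):
    rng = np.random.default_rng(seed)
    p_s = rng.dirichlet(np.ones(S), size=T).T
    p_a = rng.dirichlet(np.ones(A), size=(S, T)).transpose(2, 0, 1)
    p_m = rng.dirichlet(np.ones(M), size=(S, T)).transpose(2, 0, 1) if M else None
    return p_s, p_a, p_m


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortConfig(n_participants=3, n_days=62, seed=7)
    return cfg, generate_cohort(cfg)
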