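import numpy as np
import pytest

import tcmrec as tr
from tcmrec.fixtures import load_sample_corpus


@pytest.fixture(scope="session")
def sample_cases():
    return load_sample_corpus()


@pytest.fixture(scope="session")
def sample_stats(sample_cases):
    return tr.build_association_stats(sample_cases)


@pytest.fixture(scope="session")
def sample_vocabs(sample_cases):
    return tr.build_vocabularies(sample_cases, min_count=1)


@pytest.fixture(scope="session")
def small_spec():
    return tr.SyntheticSpec.random(n_symptoms=20, n_elements=15, n_scenes=3,
                                   n_diseases=4, seed=42)


@pytest.fixture(scope="session")
def small_corpus(small_spec):
    return tr.generate_corpus(small_spec, 400, seed=43)


@pytest.fixture(scope="session")
def tiny_config():
    return tr.ModelConfig(embed_dim=8, n_heads=2, expert_hidden=12, expert_dim=8,
                          tower_hidden=8, tower_depth=1, scene_dim=4,
                          meta_hidden=4, senet_hidden=4, mlp_hidden=(16,),
                          seed=0)


@pytest.fixture()
def tiny_model(small_corpus, tiny_config):
    return tr.EvidenceElementModel(small_corpus.cases[:100], kind="meta",
                                   config=tiny_config)


def random_corpus(rng, n_cases, n_symptoms=8, n_elements=6):
    """Small random corpora for brute-force oracle comparisons."""
    cases = []
    for i in range(n_cases):
        syms = rng.choice(n_symptoms, size=rng.integers(1, 5), replace=False)
        elems = rng.choice(n_elements, size=rng.integers(1, 4), replace=False)
        cases.append(tr.CaseRecord(
            case_id=f"r{i}",
            symptoms=[f"s{j}" for j in syms],
            elements=[f"e{j}" for j in np.repeat(elems, rng.integers(1, 3, size=len(elems)))],
            element_categories=[],
        ))
    return cases
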