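import numpy as np
import pytest

from hlalink import datasets
from hlalink.meta import StudyRecord
from hlalink.profiles import ConceptProfile


@pytest.fixture(scope="session")
def table2():
    return datasets.load_table2()


@pytest.fixture(scope="session")
def table3():
    return datasets.load_table3()


@pytest.fixture(scope="session")
def table2_profiles(table2):
    """The disease and gene concept profiles implied by the printed weight columns."""
    n = len(table2)
    prof_ad = ConceptProfile("AD", dict(zip(table2["gene"], table2["weight_in_AD"])), n)
    prof_hla = ConceptProfile("HLA-A", dict(zip(table2["gene"], table2["weight_in_HLA_A"])), n)
    return prof_ad, prof_hla


@pytest.fixture(scope="session")
def reconstructed_network():
    return datasets.reconstruct_intermediate_network()


def random_study_set(rng: np.random.Generator) -> list[StudyRecord]:
    """A small random batch of valid 2x2 studies (zero cells allowed)."""
    k = int(rng.integers(2, 9))
    studies = []
    for i in range(k):
        n_cases = int(rng.integers(15, 400))
        n_controls = int(rng.integers(15, 400))
        p_case = float(rng.uniform(0.05, 0.8))
        p_control = float(rng.uniform(0.05, 0.8))
        a = int(rng.binomial(n_cases, p_case))
        c = int(rng.binomial(n_controls, p_control))
        studies.append(StudyRecord(f"s{i}", a=a, b=n_cases - a, c=c, d=n_controls - c))
    return studies
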