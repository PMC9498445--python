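import numpy as np
import pytest

import mintruls as mt


@pytest.fixture(scope="session")
def default_dataset():
    """The standard planted-family dataset (5 x 20 miRNAs x 60 sites)."""
    return mt.generate(mt.SyntheticSpec())


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted dataset for fast end-to-end runs."""
    return mt.generate(mt.SyntheticSpec(n_families=3, mirnas_per_family=5,
                                        sites_per_family=8, seed=7))


@pytest.fixture()
def tiny_dataset():
    """Hand-built 2 miRNAs x 3 sites dataset."""
    mirnas = [
        mt.SequenceRecord("m1", mt.Role.MIRNA, "UGAGGUAGUAGGUUGUAUAGUU"),
        mt.SequenceRecord("m2", mt.Role.MIRNA, "UAAAGUGCUUAUAGUGCAGGUA"),
    ]
    sites = [
        mt.SequenceRecord("t1", mt.Role.TARGET_SITE, "AACUAUACAACCUACUACCUCA"),
        mt.SequenceRecord("t2", mt.Role.TARGET_SITE, "GCACUUUAUAGCACUUUACCUG"),
        mt.SequenceRecord("t3", mt.Role.TARGET_SITE, "UACCUGCACUAUAAGCACUUUA"),
    ]
    A = np.array([[1, 0, 0], [0, 0, 1]], dtype=np.int8)
    matrix = mt.InteractionMatrix(["m1", "m2"], ["t1", "t2", "t3"], A)
    return mt.Dataset(mirnas, sites, matrix)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_psd_kernel(rng, n):
    """Random symmetric PSD matrix with unit diagonal (a valid kernel)."""
    B = rng.normal(size=(n, n))
    M = B @ B.T
    d = np.sqrt(np.diag(M))
    M = M / np.outer(d, d)
    np.fill_diagonal(M, 1.0)
    return (M + M.T) / 2
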