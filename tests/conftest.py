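import numpy as np
import pytest

from longsim.io import make_synthetic_genome
from longsim.model import ErrorHMM, ModelSet, QualityHMM
from longsim.wgs import GenomeIndex


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_genome() -> GenomeIndex:
    name, seq = make_synthetic_genome(length=20_000, seed=3)
    return GenomeIndex([(name, seq)])


@pytest.fixture(scope="session")
def two_chrom_genome() -> GenomeIndex:
    _, seq1 = make_synthetic_genome(length=9_000, seed=1)
    _, seq2 = make_synthetic_genome(length=1_000, seed=2)
    return GenomeIndex([("chrA", seq1), ("chrB", seq2)])


def constant_q_modelset(q: int, acc_bin: int = 85) -> ModelSet:
    emit = np.zeros((1, 94))
    emit[0, q] = 1.0
    model = QualityHMM(acc_bin, np.ones(1), np.ones((1, 1)), emit)
    return ModelSet("qshmm", {acc_bin: model})


def one_state_errhmm(emit_row, acc_bin: int = 85) -> ModelSet:
    model = ErrorHMM(acc_bin, np.ones(1), np.ones((1, 1)), np.array([emit_row]))
    return ModelSet("errhmm", {acc_bin: model})


@pytest.fixture(scope="session")
def qshmm_q8() -> ModelSet:
    """Constant Q=8 quality model (error probability 0.158)."""
    return constant_q_modelset(8)


@pytest.fixture(scope="session")
def errhmm_85() -> ModelSet:
    return one_state_errhmm([0.85, 0.05, 0.05, 0.05])
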