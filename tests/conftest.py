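import numpy as np
import pytest

from canya import nnk
from canya.encoding import AA_ALPHABET, AA_INDEX
from canya.labeling import process_library
from canya.model import CanyaResults, ModelConfig
from canya import network


@pytest.fixture(scope="session")
def scored_library():
    """Small synthetic NNK library scored under the default grammar."""
    grammar = nnk.GrammarSpec(seed=7)
    peptides = nnk.sample_nnk_peptides(6000, 20, seed=7)
    return nnk.score_library(peptides, grammar)


@pytest.fixture(scope="session")
def labeled_library(scored_library):
    return process_library(scored_library, library_id="NNK1")


@pytest.fixture(scope="session")
def random_results():
    """Untrained (randomly initialised) results object: enough for encoding,
    activation and PWM machinery that only needs weights."""
    config = ModelConfig()
    rng = np.random.default_rng(123)
    params = network.init_params(config, rng)
    # non-degenerate random weights so kmer rankings are unique
    params["conv_w"] = rng.normal(0, 0.5, params["conv_w"].shape)
    params["conv_b"] = rng.normal(0, 0.1, params["conv_b"].shape)
    return CanyaResults(config=config, params=params)


class AdditiveSurrogate:
    """Strictly additive per-residue scorer: an exact oracle for GIA.

    pre_activation(seq) = sum_i weights[i, aa_i]; position-dependent but
    with no interactions, so interaction importances are exactly 0 and
    multiplicity curves are exactly linear.
    """

    def __init__(self, weights: np.ndarray):
        self.weights = np.asarray(weights, dtype=float)

    @classmethod
    def from_scale(cls, scale: dict, length: int = 20,
                   position_multiplier=None):
        w = np.zeros((length, 20))
        for aa, v in scale.items():
            w[:, AA_INDEX[aa]] = v
        if position_multiplier is not None:
            w = w * np.asarray(position_multiplier)[:, None]
        return cls(w)

    def pre_activation(self, sequences):
        return np.array([
            sum(self.weights[i, AA_INDEX[aa]] for i, aa in enumerate(seq))
            for seq in sequences
        ])


class ConstantModel:
    """Fixed-output scorer (no sequence dependence)."""

    def __init__(self, value: float = 0.0):
        self.value = value

    def pre_activation(self, sequences):
        return np.full(len(sequences), self.value)


@pytest.fixture
def hydrophobic_surrogate():
    scale = {aa: (1.0 if aa in "ILVFWYM" else -0.2) for aa in AA_ALPHABET}
    return AdditiveSurrogate.from_scale(scale)


def stop_free_peptides(n, seed):
    """Full-length stop-free peptides (GIA backgrounds are stop-free)."""
    peps = [p for p in nnk.sample_nnk_peptides(3 * n, 20, seed=seed) if "*" not in p]
    return peps[:n]


@pytest.fixture
def backgrounds():
    return stop_free_peptides(300, seed=42)


@pytest.fixture
def unit_kmer_surrogate():
    """Weight 1 on I and V only: embedding III or VVV into an I/V-free
    background changes the score by exactly 3."""
    scale = {aa: (1.0 if aa in "IV" else 0.0) for aa in AA_ALPHABET}
    return AdditiveSurrogate.from_scale(scale)


@pytest.fixture
def kmer_free_backgrounds():
    """Length-20 backgrounds over residues excluding I and V."""
    rng = np.random.default_rng(17)
    pool = list("ACDEGHKNPQRSTW")
    return ["".join(rng.choice(pool, 20)) for _ in range(150)]
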