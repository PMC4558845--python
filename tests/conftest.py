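import numpy as np
import pytest

from cytonuc import simulate as sim
from cytonuc.substitution import AminoAcidModel

AA = "ARNDCQEGHILKMFPSTWYV"


@pytest.fixture(scope="session")
def wag() -> AminoAcidModel:
    return AminoAcidModel.wag()


@pytest.fixture(scope="session")
def wag_gamma() -> AminoAcidModel:
    return AminoAcidModel.wag(gamma_shape=1.0, n_categories=4)


@pytest.fixture(scope="session")
def family():
    """An annotated 14-taxon family (8 eukaryote / 6 prokaryote tips) with a
    simulated 150-column reference alignment."""
    tree = sim.simulate_family_tree(seed=3)
    aln = sim.simulate_alignment(tree, AminoAcidModel.wag(), 150, seed=4)
    return aln, tree


def simulate_pair(model: AminoAcidModel, t: float, n: int, rng: np.random.Generator):
    """Two amino-acid sequences separated by divergence t."""
    pi = model.equilibrium_freqs
    P = model.transition_probabilities(t)
    a = rng.choice(20, size=n, p=pi)
    u = rng.random(n)
    cum = np.cumsum(P, axis=1)
    b = (u[:, None] > cum[a]).sum(axis=1)
    return ("".join(AA[i] for i in a), "".join(AA[i] for i in b))


def simulate_nt_pair(t: float, kappa: float, n: int, rng: np.random.Generator):
    from cytonuc.substitution import K80Model
    model = K80Model(kappa)
    P = model.transition_probabilities(t)
    a = rng.integers(0, 4, size=n)
    u = rng.random(n)
    cum = np.cumsum(P, axis=1)
    b = (u[:, None] > cum[a]).sum(axis=1)
    NT = "ACGT"
    return ("".join(NT[i] for i in a), "".join(NT[i] for i in b))
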