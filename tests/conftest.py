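import numpy as np
import pytest

from cneloss.phylo import PhyloTree, SubstitutionModel
from cneloss.simulate import SimulationConfig, evolve_alignment


@pytest.fixture(scope="session")
def six_taxon_tree():
    return PhyloTree.from_newick(
        "(Zv9:0.35,(hipCom0:0.22,((fr3:0.09,gasAcu1:0.08):0.05,"
        "(oryLat2:0.1,oreNil2:0.09):0.04):0.06):0.12);")


@pytest.fixture(scope="session")
def jc_model():
    return SubstitutionModel.jukes_cantor()


@pytest.fixture(scope="session")
def gtr_model():
    return SubstitutionModel([0.3, 0.2, 0.2, 0.3],
                             [1.0, 2.0, 1.0, 1.0, 2.0, 1.0])


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_elements=60, n_genes=4, gene_codons=30, background_length=30000,
        element_length_mean=60, element_length_min=40, element_length_max=120,
        loss_plan={"hipCom0": 6, "fr3": 4}, gap_plan={"gasAcu1": 4},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_result(small_config):
    return evolve_alignment(small_config)


def random_dna(rng, n):
    return "".join(np.random.default_rng(rng).choice(list("ACGT"), n)
                   if isinstance(rng, int) else rng.choice(list("ACGT"), n))
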