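import numpy as np
import pytest

import molgcn as m

#: a small spread of chemistry: chains, rings, aromatics, charges, stereo, halogens
SAMPLE_SMILES = [
    "C",
    "CCO",
    "c1ccccc1",
    "CC(=O)NC",
    "C[C@H](N)C(=O)O",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "O=[N+]([O-])c1ccccc1",
    "C1CCCCC1",
    "CCOC(=O)C",
    "BrCCCl",
    "C#N",
    "c1ccsc1",
]


@pytest.fixture(scope="session")
def sample_smiles():
    return list(SAMPLE_SMILES)


@pytest.fixture(scope="session")
def bench600():
    """The default 4-task synthetic benchmark, 600 molecules, dataset seed 0."""
    smiles, labels, mask, names, specs = m.default_benchmark(600, seed=0)
    return smiles, labels, mask, names


@pytest.fixture(scope="session")
def bench600_graphs_l3(bench600):
    smiles, labels, mask, names = bench600
    cfg = m.FeatureConfig(level=3)
    graphs = [m.build_graph(s, cfg, labels=labels[i], mask=mask[i])
              for i, s in enumerate(smiles)]
    return graphs, names, cfg


def featurize_all(smiles, labels, mask, level):
    cfg = m.FeatureConfig(level=level)
    return [m.build_graph(s, cfg, labels=labels[i], mask=mask[i])
            for i, s in enumerate(smiles)], cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
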