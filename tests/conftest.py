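import numpy as np
import pytest

from molgnn.chem import AISD_ELEMENTS, MolecularGraph, build_vocabulary, \
    smiles_to_graph
from molgnn.synthetic import SyntheticSpec, generate_molecules, make_corpus


@pytest.fixture(scope="session")
def aisd_vocab():
    return build_vocabulary(AISD_ELEMENTS)


@pytest.fixture(scope="session")
def small_corpus_smiles():
    """60 deterministic synthetic molecules (noise-free labels downstream)."""
    return generate_molecules(SyntheticSpec(n=60, sigma=0.0, seed=101))


@pytest.fixture(scope="session")
def small_graphs(small_corpus_smiles, aisd_vocab):
    rng = np.random.default_rng(5)
    graphs = []
    for s in small_corpus_smiles:
        g = smiles_to_graph(s, aisd_vocab)
        g.y = np.array([rng.normal()], dtype=np.float32)
        graphs.append(g)
    return graphs


@pytest.fixture(scope="session")
def corpus_dir(tmp_path_factory):
    """A 200-molecule corpus materialized in all three backend formats."""
    out = tmp_path_factory.mktemp("corpus")
    spec = SyntheticSpec(n=200, sigma=0.0, seed=42)
    paths = make_corpus(spec, str(out), num_writers=4)
    return paths


def random_feature_graph(rng, n_nodes, node_dim=5, edge_dim=3):
    """Random connected graph with float features, for model-level tests."""
    edges = []
    for i in range(1, n_nodes):
        j = int(rng.integers(i))
        edges += [(j, i), (i, j)]
    if n_nodes > 2 and rng.random() < 0.5:
        a, b = rng.choice(n_nodes, 2, replace=False)
        edges += [(int(a), int(b)), (int(b), int(a))]
    ei = (np.array(edges, dtype=np.int64).T if edges
          else np.zeros((2, 0), dtype=np.int64))
    return MolecularGraph(
        x=rng.normal(size=(n_nodes, node_dim)).astype(np.float32),
        edge_index=ei,
        edge_attr=rng.normal(size=(ei.shape[1], edge_dim)).astype(np.float32),
        y=np.array([rng.normal()], dtype=np.float32),
    )
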