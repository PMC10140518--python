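import numpy as np
import pandas as pd
import pytest

import rhizocomm as rc


@pytest.fixture(scope="session")
def small_dataset():
    """Deterministic 60-taxon, 27-sample synthetic survey with one planted
    block, shared across tests that only read it."""
    cfg = rc.SimulationConfig(n_taxa=60, depth=2000, seed=5, n_blocks=1)
    return rc.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_taxonomy(small_dataset):
    """Taxonomy assigning four phyla cyclically over the synthetic taxa."""
    phyla = ["Proteobacteria", "Chloroflexi", "Bacteroidetes", "Acidobacteria"]
    taxa = small_dataset.matrix.taxon_ids
    return rc.TaxonomyTable(
        pd.DataFrame(
            {
                "taxon_id": taxa,
                "kingdom": "Bacteria",
                "phylum": [phyla[i % 4] for i in range(len(taxa))],
                "genus": [f"Genus{i}" for i in range(len(taxa))],
            }
        )
    )


@pytest.fixture()
def tiny_matrix():
    df = pd.DataFrame(
        {"S1": [5, 3, 0], "S2": [1, 0, 4]},
        index=pd.Index(["t1", "t2", "t3"], name="taxon_id"),
    )
    return rc.CommunityMatrix(df)


@pytest.fixture()
def design_metadata():
    rows = []
    for comp in ("bulk", "rhizosphere", "rhizoplane"):
        for stage in ("tillering", "heading", "mature"):
            for rep in (1, 2, 3):
                rows.append(
                    {
                        "sample_id": f"{comp}_{stage}_{rep}",
                        "compartment": comp,
                        "stage": stage,
                        "replicate": rep,
                    }
                )
    return rc.SampleMetadata(pd.DataFrame(rows))


def naive_patristic(tree, a, b):
    """Independent patristic oracle: sum branch lengths along the two
    root-ward paths to the most recent common ancestor."""
    nodes = {leaf.taxon.label: leaf for leaf in tree.tree.leaf_node_iter()}
    path_a = []
    node = nodes[a]
    while node is not None:
        path_a.append(node)
        node = node.parent_node
    ancestors_a = {id(n): i for i, n in enumerate(path_a)}
    node = nodes[b]
    dist_b = 0.0
    while id(node) not in ancestors_a:
        dist_b += node.edge.length or 0.0
        node = node.parent_node
    dist_a = 0.0
    for n in path_a[: ancestors_a[id(node)]]:
        dist_a += n.edge.length or 0.0
    return dist_a + dist_b
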