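"""Shared fixtures: tiny deterministic graphs and a small synthetic KG."""

from __future__ import annotations

import numpy as np
import pytest

from spectradti.kg import RELATIONS, HeteroGraph
from spectradti.synthetic import SyntheticConfig, generate_kg


def make_hetero_graph(n_drugs, n_prot, n_pw, edges, texts=None, actions=None, families=None):
    """Hand-built HeteroGraph; `edges` maps relation -> list of (u, v)."""
    node_type = np.array([0] * n_drugs + [1] * n_prot + [2] * n_pw, dtype=np.int64)
    records = []
    for i in range(n_drugs):
        records.append({"name": f"d{i}", "smiles": "CCO", "state": "solid", "groups": ["approved"]})
    for i in range(n_prot):
        fam = families[i] if families else f"F{i % 2}"
        records.append({"name": f"p{i}", "sequence": "MKVLA" * 5, "family": fam})
    for i in range(n_pw):
        records.append({"name": f"w{i}", "category": "signaling"})
    e = {r: np.array(edges.get(r, []), dtype=np.int64).reshape(-1, 2) for r in RELATIONS}
    attrs = {}
    if actions is not None:
        attrs["drug_target"] = actions
    if texts is not None:
        attrs["drug_drug"] = texts
    return HeteroGraph(node_type=node_type, records=records, edges=e, edge_attrs=attrs)


def random_hetero_graph(rng: np.random.Generator, max_nodes: int = 12) -> HeteroGraph:
    """Random small typed graph with mixed relations (spectral oracle input)."""
    n_d = int(rng.integers(1, max(2, max_nodes // 2)))
    n_p = int(rng.integers(1, max(2, (max_nodes - n_d) // 2 + 1)))
    n_w = int(rng.integers(0, max(1, max_nodes - n_d - n_p) + 1))
    edges = {r: set() for r in RELATIONS}

    def rand_edges(rel, a_range, b_range, k):
        for _ in range(k):
            a = int(rng.integers(*a_range))
            b = int(rng.integers(*b_range))
            if a != b:
                edges[rel].add((a, b))

    rand_edges("drug_target", (0, n_d), (n_d, n_d + n_p), int(rng.integers(1, 4)))
    if n_d > 1:
        rand_edges("drug_drug", (0, n_d), (0, n_d), int(rng.integers(0, 3)))
    if n_w:
        rand_edges("drug_pathway", (0, n_d), (n_d + n_p, n_d + n_p + n_w), int(rng.integers(0, 3)))
        rand_edges("pathway_target", (n_d + n_p, n_d + n_p + n_w), (n_d, n_d + n_p),
                   int(rng.integers(0, 3)))
    return make_hetero_graph(n_d, n_p, n_w, {r: sorted(v) for r, v in edges.items()})


@pytest.fixture(scope="session")
def small_kg():
    """One small planted-signal synthetic KG shared across tests."""
    cfg = SyntheticConfig(n_drugs=30, n_proteins=10, n_pathways=4, n_families=3, seed=11)
    graph, positives, truth = generate_kg(cfg)
    return cfg, graph, positives, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
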