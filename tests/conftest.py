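"""Shared fixtures: a small synthetic breeding population used across suites.

Everything is generated at test time from seeds; no data files ship with the
package.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from spdchg import (
    SimConfig,
    generate_spdc_plan,
    infer_hybrid_genotypes,
    reml_fit,
    sim_genotypes,
    sim_trait,
)


@pytest.fixture(scope="session")
def pop():
    """80 inbreds in 5 heterotic groups, 600 SNPs, 280-cross sparse partial
    diallel, trait with 60 QTL at h2 = 0.7 (dominance ratio 0.5)."""
    cfg = SimConfig(n_lines=80, n_groups=5, n_snps=600, n_qtl=60, h2=0.7, seed=3)
    g, groups = sim_genotypes(cfg)
    plan = generate_spdc_plan(groups, n_crosses=280, between_group_fraction=0.8, seed=4)
    truth = sim_trait(g, plan, cfg)
    coding = infer_hybrid_genotypes(g, plan)
    return SimpleNamespace(
        cfg=cfg, g=g, groups=groups, plan=plan, truth=truth, coding=coding
    )


@pytest.fixture(scope="session")
def pop_fit(pop):
    """Additive+dominance GBLUP fit on the session population."""
    return reml_fit(pop.truth.phenotypes.to_numpy(), pop.coding.Za, pop.coding.Zd,
                    max_iter=200)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


# -- independent tree oracles (shared by diversity and acceptance suites) ----

def random_additive_tree(n_taxa, rng):
    """Random binary tree with positive branch lengths, returned as the exact
    pairwise path-length matrix (independent oracle for neighbor joining)."""
    import itertools

    import networkx as nx
    import pandas as pd

    G = nx.Graph()
    G.add_edge("t0", "t1", weight=float(rng.uniform(0.1, 2.0)))
    next_internal = 0
    for k in range(2, n_taxa):
        edges = list(G.edges(data=True))
        u, v, data = edges[rng.integers(len(edges))]
        w = data["weight"]
        split = float(rng.uniform(0.2, 0.8)) * w
        mid = f"n{next_internal}"
        next_internal += 1
        G.remove_edge(u, v)
        G.add_edge(u, mid, weight=split)
        G.add_edge(mid, v, weight=w - split)
        G.add_edge(mid, f"t{k}", weight=float(rng.uniform(0.1, 2.0)))
    taxa = [f"t{i}" for i in range(n_taxa)]
    D = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for a, b in itertools.combinations(taxa, 2):
        d = nx.shortest_path_length(G, a, b, weight="weight")
        D.loc[a, b] = D.loc[b, a] = d
    return D


def patristic_from_newick(nwk):
    """Pairwise path lengths of a newick tree via dendropy (independent of the
    NJ implementation under test)."""
    import dendropy
    import pandas as pd

    t = dendropy.Tree.get(data=nwk, schema="newick")
    pdm = t.phylogenetic_distance_matrix()
    taxa = {x.label: x for x in t.taxon_namespace}
    labels = sorted(taxa)
    D = pd.DataFrame(0.0, index=labels, columns=labels)
    for a in labels:
        for b in labels:
            if a < b:
                D.loc[a, b] = D.loc[b, a] = pdm.distance(taxa[a], taxa[b])
    return D
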