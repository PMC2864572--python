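"""Shared fixtures and the brute-force path oracle.

The oracle checks every ordered node tuple against the layer edge
predicates directly; it is deliberately independent of the DFS used by
the package, so agreement between the two is informative.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from pathmotifs import (
    CauseEffectNetwork,
    IntegratedNetwork,
    PathInstance,
    PathType,
    PhysicalLayer,
    SyntheticSpec,
    simulate,
)


def oracle_instances(net: IntegratedNetwork, pair, path_type: PathType) -> list[PathInstance]:
    """All typed simple paths, by exhaustive enumeration of node tuples."""
    cause, effect = pair
    nodes = sorted(net.node_universe)
    k = len(path_type)
    out = []
    for mids in itertools.product(nodes, repeat=k - 1):
        seq = (cause,) + mids + (effect,)
        if len(set(seq)) != len(seq):
            continue
        if all(
            net.layer(lab).has_edge(seq[i], seq[i + 1])
            for i, lab in enumerate(path_type.labels)
        ):
            out.append(PathInstance(cause, effect, path_type, seq))
    return out


def oracle_count(net: IntegratedNetwork, ce: CauseEffectNetwork, path_type: PathType) -> int:
    return sum(
        len(oracle_instances(net, (c, e), path_type)) for c, e in ce.iter_pairs()
    )


def random_small_network(rng: np.random.Generator, n_nodes: int = 10) -> IntegratedNetwork:
    """A random 3-layer network: TRI/PhI directed, PPI undirected."""
    genes = [f"x{i}" for i in range(n_nodes)]
    layers = []
    for label, directed in [("TRI", True), ("PPI", False), ("PhI", True)]:
        density = rng.uniform(0.05, 0.3)
        edges = []
        for a in genes:
            for b in genes:
                if a != b and rng.random() < density:
                    edges.append((a, b))
        layers.append(PhysicalLayer(label, directed, edges))
    return IntegratedNetwork(layers)


def random_cause_effect(rng: np.random.Generator, net: IntegratedNetwork,
                        n_causes: int = 2, n_effects: int = 3) -> CauseEffectNetwork:
    genes = sorted(net.node_universe)
    causes = [genes[i] for i in rng.choice(len(genes), size=n_causes, replace=False)]
    pairs = {}
    for c in causes:
        pool = [g for g in genes if g != c]
        idx = rng.choice(len(pool), size=min(n_effects, len(pool)), replace=False)
        pairs[c] = {pool[i] for i in idx}
    return CauseEffectNetwork(pairs, causes=causes)


@pytest.fixture(scope="session")
def planted_dataset():
    """The default planted-recovery conditions: 300 genes, 10 causes,
    density 0.01 layers, PPI-TRI x8 per cause with a shared
    intermediate, 20 noise targets per cause."""
    spec = SyntheticSpec(seed=7)
    net, ce, truth = simulate(spec)
    return spec, net, ce, truth


@pytest.fixture
def tiny_net():
    """Hand-wired network used by the small worked examples."""
    tri = PhysicalLayer("TRI", True, [("TF1", "g1"), ("p1", "g1"), ("p1", "g2"), ("g1", "g3")])
    ppi = PhysicalLayer("PPI", False, [("TF1", "p1"), ("p1", "p2")])
    phi = PhysicalLayer("PhI", True, [("k1", "p1"), ("TF1", "k1")])
    return IntegratedNetwork([tri, ppi, phi])
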