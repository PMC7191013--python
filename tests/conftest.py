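"""Shared builders for toy networks used across the test modules."""
from __future__ import annotations

import numpy as np
import pytest

from hrubnet import (
    CPT,
    BayesianNetwork,
    NetworkStructure,
    VariableScheme,
    VariableSpec,
)


def make_network(spec: dict[str, dict], target: str | None = None) -> BayesianNetwork:
    """Build a small network from {node: {'states': [...], 'parents': [...],
    'cpt': array}}; insertion order is the node order."""
    names = list(spec)
    scheme = VariableScheme(
        variables=tuple(
            VariableSpec(name=n, states=tuple(d["states"])) for n, d in spec.items()
        ),
        target=target or names[-1],
    )
    structure = NetworkStructure(
        nodes=tuple(names),
        parents={n: tuple(d.get("parents", ())) for n, d in spec.items()},
    )
    cpts = {
        n: CPT(
            child=n,
            parents=tuple(d.get("parents", ())),
            values=np.asarray(d["cpt"], dtype=float),
        )
        for n, d in spec.items()
    }
    return BayesianNetwork(scheme=scheme, structure=structure, cpts=cpts)


def random_network(rng: np.random.Generator, max_nodes: int = 6) -> BayesianNetwork:
    """Random DAG (topological by construction) with random Dirichlet CPTs."""
    n_nodes = int(rng.integers(2, max_nodes + 1))
    names = [f"X{i}" for i in range(n_nodes)]
    cards = rng.integers(2, 4, size=n_nodes)
    spec: dict[str, dict] = {}
    for i, name in enumerate(names):
        possible = names[:i]
        k = int(rng.integers(0, min(len(possible), 3) + 1))
        parents = list(rng.choice(possible, size=k, replace=False)) if k else []
        p_cards = tuple(int(cards[names.index(p)]) for p in parents)
        shape = p_cards + (int(cards[i]),)
        cpt = rng.dirichlet(np.ones(shape[-1]), size=shape[:-1]).reshape(shape)
        spec[name] = {
            "states": [f"s{j}" for j in range(int(cards[i]))],
            "parents": parents,
            "cpt": cpt,
        }
    return make_network(spec)


@pytest.fixture
def chain_ab() -> BayesianNetwork:
    """Two-node chain A→B with P(A=a0)=0.3 and P(B=b0|A) = (0.5, 0.2)."""
    return make_network(
        {
            "A": {"states": ["a0", "a1"], "cpt": [0.3, 0.7]},
            "B": {
                "states": ["b0", "b1"],
                "parents": ["A"],
                "cpt": [[0.5, 0.5], [0.2, 0.8]],
            },
        }
    )
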