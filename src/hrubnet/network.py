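"""Discrete Bayesian network: structure, CPTs, and exact belief updating.

The joint distribution factorizes over the DAG as
``P(X1..Xn) = prod_i P(Xi | parents(Xi))``; posteriors given evidence are
computed exactly by variable elimination with a min-degree ordering.  At the
nine-node scale of the study network exact inference is always tractable, so
no approximate engine is provided.  A brute-force enumeration routine is kept
alongside as an independent oracle for tests.

CPT storage convention (fixed for bit-exact serialization): each table is an
array with one axis per parent, in declared parent order, followed by the
child axis.  Flattened in C order this makes child states vary fastest and
parent configurations iterate lexicographically by parent order and state
order.
"""
from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence
from xml.etree import ElementTree as ET

import networkx as nx
import numpy as np
import yaml

from .scheme import VariableScheme, default_scheme

__all__ = [
    "NetworkError",
    "ImpossibleEvidenceError",
    "NetworkStructure",
    "CPT",
    "BayesianNetwork",
    "validate",
    "default_study_network",
    "joint_probability",
    "posterior",
    "posterior_joint",
    "posterior_by_enumeration",
    "evidence_probability",
    "marginals",
    "network_to_dict",
    "network_from_dict",
    "save_network",
    "load_network",
    "to_xmlbif",
    "from_xmlbif",
]

ROW_TOL = 1e-9


class NetworkError(ValueError):
    """An invalid network definition or query."""


class ImpossibleEvidenceError(NetworkError):
    """Evidence with zero probability under the network."""


@dataclass(frozen=True)
class NetworkStructure:
    """DAG over named nodes, given as an ordered node list and parent lists."""

    nodes: tuple[str, ...]
    parents: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "parents",
            {n: tuple(self.parents.get(n, ())) for n in self.nodes},
        )
        for n, ps in self.parents.items():
            for p in ps:
                if p not in self.nodes:
                    raise NetworkError(f"parent {p!r} of {n!r} is not a node")
            if len(set(ps)) != len(ps):
                raise NetworkError(f"duplicate parent in {n!r}")
        if not nx.is_directed_acyclic_graph(self.graph()):
            raise NetworkError("structure contains a directed cycle")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for n, ps in self.parents.items():
            g.add_edges_from((p, n) for p in ps)
        return g

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if node in self.parents[n])

    def topological_order(self) -> list[str]:
        order = list(nx.lexicographical_topological_sort(self.graph()))
        return order


@dataclass(frozen=True)
class CPT:
    """Conditional probability table of one node.

    ``values`` has shape ``(*parent_cards, child_card)``; every row (last
    axis) is a distribution over the child's states.
    """

    child: str
    parents: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != len(self.parents) + 1:
            raise NetworkError(
                f"CPT of {self.child!r}: expected {len(self.parents) + 1} axes, "
                f"got {self.values.ndim}"
            )

    def row_violations(self) -> list[str]:
        out = []
        flat = self.values.reshape(-1, self.values.shape[-1])
        if np.any(flat < 0):
            out.append(f"CPT of {self.child!r} has negative entries")
        bad = np.flatnonzero(np.abs(flat.sum(axis=1) - 1.0) > ROW_TOL)
        for idx in bad[:5]:
            out.append(
                f"CPT of {self.child!r}: row {int(idx)} sums to {flat[idx].sum():.6g}"
            )
        return out


@dataclass(frozen=True)
class BayesianNetwork:
    """A variable scheme, a DAG, and one CPT per node."""

    scheme: VariableScheme
    structure: NetworkStructure
    cpts: Mapping[str, CPT]

    def __post_init__(self) -> None:
        problems = validate(self)
        if problems:
            raise NetworkError("; ".join(problems))

    def card(self, name: str) -> int:
        return self.scheme[name].n_states

    def state_index(self, name: str, state: str) -> int:
        return self.scheme[name].state_index(state)


def validate(network) -> list[str]:
    """Return a list of invariant violations (empty list = valid network).

    Accepts a not-yet-frozen (scheme, structure, cpts) triple as well, so it
    can be used to inspect candidate networks without raising.
    """
    scheme, structure, cpts = network.scheme, network.structure, network.cpts
    problems: list[str] = []
    for n in structure.nodes:
        if n not in scheme:
            problems.append(f"node {n!r} missing from the scheme")
    if problems:
        return problems
    for n in structure.nodes:
        if n not in cpts:
            problems.append(f"no CPT for node {n!r}")
            continue
        cpt = cpts[n]
        if cpt.child != n:
            problems.append(f"CPT stored under {n!r} is for {cpt.child!r}")
        if tuple(cpt.parents) != tuple(structure.parents[n]):
            problems.append(f"CPT of {n!r} disagrees with structural parents")
            continue
        expect = tuple(scheme[p].n_states for p in cpt.parents) + (
            scheme[n].n_states,
        )
        if cpt.values.shape != expect:
            problems.append(
                f"CPT of {n!r} has shape {cpt.values.shape}, expected {expect}"
            )
            continue
        problems.extend(cpt.row_violations())
    return problems


# ---------------------------------------------------------------------------
# Default study structure
# ---------------------------------------------------------------------------

def default_study_network() -> NetworkStructure:
    """Expert-elicited DAG of the behavioral-safety study.

    All variables point directly at the HRUB outcome except age, whose effect
    is mediated by experience and marital status; a previous accident drives
    participation in further safety training (the employer mandates courses
    after an accident).
    """
    nodes = (
        "Age",
        "Experience",
        "MaritalStatus",
        "PreviousAccident",
        "EducationalLevel",
        "Weekday",
        "Daytime",
        "Training",
        "HRUB",
    )
    parents = {
        "Experience": ("Age",),
        "MaritalStatus": ("Age",),
        "Training": ("PreviousAccident",),
        "HRUB": (
            "Experience",
            "MaritalStatus",
            "PreviousAccident",
            "Training",
            "EducationalLevel",
            "Weekday",
            "Daytime",
        ),
    }
    return NetworkStructure(nodes=nodes, parents=parents)


# ---------------------------------------------------------------------------
# Factors and variable elimination
# ---------------------------------------------------------------------------

@dataclass
class _Factor:
    vars: tuple[str, ...]
    values: np.ndarray

    def sum_out(self, var: str) -> "_Factor":
        axis = self.vars.index(var)
        return _Factor(
            vars=self.vars[:axis] + self.vars[axis + 1 :],
            values=self.values.sum(axis=axis),
        )


def _multiply(factors: Sequence[_Factor]) -> _Factor:
    out_vars: list[str] = []
    for f in factors:
        for v in f.vars:
            if v not in out_vars:
                out_vars.append(v)
    out_vars_t = tuple(out_vars)
    result = np.ones((1,) * len(out_vars_t))
    for f in factors:
        # expand f.values to the union axes
        shape = [1] * len(out_vars_t)
        perm = [f.vars.index(v) for v in out_vars_t if v in f.vars]
        vals = np.transpose(f.values, perm)
        it = iter(vals.shape)
        for i, v in enumerate(out_vars_t):
            if v in f.vars:
                shape[i] = next(it)
        result = result * vals.reshape(shape)
    return _Factor(vars=out_vars_t, values=result)


def _reduced_factors(net: BayesianNetwork, evidence: Mapping[str, str]) -> list[_Factor]:
    ev_idx = {v: net.state_index(v, s) for v, s in evidence.items()}
    factors = []
    for n in net.structure.nodes:
        cpt = net.cpts[n]
        vars_ = tuple(cpt.parents) + (n,)
        vals = cpt.values
        keep_vars = []
        index: list = []
        for v in vars_:
            if v in ev_idx:
                index.append(ev_idx[v])
            else:
                index.append(slice(None))
                keep_vars.append(v)
        vals = vals[tuple(index)]
        factors.append(_Factor(vars=tuple(keep_vars), values=np.asarray(vals, dtype=float)))
    return factors


def _eliminate(factors: list[_Factor], keep: set[str]) -> _Factor:
    """Sum out every variable not in ``keep``, min-degree order."""
    factors = list(factors)
    while True:
        elim_vars = {v for f in factors for v in f.vars} - keep
        if not elim_vars:
            break
        # min-degree: variable whose product factor has fewest distinct vars
        def degree(v: str) -> int:
            neigh: set[str] = set()
            for f in factors:
                if v in f.vars:
                    neigh.update(f.vars)
            return len(neigh)

        var = min(sorted(elim_vars), key=degree)
        involved = [f for f in factors if var in f.vars]
        rest = [f for f in factors if var not in f.vars]
        product = _multiply(involved)
        factors = rest + [product.sum_out(var)]
    return _multiply(factors)


def _validate_evidence(net: BayesianNetwork, evidence: Mapping[str, str]) -> dict[str, str]:
    ev = {}
    for v, s in evidence.items():
        if v not in net.scheme:
            raise NetworkError(f"evidence variable {v!r} is not a node")
        ev[v] = net.scheme[v].canonical_state(s)
    return ev


def evidence_probability(net: BayesianNetwork, evidence: Mapping[str, str]) -> float:
    """Marginal probability of an evidence assignment, P(e)."""
    evidence = _validate_evidence(net, evidence)
    f = _eliminate(_reduced_factors(net, evidence), keep=set())
    return float(f.values.reshape(()))


def posterior_joint(
    net: BayesianNetwork,
    variables: Sequence[str],
    evidence: Mapping[str, str] | None = None,
) -> np.ndarray:
    """Exact joint posterior over ``variables`` (axes in the given order).

    Variables contained in the evidence get a point-mass axis on the observed
    state.  Raises :class:`ImpossibleEvidenceError` when P(e) = 0.
    """
    evidence = _validate_evidence(net, evidence or {})
    variables = tuple(variables)
    free = [v for v in variables if v not in evidence]
    f = _eliminate(_reduced_factors(net, evidence), keep=set(free))
    total = f.values.sum()
    if total <= 0.0:
        raise ImpossibleEvidenceError(
            f"impossible evidence: P({evidence}) = 0 under the network"
        )
    vals = f.values / total
    # order free axes as requested
    if free:
        perm = [f.vars.index(v) for v in free]
        vals = np.transpose(vals, perm)
    # expand point-mass axes for evidenced query variables
    out_shape = tuple(net.card(v) for v in variables)
    out = np.zeros(out_shape)
    index = []
    for v in variables:
        if v in evidence:
            index.append(net.state_index(v, evidence[v]))
        else:
            index.append(slice(None))
    out[tuple(index)] = vals
    return out


def posterior(
    net: BayesianNetwork,
    query: str,
    evidence: Mapping[str, str] | None = None,
) -> np.ndarray:
    """Posterior distribution over the states of ``query`` given evidence.

    Belief updating via Bayes' theorem, computed exactly by variable
    elimination; the returned vector is aligned with the scheme's state order
    and sums to one.
    """
    return posterior_joint(net, (query,), evidence)


def posterior_by_enumeration(
    net: BayesianNetwork,
    query: str,
    evidence: Mapping[str, str] | None = None,
) -> np.ndarray:
    """Posterior by brute-force summation over the full joint (test oracle)."""
    evidence = _validate_evidence(net, evidence or {})
    nodes = list(net.structure.nodes)
    cards = [net.card(n) for n in nodes]
    qi = nodes.index(query)
    acc = np.zeros(net.card(query))
    ev_idx = {nodes.index(v): net.state_index(v, s) for v, s in evidence.items()}
    for assign in itertools.product(*(range(c) for c in cards)):
        if any(assign[i] != s for i, s in ev_idx.items()):
            continue
        p = 1.0
        for i, n in enumerate(nodes):
            cpt = net.cpts[n]
            idx = tuple(assign[nodes.index(par)] for par in cpt.parents) + (assign[i],)
            p *= cpt.values[idx]
        acc[assign[qi]] += p
    total = acc.sum()
    if total <= 0.0:
        raise ImpossibleEvidenceError("impossible evidence (enumeration)")
    return acc / total


def joint_probability(
    net: BayesianNetwork,
    assignment: Mapping[str, str],
    log: bool = False,
) -> float:
    """Probability of one full assignment: the product of selected CPT entries.

    With ``log=True`` the result is returned in natural-log space (useful for
    dataset likelihoods); a zero entry yields ``-inf``.
    """
    missing = [n for n in net.structure.nodes if n not in assignment]
    if missing:
        raise NetworkError(f"assignment does not cover nodes {missing}")
    idx = {n: net.state_index(n, assignment[n]) for n in net.structure.nodes}
    if log:
        total = 0.0
        for n in net.structure.nodes:
            cpt = net.cpts[n]
            p = cpt.values[tuple(idx[par] for par in cpt.parents) + (idx[n],)]
            total += math.log(p) if p > 0 else -math.inf
        return total
    prod = 1.0
    for n in net.structure.nodes:
        cpt = net.cpts[n]
        prod *= cpt.values[tuple(idx[par] for par in cpt.parents) + (idx[n],)]
    return float(prod)


def marginals(net: BayesianNetwork) -> dict[str, np.ndarray]:
    """Prior marginal distribution of every node (posterior with no evidence)."""
    return {n: posterior(net, n) for n in net.structure.nodes}


# ---------------------------------------------------------------------------
# Serialization: JSON / YAML and XMLBIF
# ---------------------------------------------------------------------------

def network_to_dict(net: BayesianNetwork) -> dict:
    return {
        "scheme": net.scheme.to_dict(),
        "structure": {n: list(net.structure.parents[n]) for n in net.structure.nodes},
        "nodes": list(net.structure.nodes),
        # flat rows: child states vary fastest, parent configs lexicographic
        "cpts": {n: net.cpts[n].values.reshape(-1).tolist() for n in net.structure.nodes},
    }


def network_from_dict(data: Mapping) -> BayesianNetwork:
    scheme = VariableScheme.from_dict(data["scheme"])
    nodes = tuple(data["nodes"])
    structure = NetworkStructure(
        nodes=nodes, parents={n: tuple(ps) for n, ps in data["structure"].items()}
    )
    cpts = {}
    for n in nodes:
        parents = structure.parents[n]
        shape = tuple(scheme[p].n_states for p in parents) + (scheme[n].n_states,)
        vals = np.asarray(data["cpts"][n], dtype=float).reshape(shape)
        cpts[n] = CPT(child=n, parents=parents, values=vals)
    return BayesianNetwork(scheme=scheme, structure=structure, cpts=cpts)


def save_network(net: BayesianNetwork, path) -> None:
    path = Path(path)
    data = network_to_dict(net)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    elif path.suffix.lower() in (".xml", ".xmlbif", ".bif"):
        path.write_text(to_xmlbif(net))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_network(path) -> BayesianNetwork:
    path = Path(path)
    text = path.read_text()
    suffix = path.suffix.lower()
    if suffix in (".xml", ".xmlbif", ".bif"):
        return from_xmlbif(text)
    data = json.loads(text) if suffix == ".json" else yaml.safe_load(text)
    return network_from_dict(data)


def to_xmlbif(net: BayesianNetwork, name: str = "hrubnet") -> str:
    """Serialize to the XMLBIF interchange format.

    Table entries follow this package's storage order: child states vary
    fastest, parent configurations lexicographic by the GIVEN order.
    """
    root = ET.Element("BIF", VERSION="0.3")
    network = ET.SubElement(root, "NETWORK")
    ET.SubElement(network, "NAME").text = name
    for n in net.structure.nodes:
        var = ET.SubElement(network, "VARIABLE", TYPE="nature")
        ET.SubElement(var, "NAME").text = n
        for s in net.scheme[n].states:
            ET.SubElement(var, "OUTCOME").text = s
    for n in net.structure.nodes:
        defn = ET.SubElement(network, "DEFINITION")
        ET.SubElement(defn, "FOR").text = n
        for p in net.cpts[n].parents:
            ET.SubElement(defn, "GIVEN").text = p
        flat = net.cpts[n].values.reshape(-1)
        ET.SubElement(defn, "TABLE").text = " ".join(repr(float(x)) for x in flat)
    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True)


def from_xmlbif(text: str, target: str = "HRUB") -> BayesianNetwork:
    """Parse an XMLBIF document written by :func:`to_xmlbif`."""
    from .scheme import VariableSpec

    root = ET.fromstring(text)
    network = root.find("NETWORK")
    if network is None:
        raise NetworkError("XMLBIF document has no NETWORK element")
    specs = []
    for var in network.findall("VARIABLE"):
        name = var.findtext("NAME")
        states = tuple(o.text or "" for o in var.findall("OUTCOME"))
        specs.append(VariableSpec(name=name, states=states))
    names = tuple(s.name for s in specs)
    tgt = target if target in names else names[-1]
    scheme = VariableScheme(variables=tuple(specs), target=tgt)
    parents: dict[str, tuple[str, ...]] = {}
    tables: dict[str, np.ndarray] = {}
    for defn in network.findall("DEFINITION"):
        child = defn.findtext("FOR")
        given = tuple(g.text or "" for g in defn.findall("GIVEN"))
        parents[child] = given
        flat = np.array([float(x) for x in (defn.findtext("TABLE") or "").split()])
        shape = tuple(scheme[p].n_states for p in given) + (scheme[child].n_states,)
        tables[child] = flat.reshape(shape)
    structure = NetworkStructure(nodes=names, parents=parents)
    cpts = {
        n: CPT(child=n, parents=structure.parents[n], values=tables[n]) for n in names
    }
    return BayesianNetwork(scheme=scheme, structure=structure, cpts=cpts)
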