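"""CPT estimation from observation data via Expectation-Maximization.

Each E-step computes, per record, the exact posterior over that record's
missing variables given its observed ones (using the variable-elimination
engine) and accumulates expected counts for every node family; the M-step
renormalizes the smoothed expected counts into CPT rows.  With complete data
and no smoothing the procedure reduces to maximum-likelihood frequency
counting and converges in two iterations.

Smoothing.  The default prior is an empirical-Bayes Dirichlet: each node
carries a total prior mass ``ess`` (equivalent sample size, default 1)
spread equally over its parent configurations, with prior *mean* equal to
the node's own marginal distribution as estimated in the first E-step (and
held fixed thereafter, which keeps the EM objective monotone).  Parent
configurations never seen in the data therefore back off to the node's
marginal rather than to a uniform row — essential for sparse tables such as
the study outcome's 1458 parent configurations, where a uniform fallback
would visibly bias the fitted marginals.  A flat per-cell ``pseudocount``
(e.g. 1 for Laplace) may be supplied instead; with ``pseudocount=0``,
parent configurations with zero expected count yield a uniform row
(documented convention, not an error).

``loglik_trace`` records the maximized objective at the start of each
iteration: the dataset log-likelihood plus the log-prior term when smoothing
is active (the plain log-likelihood when ``pseudocount=0``).  By the EM/MAP
ascent property the trace is non-decreasing.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .network import (
    BayesianNetwork,
    CPT,
    NetworkStructure,
    evidence_probability,
    posterior_joint,
)
from .scheme import ObservationDataset, VariableScheme

__all__ = ["EMError", "EMConfig", "EMResult", "fit_em", "log_likelihood"]

logger = logging.getLogger(__name__)


class EMError(ValueError):
    """Invalid EM inputs or configuration."""


@dataclass(frozen=True)
class EMConfig:
    """EM hyper-parameters.

    pseudocount: flat per-cell count added to expected counts; ``None``
        (default) selects the empirical-Bayes Dirichlet prior described in
        the module docstring.
    ess: total prior mass per node for the default prior (ignored when a
        flat ``pseudocount`` is given).
    tolerance: convergence threshold on the relative objective change.
    init: 'uniform' or 'random' (random rows drawn Dirichlet(1) from seed).
    """

    pseudocount: float | None = None
    ess: float = 1.0
    tolerance: float = 1e-6
    max_iterations: int = 500
    init: str = "uniform"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.pseudocount is not None and self.pseudocount < 0:
            raise EMError("pseudocount must be ≥ 0")
        if self.ess < 0:
            raise EMError("ess must be ≥ 0")
        if self.tolerance <= 0:
            raise EMError("tolerance must be > 0")
        if self.max_iterations < 1:
            raise EMError("max_iterations must be ≥ 1")
        if self.init not in ("uniform", "random"):
            raise EMError(f"unknown init {self.init!r}")


@dataclass
class EMResult:
    """Fitted network plus the per-iteration objective trace.

    ``loglik_trace`` holds the EM objective (log-likelihood, plus the
    log-prior when smoothing is active) at the start of each iteration; it
    is non-decreasing.
    """

    network: BayesianNetwork
    loglik_trace: list[float]
    iterations: int
    converged: bool


def _initial_cpts(
    structure: NetworkStructure, scheme: VariableScheme, config: EMConfig
) -> dict[str, CPT]:
    rng = np.random.default_rng(config.seed)
    cpts = {}
    for n in structure.nodes:
        parents = structure.parents[n]
        shape = tuple(scheme[p].n_states for p in parents) + (scheme[n].n_states,)
        if config.init == "uniform":
            vals = np.full(shape, 1.0 / shape[-1])
        else:
            vals = rng.dirichlet(np.ones(shape[-1]), size=shape[:-1]).reshape(shape)
        cpts[n] = CPT(child=n, parents=parents, values=vals)
    return cpts


def _grouped_patterns(dataset: ObservationDataset, nodes: tuple[str, ...]):
    """Unique observed patterns with multiplicities and a representative index.

    Patterns are tuples of state indices with -1 for missing, aligned with
    ``nodes``.  Grouping makes the E-step cost scale with the number of
    distinct patterns, not records.
    """
    mat = dataset.state_index_matrix()
    for n in nodes:
        if n not in mat.columns:
            mat[n] = -1
    arr = mat[list(nodes)].to_numpy()
    patterns: dict[tuple, list] = {}
    for i, row in enumerate(map(tuple, arr)):
        if row in patterns:
            patterns[row][0] += 1
        else:
            patterns[row] = [1, i]
    return [(k, w, first) for k, (w, first) in patterns.items()]


def _pattern_evidence(
    pattern: tuple, nodes: tuple[str, ...], scheme: VariableScheme
) -> dict[str, str]:
    return {n: scheme[n].states[s] for n, s in zip(nodes, pattern) if s >= 0}


def log_likelihood(net: BayesianNetwork, dataset: ObservationDataset) -> float:
    """Dataset log-likelihood: Σ_records log P(observed part of the record).

    Missing variables are marginalized out by exact inference.  A record with
    zero probability makes the result ``-inf``; the offending record index is
    reported through the module logger.
    """
    if len(dataset) == 0:
        raise EMError("empty dataset")
    nodes = tuple(net.structure.nodes)
    total = 0.0
    for pattern, weight, first in _grouped_patterns(dataset, nodes):
        ev = _pattern_evidence(pattern, nodes, net.scheme)
        p = evidence_probability(net, ev) if ev else 1.0
        if p <= 0.0:
            logger.warning(
                "record %d has probability 0 under the network; "
                "log-likelihood is -inf",
                first,
            )
            return -math.inf
        total += weight * math.log(p)
    return total


def _expected_counts(
    net: BayesianNetwork, patterns, nodes: tuple[str, ...]
) -> tuple[dict[str, np.ndarray], float]:
    """E-step: expected family counts and the current data log-likelihood."""
    scheme = net.scheme
    counts = {n: np.zeros(net.cpts[n].values.shape) for n in nodes}
    loglik = 0.0
    node_pos = {n: i for i, n in enumerate(nodes)}
    for pattern, weight, first in patterns:
        ev = _pattern_evidence(pattern, nodes, scheme)
        p = evidence_probability(net, ev) if ev else 1.0
        if p <= 0.0:
            logger.warning(
                "record %d impossible under current parameters; skipped in "
                "E-step",
                first,
            )
            loglik = -math.inf
            continue
        if loglik != -math.inf:
            loglik += weight * math.log(p)
        if len(ev) == len(nodes):
            # fully observed: plain counting, no inference needed
            for n in nodes:
                cpt = net.cpts[n]
                idx = tuple(pattern[node_pos[q]] for q in cpt.parents) + (
                    pattern[node_pos[n]],
                )
                counts[n][idx] += weight
        else:
            for n in nodes:
                cpt = net.cpts[n]
                family = tuple(cpt.parents) + (n,)
                counts[n] += weight * posterior_joint(net, family, ev)
    return counts, loglik


def _prior_from_counts(
    counts: Mapping[str, np.ndarray], config: EMConfig
) -> dict[str, np.ndarray]:
    """Per-cell prior pseudo-counts, fixed after the first E-step.

    Flat ``pseudocount`` → constant arrays.  Default: per node, total mass
    ``ess`` split equally over parent configurations, with prior mean equal
    to the node's expected marginal (smoothed minimally so no state has
    exactly zero prior mass unless the node's table is degenerate).
    """
    prior: dict[str, np.ndarray] = {}
    for n, cnt in counts.items():
        if config.pseudocount is not None:
            prior[n] = np.full_like(cnt, config.pseudocount)
            continue
        k = cnt.shape[-1]
        n_rows = cnt.size // k
        marg = cnt.reshape(-1, k).sum(axis=0)
        total = marg.sum()
        mean = (marg + 1.0) / (total + k) if total > 0 else np.full(k, 1.0 / k)
        prior[n] = np.broadcast_to(
            (config.ess / n_rows) * mean, cnt.shape
        ).copy()
    return prior


def _log_prior_term(net: BayesianNetwork, prior: Mapping[str, np.ndarray]) -> float:
    total = 0.0
    for n, pseudo in prior.items():
        theta = net.cpts[n].values
        mask = pseudo > 0
        if not np.any(mask):
            continue
        with np.errstate(divide="ignore"):
            logs = np.log(theta[mask])
        total += float((pseudo[mask] * logs).sum())
    return total


def _m_step(
    net: BayesianNetwork,
    counts: Mapping[str, np.ndarray],
    prior: Mapping[str, np.ndarray],
) -> dict[str, CPT]:
    cpts = {}
    for n, cnt in counts.items():
        smoothed = cnt + prior[n]
        row_sums = smoothed.sum(axis=-1, keepdims=True)
        k = smoothed.shape[-1]
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = smoothed / row_sums
        # parent configurations with no counts and no prior → uniform row
        empty = (row_sums == 0.0).reshape(row_sums.shape[:-1])
        if np.any(empty):
            vals[empty] = 1.0 / k
        cpts[n] = CPT(child=n, parents=net.cpts[n].parents, values=vals)
    return cpts


def fit_em(
    structure: NetworkStructure,
    scheme: VariableScheme,
    dataset: ObservationDataset,
    config: EMConfig | None = None,
) -> EMResult:
    """Fit all CPTs to an observation dataset by EM.

    Records with every variable missing are legal; they contribute their
    prior expectation.  Convergence is declared when the relative change of
    the objective trace drops below ``config.tolerance`` or the parameters
    become stationary.
    """
    config = config or EMConfig()
    if len(dataset) == 0:
        raise EMError("empty dataset")
    extra = set(dataset.scheme.names) - set(structure.nodes)
    if extra:
        raise EMError(f"dataset variables {sorted(extra)} are not network nodes")
    net = BayesianNetwork(
        scheme=scheme,
        structure=structure,
        cpts=_initial_cpts(structure, scheme, config),
    )
    nodes = tuple(structure.nodes)
    patterns = _grouped_patterns(dataset, nodes)
    trace: list[float] = []
    prior: dict[str, np.ndarray] | None = None
    converged = False
    iterations = 0
    for it in range(1, config.max_iterations + 1):
        iterations = it
        counts, loglik = _expected_counts(net, patterns, nodes)
        if prior is None:
            prior = _prior_from_counts(counts, config)
        trace.append(loglik + _log_prior_term(net, prior))
        new_cpts = _m_step(net, counts, prior)
        stationary = all(
            np.array_equal(new_cpts[n].values, net.cpts[n].values)
            for n in structure.nodes
        )
        net = BayesianNetwork(scheme=scheme, structure=structure, cpts=new_cpts)
        if stationary:
            converged = True
            break
        if len(trace) >= 2 and math.isfinite(trace[-1]) and math.isfinite(trace[-2]):
            denom = abs(trace[-2]) if trace[-2] != 0.0 else 1.0
            if abs(trace[-1] - trace[-2]) / denom < config.tolerance:
                converged = True
                break
    return EMResult(
        network=net, loglik_trace=trace, iterations=iterations, converged=converged
    )
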