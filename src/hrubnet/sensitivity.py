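"""Sensitivity analysis: which variables drive the unsafe-behavior outcome.

Two complementary statistics rank the predictors of the target (HRUB = yes):

* the *variation statistic*: for each state s of a predictor X, the signed
  percent relative change of the target's adverse-state probability when X
  is observed in state s,

      V_s = 100 · (P(t | X=s) − P(t)) / P(t),

  summarized per variable as the mean of |V_s| ("absolute mean of
  variations"), and

* the *mutual information* I(X; T) = Σ p(x,t) log[p(x,t) / (p(x)p(t))]
  (bits by default), with joint and marginals obtained by exact inference.

Variables are ranked by descending absolute mean variation; ties are broken
by descending mutual information, then variable name.  Because the two
statistics need not agree, the report also carries the pure-MI ranking and
the Spearman correlation between the two orderings.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .network import BayesianNetwork, posterior, posterior_joint

__all__ = [
    "SensitivityError",
    "SensitivityEntry",
    "SensitivityReport",
    "state_variations",
    "absolute_mean_variation",
    "mutual_information",
    "rank_variables",
    "analyze",
]


class SensitivityError(ValueError):
    """Invalid sensitivity-analysis inputs."""


@dataclass(frozen=True)
class SensitivityEntry:
    """Per-variable sensitivity summary (one row of the ranking table)."""

    variable: str
    states: tuple[str, ...]
    variations: tuple[float, ...]  # signed percents, one per state
    abs_mean_variation: float  # percent
    mutual_information: float  # bits unless another base was requested
    rank: int | None = None
    mi_rank: int | None = None


@dataclass(frozen=True)
class SensitivityReport:
    """Ranked sensitivity of the target's adverse state to every predictor."""

    target: str
    adverse_state: str
    baseline: float  # P(target = adverse_state), no evidence
    entries: tuple[SensitivityEntry, ...]
    spearman: float | None = None  # agreement of variation vs MI orderings

    def to_dataframe(self) -> pd.DataFrame:
        """Ranking-table layout: per-state variations, abs mean, MI, rank.

        Variables with fewer states than the widest one get a '-' in the
        unused variation cells.
        """
        width = max(len(e.states) for e in self.entries)
        rows = []
        for e in sorted(self.entries, key=lambda e: e.rank or 0):
            row: dict = {"variable": e.variable}
            for i in range(width):
                row[f"state {i + 1}"] = (
                    round(e.variations[i], 2) if i < len(e.variations) else "-"
                )
            row["abs mean of variations"] = round(e.abs_mean_variation, 2)
            row["mutual information"] = round(e.mutual_information, 5)
            row["rank"] = e.rank
            rows.append(row)
        return pd.DataFrame(rows)

    def conditionals_dataframe(self) -> pd.DataFrame:
        """P(target = adverse | each predictor state), from the variations."""
        rows = []
        for e in self.entries:
            for s, v in zip(e.states, e.variations):
                rows.append(
                    {
                        "variable": e.variable,
                        "state": s,
                        f"P({self.target}={self.adverse_state})": self.baseline
                        * (1.0 + v / 100.0),
                    }
                )
        return pd.DataFrame(rows)


def state_variations(
    net: BayesianNetwork,
    variable: str,
    target: str | None = None,
    adverse_state: str | None = None,
) -> np.ndarray:
    """Signed percent change of P(target=adverse) under each state of a variable.

    Evidence is placed on the single queried variable only; conditioning is
    observational.
    """
    target = target or net.scheme.target
    if variable == target:
        raise SensitivityError("variable must differ from the target")
    adverse_state = adverse_state or net.scheme[target].states[-1]
    t_idx = net.state_index(target, adverse_state)
    baseline = float(posterior(net, target)[t_idx])
    if baseline <= 0.0:
        raise SensitivityError(
            f"baseline P({target}={adverse_state}) is zero; variations undefined"
        )
    out = []
    for s in net.scheme[variable].states:
        cond = float(posterior(net, target, {variable: s})[t_idx])
        out.append(100.0 * (cond - baseline) / baseline)
    return np.array(out)


def absolute_mean_variation(variations) -> float:
    """Mean of absolute per-state variations (percent).

    Two-state variables simply contribute two terms.
    """
    arr = np.asarray(list(variations), dtype=float)
    if arr.size == 0:
        raise SensitivityError("empty variation list")
    return float(np.mean(np.abs(arr)))


def mutual_information(
    net: BayesianNetwork, variable: str, target: str | None = None, base: float = 2.0
) -> float:
    """Mutual information between a variable and the target, by exact inference.

    Bits by default; pass ``base=math.e`` for nats.  Zero-probability cells
    contribute zero (0·log(0/q) := 0).
    """
    target = target or net.scheme.target
    if variable == target:
        raise SensitivityError("variable must differ from the target")
    joint = posterior_joint(net, (variable, target))
    px = joint.sum(axis=1, keepdims=True)
    pt = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(joint > 0, joint / (px * pt), 1.0)
        terms = np.where(joint > 0, joint * np.log(ratio), 0.0)
    return float(terms.sum() / math.log(base))


def rank_variables(entries) -> tuple[SensitivityEntry, ...]:
    """Assign ranks: descending abs mean variation, ties by MI, then name.

    Also assigns the pure-MI ranking (``mi_rank``) for comparison; the input
    order is irrelevant.
    """
    entries = list(entries)
    if not entries:
        raise SensitivityError("no entries to rank")
    by_var = sorted(
        entries,
        key=lambda e: (-e.abs_mean_variation, -e.mutual_information, e.variable),
    )
    by_mi = sorted(
        entries, key=lambda e: (-e.mutual_information, -e.abs_mean_variation, e.variable)
    )
    mi_rank = {e.variable: i + 1 for i, e in enumerate(by_mi)}
    return tuple(
        replace(e, rank=i + 1, mi_rank=mi_rank[e.variable])
        for i, e in enumerate(by_var)
    )


def analyze(
    net: BayesianNetwork,
    target: str | None = None,
    adverse_state: str | None = None,
    mi_base: float = 2.0,
) -> SensitivityReport:
    """Full sensitivity report over every non-target variable, ranked."""
    target = target or net.scheme.target
    adverse_state = adverse_state or net.scheme[target].states[-1]
    t_idx = net.state_index(target, adverse_state)
    baseline = float(posterior(net, target)[t_idx])
    raw = []
    for v in net.structure.nodes:
        if v == target:
            continue
        variations = state_variations(net, v, target, adverse_state)
        raw.append(
            SensitivityEntry(
                variable=v,
                states=tuple(net.scheme[v].states),
                variations=tuple(float(x) for x in variations),
                abs_mean_variation=absolute_mean_variation(variations),
                mutual_information=mutual_information(net, v, target, base=mi_base),
            )
        )
    ranked = rank_variables(raw)
    if len(ranked) >= 2:
        rho = stats.spearmanr(
            [e.rank for e in ranked], [e.mi_rank for e in ranked]
        ).statistic
    else:
        rho = None
    return SensitivityReport(
        target=target,
        adverse_state=adverse_state,
        baseline=baseline,
        entries=ranked,
        spearman=None if rho is None else float(rho),
    )
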