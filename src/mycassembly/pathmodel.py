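"""Recursive path analysis over observed (pairwise) variables.

A directed acyclic graph declares which variables drive which: each
endogenous variable is regressed on its parents by OLS after all variables
are standardized to mean 0, SD 1, so the coefficients are standardized
path coefficients. Effects on the terminal outcome decompose by path
tracing: the direct effect of a variable is its edge coefficient into the
outcome (zero if absent), each indirect effect is the product of
coefficients along a directed path of length >= 2, and the total effect is
the sum over all directed paths.

This is the saturated-recursive special case of structural equation
modelling on observed variables; there are no latent constructs and no
covariance-structure fit indices. When the variables are pairwise
(distance-scale) quantities the pairs are not independent, so nominal OLS
standard errors are optimistic — an optional permutation p-value is
provided for the outcome equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["PathSpec", "PathFit", "fit_path_model", "variance_explained"]


@dataclass
class PathSpec:
    """Directed acyclic path diagram: nodes and parent -> child edges."""

    edges: list[tuple[str, str]]
    outcome: str | None = None

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_edges_from(self.edges)
        return g

    def validate(self, variables: list[str]) -> nx.DiGraph:
        g = self.graph()
        unknown = sorted(set(g.nodes) - set(variables))
        if unknown:
            raise ValueError(f"edge endpoint(s) not in data: {unknown}")
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"path diagram contains a cycle: {cycle}")
        sinks = [n for n in g.nodes if g.out_degree(n) == 0]
        if self.outcome is None:
            if len(sinks) != 1:
                raise ValueError(
                    f"expected exactly one terminal outcome, found sinks {sinks}; "
                    "set PathSpec.outcome explicitly"
                )
            self.outcome = sinks[0]
        elif self.outcome not in g.nodes:
            raise ValueError(f"outcome {self.outcome!r} not in the diagram")
        return g

    @classmethod
    def from_dict(cls, doc: dict) -> "PathSpec":
        """Build from a YAML/JSON document: {edges: [[parent, child], ...], outcome: name}."""
        return cls(edges=[tuple(e) for e in doc["edges"]], outcome=doc.get("outcome"))

    def to_dot(self) -> str:
        lines = ["digraph paths {"]
        for a, b in self.edges:
            lines.append(f'  "{a}" -> "{b}";')
        lines.append("}")
        return "\n".join(lines)


@dataclass
class PathFit:
    coefficients: dict[tuple[str, str], float]   # (parent, child) -> standardized beta
    effects: pd.DataFrame                         # direct, indirect, total on the outcome
    r2: dict[str, float]                          # per endogenous variable
    outcome: str
    outcome_p: float = field(default=float("nan"))

    @property
    def outcome_r2(self) -> float:
        return self.r2[self.outcome]

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "coefficients": {f"{a}->{b}": v for (a, b), v in self.coefficients.items()},
            "r2": self.r2,
            "effects": self.effects.to_dict(orient="index"),
        }


def _standardize(data: pd.DataFrame) -> pd.DataFrame:
    sd = data.std(axis=0, ddof=1)
    bad = sd.index[sd == 0].tolist()
    if bad:
        raise ValueError(f"zero-variance variable(s): {bad}")
    return (data - data.mean(axis=0)) / sd


def fit_path_model(spec: PathSpec, data: pd.DataFrame,
                   permutations: int = 0, seed: int | None = None) -> PathFit:
    """Fit every structural equation of the DAG and decompose effects.

    ``data`` holds one column per variable (rows are observations — for
    this pipeline, sample pairs). Returns standardized coefficients per
    edge, R^2 per endogenous variable, and the direct/indirect/total
    effect of every non-outcome variable on the outcome.
    """
    g = spec.validate(list(data.columns))
    z = _standardize(data[[c for c in data.columns if c in g.nodes]])
    coefficients: dict[tuple[str, str], float] = {}
    r2: dict[str, float] = {}
    for child in nx.topological_sort(g):
        parents = sorted(g.predecessors(child))
        if not parents:
            continue
        X = np.column_stack([z[p].to_numpy() for p in parents])
        y = z[child].to_numpy()
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise ValueError(f"rank-deficient parent set for {child!r}: {parents}")
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        r2[child] = 1.0 - float(np.sum(resid**2)) / float(np.sum(y**2))
        for p_name, c in zip(parents, coef):
            coefficients[(p_name, child)] = float(c)

    outcome = spec.outcome
    rows = {}
    for node in g.nodes:
        if node == outcome:
            continue
        direct = coefficients.get((node, outcome), 0.0)
        indirect = 0.0
        total = 0.0
        for path in nx.all_simple_paths(g, node, outcome):
            contrib = float(np.prod([coefficients[(a, b)] for a, b in zip(path, path[1:])]))
            total += contrib
            if len(path) > 2:
                indirect += contrib
        rows[node] = {"direct": direct, "indirect": indirect, "total": total}
    effects = pd.DataFrame.from_dict(rows, orient="index",
                                     columns=["direct", "indirect", "total"])

    outcome_p = float("nan")
    if permutations > 0:
        rng = np.random.default_rng(seed)
        parents = sorted(g.predecessors(outcome))
        X = np.column_stack([z[p].to_numpy() for p in parents])
        y = z[outcome].to_numpy()
        obs = r2[outcome]
        count = 0
        for _ in range(permutations):
            y_perm = rng.permutation(y)
            coef, *_ = np.linalg.lstsq(X, y_perm, rcond=None)
            resid = y_perm - X @ coef
            r2_perm = 1.0 - float(np.sum(resid**2)) / float(np.sum((y_perm - y_perm.mean())**2))
            if r2_perm >= obs:
                count += 1
        outcome_p = (count + 1) / (permutations + 1)
    return PathFit(coefficients=coefficients, effects=effects, r2=r2,
                   outcome=outcome, outcome_p=outcome_p)


def variance_explained(fit: PathFit) -> float:
    """R^2 of the outcome's structural equation."""
    return fit.outcome_r2
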