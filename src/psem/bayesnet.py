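"""Discrete Bayesian networks: structure, MLE parameters, exact inference.

The network is a DAG over named categorical variables. Conditional
probability tables (CPTs) are stored as dense ndarrays whose axes are
``(*parent_arities, child_arity)`` in the order listed by
``structure.parents[node]``. Inference is exact variable elimination
with a min-degree heuristic; evidence may be hard (a fixed category) or
soft (a likelihood vector multiplied into the node's potential — Pearl's
virtual evidence, which is what perturbational effect estimation needs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DAGStructure", "DiscreteBN", "Evidence", "fit_cpts_mle", "query",
           "loglik_bits", "joint_table"]


@dataclass
class DAGStructure:
    """Directed acyclic graph over named categorical variables."""

    arities: dict[str, int]
    parents: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.parents = {v: tuple(self.parents.get(v, ())) for v in self.arities}
        for v, ps in self.parents.items():
            if v in ps:
                raise ValueError(f"self-arc on {v}")
            if len(set(ps)) != len(ps):
                raise ValueError(f"duplicate parents of {v}")
            for p in ps:
                if p not in self.arities:
                    raise ValueError(f"unknown parent {p} of {v}")
        if self._has_cycle():
            raise ValueError("graph is cyclic")

    @property
    def nodes(self) -> list[str]:
        return list(self.arities)

    @property
    def arcs(self) -> list[tuple[str, str]]:
        return [(p, c) for c, ps in self.parents.items() for p in ps]

    def _has_cycle(self) -> bool:
        state: dict[str, int] = {}

        def visit(v: str) -> bool:
            state[v] = 1
            for p in self.parents[v]:
                s = state.get(p, 0)
                if s == 1 or (s == 0 and visit(p)):
                    return True
            state[v] = 2
            return False

        return any(state.get(v, 0) == 0 and visit(v) for v in self.arities)

    def topological_order(self) -> list[str]:
        order, seen = [], set()

        def visit(v: str) -> None:
            if v in seen:
                return
            seen.add(v)
            for p in self.parents[v]:
                visit(p)
            order.append(v)

        for v in self.arities:
            visit(v)
        return order


@dataclass
class Evidence:
    """Hard (fixed category) and soft (likelihood vector) evidence."""

    hard: dict[str, int] = field(default_factory=dict)
    soft: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v, vec in self.soft.items():
            a = np.asarray(vec, float)
            if (a < 0).any() or a.sum() <= 0:
                raise ValueError(f"invalid soft evidence on {v}")
            self.soft[v] = a


@dataclass
class DiscreteBN:
    structure: DAGStructure
    cpts: dict[str, np.ndarray]
    sample_size_fitted: int = 0

    def __post_init__(self) -> None:
        for v, cpt in self.cpts.items():
            shape = tuple(self.structure.arities[p] for p in self.structure.parents[v])
            shape = shape + (self.structure.arities[v],)
            if cpt.shape != shape:
                raise ValueError(f"CPT shape mismatch for {v}: {cpt.shape} != {shape}")
            s = cpt.sum(axis=-1)
            if not np.allclose(s, 1.0, atol=1e-9):
                raise ValueError(f"CPT of {v} does not normalize")


def _encode(data: pd.DataFrame, cols: tuple[str, ...], arities: dict[str, int]):
    """Mixed-radix encoding of the joint configuration of ``cols``."""
    code = np.zeros(len(data), dtype=np.int64)
    size = 1
    for c in cols:
        vals = data[c].to_numpy()
        if vals.min() < 0 or vals.max() >= arities[c]:
            raise ValueError(f"category index out of range in column {c}")
        code = code * arities[c] + vals
        size *= arities[c]
    return code, size


def family_counts(
    data: pd.DataFrame, child: str, parents: tuple[str, ...], arities: dict[str, int]
) -> np.ndarray:
    """Counts with shape (*parent_arities, child_arity)."""
    cols = tuple(parents) + (child,)
    code, size = _encode(data, cols, arities)
    counts = np.bincount(code, minlength=size).astype(float)
    return counts.reshape(tuple(arities[c] for c in cols))


def fit_cpts_mle(
    structure: DAGStructure, data: pd.DataFrame, pseudocount: float = 0.0
) -> DiscreteBN:
    """Maximum-likelihood CPTs, optionally Laplace-smoothed.

    Entries are (count + pseudocount) / (parent-config count +
    pseudocount * arity); a parent configuration never observed (and
    pseudocount 0) yields a uniform distribution.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    cpts = {}
    for v in structure.nodes:
        counts = family_counts(data, v, structure.parents[v], structure.arities)
        counts = counts + pseudocount
        totals = counts.sum(axis=-1, keepdims=True)
        arity = structure.arities[v]
        with np.errstate(invalid="ignore", divide="ignore"):
            cpt = np.where(totals > 0, counts / np.where(totals > 0, totals, 1.0),
                           1.0 / arity)
        cpts[v] = cpt
    return DiscreteBN(structure, cpts, sample_size_fitted=len(data))


# ---------------------------------------------------------------- inference

class _Factor:
    __slots__ = ("vars", "table")

    def __init__(self, vars: tuple[str, ...], table: np.ndarray):
        self.vars = vars
        self.table = table

    def multiply(self, other: "_Factor") -> "_Factor":
        out_vars = self.vars + tuple(v for v in other.vars if v not in self.vars)

        def expand(f: "_Factor") -> np.ndarray:
            order = sorted(range(len(f.vars)), key=lambda i: out_vars.index(f.vars[i]))
            t = np.transpose(f.table, order) if f.vars else f.table
            idx = tuple(slice(None) if v in f.vars else np.newaxis for v in out_vars)
            return t[idx] if out_vars else t

        return _Factor(out_vars, expand(self) * expand(other))

    def marginalize(self, var: str) -> "_Factor":
        i = self.vars.index(var)
        return _Factor(self.vars[:i] + self.vars[i + 1:], self.table.sum(axis=i))

    def reduce(self, var: str, value: int) -> "_Factor":
        i = self.vars.index(var)
        return _Factor(self.vars[:i] + self.vars[i + 1:],
                       np.take(self.table, value, axis=i))


def _bn_factors(bn: DiscreteBN, evidence: Evidence | None) -> list[_Factor]:
    ev = evidence or Evidence()
    factors = []
    for v in bn.structure.nodes:
        f = _Factor(tuple(bn.structure.parents[v]) + (v,), bn.cpts[v])
        factors.append(f)
    for v, vec in ev.soft.items():
        factors.append(_Factor((v,), np.asarray(vec, float)))
    out = []
    for f in factors:
        for v, val in ev.hard.items():
            if v in f.vars:
                f = f.reduce(v, val)
        out.append(f)
    return out


def _eliminate(factors: list[_Factor], keep: set[str]) -> _Factor:
    factors = list(factors)
    all_vars = set(v for f in factors for v in f.vars)
    to_remove = sorted(all_vars - keep)
    while to_remove:
        # min-degree: eliminate the variable whose combined factor is smallest
        def cost(v: str) -> int:
            s = set()
            for f in factors:
                if v in f.vars:
                    s.update(f.vars)
            return len(s)

        v = min(to_remove, key=lambda u: (cost(u), u))
        to_remove.remove(v)
        related = [f for f in factors if v in f.vars]
        rest = [f for f in factors if v not in f.vars]
        prod = related[0]
        for f in related[1:]:
            prod = prod.multiply(f)
        factors = rest + [prod.marginalize(v)]
    prod = _Factor((), np.array(1.0))
    for f in factors:
        prod = prod.multiply(f)
    return prod


def query(bn: DiscreteBN, evidence: Evidence | None, target: str) -> np.ndarray:
    """Exact posterior P(target | evidence) by variable elimination."""
    ev = evidence or Evidence()
    if target in ev.hard:
        raise ValueError(f"target {target} is fixed by hard evidence")
    return marginal(bn, (target,), ev)


def marginal(bn: DiscreteBN, variables: tuple[str, ...],
             evidence: Evidence | None = None) -> np.ndarray:
    """Joint posterior over a (small) set of variables, axes in given order."""
    f = _eliminate(_bn_factors(bn, evidence), set(variables))
    # align axes
    missing = [v for v in variables if v not in f.vars]
    if missing:
        raise ValueError(f"variables {missing} eliminated (fixed by evidence?)")
    order = [f.vars.index(v) for v in variables]
    table = np.transpose(f.table, order)
    z = table.sum()
    if z <= 0:
        raise ValueError("impossible evidence")
    return table / z


def loglik_bits(bn: DiscreteBN, data: pd.DataFrame) -> float:
    """−Σ_rows log2 P(row); decomposes over families. +inf on impossible rows."""
    total = 0.0
    for v in bn.structure.nodes:
        cols = tuple(bn.structure.parents[v]) + (v,)
        code, size = _encode(data, cols, bn.structure.arities)
        probs = bn.cpts[v].reshape(-1)[code]
        if (probs <= 0).any():
            import warnings

            warnings.warn(f"zero-probability observation for {v}; loglik is +inf")
            return math.inf
        total -= np.log2(probs).sum()
    return float(total)


def joint_table(bn: DiscreteBN) -> tuple[list[str], np.ndarray]:
    """Full joint distribution (axes in node order). Exponential; small nets only."""
    nodes = bn.structure.nodes
    f = _eliminate(_bn_factors(bn, None), set(nodes))
    order = [f.vars.index(v) for v in nodes]
    return nodes, np.transpose(f.table, order)
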