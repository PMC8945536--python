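"""Bayesian-network structure learning by MDL minimization with tabu search.

The score is the two-part minimum description length in bits,

    MDL(G) = sc * DL_struct(G) + DL_data(D | G)

with ``DL_data`` the negative maximized log-likelihood and, per node,

    DL_struct = log2(n) * (1 + |parents|)
              + (log2 N) / 2 * (arity - 1) * prod(parent arities),

where ``n`` is the node count and ``N`` the sample size. The structural
coefficient ``sc`` in (0, 1] scales the structural term and acts as a
complexity dial: smaller sc admits denser networks. The search is greedy
hill-climbing over arc additions, deletions and reversals with a tabu
list and random restarts; family scores are cached, so move deltas are
local.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bayesnet import DAGStructure, family_counts

__all__ = ["MDLConfig", "mdl_score", "family_score", "tabu_search", "sc_scan",
           "skeleton", "skeleton_f1"]


@dataclass
class MDLConfig:
    sc: float = 0.85
    max_parents: int = 4
    tabu_length: int = 10
    n_restarts: int = 2
    seed: int = 0
    patience: int = 15          # non-improving moves tolerated before stopping
    max_iter: int = 500
    debug_check_decomposability: bool = False
    prior_arcs: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not 0 < self.sc:
            raise ValueError("sc must be > 0")
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")


def _family_dl(counts: np.ndarray) -> float:
    """Data description length of one family: N * H(child | parents) in bits."""
    child_ax = counts.ndim - 1
    totals = counts.sum(axis=child_ax, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = counts * np.log2(np.where(counts > 0, counts, 1.0)
                              / np.where(totals > 0, totals, 1.0))
    return float(-np.nansum(ll))


def family_score(
    data: pd.DataFrame,
    child: str,
    parents: tuple[str, ...],
    arities: dict[str, int],
    n_nodes: int,
    sc: float,
    waived_arcs: frozenset = frozenset(),
) -> float:
    """sc * DL_struct + DL_data for one family (bits).

    Arcs in ``waived_arcs`` (parent, child) are treated as prior knowledge:
    their graph-coding slot cost is waived (the parameter cost is not).
    """
    N = len(data)
    counts = family_counts(data, child, parents, arities)
    dl_data = _family_dl(counts)
    q = 1
    for p in parents:
        q *= arities[p]
    paid_slots = 1 + sum(1 for p in parents if (p, child) not in waived_arcs)
    dl_struct = math.log2(n_nodes) * paid_slots \
        + math.log2(max(N, 2)) / 2 * (arities[child] - 1) * q
    return sc * dl_struct + dl_data


def mdl_score(structure: DAGStructure, data: pd.DataFrame, sc: float = 1.0,
              waived_arcs: frozenset = frozenset()) -> float:
    """Total MDL of a structure on data (bits); decomposes over families."""
    n = len(structure.nodes)
    return sum(
        family_score(data, v, structure.parents[v], structure.arities, n, sc,
                     waived_arcs)
        for v in structure.nodes
    )


class _SearchState:
    """Parent sets + cached family scores + reachability bookkeeping."""

    def __init__(self, data: pd.DataFrame, arities: dict[str, int],
                 config: MDLConfig):
        self.data = data
        self.arities = arities
        self.nodes = sorted(arities)
        self.n = len(self.nodes)
        self.config = config
        self.parents: dict[str, set[str]] = {v: set() for v in self.nodes}
        self._cache: dict[tuple[str, frozenset], float] = {}

    def descendants(self) -> dict[str, set[str]]:
        children: dict[str, list[str]] = {v: [] for v in self.nodes}
        for c, ps in self.parents.items():
            for p in ps:
                children[p].append(c)
        desc: dict[str, set[str]] = {}

        def visit(v: str) -> set[str]:
            if v not in desc:
                desc[v] = set()
                for ch in children[v]:
                    desc[v].add(ch)
                    desc[v] |= visit(ch)
            return desc[v]

        for v in self.nodes:
            visit(v)
        return desc

    def fscore(self, child: str, parents: frozenset) -> float:
        key = (child, parents)
        if key not in self._cache:
            self._cache[key] = family_score(
                self.data, child, tuple(sorted(parents)), self.arities,
                self.n, self.config.sc, self.config.prior_arcs,
            )
        return self._cache[key]

    def total_score(self) -> float:
        return sum(self.fscore(v, frozenset(self.parents[v])) for v in self.nodes)

    def reaches(self, src: str, dst: str, skip_arc=None) -> bool:
        """Directed reachability src -> dst, optionally ignoring one arc."""
        stack, seen = [src], {src}
        children = {v: [] for v in self.nodes}
        for c, ps in self.parents.items():
            for p in ps:
                if skip_arc and (p, c) == skip_arc:
                    continue
                children[p].append(c)
        while stack:
            v = stack.pop()
            if v == dst:
                return True
            for c in children[v]:
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return False

    def moves(self):
        """Yield (kind, parent, child, delta) for all admissible moves."""
        cfg = self.config
        desc = self.descendants()
        for c in self.nodes:
            ps = self.parents[c]
            base = self.fscore(c, frozenset(ps))
            for p in self.nodes:
                if p == c:
                    continue
                if p in ps:
                    # delete
                    delta = self.fscore(c, frozenset(ps - {p})) - base
                    yield ("del", p, c, delta)
                    # reverse p->c to c->p
                    if len(self.parents[p]) < cfg.max_parents and \
                            not self.reaches(p, c, skip_arc=(p, c)):
                        base_p = self.fscore(p, frozenset(self.parents[p]))
                        delta_r = (
                            self.fscore(c, frozenset(ps - {p})) - base
                            + self.fscore(p, frozenset(self.parents[p] | {c}))
                            - base_p
                        )
                        yield ("rev", p, c, delta_r)
                else:
                    if len(ps) >= cfg.max_parents:
                        continue
                    if p in desc[c]:  # adding p->c would close a cycle
                        continue
                    delta = self.fscore(c, frozenset(ps | {p})) - base
                    yield ("add", p, c, delta)

    def apply(self, kind: str, p: str, c: str) -> None:
        if kind == "add":
            self.parents[c].add(p)
        elif kind == "del":
            self.parents[c].discard(p)
        elif kind == "rev":
            self.parents[c].discard(p)
            self.parents[p].add(c)

    def to_structure(self) -> DAGStructure:
        return DAGStructure(dict(self.arities),
                            {v: tuple(sorted(ps)) for v, ps in self.parents.items()})


def tabu_search(data: pd.DataFrame, config: MDLConfig,
                arities: dict[str, int] | None = None) -> DAGStructure:
    """Greedy MDL hill-climbing with tabu list and random restarts.

    Deterministic given ``config.seed``; ties between equal-scoring moves
    are broken lexicographically by (child, parent) so runs reproduce.
    """
    if arities is None:
        arities = {c: int(data[c].max()) + 1 for c in data.columns}
    if len(arities) < 2:
        raise ValueError("need at least 2 nodes")
    rng = np.random.default_rng(config.seed)
    best_parents, best_score = None, math.inf
    shared_cache: dict[tuple[str, frozenset], float] = {}

    for restart in range(max(1, config.n_restarts)):
        state = _SearchState(data, arities, config)
        state._cache = shared_cache
        if restart > 0:
            # random DAG start: random order, sparse random arcs
            order = list(rng.permutation(state.nodes))
            for i, c in enumerate(order):
                for p in order[:i]:
                    if rng.random() < 0.15 and \
                            len(state.parents[c]) < config.max_parents:
                        state.parents[c].add(p)
        # prior arcs always present at start
        for (p, c) in sorted(config.prior_arcs):
            if len(state.parents[c]) < config.max_parents and \
                    not state.reaches(c, p):
                state.parents[c].add(p)

        current = state.total_score()
        local_best, local_best_parents = current, {v: set(s) for v, s in
                                                   state.parents.items()}
        tabu: dict[tuple, int] = {}
        stall = 0
        for it in range(config.max_iter):
            candidates = []
            for kind, p, c, delta in state.moves():
                key = ("arc", p, c) if kind != "rev" else ("arc", c, p)
                if tabu.get(key, -1) >= it and current + delta >= local_best - 1e-9:
                    continue  # tabu, no aspiration
                candidates.append((delta, c, p, kind))
            if not candidates:
                break
            candidates.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
            delta, c, p, kind = candidates[0]
            if config.debug_check_decomposability:
                before = state.total_score()
            state.apply(kind, p, c)
            if config.debug_check_decomposability:
                after = state.total_score()
                assert abs((after - before) - delta) < 1e-6, \
                    "score decomposability violated"
            current += delta
            # forbid immediately re-touching the arc just changed
            tabu[("arc", p, c)] = it + config.tabu_length
            if current < local_best - 1e-9:
                local_best = current
                local_best_parents = {v: set(s) for v, s in state.parents.items()}
                stall = 0
            else:
                stall += 1
                if stall >= config.patience:
                    break
        if local_best < best_score - 1e-9:
            best_score = local_best
            best_parents = local_best_parents

    final = _SearchState(data, arities, config)
    final.parents = best_parents
    return final.to_structure()


def skeleton(structure: DAGStructure) -> set[frozenset]:
    return {frozenset((p, c)) for p, c in structure.arcs}


def skeleton_f1(learned: DAGStructure, true_arcs) -> float:
    """F1 of the undirected skeleton against a reference arc set."""
    truth = {frozenset(a) for a in true_arcs}
    got = skeleton(learned)
    tp = len(got & truth)
    if tp == 0:
        return 0.0
    prec = tp / len(got)
    rec = tp / len(truth)
    return 2 * prec * rec / (prec + rec)


def sc_scan(data: pd.DataFrame, sc_grid, config: MDLConfig,
            arities: dict[str, int] | None = None) -> pd.DataFrame:
    """One search per structural coefficient; returns the arc-count curve.

    The 'elbow' flag marks the grid point with the largest second
    difference of the arc count — a heuristic aid for choosing sc, not a
    decision rule.
    """
    rows = []
    for sc in sc_grid:
        if not 0 < sc <= 1:
            raise ValueError("sc grid values must be in (0,1]")
        cfg = replace(config, sc=float(sc))
        g = tabu_search(data, cfg, arities)
        rows.append({"sc": float(sc), "n_arcs": len(g.arcs),
                     "mdl": mdl_score(g, data, float(sc))})
    out = pd.DataFrame(rows).sort_values("sc").reset_index(drop=True)
    out["elbow"] = False
    if len(out) >= 3:
        d2 = np.abs(np.diff(out["n_arcs"].to_numpy(), n=2))
        out.loc[int(np.argmax(d2)) + 1, "elbow"] = True
    return out
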