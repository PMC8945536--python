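"""Structural part of the pSEM: covariates + latent constructs -> phenotype.

The structural network over {weight class, age, sex, compartment, diet,
LC scores} is learned by bootstrap aggregating: a tabu-MDL search runs
on each bootstrap resample, arcs appearing in at least ``freq_threshold``
of the resamples become structural priors (their graph-coding cost is
waived), and a final full-data search produces the model. Predictive
validity is a jackknife cross-validated one-vs-rest ROC AUC for the
weight classes.

Effects of a node on the target are perturbational:

* total effect — shift the node's marginal mean by ``delta`` standard
  deviations using the minimal-KL exponential tilt, propagate through
  the joint, and take the ratio of the induced change in the target's
  expected value to the change in the source's;
* direct effect — the expected within-stratum slope of E[target | source,
  other parents] against the source's numeric representatives (weighted
  least squares over source categories); exactly zero when the source is
  not a parent of the target, so a nonzero total with a zero direct is
  the signature of mediation.

Ordered categories carry numeric representatives (training-bin means),
so effects are reported in natural units, e.g. grams of body weight per
unit of construct score or per day of age.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .bayesnet import DAGStructure, DiscreteBN, Evidence, fit_cpts_mle, marginal, query
from .structure import MDLConfig, tabu_search

__all__ = ["StructuralDataset", "EffectEstimate", "learn_structural_model",
           "crossval_target_auc", "total_effect", "direct_effect",
           "effect_significance", "auc_rank"]


@dataclass
class StructuralDataset:
    """Discretized structural variables plus their numeric representatives."""

    data: pd.DataFrame                       # category codes, one row/sample
    representatives: dict[str, np.ndarray]   # node -> value per category
    target: str = "weight"

    def __post_init__(self) -> None:
        for v in self.data.columns:
            if v not in self.representatives:
                # unordered categoricals get index representatives
                self.representatives[v] = np.arange(
                    int(self.data[v].max()) + 1, dtype=float)
        reps = self.representatives[self.target]
        if len(reps) > 1 and not np.all(np.diff(reps) > 0):
            raise ValueError("target representatives must be strictly increasing")

    @property
    def arities(self) -> dict[str, int]:
        return {v: len(self.representatives[v]) for v in self.data.columns}


@dataclass
class EffectEstimate:
    source: str
    target: str
    total: float
    direct: float
    standardized_total: float
    ci_total: tuple[float, float] | None = None
    ci_direct: tuple[float, float] | None = None
    significant_total: bool | None = None
    significant_direct: bool | None = None


# ------------------------------------------------------------ learning

def learn_structural_model(
    dataset: StructuralDataset, sc: float = 0.45, n_boot: int = 100,
    freq_threshold: float = 0.5, config: MDLConfig | None = None,
    seed: int = 0, pseudocount: float = 0.5,
) -> tuple[DiscreteBN, pd.DataFrame]:
    """Bootstrap-aggregated MDL structure learning ('structural priors').

    Returns the fitted network and the arc bootstrap-frequency table.
    With ``n_boot=1`` and ``freq_threshold=1`` this reduces to a plain
    tabu search.
    """
    if n_boot < 1 or not 0 < freq_threshold <= 1:
        raise ValueError("n_boot >= 1 and freq_threshold in (0,1] required")
    cfg = config or MDLConfig()
    cfg = MDLConfig(sc=sc, max_parents=cfg.max_parents,
                    tabu_length=cfg.tabu_length, n_restarts=cfg.n_restarts,
                    seed=seed, patience=cfg.patience, max_iter=cfg.max_iter)
    rng = np.random.default_rng(seed)
    arities = dataset.arities
    counts: dict[tuple[str, str], int] = {}
    n = len(dataset.data)
    if n_boot == 1:
        g = tabu_search(dataset.data, cfg, arities)
        for a in g.arcs:
            counts[a] = 1
    else:
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            boot = dataset.data.iloc[idx].reset_index(drop=True)
            sub_cfg = MDLConfig(sc=sc, max_parents=cfg.max_parents,
                                tabu_length=cfg.tabu_length, n_restarts=1,
                                seed=int(rng.integers(2**31 - 1)),
                                patience=cfg.patience, max_iter=cfg.max_iter)
            g = tabu_search(boot, sub_cfg, arities)
            for a in g.arcs:
                counts[a] = counts.get(a, 0) + 1
    freq = pd.DataFrame(
        [{"parent": p, "child": c, "frequency": k / max(n_boot, 1)}
         for (p, c), k in sorted(counts.items())]
    )
    prior = frozenset((p, c) for (p, c), k in counts.items()
                      if k / max(n_boot, 1) >= freq_threshold)
    final_cfg = MDLConfig(sc=sc, max_parents=cfg.max_parents,
                          tabu_length=cfg.tabu_length,
                          n_restarts=cfg.n_restarts, seed=seed,
                          patience=cfg.patience, max_iter=cfg.max_iter,
                          prior_arcs=prior)
    structure = tabu_search(dataset.data, final_cfg, arities)
    bn = fit_cpts_mle(structure, dataset.data, pseudocount=pseudocount)
    return bn, freq


# ---------------------------------------------------------------- ROC AUC

def auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """One-vs-rest AUC by the Mann–Whitney rank statistic (ties averaged)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both classes")
    allv = np.concatenate([pos, neg])
    ranks = pd.Series(allv).rank(method="average").to_numpy()
    return float((ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2)
                 / (len(pos) * len(neg)))


def crossval_target_auc(
    dataset: StructuralDataset, sc: float = 0.45, n_boot: int = 1,
    freq_threshold: float = 0.5, config: MDLConfig | None = None,
    folds: int = 10, seed: int = 0, pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Jackknife cross-validated one-vs-rest ROC AUC for the target classes.

    Each fold relearns the structural model on the retained samples and
    scores the held-out ones by the exact posterior of their target class
    given all other variables. A class absent from a test fold is skipped
    with a warning.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    n = len(dataset.data)
    order = rng.permutation(n)
    chunks = np.array_split(order, folds)
    target = dataset.target
    k = dataset.arities[target]
    all_scores = np.zeros((n, k))
    for f, test_idx in enumerate(chunks):
        train_idx = np.sort(np.setdiff1d(order, test_idx))
        train = StructuralDataset(
            dataset.data.iloc[train_idx].reset_index(drop=True),
            dataset.representatives, target)
        bn, _ = learn_structural_model(
            train, sc=sc, n_boot=n_boot, freq_threshold=freq_threshold,
            config=config, seed=seed + f, pseudocount=pseudocount)
        others = [c for c in dataset.data.columns if c != target]
        for i in test_idx:
            ev = Evidence(hard={c: int(dataset.data.iloc[i][c]) for c in others})
            all_scores[i] = query(bn, ev, target)
    y = dataset.data[target].to_numpy(int)
    rows = []
    for cls in range(k):
        labels = (y == cls).astype(int)
        if labels.sum() == 0 or labels.sum() == n:
            import warnings

            warnings.warn(f"target class {cls} degenerate; skipped")
            continue
        rows.append({"class": cls, "auc": auc_rank(all_scores[:, cls], labels)})
    df = pd.DataFrame(rows)
    df.attrs["macro_auc"] = float(df["auc"].mean()) if len(df) else float("nan")
    return df


# ----------------------------------------------------------------- effects

def _mean_sd(probs: np.ndarray, reps: np.ndarray) -> tuple[float, float]:
    m = float(probs @ reps)
    var = float(probs @ (reps - m) ** 2)
    return m, np.sqrt(max(var, 0.0))


def _tilt_likelihood(p: np.ndarray, reps: np.ndarray,
                     target_mean: float) -> np.ndarray:
    """Exponential tilt of a discrete marginal to a prescribed mean.

    exp(beta * reps) is the minimal-KL likelihood vector shifting the
    mean of p to ``target_mean``; beta is solved by 1-D root finding.
    """
    lo, hi = reps.min(), reps.max()
    if not lo < target_mean < hi:
        raise ValueError("target mean outside the support of the marginal")

    def moment(beta: float) -> float:
        w = p * np.exp(beta * (reps - reps.mean()))
        return float(w @ reps / w.sum()) - target_mean

    beta = optimize.brentq(moment, -500 / max(np.ptp(reps), 1e-9),
                           500 / max(np.ptp(reps), 1e-9), xtol=1e-12)
    lik = np.exp(beta * (reps - reps.mean()))
    return lik / lik.max()


def total_effect(bn: DiscreteBN, dataset: StructuralDataset, source: str,
                 delta: float = 0.1) -> float:
    """Perturbational total effect of ``source`` on the dataset target.

    Soft evidence shifting the source's mean by ``delta`` x sd is applied
    and propagated through the whole joint; the effect is the change in
    E[target] per unit change in E[source], in target units per source
    unit.
    """
    target = dataset.target
    if source == target:
        raise ValueError("source equals target")
    reps_s = dataset.representatives[source]
    reps_t = dataset.representatives[target]
    p0_s = query(bn, None, source)
    p0_t = query(bn, None, target)
    m0s, sd_s = _mean_sd(p0_s, reps_s)
    if sd_s <= 0:
        raise ValueError(f"{source} has a single effective category")
    m0t, _ = _mean_sd(p0_t, reps_t)
    lik = _tilt_likelihood(p0_s, reps_s, m0s + delta * sd_s)
    ev = Evidence(soft={source: lik})
    p1_s = query(bn, ev, source)
    p1_t = query(bn, ev, target)
    m1s, _ = _mean_sd(p1_s, reps_s)
    m1t, _ = _mean_sd(p1_t, reps_t)
    return (m1t - m0t) / (m1s - m0s)


def direct_effect(bn: DiscreteBN, dataset: StructuralDataset,
                  source: str) -> float:
    """Other-parents-adjusted slope of the target on the source.

    Zero by construction when the source is not a parent of the target.
    Otherwise, for each configuration c of the target's other parents,
    the slope of E[target | source, c] against the source representatives
    is fitted by least squares weighted by P(source | c), and slopes are
    averaged with weights P(c).
    """
    target = dataset.target
    if source == target:
        raise ValueError("source equals target")
    parents = bn.structure.parents[target]
    if source not in parents:
        return 0.0
    reps_s = dataset.representatives[source]
    reps_t = dataset.representatives[target]
    if len(np.unique(reps_s)) < 2:
        raise ValueError(f"{source} has a single effective category")
    others = tuple(p for p in parents if p != source)
    # E[target | parent configuration] from the CPT
    cond_mean = bn.cpts[target] @ reps_t          # (*parent_arities,)
    src_ax = parents.index(source)
    cond_mean = np.moveaxis(cond_mean, src_ax, -1)  # (*other, a_s)
    if others:
        joint = marginal(bn, others + (source,))     # (*other, a_s)
        p_c = joint.sum(axis=-1)                      # (*other,)
    else:
        joint = query(bn, None, source)[None, ...]
        cond_mean = cond_mean[None, ...] if cond_mean.ndim == 1 else cond_mean
        p_c = np.array([1.0])
        joint = joint.reshape(1, -1)
        cond_mean = cond_mean.reshape(1, -1)
    flat_joint = joint.reshape(-1, len(reps_s))
    flat_mean = cond_mean.reshape(-1, len(reps_s))
    flat_pc = p_c.reshape(-1)
    slopes = np.zeros(len(flat_pc))
    for i in range(len(flat_pc)):
        if flat_pc[i] <= 0:
            continue
        w = flat_joint[i] / flat_pc[i]
        mbar = w @ reps_s
        var = w @ (reps_s - mbar) ** 2
        if var <= 1e-12:
            slopes[i] = 0.0
        else:
            cov = w @ ((reps_s - mbar) * (flat_mean[i] - w @ flat_mean[i]))
            slopes[i] = cov / var
    return float(slopes @ flat_pc / flat_pc.sum())


def standardized(bn: DiscreteBN, dataset: StructuralDataset, source: str,
                 total: float) -> float:
    reps_s = dataset.representatives[source]
    reps_t = dataset.representatives[dataset.target]
    _, sd_s = _mean_sd(query(bn, None, source), reps_s)
    _, sd_t = _mean_sd(query(bn, None, dataset.target), reps_t)
    return float(total * sd_s / sd_t) if sd_t > 0 else float("nan")


def effect_significance(
    dataset: StructuralDataset, bn: DiscreteBN, sources: list[str],
    n_boot: int = 200, seed: int = 0, delta: float = 0.1,
    pseudocount: float = 0.5, alpha: float = 0.05,
) -> list[EffectEstimate]:
    """Bootstrap CIs for total and direct effects (structure held fixed).

    Rows are resampled with replacement, CPTs refit, effects recomputed;
    ``1 - alpha`` percentile intervals; an effect is significant when its
    interval excludes zero.
    """
    if n_boot < 10:
        raise ValueError("n_boot too small for percentile intervals")
    rng = np.random.default_rng(seed)
    n = len(dataset.data)
    point: dict[str, tuple[float, float]] = {}
    for s in sources:
        t = total_effect(bn, dataset, s, delta=delta)
        d = direct_effect(bn, dataset, s)
        point[s] = (t, d)
    boots = {s: ([], []) for s in sources}
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        bdata = dataset.data.iloc[idx].reset_index(drop=True)
        bbn = fit_cpts_mle(bn.structure, bdata, pseudocount=pseudocount)
        for s in sources:
            try:
                boots[s][0].append(total_effect(bbn, dataset, s, delta=delta))
                boots[s][1].append(direct_effect(bbn, dataset, s))
            except ValueError:
                continue
    out = []
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    for s in sources:
        t, d = point[s]
        bt, bd = np.asarray(boots[s][0]), np.asarray(boots[s][1])
        ci_t = (float(np.percentile(bt, lo)), float(np.percentile(bt, hi))) \
            if len(bt) else (float("nan"),) * 2
        ci_d = (float(np.percentile(bd, lo)), float(np.percentile(bd, hi))) \
            if len(bd) else (float("nan"),) * 2
        out.append(EffectEstimate(
            source=s, target=dataset.target, total=t, direct=d,
            standardized_total=standardized(bn, dataset, s, t),
            ci_total=ci_t, ci_direct=ci_d,
            significant_total=not (ci_t[0] <= 0.0 <= ci_t[1]),
            significant_direct=(d != 0.0) and not (ci_d[0] <= 0.0 <= ci_d[1]),
        ))
    return out
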