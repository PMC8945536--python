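"""Measurement part of the pSEM: latent constructs over clusters of taxa.

Taxa are grouped by agglomerative merging restricted to pairs connected
in the learned network's skeleton, with merge priority given by the
average pairwise mutual information between clusters and a hard cap on
cluster size (ten, following common practice for naive-Bayes latent
variables). Each cluster receives a latent construct (LC): a discrete
latent variable fitted by EM so that the members are conditionally
independent given the LC (a naive-Bayes / latent-class model). Cluster
quality is summarized by

* purity — mean over samples of the maximum posterior probability of the
  latent state, in percent;
* contingency-table fit (CTF) — how much of the entropy gap between the
  independence model and the full empirical joint of the members the
  naive-Bayes model closes, in percent.

The per-sample LC *score* is the weighted average of the members'
continuous values, the weight of a member being its mutual information
with the LC divided by the largest such MI in the cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arc_metrics import mutual_information, _mi_from_table
from .bayesnet import DAGStructure
from .discretize import Binning, r2_optimal_discretize, apply_binning

__all__ = ["VariableClustering", "LatentConstruct", "cluster_variables",
           "fit_latent_naive_bayes", "purity", "contingency_table_fit",
           "lc_scores", "build_constructs", "jackknife_cluster_stability"]


@dataclass
class VariableClustering:
    clusters: list[list[str]]
    max_size: int = 10
    linkage_trace: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for cl in self.clusters:
            if not cl:
                raise ValueError("empty cluster")
            if len(cl) > self.max_size:
                raise ValueError("cluster exceeds max size")
            for t in cl:
                if t in seen:
                    raise ValueError(f"taxon {t} in two clusters")
                seen.add(t)

    def labels(self, taxa: list[str]) -> np.ndarray:
        lab = {}
        for i, cl in enumerate(self.clusters):
            for t in cl:
                lab[t] = i
        return np.array([lab[t] for t in taxa])


@dataclass
class NaiveBayesModel:
    """P(LC) and P(member | LC); member axis order matches ``members``."""

    members: list[str]
    prior: np.ndarray                  # (n_states,)
    cpts: list[np.ndarray]             # each (n_states, member arity)
    loglik: float

    @property
    def n_states(self) -> int:
        return len(self.prior)

    def posteriors(self, data: pd.DataFrame) -> np.ndarray:
        """P(LC state | member values) per sample, shape (N, n_states)."""
        logp = np.log(np.maximum(self.prior, 1e-300))[None, :].repeat(
            len(data), axis=0)
        for j, m in enumerate(self.members):
            vals = data[m].to_numpy(int)
            logp += np.log(np.maximum(self.cpts[j][:, vals].T, 1e-300))
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)

    def sample_log2lik(self, data: pd.DataFrame) -> np.ndarray:
        """log2 P(member values) per sample under the mixture."""
        logp = np.log(np.maximum(self.prior, 1e-300))[None, :].repeat(
            len(data), axis=0)
        for j, m in enumerate(self.members):
            vals = data[m].to_numpy(int)
            logp += np.log(np.maximum(self.cpts[j][:, vals].T, 1e-300))
        mx = logp.max(axis=1)
        return (mx + np.log(np.exp(logp - mx[:, None]).sum(axis=1))) / np.log(2)

    def member_mi(self) -> np.ndarray:
        """MI(member_i; LC) in bits under the fitted model distribution."""
        out = np.empty(len(self.members))
        for j, cpt in enumerate(self.cpts):
            joint = self.prior[:, None] * cpt
            out[j] = _mi_from_table(joint * 1.0)
        return out


@dataclass
class LatentConstruct:
    id: str
    members: list[str]
    nb_model: NaiveBayesModel
    mi_weights: np.ndarray
    scores: np.ndarray | None = None
    score_binning: Binning | None = None
    purity_pct: float | None = None
    ctf_pct: float | None = None


# ------------------------------------------------------------- clustering

def cluster_variables(structure: DAGStructure, data: pd.DataFrame,
                      max_size: int = 10, mi_floor: float = 0.02,
                      ) -> VariableClustering:
    """Skeleton-restricted agglomerative clustering by average pairwise MI.

    Only clusters connected by at least one skeleton edge may merge; the
    pair with the highest average pairwise MI merges first; merging stops
    when no connected pair fits within ``max_size`` or the best linkage
    falls below ``mi_floor`` bits. Taxa disconnected from everything stay
    singletons.
    """
    taxa = sorted(structure.nodes)
    idx = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    cols = {t: data[t].to_numpy(int) for t in taxa}
    mi = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mi[i, j] = mi[j, i] = mutual_information(cols[taxa[i]], cols[taxa[j]])
    adj = np.zeros((n, n), bool)
    for p, c in structure.arcs:
        adj[idx[p], idx[c]] = adj[idx[c], idx[p]] = True

    clusters: list[set[int]] = [{i} for i in range(n)]
    trace = []
    while True:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca, cb = clusters[a], clusters[b]
                if len(ca) + len(cb) > max_size:
                    continue
                if not any(adj[i, j] for i in ca for j in cb):
                    continue
                link = float(np.mean([mi[i, j] for i in ca for j in cb]))
                if best is None or link > best[0] + 1e-12:
                    best = (link, a, b)
        if best is None or best[0] < mi_floor:
            break
        link, a, b = best
        trace.append((link, sorted(taxa[i] for i in clusters[a]),
                      sorted(taxa[i] for i in clusters[b])))
        clusters[a] = clusters[a] | clusters[b]
        del clusters[b]
    # deterministic order: by smallest member name
    named = [sorted(taxa[i] for i in cl) for cl in clusters]
    named.sort(key=lambda cl: cl[0])
    return VariableClustering(named, max_size=max_size, linkage_trace=trace)


# ---------------------------------------------------------------------- EM

def fit_latent_naive_bayes(member_data: pd.DataFrame, n_states: int,
                           seed: int = 0, n_em_restarts: int = 4,
                           max_iter: int = 300, tol: float = 1e-7,
                           member_reps: dict[str, np.ndarray] | None = None,
                           ) -> NaiveBayesModel:
    """EM for a latent-class (naive Bayes) model over categorical members.

    Best of ``n_em_restarts`` random initializations by final likelihood.
    Latent state labels are canonicalized so states are increasing in the
    (MI-weighted) mean of the members' numeric bin representatives —
    a high LC state then corresponds to high member abundances.
    """
    members = list(member_data.columns)
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    if len(members) == 1:
        # degenerate: latent mirrors the single member
        vals = member_data[members[0]].to_numpy(int)
        arity = int(vals.max()) + 1
        k = min(n_states, arity)
        prior = np.bincount(np.minimum(vals, k - 1), minlength=k).astype(float)
        prior /= prior.sum()
        cpt = np.full((k, arity), 1e-9)
        for s in range(k):
            for a in range(arity):
                if min(a, k - 1) == s:
                    cpt[s, a] = 1.0
        cpt /= cpt.sum(axis=1, keepdims=True)
        model = NaiveBayesModel(members, prior, [cpt], 0.0)
        model.loglik = float(model.sample_log2lik(member_data).sum())
        return _canonicalize(model, member_reps)

    N = len(member_data)
    arities = [int(member_data[m].max()) + 1 for m in members]
    codes = [member_data[m].to_numpy(int) for m in members]
    rng = np.random.default_rng(seed)
    best: NaiveBayesModel | None = None
    attempts = 0
    restarts_done = 0
    while restarts_done < n_em_restarts and attempts < 4 * n_em_restarts:
        attempts += 1
        resp = rng.dirichlet(np.ones(n_states), size=N)
        ll_prev = -np.inf
        degenerate = False
        for _ in range(max_iter):
            # M step
            nk = resp.sum(axis=0)
            if (nk < 1e-8).any():
                degenerate = True
                break
            prior = nk / N
            cpts = []
            for j in range(len(members)):
                c = np.array([np.bincount(codes[j], weights=resp[:, s],
                                          minlength=arities[j])
                              for s in range(n_states)])
                c += 1e-6
                cpts.append(c / c.sum(axis=1, keepdims=True))
            model = NaiveBayesModel(members, prior, cpts, 0.0)
            # E step + loglik
            log2lik = model.sample_log2lik(member_data)
            ll = float(log2lik.sum())
            resp = model.posteriors(member_data)
            if ll - ll_prev < tol * max(1.0, abs(ll)):
                ll_prev = ll
                break
            ll_prev = ll
        if degenerate:
            continue
        restarts_done += 1
        model.loglik = ll_prev
        if best is None or model.loglik > best.loglik:
            best = model
    if best is None:
        raise RuntimeError("EM degenerate in every restart")
    return _canonicalize(best, member_reps)


def _canonicalize(model: NaiveBayesModel,
                  member_reps: dict[str, np.ndarray] | None) -> NaiveBayesModel:
    """Order latent states by MI-weighted mean member representative."""
    mi = model.member_mi()
    w = mi / mi.max() if mi.max() > 0 else np.ones_like(mi)
    keys = np.zeros(model.n_states)
    for j, m in enumerate(model.members):
        if member_reps is not None and m in member_reps:
            reps = np.asarray(member_reps[m], float)
        else:
            reps = np.arange(model.cpts[j].shape[1], dtype=float)
        keys += w[j] * (model.cpts[j] @ reps)
    order = np.argsort(keys, kind="stable")
    return NaiveBayesModel(
        model.members,
        model.prior[order],
        [c[order] for c in model.cpts],
        model.loglik,
    )


def _fit_mdl_selected(sub: pd.DataFrame, seed: int, n_em_restarts: int,
                      member_reps, k_grid=(2, 3, 4)) -> NaiveBayesModel:
    """Latent arity chosen by two-part MDL over a small grid.

    Description length = -log2-likelihood + (log2 N)/2 x #free parameters,
    with (k-1) prior parameters and k*(arity_i - 1) per member.
    """
    n = len(sub)
    best, best_mdl = None, np.inf
    for k in k_grid:
        model = fit_latent_naive_bayes(sub, k, seed=seed,
                                       n_em_restarts=n_em_restarts,
                                       member_reps=member_reps)
        npar = (k - 1) + k * sum(int(sub[c].max()) for c in sub.columns)
        mdl = -model.loglik + np.log2(n) / 2 * npar
        if mdl < best_mdl - 1e-9:
            best, best_mdl = model, mdl
    return best


# ------------------------------------------------------------ diagnostics

def purity(model: NaiveBayesModel, data: pd.DataFrame) -> float:
    """Mean max-posterior latent assignment probability, percent."""
    return float(model.posteriors(data).max(axis=1).mean() * 100.0)


def contingency_table_fit(model: NaiveBayesModel,
                          data: pd.DataFrame) -> float | None:
    """CTF = 100 (H_indep − H_nb) / (H_indep − H_joint), clipped to [0,100].

    H_indep sums the members' marginal entropies, H_joint is the empirical
    joint entropy and H_nb the cross-entropy of the data under the fitted
    naive-Bayes model, all in bits per sample. Returns None (with a
    warning) when the members are already mutually independent.
    """
    N = len(data)
    h_indep = 0.0
    for m in model.members:
        p = np.bincount(data[m].to_numpy(int)) / N
        p = p[p > 0]
        h_indep += float(-(p * np.log2(p)).sum())
    # empirical joint entropy
    code = np.zeros(N, dtype=np.int64)
    for m in model.members:
        vals = data[m].to_numpy(int)
        code = code * (vals.max() + 1) + vals
    _, counts = np.unique(code, return_counts=True)
    pj = counts / N
    h_joint = float(-(pj * np.log2(pj)).sum())
    h_nb = float(-model.sample_log2lik(data).mean())
    denom = h_indep - h_joint
    if denom <= 1e-12:
        import warnings

        warnings.warn("members mutually independent; CTF undefined")
        return None
    return float(np.clip(100.0 * (h_indep - h_nb) / denom, 0.0, 100.0))


# ----------------------------------------------------------------- scores

def lc_scores(weights: np.ndarray, member_values: np.ndarray,
              zero_fill: np.ndarray | None = None) -> np.ndarray:
    """Per-sample construct score: MI-weighted average of member values.

    ``member_values`` is (N, m) with NaN zero marks; a zero-marked entry
    enters the average as that member's ``zero_fill`` value (one unit
    below its observed minimum by default), so the score is defined for
    every sample.
    """
    v = np.asarray(member_values, float).copy()
    if zero_fill is None:
        with np.errstate(all="ignore"):
            zero_fill = np.nanmin(v, axis=0) - 1.0
        zero_fill = np.where(np.isfinite(zero_fill), zero_fill, 0.0)
    for j in range(v.shape[1]):
        v[np.isnan(v[:, j]), j] = zero_fill[j]
    w = np.asarray(weights, float)
    return (v @ w) / w.sum()


def build_constructs(clustering: VariableClustering, disc_data: pd.DataFrame,
                     cont_values: pd.DataFrame,
                     member_reps: dict[str, np.ndarray] | None = None,
                     n_states: int | None = None, seed: int = 0,
                     n_em_restarts: int = 4) -> list[LatentConstruct]:
    """Fit one latent construct per cluster and score every sample.

    ``disc_data`` holds the members' category codes, ``cont_values`` the
    aligned continuous (log-abundance) values with NaN zero marks. The
    latent arity defaults to the modal member arity of the cluster.
    Scores are discretized with the R²-optimal binning for use in the
    structural model.
    """
    out = []
    for i, cl in enumerate(clustering.clusters):
        sub = disc_data[cl]
        if n_states is None:
            model = _fit_mdl_selected(sub, seed=seed + i,
                                      n_em_restarts=n_em_restarts,
                                      member_reps=member_reps)
        else:
            model = fit_latent_naive_bayes(sub, n_states, seed=seed + i,
                                           n_em_restarts=n_em_restarts,
                                           member_reps=member_reps)
        mi = model.member_mi()
        w = mi / mi.max() if mi.max() > 0 else np.ones_like(mi)
        scores = lc_scores(w, cont_values[cl].to_numpy(float))
        binning = r2_optimal_discretize(scores, variable=f"LC{i}",
                                        zero_class=False)
        lc = LatentConstruct(
            id=f"LC{i}", members=list(cl), nb_model=model, mi_weights=w,
            scores=scores, score_binning=binning,
            purity_pct=purity(model, sub),
            ctf_pct=contingency_table_fit(model, sub),
        )
        out.append(lc)
    return out


# -------------------------------------------------------------- stability

def jackknife_cluster_stability(disc_data: pd.DataFrame,
                                reference: VariableClustering,
                                learn_fn, folds: int = 10, seed: int = 0,
                                max_size: int = 10, mi_floor: float = 0.02,
                                ) -> pd.DataFrame:
    """Cluster correspondence across jackknife folds.

    Each fold drops 1/``folds`` of the samples, relearns the network
    (via ``learn_fn(data) -> DAGStructure``) and the clustering, and
    scores each reference cluster by its best-overlap correspondence:
    100 x |best intersection| / |reference cluster| (greedy matching,
    ties broken by cluster order).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(disc_data))
    chunks = np.array_split(order, folds)
    corr = np.zeros((len(reference.clusters), folds))
    for f, drop in enumerate(chunks):
        keep = np.setdiff1d(order, drop)
        sub = disc_data.iloc[np.sort(keep)].reset_index(drop=True)
        structure = learn_fn(sub)
        cl = cluster_variables(structure, sub, max_size=max_size,
                               mi_floor=mi_floor)
        fold_sets = [set(c) for c in cl.clusters]
        for i, ref in enumerate(reference.clusters):
            rset = set(ref)
            best = max((len(rset & fs) for fs in fold_sets), default=0)
            corr[i, f] = 100.0 * best / len(rset)
    rows = [{"cluster": i, "members": len(reference.clusters[i]),
             "mean_correspondence_pct": corr[i].mean()}
            for i in range(len(reference.clusters))]
    df = pd.DataFrame(rows)
    df.attrs["overall_mean_pct"] = float(corr.mean())
    return df
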