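"""End-to-end pSEM pipeline: one resolved config in, one run directory out.

Stages: preprocess -> discretize -> taxa network -> arc report ->
variable clustering -> latent constructs & scores -> structural network
(bootstrap-aggregated) -> cross-validated AUC -> total/direct effects.
Every stage writes a plain-text artifact; a JSON manifest records the
resolved configuration, its hash and the artifact list, so two runs with
equal hashes produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess as pp
from .arc_metrics import arc_report
from .bayesnet import fit_cpts_mle
from .constructs import build_constructs, cluster_variables
from .discretize import Binning, apply_binning, kmeans_discretize, \
    r2_optimal_discretize
from .effects import StructuralDataset, crossval_target_auc, \
    effect_significance, learn_structural_model
from .simulate import GeneratorSpec, generate
from .structure import MDLConfig, sc_scan, tabu_search

__all__ = ["RunConfig", "run_pipeline", "build_structural_dataset"]

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Every stage parameter of a pipeline run; all seeds explicit."""

    out_dir: str = "psem_run"
    # inputs: either paths, or None to simulate
    counts_tsv: str | None = None
    metadata_tsv: str | None = None
    simulate_preset: str = "study"
    seed: int = 0
    # preprocess
    filter_threshold: float = 1e-4
    filter_group_key: str = "replicate"
    log_base: float = 10.0
    # discretization
    ra_k_candidates: tuple = (2, 3, 4, 5)
    ra_r2_target: float = 0.95
    weight_k: int = 5
    # taxa network; "auto" picks the arc-count elbow of an SC scan
    taxa_sc: float | str = "auto"
    max_parents: int = 4
    n_restarts: int = 2
    sc_grid: tuple = (0.15, 0.3, 0.45, 0.6, 0.75, 0.9)
    # clustering / constructs
    max_cluster_size: int = 10
    mi_floor: float = 0.02
    n_em_restarts: int = 4
    # structural model
    structural_sc: float = 0.45
    structural_n_boot: int = 30
    structural_freq_threshold: float = 0.5
    crossval_folds: int = 10
    crossval_n_boot: int = 1
    effects_n_boot: int = 200
    effects_delta: float = 0.1
    inference_pseudocount: float = 0.5

    def to_toml(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            if isinstance(v, str):
                lines.append(f'{f.name} = "{v}"')
            elif isinstance(v, bool):
                lines.append(f"{f.name} = {str(v).lower()}")
            elif isinstance(v, tuple):
                lines.append(f"{f.name} = [{', '.join(repr(x) for x in v)}]")
            else:
                lines.append(f"{f.name} = {v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_toml(cls, text: str) -> "RunConfig":
        import tomllib

        d = tomllib.loads(text)
        for k in ("ra_k_candidates", "sc_grid"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, float_format=_FLOAT_FMT, index=index, lineterminator="\n")


def build_structural_dataset(meta: pd.DataFrame, constructs,
                             weight_binning: Binning) -> StructuralDataset:
    """Assemble the structural table: covariates + LC scores + weight class."""
    data = {}
    reps = {}
    ages = np.sort(meta["age_d"].unique()).astype(float)
    data["age"] = meta["age_d"].map({a: i for i, a in enumerate(ages)}).to_numpy()
    reps["age"] = ages
    data["sex"] = (meta["sex"] == "male").astype(int).to_numpy()
    reps["sex"] = np.array([0.0, 1.0])
    comps = sorted(meta["compartment"].unique())
    data["compartment"] = meta["compartment"].map(
        {c: i for i, c in enumerate(comps)}).to_numpy()
    reps["compartment"] = np.arange(len(comps), dtype=float)
    diets = np.sort(meta["bsf_pct"].unique()).astype(float)
    data["bsf"] = meta["bsf_pct"].map(
        {d: i for i, d in enumerate(diets)}).to_numpy()
    reps["bsf"] = diets
    data["weight"] = apply_binning(meta["weight_g"].to_numpy(float),
                                   weight_binning)
    reps["weight"] = weight_binning.category_representatives()
    for lc in constructs:
        data[lc.id] = apply_binning(lc.scores, lc.score_binning)
        reps[lc.id] = lc.score_binning.category_representatives()
    return StructuralDataset(pd.DataFrame(data), reps, target="weight")


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and return the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    resolved = config.to_toml()
    (out / "config.toml").write_text(resolved)
    cfg_hash = hashlib.sha256(resolved.encode()).hexdigest()
    artifacts: list[str] = ["config.toml"]

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as e:  # noqa: BLE001 - annotate and re-raise
                raise RuntimeError(f"stage {name!r} failed: {e}") from e
        return wrap

    # -- inputs
    if config.counts_tsv and config.metadata_tsv:
        counts = pp.read_counts_tsv(config.counts_tsv)
        meta = pp.read_metadata_tsv(config.metadata_tsv)
        truth = None
    else:
        from .simulate import preset

        spec = preset(config.simulate_preset, seed=config.seed)
        counts, meta, truth = generate(spec)
        counts.to_csv(out / "counts.tsv", sep="\t", lineterminator="\n")
        _write_csv(meta, out / "metadata.tsv")
        (out / "ground_truth.json").write_text(truth.to_json())
        artifacts += ["counts.tsv", "metadata.tsv", "ground_truth.json"]

    # -- preprocess
    def _pre():
        table = pp.compute_relative_abundances(counts, meta)
        filtered, report = pp.filter_low_abundance(
            table, config.filter_threshold, config.filter_group_key)
        logs = pp.log_transform_nonzero(filtered, base=config.log_base)
        return filtered, report, logs

    filtered, filter_report, logra = stage("preprocess")(_pre)
    _write_csv(filter_report.reset_index(names="taxon"),
               out / "filter_report.csv")
    filtered.rel_abund.to_csv(out / "filtered_rel_abund.tsv", sep="\t",
                              float_format=_FLOAT_FMT, lineterminator="\n")
    artifacts += ["filter_report.csv", "filtered_rel_abund.tsv"]

    # -- discretize taxa (samples x taxa orientation from here on)
    def _disc():
        disc = {}
        binnings = {}
        for taxon in logra.index:
            vals = logra.loc[taxon].to_numpy(float)
            b = r2_optimal_discretize(vals, config.ra_k_candidates,
                                      config.ra_r2_target, variable=taxon)
            disc[taxon] = apply_binning(vals, b)
            binnings[taxon] = b
        return pd.DataFrame(disc, index=logra.columns), binnings

    disc_data, binnings = stage("discretize")(_disc)
    (out / "binnings.json").write_text(json.dumps(
        {t: json.loads(b.to_json()) for t, b in binnings.items()}, indent=1))
    _write_csv(disc_data.reset_index(names="sample_id"),
               out / "discretized_ra.csv")
    artifacts += ["binnings.json", "discretized_ra.csv"]

    # -- taxa network (sc from the scan elbow unless fixed by config)
    taxa_sc = config.taxa_sc
    mdl_cfg = MDLConfig(max_parents=config.max_parents,
                        n_restarts=config.n_restarts, seed=config.seed)
    if config.sc_grid:
        curve = stage("sc-scan")(
            lambda: sc_scan(disc_data, config.sc_grid, mdl_cfg))
        _write_csv(curve, out / "sc_scan.csv")
        artifacts.append("sc_scan.csv")
        if taxa_sc == "auto":
            flagged = curve.loc[curve["elbow"]]
            taxa_sc = float(flagged["sc"].iloc[0]) if len(flagged) \
                else float(curve["sc"].iloc[len(curve) // 2])
    elif taxa_sc == "auto":
        taxa_sc = 0.85
    mdl_cfg = dataclasses.replace(mdl_cfg, sc=float(taxa_sc))
    taxa_net = stage("taxa-network")(lambda: tabu_search(disc_data, mdl_cfg))
    bn = fit_cpts_mle(taxa_net, disc_data)
    cont = logra.T  # samples x taxa continuous values
    report = arc_report(bn, disc_data, raw_values=cont)
    _write_csv(report, out / "taxa_arc_report.csv")
    (out / "taxa_network.dot").write_text(_to_dot(taxa_net, report))
    artifacts += ["taxa_arc_report.csv", "taxa_network.dot"]

    # -- clustering + constructs
    clustering = stage("cluster")(lambda: cluster_variables(
        taxa_net, disc_data, config.max_cluster_size, config.mi_floor))
    member_reps = {t: binnings[t].category_representatives()
                   for t in disc_data.columns}
    constructs = stage("constructs")(lambda: build_constructs(
        clustering, disc_data, cont, member_reps=member_reps,
        seed=config.seed, n_em_restarts=config.n_em_restarts))
    quality = pd.DataFrame(
        [{"construct": lc.id, "n_members": len(lc.members),
          "members": ";".join(lc.members),
          "purity_pct": lc.purity_pct,
          "ctf_pct": lc.ctf_pct if lc.ctf_pct is not None else np.nan}
         for lc in constructs])
    _write_csv(quality, out / "construct_quality.csv")
    scores = pd.DataFrame({lc.id: lc.scores for lc in constructs},
                          index=disc_data.index)
    scores.insert(0, "sample_id", disc_data.index)
    _write_csv(scores, out / "lc_scores.tsv")
    artifacts += ["construct_quality.csv", "lc_scores.tsv"]

    # -- structural model
    weight_binning = kmeans_discretize(meta["weight_g"].to_numpy(float),
                                       k=config.weight_k, variable="weight")
    sdata = build_structural_dataset(meta, constructs, weight_binning)
    struct_cfg = MDLConfig(sc=config.structural_sc,
                           max_parents=config.max_parents,
                           n_restarts=config.n_restarts, seed=config.seed)
    sbn, freq = stage("structural")(lambda: learn_structural_model(
        sdata, sc=config.structural_sc, n_boot=config.structural_n_boot,
        freq_threshold=config.structural_freq_threshold, config=struct_cfg,
        seed=config.seed, pseudocount=config.inference_pseudocount))
    _write_csv(freq, out / "structural_arc_frequency.csv")
    sreport = arc_report(fit_cpts_mle(sbn.structure, sdata.data), sdata.data)
    _write_csv(sreport, out / "structural_arc_report.csv")
    (out / "structural_network.dot").write_text(_to_dot(sbn.structure, sreport))
    artifacts += ["structural_arc_frequency.csv", "structural_arc_report.csv",
                  "structural_network.dot"]

    # -- cross-validation
    auc = stage("crossval")(lambda: crossval_target_auc(
        sdata, sc=config.structural_sc, n_boot=config.crossval_n_boot,
        config=struct_cfg, folds=config.crossval_folds, seed=config.seed,
        pseudocount=config.inference_pseudocount))
    auc_out = auc.copy()
    auc_out["macro_auc"] = auc.attrs.get("macro_auc", np.nan)
    _write_csv(auc_out, out / "crossval_auc.csv")
    artifacts.append("crossval_auc.csv")

    # -- effects
    sources = [c for c in sdata.data.columns if c != sdata.target]
    est = stage("effects")(lambda: effect_significance(
        sdata, sbn, sources, n_boot=config.effects_n_boot, seed=config.seed,
        delta=config.effects_delta,
        pseudocount=config.inference_pseudocount))
    eff = pd.DataFrame(
        [{"node": e.source, "total": e.total, "direct": e.direct,
          "standardized_total": e.standardized_total,
          "ci_total_low": e.ci_total[0], "ci_total_high": e.ci_total[1],
          "ci_direct_low": e.ci_direct[0], "ci_direct_high": e.ci_direct[1],
          "significant_total": e.significant_total,
          "significant_direct": e.significant_direct}
         for e in est])
    _write_csv(eff, out / "effects.csv")
    artifacts.append("effects.csv")

    manifest = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        "n_samples": int(len(meta)),
        "n_taxa_retained": int(len(filtered.taxa)),
        "n_taxa_arcs": int(len(taxa_net.arcs)),
        "n_clusters": int(len(clustering.clusters)),
        "n_structural_arcs": int(len(sbn.structure.arcs)),
        "macro_auc": float(auc.attrs.get("macro_auc", np.nan)),
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    summary = [
        f"samples: {len(meta)}",
        f"taxa retained: {len(filtered.taxa)}",
        f"taxa network arcs: {len(taxa_net.arcs)}",
        f"clusters: {len(clustering.clusters)}",
        f"mean purity %: {quality['purity_pct'].mean():.2f}",
        f"mean CTF %: {quality['ctf_pct'].mean():.2f}",
        f"structural arcs: {len(sbn.structure.arcs)}",
        f"cross-validated macro AUC: {auc.attrs.get('macro_auc', float('nan')):.4f}",
    ]
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    return out


def _to_dot(structure, report: pd.DataFrame | None = None) -> str:
    lines = ["digraph G {"]
    for v in sorted(structure.nodes):
        lines.append(f'  "{v}";')
    kl = {}
    if report is not None:
        kl = {(r.parent, r.child): r.KL for r in report.itertuples()}
    for p, c in sorted(structure.arcs):
        attr = f' [label="{kl[(p, c)]:.3f}"]' if (p, c) in kl else ""
        lines.append(f'  "{p}" -> "{c}"{attr};')
    lines.append("}")
    return "\n".join(lines) + "\n"
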