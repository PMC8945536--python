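#!/usr/bin/env python
"""Relative abundances, the 0.01% editing filter, and the log transform.

Reads results/data/, writes results/preprocess/: the filter report (max
relative abundance per replicate group, kept/dropped), the filtered
abundances, the log10 values (zeros carried as empty cells), and the
per-taxon discretization (ordered categories, zero class = 0).
"""

import json
from pathlib import Path

import pandas as pd

from psem.discretize import apply_binning, r2_optimal_discretize
from psem.preprocess import (compute_relative_abundances,
                             filter_low_abundance, log_transform_nonzero,
                             read_counts_tsv, read_metadata_tsv)

DATA = Path("results/data")
OUT = Path("results/preprocess")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts = read_counts_tsv(DATA / "counts.tsv")
    meta = read_metadata_tsv(DATA / "metadata.tsv")
    table = compute_relative_abundances(counts, meta)
    filtered, report = filter_low_abundance(table, threshold=1e-4,
                                            group_key="replicate")
    report.reset_index(names="taxon").to_csv(
        OUT / "filter_report.csv", index=False, float_format="%.10g",
        lineterminator="\n")
    logra = log_transform_nonzero(filtered, base=10.0)
    logra.to_csv(OUT / "log_rel_abund.tsv", sep="\t", float_format="%.10g",
                 lineterminator="\n")

    disc, bins = {}, {}
    for t in logra.index:
        vals = logra.loc[t].to_numpy(float)
        b = r2_optimal_discretize(vals, variable=t)
        disc[t] = apply_binning(vals, b)
        bins[t] = json.loads(b.to_json())
    disc = pd.DataFrame(disc, index=logra.columns)
    disc.reset_index(names="sample_id").to_csv(
        OUT / "discretized_ra.csv", index=False, lineterminator="\n")
    (OUT / "binnings.json").write_text(json.dumps(bins, indent=1))

    kept = int(report["kept"].sum())
    ks = pd.Series([b["thresholds"] and len(b["representatives"]) or 1
                    for b in bins.values()])
    print(f"{kept}/{len(report)} genera pass the >0.01% filter")
    print(f"bins per taxon (excluding the zero class): "
          f"median {int(ks.median())}, range {ks.min()}-{ks.max()}")
    print(f"wrote {OUT}/filter_report.csv, log_rel_abund.tsv, "
          f"discretized_ra.csv, binnings.json")


if __name__ == "__main__":
    main()
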