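"""Count-table ingestion, relative abundances, abundance filter, log transform.

Relative abundances are counts divided by the per-sample total. The
editing filter keeps a genus only if its relative abundance exceeds a
threshold (default 0.01%) in at least one sample of at least one
replicate group; ties at the threshold are dropped (strict inequality)
and the surviving abundances are deliberately *not* renormalized, so the
log values fed downstream are unchanged by the filter. Non-zero
abundances are log-transformed (base 10 by default); zeros are carried
as NaN "zero marks" and later binned into a dedicated ordered category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AbundanceTable", "read_counts_tsv", "read_metadata_tsv",
           "read_mothur_shared", "compute_relative_abundances",
           "filter_low_abundance", "log_transform_nonzero"]

REQUIRED_METADATA = ["sample_id", "weight_g", "age_d", "sex", "compartment",
                     "bsf_pct", "replicate"]


@dataclass
class AbundanceTable:
    """Samples x genera counts and relative abundances with covariates.

    ``counts`` and ``rel_abund`` are taxa-by-sample DataFrames sharing
    index (taxa) and columns (sample ids); ``metadata`` has one row per
    sample, aligned on ``sample_id``.
    """

    counts: pd.DataFrame
    rel_abund: pd.DataFrame
    metadata: pd.DataFrame
    sample_totals: pd.Series = field(default=None)
    # False after the abundance filter: columns then sum to less than 1
    strict_simplex: bool = True

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate taxa labels")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        sums = self.rel_abund.sum(axis=0)
        if self.strict_simplex and not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("relative abundances do not sum to 1 per sample")
        if (sums > 1 + 1e-9).any():
            raise ValueError("relative abundances exceed 1 per sample")

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


def read_counts_tsv(path) -> pd.DataFrame:
    """Taxa-by-sample integer count table: rows taxa, header of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(int)


def read_metadata_tsv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_METADATA if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    return meta


def read_mothur_shared(shared_path, taxonomy_path=None) -> pd.DataFrame:
    """Read a mothur ``.shared`` table (label/Group/numOtus dialect).

    Returns a taxa-by-sample count table. When a ``.taxonomy`` file is
    given (OTU <tab> size? <tab> lineage), OTU columns are renamed to
    their genus (the last non-empty, confidence-stripped lineage level)
    and counts of OTUs assigned to the same genus are summed.
    """
    df = pd.read_csv(shared_path, sep="\t")
    for col in ("label", "numOtus", "numASVs"):
        if col in df.columns:
            df = df.drop(columns=col)
    df = df.set_index("Group")
    counts = df.T  # OTUs x samples
    if taxonomy_path is not None:
        tax = pd.read_csv(taxonomy_path, sep="\t")
        tax.columns = [c.strip() for c in tax.columns]
        otu_col = tax.columns[0]
        lineage_col = tax.columns[-1]

        def genus(lineage: str) -> str:
            parts = [p for p in str(lineage).strip().rstrip(";").split(";") if p]
            last = parts[-1]
            return last.split("(")[0].strip()

        mapping = {row[otu_col]: genus(row[lineage_col])
                   for _, row in tax.iterrows()}
        counts = counts.rename(index=mapping)
        counts = counts.groupby(level=0).sum()
    return counts.astype(int)


def compute_relative_abundances(counts: pd.DataFrame,
                                metadata: pd.DataFrame) -> AbundanceTable:
    """Per-sample fractions: count of a genus over the sample total."""
    if counts.shape[0] < 1 or counts.shape[1] < 1:
        raise ValueError("need at least one taxon and one sample")
    totals = counts.sum(axis=0)
    empty = totals[totals == 0]
    if len(empty):
        raise ValueError(f"sample(s) with zero total counts: {list(empty.index)}")
    rel = counts / totals
    meta = metadata.set_index("sample_id", drop=False).loc[counts.columns] \
        .reset_index(drop=True)
    return AbundanceTable(counts=counts, rel_abund=rel, metadata=meta,
                          sample_totals=totals)


def filter_low_abundance(table: AbundanceTable, threshold: float = 1e-4,
                         group_key: str = "replicate",
                         ) -> tuple[AbundanceTable, pd.DataFrame]:
    """Keep taxa whose abundance strictly exceeds ``threshold`` within at
    least one group of samples (default: one replicate).

    Returns the filtered table and a per-taxon report (max abundance per
    group, kept flag). Abundances are not renormalized afterwards.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be a fraction in (0,1)")
    if group_key not in table.metadata.columns:
        raise ValueError(f"unknown group key {group_key!r}")
    groups = table.metadata[group_key]
    report = pd.DataFrame(index=table.rel_abund.index)
    keep = pd.Series(False, index=table.rel_abund.index)
    for g in sorted(groups.unique()):
        cols = table.metadata.loc[groups == g, "sample_id"]
        gmax = table.rel_abund[cols].max(axis=1)
        report[f"max_ra_{g}"] = gmax
        keep |= gmax > threshold
    report["kept"] = keep
    kept_taxa = report.index[keep]
    if len(kept_taxa) == 0:
        raise ValueError("all taxa removed by the abundance filter")
    filtered = AbundanceTable(
        counts=table.counts.loc[kept_taxa],
        rel_abund=table.rel_abund.loc[kept_taxa],
        metadata=table.metadata,
        sample_totals=table.sample_totals,
        strict_simplex=False,
    )
    return filtered, report


def log_transform_nonzero(table: AbundanceTable, base: float = 10.0,
                          ) -> pd.DataFrame:
    """log_base of the non-zero abundances; zeros become NaN zero marks."""
    if base <= 1:
        raise ValueError("base must be > 1")
    ra = table.rel_abund.to_numpy(float)
    if (ra < 0).any():
        raise ValueError("negative abundance")
    with np.errstate(divide="ignore"):
        out = np.where(ra > 0, np.log(np.maximum(ra, 1e-300)) / np.log(base),
                       np.nan)
    return pd.DataFrame(out, index=table.rel_abund.index,
                        columns=table.rel_abund.columns)
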