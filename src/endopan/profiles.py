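"""Taxonomic binning of scaffolds and read-based abundance profiles.

Scaffolds are assigned to the lowest annotated taxon of their best
qualifying alignment hit (best bitscore at e-value <= 1e-5), reads mapped
to each scaffold are summed into a taxon-by-sample abundance table, and two
normalizations are provided: median scaling of sample totals, and
coverage-ranked scaffold subsampling that equalizes sequencing effort
across samples before set analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "assign_scaffold_taxon",
    "bin_scaffolds",
    "build_abundance",
    "normalize_to_median",
    "subsample_scaffolds_by_coverage",
    "filter_taxa",
]

DEFAULT_E_THRESHOLD = 1e-5


@dataclass
class AbundanceTable:
    """Taxon x sample count matrix with a normalization flag.

    ``scale_factors`` records the per-sample factor applied by
    :func:`normalize_to_median` (None while raw).
    """

    data: pd.DataFrame
    normalized: bool = False
    scale_factors: pd.Series | None = None

    @property
    def samples(self) -> list:
        return list(self.data.columns)

    @property
    def taxa(self) -> list:
        return list(self.data.index)

    def presence(self, min_reads: float = 1.0) -> pd.DataFrame:
        """Boolean occurrence matrix: a taxon occurs iff reads >= min_reads."""
        return self.data >= min_reads


def assign_scaffold_taxon(hits: pd.DataFrame,
                          e_threshold: float = DEFAULT_E_THRESHOLD) -> str:
    """Best-hit taxon for one scaffold's alignment rows.

    Among rows with ``evalue <= e_threshold``, the subject taxon of the
    maximum bitscore wins; ties break toward the smaller e-value, then the
    lexicographically smaller subject. No qualifying row -> "unclassified".
    """
    if len(hits) == 0:
        return "unclassified"
    queries = hits["qseqid"].unique()
    if len(queries) > 1:
        raise ValueError(f"hits mix multiple query ids: {sorted(queries)}")
    ok = hits[hits["evalue"] <= e_threshold]
    if len(ok) == 0:
        return "unclassified"
    ranked = ok.sort_values(["bitscore", "evalue", "sseqid"],
                            ascending=[False, True, True], kind="mergesort")
    return str(ranked.iloc[0]["sseqid"])


def bin_scaffolds(hits: pd.DataFrame, scaffold_ids,
                  e_threshold: float = DEFAULT_E_THRESHOLD) -> pd.Series:
    """Vectorized best-hit binning for many scaffolds at once.

    Scaffolds absent from the hit table are "unclassified".
    """
    result = pd.Series("unclassified", index=pd.Index(scaffold_ids, name="scaffold_id"))
    ok = hits[hits["evalue"] <= e_threshold]
    if len(ok):
        ranked = ok.sort_values(["bitscore", "evalue", "sseqid"],
                                ascending=[False, True, True], kind="mergesort")
        best = ranked.drop_duplicates("qseqid").set_index("qseqid")["sseqid"]
        common = result.index.intersection(best.index)
        result.loc[common] = best.loc[common].astype(str)
    return result


def build_abundance(scaffolds: pd.DataFrame, reads: pd.DataFrame) -> AbundanceTable:
    """Sum mapped reads per (taxon, sample) over binned scaffolds.

    ``scaffolds`` needs columns scaffold_id, sample, taxon; ``reads`` needs
    scaffold_id, reads (the sample is taken from the scaffold record).
    Column sums equal the total reads supplied per sample; "unclassified"
    is kept as an ordinary row.
    """
    known = set(scaffolds["scaffold_id"])
    missing = sorted(set(reads["scaffold_id"]) - known)
    if missing:
        raise ValueError(f"reads reference unknown scaffolds: {missing[:10]}")
    merged = reads[["scaffold_id", "reads"]].merge(
        scaffolds[["scaffold_id", "sample", "taxon"]],
        on="scaffold_id", how="left")
    table = (merged.pivot_table(index="taxon", columns="sample", values="reads",
                                aggfunc="sum", fill_value=0)
             .astype(float))
    table.columns.name = None
    table.index.name = None
    return AbundanceTable(data=table.sort_index(), normalized=False)


def normalize_to_median(table: AbundanceTable) -> AbundanceTable:
    """Scale each sample to the median of all sample totals.

    Each column is multiplied by ``median(totals) / column_total`` so all
    normalized totals equal the median; the factors are kept on the result.
    Idempotent up to floating point.
    """
    totals = table.data.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total reads: {list(zero.index)}")
    med = float(np.median(totals.to_numpy()))
    factors = med / totals
    out = table.data * factors
    return AbundanceTable(data=out, normalized=True, scale_factors=factors)


def subsample_scaffolds_by_coverage(scaffolds: pd.DataFrame,
                                    read_totals: pd.Series) -> pd.DataFrame:
    """Equalize assembly effort by dropping low-coverage scaffolds.

    For sample *s* with read total R_s, retain the top
    ``ceil((min_t R_t / R_s) * n_s)`` scaffolds ordered by coverage
    descending (ties: longer scaffold first, then lexicographic id); the
    sample with the minimum read total keeps everything. Low-coverage
    scaffolds are thus removed in inverse proportion to relative read
    numbers.
    """
    samples = scaffolds["sample"].unique()
    missing = [s for s in samples if s not in read_totals.index]
    if missing:
        raise ValueError(f"missing read totals for samples: {missing}")
    if (read_totals.loc[samples] <= 0).any():
        raise ValueError("all samples must have read_total > 0")
    r_min = float(read_totals.loc[samples].min())
    kept = []
    for s in samples:
        grp = scaffolds[scaffolds["sample"] == s]
        f = r_min / float(read_totals.loc[s])
        k = math.ceil(f * len(grp))
        ordered = grp.sort_values(["coverage", "length", "scaffold_id"],
                                  ascending=[False, False, True], kind="mergesort")
        kept.append(ordered.iloc[:k])
    return pd.concat(kept, axis=0).reset_index(drop=True)


def filter_taxa(table: AbundanceTable, drop_labels) -> AbundanceTable:
    """Drop rows whose taxon name contains any of the given labels.

    Used to remove host-plant, animal, or applied-biocontrol lineages
    (e.g. Viridiplantae, Metazoa, Beauveria) by plain substring match.
    """
    labels = list(drop_labels)
    keep = [t for t in table.data.index
            if not any(lab.lower() in str(t).lower() for lab in labels)]
    return AbundanceTable(data=table.data.loc[keep],
                          normalized=table.normalized,
                          scale_factors=table.scale_factors)
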