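"""Core/shell/cloud partitioning and set analysis of ortholog clusters.

A cluster matrix holds one row per ortholog cluster (with gene name and
annotation) and one copy-count column per sample. Presence is count >= 1.
The partition follows the standard pangenome vocabulary: *core* clusters
occur in every chosen sample, *cloud* clusters in exactly one, and *shell*
clusters in two or more but not all.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "ClusterMatrix",
    "PangenomePartition",
    "partition",
    "pan_overlap",
    "consolidate",
    "top_shared",
    "percent",
]

_META_COLS = ("gene_name", "annotation")
_GROUP_RE = re.compile(r"^group_?\d+$")
_SUFFIX_RE = re.compile(r"^(.*)_(\d+)$")


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage reported at a fixed precision (round-half-even).

    The raw ratio should always be kept alongside; this is the display
    arithmetic used for all reported fractions.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty total")
    return round(100.0 * numerator / denominator, decimals)


@dataclass
class ClusterMatrix:
    """Ortholog clusters x samples, with per-cluster gene name/annotation."""

    counts: pd.DataFrame          # clusters x samples, integer copy counts
    gene_name: pd.Series
    annotation: pd.Series

    def __post_init__(self):
        if not self.counts.index.is_unique:
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate cluster ids: {dupes[:5]}")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ClusterMatrix":
        """Split a combined frame (gene_name, annotation, sample columns)."""
        missing = [c for c in _META_COLS if c not in frame.columns]
        if missing:
            raise ValueError(f"missing metadata columns: {missing}")
        samples = [c for c in frame.columns if c not in _META_COLS]
        return cls(counts=frame[samples].astype(int),
                   gene_name=frame["gene_name"].astype(str),
                   annotation=frame["annotation"].astype(str))

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out.insert(0, "gene_name", self.gene_name)
        out.insert(1, "annotation", self.annotation)
        return out

    @property
    def samples(self) -> list:
        return list(self.counts.columns)

    def presence(self) -> pd.DataFrame:
        return self.counts >= 1


@dataclass
class PangenomePartition:
    """Disjoint core/shell/cloud cluster-id sets over a sample subset."""

    core: set
    shell: set
    cloud: set
    absent: set = field(default_factory=set)  # present in no chosen sample

    @property
    def n_present(self) -> int:
        return len(self.core) + len(self.shell) + len(self.cloud)

    def counts(self) -> dict:
        return {"core": len(self.core), "shell": len(self.shell),
                "cloud": len(self.cloud)}

    def fractions(self, decimals: int = 2, denominator: int | None = None) -> dict:
        """Percentages of each compartment; denominator defaults to the
        number of clusters present in >= 1 chosen sample."""
        den = self.n_present if denominator is None else denominator
        return {k: percent(v, den, decimals) for k, v in self.counts().items()}


def partition(matrix: ClusterMatrix, sample_subset=None) -> PangenomePartition:
    """Partition clusters by presence over the chosen sample columns.

    core = present in all chosen samples; cloud = in exactly one;
    shell = the rest with presence >= 2. Clusters absent from every chosen
    sample are excluded from the partition and reported separately.
    """
    samples = matrix.samples if sample_subset is None else list(sample_subset)
    if len(samples) == 0:
        raise ValueError("sample subset must be non-empty")
    unknown = [s for s in samples if s not in matrix.counts.columns]
    if unknown:
        raise ValueError(f"unknown samples: {unknown}")
    pres = (matrix.counts[samples] >= 1).sum(axis=1)
    n = len(samples)
    core = set(pres.index[pres == n])
    cloud = set(pres.index[pres == 1]) if n > 1 else set()
    absent = set(pres.index[pres == 0])
    shell = set(pres.index) - core - cloud - absent
    if n == 1:
        # with a single sample every present cluster is trivially core
        cloud = set()
    return PangenomePartition(core=core, shell=shell, cloud=cloud, absent=absent)


def pan_overlap(item_sets: dict) -> dict:
    """Venn region counts for 2-7 named sets.

    Returns a dict keyed by frozenset of group names (the groups whose
    exclusive intersection the region is) -> count. Region counts sum to
    the size of the union.
    """
    names = list(item_sets)
    if not 2 <= len(names) <= 7:
        raise ValueError("pan_overlap supports between 2 and 7 groups")
    sets = {k: set(v) for k, v in item_sets.items()}
    regions = {}
    for r in range(1, len(names) + 1):
        for inside in itertools.combinations(names, r):
            region = set.intersection(*(sets[k] for k in inside))
            for out in names:
                if out not in inside:
                    region -= sets[out]
            regions[frozenset(inside)] = len(region)
    return regions


def _strip_suffix(name: str) -> str:
    m = _SUFFIX_RE.match(name)
    return m.group(1) if m else name


def consolidate(matrix: ClusterMatrix, drop_hypothetical: bool = False,
                synonym_map: dict | None = None) -> ClusterMatrix:
    """Merge diverged cluster variants of the same gene.

    One trailing ``_<int>`` suffix is stripped from each gene name
    (``adhP_2`` -> ``adhP`` but ``abc_1_2`` -> ``abc_1``), optional
    synonyms are rewritten, rows whose stripped name is a ``group_#``
    placeholder are removed, and rows sharing a stripped name are merged
    (copy counts summed, so presence is the logical OR). With
    ``drop_hypothetical``, rows annotated exactly "hypothetical protein"
    (case-insensitive) are removed before merging. Idempotent.
    """
    frame = matrix.to_frame()
    if drop_hypothetical:
        keep = frame["annotation"].str.lower() != "hypothetical protein"
        frame = frame[keep]
    stripped = frame["gene_name"].map(_strip_suffix)
    if synonym_map:
        stripped = stripped.map(lambda n: synonym_map.get(n, n))
    is_group = (frame["gene_name"].map(lambda n: bool(_GROUP_RE.match(n)))
                | stripped.map(lambda n: bool(_GROUP_RE.match(n))))
    frame = frame[~is_group]
    stripped = stripped[~is_group]
    samples = [c for c in frame.columns if c not in _META_COLS]
    grouped = frame[samples].groupby(stripped, sort=True).sum()
    grouped.index.name = None
    ann = frame["annotation"].groupby(stripped).first()
    ann.index.name = None
    merged_names = pd.Series(grouped.index, index=grouped.index)
    return ClusterMatrix(counts=grouped, gene_name=merged_names,
                         annotation=ann.loc[grouped.index])


def top_shared(matrix: ClusterMatrix, tissue_of: dict | None = None,
               n_top: int = 100, subset: str = "all") -> pd.DataFrame:
    """Top-N genes by total copies, with per-sample relative copy numbers.

    ``subset='root_not_leaf'`` restricts to genes present in every root
    sample and absent from all leaf samples (``tissue_of`` maps sample ->
    'leaf'|'root'); ``'all'`` keeps everything. Relative copy number is
    the count divided by its sample's column total. If fewer than N genes
    qualify, the full qualifying list is returned.
    """
    counts = matrix.counts
    if subset == "root_not_leaf":
        if not tissue_of:
            raise ValueError("tissue metadata required for the root_not_leaf subset")
        roots = [s for s in counts.columns if tissue_of.get(s) == "root"]
        leaves = [s for s in counts.columns if tissue_of.get(s) == "leaf"]
        mask = (counts[roots] >= 1).all(axis=1) & (counts[leaves] == 0).all(axis=1)
        counts = counts[mask]
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    totals = counts.sum(axis=1)
    ranked = totals.sort_values(ascending=False, kind="mergesort").index[:n_top]
    col_totals = matrix.counts.sum(axis=0).replace(0, 1)
    rel = counts.loc[ranked].div(col_totals, axis=1)
    out = rel.copy()
    out.insert(0, "gene_name", matrix.gene_name.loc[ranked])
    out.insert(1, "total_copies", totals.loc[ranked].astype(int))
    return out
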