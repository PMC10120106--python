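"""Screening gene trees for topological concordance with the host phylogeny.

Ortholog-cluster gene trees typically carry several strain-level leaves per
host genotype. Concordance is assessed at the genotype level: leaves are
collapsed into mean patristic distances between genotypes, the distance
matrix is clustered with UPGMA, and the resulting dendrogram is checked for
the required host clades (by default every internal clade of 2-3 genotypes
of the host tree). A cluster "matches" when all required clades appear as
exact monophyletic groups; genotypes outside the required clades are
unconstrained.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from endopan.pangenome import percent
from endopan.simulate import GeneTree, GeneTreeSet

__all__ = [
    "HostReference",
    "Dendrogram",
    "ScreenReport",
    "eligible",
    "genotype_distances",
    "upgma",
    "matches_host",
    "screen",
]


@dataclass
class HostReference:
    """Rooted host tree over genotype codes plus the clades to require."""

    tree: dendropy.Tree
    required_clades: list  # list of frozensets of genotype codes

    @classmethod
    def from_newick(cls, newick: str, required_clades=None) -> "HostReference":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        if required_clades is None:
            required_clades = derive_required_clades(tree)
        return cls(tree=tree, required_clades=[frozenset(c) for c in required_clades])

    @property
    def genotypes(self) -> list:
        return sorted(l.taxon.label for l in self.tree.leaf_node_iter())


def derive_required_clades(tree: dendropy.Tree, min_size: int = 2,
                           max_size: int = 3) -> list:
    """All internal clades of the host tree with 2-3 leaves.

    The full leaf set (the root) is never required; the clades obtained
    are nested or disjoint by construction.
    """
    n_leaves = sum(1 for _ in tree.leaf_node_iter())
    clades = []
    for node in tree.preorder_internal_node_iter():
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        if min_size <= len(leaves) <= max_size and len(leaves) < n_leaves:
            clades.append(leaves)
    return sorted(set(clades), key=sorted)


def _leaf_genotype(tree_or_gt, label: str) -> str:
    if isinstance(tree_or_gt, GeneTree) and label in tree_or_gt.leaf_map:
        return tree_or_gt.leaf_map[label][0]
    return label.split("|", 1)[0]


def eligible(trees: GeneTreeSet, genotypes) -> GeneTreeSet:
    """Clusters retaining at least one leaf for every listed genotype."""
    genotypes = list(genotypes)
    if not genotypes:
        raise ValueError("genotype list must be non-empty")
    kept = {}
    for gt in trees:
        seen = {_leaf_genotype(gt, l.taxon.label) for l in gt.tree.leaf_node_iter()}
        if all(g in seen for g in genotypes):
            kept[gt.cluster_id] = gt
    return GeneTreeSet(trees=kept)


def genotype_distances(gene_tree: GeneTree, genotypes=None) -> pd.DataFrame:
    """Mean patristic distance between every pair of genotypes.

    Entry (g, h) averages the branch-length path distance over all leaf
    pairs with one leaf in genotype g and one in h. A degenerate tree in
    which every between-genotype distance is zero is rejected.
    """
    tree = gene_tree.tree
    leaves = list(tree.leaf_node_iter())
    groups: dict = {}
    for leaf in leaves:
        g = _leaf_genotype(gene_tree, leaf.taxon.label)
        groups.setdefault(g, []).append(leaf.taxon)
    if genotypes is None:
        genotypes = sorted(groups)
    missing = [g for g in genotypes if g not in groups]
    if missing:
        raise ValueError(f"cluster {gene_tree.cluster_id} lacks genotypes {missing}")
    pdm = tree.phylogenetic_distance_matrix()
    n = len(genotypes)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dists = [pdm.patristic_distance(a, b)
                     for a in groups[genotypes[i]] for b in groups[genotypes[j]]]
            out[i, j] = out[j, i] = float(np.mean(dists))
    if n > 1 and np.allclose(out, 0.0):
        raise ValueError(
            f"cluster {gene_tree.cluster_id}: degenerate zero-length tree")
    return pd.DataFrame(out, index=genotypes, columns=genotypes)


@dataclass
class Dendrogram:
    """Rooted ultrametric dendrogram from UPGMA.

    ``node`` is a label (leaf) or a tuple of child Dendrograms; ``height``
    is the merge height (half the linkage distance).
    """

    node: object
    height: float = 0.0
    _leaves: frozenset = field(default=None, repr=False)

    @property
    def leaves(self) -> frozenset:
        if self._leaves is None:
            if isinstance(self.node, str):
                object.__setattr__(self, "_leaves", frozenset([self.node]))
            else:
                object.__setattr__(self, "_leaves", frozenset().union(
                    *(c.leaves for c in self.node)))
        return self._leaves

    def clades(self) -> list:
        """Leaf sets of every internal node, root included."""
        if isinstance(self.node, str):
            return []
        out = [self.leaves]
        for c in self.node:
            out.extend(c.clades())
        return out

    def to_newick(self) -> str:
        def fmt(d: "Dendrogram", parent_height: float) -> str:
            length = parent_height - d.height
            if isinstance(d.node, str):
                return f"{d.node}:{length:.6g}"
            inner = ",".join(fmt(c, d.height) for c in d.node)
            return f"({inner}):{length:.6g}"
        if isinstance(self.node, str):
            return f"{self.node};"
        inner = ",".join(fmt(c, self.height) for c in self.node)
        return f"({inner});"


def upgma(matrix: pd.DataFrame) -> Dendrogram:
    """UPGMA (average-linkage) agglomeration of a distance matrix.

    Ties in the minimum distance are broken by merging the pair whose
    (lexicographically smallest member label of each side) sorts first,
    which makes the dendrogram deterministic; merge heights are half the
    linkage distance, so an ultrametric input is recovered exactly.
    """
    d = matrix.to_numpy(dtype=float)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    labels = list(matrix.index)
    if d.shape[0] != d.shape[1] or list(matrix.columns) != labels:
        raise ValueError("matrix must be square with matching labels")
    clusters = {i: Dendrogram(node=lab) for i, lab in enumerate(labels)}
    sizes = {i: 1 for i in clusters}
    reps = {i: lab for i, lab in enumerate(labels)}  # lexicographically smallest member
    dist = {(i, j): d[i, j] for i in clusters for j in clusters if i < j}
    next_id = len(labels)
    while len(clusters) > 1:
        best = min(dist.items(),
                   key=lambda kv: (kv[1], tuple(sorted((reps[kv[0][0]], reps[kv[0][1]])))))
        (i, j), dij = best
        merged = Dendrogram(node=(clusters[i], clusters[j]), height=dij / 2.0)
        for k in list(clusters):
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dnew = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
            dist[(k, next_id)] = dnew
        for key in [key for key in dist if i in key or j in key]:
            del dist[key]
        sizes[next_id] = sizes[i] + sizes[j]
        reps[next_id] = min(reps[i], reps[j])
        clusters[next_id] = merged
        del clusters[i], clusters[j], sizes[i], sizes[j]
        next_id += 1
    return next(iter(clusters.values()))


def matches_host(dendrogram: Dendrogram, host_ref: HostReference):
    """True iff every required host clade is an exact clade of the dendrogram.

    Returns ``(matched, per_clade)`` where *per_clade* maps each required
    clade to whether it was found (for auditing).
    """
    leaves = dendrogram.leaves
    needed = frozenset().union(*host_ref.required_clades) if host_ref.required_clades else frozenset()
    missing = needed - leaves
    if missing:
        raise ValueError(f"dendrogram lacks genotype leaves: {sorted(missing)}")
    clades = set(dendrogram.clades())
    per_clade = {clade: clade in clades for clade in host_ref.required_clades}
    return all(per_clade.values()), per_clade


@dataclass
class ScreenReport:
    n_clusters_total: int
    n_eligible: int
    n_matched: int
    matched_ids: list
    per_clade: dict            # cluster_id -> {clade: bool}
    taxon_tally: Counter
    gene_tally: Counter
    triples: Counter           # (genotype, taxon, gene) -> leaf count

    @property
    def fraction_matched(self) -> float:
        return self.n_matched / self.n_eligible if self.n_eligible else 0.0

    @property
    def fraction_matched_pct(self) -> float:
        """Matched fraction of eligible clusters, as a percentage (1 dp)."""
        if self.n_eligible == 0:
            return 0.0
        return percent(self.n_matched, self.n_eligible, 1)


def screen(trees: GeneTreeSet, host_ref: HostReference) -> ScreenReport:
    """Full phylosymbiosis screen over a set of cluster gene trees.

    eligible -> genotype mean patristic distances -> UPGMA -> required-clade
    match, per cluster; matched clusters are tallied by the taxon behind
    each leaf ("unbinned" kept separate), by gene name, and by
    (host genotype, taxon, gene) triples for Sankey export.
    """
    genotypes = host_ref.genotypes
    elig = eligible(trees, genotypes)
    matched_ids = []
    per_clade_all = {}
    taxon_tally: Counter = Counter()
    gene_tally: Counter = Counter()
    triples: Counter = Counter()
    for gt in elig:
        try:
            dmat = genotype_distances(gt, genotypes)
            dendro = upgma(dmat)
            ok, per_clade = matches_host(dendro, host_ref)
        except ValueError as exc:
            raise ValueError(f"cluster {gt.cluster_id}: {exc}") from exc
        per_clade_all[gt.cluster_id] = per_clade
        if not ok:
            continue
        matched_ids.append(gt.cluster_id)
        for leaf in gt.tree.leaf_node_iter():
            label = leaf.taxon.label
            genotype = _leaf_genotype(gt, label)
            taxon = gt.leaf_map.get(label, (genotype, "unbinned"))[1]
            taxon_tally[taxon] += 1
            gene_tally[gt.gene_name] += 1
            triples[(genotype, taxon, gt.gene_name)] += 1
    return ScreenReport(
        n_clusters_total=len(trees),
        n_eligible=len(elig),
        n_matched=len(matched_ids),
        matched_ids=matched_ids,
        per_clade=per_clade_all,
        taxon_tally=taxon_tally,
        gene_tally=gene_tally,
        triples=triples,
    )
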