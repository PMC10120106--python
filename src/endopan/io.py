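"""Readers and writers for every external format the pipeline touches.

Tabular data are headered TSVs except for two established dialects: the
12-column tab-separated aligner hit table (outfmt-6, headerless) and the
quoted Roary ``gene_presence_absence.csv`` (CSV, one column per sample,
non-empty cell = presence, tab-joined ids = copy count). Trees travel as
newick (one ``cluster_id<TAB>gene_name<TAB>newick`` line per cluster for
gene-tree sets) and the GO DAG as OBO with is_a edges only. All readers are
gzip-transparent and reject malformed records rather than coercing them.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import dendropy
import networkx as nx
import obonet
import pandas as pd
import yaml

from endopan.go import GoUniverse
from endopan.pangenome import ClusterMatrix
from endopan.profiles import AbundanceTable
from endopan.simulate import GeneTree, GeneTreeSet

__all__ = [
    "read_tsv", "write_tsv",
    "read_abundance", "write_abundance",
    "read_hits", "write_hits",
    "read_roary_csv", "write_roary_csv",
    "read_obo", "write_obo",
    "read_gene2go", "write_gene2go",
    "read_trees", "write_trees", "read_newick",
    "load_config",
]

HIT_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
               "qstart", "qend", "sstart", "send", "evalue", "bitscore"]

# Fixed metadata columns of the Roary dialect; anything else is a sample.
ROARY_META_COLUMNS = (
    "Gene", "Non-unique Gene name", "Annotation", "No. isolates",
    "No. sequences", "Avg sequences per isolate", "Genome Fragment",
    "Order within Fragment", "Accessory Fragment",
    "Accessory Order with Fragment", "QC", "Min group size nuc",
    "Max group size nuc", "Avg group size nuc",
)


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode, encoding="utf-8")


def read_tsv(path, index_col=None) -> pd.DataFrame:
    with _open_text(path) as fh:
        return pd.read_csv(fh, sep="\t", index_col=index_col)


def write_tsv(frame: pd.DataFrame, path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_abundance(path) -> AbundanceTable:
    frame = read_tsv(path, index_col=0)
    if frame.isna().any().any():
        raise ValueError(f"{path}: abundance table has missing cells")
    return AbundanceTable(data=frame.astype(float))


def write_abundance(table: AbundanceTable, path) -> None:
    write_tsv(table.data, path)


def read_hits(path) -> pd.DataFrame:
    """Headerless 12-column outfmt-6 hit table."""
    with _open_text(path) as fh:
        frame = pd.read_csv(fh, sep="\t", header=None)
    if frame.shape[1] != 12:
        raise ValueError(f"{path}: expected 12 columns, found {frame.shape[1]}")
    frame.columns = HIT_COLUMNS
    return frame


def write_hits(hits: pd.DataFrame, path) -> None:
    hits[HIT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_roary_csv(path) -> ClusterMatrix:
    """Quoted Roary-dialect CSV -> cluster copy-count matrix.

    Presence = non-empty sample cell; multi-entry cells (ids joined by
    tabs) count as copy number. Cluster ids are taken from the Gene
    column.
    """
    with _open_text(path) as fh:
        frame = pd.read_csv(fh, dtype=str, keep_default_na=False)
    for required in ("Gene", "Annotation"):
        if required not in frame.columns:
            raise ValueError(f"{path}: missing required column {required!r} "
                             "in header (line 1)")
    samples = [c for c in frame.columns if c not in ROARY_META_COLUMNS]
    counts = frame[samples].map(lambda cell: len(cell.split("\t")) if cell else 0)
    counts.index = frame["Gene"]
    counts.index.name = None
    return ClusterMatrix(
        counts=counts.astype(int),
        gene_name=pd.Series(list(frame["Gene"]), index=counts.index),
        annotation=pd.Series(list(frame["Annotation"]), index=counts.index),
    )


def write_roary_csv(matrix: ClusterMatrix, path) -> None:
    rows = []
    for cid in matrix.counts.index:
        row = {
            "Gene": matrix.gene_name.loc[cid],
            "Non-unique Gene name": "",
            "Annotation": matrix.annotation.loc[cid],
            "No. isolates": int((matrix.counts.loc[cid] >= 1).sum()),
        }
        for sample in matrix.counts.columns:
            n = int(matrix.counts.loc[cid, sample])
            row[sample] = "\t".join(f"{cid}_{sample}_{i + 1}" for i in range(n))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_obo(path):
    """OBO file -> (DAG with child->parent is_a edges, names, namespaces).

    Obsolete terms are skipped; a cyclic is_a graph is rejected.
    """
    with _open_text(path) as fh:
        graph = obonet.read_obo(fh)
    dag = nx.DiGraph()
    names, namespaces = {}, {}
    for term, data in graph.nodes(data=True):
        dag.add_node(term)
        names[term] = data.get("name", "")
        namespaces[term] = data.get("namespace", "")
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            dag.add_edge(child, parent)
    try:
        cycle = nx.find_cycle(dag)
        raise ValueError(f"{path}: cyclic is_a graph through {cycle[0][0]}")
    except nx.NetworkXNoCycle:
        pass
    return dag, names, namespaces


def write_obo(universe: GoUniverse, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n\n")
        for term in sorted(universe.dag.nodes):
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {universe.names.get(term, term)}\n")
            ns = universe.namespaces.get(term)
            if ns:
                fh.write(f"namespace: {ns}\n")
            for parent in sorted(universe.dag.successors(term)):
                fh.write(f"is_a: {parent} ! {universe.names.get(parent, '')}\n")
            fh.write("\n")


def read_gene2go(path) -> pd.DataFrame:
    frame = read_tsv(path)
    if list(frame.columns[:2]) != ["gene", "term"]:
        raise ValueError(f"{path}: expected columns gene, term")
    return frame


def write_gene2go(gene2terms: dict, path) -> None:
    rows = [{"gene": g, "term": t}
            for g in sorted(gene2terms) for t in sorted(gene2terms[g])]
    write_tsv(pd.DataFrame(rows, columns=["gene", "term"]), path, index=False)


def read_newick(path_or_string) -> dendropy.Tree:
    text = str(path_or_string)
    if "(" in text and ";" in text:
        return dendropy.Tree.get(data=text, schema="newick")
    with _open_text(text) as fh:
        return dendropy.Tree.get(data=fh.read(), schema="newick")


def read_trees(path, genotypes=None) -> GeneTreeSet:
    """Multi-newick gene-tree file: ``cluster_id<TAB>gene_name<TAB>newick``.

    Leaf labels follow ``genotype|...|strain``; if ``genotypes`` is given,
    an unknown genotype prefix raises with the offending cluster id.
    """
    trees = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            cid, gene_name, newick = parts
            try:
                tree = dendropy.Tree.get(data=newick, schema="newick")
            except Exception as exc:
                raise ValueError(f"{path}:{lineno}: cluster {cid}: bad newick "
                                 f"({exc})") from exc
            leaf_map = {}
            for leaf in tree.leaf_node_iter():
                label = leaf.taxon.label
                genotype = label.split("|", 1)[0]
                if genotypes is not None and genotype not in genotypes:
                    raise ValueError(
                        f"{path}:{lineno}: cluster {cid}: unknown genotype "
                        f"prefix {genotype!r} in leaf {label!r}")
                leaf_map[label] = (genotype, "unbinned")
            trees[cid] = GeneTree(cluster_id=cid, gene_name=gene_name,
                                  tree=tree, leaf_map=leaf_map)
    return GeneTreeSet(trees=trees)


def write_trees(trees: GeneTreeSet, path, taxon_map_path=None) -> None:
    """Write the gene-tree set; optionally also a leaf->taxon map TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        for gt in trees:
            newick = gt.tree.as_string(schema="newick",
                                       suppress_rooting=True).strip()
            fh.write(f"{gt.cluster_id}\t{gt.gene_name}\t{newick}\n")
    if taxon_map_path is not None:
        rows = [{"cluster_id": gt.cluster_id, "leaf": label,
                 "genotype": g, "taxon": taxon}
                for gt in trees for label, (g, taxon) in sorted(gt.leaf_map.items())]
        write_tsv(pd.DataFrame(rows), taxon_map_path, index=False)


def apply_taxon_map(trees: GeneTreeSet, taxon_map: pd.DataFrame) -> GeneTreeSet:
    """Attach taxon labels from a leaf->taxon map TSV to a read tree set."""
    lookup = {(r.cluster_id, r.leaf): (r.genotype, r.taxon)
              for r in taxon_map.itertuples()}
    for gt in trees:
        for label in list(gt.leaf_map):
            if (gt.cluster_id, label) in lookup:
                gt.leaf_map[label] = lookup[(gt.cluster_id, label)]
    return trees


_CONFIG_KEYS = {
    "seed", "outdir", "label_filter", "e_threshold", "normalize",
    "alpha_elim", "algorithm", "host_tree", "required_clades",
    "simulate",  # nested block of SimConfig overrides
}


def load_config(path) -> dict:
    """Declarative YAML run configuration; unknown top-level keys rejected."""
    with _open_text(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    return data


def newick_roundtrip_equal(a: dendropy.Tree, b: dendropy.Tree,
                           tol: float = 1e-9) -> bool:
    """Topology + branch-length equality helper used by round-trip tests."""
    ta = a.as_string(schema="newick")
    tb = b.as_string(schema="newick")
    if ta == tb:
        return True
    tns = dendropy.TaxonNamespace()
    a2 = dendropy.Tree.get(data=ta, schema="newick", taxon_namespace=tns)
    b2 = dendropy.Tree.get(data=tb, schema="newick", taxon_namespace=tns)
    a2.encode_bipartitions()
    b2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(a2, b2) == 0
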