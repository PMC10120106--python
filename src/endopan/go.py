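"""GO term enrichment over an is_a DAG with elim decorrelation.

The universe couples a rooted acyclic is_a graph with gene -> term
annotations. Annotations are closed under ancestry (the true-path rule)
before testing. Each term is tested with the upper-tail hypergeometric
(one-sided Fisher) p-value; the *elim* algorithm then decorrelates the DAG
by removing the genes of significantly enriched terms from all their
ancestors before the ancestors are tested, so enrichment signal is
attributed to the most specific terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from scipy import stats

__all__ = ["GoUniverse", "propagate", "fisher_term", "enrich", "merge_mappings"]


@dataclass
class GoUniverse:
    """is_a DAG (edges child -> parent) plus gene annotations.

    ``gene2terms`` maps gene symbol -> set of directly annotated terms;
    after :func:`propagate`, ``term2genes`` holds the ancestry-closed
    annotation sets.
    """

    dag: nx.DiGraph
    gene2terms: dict
    universe_genes: set
    names: dict = field(default_factory=dict)
    namespaces: dict = field(default_factory=dict)
    term2genes: dict | None = None   # filled by propagate()

    @classmethod
    def from_edges(cls, terms, parent_map, gene2terms, names=None, namespaces=None):
        dag = nx.DiGraph()
        dag.add_nodes_from(terms)
        for child, parents in parent_map.items():
            for p in parents:
                dag.add_edge(child, p)
        return cls(dag=dag, gene2terms={g: set(t) for g, t in gene2terms.items()},
                   universe_genes=set(gene2terms),
                   names=dict(names or {}), namespaces=dict(namespaces or {}))

    def roots(self) -> list:
        return sorted(t for t in self.dag.nodes if self.dag.out_degree(t) == 0)

    def depths(self) -> dict:
        """Longest path (in edges) from each term up to a root."""
        order = list(nx.topological_sort(self.dag))  # parents after children
        depth: dict = {}
        for term in reversed(order):  # roots first
            parents = list(self.dag.successors(term))
            depth[term] = 0 if not parents else 1 + max(depth[p] for p in parents)
        return depth


def propagate(universe: GoUniverse) -> GoUniverse:
    """Close annotation sets under ancestry (true-path rule).

    A gene directly annotated to a term is annotated to every ancestor;
    genes are held in sets, so diamond paths never double-count. Raises if
    the graph has a cycle (naming a member).
    """
    try:
        cycle = nx.find_cycle(universe.dag)
        raise ValueError(f"is_a graph has a cycle through {cycle[0][0]}")
    except nx.NetworkXNoCycle:
        pass
    term2genes: dict = {t: set() for t in universe.dag.nodes}
    missing = set()
    for gene, terms in universe.gene2terms.items():
        for t in terms:
            if t not in term2genes:
                missing.add(t)
                continue
            term2genes[t].add(gene)
    if missing:
        warnings.warn(f"{len(missing)} annotated term(s) absent from the DAG; dropped")
    order = list(nx.topological_sort(universe.dag))  # children before parents
    for term in order:
        for parent in universe.dag.successors(term):
            term2genes[parent] |= term2genes[term]
    universe.term2genes = term2genes
    return universe


def fisher_term(k: int, study_n: int, big_k: int, universe_n: int) -> float:
    """Upper-tail hypergeometric p-value, P(X >= k).

    X ~ Hypergeom(universe_n, big_k, study_n): the number of study genes
    annotated to the term under random draws from the universe.
    """
    if not (0 <= k <= min(study_n, big_k)) or big_k > universe_n or study_n > universe_n:
        raise ValueError(
            f"inconsistent counts: k={k}, study_n={study_n}, K={big_k}, N={universe_n}")
    return float(stats.hypergeom.sf(k - 1, universe_n, big_k, study_n))


def enrich(study_genes, universe: GoUniverse, algorithm: str = "elim",
           alpha_elim: float = 0.01, fdr: bool = False) -> pd.DataFrame:
    """Per-term enrichment of a study gene set.

    ``algorithm='classic'`` tests every term independently;
    ``'elim'`` processes terms from the deepest level upward (depth =
    longest path to a root, ties in lexicographic term order) and, when a
    term's current p-value falls below ``alpha_elim``, removes its
    currently annotated genes from all its ancestors before those are
    tested. Study genes absent from the universe are dropped with a
    warning. Rows are sorted by the decorrelated p, then term id.

    Returns a DataFrame with columns term, name, K (annotated in
    universe), k (annotated in study), expected, p_classic,
    p_decorrelated (equal to p_classic under 'classic'), and optionally a
    Benjamini-Hochberg ``fdr`` column on the decorrelated p.
    """
    if algorithm not in ("classic", "elim"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if universe.term2genes is None:
        propagate(universe)
    study = set(study_genes)
    stray = sorted(study - universe.universe_genes)
    if stray:
        warnings.warn(f"study genes absent from universe, dropped: {stray[:10]}"
                      f" ({len(stray)} total)")
        study -= set(stray)
    n_universe = len(universe.universe_genes)
    n_study = len(study)

    term2genes = universe.term2genes
    classic = {}
    for term, genes in term2genes.items():
        big_k = len(genes)
        k = len(genes & study)
        classic[term] = (k, big_k,
                         fisher_term(k, n_study, big_k, n_universe) if big_k else 1.0)

    if algorithm == "classic":
        decorrelated = {t: p for t, (_, _, p) in classic.items()}
        current = {t: (k, big_k) for t, (k, big_k, _) in classic.items()}
    else:
        depths = universe.depths()
        order = sorted(term2genes, key=lambda t: (-depths[t], t))
        working = {t: set(g) for t, g in term2genes.items()}
        decorrelated = {}
        current = {}
        for term in order:
            genes = working[term]
            big_k = len(genes)
            k = len(genes & study)
            p = fisher_term(k, n_study, big_k, n_universe) if big_k else 1.0
            decorrelated[term] = p
            current[term] = (k, big_k)
            if p < alpha_elim and big_k:
                for anc in nx.descendants(universe.dag, term):  # ancestors (child->parent edges)
                    working[anc] -= genes

    rows = []
    for term in term2genes:
        k_cls, big_k_cls, p_cls = classic[term]
        rows.append({
            "term": term,
            "name": universe.names.get(term, ""),
            "K": big_k_cls,
            "k": k_cls,
            "expected": n_study * big_k_cls / n_universe if n_universe else 0.0,
            "p_classic": p_cls,
            "p_decorrelated": decorrelated[term],
        })
    out = pd.DataFrame(rows).sort_values(["p_decorrelated", "term"],
                                         kind="mergesort").reset_index(drop=True)
    if fdr:
        m = len(out)
        p = out["p_decorrelated"].to_numpy()
        order = p.argsort(kind="mergesort")
        q = pd.Series(index=out.index, dtype=float)
        prev = 1.0
        for rank_pos in range(m - 1, -1, -1):
            i = order[rank_pos]
            val = min(prev, p[i] * m / (rank_pos + 1))
            q.iloc[i] = val
            prev = val
        out["fdr"] = q
    return out


def merge_mappings(tables, universe_dag: nx.DiGraph | None = None,
                   synonym_map: dict | None = None):
    """Union gene->term mapping tables into one curated map.

    Each table is a DataFrame with columns (gene, term). Gene symbols are
    keyed case-insensitively (first-seen casing is kept); optional
    synonyms are rewritten first. Pairs whose term is absent from a
    supplied DAG are dropped with a warning count. Returns
    ``(gene2terms, provenance)`` where provenance counts retained pairs
    per source table index.
    """
    gene2terms: dict = {}
    canonical: dict = {}
    provenance: dict = {}
    dropped = 0
    for i, table in enumerate(tables):
        kept = 0
        for gene, term in zip(table.iloc[:, 0], table.iloc[:, 1]):
            gene = str(gene).strip()
            term = str(term).strip()
            if synonym_map and gene in synonym_map:
                gene = synonym_map[gene]
            if universe_dag is not None and term not in universe_dag:
                dropped += 1
                continue
            key = gene.lower()
            name = canonical.setdefault(key, gene)
            before = len(gene2terms.get(name, ()))
            gene2terms.setdefault(name, set()).add(term)
            kept += len(gene2terms[name]) > before
        provenance[i] = kept
    if dropped:
        warnings.warn(f"{dropped} mapping pair(s) referenced terms absent from the DAG")
    return gene2terms, provenance
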