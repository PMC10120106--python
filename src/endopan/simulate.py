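"""Synthetic endosphere community generator.

Every downstream stage of the pipeline (binning, diversity, pangenome
partitioning, GO enrichment, phylosymbiosis screening) can be exercised on
data produced here, with ground-truth labels recorded in :class:`SimTruth`.
The generator emulates the qualitative structure of a multi-genotype,
two-tissue plant endosphere survey:

* genotype- and tissue-structured taxon occupancy, with root communities
  richer than leaf communities;
* log-normal relative abundances observed through multinomial read sampling;
* ortholog gene clusters with planted core/shell/cloud presence patterns and
  a majority of unannotated "hypothetical protein" clusters;
* a random GO DAG with planted over-represented terms in a study gene set;
* per-cluster gene trees, a planted fraction of which mirror the host
  phylogeny topology.

All randomness flows from one integer seed; each output kind draws from its
own fixed sub-stream so that, e.g., enlarging the taxon pool does not
reshuffle the gene trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimTruth",
    "GeneTree",
    "GeneTreeSet",
    "DEFAULT_HOST_NEWICK",
    "simulate_metadata",
    "simulate_communities",
    "simulate_pangenome",
    "simulate_go",
    "simulate_gene_trees",
    "simulate_hits_and_scaffolds",
]

# Ultrametric host phylogeny over the six retained genotypes: the two wild
# BB-genome accessions are sisters, M. textilis then M. sikkimensis attach
# successively, and the two cultivated triploids form the other root clade.
DEFAULT_HOST_NEWICK = "((((BB:1.0,MB:1.0):1.0,MT:2.0):1.0,MS:3.0):1.0,(DC:1.5,FH:1.5):2.5);"

DEFAULT_GENOTYPES = ("BB", "MB", "MT", "MS", "DC", "FH")

# Below-ground sample-code letters as used in the field (corm vs root).
_ROOT_LETTER = {"BB": "C", "MB": "R", "MT": "C", "MS": "R", "DC": "R", "FH": "C"}

_GENERA = (
    "Agrobacterium", "Rhizobium", "Pseudomonas", "Variovorax", "Stenotrophomonas",
    "Chitinophaga", "Kosakonia", "Enterobacter", "Klebsiella", "Pantoea",
    "Acidovorax", "Paraburkholderia", "Sphingobium", "Serratia", "Herbaspirillum",
    "Flavobacterium", "Luteimonas", "Bradyrhizobium", "Rhodopseudomonas", "Citrobacter",
)

_GENE_POOL = (
    ("adhP", "alcohol dehydrogenase, propanol-preferring"),
    ("xerC", "tyrosine recombinase"),
    ("rhaS", "arabinose operon regulatory protein"),
    ("mdtA", "multidrug efflux pump periplasmic linker"),
    ("hcaB", "2-dehydro-3-deoxy-D-gluconate 5-dehydrogenase"),
    ("malT", "transcriptional regulator of maltose regulon"),
    ("rbsA", "ribose import ATP-binding protein"),
    ("gsiD", "glutathione transport system permease"),
    ("mopR", "phenol degradation regulator"),
    ("ompR", "osmoregulation transcriptional regulator"),
    ("trg", "methyl-accepting chemotaxis protein III"),
    ("butA", "diacetyl reductase"),
    ("cspA", "cold shock protein"),
    ("betA", "oxygen-dependent choline dehydrogenase"),
    ("ctpF", "cation-transporting ATPase F"),
    ("ttgB", "toluene efflux pump membrane transporter"),
    ("clpB", "chaperone protein ClpB"),
    ("mdtB", "multidrug resistance protein"),
    ("acdS", "1-aminocyclopropane-1-carboxylate deaminase"),
    ("nifH", "nitrogenase iron protein"),
    ("chiA", "chitinase A"),
    ("pelB", "pectate lyase B"),
    ("celC", "endoglucanase C"),
    ("iaaM", "tryptophan 2-monooxygenase"),
    ("budC", "acetoin reductase"),
    ("katG", "catalase-peroxidase"),
    ("sodB", "superoxide dismutase"),
    ("fhuA", "ferrichrome outer membrane transporter"),
    ("phoB", "phosphate regulon response regulator"),
    ("cheY", "chemotaxis response regulator"),
)

# Fixed sub-stream ids: one per output kind, so streams are independent.
_STREAMS = {
    "metadata": 11,
    "communities": 23,
    "pangenome": 37,
    "go": 41,
    "trees": 53,
    "scaffolds": 67,
}


@dataclass(frozen=True)
class SimConfig:
    """All tunable parameters of the synthetic community, plus the seed."""

    seed: int = 0
    genotypes: tuple = DEFAULT_GENOTYPES
    tissues: tuple = ("leaf", "root")
    # community structure
    n_taxa_pool: int = 300
    root_leaf_richness_ratio: float = 0.3
    core_taxon_fraction: float = 0.05
    abundance_lognormal_mu: float = 0.0
    abundance_lognormal_sigma: float = 1.5
    depth_per_sample: int = 50_000
    # pangenome structure
    n_clusters: int = 2000
    target_core_shell_cloud: tuple = (0.017, 0.271, 0.712)
    hypothetical_fraction: float = 0.62
    # GO universe
    n_go_terms: int = 150
    go_depth: int = 5
    n_go_genes: int = 1500
    study_size: int = 200
    n_enriched_terms: int = 5
    enrichment_odds: float = 10.0
    # gene trees
    n_gene_trees: int = 500
    n_seq_per_genotype: int = 3
    frac_phylosymbiotic: float = 0.054
    branch_noise_sigma: float = 0.1
    nonphylo_mode: str = "uniform"  # or "permute"
    frac_unbinned: float = 0.46
    # scaffolds & hits
    n_scaffolds_per_sample: int = 200
    frac_hitfree: float = 0.2
    hit_error_rate: float = 0.0

    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    def validate(self) -> None:
        fracs = {
            "root_leaf_richness_ratio": self.root_leaf_richness_ratio,
            "core_taxon_fraction": self.core_taxon_fraction,
            "hypothetical_fraction": self.hypothetical_fraction,
            "frac_phylosymbiotic": self.frac_phylosymbiotic,
            "frac_unbinned": self.frac_unbinned,
            "frac_hitfree": self.frac_hitfree,
            "hit_error_rate": self.hit_error_rate,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"SimConfig.{name} must be in [0, 1], got {value}")
        if self.root_leaf_richness_ratio <= 0.0:
            raise ValueError("SimConfig.root_leaf_richness_ratio must be in (0, 1]")
        if len(self.target_core_shell_cloud) != 3:
            raise ValueError("SimConfig.target_core_shell_cloud must have 3 entries")
        if abs(sum(self.target_core_shell_cloud) - 1.0) > 1e-9:
            raise ValueError("SimConfig.target_core_shell_cloud must sum to 1")
        if self.n_genotypes < 1:
            raise ValueError("SimConfig.genotypes must be non-empty")
        if len(self.tissues) != 2:
            raise ValueError("SimConfig.tissues must be a (leaf, root) pair")
        if self.depth_per_sample <= 0:
            raise ValueError("SimConfig.depth_per_sample must be positive")
        if self.n_seq_per_genotype < 1:
            raise ValueError("SimConfig.n_seq_per_genotype must be >= 1")
        if self.go_depth < 1:
            raise ValueError("SimConfig.go_depth must be >= 1")
        if self.branch_noise_sigma < 0:
            raise ValueError("SimConfig.branch_noise_sigma must be >= 0")
        if self.nonphylo_mode not in ("uniform", "permute"):
            raise ValueError("SimConfig.nonphylo_mode must be 'uniform' or 'permute'")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class SimTruth:
    """Ground-truth labels for everything the generator planted."""

    taxon_category: dict = field(default_factory=dict)      # taxon -> core | genotype-specific | tissue-specific
    cluster_category: dict = field(default_factory=dict)    # cluster_id -> core | shell | cloud
    enriched_go_terms: set = field(default_factory=set)
    phylosymbiotic_cluster_ids: set = field(default_factory=set)
    scaffold_taxon: dict = field(default_factory=dict)      # scaffold_id -> planted taxon or "unclassified"


@dataclass
class GeneTree:
    cluster_id: str
    gene_name: str
    tree: dendropy.Tree
    leaf_map: dict  # leaf label -> (genotype, taxon label or "unbinned")


@dataclass
class GeneTreeSet:
    trees: dict  # cluster_id -> GeneTree

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees.values())


def _rng(config: SimConfig, kind: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[kind], config.seed % (2**31)])


def _sample_code(genotype: str, tissue: str) -> str:
    if tissue == "leaf":
        return genotype + "L"
    return genotype + _ROOT_LETTER.get(genotype, "R")


def simulate_metadata(config: SimConfig) -> pd.DataFrame:
    """Sample sheet: one leaf and one below-ground sample per genotype.

    Returns a DataFrame with columns sample, genotype, tissue, read_total.
    Read totals are log-normally dispersed around ``depth_per_sample``.
    """
    config.validate()
    rng = _rng(config, "metadata")
    rows = []
    for genotype in config.genotypes:
        for tissue in config.tissues:
            total = max(1, int(round(config.depth_per_sample * rng.lognormal(0.0, 0.4))))
            rows.append({
                "sample": _sample_code(genotype, tissue),
                "genotype": genotype,
                "tissue": tissue,
                "read_total": total,
            })
    return pd.DataFrame(rows)


def _taxon_pool(config: SimConfig) -> list:
    return [
        f"{_GENERA[i % len(_GENERA)]} sp. T{i:04d}" for i in range(config.n_taxa_pool)
    ]


def simulate_communities(config: SimConfig):
    """Taxon-by-sample read count table plus planted occupancy truth.

    Core taxa occur in every sample. The remaining taxa are split evenly
    across genotypes; each genotype's root sample carries its full share,
    and its leaf sample a seeded subset of size
    ``ceil(root_leaf_richness_ratio * share)`` — leaf communities are
    therefore nested within, and poorer than, their paired root
    communities. Relative abundances are i.i.d. log-normal per sample and
    observed counts multinomial at ``depth_per_sample``.

    Returns ``(table, truth)`` with *table* a DataFrame (taxa x samples).
    """
    config.validate()
    if config.depth_per_sample <= 0:
        raise ValueError("depth_per_sample must be positive")
    rng = _rng(config, "communities")
    pool = _taxon_pool(config)
    order = rng.permutation(len(pool))
    n_core = int(round(config.core_taxon_fraction * len(pool)))
    core = [pool[i] for i in order[:n_core]]
    rest = [pool[i] for i in order[n_core:]]

    shares = {g: [] for g in config.genotypes}
    for j, taxon in enumerate(rest):
        shares[config.genotypes[j % config.n_genotypes]].append(taxon)

    truth = SimTruth()
    for t in core:
        truth.taxon_category[t] = "core"

    meta = simulate_metadata(config)
    present: dict = {}
    for genotype in config.genotypes:
        share = shares[genotype]
        root_set = core + share
        k = math.ceil(config.root_leaf_richness_ratio * len(share))
        perm = rng.permutation(len(share))
        leaf_extra = [share[i] for i in perm[:k]]
        leaf_set = core + leaf_extra
        for t in leaf_extra:
            truth.taxon_category[t] = "genotype-specific"
        for t in share:
            if t not in truth.taxon_category:
                truth.taxon_category[t] = "tissue-specific"
        for tissue in config.tissues:
            code = _sample_code(genotype, tissue)
            present[code] = leaf_set if tissue == "leaf" else root_set

    samples = list(meta["sample"])
    table = pd.DataFrame(0, index=pool, columns=samples, dtype=int)
    for code in samples:
        taxa = present[code]
        w = rng.lognormal(config.abundance_lognormal_mu,
                          config.abundance_lognormal_sigma, size=len(taxa))
        p = w / w.sum()
        counts = rng.multinomial(config.depth_per_sample, p)
        table.loc[taxa, code] = counts
    # taxa never observed anywhere are dropped from the table but keep truth
    table = table.loc[table.sum(axis=1) > 0]
    return table, truth


def _largest_remainder_counts(total: int, fractions) -> list:
    raw = [f * total for f in fractions]
    base = [int(math.floor(x)) for x in raw]
    short = total - sum(base)
    remainders = sorted(range(len(raw)), key=lambda i: (raw[i] - base[i]), reverse=True)
    for i in remainders[:short]:
        base[i] += 1
    return base


def simulate_pangenome(config: SimConfig):
    """Ortholog-cluster copy-count matrix with planted core/shell/cloud labels.

    Cluster categories are fixed deterministically by the target fractions
    (largest-remainder apportionment), then presence patterns are sampled
    conditional on category: core clusters occupy every sample, cloud
    clusters exactly one, and shell clusters an independent Bernoulli(0.5)
    pattern rejection-sampled until it covers >= 2 but not all samples.
    A ``hypothetical_fraction`` of clusters is named ``group_k`` with
    annotation "hypothetical protein"; the rest cycle through a pool of
    gene symbols with Roary-style ``_1, _2`` variant suffixes.
    """
    config.validate()
    meta = simulate_metadata(config)
    samples = list(meta["sample"])
    if len(samples) < 2:
        raise ValueError("simulate_pangenome requires >= 2 samples")
    rng = _rng(config, "pangenome")
    n = config.n_clusters
    n_core, n_shell, n_cloud = _largest_remainder_counts(n, config.target_core_shell_cloud)
    categories = ["core"] * n_core + ["shell"] * n_shell + ["cloud"] * n_cloud

    n_hyp = int(round(config.hypothetical_fraction * n))
    hyp_flags = np.zeros(n, dtype=bool)
    hyp_flags[rng.permutation(n)[:n_hyp]] = True

    truth = SimTruth()
    ns = len(samples)
    patterns = np.zeros((n, ns), dtype=int)
    names, annotations, ids = [], [], []
    name_counter: dict = {}
    hyp_counter = 0
    for i in range(n):
        cid = f"oc{i:05d}"
        ids.append(cid)
        cat = categories[i]
        truth.cluster_category[cid] = cat
        if cat == "core":
            pres = np.ones(ns, dtype=bool)
        elif cat == "cloud":
            pres = np.zeros(ns, dtype=bool)
            pres[rng.integers(ns)] = True
        else:
            while True:
                pres = rng.random(ns) < 0.5
                if 2 <= pres.sum() < ns:
                    break
        copies = np.where(pres, 1 + rng.poisson(0.7, size=ns), 0)
        patterns[i] = copies
        if hyp_flags[i]:
            hyp_counter += 1
            names.append(f"group_{hyp_counter}")
            annotations.append("hypothetical protein")
        else:
            base, desc = _GENE_POOL[i % len(_GENE_POOL)]
            name_counter[base] = name_counter.get(base, 0) + 1
            names.append(f"{base}_{name_counter[base]}")
            annotations.append(desc)

    matrix = pd.DataFrame(patterns, index=ids, columns=samples)
    matrix.insert(0, "gene_name", names)
    matrix.insert(1, "annotation", annotations)
    return matrix, truth


def simulate_go(config: SimConfig):
    """Random rooted GO-like DAG, gene annotations, and a planted study set.

    The DAG has ``go_depth`` levels below a single root; each non-root term
    draws 1-2 ``is_a`` parents from strictly shallower levels, so every term
    reaches the root. Genes are annotated to childless ("leaf-ish") terms.
    The study set over-samples genes of ``n_enriched_terms`` planted terms
    with an ``enrichment_odds`` weight multiplier; odds 1 reduces to a
    uniform draw (the null).

    Returns ``(universe, study_genes, truth)`` where *universe* is a
    :class:`endopan.go.GoUniverse` with direct (unpropagated) annotations.
    """
    from endopan.go import GoUniverse  # local import to avoid a cycle

    config.validate()
    rng = _rng(config, "go")
    n = config.n_go_terms
    terms = [f"GO:{i + 1:07d}" for i in range(n)]
    levels = {terms[0]: 0}
    # spread remaining terms over levels 1..go_depth, at least one per level
    for i, term in enumerate(terms[1:], start=1):
        if i <= config.go_depth:
            levels[term] = i
        else:
            levels[term] = int(rng.integers(1, config.go_depth + 1))
    parents: dict = {terms[0]: []}
    for term in terms[1:]:
        shallower = [t for t in terms if levels[t] < levels[term]]
        k = min(len(shallower), int(rng.integers(1, 3)))
        idx = rng.choice(len(shallower), size=k, replace=False)
        parents[term] = sorted(shallower[j] for j in idx)

    has_child = set()
    for term, ps in parents.items():
        has_child.update(ps)
    leaf_terms = sorted(t for t in terms if t not in has_child)

    # one direct leaf term per gene: terms correlate only through ancestry,
    # which keeps planted signal attributable to its term
    genes = [f"g{i:05d}" for i in range(config.n_go_genes)]
    gene2terms = {g: {leaf_terms[int(rng.integers(len(leaf_terms)))]}
                  for g in genes}

    counts = {t: sum(1 for g in genes if t in gene2terms[g]) for t in leaf_terms}
    eligible = [t for t in leaf_terms if counts[t] >= 20]
    if len(eligible) < config.n_enriched_terms:
        eligible = sorted(leaf_terms, key=lambda t: (-counts[t], t))
    idx = rng.choice(len(eligible), size=config.n_enriched_terms, replace=False)
    planted = {eligible[j] for j in idx}

    planted_genes = {g for g in genes if gene2terms[g] & planted}
    weights = np.array([config.enrichment_odds if g in planted_genes else 1.0
                        for g in genes])
    weights = weights / weights.sum()
    study_idx = rng.choice(len(genes), size=min(config.study_size, len(genes)),
                           replace=False, p=weights)
    study_genes = sorted(genes[j] for j in study_idx)

    truth = SimTruth(enriched_go_terms=planted)
    universe = GoUniverse.from_edges(
        terms=terms,
        parent_map=parents,
        gene2terms=gene2terms,
        names={t: f"synthetic term {t}" for t in terms},
        namespaces={t: "biological_process" for t in terms},
    )
    return universe, study_genes, truth


def _yule_subtree(rng: np.random.Generator, labels, edge_scale: float = 0.01):
    """Random rooted subtree over ``labels`` (Yule/coalescent topology law).

    Built by random pairwise joins; edge lengths are exponential with a
    small scale so strain subtrees stay shallow relative to host branches.
    Returned as a nested ``(subtree, edge_length)`` structure where
    *subtree* is a label string or a list of child nodes.
    """
    nodes = [(lab, edge_scale * rng.exponential()) for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(int(x) for x in rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(([a, b], edge_scale * rng.exponential()))
    return nodes[0]


def _newick_of(node) -> str:
    sub, length = node
    if isinstance(sub, str):
        return f"{sub}:{length:.6f}"
    return "(" + ",".join(_newick_of(c) for c in sub) + f"):{length:.6f}"


def _host_clone_newick(node, rng, sigma, tip_subtrees) -> str:
    """Serialize a dendropy node, perturbing lengths and grafting tip subtrees."""
    length = node.edge.length or 0.0
    if sigma > 0:
        length *= float(rng.lognormal(0.0, sigma))
    if node.is_leaf():
        sub, _ = tip_subtrees[node.taxon.label]
        if isinstance(sub, str):
            return f"{sub}:{length:.6f}"
        return "(" + ",".join(_newick_of(c) for c in sub) + f"):{length:.6f}"
    inner = ",".join(_host_clone_newick(c, rng, sigma, tip_subtrees)
                     for c in node.child_nodes())
    return f"({inner}):{length:.6f}"


def _uniform_rooted_topology(rng: np.random.Generator, items) -> list:
    """Uniform rooted binary topology over ``items`` (nested-list form).

    Grown by attaching each new leaf to a uniformly chosen edge, including
    the edge above the root: a tree with k leaves has 2k-1 such edges, so
    the construction yields the uniform distribution over the (2n-3)!!
    rooted labelled topologies.
    """
    if len(items) == 1:
        return [items[0]]
    tree: list = [0, 1]
    for leaf in range(2, len(items)):
        slots = [None]  # None encodes the root edge
        stack = [(tree, 0), (tree, 1)]
        while stack:
            holder, i = stack.pop()
            slots.append((holder, i))
            node = holder[i]
            if isinstance(node, list):
                stack.extend([(node, 0), (node, 1)])
        choice = slots[int(rng.integers(len(slots)))]
        if choice is None:
            tree = [tree, leaf]
        else:
            holder, i = choice
            holder[i] = [holder[i], leaf]

    def to_items(node):
        if isinstance(node, list):
            return [to_items(c) for c in node]
        return items[node]

    return to_items(tree)


def _nested_to_newick_ultrametric(node, rng, height: float) -> str:
    """Serialize a nested topology with random clock-like (ultrametric) depths.

    Every genotype tip sits at height 0, so UPGMA on the resulting
    patristic distances recovers exactly the generated topology — the
    uniform-topology null therefore carries over unchanged to the matcher.
    Leaves are pre-serialized subtree fragments without a top edge length.
    """
    if isinstance(node, list):
        parts = []
        for child in node:
            if isinstance(child, list):
                child_height = height * float(rng.uniform(0.35, 0.75))
                inner = _nested_to_newick_ultrametric(child, rng, child_height)
                parts.append(f"{inner}:{height - child_height:.6f}")
            else:
                parts.append(f"{child}:{height:.6f}")
        return "(" + ",".join(parts) + ")"
    return node


def simulate_gene_trees(config: SimConfig, host_tree=None):
    """Per-cluster gene trees, a planted fraction concordant with the host.

    For a phylosymbiotic cluster the gene tree is the host topology with
    every genotype tip replaced by a small Yule subtree of
    ``n_seq_per_genotype`` strain leaves and all host branch lengths
    perturbed by multiplicative log-normal noise (``branch_noise_sigma``).
    Non-phylosymbiotic clusters draw a uniform-random rooted topology over
    the genotype subtrees (default) or randomly permute genotype labels
    (``nonphylo_mode='permute'``).

    Leaf labels follow ``genotype|cluster_id|strainNN``; the taxon (or
    "unbinned") behind each strain is recorded in the per-tree leaf map.
    """
    config.validate()
    if config.n_seq_per_genotype < 1:
        raise ValueError("n_seq_per_genotype must be >= 1")
    if host_tree is None:
        host_tree = DEFAULT_HOST_NEWICK
    if isinstance(host_tree, str):
        host = dendropy.Tree.get(data=host_tree, schema="newick")
    else:
        host = host_tree
    host_leaves = sorted(l.taxon.label for l in host.leaf_node_iter())
    if host_leaves != sorted(config.genotypes):
        raise ValueError(
            f"host tree leaves {host_leaves} do not match genotypes {sorted(config.genotypes)}"
        )

    rng = _rng(config, "trees")
    n = config.n_gene_trees
    n_phylo = int(round(config.frac_phylosymbiotic * n))
    phylo_flags = np.zeros(n, dtype=bool)
    phylo_flags[rng.permutation(n)[:n_phylo]] = True

    taxon_pool = _taxon_pool(config)
    truth = SimTruth()
    trees: dict = {}
    name_counter: dict = {}
    for i in range(n):
        cid = f"pc{i:05d}"
        base, _ = _GENE_POOL[int(rng.integers(len(_GENE_POOL)))]
        name_counter[base] = name_counter.get(base, 0) + 1
        gene_name = f"{base}_{name_counter[base]}"

        leaf_map = {}
        tip_subtrees = {}
        for genotype in config.genotypes:
            labels = []
            for k in range(config.n_seq_per_genotype):
                label = f"{genotype}|{cid}|s{k:02d}"
                if rng.random() < config.frac_unbinned:
                    taxon = "unbinned"
                else:
                    taxon = taxon_pool[int(rng.integers(len(taxon_pool)))]
                leaf_map[label] = (genotype, taxon)
                labels.append(label)
            if len(labels) == 1:
                tip_subtrees[genotype] = (labels[0], 0.0)
            else:
                tip_subtrees[genotype] = _yule_subtree(rng, labels)

        if phylo_flags[i]:
            newick = _host_clone_newick(host.seed_node, rng,
                                        config.branch_noise_sigma, tip_subtrees) + ";"
            truth.phylosymbiotic_cluster_ids.add(cid)
        elif config.nonphylo_mode == "permute":
            perm = rng.permutation(config.n_genotypes)
            permuted = {config.genotypes[j]: tip_subtrees[config.genotypes[int(perm[j])]]
                        for j in range(config.n_genotypes)}
            newick = _host_clone_newick(host.seed_node, rng,
                                        config.branch_noise_sigma, permuted) + ";"
        else:
            parts = []
            for genotype in config.genotypes:
                sub, _ = tip_subtrees[genotype]
                if isinstance(sub, str):
                    parts.append(sub)
                else:
                    parts.append("(" + ",".join(_newick_of(c) for c in sub) + ")")
            nested = _uniform_rooted_topology(rng, parts)
            body = _nested_to_newick_ultrametric(nested, rng, 1.0)
            if not body.startswith("("):  # single-genotype edge case
                body = f"({body}:1.0)"
            newick = body + ";"
        tree = dendropy.Tree.get(data=newick, schema="newick")
        trees[cid] = GeneTree(cluster_id=cid, gene_name=gene_name,
                              tree=tree, leaf_map=leaf_map)
    return GeneTreeSet(trees=trees), truth


def simulate_hits_and_scaffolds(config: SimConfig):
    """Alignment hit rows, scaffold metadata and read counts per scaffold.

    Each scaffold is planted on a taxon drawn from its sample's community
    abundances. With probability ``1 - hit_error_rate`` the planted taxon
    holds the top bitscore among that scaffold's qualifying hit rows;
    ``frac_hitfree`` of scaffolds receive no rows at all and are therefore
    binned "unclassified". Read counts are proportional to coverage x length.

    Returns ``(hits, scaffolds, reads, truth)`` as DataFrames (hits in the
    12-column tabular outfmt-6 dialect) plus planted per-scaffold truth.
    """
    config.validate()
    rng = _rng(config, "scaffolds")
    table, _ = simulate_communities(config)
    meta = simulate_metadata(config)
    truth = SimTruth()
    hit_rows, scaffold_rows, read_rows = [], [], []
    all_taxa = list(table.index)
    for code in meta["sample"]:
        col = table[code]
        present = col[col > 0]
        p = (present / present.sum()).to_numpy()
        taxa = list(present.index)
        for j in range(config.n_scaffolds_per_sample):
            sid = f"{code}_sc{j:04d}"
            length = int(rng.integers(500, 20001))
            coverage = float(rng.lognormal(1.0, 1.0))
            planted = taxa[int(rng.choice(len(taxa), p=p))]
            hitfree = rng.random() < config.frac_hitfree
            recorded = "unclassified" if hitfree else planted
            truth.scaffold_taxon[sid] = recorded
            scaffold_rows.append({"scaffold_id": sid, "sample": code,
                                  "length": length, "coverage": coverage,
                                  "taxon": recorded})
            reads = max(1, int(round(coverage * length / 150.0)))
            read_rows.append({"scaffold_id": sid, "sample": code, "reads": reads})
            if hitfree:
                continue
            top_bits = float(rng.uniform(200, 500))
            winner = planted
            if config.hit_error_rate > 0 and rng.random() < config.hit_error_rate:
                winner = all_taxa[int(rng.integers(len(all_taxa)))]
                truth.scaffold_taxon[sid] = planted  # truth keeps the planted taxon
            hit_rows.append(_hit_row(sid, winner, top_bits, 1e-30, rng, length))
            for _ in range(int(rng.integers(1, 4))):
                decoy = all_taxa[int(rng.integers(len(all_taxa)))]
                bits = top_bits * float(rng.uniform(0.3, 0.95))
                hit_rows.append(_hit_row(sid, decoy, bits, 1e-10, rng, length))
    hits = pd.DataFrame(hit_rows, columns=[
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore"])
    scaffolds = pd.DataFrame(scaffold_rows)
    reads = pd.DataFrame(read_rows)
    return hits, scaffolds, reads, truth


def _hit_row(sid, taxon, bits, evalue, rng, qlen):
    aln = int(rng.integers(100, max(101, qlen // 3 + 1)))
    return {
        "qseqid": sid, "sseqid": taxon,
        "pident": round(float(rng.uniform(60, 100)), 1),
        "length": aln, "mismatch": int(rng.integers(0, 30)),
        "gapopen": int(rng.integers(0, 5)),
        "qstart": 1, "qend": aln, "sstart": 1, "send": aln,
        "evalue": evalue, "bitscore": round(bits, 1),
    }
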