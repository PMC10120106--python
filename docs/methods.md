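# Methods

This note records the statistical procedures `endopan` implements, the
design of the synthetic-data generator, the numerical conventions, and the
limits of what the test suite demonstrates.

## Taxonomic binning and abundance profiles

A scaffold is assigned to the subject taxon of its best qualifying
alignment hit: among rows with e-value ≤ `e_threshold` (default 10⁻⁵), the
maximum bitscore wins, with ties broken by smaller e-value and then
lexicographic subject name so the assignment is deterministic. This is
best-hit binning, not lowest-common-ancestor binning: the intended use is
strain/species-level profiling where the hit table already reports the
lowest annotated rank. Scaffolds with no qualifying hit are "unclassified"
and kept as an ordinary row so read totals are conserved.

Two normalizations are provided:

* **Median scaling** multiplies each sample column by
  `median(all column totals) / column total`, so every normalized total
  equals the median. The transform is idempotent and preserves
  within-sample composition; the per-sample factors are kept on the result.
* **Coverage-ranked scaffold subsampling** equalizes assembly effort before
  presence/absence set analyses. For sample *s* with read total `R_s`,
  scaffolds are sorted by coverage (descending; ties to the longer
  scaffold, then lexicographic id) and the top `ceil((min_t R_t / R_s) ·
  n_s)` are retained — lower-coverage scaffolds are removed in inverse
  proportion to relative read numbers, and the shallowest sample keeps
  everything. Subsampling is by scaffold count; a length-weighted variant
  would retain scaffolds until a summed-length quota is met and is not
  implemented.

A taxon "occurs" in a sample iff it has ≥ 1 mapped read (the presence
threshold used by all set analyses). Host-plant, animal and
applied-biocontrol lineages are removed by a plain substring label filter,
not by a taxonomy engine.

## Diversity statistics

All statistics are computed from their defining formulas; scikit-bio and
scipy implementations appear only as independent oracles in the tests.

* Shannon uses the natural logarithm (the ecology default; the log base
  only rescales). Simpson is reported as `1 − Σ pᵢ²` so that a single-taxon
  sample scores 0.
* Chao1 is the bias-corrected form `S_obs + F₁(F₁−1)/(2(F₂+1))`. ACE uses
  rare-count cutoff 10; when every rare taxon is a singleton the coverage
  estimate is zero and ACE is undefined, in which case Chao1 is returned
  instead of NaN.
* Rarefaction offers seeded subsampling without replacement and the exact
  expectation `E[S_d] = Σᵢ [1 − C(N−nᵢ, d)/C(N, d)]`; the tests verify the
  sampler against the closed form and the closed form against full subset
  enumeration.
* PCoA eigendecomposes `B = −½ J D² J`; negative eigenvalues are reported
  but carry no coordinates. NMDS minimizes Kruskal stress-1 by alternating
  isotonic regression of embedded distances on dissimilarity ranks with a
  Guttman-transform update, over 20 seeded random starts (2 dimensions,
  tolerance 10⁻⁶) — none of these constants is canonical; they are
  package defaults chosen for reliable convergence on tens of samples.
* One-way PERMANOVA uses the distance-based sums of squares
  (`SS_total = Σ_{i<j} d²_{ij}/N`, within-group analogue per group) and
  pseudo-F with (a−1, N−a) degrees of freedom. The p-value is
  `(1 + #{F_perm ≥ F_obs})/(n_perm + 1)` from seeded label permutations
  (default 999), or the exact proportion over all distinct label
  arrangements when there are ≤ 10,000 of them. Its type-I error at
  α = 0.05 is verified to sit in [0.03, 0.07] over 1000 null simulations.
* Welch's t uses the Satterthwaite degrees of freedom; ANOVA the standard
  decomposition. Tail probabilities come from scipy's t and F
  distributions.

## Metapangenome partition and consolidation

Over a chosen sample subset, a cluster present in every sample is *core*,
in exactly one *cloud*, and otherwise (presence ≥ 2) *shell*; clusters
absent from all chosen samples are excluded from the partition and reported
separately. Percentages are reported at fixed precision with
round-half-even, and raw counts are always emitted alongside.

Consolidation strips exactly one trailing `_<integer>` from each gene name
(`ybgI_2 → ybgI`, but `abc_1_2 → abc_1`), rewrites optional user-supplied
synonyms, removes `group_#` placeholder clusters (matched against both the
original and the stripped name, exact pattern `group[_]?<int>`), and merges
rows sharing a name by summing copy counts (presence = logical OR). The
hypothetical-protein filter is an exact, case-insensitive string match so
the rule stays auditable. Only exact-name merging is automated; synonym
resolution across annotation sources is the caller's responsibility via
the synonym map.

## GO enrichment

Annotations are closed under is_a ancestry (true-path rule) with genes held
in sets, so diamond paths never double-count. Each term is tested with the
exact upper-tail hypergeometric p-value `P(X ≥ k)` for `X ~
Hypergeom(N, K, n)`.

Graph decorrelation uses the *elim* algorithm: terms are processed in order
of decreasing depth (longest path to the root; ties in lexicographic term
order for determinism), and when a term's current p falls below
`alpha_elim` (default 0.01) its currently annotated genes are removed from
all ancestors before those are tested. elim is the deterministic half of
the weight01 hybrid used by topGO-style pipelines; it is exactly
specifiable and exactly testable, which is why it was chosen over a
weight01 port. Removing a significant child's genes can only weaken an
ancestor's enrichment except at the root, whose classic p is pinned at
exactly 1 (K = N) and can drop infinitesimally below 1 after removal. No
multiple-testing correction is applied by default (the decorrelated
p-values are intended to be interpreted directly); a Benjamini–Hochberg
column is available behind a flag, and the reporting cutoff `alpha_report`
defaults to 0.05.

## Phylosymbiosis screen

Gene trees typically carry several strain leaves per host genotype, so
concordance is assessed at genotype level:

1. **Eligibility** — only clusters retaining ≥ 1 leaf per host genotype.
2. **Collapse** — mean patristic distance between every genotype pair
   (average over all between-group leaf pairs). The reduction is
   deterministic and does not require per-genotype monophyly.
3. **UPGMA** — average-linkage agglomeration with ties broken toward the
   pair whose lexicographically smallest member labels sort first; merge
   heights are half the linkage distance, so ultrametric input is
   recovered exactly.
4. **Clade match** — a cluster matches iff *all* required clades appear as
   exact clades of the dendrogram. Required clades default to every
   internal clade of the host tree with 2–3 leaves (never the full leaf
   set); for the default six-genotype host tree these are `{BB,MB}`,
   `{BB,MB,MT}` and `{DC,FH}`, leaving MS unconstrained. The conjunction of
   all required clades is used (a per-clade audit is reported); matching is
   on rooted dendrograms.

Under a uniform null over the 945 rooted binary topologies on six
genotypes, exactly 3 topologies contain all three clades (verified by
exhaustive enumeration in the tests), so the false-positive rate of the
screen is 3/945 ≈ 0.32%. Matched clusters are tallied by the taxon behind
each leaf (with "unbinned" kept separate), by gene name, and by
(genotype, taxon, gene) triples for Sankey-style export; tallies conserve
leaf counts.

## The synthetic-data generator

The generator emulates a two-tissue (leaf, below-ground), six-genotype
endosphere survey and writes every downstream input format with truth
labels. All randomness flows from one seed; each output kind draws from its
own fixed sub-stream so changing one component's size never reshuffles
another's draws. Identical configurations produce byte-identical files.

**Communities.** Core taxa (fraction 0.05 of a 300-taxon pool at desk
scale) occur in every sample; the remaining taxa are split evenly across
genotypes, the root sample carries its genotype's full share, and the leaf
sample a seeded subset of `ceil(0.3 · share)` of it plus all core taxa —
leaf communities are nested within and poorer than their paired root
communities, reproducing the root-richer-than-leaf alpha-diversity
contrast. Relative abundances are i.i.d. log-normal(0, 1.5) per sample and
observed counts multinomial at 50,000 reads. The Welch test on per-sample
Shannon separates tissues with power ≥ 0.8 across seeds.

**Pangenome.** Cluster categories are fixed deterministically by
largest-remainder apportionment of the target fractions (0.017, 0.271,
0.712 — the full-scale root compartment counts renormalized to sum to 1),
then presence patterns are sampled conditional on category; shell patterns
are Bernoulli(0.5) rejection-sampled until they cover ≥ 2 but not all
samples, so truth labels are unambiguous and the partition recovers them
exactly. 62% of clusters are `group_k` placeholders annotated
"hypothetical protein"; the rest cycle through a pool of real gene symbols
with `_1, _2` variant suffixes.

**GO universe.** A rooted DAG of 150 terms over 5 levels; each non-root
term draws 1–2 is_a parents from strictly shallower levels. Each of 1500
genes is annotated to exactly one childless term, so terms correlate only
through ancestry and planted signal is attributable to its term — real GO
annotation is heavier-tailed and multi-term, which this deliberately
simplifies for testability. Five planted terms (chosen among terms with
≥ 20 genes) have their genes over-weighted by odds 10 in a 200-gene study
draw; these defaults come from a power analysis run before the tests were
frozen, chosen so that all planted terms rank in the top 5 in ≥ 90% of
seeds while the odds = 1 null stays calibrated. Under the null the
fraction of terms at p < 0.05 is accepted in [0.01, 0.075]: exact
hypergeometric tests are conservative for small annotation counts, so
rates modestly below 5% are expected, not a defect.

**Gene trees.** A planted fraction (default 0.054) of clusters are
concordant: the host topology (an ultrametric six-genotype tree) with each
genotype tip replaced by a shallow random subtree of `n_seq_per_genotype`
strain leaves and every host branch length multiplied by
log-normal(0, `branch_noise_sigma`) noise. Because strain subtrees are two
orders of magnitude shallower than the host's inter-clade gaps, the screen
has sensitivity 1.0 at zero noise, and sensitivity decays monotonically as
noise grows. Non-concordant clusters draw a uniform-random rooted topology
over the genotype subtrees with random clock-like (ultrametric) node
heights, so UPGMA recovers the drawn topology exactly and the analytic
3/945 null carries over to the matcher unchanged; a label-permutation mode
is available instead (its null rate is 4/720 because identity-like
permutations preserve the required clades). Strain leaves carry a taxon
label from the community pool or "unbinned" (probability 0.46).

**Hits and scaffolds.** Each scaffold is planted on a taxon drawn from its
sample's community abundances; its top hit carries the planted taxon with
probability 1 − `hit_error_rate` among decoys with lower bitscores, 20% of
scaffolds are hit-free (binned "unclassified"), and read counts are
proportional to coverage × length. With zero error the abundance builder
reproduces planted per-taxon counts exactly.

**What passing tests do and do not show.** The generator's communities are
genotype-dominated: because non-core taxa are private to genotypes while
leaf sets are nested in root sets, Bray–Curtis beta diversity separates
genotypes strongly and tissues weakly — the opposite emphasis from field
data, where tissue is typically the stronger axis. Passing tests therefore
demonstrate the correctness of the statistics and the recoverability of
planted structure, not that the generator is a faithful ecological model.
Real data also differ in ways the generator ignores: taxon abundance
correlations across samples, copy-number variation within clusters,
annotation noise in gene names, non-ultrametric host trees, and
incomplete lineage sorting in gene trees.

## Problem sizes and defaults

Desk-scale defaults (300 taxa, 2000 clusters, 500 gene trees, 150 GO
terms, 12 samples) keep every stage in seconds while preserving the
qualitative structure of a full-scale survey, whose compartment counts are
two to three orders of magnitude larger. The acceptance script scales two
stages up where the statistics demand it: 2000 gene trees for the planted
concordant fraction and 10,000 trees for the uniform-topology null.

## Known limitations

* Best-hit binning ignores hit ambiguity; no LCA or coverage-weighted
  voting.
* The elim algorithm approximates, but is not identical to, the weight01
  hybrid; p-values for terms whose signal is split across siblings will
  differ from a weight01 implementation.
* The phylosymbiosis criterion is topological only; branch-length
  concordance and formal congruence statistics (e.g. permutation tests on
  Robinson–Foulds distances) are out of scope.
* NMDS can converge to local minima for pathological rank patterns despite
  multiple starts; the stress of the returned configuration is always
  reported.
* UPGMA tie-breaking is deterministic but arbitrary; exactly tied
  distances (measure-zero for continuous data) resolve by label order.
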