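# Methods

This note documents the models and procedures `finet` implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical conventions that make runs reproducible.

## Functional-interaction extraction

A functional interaction (FI) is an unordered protein pair that either
acts in the same reaction — in an input, catalyst, activator or
inhibitor role — or belongs to the same complex (components flattened
recursively; cyclic nesting is a structural error). Reaction outputs
never contribute: producing a protein is not evidence of acting with
it. Role sets may overlap and are flattened before pairing; complexes
appearing in reaction roles are flattened too, so their internal pairs
are emitted along the way (they are complex FIs regardless, and this
keeps deduplication trivial).

Direction tags follow pathway-diagram semantics: catalyst/activator →
`activates` toward each input, inhibitor → `inhibits` toward each
input, transcription-factor→target records → `expression_regulates`;
everything else is undirected. When the same pair is reported both
directed and undirected, the directed report wins; when a pair is both
pathway-derived and predicted, pathway provenance wins and source
labels are unioned. Direction matters downstream: an alteration in a
regulator supports hypotheses about its targets, not conversely.

Pathway content is read from a simple line-oriented TSV (PATHWAY /
REACTION / COMPLEX records) rather than BioPAX/SBML/KGML; the format
carries exactly the fields the FI definition consumes. Splice-isoform
suffixes (`P12345-2`) are stripped so identity is by base accession.

## Evidence features and screening

Nine boolean features describe a candidate pair: human physical PPI;
fly, worm and yeast interologs (foreign-species pairs projected through
a many-to-many ortholog map, self-pairs dropped); domain–domain
interaction (any domain of one protein interacting with any domain of
the other); two independent co-expression pair lists (consumed
precomputed); shared GO biological-process annotation; and a text-mined
PPI. Absence of a record means false (closed world).

Interaction records with more than four distinct participants are
dropped before matrix expansion into pairs: large pulldown records
correlate much more weakly with pathway-derived FIs. Shared-GO counting
excludes the BP root and any term annotating ≥ 25% (configurable) of
annotated proteins — very broad terms signal nothing about shared
specific processes; all evidence codes are accepted.

Sources are screened by an odds ratio against the reference FI set:
equal-size control groups of random pairs are drawn from the reference
protein universe (10 permutations by default, mean ± sd reported), the
2×2 table crossing source membership with reference-vs-control origin.
Zero cells get the Haldane–Anscombe +0.5 correction.

## The naïve Bayes classifier

Class conditionals are Laplace-smoothed maximum-likelihood estimates,
θ = (count + 1)/(n + 2), so no likelihood is exactly 0 or 1. The
scoring prior is the pair density of the filtered positives,
π = n_pos / C(n_proteins, 2) — *not* the training class balance. The
negatives-per-positive ratio ρ (10 or 100) only controls the precision
of the negative-class conditional estimates; this is why the ROC is
essentially invariant to ρ. Negatives are sampled uniformly without
replacement from the positive set's protein universe, excluding known
positive pairs (cheap, removes label noise). Scores are accumulated in
log space and compared to a threshold τ = 0.50 by default; pairs with
no true feature are never predicted, mirroring the training-set filter.

Training and evaluation use a pathway-level split (default 70/30): test
positives are FIs from held-out pathways minus any training pair,
emulating evaluation against independent pathway databases. Test
negatives are drawn once from the test-pathway protein universe at 10
per positive and shared by every model evaluated on the split, so
comparisons between training configurations (e.g. ρ = 10 vs ρ = 100)
see identical test data. ROC points are computed at every distinct
score; AUC by the trapezoid rule.

## Network construction and validation

The merged network is an undirected graph with per-edge provenance,
direction and source labels. Descriptive statistics report node/edge
counts, mean and maximum degree, and component sizes. As an independent
sanity check (cellular-component annotations are not a training
feature), the CC-sharing rate of predicted FIs is compared with that of
the raw PPI evidence; edges with an unannotated endpoint are excluded
from the denominator. Gene-symbol networks are produced by mapping
accessions through a symbol table, dropping unmapped accessions (count
logged) and re-deduplicating; self-edges arising from shared symbols
are discarded.

## Cohort analyses

**Modules.** The subnetwork induced by a cohort's altered genes
(isolated genes reported separately) is clustered by Girvan–Newman
edge-betweenness: repeatedly remove the edge of maximal betweenness
(ties broken by the lexicographically smallest edge) and keep the
component partition of maximal Newman–Girvan modularity over the whole
removal sequence, evaluated on the original subnetwork. Modules are
ordered by descending size. The stopping rule is maximum modularity;
when several cuts tie at the optimum the algorithm's answer is one of
them, and the test suite treats equal-modularity partitions from an
independent implementation as agreement.

**Co-hit test.** The observed statistic is the fraction of samples with
≥ 1 altered gene in each of two modules. The null redraws each sample's
in-universe genes uniformly from the clustered subnetwork's gene
universe, preserving per-sample counts, and recomputes the fraction;
p is the fraction of permutations at least as extreme, reported as
"< 1/n_perm" when none reach the observed value (default n_perm =
10,000).

**Sample clustering.** Samples are described by their binary
module-hit fingerprints and clustered by complete linkage under the
asymmetric binary distance d = discordant / (positions where either is
1), with d = 0 for two all-zero rows; the dendrogram is cut at a
supplied height or cluster count (the cut is a parameter — no canonical
value exists).

**Enrichment.** Per term, p = P(X ≥ k) with X ~ Binomial(n = module
size, p_bg = annotated fraction of the network universe), computed
exactly. The permutation FDR of a term is the mean number of null
p-values (from random same-size gene sets, default 1,000 draws) at or
below its observed p, divided by the observed p's rank, clipped to
[0, 1] and monotonized in p. One-off 2×2 associations use one-sided
Fisher exact or hypergeometric tails.

## Recurrence, ASP and core subnetworks

The recurrence curve reports the fraction of altered genes occurring in
≥ s samples, against a null that redraws per-sample gene sets uniformly
from the universe with counts preserved (mean and 2.5/97.5% envelope),
plus the ASP of each ≥ s gene set.

ASP is the mean unweighted shortest-path length over all unordered
pairs of genes inside the network's largest connected component;
out-of-component genes are excluded and counted. Distances come from a
cached all-pairs BFS matrix, so 1,000-fold permutation tests are cheap.
The uniform null draws equally many component nodes; the
degree-stratified null builds bins greedily over the sorted candidate
degrees — each bin grown until it holds at least max(5, bin count)
component nodes, short trailing bins merged — and draws bin-matched
counts, so every null set reproduces the candidates' degree histogram
bin by bin. p is the fraction of null ASPs at or below the observed
value.

Candidate genes are clustered by average linkage on the shortest-path
matrix. Merges at equal heights are treated as forming together, and
after each height level the smallest live cluster holding more than the
coverage fraction (default 0.70) of usable genes is returned; if none
qualifies below the root, the root is returned with a warning. The
height-grouping matters for flat dendrograms (a clique merges as one
cluster, not as an arbitrary sub-pair).

The core subnetwork starts from each in-component candidate as a
singleton cluster and repeatedly joins the two clusters at the smallest
shortest-path distance along one such path (among ties, the
lexicographically smallest node sequence), path interiors becoming
linker genes. A refinement pass then (a) drops any linker whose removal
keeps the candidates connected and (b) replaces any linker pair by a
single substitute node where one exists — the pairwise greedy can miss
a shared hub. Exact minimum Steiner trees are out of scope at scale,
but on exhaustively checkable instances (≤ 8 nodes) the refined greedy
attains the brute-force minimum.

## Synthetic worlds

The generator builds, from a seed: (1) a pathway world — proteins
assigned evenly to compartments, pathways with a round-robin home
compartment whose reactions and complexes draw members by cycling
through the compartment in shuffled order (with 10% universe-wide
picks), emulating curation that spreads broadly over co-localized
proteins; (2) evidence sources — every planted FI enters source *i*
with probability q_pos[i], every background (non-FI) pair with
q_neg[i]; interolog sources are emitted under foreign namespaces with
ortholog maps, GO-BP sharing is realized as per-pair terms plus one
deliberately broad term that the breadth filter must remove, domains as
one domain per protein plus an interacting-domain table, and CC
annotations as the compartment labels; (3) cohorts — per sample, each
planted driver module is hit with its probability (one uniform module
gene), plus Poisson(λ) passengers uniform over the universe.

Defaults: 500 proteins, 40 pathways, 10 compartments, reactions 4–7
per pathway with 1–2 inputs and catalyst/activator/inhibitor
probabilities 0.5/0.2/0.2, complexes 1–2 of size 2–3, q_pos spanning
0.15–0.80 against q_neg 0.01–0.05. These sizes put the world's FI
density (and hence the prior, ~0.008) in the realistic sub-percent
regime, which also makes the 1:100 negative ratio feasible — in a dense
world there are simply not enough non-positive pairs to draw. Cohorts
default to 91 samples; analyses that rely on recurrence filtering use a
passenger rate λ ≈ 1 so the per-gene passenger occurrence n·λ/U stays
well below one, as it is in real cohorts where the gene universe dwarfs
the per-sample alteration count. With λ large relative to U/n,
passengers recur by chance and recurrence stops enriching for drivers —
a scaling artifact of small universes, not a property of the method.

What the generator does *not* emulate: correlated evidence sources
(features are conditionally independent given FI status by
construction, so the naïve-Bayes independence assumption holds exactly
— real PPI/domain/GO sources share phylogenetic provenance and violate
it mildly); study bias (every protein is equally likely to be
curated); isoform-level identity; hub structure beyond what pathway
co-membership induces; and realistic mutation processes (passengers
are uniform, drivers are one-gene-per-module hits). Passing tests
demonstrate correctness of the machinery and recovery of planted
structure under the model's assumptions, not performance on real 2009
databases.

## Numerical conventions

All randomness flows through `numpy.random.default_rng(seed)`; every
public sampling function takes a seed and the CLI threads one
everywhere. Betweenness and modularity ties break lexicographically;
pair sampling uses exact combinatorial unranking (with integer fix-up
of float round-off) rather than rejection over the universe; scores are
log-space; permutation p-values are r/n with the "< 1/n" convention at
r = 0. Tests and the acceptance script use permutation counts of
200–1,000 and worlds of a few hundred proteins to keep runs within
seconds while leaving sampling error far below the asserted margins.
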