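# Methods

This note records the exact procedures, parameter defaults, and numerical
choices implemented in `gvortho`, and what the synthetic generators do and
do not emulate.

## 1. Two-stage orthogroup clustering

**Inputs.** Pairwise similarity tables (`query, target, score, qcov, tcov,
evalue`): sequence-identity fractions and structural TM-scores, both in
[0, 1], produced by any all-vs-all search tool. Self-hits are kept by the
readers (and flagged), ignored by clustering.

**Stage 1 — sequence.** Edges are retained at identity ≥ `min_identity`
(default 0.2) with coverage ≥ `min_cov` (default 0.7) on *both* query and
target. Clustering is greedy set cover: candidate representatives are
ordered by retained-edge degree (ties: longer protein, then lexicographic
ID); each claims its unclaimed neighbours. Proteins without retained edges
become singletons. The defaults are the field-standard permissive identity
floor below which sequence similarity stops being reliable, with a coverage
requirement that prevents domain-level hits from chaining unrelated
multi-domain proteins.

**Stage 2 — structure.** The same greedy procedure runs on the
representatives only, with TM-score ≥ `min_tm` (default 0.4; above the
~0.3–0.4 random-fold regime) and the same coverage rule. Every protein
inherits its representative's structural cluster.

**Merge step.** For each cluster pair bridged by ≥ 1 structural edge, the
link fraction `link(A→B) = |{a ∈ A : adj(a) ∩ B ≠ ∅}| / |A|` is computed
in both directions **on the original clusters**. A pair is eligible when
either direction is *strictly greater than* `merge_threshold` (default
0.65, "over 65% of proteins in one cluster"). Eligible pairs are closed
transitively with union-find, so the final count never increases and does
not depend on evaluation order. The merged representative comes from the
largest constituent (ties: lexicographically smallest representative).
An optional iterated mode re-evaluates on merged clusters to a fixpoint;
the default is the single-pass original-cluster semantics.

**Comparison.** Partitions are scored with normalized mutual information,
arithmetic normalization, restricted to the shared universe
(`sklearn.metrics.normalized_mutual_info_score`).

## 2. Taxonomic annotation

Eight ranks, shallow to deep: superkingdom, phylum, class, order, family,
subfamily, genus, species. The **LCA level** of a cluster is the deepest
rank at which all member genomes carry one identical non-absent taxon;
absent ranks (e.g. subfamily outside the one family where it is annotated)
never qualify; if even the superkingdom differs the sentinel `none` is
returned. A cluster is a **genus ORFan** when its LCA rank is genus or
species and the genus is the focal one. **Paralog bins** for the focal
genome: 0, 1, 2–5, 6–10, 11–20, 21+. **Shape class** is `mixed` as soon as
one member genome has a non-icosahedral virion (monotone under cluster
growth), `icosahedral_only` when at least one shape is known and all known
shapes are icosahedral, else `unknown`.

## 3. IP-MS differential enrichment

**Filtering.** Contaminants out; a protein is kept iff quantified in
≥ `min_reps` (default 3) replicates of *at least one* condition (a stricter
both-conditions mode exists). Pre-imputation per-condition replicate counts
are retained for the invalidation rule.

**Normalization (`median_mad`).** Log2, per-sample median centering, then
equalization of the per-sample MADs to their *across-sample median*. This
is deliberately scale-preserving: scaling every sample to unit MAD (as a
literal z-score/MAD normalization would) rescales log2 fold changes by the
typical sample MAD (~2.5 on realistic data) and silently redefines the
"log2FC ≥ 1" selection threshold in MAD units. Equalizing to the median MAD
removes between-sample spread differences while keeping fold changes in
log2 units — the behaviour of standard proteomics pipelines.

**Imputation.** Two regimes per protein and condition:
*partially observed* → least-squares regression against the
`slsa_neighbors` (default 10) most-correlated fully observed proteins
(fallback: observed mean); *condition-wide absent* → the deterministic
2.5th percentile of each sample's observed values (absence from a whole
condition is treated as censoring at the detection limit).

**Moderated t-test.** Per-protein pooled variance s² with
d = n_b + n_c − 2 residual df. The prior (d₀, s₀²) is fitted by method of
moments on z = log s²: with e = z − ψ(d/2) + log(d/2),
`d₀ = 2·ψ₁⁻¹(var(e) − ψ₁(d/2))` and
`s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2))`, where ψ, ψ₁ are di/trigamma
and ψ₁⁻¹ is inverted by Newton iteration. Degenerate spread (var(e) ≤
expected sampling variance) gives "infinite" shrinkage (d₀ capped at 10⁶,
s₀² = mean of the floored variances); sample variances are floored at
10⁻⁵ × median to guard exact zeros. Posterior
`s²_post = (d₀s₀² + d·s²)/(d₀ + d)`; two-sided p from t with
`min(d₀ + d, n_proteins·d)` df (the total-df cap of the published
empirical-Bayes procedure). The test suite verifies agreement with R
`limma::eBayes` to ~10⁻¹⁴ on a frozen fixture and against an independent
in-test re-derivation (root-finding instead of Newton) on random data.

**Selection.** log2FC ≥ 1 and raw p < 0.01 (strict). A selected protein
with < 3 pre-imputation quantified replicates in its more abundant
condition is invalidated: deselected and its p reset to 1.
Benjamini–Hochberg adjusted p-values are attached for audit only — the
selection rule itself uses raw p, matching the source procedure.

**Networks.** Bait pair weight `Nc + 10·Ndc`, where Nc = shared selected
interactors and Ndc ∈ {0, 1, 2} counts direct bait-in-bait detections; the
×10 premium encodes that a direct detection is far stronger evidence than
one shared prey. Communities via seeded Louvain modularity maximization
(`networkx.community.louvain_communities`; same Blondel et al. algorithm
as the classical `python-louvain` implementation). The global bait → prey
network carries node annotations with region precedence
membrane > nucleoid > viral-factory/inclusion > virion; host preys are
labelled `host`; unannotated viral preys `virion_unassigned`.

## 4. Annotation layers

*Consensus TMD:* positive iff ≥ k of the configured predictors agree
(default 2 of 3 — one predictor's false positives are uncorrelated with
the others'). *Enrichment:* Fisher's exact test (sample odds ratio ad/bc;
inf when bc = 0 with ad > 0, NaN when both products vanish), one-sided
"greater" for term enrichment, Bonferroni-corrected over tested terms,
significance at corrected p < 0.01. *Nucleoid filter:* ≥ 2 peptides AND
(nucleoid-exclusive OR ≥ 2-fold nucleoid/virion ratio) in the pellet or
supernatant comparison. *Label transfer:* reciprocal best hits, ranked by
(e-value, score, target ID) for a deterministic one-to-one matching.

## 5. Complexes

Complex hits are ranked by homologous-chain count and greedily grouped
when the cosine of their homolog sets, `|a∩b| / √(|a||b|)`, reaches 0.8 —
high enough that only near-identical depositions collapse. Interface
edges connect homolog-labelled chains with minimum inter-chain point
distance strictly below 8 Å (the standard heavy-atom contact shell);
distances use a direct pairwise scan up to 5000 points and a k-d tree
beyond (bit-identical minima, verified in tests).

## 6. Synthetic data

Generators are pure functions of (parameters, seed). Defaults were fixed
before any evaluation:

| parameter | default | rationale |
| --- | --- | --- |
| log2 baseline | U(20, 30) | typical LFQ intensity range |
| replicate CV | 0.2 → sd = log2(1.2) | label-free replicate noise |
| spike effect | +2 log2 (4-fold) | clear but not trivial enrichment |
| MCAR rate | 0.02 | sporadic missingness |
| MNAR threshold | 20.5 (log2) | censors the low-abundance tail |
| design | 3 vs 3 | the standard triplicate design |

Orthogroups are emitted as similarity cliques above the clustering
thresholds (plus self-hits, so edge files are self-contained even for
singleton groups); planted *splits* realize the merge scenario — two
sequence cliques whose representatives share no structural edge but whose
members cross-link with fraction > 0.65. Complex geometries place chains
on a circle (50 Å spacing) and insert interface points so designated
contact pairs land in the (4, 8) Å window while all others stay > 10 Å;
feasibility is verified post hoc and violations raise.

**What is emulated:** threshold-relative similarity structure, paralogy,
tree-consistent partially annotated taxonomies, intensity-dependent
missingness, heteroscedastic replicate noise. **What is not:** realistic
score distributions near the thresholds, correlated protein abundances
(except in the imputation test fixtures), shared-peptide quantification
ambiguity, homology-graph topology of real proteomes, and crystallographic
packing artifacts.

## 7. Problem sizes and limitations

Default validation sizes are the package's own choices: 10,000-protein
null and 1000-protein spike-in matrices run in seconds; merge oracles are
checked up to 200 proteins; Fisher p-values against full enumeration for
table totals ≤ 40. The pairwise merge evaluation is O(C²) over bridged
cluster pairs and the SLSA-style imputer is O(proteins × complete rows)
per missing row — both fine at proteome scale (10⁴–10⁵ proteins), not
tuned for metagenome-scale inputs. Louvain is a heuristic: community
assignments are seed-stable but not guaranteed modularity-optimal (the
test suite verifies optimality exhaustively on the six-bait worked
example). The LCA logic assumes a tree-consistent taxonomy; a validator
reports violations but does not repair them.
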