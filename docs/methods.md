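# Methods

## Pipeline overview

The package operates on lineage-annotated count tables (taxa × samples) with
per-sample metadata (study id, condition). Counts are aggregated to a
taxonomic rank (phylum / class / family) by summing rows that share the rank
label, then converted to per-sample relative abundance. All downstream
statistics — diversity, fold changes, the co-abundance network — run on
these proportions. Relative abundance was chosen as the working scale
because multi-study tables have widely varying sequencing depth (the
generator emulates per-sample depths from roughly 7,000 to 100,000 reads);
raw counts from such tables are not comparable across samples. Rarefying to
a common depth before analysis is deliberately *not* done by default; the
prevalence filter below handles the degenerate vectors that motivate it.

Matrix orientation is taxa-in-rows, samples-in-columns everywhere.

## Taxonomy handling

Lineages are parsed from prefix (`k__...;p__...`), positional (SILVA-style)
or split-column annotations. Any missing or empty rank becomes the sentinel
`unclassified`. At aggregation, taxa are identified purely by their label at
the target rank (case-sensitive after trimming); no synonym resolution is
attempted, because none is defensible without a reference database. When
the same rank label occurs under several upper lineages, the aggregated
taxon keeps the lexicographically smallest upper lineage — an arbitrary but
deterministic rule that only affects annotation, never counts. The
`unclassified` pool is retained by aggregation (totals are conserved
exactly) but excluded from network nodes by default, since a pooled
pseudo-family has no biological identity to correlate.

## Diversity

Richness is the count of taxa with positive counts. Shannon diversity is
H = −Σ p_i ln p_i over positive entries, in nats by default (a `base`
argument gives bits or any other base); the bound H ≤ ln(richness), with
equality at uniform composition, is enforced by property tests. Rarefaction
uses the analytic hypergeometric expectation

    E[S_d] = S − Σ_i C(N − N_i, d) / C(N, d),

evaluated with log-gamma functions so counts in the 10^5 range do not
overflow; resampling is used only as a Monte-Carlo oracle in tests. The
curve is provably nondecreasing and concave in depth, which the tests check
on fuzzed inputs.

## Differential abundance

Per-condition central tendency is the arithmetic mean of relative
abundances (median available via `central="median"`). The fold change adds
a pseudocount ε = 1e−6 (on the proportion scale) to both means so that taxa
absent from one condition get a large but finite fold rather than a division
by zero; with both means well above ε the fold converges to the plain ratio.
The direction classification uses a strict threshold, fold > 1.5 by default:
a fold of exactly 1.5 is "unchanged". No P-values or multiple-testing
correction are attached to fold changes — the classification is a
descriptive screen, not an inference, and should be read as such.

The "most abundant families" set used for subnetwork extraction is the
top k = 15 families by condition mean, ties broken lexicographically. k is
a screening size, not an estimate; results should be checked for
sensitivity to it.

## Co-abundance network

Eligible nodes are families present (> 0) in at least `min_prevalence`
samples (default 10) with a named phylum. The prevalence floor exists
because near-constant vectors produce unstable correlations and, in the
limit, zero variance (a constant family is flagged untestable and can never
form an edge). Pearson r is computed on pooled proportions across all
samples and studies; pooling mirrors the practice of building one global
network from heterogeneous public studies, and a stratified option
(unweighted mean of per-study correlation matrices) is provided for users
who want to damp study-level confounding. The P-value is the two-sided
t-transform with n−2 degrees of freedom — the standard exact test under
bivariate normality. Both edge thresholds are strict inequalities
(r > 0.3, P < 1e−10). Edges are stored once with lexicographically ordered
endpoints, and all outputs are deterministically ordered.

The intra-phylum edge fraction is compared with a uniform G(n, m) random
graph: same node set, same edge count, edges placed uniformly without
replacement. Its expectation Σ_p C(n_p, 2)/C(N, 2) follows from each node
pair being equally likely to be chosen; the Monte-Carlo null draws edge
sets from the same distribution with a seeded generator. Degree-preserving
rewiring was considered and not made the default: with the modest node
counts involved, the uniform null is transparent, analytic and sufficient
to expose phylum assortativity, but the simplification should be kept in
mind when degree distributions are very skewed.

The condition subnetwork keeps an edge iff (at least one endpoint is in the
union of the two conditions' most-abundant family sets) AND (at least one
endpoint changed more than 1.5-fold in either direction between disease and
healthy). Node annotations (direction class for colouring, healthy-state
mean abundance for sizing) never alter topology, and subnetwork edges are
always a subset of the global network's edges. The differential records are
expected with the disease as condition a and healthy as condition b.

## Synthetic cohort generator

The generator produces the statistical structure the analysis is designed
to detect, with known ground truth:

* **Phylum blocks.** Each sample draws one latent standard-normal factor per
  phylum; family log abundance mixes that factor with idiosyncratic noise,
  `√ρ·factor + √(1−ρ)·noise`, so within-phylum pairs share latent
  correlation ρ (`block_rho`, default 0.8) and between-phylum pairs share
  none (a `between_rho` knob adds a global factor when wanted).
* **Scale.** Family log abundances are `base_logmean + log(condition fold) +
  σ·latent`. Defaults: base log-means on an even grid from +1 to −1 (about a
  7-fold abundance spread) and dispersion σ = 0.35. σ was calibrated once,
  before any acceptance run, to the generator's own marginal contract: after
  exponentiation and closure to proportions, the Jensen gap biases mean
  proportions away from softmax(base_logmeans), and σ = 0.35 keeps that bias
  within the documented 5% relative band at the default 20-family layout
  while leaving block correlations strong enough that planted edges are
  recovered essentially perfectly at n = 1000.
* **Counts.** Proportions are sampled multinomially at a per-sample depth
  uniform in (6,936, 100,972) — the read-depth range typical of 16S runs —
  which forces every consumer through normalisation. An optional ASV mode
  splits each family into 1–30 ASVs with Dirichlet weights, for testing
  rank aggregation.
* **IBD preset.** `generate_ibd_cohort` builds a CD/UC/healthy cohort over
  20 named families in the four dominant gut phyla (8 Firmicutes,
  4 Bacteroidetes, 4 Proteobacteria, 4 Actinobacteria), planting a 2.4-fold
  Bacteroidaceae decrease and a 3.8-fold Enterobacteriaceae increase in CD
  and a 3.4-fold Enterobacteriaceae decrease in UC — the canonical
  magnitudes of IBD phylum-level imbalance. Samples are spread over three
  synthetic studies with conditions interleaved.

Every dataset ships with its `GroundTruth` (planted within-phylum pairs and
per-condition direction classes), written as TSVs next to the data, so tests
and the acceptance script compare against the plant rather than re-deriving
it. Generation is bit-reproducible from the seed (fixed draw order on
numpy's PCG64).

**What the generator does not emulate:** compositional zero inflation,
phylogenetic signal below family rank, batch effects between studies,
overdispersion beyond log-normal × multinomial, or ecological dynamics.
Passing tests therefore demonstrate that the pipeline's statistics are
implemented correctly and are well calibrated under the stated model — not
that the thresholds are optimal for any particular real dataset. One
consequence worth knowing: planted fold effects on one family shift every
other family's proportions slightly (closure), so observed folds deviate
from planted folds by a few percent, and with large planted effects the
"unchanged" families drift toward the 1.5 threshold. At the preset's effect
sizes this drift is ~5–10%, far from the threshold.

## Problem sizes and numerical choices

The test-suite and acceptance runs use n = 500–1,000 samples for network
calibration (100 independent replicates for the false-positive check),
n = 200 per condition for fold recovery, and 10,000 Monte-Carlo replicates
for the small-graph null — sizes at which every stated property has
comfortable statistical margin while the whole suite runs in seconds.
Correlation matrices are computed vectorised (`numpy.corrcoef`) and checked
edge-by-edge against the scalar implementation; P-values below ~1e−300
underflow to 0.0, which only ever makes strict thresholds easier to apply
consistently. The intra-phylum fraction is undefined (an error, not NaN) on
an empty edge set.

## Known limitations

Pearson correlation on closed (compositional) data is biased — the
well-known motivation for SparCC / SPIEC-EASI style estimators — and this
package intentionally implements the plain thresholded-Pearson design it
models, not a compositionality-corrected one. The extremely stringent
P < 1e−10 cut partially masks the issue at moderate family counts (the
closure-induced correlations on the synthetic null never approach the
threshold), but users applying the network to small sample sizes or very
uneven compositions should treat negative and weak positive edges with
caution. Fold-change classification carries no uncertainty statement, and
the top-k abundant-family rule is a screen whose k is a convention.
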