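# Methods

This note documents the models and procedures implemented in panevo, the
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical conventions that matter for
reproducing results.

## Pangenome structure and Heaps' law

**Partition.** Prevalence of a COG is the exact ratio (genome count
carrying it) / (total genomes), computed in integer arithmetic before
division. Class boundaries follow the usual convention for this kind of
study: core ≥ 99%, soft-core ≥ 95%, shell ≥ 15%, cloud < 15%; a COG
sitting exactly on a boundary belongs to the upper class (exactly 15%
is shell). All four thresholds are arguments of
`partition_pangenome`.

**Accumulation curves.** `accumulation_curves` adds genomes in random
order and records, per step, the cumulative number of distinct COGs and
the number of novel COGs; means and standard deviations are taken across
permutations (default 1,000). The mean pangenome-size increments equal the
mean new-gene counts by construction (both derive from the same cumulative
union), which the tests assert to 1e-9.

**Heaps fit.** The openness statistic is the decay exponent of the
new-gene law *n*(N) = κ·N^(−α) (the Tettelin convention), estimated by OLS
of log *n*(N) on log N. The first point is excluded by default
(`skip_first=1`): the first genome contributes its entire gene complement,
which is not a discovery-law observation. Points with *n*(N) = 0 are
excluded (log undefined); fewer than 3 usable points is an error rather
than a degenerate fit. Verdict: closed iff α > 1. Note the verdict is a
step function of α: for a pangenome whose true exponent is exactly 1 the
verdict is inherently unstable under resampling, and only the exponent
estimate is meaningful there.

**Species-exclusive soft-core COGs.** `find_species_specific_cogs` returns
COGs at prevalence ≥ `soft_min` (default 0.95) in the focal species and
≤ `other_max` (default 0, i.e. complete absence) in *every* other species
of a cross-species matrix.

## Synthetic pangenome generator

The generator must control the *permutation-averaged* discovery curve,
because that is the curve the analysis fits. Genome order is therefore
made exchangeable: each accessory COG draws a prevalence count *m* from a
gene-frequency spectrum and is placed in a uniformly random subset of *m*
genomes. For a COG present in *m* of *G* genomes, the probability that it
is first discovered at position *k* of a random ordering is the
hypergeometric survival difference
C(G−m, k−1)/C(G, k−1) − C(G−m, k)/C(G, k). The spectrum is obtained by
nonnegative least squares against the target curve κ·N^(−α) on N = 2..G,
scaled so the expected number of accessory COGs fills the requested pool
(with a 5-sigma Poisson margin; an over-draw beyond the pool is an error
suggesting a larger pool). Per-spectrum-entry counts are Poisson so the
expectation is exact. This controls E[new genes at N] ∝ N^(−α) directly —
at G = 200 the fitted α typically lands within 0.01–0.05 of the target —
whereas schemes that control the curve in construction order do not
survive the permutation averaging. `cloud_fraction`, when given, reweights
the spectrum mass below the 15% prevalence line; the discovery curve is
then only approximately a power law, so the default leaves it to the
spectrum.

## Genome clustering, PCoA and gene influence

Distances: 1 − gANI (percent-scale identity matrices are normalised to
fractions first; asymmetry beyond 1e-6 is an error) or binary Jaccard on
gene sets (both-empty pairs get distance 0). Distances are fed to
group-average (UPGMA) linkage **as-is**, with no re-standardisation — in a
monospecific collection the identity differences are small and
normalisation would amplify noise. The within-cluster sum of squares for
each candidate k is the sum of squared distances to each cluster's medoid
(the member minimising that sum), since only distances, not coordinates,
are guaranteed to exist. The elbow is the k maximising the perpendicular
distance from (k, WCSS_k) to the chord joining the first and last curve
points, ties toward smaller k (an exactly linear curve yields k = 2).

PCoA is classical scaling: double-centre −½·d², eigendecompose, scale
eigenvectors by sqrt(eigenvalue). Negative eigenvalues (non-Euclidean
distances) are dropped from the variance-explained denominator and logged;
if fewer positive eigenvalues than requested axes exist, fewer axes are
returned with a warning. Three axes are examined by default.

**Gene influence.** For each gene with variation and each retained axis,
the observed statistic is the difference between the mean axis coordinate
of carrier and non-carrier genomes. The null redistributes the gene's
presence labels uniformly (independent draws per gene, default 1,000;
fewer than 100 is refused as unstable); z = (obs − null mean)/null SD and
the two-sided p comes from the standard-normal tail of z. This
empirical-normal convention gives finer resolution than the discrete
permutation p at moderate permutation counts and is well calibrated in
the package's null tests (Kolmogorov–Smirnov distance ≈ 0.01 at 3,000
null tests). BH correction runs across all gene × axis tests; a gene is
additionally flagged if significant on any axis. The per-axis definition
(rather than an aggregate across axes) is this package's choice, recorded
in output metadata.

**Enrichment.** Cluster-versus-category association uses one-vs-rest 2×2
Fisher exact tests for every (cluster, category) pair, BH over all pairs,
and the dual threshold p < 1e−5 AND FDR < 0.05. Categories covering all
items (empty complement) are excluded with a warning.

## Codon metrics and the HGT screen

All codon statistics use the sense codons of the bacterial code
(transl_table 11); stop codons and the single-codon families Met and Trp
are excluded from RSCU-derived statistics. A terminal stop codon is
stripped; CDS with internal stops or lengths not divisible by 3 are
excluded with a logged reason.

* **RSCU**: x_c · n_family / Σ_family x; unobserved families are NaN. The
  scalar thresholded by the screen, `rscu_deviation`, is the mean absolute
  difference between the gene's RSCU vector and the genome-average RSCU
  (RSCU of the pooled codon counts of all usable genes), over codons whose
  family the gene observes.
* **ENC** (Wright): F̂ = (nΣp² − 1)/(n − 1) per family with n ≥ 2 codons
  observed; families with F̂ ≤ 0 are excluded from their size-class mean;
  ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, a missing F̄₃ (Ile unobserved)
  imputed as the mean of F̄₂ and F̄₄, the result capped to [20, 61]. The
  cap makes the uniform-usage closed form exact (finite-sample F̂ falls
  slightly below its asymptote, pushing raw ENC above 61). Because F̂
  carries a finite-sample correction, ENC is only asymptotically
  length-invariant — doubling a gene moves ENC slightly toward its
  asymptote — while RSCU and CAI are exactly invariant.
* **CAI**: geometric mean over the gene's degenerate codons of
  w_c = RSCU_ref,c / max_family RSCU_ref, with reference codon counts
  given a +0.5 pseudocount. The reference set defaults to genes whose
  product label contains "ribosomal protein" (standard CAI practice); with
  fewer than 20 such genes it falls back to the 5% of genes with the
  lowest ENC (most biased ≈ most expression-adapted), and is always
  user-overridable.
* **GC**: (G+C)/length over the full CDS.

**Thresholds.** Per genome (never pooled across genomes, since a gene's
deviation is judged against the other genes of *its* genome): nearest-rank
percentiles (smallest value with cumulative fraction ≥ p) — 90th for GC,
RSCU deviation and ENC, 10th for CAI — computed from genes with all four
metrics defined; genomes with fewer than 50 such genes are skipped with a
warning. By construction each factor flags at most 10% of genes, so the
conjunction (the hcHTG call) flags at most 10% and, under independent
factors, concentrates orders of magnitude lower.

**Modes.** The default `raw_tail` mode implements the literal rule: flag
GC *above* the 90th percentile. A high-GC host acquiring genes from a
low-GC donor is invisible to that rule, so an `abs_deviation` mode
replaces GC with |gc − genome median| before taking the percentile;
fidelity first, utility as an option.

**Mobile context.** A flagged gene is `near_transposase` iff a gene on the
same contig whose product label contains a marker term (default
"transposase", case-insensitive) lies within 2,000 nt of its nearest
boundary; the gap counts nucleotides strictly between boundaries, overlap
is gap 0, and the window is boundary-inclusive (gap exactly 2,000 is
near).

## Synthetic CDS generator

Native genes draw codons from a per-family preference vector — the
preferred codon gets weight 1/n + b·(1 − 1/n), the rest share the
remainder, b the bias strength — exponentially tilted by codon G+C count
so the expected GC (uniform amino-acid usage) hits the target, solved by
scalar root finding. Alien genes use an independently drawn preference
vector and their own GC and bias. Defaults (950 native at GC 0.45 with
bias 0.6; 50 alien at GC 0.55 with bias 0.1) put the aliens in the regime
the raw-tail screen targets: higher GC, weaker codon bias (higher ENC),
different preferred codons (high RSCU deviation, low CAI). Two notes on
the defaults: aliens sit on the GC-*rich* side because the literal screen
flags the upper GC tail only; and both GC targets sit in the mid-range
because the achievable GC under codon choice alone is bounded (≈ 0.27–0.63
for uniform amino-acid usage) and an extreme tilt would itself impose
codon bias, confounding the ENC contrast between natives and aliens.
Transposase-labelled genes can be planted adjacent to alien genes or far
from all of them, to exercise the 2,000-nt window logic in both
directions.

## Wagner parsimony and event significance

`wagner_events` runs Sankoff dynamic programming with costs
c(0→1) = gain_cost (default 2), c(1→0) = loss_cost (default 1). Presence
at the root is charged one additional gain — a virtual origin from an
absent ancestor. Without this convention, loss being cheaper than gain
makes any two sister carriers pull presence to the root, systematically
inflating losses; with it, the gain penalty acts on origins as intended.
The convention can be disabled (`root_origin=False`, CLI
`--no-root-origin`); with symmetric unit costs and the convention off, the
minimum cost equals the Fitch parsimony length (cross-checked against an
independent Fitch implementation in the tests). Co-optimal reconstructions
are resolved deterministically: fewer gains first, then absence — the
secondary objective is additive, so it is threaded through the DP
lexicographically rather than applied post hoc. The reported cost always
satisfies cost = gain_cost·gains + loss_cost·losses, with the origin gain
included in `gains`. `pangenome_events` reconstructs each distinct
presence pattern once and shares the result across identical columns.

**Significance.** The null for a COG shuffles its tip states across tips;
since shuffling preserves the carrier count k, the null distribution
depends on k only and is computed once per distinct k (seeded, default
1,000 draws). Per tail, p = (1 + #{null ≥ observed})/(1 + n) — upper-tail
with add-one smoothing — and BH runs across COGs per tail. The nominal
dual threshold p < 1e−5 AND FDR < 0.05 needs ≥ 1e5 permutations to be
attainable; with fewer, the p cutoff falls back to the smallest attainable
value 1/(1 + n) with a logged warning. Stability is the fraction of
subsample rounds (default 100 rounds of 80% of tips, induced subtree) that
reproduce the full-data class. The whole procedure — permutation null,
smoothed upper-tail p, subsample stability — is this package's own
definition of event significance and is labelled as such in the report
metadata.

**Lineage classification.** Against sibling-species prevalences: a
lineage-gain candidate is a COG in the focal soft-core (prevalence ≥ 0.95,
i.e. soft-core or core) with prevalence < 0.15 in every sibling; a
lineage-loss candidate is in the focal cloud with prevalence ≥ 0.90 in at
least one sibling. When per-COG significance classes are supplied, a
candidate must also carry the matching class (or "both").

## Gain/loss history generator

Each COG evolves independently along the tree as a two-state
continuous-time Markov chain (0→1 at `gain_rate`, 1→0 at `loss_rate`, per
unit branch length) from a Bernoulli root state, simulated by explicit
exponential waiting times so every realised event is recorded per branch.
All-absent tip patterns are dropped from the returned matrix (as they
would be invisible to any real pipeline) but remain in the truth record.

## Co-occurrence network

Zeros are genuine observations and enter the Spearman ranks with average
tie handling. Partners below `min_prevalence` (default 0.05, configurable;
an analysis choice, not a literature value) in a stratum are excluded
there. p-values use the large-sample t approximation, with exact
permutation enumeration below n = 12 (strata with fewer than 20 samples
are skipped outright, so the exact branch only serves direct small-n
calls). BH families are all partners of one (focal, stratum) combination;
significance uses the dual threshold p < 1e−5 AND FDR < 0.05; each
pooled-significant pair is annotated with the strata where it is
independently significant, so both the pooled and the per-stratum readings
are available.

## Abundance generator

A latent Gaussian copula realised through a single factor: the focal taxon
and each planted partner load ±sqrt(s) on a shared factor, giving
focal–partner latent correlation exactly ±s; all other taxa are
independent of the focal. The one-factor construction keeps the implied
correlation matrix positive definite for every s < 1 — a matrix with
20 partners correlated only to the focal at s = 0.5 would not be — at the
price of planted partners sharing correlation s² among themselves, which
is documented and harmless for sign-recovery benchmarks. Marginals are
log-normal (per-taxon location N(−3, 1), scale U(0.5, 1.5)); zero
inflation is a hurdle tied to the latent scale (the lowest-quantile mass
of each taxon becomes a structural zero), so it preserves rank structure
apart from the ties at zero. Scaling to percent units uses one global
factor (per-sample sums ≤ 100, the largest sample at 100): per-sample
closure would couple every taxon's ranks through the shared denominator —
a real compositional artefact of relative-abundance data — and the
generator's null must be a true null for the network's calibration to be
testable. Consequently the generator does not emulate compositionality,
sequencing depth variation, or batch structure; passing the network tests
shows correct behaviour on rank-faithful data, not robustness to
compositional bias.

## Problem sizes and determinism

Every stochastic routine takes a seed and is bit-reproducible given
parameters + seed. The test-suite and acceptance-script problem sizes —
200 genomes × ~2,000 accessory COGs with 1,000 orderings for Heaps
recovery, 1,000 genes for the HGT screen, 500 samples × 200 taxa for the
network, 200 random trees against exhaustive enumeration, 50-seed null
batches for calibration — are chosen so each check exercises the regime
the method targets while a full run completes in minutes on one CPU.

## Known limitations

* The Heaps verdict is a point decision at α = 1; near-critical pangenomes
  need the exponent and its spread, not the verdict.
* ENC is capped to [20, 61] and uses Wright's imputation for missing
  Ile; very short genes (few countable codons) give noisy ENC and CAI.
* The gene-influence statistic assumes a binary predictor; it does not
  model linked genes (co-occurring genes share influence credit).
* The event-significance null permutes tips freely and therefore ignores
  phylogenetic autocorrelation of presence patterns; its p-values are
  calibrated against that null, not against a birth–death model.
* The abundance generator is rank-faithful by design; methods that must
  survive compositional closure should be benchmarked elsewhere.
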