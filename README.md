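# panevo

Pangenome-evolution analyses for bacterial genome collections, built for
studies of gut commensals such as *Bifidobacterium adolescentis*: how open
a species' pangenome is, how its genomes cluster, which genes were likely
acquired horizontally, where gene families were gained and lost on the
phylogeny, and which community members the species co-occurs with in
metagenomes.

The package takes the standard intermediate files of a pangenome study —
Roary-style gene presence/absence matrices, FASTA + GFF3 annotations,
square gANI identity matrices, Newick trees, and sample-by-taxon relative
abundance tables — and provides five analysis stages plus a synthetic-data
generator that can produce every input with known ground truth.

## Methods at a glance

* **Pangenome openness.** COGs (gene clusters) are partitioned by
  prevalence into core (≥ 99%), soft-core (≥ 95%), shell (≥ 15%) and cloud
  (< 15%). Gene-accumulation curves are averaged over 1,000 random genome
  orderings, and Heaps' law is fitted to the mean number of novel genes
  contributed by the *N*-th genome, *n*(N) = κ·N^(−α), by ordinary least
  squares on the log-log curve. The pangenome is called **closed** iff
  α > 1.
* **Genome clustering.** Distances are 1 − gANI or binary Jaccard on gene
  content; clustering is group-average (UPGMA) agglomeration with the
  cluster count chosen by the elbow of the intra-cluster sum-of-squares
  curve; PCoA (classical scaling) embeds the distances, and each gene's
  influence on each axis is scored by a permutation Z on the
  carrier/non-carrier centroid separation, with Benjamini–Hochberg
  correction. Cluster–metadata enrichment uses one-vs-rest Fisher exact
  tests at the dual threshold *p* < 1e−5 and FDR < 0.05.
* **HGT screen.** Per gene: GC content, RSCU deviation from the genome
  average, Wright's effective number of codons (ENC), and the codon
  adaptation index (CAI) against a highly expressed reference set. A gene
  above its genome's 90th percentile for GC, RSCU deviation and ENC and
  below the 10th for CAI — all four simultaneously — is a high-confidence
  horizontally transferred gene (hcHTG). Transposase context is annotated
  within a 2,000-nt window.
* **Gain/loss parsimony.** Per-COG Wagner parsimony on a rooted tree with
  gain cost 2 and loss cost 1; presence at the root is charged one origin
  gain. Significance comes from a tip-label permutation null plus a
  tip-subsampling stability score; lineage-specific gains and losses are
  classified against sibling-species prevalences.
* **Co-occurrence network.** Spearman correlation of focal taxa against
  all partners, pooled and per region stratum, with BH FDR per
  (focal, stratum) family and the dual significance threshold.

## Worked example

Simulate a 200-genome species with a closing pangenome (planted decay
exponent α = 1.5) and analyse it:

```bash
panevo simulate --stage pangenome --config sim.cfg --seed 42 --out-dir fixtures
panevo pangenome --matrix fixtures/matrix.Rtab --permutations 1000 --seed 43 --out-dir results
```

with `sim.cfg` containing
`n_genomes=200`, `n_core=1500`, `accessory_pool=2000`, `heaps_alpha=1.5`.
The second command prints

```
pangenome verdict: closed (alpha=1.465, kappa=680.1)
```

and writes `results/heaps.tsv`:

```
# panevo 0.1.0 seed=43 permutations=1000
kappa	alpha	r_squared	verdict
680.1438074762209	1.4649280493110268	0.9990203933592552	closed
```

The fitted decay exponent 1.465 recovers the planted 1.5 within the
sampling error of a single replicate; because α > 1 the expected number of
new genes per added genome shrinks fast enough that the pangenome size
converges — a closed pangenome. `results/partition.tsv` classifies all
3,295 COGs (here: 1,511 core, 75 soft-core, 1,144 shell, 564 cloud), and
`results/curves.tsv` holds the permutation-averaged accumulation curves
with their standard deviations.

The same pattern applies to the other stages: `panevo simulate --stage
cds|gainloss|abundance` writes fixtures with a `truth.tsv`, and
`panevo hgt|gainloss|cooccur|cluster` analyse them (or your real data in
the same formats). Every report starts with a `#` header recording the
tool version, seed and parameters.

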