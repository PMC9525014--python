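# Methods

## Overview

`sagebin` bins metagenomic contigs by combining three signals: k-mer
composition, multi-sample read depth, and the topology + read coverage of
the assembly graph. Contig-specific features are compressed by a
variational auto-encoder (VAE); a GraphSAGE-style network refines the
embeddings on the assembly graph with coverage-weighted edge sampling and
a coverage-scaled unsupervised loss; the concatenated embeddings are
clustered with iterative medoid clustering. The binning unit is the GFA
*segment* (the graph "edge" in Flye terminology): in long-read
assemblies most contigs consist of a single graph edge, so segments are
binned directly and contig P-lines are ignored.

## Input conventions

* **GFA v1.** Segments become contigs. Links become undirected edges;
  orientation fields are parsed but collapsed, self-loops are dropped,
  and duplicate links (e.g. reverse-orientation duplicates) collapse to
  one edge keeping the maximum coverage. Edge read coverage is resolved
  in order: a coverage tag on the L line itself; else the arithmetic
  mean of the endpoint segments' `dp:i:`/`dp:f:`/`KC:i:` tags (`KC`
  k-mer counts are divided by segment length); else 1.0 for every edge,
  which makes all edges equally relevant. The endpoint mean is our
  choice for the tag-only dialect — the convention mapping per-segment
  coverage onto links is not standardized — and the symmetric default.
* **Depth tables** follow the MetaBAT2/VAMB layout (`contigName`,
  `contigLen`, `totalAvgDepth`, then mean/variance column pairs, TSV or
  CSV). Variance columns are parsed but excluded from features by
  default (`include_variance` flag); their usefulness is unestablished.
* **Marker CSVs** accept `contig,marker` rows or `contig,"m1;m2"` lists
  with multiset semantics (a marker seen twice counts twice).
* Sequences are uppercased; IUPAC ambiguity codes map to N, and any
  4-mer window containing N is skipped in composition counting.
* Parsing is lenient by default (malformed or dangling lines are skipped
  with a logged warning); `strict=True` raises with the line number.

## Features

Composition: canonical 4-mer frequencies. A k-mer and its reverse
complement are identified, giving 136 classes for k=4 (120 complement
pairs + 16 palindromes); counts are normalized by the number of valid
windows and z-scored per dimension across contigs (zero-spread
dimensions stay 0). Canonical tetranucleotides are the de facto standard
for binning; composition is invariant under reverse complementation of
the input by construction.

Abundance: with S > 1 samples each contig's mean-depth vector is divided
by its own sum, keeping only the differential-abundance shape across
samples (all-zero contigs get uniform 1/S); with S = 1 the shape is
meaningless, so depths are log(1+d)-transformed and min-max scaled over
contigs. Both choices keep the block in a range comparable to the
z-scored composition, which the weighted VAE reconstruction assumes.

## VAE

Encoder and decoder are two-hidden-layer MLPs (512, 512, ReLU), latent
dimension 32 (configurable; 32 follows the convention of
composition+abundance binners). The loss is

    0.1 · MSE(composition block) + 0.9 · MSE(abundance block)
    + kl_weight · KL(N(mu, diag e^logvar) || N(0, I)),

with each MSE the mean squared error over its block and the KL the
per-contig closed form averaged over the batch. Both reconstruction
terms are Gaussian; a softmax/cross-entropy form for the abundance block
was considered and rejected for testability (the MSE forms have simple
scalar oracles). `kl_weight` defaults to `1/(latent_dim · input_dim)`:
this is the usual `1/latent_dim` weight for *sum*-reconstruction
re-expressed for mean-MSE scaling. With block-mean reconstruction a bare
`1/latent_dim` over-weights the KL by a factor of ~input_dim and
collapses the latent space (measured on the default synthetic community:
gold-label silhouette 0.06 versus 0.65, VAE-only clustering ARI 0.17
versus 0.82). The KL weight is warmed up linearly over the first 10% of
epochs. Training: Adam, lr 1e-3, batch 64, 100 epochs. The embedding is
the posterior mean, so everything downstream is deterministic given the
seed.

## Graph network

Architecture: 3 GraphSAGE layers, hidden 512, output 64, ReLU between
layers, mean aggregator over up to 10 sampled neighbors per layer,
hidden states L2-normalized after every layer as in the original
GraphSAGE algorithm. Each layer computes
`act(W · [h_self ‖ mean(h_neighbors)])`; a neighborless contig uses the
zero vector as its aggregate. Initial hidden states are the VAE
embeddings. The per-layer normalization matters: without it, the
unsupervised loss has a saddle at z = 0 that small graphs fall into
(gradients of both loss terms vanish as the embedding norms shrink), and
training stalls at the trivial loss level.

Sampling: for contig u with neighbors v_i at coverages rc_i,
P_pos(v_i|u) = rc_i/Σrc and P_neg(v_i|u) = (1/rc_i)/Σ(1/rc). A
disconnected contig has no positive and draws negatives uniformly from
all other contigs; a degree-1 contig draws negatives uniformly from
non-neighbors (its single-point inverse law is vacuous).

Loss: one coverage-sampled positive per connected contig per epoch, Q = 5
negatives per contig (disconnected contigs contribute negative-only
terms),

    J(z_u) = −rc_norm(u,v) · log σ(z_u·z_v) − Q · mean_n log σ(−z_u·z_vn),

logs clamped at 1e-9, rc_norm the edge coverage divided by the
graph-wide maximum (values in (0,1], ratios preserved; with untagged
input all rc_norm = 1 and the loss reduces to plain unsupervised
GraphSAGE). The `Q · E[…]` factor is read as Q times the Monte-Carlo
mean over the Q draws, i.e. the sum over sampled negatives.

Training-time negatives mix the inverse-coverage neighbor law with
uniform non-neighbor draws. The neighbor law is only informative where
coverage actually distinguishes a node's links — with uniform coverages
it coincides with the positive law, and sampling from it pushes true
neighbors apart (measured: trained intra-genome cosine similarity went
*negative* on clean graphs under a fixed 50/50 mix). The probability of
a neighbor draw is therefore
`(1 − random_negative_frac) · (1 − min(rc)/max(rc))` per node: zero on
uniform links, high when a low-coverage (likely spurious) link hangs off
a well-supported contig. The pure inverse-coverage law remains available
through `sample_edges` and governs wherever coverage varies.

Optimization: Adam at the tool's default lr 5e-5 for 100 epochs,
mini-batched over contigs (batch auto-scaled to graph size). For graphs
very unlike the defaults' regime the advised grid is hidden 128–512,
output 32–128, lr 1e-2–1e-5 (`run_grid`/`sagebin grid`). Early stopping
on a loss plateau (patience 2) is available but off by default: the
per-epoch loss is stochastic (edges are resampled every epoch), so a
meaningful plateau delta is dataset-specific.

Checkpoint selection: when markers (or gold labels) are provided, each
epoch's embeddings are concatenated with the VAE block, clustered, and
scored; the best checkpoint is kept, otherwise the last epoch.
The marker score ranks by (HQ-bin count, Σ completeness over HQ bins),
then by the analogous medium-quality ladder (completeness ≥ 50,
contamination < 10), then by a continuous concentration term
Σ completeness² over low-contamination bins. The tail components exist
because early in training no checkpoint has HQ bins and a two-component
score is constant — selection would degenerate to "first epoch". With
labels, checkpoints are ranked by (HQ count, F1) instead. This scoring
is a stand-in for full reference-based quality estimation, used only to
pick an epoch.

## Clustering

The VAE and GNN embeddings are each L2-normalized and concatenated
(cosine similarity on the concatenation is then the mean of the
per-block cosines, so neither block dominates by scale). Iterative
medoid clustering in cosine distance: seeds are visited in a random
order drawn once per run; from each unassigned seed the medoid moves to
the unassigned contig within the current threshold-ball whose own ball
holds the most unassigned contigs (ties to the lowest contig index), for
at most `max_steps` = 25 moves; the bin is every unassigned contig
within the threshold of the final medoid. No preset number of clusters;
singleton bins are legal; no bin-size filtering on output.

The distance threshold defaults to the valley between the intra- and
inter-cluster modes of a 20 000-pair sample of the pairwise distance
histogram (50 bins, 3-bin moving average), falling back to 0.1 when no
bimodal structure is detectable (< 20 contigs, or no second mode). The
metric, threshold rule and stopping rule are design choices of this
package; a brute-force best-medoid oracle pins the algorithm's behavior
on small instances in the test suite.

## Synthetic communities

The generator plants genomes from genome-specific third-order Markov
chains, interpolated between one shared chain and per-genome chains by
`composition_divergence` (0 = identical composition statistics, 1 =
independent). Each genome is split into contigs at random breakpoints;
consecutive contigs are linked with coverage ~ Normal(intra, 10% rsd,
truncated positive), and spurious inter-genome links are planted at
`spurious_edge_rate` × (intra edge count) with coverage ~
Normal(spurious, 10% rsd). Per-contig, per-sample depth is the genome's
abundance × Normal(1, 5% rsd); the written depth table's variance
columns are 0.2 × mean (parsed but unused by default). Each genome
carries the same universe of `markers_per_genome` single-copy markers
placed on random contigs. Output files use exactly the dialects the
readers accept (GFA v1 with `dp:f:` tags on S and L lines,
MetaBAT2-style depth table) and are byte-stable for a fixed seed.

Default condition (the `easy` profile): 5 genomes × 50 kb × 20 contigs,
divergence 0.75, 2 samples with log-uniform(5, 50) genome depths, intra
coverage 20, spurious rate 0.05 at coverage 2.

Stress profiles:

* `graph_only` — divergence 0 and a single sample with identical 30×
  depth for every genome: contig features carry no genome signal at all,
  only the graph does. This profile uses 20 genomes × 20 kb × 8 contigs.
  The genome count matters for a reason intrinsic to the loss, not to
  this implementation: negatives are (mostly) uniform random contigs, so
  a fraction ≈ 1/n_genomes of negative draws hits a same-genome contig,
  and below ~10 genomes that collision rate is high enough that the
  genome-clustered embedding has a *higher* expected loss than an
  orthogonal spread — no graph method trained on this objective could
  show added signal there. Twenty genomes of ~8 graph edges each also
  matches the shape of a many-strain long-read community far better than
  five 20-edge paths. `easy`/`hard` keep 5 × 20.
* `composition_only` — no graph edges at all (0 L lines).
* `hard` — divergence 0.2, spurious rate 0.5 at coverage 10 (close to
  the intra 20): a tangled, noisy graph over weakly separated genomes.

What the generator does *not* emulate: chimeric or misassembled contigs,
repeat-collapsed segments shared between genomes, strain-level graph
tangles, and read-level error profiles. Passing the planted-truth tests
therefore demonstrates that the pipeline exploits composition, abundance
and graph signal as designed — not that it is robust to assembler
artifacts on real data.

## Evaluation

Marker-based (checkpoint selection): per bin, completeness =
100 · distinct markers / universe, contamination = 100 · duplicated
marker observations / universe.

Label-based: bin purity = bp of the bin's majority genome / bin bp
(contamination = 1 − purity); bin completeness = bp of that genome in
the bin / the genome's total bp; averages weighted by bin bp (purity)
and by the majority genome's bp (completeness); F1 is their harmonic
mean. HQ bins: completeness > 90% and contamination < 5%, strict
inequalities at both thresholds (a bin at exactly 90/5 is not HQ). MQ
bins: completeness ≥ 50% and contamination < 10%, not already HQ,
following the community convention for medium quality.

## Determinism and numerics

A single run seed derives independent stage seeds (NumPy SeedSequence)
for the VAE, the GNN and the clustering seed order; all three models are
NumPy-only (hand-written gradients, Adam), so two runs with the same
seed produce byte-identical bins TSVs on CPU. Gradients of both networks
are verified against central finite differences in the test suite.
Degenerate inputs are defined rather than special-cased: sequences
shorter than k give zero composition vectors, all-zero depth rows give
uniform abundance, z-scoring leaves zero-spread dimensions at 0 (with an
absolute guard at 1e-12 relative to the mean against float-noise
amplification), logs in the loss are clamped at 1e-9, and empty edge
sets yield the disconnected sampling path everywhere.

## Problem sizes

The bundled study conditions are desk-scale by design: 100–160 contigs,
50–400 kb of planted sequence, graphs of ~100 edges. A full pipeline run
(feature extraction, 100 VAE epochs, 100 GNN epochs with per-epoch
checkpoint clustering, final clustering) takes roughly 10–15 s on one
CPU, and the complete acceptance recomputation about two minutes.

## Known limitations

* Contigs absent from the depth table abort the run (no imputation).
* The GFA reader targets the Flye dialect; GFA v2 and path-aware
  semantics are out of scope, as is computing depth from BAM.
* The marker-based quality is a selection heuristic, not a substitute
  for reference-based completeness/contamination estimation.
* The unsupervised objective ceases to favor genome-clustered embeddings
  when the community has very few genomes (see the `graph_only`
  discussion above) — a property of the loss itself.
* Embeddings of very large graphs (10⁵+ contigs) would need minibatched
  receptive-field forward passes; the current implementation computes
  full-graph forward passes per step, which is the right trade-off at
  the scales it targets.
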