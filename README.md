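# sagebin

Assembly-graph-aware metagenomic binning for long-read assemblies.

Metagenomic binners group assembled contigs into genome bins (MAGs) using
k-mer composition and read-depth profiles. Those signals alone routinely
split genomes or merge near-relatives. Long-read assemblers such as Flye
also emit an **assembly graph** whose links record read-supported
adjacencies between contigs, each with a read coverage `rc` — direct,
per-junction evidence that two contigs belong together. `sagebin` uses all
three signals:

1. **Contig features** — canonical tetranucleotide frequencies (136
   reverse-complement-collapsed classes, z-scored) concatenated with
   normalized multi-sample abundance from a MetaBAT2/VAMB-style depth
   table.
2. **VAE** — a variational auto-encoder compresses the features into a
   32-d latent embedding per contig, trained with a two-part
   reconstruction loss (10% composition, 90% abundance) plus a KL term.
3. **Coverage-weighted GraphSAGE** — a 3-layer graph network refines the
   embeddings on the assembly graph. Neighbors are sampled as *positives*
   with probability proportional to link coverage and as *negatives*
   proportional to its inverse, and the unsupervised loss scales the
   positive term by the normalized coverage:

   ```
   J(z_u) = -rc_norm(u,v) · log σ(z_uᵀ z_v) − Q · E_{vn∼Pn} [ log σ(−z_uᵀ z_vn) ]
   ```

   so weak (likely spurious) links barely pull embeddings together,
   while well-supported links dominate training.
4. **Iterative medoid clustering** — the L2-normalized VAE and GNN
   embeddings are concatenated and clustered in cosine distance around
   density-optimal medoid contigs, with no preset number of bins.

When a CSV of essential single-copy marker genes per contig is supplied,
the tool clusters every training checkpoint, scores it by the number of
near-complete low-contamination bins, and keeps the best epoch;
otherwise the last epoch is used.

## Worked example

```bash
python examples/bin_community.py
```

generates a 5-genome, 100-contig community (2 depth samples, high-coverage
intra-genome links, a few low-coverage spurious links), runs the full
pipeline and prints:

```
bins:                  5  (5 genomes planted)
clustering threshold:  0.706  (estimated from the distance histogram)
selected GNN epoch:    16  (marker/label checkpoint selection)
adjusted Rand index:   1.000  (1.0 = perfect recovery)
bp-weighted purity:    1.000
bp-weighted compl.:    1.000
F1:                    1.000
HQ bins (>90% compl, <5% contam): 5 of 5
```

All five planted genomes are recovered as high-quality bins (completeness
> 90%, contamination < 5%, both strict). The other scripts in `examples/`
demonstrate the community generator, the coverage-weighted sampling laws
and the two bin-evaluation views.

## Command line

```bash
sagebin synth --profile easy --outdir data --seed 3     # synthetic inputs
sagebin run --graph data/assembly_graph.gfa \
            --depth data/depth.tsv \
            --markers data/markers.csv \
            --outdir out --seed 3                        # bin contigs
sagebin grid --graph ... --depth ... --outdir out        # hyperparameter sweep
```

`run` accepts Flye-style GFA v1 (segment `dp:i:`/`dp:f:`/`KC:i:` coverage
tags; untagged graphs default every edge to coverage 1.0), FASTA,
MetaBAT2/VAMB depth tables, marker CSVs and gold-label TSVs, and writes a
two-column `bins.tsv`, per-stage loss traces, the selected checkpoint and
a metrics report.

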