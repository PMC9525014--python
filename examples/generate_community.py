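"""Generate a planted-truth synthetic metagenomic community.

Builds the 'easy' study condition (5 genomes, 100 contigs, 2 abundance
samples, clean coverage-weighted assembly graph), writes the standard
input files (FASTA, GFA, depth table, marker CSV, label TSV), and prints
a summary of what was planted.
"""

from pathlib import Path

from sagebin import generate_community, stress_profile

outdir = Path("scratch/example_community")
comm = generate_community(stress_profile("easy", seed=42), outdir=outdir)

genomes = sorted(set(comm.gold_labels.values()))
intra = sum(
    1 for e in comm.graph.edge_coverage if len({comm.gold_labels[c] for c in e}) == 1
)
spurious = len(comm.graph.edge_coverage) - intra

print(f"community written to {outdir}/")
print(f"  genomes:        {len(genomes)}")
print(f"  contigs:        {len(comm.graph.contig_ids)}")
print(f"  graph edges:    {len(comm.graph.edge_coverage)} "
      f"({intra} intra-genome, {spurious} spurious inter-genome)")
print(f"  depth samples:  {comm.config.n_samples}")
print(f"  marker universe:{comm.config.markers_per_genome} single-copy genes per genome")

# Intra-genome edges carry high read coverage, spurious ones low coverage;
# this asymmetry is what the coverage-weighted GNN sampling exploits.
covs = sorted(comm.graph.edge_coverage.values())
print(f"  edge coverage:  min {covs[0]:.1f}, max {covs[-1]:.1f}")
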