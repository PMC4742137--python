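"""Generate a small synthetic cohort and look at the ground truth.

Builds a 100 kb genome with 6 stranded, intron-containing genes, plants
SNPs and A-to-I editing sites (including two hyper-editing clusters inside
Alu-like repeats), and simulates one sample's paired DNA/RNA pileups.
"""

from editome import SimConfig, generate_genome, plant_variants, simulate_pileups

cfg = SimConfig(genome_length=100_000, n_genes=6, n_edit_sites=60,
                n_snp_het=20, n_snp_hom=8, n_hyperedit_clusters=2, seed=42)
genome = generate_genome(cfg)
truth = plant_variants(genome, cfg)
dna, rna = simulate_pileups(genome, truth, cfg, "sample1")

print(f"genome: {len(genome.seq):,} bp, {len(genome.genes)} genes, "
      f"{len(genome.repeats)} repeat intervals")
print("planted variants:", truth["kind"].value_counts().to_dict())
print("\nfirst planted edits (ref is the plus-strand base; minus-strand")
print("genes carry T>C because the edited A sits on the sense strand):")
print(truth[truth["kind"] == "EDIT"].head(5).to_string(index=False))

site = truth[truth["kind"] == "EDIT"].iloc[0]
row = rna[rna["pos"] == site["pos"]].iloc[0]
print(f"\nRNA pileup at planted edit {site['chrom']}:{site['pos']} "
      f"(edit fraction {site['edit_fraction']}):")
print(row[["ref", "A", "C", "G", "T"]].to_dict())
print("-> the alternate reads appear only in RNA; DNA at this site is "
      "pure reference.")
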