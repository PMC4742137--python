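"""Call RNA-DNA differences with the two-stage filter cascade.

Stage 1 requires 10x DNA and RNA coverage, zero non-reference DNA reads,
and >=2 alternate RNA reads at >=10% frequency; stage 2 tightens to 20x
RNA coverage and >=20% frequency. SNP positions are removed with a mask.
"""

from editome import (SimConfig, Thresholds, apply_confidence_stage,
                     call_pileups, generate_genome, mask_snps,
                     plant_variants, simulate_pileups)

cfg = SimConfig(genome_length=100_000, n_genes=6, n_edit_sites=60,
                n_snp_het=20, n_snp_hom=8, n_hyperedit_clusters=2, seed=42)
genome = generate_genome(cfg)
truth = plant_variants(genome, cfg)
dna, rna = simulate_pileups(genome, truth, cfg, "sample1")

t = Thresholds()
stage1, reasons = call_pileups(dna, rna, t)
stage2 = apply_confidence_stage(stage1, t)
mask = {(genome.chrom, int(p)) for p in truth[truth.kind != "EDIT"]["pos"]}
final, n_masked = mask_snps(stage2, mask)

print(f"stage 1 (10x/10%): {len(stage1)} calls")
print(f"stage 2 (20x/20%): {len(stage2)} calls")
print(f"after SNP mask:    {len(final)} calls ({n_masked} masked)")
print("rejection tally over all sites:", reasons)

edits = set(truth[truth.kind == "EDIT"]["pos"])
called = set(final["pos"])
print(f"\nplanted edits recovered: {len(called & edits)}/{len(edits)}; "
      f"false calls: {len(called - edits)}")
print("-> SNPs never survive the zero-DNA-variant filter; the few missed "
      "edits drew shallow or low-fraction reads.")
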