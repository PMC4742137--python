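import numpy as np
import pandas as pd
import pytest

from editome import (SimConfig, SitePileup, generate_genome,
                     generate_mirna_targets, plant_variants, simulate_pileups)
from editome import io as eio


@pytest.fixture(scope="session")
def small_cfg():
    """A compact error-free cohort: 5 genes in 80 kb, 65 planted edits."""
    return SimConfig(genome_length=80_000, n_genes=5, n_edit_sites=55,
                     n_snp_het=15, n_snp_hom=5, n_hyperedit_clusters=2,
                     sites_per_cluster=5, seed=11)


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    return generate_genome(small_cfg)


@pytest.fixture(scope="session")
def small_truth(small_cfg, small_genome):
    return plant_variants(small_genome, small_cfg)


@pytest.fixture(scope="session")
def small_pileups(small_cfg, small_genome, small_truth):
    """(dna, rna) pileup tables for one sample of the small cohort."""
    return simulate_pileups(small_genome, small_truth, small_cfg, "s1")


@pytest.fixture(scope="session")
def small_mirna(small_cfg, small_genome):
    """(mirna seqs, target table, utr map) for the small cohort."""
    return generate_mirna_targets(small_genome, small_cfg)


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory, small_cfg, small_genome, small_truth,
                     small_mirna):
    """The small cohort written to disk as the pipeline would consume it."""
    d = tmp_path_factory.mktemp("cohort")
    small_genome.write(d)
    small_truth.to_csv(d / "truth.tsv", sep="\t", index=False)
    snps = small_truth[small_truth["kind"].str.startswith("SNP")]
    snps[["chrom", "pos"]].to_csv(d / "snp_mask.tsv", sep="\t", index=False)
    mirnas, targets, utr_map = small_mirna
    eio.write_fasta(mirnas, d / "mirnas.fa")
    targets.to_csv(d / "mirna_targets.tsv", sep="\t", index=False)
    utr_map.to_csv(d / "utr_map.tsv", sep="\t", index=False)
    for sid in ("s1", "s2", "s3"):
        dna, rna = simulate_pileups(small_genome, small_truth, small_cfg, sid)
        eio.write_pileup(dna, d / f"{sid}.dna.pileup.tsv")
        eio.write_pileup(rna, d / f"{sid}.rna.pileup.tsv")
    return d


@pytest.fixture()
def toy_pileup():
    """Factory for single-site pileups."""
    def make(ref="A", dna=(30, 0, 0, 0), rna=(30, 0, 10, 0)):
        return SitePileup("chr1", 100, ref, tuple(dna), tuple(rna))

    return make


def random_pileup_tables(rng: np.random.Generator, n_sites: int = 2000,
                         chrom: str = "chr1"):
    """Paired random DNA/RNA count tables spanning the filter boundaries."""
    bases = ["A", "C", "G", "T"]
    ref = rng.choice(bases, n_sites)
    rows_d, rows_r = [], []
    for i in range(n_sites):
        d = rng.integers(0, 30, size=4)
        r = rng.integers(0, 30, size=4)
        # bias toward clean DNA so a fair share of sites pass the cascade
        if rng.random() < 0.6:
            d = np.zeros(4, dtype=int)
            d[bases.index(ref[i])] = rng.integers(0, 40)
        rows_d.append(d)
        rows_r.append(r)
    dna = pd.DataFrame(rows_d, columns=bases)
    rna = pd.DataFrame(rows_r, columns=bases)
    for df in (dna, rna):
        df.insert(0, "ref", ref)
        df.insert(0, "pos", range(1, n_sites + 1))
        df.insert(0, "chrom", chrom)
    return dna, rna
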