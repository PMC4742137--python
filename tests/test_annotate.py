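"""Feature assignment, codon consequences, cluster detection, repeat
overlap and the known-database comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest

from editome import (GeneModel, aa_consequence, assign_feature, compare_known,
                     detect_clusters, flag_hyperedited_genes, repeat_overlap,
                     summarize_features)
from editome.annotate import GeneIndex, sites_per_gene
from editome.seqs import BASES, revcomp, translate


@pytest.fixture(scope="module")
def toy_gene():
    # exon1 101-200 (UTR5 101-150, CDS 151-200), intron 201-300,
    # exon2 301-400 (CDS 301-340, UTR3 341-400)
    return GeneModel("g1", "t1", "chr1", "+",
                     exons=[(101, 200), (301, 400)],
                     cds=[(151, 200), (301, 340)],
                     utr5=[(101, 150)], utr3=[(341, 400)])


def test_feature_assignment_basics(toy_gene):
    idx = GeneIndex([toy_gene])
    assert assign_feature("chr1", 160, idx) == ("CDS", "g1")
    assert assign_feature("chr1", 250, idx) == ("INTRON", "g1")
    assert assign_feature("chr1", 120, idx) == ("UTR5", "g1")
    assert assign_feature("chr1", 350, idx) == ("UTR3", "g1")
    assert assign_feature("chr1", 5000, idx) == ("UNKNOWN", None)
    assert assign_feature("chr2", 160, idx) == ("UNKNOWN", None)


def test_precedence_across_overlapping_transcripts(toy_gene):
    # a second transcript whose exon covers 250 as non-coding sequence
    nc = GeneModel("g2", "t2", "chr1", "+", exons=[(230, 280)])
    idx = GeneIndex([toy_gene, nc])
    # EXON_NC beats the first gene's INTRON claim
    assert assign_feature("chr1", 250, idx) == ("EXON_NC", "g2")
    # CDS still wins where both overlap
    cds2 = GeneModel("g3", "t3", "chr1", "-", exons=[(155, 166)],
                     cds=[(155, 166)])
    idx = GeneIndex([toy_gene, cds2])
    assert assign_feature("chr1", 160, idx)[0] == "CDS"


def test_synthetic_truth_features_recovered(small_genome, small_truth):
    """Planted-site features must be reproduced exactly from the models."""
    idx = GeneIndex(small_genome.genes)
    for r in small_truth.itertuples():
        feature, _ = assign_feature(r.chrom, r.pos, idx)
        expected = "UNKNOWN" if r.feature_truth == "INTERGENIC" else r.feature_truth
        assert feature == expected, f"pos {r.pos}"


def test_feature_summary_percentages():
    counts = {"INTRON": 1050, "UTR3": 968, "EXON_NC": 138, "CDS": 120,
              "UNKNOWN": 1130, "UTR5": 41}
    table = summarize_features(counts)
    assert table["count"].sum() == 3447
    assert table.loc["UNKNOWN", "percent"] == 32.78
    assert abs(table["percent"].sum() - 100) <= 0.05
    single = summarize_features({"CDS": 1})
    assert single.loc["CDS", "percent"] == 100.0
    empty = summarize_features(pd.DataFrame(columns=["feature"]))
    assert (empty["count"] == 0).all()


# ---------------------------------------------------------------------------
# codon consequences

def _single_exon_gene(codon, strand="+"):
    cds = "ATG" + codon + "TAA"
    if strand == "+":
        seq = "N" * 10 + cds + "N" * 10
    else:
        seq = "N" * 10 + revcomp(cds) + "N" * 10
    gene = GeneModel("g", "t", "chrC", strand, exons=[(11, 10 + len(cds))],
                     cds=[(11, 10 + len(cds))])
    return gene, seq


def test_consequence_examples():
    gene, seq = _single_exon_gene("GAT")
    # middle codon starts at genomic 14; its 2nd base is position 15
    c = aa_consequence(15, "A", "G", gene, seq)
    assert (c.effect, c.ref_aa, c.alt_aa) == ("NONSYNONYMOUS", "D", "G")
    gene, seq = _single_exon_gene("CTA")
    c = aa_consequence(16, "A", "G", gene, seq)
    assert (c.effect, c.ref_aa, c.alt_aa) == ("SYNONYMOUS", "L", "L")


def test_consequence_exhaustive_a_to_g_oracle():
    """All 48 (codon containing A, offset) cases must match a
    translate-both-codons oracle, on both strands."""
    checked = 0
    for codon in map("".join, itertools.product(BASES, repeat=3)):
        for off in range(3):
            if codon[off] != "A":
                continue
            mutated = codon[:off] + "G" + codon[off + 1:]
            ref_aa, alt_aa = translate(codon), translate(mutated)
            if ref_aa == alt_aa:
                expected = "SYNONYMOUS"
            elif alt_aa == "*":
                expected = "STOP_GAINED"
            elif ref_aa == "*":
                expected = "STOP_LOST"
            else:
                expected = "NONSYNONYMOUS"
            for strand in "+-":
                gene, seq = _single_exon_gene(codon, strand)
                if strand == "+":
                    pos, ref, alt = 14 + off, "A", "G"
                else:
                    pos, ref, alt = 10 + len("ATG" + codon + "TAA") - (3 + off), "T", "C"
                c = aa_consequence(pos, ref, alt, gene, seq)
                assert c.effect == expected, (codon, off, strand)
                assert (c.ref_codon, c.alt_codon) == (codon, mutated)
            checked += 1
    assert checked > 16  # every A-containing codon exercised


def test_consequence_spliced_minus_strand(small_genome, small_truth):
    """Planted CDS edits on real multi-exon models translate consistently."""
    by_id = {m.gene_id: m for m in small_genome.genes}
    cds_edits = small_truth[(small_truth["kind"] == "EDIT")
                            & (small_truth["feature_truth"] == "CDS")]
    assert len(cds_edits) > 0
    for r in cds_edits.itertuples():
        c = aa_consequence(r.pos, r.ref, r.alt, by_id[r.gene_id],
                           small_genome.seq)
        assert c.effect in {"SYNONYMOUS", "NONSYNONYMOUS", "STOP_GAINED",
                            "STOP_LOST"}
        assert len(c.ref_codon) == 3 and c.ref_codon != c.alt_codon


def test_consequence_reference_mismatch_raises(toy_gene):
    seq = "A" * 500
    with pytest.raises(ValueError, match="mismatch"):
        aa_consequence(160, "C", "T", toy_gene, seq)


# ---------------------------------------------------------------------------
# clusters

def brute_force_clusters(positions, window, min_sites):
    """Mark sites in any qualifying fixed-length window, then chain marked
    sites closer than the window length."""
    pos = sorted(set(positions))
    marked = set()
    for start in {p for p in pos}:
        inside = [p for p in pos if start <= p <= start + window - 1]
        if len(inside) >= min_sites:
            marked.update(inside)
    clusters, current = [], []
    for p in pos:
        if p not in marked:
            continue
        if current and p - current[-1] > window - 1:
            clusters.append(tuple(current))
            current = []
        current.append(p)
    if current:
        clusters.append(tuple(current))
    return clusters


def test_cluster_examples():
    cl, frac = detect_clusters([("chr1", p) for p in (10, 40, 70, 100)])
    assert len(cl) == 1 and cl[0].positions == (10, 40, 70, 100)
    assert frac == 1.0
    cl, frac = detect_clusters([("chr1", p) for p in (10, 40, 70)])
    assert cl == [] and frac == 0.0


def test_cluster_detection_matches_brute_force():
    rng = np.random.default_rng(2024)
    for trial in range(4):
        # dense enough that clusters actually occur
        n = 200
        positions = sorted(rng.choice(20_000, size=n, replace=False))
        cl, frac = detect_clusters([("chr1", int(p)) for p in positions],
                                   window=100, min_sites=4)
        expected = brute_force_clusters(positions, 100, 4)
        assert [c.positions for c in cl] == expected
        n_clustered = sum(len(c) for c in expected)
        assert frac == pytest.approx(n_clustered / n)


def test_cluster_detection_order_invariant():
    rng = np.random.default_rng(77)
    positions = [int(p) for p in rng.choice(5000, size=120, replace=False)]
    a, _ = detect_clusters([("chr1", p) for p in positions])
    b, _ = detect_clusters([("chr1", p) for p in reversed(positions)])
    assert a == b


def test_cluster_members_chain_within_window():
    rng = np.random.default_rng(3)
    positions = [int(p) for p in rng.choice(8000, size=300, replace=False)]
    clusters, _ = detect_clusters([("chr1", p) for p in positions], 100, 4)
    assert clusters
    for c in clusters:
        gaps = np.diff(c.positions)
        assert (gaps <= 99).all()
        assert c.n_sites >= 4


# ---------------------------------------------------------------------------
# gene flags, repeats, known DB

def test_hyperedited_gene_boundary():
    counts = {"a": 10, "b": 9, "c": 25}
    assert flag_hyperedited_genes(counts) == {"a", "c"}
    assert flag_hyperedited_genes({}) == set()
    assert flag_hyperedited_genes(counts, threshold=26) == set()


def test_repeat_overlap_coordinate_convention():
    sites = pd.DataFrame({"chrom": ["chr1", "chr1", "chr1"],
                          "pos": [101, 100, 500]})
    flags, frac = repeat_overlap(sites, [("chr1", 100, 101, "alu")])
    assert list(flags) == [True, False, False]
    assert frac == pytest.approx(1 / 3)
    _, frac = repeat_overlap(sites, [])
    assert frac == 0.0


def test_known_db_comparison_arithmetic():
    """Worked comparison: 755 of 2,805 query sites in the database."""
    query = {("chr1", i) for i in range(2805)}
    db = {("chr1", i) for i in range(755)} | \
         {("chrX", i) for i in range(220_604 - 755)}
    res = compare_known(query, db)
    assert res["overlap"] == 755
    assert res["query_unique"] == 2050
    assert res["overlap_pct_of_query"] == 26.92
    assert res["unique_pct_of_query"] == 73.08
    assert res["overlap_pct_of_db"] == 0.34
    # percentages recompute exactly from the returned integers
    assert res["overlap_pct_of_query"] == round(
        100 * res["overlap"] / res["n_query"], 2)

    disjoint = compare_known({("chr1", 1)}, {("chr2", 2)})
    assert disjoint["overlap"] == 0 and disjoint["query_unique"] == 1


def test_sites_per_gene_counts():
    df = pd.DataFrame({"gene_id": ["a", "a", "b", None]})
    assert sites_per_gene(df) == {"a": 2, "b": 1}
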