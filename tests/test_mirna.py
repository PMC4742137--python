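"""miRNA target filtering, coordinate lift, edit intersection and seed
bookkeeping."""

import numpy as np
import pytest

from editome import (MiRNATarget, filter_targets, intersect_edits,
                     lift_inverse, lift_to_genome, seed_annotation, seed_scan,
                     summarize_mir_editing)
from editome.mirna import lift_all, targets_from_frame
from editome.seqs import revcomp


def target(**kw):
    defaults = dict(mirna_id="m1", transcript_id="t1", gene_id="g1",
                    utr_rel_start=1, utr_rel_end=22, score=180.0, energy=-25.0)
    defaults.update(kw)
    return MiRNATarget(**defaults)


@pytest.mark.parametrize("energy,score,kept", [
    (-25.0, 160.0, True),
    (-20.0, 200.0, False),   # energy boundary is strict
    (-30.0, 155.0, False),   # score boundary is strict
    (-20.01, 155.01, True),
])
def test_energy_score_filter_is_strict(energy, score, kept):
    out = filter_targets([target(energy=energy, score=score)])
    assert (len(out) == 1) is kept


def test_lift_plus_strand_offset_identity():
    t = target(utr_rel_start=1, utr_rel_end=10)
    lifted = lift_to_genome(t, {"t1": ("chr1", "+", 1000, 1999)})
    assert (lifted.genomic_start, lifted.genomic_end) == (1000, 1009)
    t2 = target(utr_rel_start=50, utr_rel_end=71)
    lifted2 = lift_to_genome(t2, {"t1": ("chr1", "+", 10_000, 11_000)})
    assert (lifted2.genomic_start, lifted2.genomic_end) == (10_049, 10_070)


def test_lift_minus_strand_counts_back_from_utr_end():
    t = target(utr_rel_start=1, utr_rel_end=10)
    lifted = lift_to_genome(t, {"t1": ("chr1", "-", 2000, 2099)})
    assert (lifted.genomic_start, lifted.genomic_end) == (2090, 2099)
    assert lifted.genomic_end - lifted.genomic_start == t.length - 1


def test_lift_minus_strand_extracts_the_right_sequence():
    """The lifted minus-strand interval, reverse-complemented, equals the
    UTR-relative slice of the transcript sequence."""
    rng = np.random.default_rng(5)
    utr_sense = "".join(rng.choice(list("ACGT"), 100))
    g_start, g_end = 2000, 2099
    chrom = "N" * (g_start - 1) + revcomp(utr_sense) + "N" * 10
    t = target(utr_rel_start=13, utr_rel_end=34)
    lifted = lift_to_genome(t, {"t1": ("chr1", "-", g_start, g_end)})
    genomic_slice = chrom[lifted.genomic_start - 1:lifted.genomic_end]
    assert revcomp(genomic_slice) == utr_sense[12:34]


def test_lift_roundtrip_both_strands():
    rng = np.random.default_rng(99)
    utr_map = {"plus": ("chr1", "+", 10_000, 12_000),
               "minus": ("chr2", "-", 50_000, 53_000)}
    for _ in range(1000):
        tx = "plus" if rng.random() < 0.5 else "minus"
        span = utr_map[tx][3] - utr_map[tx][2] + 1
        s = int(rng.integers(1, span - 30))
        e = s + int(rng.integers(0, 30))
        t = lift_to_genome(target(transcript_id=tx, utr_rel_start=s,
                                  utr_rel_end=e), utr_map)
        assert lift_inverse(t, utr_map) == (s, e)
        assert t.genomic_end - t.genomic_start == e - s


def test_lift_outside_utr_raises_and_missing_tx_is_skipped(caplog):
    with pytest.raises(ValueError, match="outside"):
        lift_to_genome(target(utr_rel_start=95, utr_rel_end=120),
                       {"t1": ("chr1", "+", 1000, 1099)})
    out = lift_all([target(transcript_id="absent")], {})
    assert out == []


def test_intersect_containment():
    t = lift_to_genome(target(utr_rel_start=101, utr_rel_end=122),
                       {"t1": ("chr1", "+", 1000, 1999)})
    # target at 1100..1121
    events = intersect_edits([t], [("chr1", 1100), ("chr1", 1121),
                                   ("chr1", 1099), ("chr2", 1100)])
    assert [(e.pos, e.offset_in_target) for e in events] == [(1100, 1), (1121, 22)]


def test_intersect_offset_in_transcript_orientation():
    t = lift_to_genome(target(utr_rel_start=1, utr_rel_end=10),
                       {"t1": ("chr1", "-", 2000, 2099)})
    # genomic 2090..2099; transcript runs 2099 -> 2090
    events = intersect_edits([t], [("chr1", 2099), ("chr1", 2090)])
    assert [(e.pos, e.offset_in_target) for e in events] == [(2099, 1), (2090, 10)]


def test_seed_scan_hand_example():
    # miRNA nt2-8 = AAGGCAU; a target site carries its reverse complement
    mirna = "C" + "AAGGCAU" + "CCCCCCCCCCCCC"
    utr = "GGGG" + "ATGCCTT" + "GGGGGGGGGGGGGGGGGGGG"
    hits = seed_scan(utr, mirna, target_len=10)
    assert len(hits) == 1
    ts, te, seed_start = hits[0]
    assert seed_start == 5 and te == 11 and ts == 2
    assert seed_scan("GGGGGGGG", mirna) == []


def test_seed_scan_full_complement():
    rng = np.random.default_rng(1)
    mirna = "".join(rng.choice(list("ACGU"), 21))
    utr = revcomp(mirna.replace("U", "T"))
    assert len(seed_scan(utr, mirna)) == 1


def test_seed_annotation_positions():
    utr_map = {"t1": ("chr1", "+", 1000, 1999)}
    seqs = {"m1": "X" * 21}
    # seed occupies UTR-relative 16..22 inside a 22-nt target at 1..22
    t = lift_to_genome(target(seed_rel_start=16), utr_map)
    events = {e.pos: e for e in intersect_edits(
        [t], [("chr1", 1000 + k) for k in range(22)])}
    # first seed base (rel 16 -> genomic 1015) pairs miRNA nt 8
    assert seed_annotation(events[1015], t, seqs).seed_position == 8
    last = seed_annotation(events[1021], t, seqs)
    assert last.seed_position == 2 and last.in_seed
    outside = seed_annotation(events[1010], t, seqs)
    assert outside.seed_position is None and not outside.in_seed
    # seed-relative index is miRNA index minus one
    assert seed_annotation(events[1015], t, seqs).seed_index == 7


def test_seed_annotation_default_assumes_three_prime_end():
    utr_map = {"t1": ("chr1", "+", 1000, 1999)}
    t = lift_to_genome(target(), utr_map)  # no seed_rel_start
    seqs = {"m1": "X" * 21}
    ev = intersect_edits([t], [("chr1", 1021)])[0]  # last target base
    assert seed_annotation(ev, t, seqs).seed_position == 2
    ev9 = intersect_edits([t], [("chr1", 1014)])[0]
    ann = seed_annotation(ev9, t, seqs)
    assert not ann.in_seed and ann.seed_position is None


def test_seed_annotation_unknown_mirna_raises():
    utr_map = {"t1": ("chr1", "+", 1000, 1999)}
    t = lift_to_genome(target(), utr_map)
    ev = intersect_edits([t], [("chr1", 1005)])[0]
    with pytest.raises(KeyError):
        seed_annotation(ev, t, {})


def test_summarize_counting_semantics():
    utr_map = {"t1": ("chr1", "+", 1000, 1999),
               "t2": ("chr1", "+", 3000, 3999)}
    t1 = lift_to_genome(target(), utr_map)
    t2 = lift_to_genome(target(mirna_id="m2", transcript_id="t2",
                               utr_rel_start=5, utr_rel_end=26), utr_map)
    events = intersect_edits([t1, t2], [("chr1", 1005), ("chr1", 3010),
                                        ("chr1", 3012)])
    s = summarize_mir_editing(events)
    assert (s["n_events"], s["n_targets"], s["n_genes"]) == (3, 2, 1)
    assert list(s["per_chromosome"]["n_events"]) == [3]
    s2 = summarize_mir_editing(events, cohort_genes={"g1", "gX"})
    assert s2["edited_target_gene_pct"] == 50.0
    empty = summarize_mir_editing([])
    assert (empty["n_events"], empty["n_targets"], empty["n_genes"]) == (0, 0, 0)


def test_planted_in_seed_edits_recovered_exactly(small_cfg, small_genome):
    """With every generated target passing the filter, intersecting A-to-G
    sites planted inside the seed matches recovers them all, in seed, and
    nothing else."""
    from editome import SimConfig, generate_mirna_targets

    cfg = SimConfig(**{**small_cfg.__dict__, "target_fail_fraction": 0.0})
    _, targets_df, utr_map_df = generate_mirna_targets(small_genome, cfg)
    utr_map = {r.transcript_id: (r.chrom, r.strand, r.utr3_genomic_start,
                                 r.utr3_genomic_end)
               for r in utr_map_df.itertuples()}
    lifted = lift_all(filter_targets(targets_from_frame(targets_df)), utr_map)
    assert len(lifted) == len(targets_df)

    planted, decoys = [], []
    for t in lifted:
        seed_off = t.seed_rel_start - t.utr_rel_start + 1
        k = 2  # second seed base pairs miRNA nt 7
        if t.strand == "+":
            pos = t.genomic_start + (seed_off + k - 1) - 1
            decoys.append((t.chrom, t.genomic_start - 1))
        else:
            pos = t.genomic_end - (seed_off + k - 1) + 1
            decoys.append((t.chrom, t.genomic_end + 1))
        planted.append((t.chrom, pos))

    events = intersect_edits(lifted, planted + decoys)
    by_key = {(t.mirna_id, t.transcript_id, t.genomic_start,
               t.genomic_end): t for t in lifted}
    mirnas, _, _ = generate_mirna_targets(small_genome, cfg)
    annotated = [seed_annotation(e, by_key[e.target_key], mirnas)
                 for e in events]
    assert {(e.chrom, e.pos) for e in annotated} == set(planted)
    assert all(e.in_seed and e.seed_position == 7 for e in annotated)
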