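"""miRNA target-site handling: score/energy filtering, UTR-to-genome
coordinate lift, intersection with A-to-G edit sites, and seed-position
bookkeeping.

Seed model: the 7-mer reverse complement of mature-miRNA nucleotides 2-8
pairs the target antiparallel, so the first base of the seed match (in
transcript orientation) pairs miRNA nt 8 and the last pairs nt 2. Targets
may carry the UTR-relative position of their seed match (seed_scan provides
it); when absent, the seed is assumed to occupy the target's 3'-most 7
bases — a simplification of a full alignment, adequate for bookkeeping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .seqs import revcomp, rna_to_dna

log = logging.getLogger(__name__)

SEED_SPAN = (2, 8)  # mature-miRNA nucleotides forming the seed


@dataclass(frozen=True)
class MiRNATarget:
    """One predicted miRNA binding site in a 3'UTR.

    UTR-relative coordinates are 1-based inclusive in transcript
    orientation; genomic coordinates are filled by :func:`lift_to_genome`.
    ``seed_rel_start`` is the UTR-relative start of the 7-mer seed match,
    if known.
    """

    mirna_id: str
    transcript_id: str
    gene_id: str
    utr_rel_start: int
    utr_rel_end: int
    score: float
    energy: float
    chrom: str | None = None
    strand: str | None = None
    genomic_start: int | None = None
    genomic_end: int | None = None
    seed_rel_start: int | None = None

    def __post_init__(self) -> None:
        if self.utr_rel_start > self.utr_rel_end:
            raise ValueError("utr_rel_start must be <= utr_rel_end")

    @property
    def length(self) -> int:
        return self.utr_rel_end - self.utr_rel_start + 1

    @property
    def key(self) -> tuple:
        return (self.mirna_id, self.transcript_id,
                self.utr_rel_start, self.utr_rel_end)


@dataclass(frozen=True)
class MirEditEvent:
    """An A-to-G edit falling inside a (lifted) miRNA target site."""

    chrom: str
    pos: int
    mirna_id: str
    transcript_id: str
    gene_id: str
    offset_in_target: int          # 1-based, transcript orientation
    target_key: tuple = ()         # (mirna, transcript, genomic interval)
    in_seed: bool = False
    seed_position: int | None = None   # 1-based index in the mature miRNA
    seed_index: int | None = None      # 1-based index within the seed (nt2 -> 1)

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, *self.target_key)


# ---------------------------------------------------------------------------

def targets_from_frame(df: pd.DataFrame) -> list[MiRNATarget]:
    seed_col = "seed_utr_start" if "seed_utr_start" in df.columns else None
    out = []
    for r in df.itertuples():
        out.append(MiRNATarget(
            r.mirna_id, r.transcript_id, getattr(r, "gene_id", ""),
            int(r.utr_start), int(r.utr_end), float(r.score), float(r.energy),
            seed_rel_start=int(getattr(r, seed_col)) if seed_col else None))
    return out


def filter_targets(targets: Iterable[MiRNATarget], max_energy: float = -20.0,
                   min_score: float = 155.0) -> list[MiRNATarget]:
    """Keep targets with energy strictly below ``max_energy`` (kcal/mol)
    and score strictly above ``min_score``; boundary values are excluded."""
    return [t for t in targets if t.energy < max_energy and t.score > min_score]


def lift_to_genome(target: MiRNATarget,
                   utr_map: Mapping[str, tuple[str, str, int, int]]
                   ) -> MiRNATarget:
    """Convert UTR-relative coordinates to genomic by offsetting from the
    transcript's 3'UTR genomic span.

    Plus strand adds the UTR start; minus strand counts back from the UTR's
    genomic end so that UTR-relative position 1 is the UTR's first
    transcribed base. Raises KeyError for transcripts absent from the map
    and ValueError if the lifted interval leaves the UTR span.
    """
    chrom, strand, g_start, g_end = utr_map[target.transcript_id]
    if strand == "+":
        gs = g_start + target.utr_rel_start - 1
        ge = g_start + target.utr_rel_end - 1
    else:
        ge = g_end - (target.utr_rel_start - 1)
        gs = g_end - (target.utr_rel_end - 1)
    if gs < g_start or ge > g_end:
        raise ValueError(
            f"{target.mirna_id}@{target.transcript_id}: lifted interval "
            f"({gs}, {ge}) outside the 3'UTR span ({g_start}, {g_end})")
    return replace(target, chrom=chrom, strand=strand,
                   genomic_start=gs, genomic_end=ge)


def lift_inverse(target: MiRNATarget,
                 utr_map: Mapping[str, tuple[str, str, int, int]]
                 ) -> tuple[int, int]:
    """Recover UTR-relative coordinates from a lifted target."""
    _, strand, g_start, g_end = utr_map[target.transcript_id]
    if strand == "+":
        return (target.genomic_start - g_start + 1,
                target.genomic_end - g_start + 1)
    return (g_end - target.genomic_end + 1, g_end - target.genomic_start + 1)


def lift_all(targets: Iterable[MiRNATarget],
             utr_map: Mapping[str, tuple[str, str, int, int]]
             ) -> list[MiRNATarget]:
    """Lift every target, skipping (with a log entry) transcripts that are
    not in the map — e.g. those without a single validated 3'UTR start."""
    out = []
    for t in targets:
        try:
            out.append(lift_to_genome(t, utr_map))
        except KeyError:
            log.warning("transcript %s not in UTR map; target %s skipped",
                        t.transcript_id, t.mirna_id)
    return out


# ---------------------------------------------------------------------------

def intersect_edits(targets: Iterable[MiRNATarget],
                    ag_sites: Iterable[tuple[str, int]]) -> list[MirEditEvent]:
    """One event per (A-to-G site, lifted target) pair with the site inside
    the target's genomic interval; the in-target offset is reported in
    transcript orientation."""
    by_chrom: dict[str, list[MiRNATarget]] = {}
    for t in targets:
        if t.genomic_start is None:
            raise ValueError(f"target {t.mirna_id}@{t.transcript_id} not lifted")
        by_chrom.setdefault(t.chrom, []).append(t)

    events = []
    for chrom, pos in ag_sites:
        for t in by_chrom.get(chrom, []):
            if t.genomic_start <= pos <= t.genomic_end:
                if t.strand == "+":
                    off = pos - t.genomic_start + 1
                else:
                    off = t.genomic_end - pos + 1
                tkey = (t.mirna_id, t.transcript_id,
                        t.genomic_start, t.genomic_end)
                events.append(MirEditEvent(chrom, pos, t.mirna_id,
                                           t.transcript_id, t.gene_id, off,
                                           target_key=tkey))
    return events


def seed_annotation(event: MirEditEvent, target: MiRNATarget,
                    mirna_seqs: Mapping[str, str]) -> MirEditEvent:
    """Mark whether the edited base pairs the miRNA seed (nt 2-8).

    The seed match's first base (transcript orientation) pairs miRNA nt 8;
    each following base pairs one nucleotide closer to the miRNA 5' end.
    Reports both the mature-miRNA index and the seed-relative index
    (seed nt 1 = miRNA nt 2). Raises KeyError if the miRNA is unknown.
    """
    if event.mirna_id not in mirna_seqs:
        raise KeyError(f"no mature sequence for {event.mirna_id}")
    if target.seed_rel_start is not None:
        seed_offset = target.seed_rel_start - target.utr_rel_start + 1
    else:
        seed_offset = target.length - 6  # assume seed = last 7 target bases
    k = event.offset_in_target - seed_offset  # 0..6 inside the seed match
    if 0 <= k <= 6:
        mirna_pos = SEED_SPAN[1] - k
        in_seed = SEED_SPAN[0] <= mirna_pos <= SEED_SPAN[1]
        return replace(event, in_seed=in_seed, seed_position=mirna_pos,
                       seed_index=mirna_pos - 1)
    return replace(event, in_seed=False, seed_position=None, seed_index=None)


def seed_scan(utr_seq: str, mature_mirna_seq: str, target_len: int = 22
              ) -> list[tuple[int, int, int]]:
    """Exact seed-match scan: every UTR position where the reverse
    complement of miRNA nt 2-8 occurs.

    Returns (utr_rel_start, utr_rel_end, seed_rel_start) triples, 1-based
    inclusive; the target interval is padded to ``target_len`` with the
    seed match at its 3' end, clipped at the UTR boundary.
    """
    utr = rna_to_dna(utr_seq)
    mir = rna_to_dna(mature_mirna_seq)
    seed = mir[SEED_SPAN[0] - 1:SEED_SPAN[1]]
    site = revcomp(seed)
    hits = []
    start = utr.find(site)
    while start != -1:
        seed_rel = start + 1
        t_end = seed_rel + 6
        t_start = max(1, t_end - target_len + 1)
        hits.append((t_start, t_end, seed_rel))
        start = utr.find(site, start + 1)
    return hits


# ---------------------------------------------------------------------------

def summarize_mir_editing(events: Sequence[MirEditEvent],
                          cohort_genes: set[str] | None = None) -> dict:
    """Totals and per-chromosome tables of miRNA-target editing.

    Events are distinct (site, target) pairs; targets are distinct
    (miRNA, transcript, interval) keys; genes are distinct gene ids. If a
    cohort gene list is supplied, the edited-target share of those genes is
    reported to 2 decimals.
    """
    ev_keys = {e.key for e in events}
    anchors = {e.target_key for e in events}
    genes = {e.gene_id for e in events}
    per_chrom = {}
    for e in events:
        d = per_chrom.setdefault(e.chrom, {"events": set(), "targets": set(),
                                           "genes": set()})
        d["events"].add(e.key)
        d["targets"].add(e.target_key)
        d["genes"].add(e.gene_id)
    per_chrom_df = pd.DataFrame(
        [[c, len(d["events"]), len(d["targets"]), len(d["genes"])]
         for c, d in sorted(per_chrom.items())],
        columns=["chrom", "n_events", "n_targets", "n_genes"])

    out = {"n_events": len(ev_keys), "n_targets": len(anchors),
           "n_genes": len(genes), "per_chromosome": per_chrom_df}
    if cohort_genes is not None:
        out["n_cohort_genes"] = len(cohort_genes)
        out["edited_target_gene_pct"] = (
            round(100 * len(genes & cohort_genes) / len(cohort_genes), 2)
            if cohort_genes else 0.0)
    return out


def events_to_frame(events: Sequence[MirEditEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [[e.chrom, e.pos, e.mirna_id, e.transcript_id, e.gene_id,
          e.offset_in_target, e.in_seed, e.seed_position, e.seed_index]
         for e in events],
        columns=["chrom", "pos", "mirna_id", "transcript_id", "gene_id",
                 "offset_in_target", "in_seed", "seed_position", "seed_index"])
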