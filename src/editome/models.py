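"""Gene-model container: stranded transcript structure with exon/CDS/UTR intervals.

Coordinates are 1-based inclusive genomic intervals on the plus strand
(BED conversion lives in :mod:`editome.io`). Interval lists are kept sorted
in genomic order regardless of transcript strand; transcript-orientation
logic (codon reconstruction, UTR-relative offsets) handles the flip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqs import revcomp

Interval = tuple[int, int]

# Feature labels used throughout annotation. EXON_NC = exonic but neither
# CDS nor UTR in any transcript (non-coding exon portion).
FEATURES = ("CDS", "UTR3", "UTR5", "EXON_NC", "INTRON", "UNKNOWN")

#: When overlapping transcripts disagree, the most consequence-specific wins.
FEATURE_PRECEDENCE = ("CDS", "UTR3", "UTR5", "EXON_NC", "INTRON")


def _check_sorted_disjoint(ivs: list[Interval], label: str) -> None:
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 <= e1:
            raise ValueError(f"{label} intervals overlap or are unsorted: "
                             f"({s1},{e1}) vs ({s2},{e2})")


def _contains(ivs: list[Interval], pos: int) -> bool:
    return any(s <= pos <= e for s, e in ivs)


@dataclass
class GeneModel:
    """One transcript of one gene, with its coding/UTR structure."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError("gene model needs at least one exon")
        for name in ("exons", "cds", "utr5", "utr3"):
            ivs = sorted(getattr(self, name))
            setattr(self, name, ivs)
            _check_sorted_disjoint(ivs, name)
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {self.cds_length} "
                "not divisible by 3")
        for name in ("cds", "utr5", "utr3"):
            for s, e in getattr(self, name):
                if not any(es <= s and e <= ee for es, ee in self.exons):
                    raise ValueError(
                        f"{self.transcript_id}: {name} interval ({s},{e}) "
                        "not contained in an exon")

    # -- geometry -----------------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def introns(self) -> list[Interval]:
        return [(e1 + 1, s2 - 1) for (_, e1), (s2, _) in
                zip(self.exons, self.exons[1:])]

    def feature_at(self, pos: int) -> str | None:
        """Feature class of a genomic position, or None if outside the gene."""
        if not (self.start <= pos <= self.end):
            return None
        if _contains(self.cds, pos):
            return "CDS"
        if _contains(self.utr3, pos):
            return "UTR3"
        if _contains(self.utr5, pos):
            return "UTR5"
        if _contains(self.exons, pos):
            return "EXON_NC"
        return "INTRON"

    # -- sequence extraction ------------------------------------------------

    def spliced_cds(self, chrom_seq: str) -> str:
        """CDS sequence in transcript orientation (ATG..stop for real genes)."""
        parts = [chrom_seq[s - 1:e] for s, e in self.cds]
        seq = "".join(parts)
        return seq if self.strand == "+" else revcomp(seq)

    def cds_offset_of(self, pos: int) -> int:
        """0-based offset of a genomic position within the spliced CDS.

        Offsets count in transcript orientation; raises if the position is
        not inside a CDS interval.
        """
        if not _contains(self.cds, pos):
            raise ValueError(f"position {pos} not in CDS of {self.transcript_id}")
        off = 0
        for s, e in self.cds:
            if s <= pos <= e:
                off += pos - s
                break
            off += e - s + 1
        if self.strand == "-":
            off = self.cds_length - 1 - off
        return off

    def utr3_span(self) -> Interval | None:
        """Genomic (start, end) of the 3'UTR if it is one contiguous block."""
        if len(self.utr3) != 1:
            return None
        return self.utr3[0]
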