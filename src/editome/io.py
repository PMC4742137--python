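"""Readers and writers for the interchange formats, with coordinate
conventions centralized here.

Conventions: site positions and GFF-style intervals are 1-based inclusive;
BED is 0-based half-open. A 1-based position ``pos`` falls in a BED interval
``(start, end)`` iff ``start < pos <= end``.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel
from .seqs import BASES

PILEUP_COLUMNS = ["chrom", "pos", "ref", "A", "C", "G", "T"]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Pileup TSV (chrom, pos, ref, A, C, G, T)

def read_pileup(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pileup {path} missing columns: {sorted(missing)}")
    return df[PILEUP_COLUMNS]


def write_pileup(df: pd.DataFrame, path: str | Path) -> None:
    df[PILEUP_COLUMNS].to_csv(path, sep="\t", index=False)


_MPILEUP_INDEL = re.compile(r"[+-](\d+)")


def read_mpileup_text(path: str | Path) -> pd.DataFrame:
    """Convenience reader for single-sample ``samtools mpileup`` text output.

    Counts A/C/G/T calls from the read-base string; '.'/',' count toward the
    reference base, read start/end markers and indel insertions are skipped.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: not an mpileup line")
            chrom, pos, ref, _depth, bases = fields[:5]
            ref = ref.upper()
            counts = dict.fromkeys(BASES, 0)
            i = 0
            while i < len(bases):
                c = bases[i]
                if c == "^":          # read start: skip mapping-quality char
                    i += 2
                    continue
                if c == "$":
                    i += 1
                    continue
                if c in "+-":         # indel: skip the inserted/deleted bases
                    m = _MPILEUP_INDEL.match(bases, i)
                    n = int(m.group(1))
                    i = m.end() + n
                    continue
                if c in ".,":
                    if ref in counts:
                        counts[ref] += 1
                elif c.upper() in counts:
                    counts[c.upper()] += 1
                i += 1
            rows.append([chrom, int(pos), ref, *[counts[b] for b in BASES]])
    return pd.DataFrame(rows, columns=PILEUP_COLUMNS)


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read BED (>=3 columns) as (chrom, start, end, name) with BED coords."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has <3 columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad BED coordinates") from exc
            name = f[3] if len(f) > 3 else f"iv{lineno}"
            out.append((f[0], start, end, name))
    return out


def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def point_in_bed(pos: int, start: int, end: int) -> bool:
    """Is 1-based position ``pos`` inside 0-based half-open (start, end)?"""
    return start < pos <= end


# ---------------------------------------------------------------------------
# BED12 gene models

def _blocks_to_intervals(chrom_start: int, sizes: list[int],
                         starts: list[int]) -> list[tuple[int, int]]:
    return [(chrom_start + st + 1, chrom_start + st + sz)
            for sz, st in zip(sizes, starts)]


def _clip(ivs, lo, hi):
    """Intersect 1-based inclusive intervals with [lo, hi]."""
    out = []
    for s, e in ivs:
        s2, e2 = max(s, lo), min(e, hi)
        if s2 <= e2:
            out.append((s2, e2))
    return out


def read_gene_models_bed12(path: str | Path) -> list[GeneModel]:
    """Parse BED12 transcript lines into :class:`GeneModel` objects.

    The name field is ``gene_id:transcript_id`` (or a bare id used for both).
    thickStart==thickEnd denotes a non-coding transcript.
    """
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 needs 12 columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name, strand = f[3], f[5]
            thick_s, thick_e = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != int(f[9]) or len(starts) != int(f[9]):
                raise ValueError(f"{path}:{lineno}: block count mismatch")
            exons = _blocks_to_intervals(start, sizes, starts)
            if exons[0][0] != start + 1 or exons[-1][1] != end:
                raise ValueError(f"{path}:{lineno}: blocks do not span record")
            gene_id, _, tx_id = name.partition(":")
            tx_id = tx_id or name
            cds = utr5 = utr3 = []
            if thick_e > thick_s:
                cds = _clip(exons, thick_s + 1, thick_e)
                left = _clip(exons, 1, thick_s)
                right = _clip(exons, thick_e + 1, end)
                utr5, utr3 = (left, right) if strand == "+" else (right, left)
            models.append(GeneModel(gene_id, tx_id, chrom, strand,
                                    exons, cds, utr5, utr3))
    return models


def write_gene_models_bed12(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            start = m.start - 1
            sizes = ",".join(str(e - s + 1) for s, e in m.exons)
            starts = ",".join(str(s - 1 - start) for s, _ in m.exons)
            if m.cds:
                thick_s, thick_e = m.cds[0][0] - 1, m.cds[-1][1]
            else:
                thick_s = thick_e = start
            fh.write("\t".join(map(str, [
                m.chrom, start, m.end, f"{m.gene_id}:{m.transcript_id}", 0,
                m.strand, thick_s, thick_e, "0,0,0", len(m.exons),
                sizes, starts])) + "\n")


# ---------------------------------------------------------------------------
# SNP masks and known-site tables

def read_snp_mask(path: str | Path) -> set[tuple[str, int]]:
    """Positions to mask, from a VCF (``.vcf``) or a chrom/pos TSV."""
    path = Path(path)
    if path.suffix in {".vcf", ".gz", ".bcf"}:
        from cyvcf2 import VCF
        return {(v.CHROM, v.POS) for v in VCF(str(path))}
    positions = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("chrom"):
                continue
            f = line.split("\t")
            if len(f) < 2:
                raise ValueError(f"{path}:{lineno}: need chrom<TAB>pos")
            try:
                positions.add((f[0], int(f[1])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad position {f[1]!r}") from exc
    return positions


def read_known_sites(path: str | Path) -> set[tuple[str, int, str]]:
    """DARNED-style table: chrom, pos, substitution ('A-to-G' or 'ref>alt')."""
    out = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("chrom"):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: need chrom, pos, substitution")
            sub = f[2]
            if ">" in sub:
                ref, alt = sub.split(">")
                sub = f"{ref}-to-{alt}"
            out.add((f[0], int(f[1]), sub))
    return out


# ---------------------------------------------------------------------------
# miRNA target tables

MIRANDA_COLUMNS = ["mirna_id", "transcript_id", "gene_id",
                   "utr_start", "utr_end", "score", "energy"]


def read_miranda(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"mirna_id", "transcript_id", "utr_start", "utr_end",
               "score", "energy"} - set(df.columns)
    if missing:
        raise ValueError(f"miRNA target table {path} missing: {sorted(missing)}")
    return df


def read_utr_map(path: str | Path) -> dict[str, tuple[str, str, int, int]]:
    """transcript -> (chrom, strand, utr3 genomic start, end), 1-based incl.

    Transcripts listed more than once (several annotated 3'UTR starts) are
    dropped entirely, keeping only those with a single validated UTR start.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "transcript_id": str})
    dup = df["transcript_id"].duplicated(keep=False)
    df = df[~dup]
    return {r.transcript_id: (r.chrom, r.strand,
                              int(r.utr3_genomic_start), int(r.utr3_genomic_end))
            for r in df.itertuples()}
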