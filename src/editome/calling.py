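"""Per-site RNA-DNA difference calling.

The caller compares paired DNA and RNA base counts at each site and keeps
sites where the RNA shows an allele the DNA lacks. The stage-1 cascade
requires 10x coverage in both sources, zero non-reference DNA reads, and at
least 2 alternate RNA reads at >= 10% frequency; the stage-2 confidence
filter tightens to 20x RNA coverage and >= 20% frequency. Thresholds compare
with >= ("at least"), and rejection reasons accumulate rather than
short-circuit so a site's full failure profile is visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqs import BASES, complement, substitution_label

STAGE1 = "STAGE1_10X"
STAGE2 = "STAGE2_20X"

REJECTION_CODES = ("LOW_DNA_DEPTH", "LOW_RNA_DEPTH", "DNA_VARIANT",
                   "LOW_ALT_READS", "LOW_ALT_FREQ")

CALL_COLUMNS = ["chrom", "pos", "ref", "alt", "substitution_plus",
                "substitution_stranded", "strand", "dna_depth", "rna_depth",
                "alt_reads", "edit_freq", "confidence_stage", "other_alt_reads"]


@dataclass(frozen=True)
class Thresholds:
    """Filter cascade knobs (defaults: the stringent 10x/20x heuristic)."""

    min_dna_depth: int = 10
    min_rna_depth: int = 10
    min_alt_reads: int = 2
    min_alt_freq: float = 0.10
    conf_min_rna_depth: int = 20
    conf_min_alt_freq: float = 0.20
    max_dna_nonref_reads: int = 0

    def __post_init__(self) -> None:
        if min(self.min_dna_depth, self.min_rna_depth, self.min_alt_reads,
               self.max_dna_nonref_reads) < 0:
            raise ValueError("thresholds must be >= 0")
        for f in (self.min_alt_freq, self.conf_min_alt_freq):
            if not 0 <= f <= 1:
                raise ValueError("frequencies must be in [0, 1]")
        if (self.conf_min_rna_depth < self.min_rna_depth
                or self.conf_min_alt_freq < self.min_alt_freq):
            raise ValueError("confidence thresholds must be >= stage-1 values")


@dataclass(frozen=True)
class SitePileup:
    """Per-site DNA and RNA base counts against a reference base."""

    chrom: str
    pos: int
    ref: str
    dna_counts: tuple[int, int, int, int]  # A, C, G, T
    rna_counts: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if self.ref not in BASES:
            raise ValueError(f"reference base must be one of ACGT, got {self.ref!r}")
        if min(self.dna_counts) < 0 or min(self.rna_counts) < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class EditCall:
    """One candidate RNA-editing site (possibly rejected)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    substitution_plus: str
    substitution_stranded: str = ""
    strand: str = "unknown"
    dna_depth: int = 0
    rna_depth: int = 0
    alt_reads: int = 0
    edit_freq: float = 0.0
    confidence_stage: str = STAGE1
    filter_reasons: frozenset[str] = frozenset()
    other_alt_reads: int = 0  # non-ref reads not on the evaluated allele

    @property
    def passed(self) -> bool:
        return not self.filter_reasons

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def call_site(site: SitePileup, t: Thresholds = Thresholds()) -> EditCall:
    """Evaluate one site against the stage-1 cascade.

    The evaluated alternate allele is the highest-count non-reference RNA
    base (ties broken alphabetically); its frequency uses the total RNA
    depth over all four bases as denominator. All failed filters are
    reported, not just the first.
    """
    ref_i = BASES.index(site.ref)
    dna_depth = sum(site.dna_counts)
    rna_depth = sum(site.rna_counts)
    dna_nonref = dna_depth - site.dna_counts[ref_i]

    nonref = [(site.rna_counts[i], b) for i, b in enumerate(BASES) if i != ref_i]
    alt_reads, alt = max(nonref, key=lambda cb: (cb[0], -ord(cb[1])))
    # max() with negated ord breaks count ties toward the alphabetically
    # first base
    freq = alt_reads / rna_depth if rna_depth else 0.0

    reasons = set()
    if dna_depth < t.min_dna_depth:
        reasons.add("LOW_DNA_DEPTH")
    if rna_depth < t.min_rna_depth:
        reasons.add("LOW_RNA_DEPTH")
    if dna_nonref > t.max_dna_nonref_reads:
        reasons.add("DNA_VARIANT")
    if alt_reads < t.min_alt_reads:
        reasons.add("LOW_ALT_READS")
    if freq < t.min_alt_freq:
        reasons.add("LOW_ALT_FREQ")

    sub = substitution_label(site.ref, alt)
    return EditCall(site.chrom, site.pos, site.ref, alt, sub, sub,
                    dna_depth=dna_depth, rna_depth=rna_depth,
                    alt_reads=alt_reads, edit_freq=freq,
                    filter_reasons=frozenset(reasons),
                    other_alt_reads=rna_depth - site.rna_counts[ref_i] - alt_reads)


# ---------------------------------------------------------------------------
# vectorized table interface

def call_pileups(dna: pd.DataFrame, rna: pd.DataFrame,
                 t: Thresholds = Thresholds()
                 ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Run the stage-1 cascade over whole pileup tables.

    DNA and RNA tables are joined on (chrom, pos); sites present in only one
    source cannot satisfy both depth filters and are dropped. Returns the
    passing calls and a tally of rejection reasons (a rejected site can
    count toward several).
    """
    m = dna.merge(rna, on=["chrom", "pos", "ref"], suffixes=("_d", "_r"))
    d = m[[f"{b}_d" for b in BASES]].to_numpy()
    r = m[[f"{b}_r" for b in BASES]].to_numpy()
    ref_i = np.searchsorted(np.array(BASES), m["ref"].to_numpy())
    rows = np.arange(len(m))

    dna_depth = d.sum(axis=1)
    rna_depth = r.sum(axis=1)
    dna_nonref = dna_depth - d[rows, ref_i]

    r_nonref = r.copy()
    r_nonref[rows, ref_i] = -1
    alt_i = r_nonref.argmax(axis=1)  # argmax takes the first max: A<C<G<T tie-break
    alt_reads = r[rows, alt_i]
    freq = np.divide(alt_reads, rna_depth, out=np.zeros(len(m)),
                     where=rna_depth > 0)

    fails = {
        "LOW_DNA_DEPTH": dna_depth < t.min_dna_depth,
        "LOW_RNA_DEPTH": rna_depth < t.min_rna_depth,
        "DNA_VARIANT": dna_nonref > t.max_dna_nonref_reads,
        "LOW_ALT_READS": alt_reads < t.min_alt_reads,
        "LOW_ALT_FREQ": freq < t.min_alt_freq,
    }
    reason_counts = {k: int(v.sum()) for k, v in fails.items()}
    ok = ~np.logical_or.reduce(list(fails.values()))

    alt = np.array(BASES)[alt_i[ok]]
    ref = m["ref"].to_numpy()[ok]
    sub = np.char.add(np.char.add(ref.astype("U1"), "-to-"), alt.astype("U1"))
    calls = pd.DataFrame({
        "chrom": m["chrom"].to_numpy()[ok], "pos": m["pos"].to_numpy()[ok],
        "ref": ref, "alt": alt, "substitution_plus": sub,
        "substitution_stranded": sub, "strand": "unknown",
        "dna_depth": dna_depth[ok], "rna_depth": rna_depth[ok],
        "alt_reads": alt_reads[ok], "edit_freq": freq[ok],
        "confidence_stage": STAGE1,
        "other_alt_reads": (rna_depth - r[rows, ref_i] - alt_reads)[ok],
    })
    return calls.reset_index(drop=True), reason_counts


def apply_confidence_stage(calls: pd.DataFrame,
                           t: Thresholds = Thresholds()) -> pd.DataFrame:
    """Stage-2 confidence filter: >=20x RNA depth and >=20% frequency."""
    keep = ((calls["rna_depth"] >= t.conf_min_rna_depth)
            & (calls["edit_freq"] >= t.conf_min_alt_freq))
    out = calls[keep].copy()
    out["confidence_stage"] = STAGE2
    return out.reset_index(drop=True)


def mask_snps(calls: pd.DataFrame,
              snp_positions: set[tuple[str, int]]) -> tuple[pd.DataFrame, int]:
    """Drop calls at known-SNP positions; returns (calls, n removed)."""
    if not snp_positions:
        return calls, 0
    masked = calls.apply(lambda r: (r["chrom"], r["pos"]) in snp_positions,
                         axis=1) if len(calls) else pd.Series([], dtype=bool)
    n_removed = int(masked.sum()) if len(calls) else 0
    return calls[~masked].reset_index(drop=True), n_removed


# ---------------------------------------------------------------------------
# strand-aware substitution typing

def classify_substitution(ref: str, alt: str, gene_strand: str) -> str:
    """Strand-corrected 'X-to-Y' type: minus-strand genes complement both
    bases (an observed T-to-C on plus is an A-to-G edit on the gene), and
    strand-unknown sites keep the plus-strand reading."""
    if gene_strand == "-":
        return substitution_label(complement(ref), complement(alt))
    return substitution_label(ref, alt)


def classify_calls(calls: pd.DataFrame, gene_models) -> pd.DataFrame:
    """Set strand and substitution_stranded from the overlapping gene.

    ``gene_models`` is an iterable of GeneModel; intergenic sites stay
    strand-unknown. Overlaps are resolved by the first covering gene
    (models are non-overlapping in this pipeline).
    """
    from intervaltree import IntervalTree
    trees: dict[str, IntervalTree] = {}
    for g in gene_models:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g.strand)

    strands, subs = [], []
    for r in calls.itertuples():
        hits = trees.get(r.chrom, IntervalTree())[r.pos]
        strand = min(iv.data for iv in hits) if hits else "unknown"
        strands.append(strand)
        subs.append(classify_substitution(r.ref, r.alt, strand))
    out = calls.copy()
    out["strand"] = strands
    out["substitution_stranded"] = subs
    return out


def call_to_row(call: EditCall) -> dict:
    return {c: getattr(call, c) for c in CALL_COLUMNS}


def calls_to_frame(calls: list[EditCall]) -> pd.DataFrame:
    return pd.DataFrame([call_to_row(c) for c in calls], columns=CALL_COLUMNS)


def write_calls_vcf(calls: pd.DataFrame, path) -> None:
    """Minimal VCF-like export of passing calls."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##INFO=<ID=DP_DNA,Number=1,Type=Integer,Description=\"DNA depth\">\n")
        fh.write("##INFO=<ID=DP_RNA,Number=1,Type=Integer,Description=\"RNA depth\">\n")
        fh.write("##INFO=<ID=ALTC,Number=1,Type=Integer,Description=\"Alt RNA reads\">\n")
        fh.write("##INFO=<ID=FREQ,Number=1,Type=Float,Description=\"Alt RNA frequency\">\n")
        fh.write("##INFO=<ID=TYPE,Number=1,Type=String,Description=\"Stranded substitution\">\n")
        fh.write("##INFO=<ID=STRAND,Number=1,Type=String,Description=\"Gene strand\">\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in calls.itertuples():
            info = (f"DP_DNA={r.dna_depth};DP_RNA={r.rna_depth};"
                    f"ALTC={r.alt_reads};FREQ={r.edit_freq:.4f};"
                    f"TYPE={r.substitution_stranded};STRAND={r.strand}")
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}\n")


__all__ = ["Thresholds", "SitePileup", "EditCall", "call_site",
           "call_pileups", "apply_confidence_stage", "mask_snps",
           "classify_substitution", "classify_calls", "calls_to_frame",
           "write_calls_vcf", "STAGE1", "STAGE2", "REJECTION_CODES",
           "CALL_COLUMNS"]
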