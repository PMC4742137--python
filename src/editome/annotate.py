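"""Genomic annotation of edited sites: feature assignment, amino-acid
consequences, A-to-G cluster detection, hyper-edited genes, repeat overlap,
and comparison against a known-editing-site database.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .models import FEATURE_PRECEDENCE, FEATURES, GeneModel
from .seqs import complement, translate


# ---------------------------------------------------------------------------
# feature assignment

class GeneIndex:
    """Interval index over gene spans for fast site -> transcript lookup."""

    def __init__(self, models: Iterable[GeneModel]):
        self.models = list(models)
        self._trees: dict[str, IntervalTree] = {}
        for m in self.models:
            self._trees.setdefault(m.chrom, IntervalTree()).addi(
                m.start, m.end + 1, m)

    def overlapping(self, chrom: str, pos: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        return [iv.data for iv in tree[pos]] if tree else []


def assign_feature(chrom: str, pos: int, index: GeneIndex,
                   precedence: Sequence[str] = FEATURE_PRECEDENCE
                   ) -> tuple[str, str | None]:
    """Classify a site as (feature, gene_id).

    Overlapping transcripts vote with their own feature class and the most
    consequence-specific one wins (default CDS > UTR3 > UTR5 > EXON_NC >
    INTRON); sites outside every gene span are UNKNOWN.
    """
    votes = []
    for m in index.overlapping(chrom, pos):
        f = m.feature_at(pos)
        if f is not None:
            votes.append((precedence.index(f), f, m.gene_id))
    if not votes:
        return "UNKNOWN", None
    _, feature, gene_id = min(votes)
    return feature, gene_id


def assign_features(calls: pd.DataFrame, models: Iterable[GeneModel],
                    precedence: Sequence[str] = FEATURE_PRECEDENCE
                    ) -> pd.DataFrame:
    index = models if isinstance(models, GeneIndex) else GeneIndex(models)
    feats, genes = [], []
    for r in calls.itertuples():
        f, g = assign_feature(r.chrom, r.pos, index, precedence)
        feats.append(f)
        genes.append(g)
    out = calls.copy()
    out["feature"] = feats
    out["gene_id"] = genes
    return out


def summarize_features(assignments) -> pd.DataFrame:
    """Counts and percentages (2 decimals) per feature class.

    Accepts either a frame with a ``feature`` column or a mapping
    feature -> count. Percentages are of the total; an empty input yields
    an all-zero summary.
    """
    if isinstance(assignments, Mapping):
        counts = dict(assignments)
    else:
        counts = assignments["feature"].value_counts().to_dict() \
            if len(assignments) else {}
    unknown = set(counts) - set(FEATURES)
    if unknown:
        raise ValueError(f"unrecognized features: {sorted(unknown)}")
    total = sum(counts.values())
    rows = [[f, counts.get(f, 0),
             round(100 * counts.get(f, 0) / total, 2) if total else 0.0]
            for f in FEATURES]
    return pd.DataFrame(rows, columns=["feature", "count", "percent"]
                        ).set_index("feature")


# ---------------------------------------------------------------------------
# amino-acid consequence

@dataclass(frozen=True)
class Consequence:
    effect: str          # SYNONYMOUS / NONSYNONYMOUS / STOP_GAINED / STOP_LOST
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    codon_number: int    # 1-based along the protein
    codon_offset: int    # 1-based position of the edit within the codon


def aa_consequence(pos: int, ref: str, alt: str, gene: GeneModel,
                   chrom_seq: str) -> Consequence:
    """Amino-acid effect of a substitution inside a CDS.

    ``ref``/``alt`` are the plus-strand observed bases; for minus-strand
    genes they are complemented into transcript orientation before the
    codon (reconstructed from the spliced CDS) is mutated and both codons
    translated with the standard code.
    """
    cds = gene.spliced_cds(chrom_seq)
    off = gene.cds_offset_of(pos)
    tref, talt = (ref, alt) if gene.strand == "+" else \
        (complement(ref), complement(alt))
    if cds[off] != tref:
        raise ValueError(
            f"reference mismatch at {gene.transcript_id} CDS offset {off}: "
            f"model has {cds[off]}, call has {tref}")
    ci, co = divmod(off, 3)
    ref_codon = cds[3 * ci:3 * ci + 3]
    alt_codon = ref_codon[:co] + talt + ref_codon[co + 1:]
    ref_aa, alt_aa = translate(ref_codon), translate(alt_codon)
    if ref_aa == alt_aa:
        effect = "SYNONYMOUS"
    elif alt_aa == "*":
        effect = "STOP_GAINED"
    elif ref_aa == "*":
        effect = "STOP_LOST"
    else:
        effect = "NONSYNONYMOUS"
    return Consequence(effect, ref_codon, alt_codon, ref_aa, alt_aa,
                       ci + 1, co + 1)


# ---------------------------------------------------------------------------
# A-to-G clusters

@dataclass(frozen=True)
class Cluster:
    chrom: str
    start: int
    end: int
    positions: tuple[int, ...]

    @property
    def n_sites(self) -> int:
        return len(self.positions)


def detect_clusters(sites: pd.DataFrame | Iterable[tuple[str, int]],
                    window: int = 100, min_sites: int = 4
                    ) -> tuple[list[Cluster], float]:
    """Find clustered sites: >= ``min_sites`` within any ``window``-bp span.

    Every maximal qualifying window marks its member sites; overlapping
    marked runs merge into one cluster, so each site belongs to at most one
    cluster (merged clusters may span more than one window). Returns the
    clusters and the fraction of input sites that are clustered.
    """
    if isinstance(sites, pd.DataFrame):
        pairs = list(zip(sites["chrom"], sites["pos"]))
    else:
        pairs = list(sites)
    by_chrom: dict[str, list[int]] = {}
    for c, p in pairs:
        by_chrom.setdefault(c, []).append(int(p))

    clusters: list[Cluster] = []
    n_clustered = 0
    for chrom in sorted(by_chrom):
        pos = sorted(set(by_chrom[chrom]))
        n = len(pos)
        marked = [False] * n
        j = 0
        for i in range(n):
            if j < i:
                j = i
            while j + 1 < n and pos[j + 1] - pos[i] <= window - 1:
                j += 1
            if j - i + 1 >= min_sites:
                for k in range(i, j + 1):
                    marked[k] = True
        i = 0
        while i < n:
            if marked[i]:
                j = i
                while j + 1 < n and marked[j + 1] and pos[j + 1] - pos[j] <= window - 1:
                    j += 1
                members = tuple(pos[i:j + 1])
                clusters.append(Cluster(chrom, members[0], members[-1], members))
                n_clustered += len(members)
                i = j + 1
            else:
                i += 1
    frac = n_clustered / len(set(pairs)) if pairs else 0.0
    return clusters, frac


# ---------------------------------------------------------------------------
# gene-level summaries

def flag_hyperedited_genes(site_counts: Mapping[str, int],
                           threshold: int = 10) -> set[str]:
    """Genes carrying ``threshold`` (default 10) or more editing sites."""
    return {g for g, n in site_counts.items() if n >= threshold}


def repeat_overlap(sites: pd.DataFrame,
                   repeats: Iterable[tuple]) -> tuple[pd.Series, float]:
    """Flag sites inside repeat intervals (BED coords); return flags and
    the overlapping fraction."""
    trees: dict[str, IntervalTree] = {}
    for rec in repeats:
        chrom, start, end = rec[0], int(rec[1]), int(rec[2])
        if end > start:
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    flags = []
    for r in sites.itertuples():
        tree = trees.get(r.chrom)
        # BED is 0-based half-open: 1-based pos p is inside iff start < p <= end
        flags.append(bool(tree and tree[r.pos - 1]))
    flags = pd.Series(flags, index=sites.index, name="in_repeat")
    frac = float(flags.mean()) if len(flags) else 0.0
    return flags, frac


def compare_known(query: set[tuple[str, int]],
                  db: set[tuple[str, int]]) -> dict[str, float]:
    """Set comparison against a known-editing-site database.

    Both sets are (chrom, pos) keys, already restricted to the substitution
    class of interest (A-to-G for a DARNED-style comparison). Percentages
    are of the query and of the database, to 2 decimals.
    """
    overlap = len(query & db)
    out = {
        "n_query": len(query),
        "n_db": len(db),
        "overlap": overlap,
        "query_unique": len(query) - overlap,
        "db_unique": len(db) - overlap,
    }
    out["overlap_pct_of_query"] = round(100 * overlap / len(query), 2) if query else 0.0
    out["unique_pct_of_query"] = round(100 * out["query_unique"] / len(query), 2) \
        if query else 0.0
    out["overlap_pct_of_db"] = round(100 * overlap / len(db), 2) if db else 0.0
    return out


def sites_per_gene(assigned: pd.DataFrame) -> dict[str, int]:
    """Editing-site counts per gene from an assign_features frame."""
    genic = assigned[assigned["gene_id"].notna()]
    return genic.groupby("gene_id").size().to_dict()
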