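"""Synthetic cohort generator: toy genome, gene models, repeats, planted
variants, and paired DNA/RNA pileups.

The generator exists so the whole calling/annotation/miRNA pipeline can be
exercised and scored against known truth without any sequencing data. It
emulates the per-site evidence the pipeline consumes:

* a random genome with non-overlapping, stranded, intron-containing genes
  (stop-free CDS, 5'/3' UTRs confined to the terminal exons);
* Alu-like repeat intervals inside 3'UTRs and introns, which host planted
  hyper-editing clusters;
* heterozygous/homozygous SNPs (present in DNA and RNA) and A-to-I editing
  sites (RNA-only, ref A on the gene's sense strand) with per-site editing
  fractions;
* per-site sequencing depth ~ Poisson and a uniform per-read-base error.

Everything is deterministic given the config seed; per-sample read streams
are derived from (seed, sample_id) so cohorts are reproducible sample by
sample.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .models import GeneModel
from .seqs import BASES, revcomp

log = logging.getLogger(__name__)

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES
                 if a + b + c not in _STOPS]

TRUTH_COLUMNS = ["chrom", "pos", "kind", "ref", "alt", "edit_fraction",
                 "in_repeat", "gene_id", "feature_truth"]


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic study.

    Defaults describe the reference cohort the test-bed is scored on:
    mean 40x DNA / 40x RNA coverage, 200 planted edits (170 dispersed plus
    6 clusters of 5) with editing fractions uniform on [0.25, 0.9], 50
    heterozygous and 20 homozygous SNPs, and error-free reads unless
    ``base_error_rate`` is raised.
    """

    genome_length: int = 200_000
    n_genes: int = 12
    mean_dna_depth: float = 40.0
    mean_rna_depth: float = 40.0
    base_error_rate: float = 0.0
    n_snp_het: int = 50
    n_snp_hom: int = 20
    n_edit_sites: int = 170
    edit_fraction_range: tuple[float, float] = (0.25, 0.9)
    n_hyperedit_clusters: int = 6
    cluster_span: int = 80
    sites_per_cluster: int = 5
    target_fail_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.genome_length, self.n_genes, self.n_snp_het,
                  self.n_snp_hom, self.n_edit_sites,
                  self.n_hyperedit_clusters, self.sites_per_cluster)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        if not 0 <= self.base_error_rate < 0.5:
            raise ValueError("base_error_rate must be in [0, 0.5)")
        lo, hi = self.edit_fraction_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("edit fractions must satisfy 0 < lo <= hi <= 1")
        if self.cluster_span <= 0:
            raise ValueError("cluster_span must be positive")


@dataclass
class Genome:
    """A generated reference with its annotation."""

    chrom: str
    seq: str
    genes: list[GeneModel]
    repeats: list[tuple[str, int, int, str]] = field(default_factory=list)  # BED coords

    def utr3_sense_seq(self, gene: GeneModel) -> str:
        s, e = gene.utr3_span()
        seq = self.seq[s - 1:e]
        return seq if gene.strand == "+" else revcomp(seq)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"fasta": outdir / "genome.fa",
                 "genes": outdir / "genes.bed12",
                 "repeats": outdir / "repeats.bed"}
        eio.write_fasta({self.chrom: self.seq}, paths["fasta"])
        eio.write_gene_models_bed12(self.genes, paths["genes"])
        eio.write_bed(self.repeats, paths["repeats"])
        return paths


# ---------------------------------------------------------------------------
# genome construction

def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n)) if n else ""


def _build_gene(rng: np.random.Generator):
    """Return (sense sequence, sense-relative structure dict)."""
    utr5_len = int(rng.integers(80, 160))
    n_codons = int(rng.integers(80, 160))
    utr3_len = int(rng.integers(500, 900))
    cds = "ATG" + "".join(rng.choice(_SENSE_CODONS, size=n_codons - 2)) + \
        str(rng.choice(("TAA", "TAG", "TGA")))
    utr5 = _random_dna(rng, utr5_len)
    utr3 = _random_dna(rng, utr3_len)

    n_introns = int(rng.integers(1, 3))
    # cut the CDS (never the UTRs) so UTRs stay inside terminal exons
    cuts = sorted(rng.choice(np.arange(10, len(cds) - 10), size=n_introns,
                             replace=False))
    cds_chunks, prev = [], 0
    for c in cuts:
        cds_chunks.append(cds[prev:c])
        prev = c
    cds_chunks.append(cds[prev:])
    introns = [_random_dna(rng, int(rng.integers(150, 400)))
               for _ in range(n_introns)]

    pieces, exon_ivs, cds_ivs = [], [], []
    cursor = 1  # 1-based within the sense gene sequence

    def emit(seq):
        nonlocal cursor
        start = cursor
        pieces.append(seq)
        cursor += len(seq)
        return (start, cursor - 1)

    # first exon: 5'UTR + first CDS chunk
    utr5_iv = emit(utr5)
    exon_start = utr5_iv[0]
    cds_ivs.append(emit(cds_chunks[0]))
    exon_ivs.append((exon_start, cds_ivs[-1][1]))
    for intron_seq, chunk in zip(introns, cds_chunks[1:-1]):
        emit(intron_seq)
        cds_ivs.append(emit(chunk))
        exon_ivs.append(cds_ivs[-1])
    # last intron, then terminal exon: last CDS chunk + 3'UTR
    emit(introns[-1])
    last_cds = emit(cds_chunks[-1])
    cds_ivs.append(last_cds)
    utr3_iv = emit(utr3)
    exon_ivs.append((last_cds[0], utr3_iv[1]))

    return "".join(pieces), {
        "exons": exon_ivs, "cds": cds_ivs,
        "utr5": [utr5_iv], "utr3": [utr3_iv],
    }


def _mirror(ivs, gene_len):
    return sorted((gene_len - e + 1, gene_len - s + 1) for s, e in ivs)


def generate_genome(config: SimConfig, chrom: str = "chr1") -> Genome:
    """Build the reference sequence, gene models and repeat intervals."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    seq = np.array(list(_random_dna(rng, config.genome_length)))

    genes, repeats = [], []
    cursor = int(rng.integers(1500, 3000))
    for i in range(config.n_genes):
        strand = "+" if i % 2 == 0 else "-"
        sense_seq, struct = _build_gene(rng)
        glen = len(sense_seq)
        if cursor + glen > config.genome_length - 1000:
            raise ValueError(
                f"genome_length {config.genome_length} too small to place "
                f"{config.n_genes} genes")
        offset = cursor - 1  # 0-based genomic offset of gene start
        plus_seq = sense_seq if strand == "+" else revcomp(sense_seq)
        seq[offset:offset + glen] = list(plus_seq)

        def lift(ivs):
            ivs = ivs if strand == "+" else _mirror(ivs, glen)
            return [(s + offset, e + offset) for s, e in ivs]

        gene = GeneModel(f"gene{i:02d}", f"tx{i:02d}", chrom, strand,
                         lift(struct["exons"]), lift(struct["cds"]),
                         lift(struct["utr5"]), lift(struct["utr3"]))
        genes.append(gene)

        # one Alu-like repeat inside the 3'UTR of every gene, plus one in
        # the first intron of every other gene
        rep_len = config.cluster_span + 60
        u3s, u3e = gene.utr3_span()
        if u3e - u3s + 1 > rep_len + 10:
            rs = int(rng.integers(u3s, u3e - rep_len))
            repeats.append((chrom, rs - 1, rs - 1 + rep_len,
                            f"ALUSIM_{len(repeats):03d}"))
        if i % 2 == 0 and gene.introns:
            ins, ine = gene.introns[0]
            if ine - ins + 1 > rep_len + 10:
                rs = int(rng.integers(ins, ine - rep_len))
                repeats.append((chrom, rs - 1, rs - 1 + rep_len,
                                f"ALUSIM_{len(repeats):03d}"))
        cursor += glen + int(rng.integers(2000, 5000))

    return Genome(chrom, "".join(seq), genes, repeats)


# ---------------------------------------------------------------------------
# variant planting

def _sense_a_positions(genome: Genome, gene: GeneModel) -> np.ndarray:
    """Genomic positions in the gene whose sense-strand base is A."""
    want = "A" if gene.strand == "+" else "T"
    sub = np.frombuffer(genome.seq[gene.start - 1:gene.end].encode(), dtype="S1")
    return np.nonzero(sub == want.encode())[0] + gene.start


def plant_variants(genome: Genome, config: SimConfig) -> pd.DataFrame:
    """Plant SNPs, dispersed edits and hyper-editing clusters; return truth.

    Edits are always A on the gene's sense strand: stored plus-strand as
    A>G for plus-strand genes and T>C for minus-strand genes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    chrom, L = genome.chrom, len(genome.seq)

    in_repeat = np.zeros(L + 1, dtype=bool)
    for _, s, e, _ in genome.repeats:
        in_repeat[s + 1:e + 1] = True

    gene_of: dict[int, GeneModel] = {}
    pool = []  # (pos, gene) eligible A-sense positions
    for g in genome.genes:
        for p in _sense_a_positions(genome, g):
            gene_of[int(p)] = g
            pool.append(int(p))
    pool = np.array(sorted(set(pool)), dtype=int)

    used: set[int] = set()
    rows = []

    def add_edit(pos: int, frac: float) -> None:
        g = gene_of[pos]
        ref, alt = ("A", "G") if g.strand == "+" else ("T", "C")
        rows.append([chrom, pos, "EDIT", ref, alt, round(float(frac), 4),
                     bool(in_repeat[pos]), g.gene_id, g.feature_at(pos)])
        used.add(pos)

    lo, hi = config.edit_fraction_range

    # hyper-editing clusters inside repeats that overlap genes
    genic_repeats = [(s + 1, e) for _, s, e, _ in genome.repeats
                     if any(g.start <= s + 1 and e <= g.end for g in genome.genes)]
    if config.n_hyperedit_clusters > len(genic_repeats):
        raise ValueError(
            f"requested {config.n_hyperedit_clusters} clusters but only "
            f"{len(genic_repeats)} genic repeats available")
    picks = rng.choice(len(genic_repeats), size=config.n_hyperedit_clusters,
                       replace=False)
    for k in picks:
        rs, re_ = genic_repeats[int(k)]
        span = min(config.cluster_span, re_ - rs + 1)
        ws = int(rng.integers(rs, re_ - span + 2))
        cand = pool[(pool >= ws) & (pool <= ws + span - 1)]
        cand = np.array([p for p in cand if p not in used])
        if len(cand) < config.sites_per_cluster:
            cand = pool[(pool >= rs) & (pool <= re_)]  # fall back to full repeat
            cand = np.array([p for p in cand if p not in used])
        if len(cand) < config.sites_per_cluster:
            raise ValueError("not enough eligible A positions for a cluster")
        for p in rng.choice(cand, size=config.sites_per_cluster, replace=False):
            add_edit(int(p), rng.uniform(lo, hi))

    # dispersed edits
    cand = np.array([p for p in pool if p not in used])
    if len(cand) < config.n_edit_sites:
        raise ValueError("not enough eligible A positions for dispersed edits")
    for p in rng.choice(cand, size=config.n_edit_sites, replace=False):
        add_edit(int(p), rng.uniform(lo, hi))

    # SNPs anywhere in the genome, away from edit sites
    n_snps = config.n_snp_het + config.n_snp_hom
    snp_pos = []
    while len(snp_pos) < n_snps:
        p = int(rng.integers(1, L + 1))
        if p not in used:
            snp_pos.append(p)
            used.add(p)
    for j, p in enumerate(snp_pos):
        kind = "SNP_HET" if j < config.n_snp_het else "SNP_HOM"
        ref = genome.seq[p - 1]
        alt = str(rng.choice([b for b in BASES if b != ref]))
        g = gene_of.get(p)
        feat = g.feature_at(p) if g else None
        if feat is None:
            g2 = next((gg for gg in genome.genes if gg.start <= p <= gg.end), None)
            feat = g2.feature_at(p) if g2 else "INTERGENIC"
            g = g2
        rows.append([chrom, p, kind, ref, alt, np.nan,
                     bool(in_repeat[p]), g.gene_id if g else "", feat])

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return truth.sort_values("pos", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# pileup simulation

def _sample_streams(config: SimConfig, sample_id: str, salt: int = 3):
    """Four independent child generators per sample: (DNA reads, DNA errors,
    RNA reads, RNA errors). Separate error streams keep depths and planted
    counts identical across error rates for the same seed."""
    tag = zlib.crc32(sample_id.encode())
    ss = np.random.SeedSequence([config.seed, salt, tag])
    return [np.random.default_rng(child) for child in ss.spawn(4)]


def _apply_errors(counts: np.ndarray, rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Mutate each read-base to a uniform different base with prob ``rate``."""
    if rate == 0:
        return counts
    out = counts.copy()
    for b in range(4):
        nerr = rng.binomial(counts[:, b], rate)
        out[:, b] -= nerr
        others = [o for o in range(4) if o != b]
        n1 = rng.binomial(nerr, 1 / 3)
        n2 = rng.binomial(nerr - n1, 1 / 2)
        out[:, others[0]] += n1
        out[:, others[1]] += n2
        out[:, others[2]] += nerr - n1 - n2
    return out


def simulate_pileups(genome: Genome, truth: pd.DataFrame, config: SimConfig,
                     sample_id: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one sample's DNA and RNA per-site base-count tables.

    DNA/RNA depths are i.i.d. Poisson per site. At SNPs the alternate allele
    is present in both sources (Binomial(depth, 0.5) for hets, all reads for
    homs); at edit sites only the RNA carries the alternate, with
    Binomial(depth, edit_fraction) reads. Uniform per-read-base errors are
    applied last. Deterministic given (config.seed, sample_id).
    """
    dna_rng, dna_err_rng, rna_rng, rna_err_rng = _sample_streams(config, sample_id)
    L = len(genome.seq)
    base_idx = {b: i for i, b in enumerate(BASES)}
    ref_idx = np.frombuffer(genome.seq.encode(), dtype="S1")
    ref_idx = np.searchsorted(np.array([b.encode() for b in BASES]), ref_idx)

    alt_idx = np.full(L, -1, dtype=int)
    kind = np.zeros(L, dtype=int)  # 0 none, 1 het, 2 hom, 3 edit
    frac = np.zeros(L)
    kmap = {"SNP_HET": 1, "SNP_HOM": 2, "EDIT": 3}
    for r in truth.itertuples():
        i = r.pos - 1
        kind[i] = kmap[r.kind]
        alt_idx[i] = base_idx[r.alt]
        if r.kind == "EDIT":
            frac[i] = r.edit_fraction

    def one_source(mean_depth: float, is_rna: bool, rng, err_rng) -> pd.DataFrame:
        depth = rng.poisson(mean_depth, size=L)
        alt = np.zeros(L, dtype=int)
        het = kind == 1
        alt[het] = rng.binomial(depth[het], 0.5)
        hom = kind == 2
        alt[hom] = depth[hom]
        if is_rna:
            ed = kind == 3
            alt[ed] = rng.binomial(depth[ed], frac[ed])
        counts = np.zeros((L, 4), dtype=int)
        rows = np.arange(L)
        np.add.at(counts, (rows, ref_idx), depth - alt)
        has_alt = alt_idx >= 0
        np.add.at(counts, (rows[has_alt], alt_idx[has_alt]), alt[has_alt])
        counts = _apply_errors(counts, config.base_error_rate, err_rng)
        df = pd.DataFrame(counts, columns=list(BASES))
        df.insert(0, "ref", np.array(list(genome.seq)))
        df.insert(0, "pos", rows + 1)
        df.insert(0, "chrom", genome.chrom)
        return df

    return one_source(config.mean_dna_depth, False, dna_rng, dna_err_rng), \
        one_source(config.mean_rna_depth, True, rna_rng, rna_err_rng)


# ---------------------------------------------------------------------------
# miRNA target generation

def generate_mirna_targets(genome: Genome, config: SimConfig,
                           target_len: int = 22):
    """Emit mature miRNAs, a miRanda-style target table, and the UTR map.

    One miRNA is invented per transcript: its seed (nt 2-8) is the reverse
    complement of a 7-mer drawn from that transcript's 3'UTR, so a true seed
    match exists by construction; `seed_scan` then reports every match.
    A ``target_fail_fraction`` of records draw score/energy values that fail
    the downstream 'energy < -20 and score > 155' filter.
    """
    from .mirna import seed_scan  # deferred to avoid an import cycle

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    mirnas: dict[str, str] = {}
    target_rows, map_rows = [], []
    for i, gene in enumerate(genome.genes):
        if gene.utr3_span() is None:
            log.warning("transcript %s has no single-block 3'UTR; skipped",
                        gene.transcript_id)
            continue
        utr = genome.utr3_sense_seq(gene)
        if len(utr) < target_len + 20:
            log.warning("3'UTR of %s too short for a target; skipped",
                        gene.transcript_id)
            continue
        j = int(rng.integers(target_len - 7, len(utr) - 7))
        site7 = utr[j:j + 7]
        mir_id = f"sim-miR-{i:03d}"
        mir = _random_dna(rng, 1) + revcomp(site7) + _random_dna(rng, 13)
        mirnas[mir_id] = mir.replace("T", "U")

        for (ts, te, seed_start) in seed_scan(utr, mir, target_len=target_len):
            if rng.random() < config.target_fail_fraction:
                if rng.random() < 0.5:
                    score, energy = rng.uniform(160, 200), rng.uniform(-19, -10)
                else:
                    score, energy = rng.uniform(100, 155), rng.uniform(-30, -25)
            else:
                score, energy = rng.uniform(160, 200), rng.uniform(-30, -21)
            target_rows.append([mir_id, gene.transcript_id, gene.gene_id,
                                ts, te, round(float(score), 1),
                                round(float(energy), 1), seed_start])
        u3s, u3e = gene.utr3_span()
        map_rows.append([gene.transcript_id, genome.chrom, gene.strand,
                         u3s, u3e])

    targets = pd.DataFrame(target_rows, columns=[
        "mirna_id", "transcript_id", "gene_id", "utr_start", "utr_end",
        "score", "energy", "seed_utr_start"])
    utr_map = pd.DataFrame(map_rows, columns=[
        "transcript_id", "chrom", "strand",
        "utr3_genomic_start", "utr3_genomic_end"])
    return mirnas, targets, utr_map
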