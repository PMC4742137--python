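# Methods

## The RNA–DNA difference model

`editome` treats editing detection as a per-site decision problem on
paired allele counts. For each genomic position it observes DNA counts
$d$ and RNA counts $n$ over {A, C, G, T} against a reference base. The
candidate allele is the highest-count non-reference RNA base (count ties
break alphabetically); its frequency uses the site's total RNA depth over
the four bases as denominator. The stage-1 cascade (10x DNA, 10x RNA,
zero non-reference DNA reads, ≥2 alternate reads, ≥10% frequency) encodes
the assumption that germline variation must be visible in DNA: a single
non-reference DNA read disqualifies the site, which makes the caller
deliberately conservative in the presence of DNA contamination or
mis-mapping. The stage-2 confidence set (20x RNA, ≥20% frequency) trades
sensitivity at shallow sites for precision. All comparisons are
"at least" (≥); rejection reasons accumulate rather than short-circuit so
a site's full failure profile is reported. Thresholds are a frozen
dataclass and every one is configurable; the confidence values must
dominate their stage-1 counterparts.

Cohort replication requires the identical plus-strand (chrom, pos, ref,
alt) key in every sample. The key is deliberately *not* strand-corrected:
observed bases are sample-independent, whereas strand assignment depends
on annotation, so strand-unknown sites still compare consistently.
"Unique" sites are those present in exactly one sample, not merely absent
from the overlap. Strand correction happens afterwards through the
overlapping gene model; intergenic sites keep their plus-strand reading
and `strand=unknown` — the pipeline does not guess transcript orientation
where no annotation exists.

## Annotation

Feature assignment resolves disagreements between overlapping transcripts
by most-specific-consequence-first: CDS > 3′UTR > 5′UTR > non-coding exon
> intron. "Non-coding exon" (EXON_NC) realises the distinction between
exonic-but-untranslated sequence and CDS proper; both categories are
reported separately. Amino-acid consequences reconstruct the codon from
the spliced CDS in transcript orientation (minus-strand genes are
reverse-complemented), substitute the edited base at its in-codon offset
and translate both codons with the standard code; the implementation is
checked against a translate-both-codons oracle over every (codon, offset)
pair. Cluster detection marks every site inside any 100-bp window that
holds ≥4 A-to-G sites and merges overlapping marked runs, so members of
one cluster chain together with inter-site gaps ≤99 bp; a merged cluster
may span more than one window, which matches the brute-force all-windows
scan used as its oracle. Hyper-edited genes carry ≥10 sites. The
known-site comparison is a plain keyed intersection restricted to A-to-G,
with percentages of the query and of the database reported to two
decimals and recomputable from the returned integers.

Coordinate conventions are centralised in the I/O layer: site positions
and gene-model intervals are 1-based inclusive, BED is 0-based half-open
(a 1-based position p is inside BED (start, end] iff start < p ≤ end).
Gene models are serialised as BED12 because one line carries the whole
transcript (blocks = exons, thick = CDS) and round-trips without loss.

## miRNA target intersection

Predictions are kept when energy < −20 kcal/mol **and** score > 155, both
strict, as the boundary semantics of the upstream predictor print them.
UTR-relative target coordinates (1-based, transcript orientation) lift to
the genome by offsetting from the transcript's single validated 3′UTR
span: plus strand adds the UTR genomic start; minus strand counts back
from the UTR genomic end. The inverse lift is provided and round-trip
tested on both strands. Transcripts with zero or multiple annotated 3′UTR
starts are excluded (the UTR-map reader drops duplicated transcripts).

Seed bookkeeping models pairing as a contiguous exact 7-mer: the reverse
complement of mature-miRNA nucleotides 2–8 matched in the UTR, antiparallel,
so the first matched target base (transcript orientation) pairs miRNA
nt 8 and the last pairs nt 2. This is a simplification of a full
alignment — G:U wobbles, bulges and 3′-compensatory pairing are ignored —
sufficient for locating an edit within the seed. Targets may carry the
UTR-relative position of their seed match (the in-package `seed_scan`
produces it, and external tables may supply it); when absent, the seed is
assumed to occupy the target's 3′-most seven bases. Both a mature-miRNA
index (1–21) and a seed-relative index (miRNA index − 1) are reported,
since published figures number seed positions from either origin.

## The synthetic study

The generator emulates the features the pipeline actually consumes, not
sequencing reads. A random genome hosts non-overlapping stranded genes,
each with 5′UTR (80–160 bp), a stop-free CDS of 80–160 codons split by 1–2
introns (150–400 bp), and a 3′UTR (500–900 bp) confined to the terminal
exon so every transcript has a single contiguous 3′UTR span. Alu-like
repeat intervals (cluster span + 60 bp) are placed inside 3′UTRs and first
introns. Edits are planted only at adenosines on the gene's sense strand
(stored plus-strand as T>C for minus-strand genes), matching ADAR
substrate specificity; hyper-editing clusters put 5 edits within an 80-bp
window inside a genic repeat. SNPs (het and hom) land anywhere. Depths
are i.i.d. Poisson per site and source; alternate reads are
Binomial(depth, 0.5) at hets, all reads at homs, and
Binomial(depth, editing fraction) in RNA only at edit sites; each read
base then mutates to a uniformly chosen different base with the per-base
error probability. One master seed drives everything; per-sample streams
derive from (seed, CRC32(sample id)) with separate child streams for read
structure and for errors, so depths and planted counts are identical
across error rates at the same seed.

The reference conditions — and the `SimConfig` defaults — are a cohort of
3 samples at mean 40x DNA / 40x RNA, 200 planted edits (170 dispersed plus
6 clusters of 5) with editing fractions uniform on [0.25, 0.9], 50
heterozygous and 20 homozygous SNPs on a 200-kb, 12-gene genome; the
error-rate runs use 1% per read base. One miRNA is invented per
transcript with its seed complementary to a real 7-mer of that
transcript's 3′UTR, so seed matches exist by construction, and a
configurable fraction of target records draws score/energy values that
fail the downstream filter.

What the generator does **not** model: alignment and mapping artifacts,
splice-junction errors, strand-specific library biases, base-quality
variation, overdispersed or expression-coupled coverage, linked errors
within reads, and real repeat sequence content. Passing tests therefore
demonstrate the correctness of the decision rules and bookkeeping on
clean evidence, and the statistical behaviour of binomial sampling — not
robustness to the mapping artifacts that dominate false positives in real
editing studies, which this pipeline delegates to its upstream aligner
and to the strict DNA-variant filter.

Sensitivity on synthetic data is scored against *supported* edits: those
whose realized RNA evidence (depth ≥ 20, ≥2 alternate reads, alternate
fraction ≥ 0.20) meets the confidence thresholds. An edit planted at
fraction 0.25 can legitimately draw, say, 7 alternate reads in 40 — below
the 20% filter — so unconditional sensitivity 1.0 is not attainable by
any implementation of these thresholds; the supported-edit definition
isolates algorithmic loss (merge, typing, masking) from binomial sampling
noise, and the acceptance script reports the support count alongside the
rate.

## Numerical and design choices

- "No variant alleles in DNA" is a strict zero non-reference reads
  (`max_dna_nonref_reads=0`, configurable), taking the rule absolutely.
- Frequency denominator is the four-base RNA depth; ambiguous bases are
  excluded upstream.
- Multi-allelic RNA sites evaluate only the top non-reference allele;
  remaining non-reference reads are reported in a diagnostics column.
- Cluster geometry: ≥4 sites per 100-bp window, both knobs configurable,
  since published phrasings of clustering rules vary; window membership
  uses span ≤ window − 1 between extreme members.
- Percentages in summaries are rounded half-even to 2 decimals at the
  reporting boundary only; internal arithmetic is exact integer counting.
- Degenerate inputs (empty cohorts, empty masks, zero-depth sites,
  transcripts without UTRs) return empty-but-well-formed results rather
  than raising, except where the input is structurally invalid (duplicate
  positions within a sample, malformed models, CDS length not divisible
  by 3), which raise with located messages.
- Pileups interchange as TSV (chrom, pos, ref, A, C, G, T) per source to
  keep the pipeline dependency-light; a `samtools mpileup` text reader is
  provided as a convenience.

## Problem sizes

The test suite runs cohorts of 80–200 kb with 5–12 genes and 65–200
planted variants; oracle-equivalence checks use 3,000–4,000 random sites,
the cluster oracle 200 sites on 1 Mb, and the lift round trip 1,000
random targets per strand. These sizes exercise every filter boundary and
keep the full suite and the acceptance script each under a few minutes on
one CPU.

## Known limitations

- Strand assignment relies entirely on gene annotation; antisense
  transcription and intergenic editing remain strand-unknown.
- The seed model cannot represent non-canonical pairing, so seed-position
  reports for targets found by energy-based aligners are approximate when
  the true alignment is gapped near the seed.
- The cohort overlap is exact-position; editing sites shifted by indels
  or alignment jitter across samples will not merge.
- The generator's i.i.d. Poisson coverage understates the depth
  correlation of real RNA-seq along transcripts, which mainly affects how
  often neighbouring cluster members are jointly callable.
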