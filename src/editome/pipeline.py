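"""End-to-end orchestration: call -> confidence -> SNP mask -> cohort
overlap -> classification/annotation -> clusters/repeats/known-site
comparison -> miRNA intersection, with every intermediate written to disk
and a single summary JSON recomputed from the stage outputs.

Also houses the Sanger-trace decision rule as a pure classifier: an edit is
validated when the cDNA trace shows both the reference and the edited peak
while the genomic DNA shows only the reference peak.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate, calling, cohort, io as eio, mirna

log = logging.getLogger(__name__)

STAGES = ("call", "confidence", "mask", "overlap", "annotate", "mirna", "report")


class StageError(RuntimeError):
    """Failure in a named pipeline stage; exit code is stage-specific."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.exit_code = 10 + STAGES.index(stage)


@dataclass
class PipelineConfig:
    """All knobs and file paths for one pipeline run."""

    samples: dict[str, dict[str, str]]     # sample -> {"dna": path, "rna": path}
    genes: str | None = None               # BED12 gene models
    repeats: str | None = None             # BED repeat intervals
    snp_mask: str | None = None            # VCF or chrom/pos TSV
    known_sites: str | None = None         # DARNED-style TSV
    mirna_targets: str | None = None       # miRanda-style TSV
    utr_map: str | None = None             # transcript -> 3'UTR span TSV
    mirna_fasta: str | None = None         # mature miRNA sequences
    thresholds: calling.Thresholds = field(default_factory=calling.Thresholds)
    cluster_window: int = 100
    cluster_min_sites: int = 4
    hyperedit_threshold: int = 10
    mirna_max_energy: float = -20.0
    mirna_min_score: float = 155.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thr = calling.Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage tag
                raise StageError(name, exc) from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage, write intermediates under ``outdir``, return the
    summary dict (also written as summary.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"samples": {}}

    models = eio.read_gene_models_bed12(config.genes) if config.genes else []
    repeats = eio.read_bed(config.repeats) if config.repeats else []
    snp_mask = eio.read_snp_mask(config.snp_mask) if config.snp_mask else set()

    # stage 1+2+mask per sample
    per_sample: dict[str, pd.DataFrame] = {}
    for sid, paths in config.samples.items():
        dna = _stage("call")(eio.read_pileup)(paths["dna"])
        rna = _stage("call")(eio.read_pileup)(paths["rna"])
        stage1, reasons = _stage("call")(calling.call_pileups)(
            dna, rna, config.thresholds)
        stage2 = _stage("confidence")(calling.apply_confidence_stage)(
            stage1, config.thresholds)
        masked, n_masked = _stage("mask")(calling.mask_snps)(stage2, snp_mask)
        log.info("%s: stage1 %d, stage2 %d, SNP-masked %d",
                 sid, len(stage1), len(stage2), n_masked)
        stage1.to_csv(outdir / f"{sid}.stage1.tsv", sep="\t", index=False)
        masked.to_csv(outdir / f"{sid}.calls.tsv", sep="\t", index=False)
        calling.write_calls_vcf(masked, outdir / f"{sid}.calls.vcf")
        per_sample[sid] = masked
        summary["samples"][sid] = {
            "stage1_calls": len(stage1), "stage2_calls": len(stage2),
            "snp_masked": n_masked, "final_calls": len(masked),
            "rejection_reasons": reasons,
        }

    overlap, uniques = _stage("overlap")(cohort.intersect_samples)(per_sample)
    overlap = calling.classify_calls(overlap, models)
    overlap.to_csv(outdir / "overlap.tsv", sep="\t", index=False)
    for sid, df in uniques.items():
        df.to_csv(outdir / f"{sid}.unique.tsv", sep="\t", index=False)
    summary["overlap"] = {"n_sites": len(overlap),
                          "unique_per_sample": {s: len(d) for s, d in uniques.items()}}

    # annotation block
    ann = _stage("annotate")(annotate.assign_features)(overlap, models)
    ann.to_csv(outdir / "overlap.annotated.tsv", sep="\t", index=False)
    sub_table = cohort.tabulate_substitutions(ann)
    sub_table.to_csv(outdir / "substitutions.tsv", sep="\t")
    summary["substitutions"] = {
        **cohort.canonical_split(sub_table),
        "by_type": sub_table["count"].to_dict(),
    }
    feat = annotate.summarize_features(ann)
    feat.to_csv(outdir / "features.tsv", sep="\t")
    summary["features"] = {f: {"count": int(r["count"]), "percent": r["percent"]}
                           for f, r in feat.iterrows()}

    ag = ann[ann["substitution_stranded"] == "A-to-G"]
    clusters, frac = annotate.detect_clusters(
        ag, config.cluster_window, config.cluster_min_sites)
    eio.write_bed([(c.chrom, c.start - 1, c.end, f"cluster{i:03d}", c.n_sites)
                   for i, c in enumerate(clusters)], outdir / "clusters.bed")
    summary["clusters"] = {"n_clusters": len(clusters),
                           "fraction_sites_clustered": round(frac, 4)}

    gene_counts = annotate.sites_per_gene(ag)
    hyper = annotate.flag_hyperedited_genes(gene_counts, config.hyperedit_threshold)
    summary["genes"] = {"n_edited_genes": len(gene_counts),
                        "n_hyperedited": len(hyper),
                        "hyperedited": sorted(hyper)}

    flags, rep_frac = annotate.repeat_overlap(ann, repeats)
    summary["repeats"] = {"fraction_in_repeats": round(rep_frac, 4),
                          "n_in_repeats": int(flags.sum())}

    if config.known_sites:
        db = eio.read_known_sites(config.known_sites)
        db_ag = {(c, p) for c, p, s in db if s == "A-to-G"}
        query = {(r.chrom, r.pos) for r in ag.itertuples()}
        summary["known_db"] = annotate.compare_known(query, db_ag)

    # miRNA stage
    if config.mirna_targets and config.utr_map:
        targets = mirna.targets_from_frame(
            _stage("mirna")(eio.read_miranda)(config.mirna_targets))
        kept = mirna.filter_targets(targets, config.mirna_max_energy,
                                    config.mirna_min_score)
        utr_map = eio.read_utr_map(config.utr_map)
        lifted = mirna.lift_all(kept, utr_map)
        ag_sites = [(r.chrom, r.pos) for r in ag.itertuples()]
        events = _stage("mirna")(mirna.intersect_edits)(lifted, ag_sites)
        if config.mirna_fasta:
            seqs = eio.read_fasta(config.mirna_fasta)
            by_key = {(t.mirna_id, t.transcript_id, t.genomic_start,
                       t.genomic_end): t for t in lifted}
            events = [mirna.seed_annotation(e, by_key[e.target_key], seqs)
                      for e in events]
        mirna.events_to_frame(events).to_csv(outdir / "mir_edit_events.tsv",
                                             sep="\t", index=False)
        msum = mirna.summarize_mir_editing(events,
                                           cohort_genes=set(gene_counts))
        msum["per_chromosome"].to_csv(outdir / "mir_edit_by_chrom.tsv",
                                      sep="\t", index=False)
        summary["mirna"] = {k: v for k, v in msum.items()
                            if k != "per_chromosome"}
        summary["mirna"]["n_targets_input"] = len(targets)
        summary["mirna"]["n_targets_pass_filter"] = len(kept)
        summary["mirna"]["n_targets_lifted"] = len(lifted)
        summary["mirna"]["n_in_seed"] = sum(e.in_seed for e in events)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


# ---------------------------------------------------------------------------
# Sanger-trace decision rule

@dataclass(frozen=True)
class TraceCall:
    """Peak calls read off chromatograms at one site."""

    chrom: str
    pos: int
    gdna_peaks: frozenset[str]
    cdna_peaks: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gdna_peaks or not self.cdna_peaks:
            raise ValueError("peak sets must be non-empty")


def classify_trace(trace: TraceCall, ref: str, alt: str) -> str:
    """Classify a validation trace.

    VALIDATED: gDNA shows only the reference peak and cDNA shows both the
    reference and edited peaks. NOT_VALIDATED: both traces show only the
    reference peak. Anything else (e.g. a germline het with two gDNA peaks)
    is INDETERMINATE.
    """
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if trace.gdna_peaks == {ref}:
        if trace.cdna_peaks == {ref, alt}:
            return "VALIDATED"
        if trace.cdna_peaks == {ref}:
            return "NOT_VALIDATED"
    return "INDETERMINATE"
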