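"""Post-assembly transcript filters and the lncRNA locus selection cascade.

Every candidate gene receives a pass/fail/NA outcome for every filter,
recorded in a :class:`FilterAudit`; a locus is retained as lncRNA only
when all applicable filters pass.  Filters that apply only to newly
assembled (non-reference) loci — exonic length, unmappable overlap,
intergenic distance, junction support — are marked NA for reference genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import spearmanr

from .gene_models import AnnotationSet, GeneModel, TranscriptModel, exon_blocks, exonic_length
from .intervals import GenomicInterval, union_overlap_len

logger = logging.getLogger(__name__)

# Ensembl biotypes accepted as noncoding lncRNA candidates
NONCODING_BIOTYPES = (
    "lincRNA",
    "processed_transcript",
    "antisense",
    "TEC",
    "macro_lncRNA",
    "bidirectional_promoter_lncRNA",
    "sense_intronic",
)

FILTER_NAMES = (
    "noncoding",
    "exonic_length",
    "unmappable",
    "intergenic_distance",
    "junction_support",
    "retrogene_overlap",
    "trna_overlap",
    "repeat_overlap",
    "min_unique_reads",
    "sense_antisense_ratio",
    "antisense_concordance",
)


@dataclass
class TranscriptEvidence:
    transcript_id: str
    sense_unique_reads: int
    antisense_unique_reads: int
    # one bool per intron, in genomic order: junction seen with correct strand
    junction_support: list[bool] = field(default_factory=list)


@dataclass
class LocusEvidence:
    gene_id: str
    unique_reads_per_sample: np.ndarray
    sense_antisense_ratio_per_sample: np.ndarray
    full_tpm: np.ndarray | None = None
    nonoverlap_tpm: np.ndarray | None = None


@dataclass
class FilterAudit:
    gene_id: str
    outcomes: dict[str, str]  # filter -> "pass" | "fail" | "NA"
    final_class: str = ""

    def failed(self) -> list[str]:
        return [k for k, v in self.outcomes.items() if v == "fail"]


# ---------------------------------------------------------------------------
# Post-assembly transcript filters


def filter_assembled_transcripts(
    transcripts: Sequence[TranscriptModel],
    reference_ann: AnnotationSet,
    evidence: Mapping[str, TranscriptEvidence],
    min_sense_antisense_ratio: float = 0.01,
) -> tuple[list[TranscriptModel], dict[str, dict[str, str]]]:
    """Drop read-through, antisense-artifact, and unsupported transcripts.

    Removes transcripts that (a) overlap exons of two or more multiexonic
    reference genes (read-through), (b) have a sense/antisense unique-read
    ratio below `min_sense_antisense_ratio`, or (c) are multiexonic with
    any intron lacking correct-strand junction support.  Returns kept
    transcripts and a per-transcript audit map.
    """
    kept: list[TranscriptModel] = []
    audit: dict[str, dict[str, str]] = {}
    multiexonic_ref = AnnotationSet(g for g in reference_ann if g.is_multiexonic)
    for tx in transcripts:
        out = {"read_through": "pass", "sense_antisense_ratio": "pass", "junction_support": "pass"}
        ev = evidence.get(tx.id)
        hit_genes = multiexonic_ref.genes_with_exonic_overlap(tx.exons)
        if len(hit_genes) >= 2:
            out["read_through"] = "fail"
        if ev is None:
            logger.warning("transcript %s: missing evidence", tx.id)
            out["sense_antisense_ratio"] = "NA"
            out["junction_support"] = "NA"
        else:
            if ev.antisense_unique_reads > 0:
                ratio = ev.sense_unique_reads / ev.antisense_unique_reads
                if ratio < min_sense_antisense_ratio:
                    out["sense_antisense_ratio"] = "fail"
            if tx.is_multiexonic:
                n_introns = len(tx.exons) - 1
                support = ev.junction_support
                if len(support) != n_introns or not all(support):
                    out["junction_support"] = "fail"
        audit[tx.id] = out
        if all(v == "pass" for v in out.values()):
            kept.append(tx)
    return kept, audit


def merge_with_reference(
    novel_genes: Sequence[GeneModel], reference_ann: AnnotationSet
) -> AnnotationSet:
    """Combine novel loci with the reference annotation.

    Novel genes with no exonic overlap with reference genes are added as
    new loci; novel isoforms overlapping exactly one reference gene are
    attached to it; overlap with two or more genes (potential read-through
    or fusion) discards the novel gene.
    """
    merged = AnnotationSet()
    attach: dict[str, list[TranscriptModel]] = {}
    new_loci: list[GeneModel] = []
    for novel in novel_genes:
        if novel.id in reference_ann:
            raise ValueError(f"novel gene id {novel.id} collides with reference")
        blocks = exon_blocks(novel)
        hits = reference_ann.genes_with_exonic_overlap(blocks)
        if len(hits) == 0:
            new_loci.append(
                GeneModel(novel.id, novel.transcripts, biotype=novel.biotype, source="novel")
            )
        elif len(hits) == 1:
            host = hits[0]
            if novel.strand == host.strand:
                attach.setdefault(host.id, []).extend(
                    TranscriptModel(t.id, host.id, t.exons, t.biotype) for t in novel.transcripts
                )
            # opposite-strand overlap: not the same locus, keep as new locus
            else:
                new_loci.append(
                    GeneModel(novel.id, novel.transcripts, biotype=novel.biotype, source="novel")
                )
        # >= 2 hits: discarded
    for gene in reference_ann:
        txs = list(gene.transcripts) + attach.get(gene.id, [])
        merged.add(GeneModel(gene.id, txs, biotype=gene.biotype,
                             gene_class=gene.gene_class, source=gene.source))
    for gene in new_loci:
        merged.add(gene)
    return merged


# ---------------------------------------------------------------------------
# Locus selection cascade


def antisense_concordance(full_tpm: np.ndarray, nonoverlap_tpm: np.ndarray) -> float:
    """Spearman correlation between expression estimated on the complete
    annotation and on exonic regions free of other genes, across samples.
    Returns NaN when either vector has zero variance."""
    full_tpm = np.asarray(full_tpm, dtype=float)
    nonoverlap_tpm = np.asarray(nonoverlap_tpm, dtype=float)
    if full_tpm.shape != nonoverlap_tpm.shape or full_tpm.size < 3:
        raise ValueError("need matched vectors of >=3 samples")
    if np.ptp(full_tpm) == 0 or np.ptp(nonoverlap_tpm) == 0:
        return float("nan")
    rho = spearmanr(full_tpm, nonoverlap_tpm).statistic
    return float(rho)


@dataclass
class SelectionThresholds:
    min_exonic_multi: int = 200
    min_exonic_mono: int = 500
    max_unmappable_frac: float = 0.05      # strict >
    min_pc_distance: int = 5_000           # same strand, bp
    max_retrogene_frac: float = 0.50       # inclusive >=
    max_repeat_frac: float = 0.25          # inclusive >= (RNA-type repeats)
    min_unique_reads: int = 10             # in >=1 sample... summed support
    min_sense_antisense_pct: float = 0.01  # >=1% in >=1 sample
    min_concordance_rho: float = 0.9


def _span_overlap_frac(gene: GeneModel, regions: Sequence[GenomicInterval]) -> float:
    span = gene.span_interval
    ov = union_overlap_len([span], regions)
    return ov / len(span)


def _exonic_overlap_frac(gene: GeneModel, regions: Sequence[GenomicInterval]) -> float:
    blocks = exon_blocks(gene)
    ov = union_overlap_len(blocks, regions)
    return ov / sum(len(b) for b in blocks)


def select_lncrnas(
    ann: AnnotationSet,
    locus_evidence: Mapping[str, LocusEvidence],
    region_sets: Mapping[str, Sequence[GenomicInterval]],
    coding_flags: Mapping[str, str],
    junction_ok: Mapping[str, bool] | None = None,
    thresholds: SelectionThresholds | None = None,
    noncoding_biotypes: Sequence[str] = NONCODING_BIOTYPES,
) -> dict[str, FilterAudit]:
    """Run the full lncRNA selection cascade; one audit per candidate gene.

    `coding_flags` maps gene id to the coding-potential call
    ("protein_coding" / "candidate_noncoding"); `region_sets` may provide
    "unmappable", "retrogenes", "trna", "rna_repeats" interval lists —
    a missing set makes the corresponding filter NA with a warning.
    `junction_ok` gives per-gene correct-strand junction support for novel
    multiexonic loci.
    """
    th = thresholds or SelectionThresholds()
    nc_biotypes = set(noncoding_biotypes)
    audits: dict[str, FilterAudit] = {}

    pc_genes = [g for g in ann if g.biotype == "protein_coding"
                or coding_flags.get(g.id) == "protein_coding"]

    for gene in ann:
        out = {name: "NA" for name in FILTER_NAMES}

        # candidate must be noncoding: novel genes by coding-potential call,
        # reference genes by an accepted noncoding biotype
        if gene.source == "novel":
            noncoding = coding_flags.get(gene.id) == "candidate_noncoding"
        else:
            noncoding = gene.biotype in nc_biotypes
        out["noncoding"] = "pass" if noncoding else "fail"
        if not noncoding:
            audits[gene.id] = FilterAudit(gene.id, out, final_class="excluded")
            continue

        ev = locus_evidence.get(gene.id)
        novel = gene.source == "novel"

        if novel:
            exlen = exonic_length(gene)
            need = th.min_exonic_multi if gene.is_multiexonic else th.min_exonic_mono
            out["exonic_length"] = "pass" if exlen >= need else "fail"

            if "unmappable" in region_sets:
                frac = _exonic_overlap_frac(gene, region_sets["unmappable"])
                out["unmappable"] = "fail" if frac > th.max_unmappable_frac else "pass"
            else:
                logger.warning("no unmappable region set; filter NA")

            # intergenic: no exonic overlap with protein-coding genes on either
            # strand, and >= 5 kb from same-strand protein-coding gene spans
            intergenic = True
            blocks = exon_blocks(gene)
            for pc in pc_genes:
                if pc.id == gene.id or pc.chrom != gene.chrom:
                    continue
                if any(b.overlaps(pb) for pb in exon_blocks(pc) for b in blocks):
                    intergenic = False
                    break
                if pc.strand == gene.strand:
                    dist = max(pc.start - gene.end, gene.start - pc.end, 0)
                    if dist < th.min_pc_distance:
                        intergenic = False
                        break
            out["intergenic_distance"] = "pass" if intergenic else "fail"

            if gene.is_multiexonic:
                if junction_ok is not None and gene.id in junction_ok:
                    out["junction_support"] = "pass" if junction_ok[gene.id] else "fail"
                else:
                    logger.warning("gene %s: no junction evidence; filter NA", gene.id)

        if "retrogenes" in region_sets:
            frac = _span_overlap_frac(gene, region_sets["retrogenes"])
            out["retrogene_overlap"] = "fail" if frac >= th.max_retrogene_frac else "pass"
        else:
            logger.warning("no retrogene set; filter NA")

        if "trna" in region_sets:
            hit = union_overlap_len(exon_blocks(gene), region_sets["trna"]) > 0
            out["trna_overlap"] = "fail" if hit else "pass"
        else:
            logger.warning("no tRNA set; filter NA")

        if "rna_repeats" in region_sets:
            frac = _span_overlap_frac(gene, region_sets["rna_repeats"])
            out["repeat_overlap"] = "fail" if frac >= th.max_repeat_frac else "pass"
        else:
            logger.warning("no RNA-repeat set; filter NA")

        if ev is not None:
            total_reads = int(np.sum(ev.unique_reads_per_sample))
            out["min_unique_reads"] = "pass" if total_reads >= th.min_unique_reads else "fail"
            ratios = np.asarray(ev.sense_antisense_ratio_per_sample, dtype=float)
            out["sense_antisense_ratio"] = (
                "pass" if ratios.size and np.nanmax(ratios) >= th.min_sense_antisense_pct else "fail"
            )
            if ev.full_tpm is not None and ev.nonoverlap_tpm is not None:
                rho = antisense_concordance(ev.full_tpm, ev.nonoverlap_tpm)
                if np.isnan(rho):
                    out["antisense_concordance"] = "fail"
                else:
                    out["antisense_concordance"] = (
                        "pass" if rho >= th.min_concordance_rho else "fail"
                    )
            # no overlap with other genes -> concordance NA
        else:
            logger.warning("gene %s: missing locus evidence", gene.id)
            out["min_unique_reads"] = "NA"
            out["sense_antisense_ratio"] = "NA"

        final = "lncRNA" if all(v != "fail" for v in out.values()) else "excluded"
        audits[gene.id] = FilterAudit(gene.id, out, final_class=final)
    return audits


def expressed_above_noise(
    mean_tpm_by_condition, threshold: float = 1.0
) -> dict:
    """Per-condition gene sets with replicate-averaged TPM >= `threshold`.

    `mean_tpm_by_condition` is a DataFrame genes x conditions.
    """
    out = {}
    for cond in mean_tpm_by_condition.columns:
        col = mean_tpm_by_condition[cond]
        out[cond] = set(col.index[col >= threshold])
    return out


def audit_table(audits: Mapping[str, FilterAudit]):
    """Audit map as a DataFrame: one row per gene, one column per filter."""
    import pandas as pd

    rows = []
    for gid, a in audits.items():
        row = {"gene_id": gid, **a.outcomes, "final_class": a.final_class}
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")
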