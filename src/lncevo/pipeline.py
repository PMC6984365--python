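"""End-to-end orchestration helpers tying the modules together."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import orthology
from .gene_models import AnnotationSet
from .orthology import (
    ChainMap,
    GeneProjection,
    HomologyCandidate,
    alignment_stats,
    best_hit,
    cluster_candidates,
    project_gene,
    reciprocal_best_hits,
)
from .synthetic import SyntheticGenomes, exonic_sequence

logger = logging.getLogger(__name__)


@dataclass
class OrthologyResult:
    projections: dict[str, GeneProjection]        # ref gene -> projection
    best_hits: dict[str, str | None]
    pairs: list[tuple[str, str]]                  # reciprocal best hits
    candidates: list[HomologyCandidate]


def _direction(
    ref_ann: AnnotationSet,
    target_ann: AnnotationSet,
    chainmap: ChainMap,
    ref_seqs: dict[str, str],
    target_seqs: dict[str, str],
    min_remap: float,
    bounds: tuple[float, float],
    aligner,
) -> tuple[dict[str, GeneProjection], dict[str, str | None], list[HomologyCandidate]]:
    projections = {
        g.id: project_gene(g, chainmap, min_remap=min_remap, bounds=bounds) for g in ref_ann
    }
    clusters = cluster_candidates(projections, target_ann)
    candidates: dict[str, list[HomologyCandidate]] = {}
    all_cands = []
    for refs, tgts in clusters:
        for r in refs:
            rseq = exonic_sequence(ref_ann[r], ref_seqs[ref_ann[r].chrom])
            for t in tgts:
                tseq = exonic_sequence(target_ann[t], target_seqs[target_ann[t].chrom])
                cand = alignment_stats(r, t, rseq, tseq, aligner)
                candidates.setdefault(r, []).append(cand)
                all_cands.append(cand)
    hits = {r: best_hit(cands) for r, cands in candidates.items()}
    return projections, hits, all_cands


def run_orthology(
    genomes: SyntheticGenomes,
    min_remap: float = 0.10,
    bounds: tuple[float, float] = orthology.RODENT_BOUNDS,
    aligner=None,
) -> OrthologyResult:
    """Full two-species orthology pipeline on a synthetic fixture:
    projection, size filtering, consensus resolution, overlap clustering,
    exonic alignment, best hits in both directions, reciprocal best hits."""
    aligner = aligner or orthology.biopython_global_aligner()
    ann_a = genomes.annotations["speciesA"]
    ann_b = genomes.annotations["speciesB"]
    seqs_a = genomes.sequences["speciesA"]
    seqs_b = genomes.sequences["speciesB"]
    proj_ab, hits_ab, cands = _direction(
        ann_a, ann_b, genomes.chain_ab, seqs_a, seqs_b, min_remap, bounds, aligner
    )
    _proj_ba, hits_ba, _ = _direction(
        ann_b, ann_a, genomes.chain_ba, seqs_b, seqs_a, min_remap, bounds, aligner
    )
    pairs = reciprocal_best_hits(hits_ab, hits_ba)
    return OrthologyResult(proj_ab, hits_ab, pairs, cands)


def ortholog_table(result: OrthologyResult) -> pd.DataFrame:
    """Flat per-reference-gene table: projection status, best hit, 1-to-1 partner."""
    partner = dict(result.pairs)
    rows = []
    for gid, proj in result.projections.items():
        rows.append(
            {
                "ref_gene": gid,
                "status": proj.status,
                "reason": proj.reason,
                "best_hit": result.best_hits.get(gid),
                "ortholog": partner.get(gid),
            }
        )
    return pd.DataFrame(rows).set_index("ref_gene")
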