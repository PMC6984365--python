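"""Coding-potential classification from codon substitution frequencies.

The codon substitution frequency (CSF) score asks whether an aligned
window of two sequences shows the substitution pattern of protein-coding
evolution (synonymous changes tolerated, frame-preserving) or of neutral
evolution.  Two tables of ordered codon-pair frequencies are estimated
from training alignments — one from coding regions, one from neutral
regions — and a window is scored as the summed log-ratio
log(f_coding / f_noncoding) over its gapless codon pairs, maximised over
the three reading frames of each strand.

Sliding-window scans (75 bp windows, 3 bp step) produce per-strand
score vectors; a transcript is called protein-coding when positive-score
windows cover at least 150 bp of its exons outside other genes' exons,
or when qualifying protein-similarity hits cover at least 150 bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, merge_intervals, subtract_intervals, total_length

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
# 61 sense codons + one pooled stop state
SENSE_CODONS = tuple(
    a + b + c for a in _BASES for b in _BASES for c in _BASES if a + b + c not in _STOPS
)
_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
STOP_STATE = len(SENSE_CODONS)  # pooled stop codons
N_STATES = STOP_STATE + 1

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _codon_state(codon: str) -> int | None:
    """State index of a codon, or None if gapped/ambiguous."""
    if codon in _CODON_INDEX:
        return _CODON_INDEX[codon]
    if codon in _STOPS:
        return STOP_STATE
    return None


@dataclass
class CodonSubstitutionModel:
    """Log-ratio scoring model over ordered codon-pair states."""

    log_ratio: np.ndarray  # (N_STATES, N_STATES): log(f_coding / f_noncoding)
    f_coding: np.ndarray
    f_noncoding: np.ndarray
    pseudocount: float

    def pair_score(self, ref_codon: str, other_codon: str) -> float:
        i = _codon_state(ref_codon)
        j = _codon_state(other_codon)
        if i is None or j is None:
            return 0.0  # gaps/ambiguity contribute nothing
        return float(self.log_ratio[i, j])


def _count_codon_pairs(pairs: Iterable[tuple[str, str]], counts: np.ndarray) -> int:
    """Accumulate ordered codon-pair counts from aligned sequence pairs.

    Alignments are read frame 0; a trailing partial codon is ignored.
    Returns the number of usable codon columns counted.
    """
    used = 0
    for ref, other in pairs:
        if len(ref) != len(other):
            raise ValueError("aligned pair has unequal lengths")
        ref, other = ref.upper(), other.upper()
        n = len(ref)
        if n % 3:
            logger.debug("alignment length %d not a multiple of 3; trailing bases ignored", n)
        for k in range(0, n - n % 3, 3):
            i = _codon_state(ref[k:k + 3])
            j = _codon_state(other[k:k + 3])
            if i is None or j is None:
                continue
            counts[i, j] += 1
            used += 1
    return used


def train_csf_model(
    coding_pairs: Sequence[tuple[str, str]],
    noncoding_pairs: Sequence[tuple[str, str]],
    pseudocount: float = 0.5,
) -> CodonSubstitutionModel:
    """Estimate coding and neutral codon-pair frequency tables.

    Coding alignments must be in frame (frame 0 of the given sequences);
    noncoding alignments are read in the same fixed frame, which is
    arbitrary but consistent.  Additive smoothing with `pseudocount`
    guarantees strictly positive frequencies.
    """
    if not coding_pairs or not noncoding_pairs:
        raise ValueError("empty training set")
    c_counts = np.zeros((N_STATES, N_STATES))
    n_counts = np.zeros((N_STATES, N_STATES))
    if _count_codon_pairs(coding_pairs, c_counts) == 0:
        raise ValueError("no usable codon pairs in coding training set")
    if _count_codon_pairs(noncoding_pairs, n_counts) == 0:
        raise ValueError("no usable codon pairs in noncoding training set")
    f_c = c_counts + pseudocount
    f_n = n_counts + pseudocount
    f_c /= f_c.sum()
    f_n /= f_n.sum()
    return CodonSubstitutionModel(
        log_ratio=np.log(f_c) - np.log(f_n),
        f_coding=f_c,
        f_noncoding=f_n,
        pseudocount=pseudocount,
    )


@dataclass
class WindowScore:
    start: int          # alignment coordinate of window start
    length: int
    strand: str
    score: float        # max over the strand's 3 frames


def _frame_score(model: CodonSubstitutionModel, ref: str, other: str, frame: int) -> float:
    s = 0.0
    n = len(ref)
    for k in range(frame, n - 2, 3):
        s += model.pair_score(ref[k:k + 3], other[k:k + 3])
    return s


def csf_window_scan(
    aligned_pair: tuple[str, str],
    model: CodonSubstitutionModel,
    window: int = 75,
    step: int = 3,
) -> dict[str, list[WindowScore]]:
    """Score sliding windows on both strands of a pairwise alignment.

    For each window start (stride `step`) the score per strand is the
    maximum over that strand's three reading frames of the summed codon
    pair log-ratios.  Windows extending past the end are omitted.
    Returns {"+": [...], "-": [...]} in ascending window-start order.
    """
    if window % 3:
        raise ValueError("window must be a multiple of 3")
    ref, other = aligned_pair
    if len(ref) != len(other):
        raise ValueError("aligned pair has unequal lengths")
    ref, other = ref.upper(), other.upper()
    n = len(ref)
    out: dict[str, list[WindowScore]] = {"+": [], "-": []}
    if n < window:
        logger.debug("alignment length %d shorter than window %d", n, window)
        return out
    rc_ref, rc_other = revcomp(ref), revcomp(other)
    for start in range(0, n - window + 1, step):
        w_ref = ref[start:start + window]
        w_other = other[start:start + window]
        plus = max(_frame_score(model, w_ref, w_other, f) for f in range(3))
        # minus strand: reverse-complement of this window
        rc_start = n - (start + window)
        w_ref_rc = rc_ref[rc_start:rc_start + window]
        w_other_rc = rc_other[rc_start:rc_start + window]
        minus = max(_frame_score(model, w_ref_rc, w_other_rc, f) for f in range(3))
        out["+"].append(WindowScore(start, window, "+", plus))
        out["-"].append(WindowScore(start, window, "-", minus))
    return out


def positive_window_cover(
    window_scores: Sequence[WindowScore], offset: int = 0, chrom: str = "", strand: str = "+"
) -> list[GenomicInterval]:
    """Union of genomic intervals covered by strictly positive windows.

    `offset` maps alignment coordinate 0 to a genomic position.
    """
    pos = [
        GenomicInterval(chrom or "aln", offset + w.start, offset + w.start + w.length, strand)
        for w in window_scores
        if w.score > 0
    ]
    return merge_intervals(pos) if pos else []


def classify_coding_by_csf(
    exons: Sequence[GenomicInterval],
    positive_cover: Sequence[GenomicInterval],
    masked_regions: Sequence[GenomicInterval] = (),
    min_overlap: int = 150,
) -> bool:
    """True when unmasked exonic bases under positive CSF windows total
    >= `min_overlap` bp.  `masked_regions` are exonic regions of other
    genes, excluded because antisense coding signal bleeds through the
    partial strand-symmetry of the genetic code."""
    unmasked = subtract_intervals(exons, masked_regions)
    covered = 0
    for ex in unmasked:
        for pc in positive_cover:
            covered += ex.overlap_len(pc)
    return covered >= min_overlap


@dataclass
class SimilarityHit:
    transcript_id: str
    start: int  # on transcript, 0-based half-open
    end: int
    e_value: float
    pct_identity: float

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError("e_value < 0")
        if not 0 <= self.pct_identity <= 100:
            raise ValueError("pct_identity outside [0,100]")


def read_blast_tab(path) -> list[SimilarityHit]:
    """Read a BLAST outfmt-6-like table: query, subject, pct_identity,
    length, mismatches, gapopen, qstart, qend, sstart, send, evalue, bitscore.
    Query coordinates (1-based inclusive) are converted to 0-based half-open."""
    df = pd.read_csv(path, sep="\t", header=None)
    hits = []
    for row in df.itertuples(index=False):
        qstart, qend = int(row[6]), int(row[7])
        lo, hi = min(qstart, qend), max(qstart, qend)
        hits.append(SimilarityHit(str(row[0]), lo - 1, hi, float(row[10]), float(row[2])))
    return hits


def classify_coding_by_similarity(
    hits: Sequence[SimilarityHit],
    max_evalue: float = 1e-3,
    min_identity: float = 40.0,
    min_overlap: int = 150,
) -> bool:
    """True when qualifying hits (e-value <= `max_evalue`, identity >=
    `min_identity` %) cover >= `min_overlap` bp of the transcript."""
    keep = [
        GenomicInterval("tx", h.start, h.end)
        for h in hits
        if h.e_value <= max_evalue and h.pct_identity >= min_identity
    ]
    if not keep:
        return False
    return total_length(merge_intervals(keep)) >= min_overlap


def gene_coding_status(per_transcript_flags: dict[str, tuple[bool, bool]]) -> str:
    """Gene-level call from per-isoform (csf_flag, similarity_flag) pairs:
    protein-coding if any isoform is positive on either criterion."""
    if any(csf or sim for csf, sim in per_transcript_flags.values()):
        return "protein_coding"
    return "candidate_noncoding"


def write_bedgraph_windows(window_scores: Sequence[WindowScore], path, chrom: str, offset: int = 0):
    with open(path, "w") as fh:
        for w in window_scores:
            fh.write(f"{chrom}\t{offset + w.start}\t{offset + w.start + w.length}\t{w.score:.6g}\n")
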