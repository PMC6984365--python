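"""Sequence-conservation aggregation and cross-species expression
conservation/divergence statistics.

Per-base conservation scores (e.g. PhastCons) are consumed as bedGraph
tracks and averaged over gene regions with cross-gene exon masking.  The
expression conservation (EC) index is the ratio of between-species to
within-species Spearman correlations of log-expression over a gene set in
one organ/stage; per-gene expression divergence is the Euclidean distance
between sum-normalized relative expression profiles, decomposed into
per-condition contributions and regressed on expression level.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .intervals import GenomicInterval, subtract_intervals

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Conservation tracks


class ConservationTrack:
    """Sparse per-base scores: non-overlapping scored intervals per chrom.

    Bases not covered by any interval are treated as missing (not zero).
    """

    def __init__(self, intervals: Mapping[str, Sequence[tuple[int, int, float]]]):
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, ivs in intervals.items():
            ivs = sorted(ivs)
            starts = np.array([s for s, _, _ in ivs], dtype=np.int64)
            ends = np.array([e for _, e, _ in ivs], dtype=np.int64)
            scores = np.array([x for _, _, x in ivs], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping scored intervals on {chrom}")
            self._data[chrom] = (starts, ends, scores)

    @classmethod
    def read_bedgraph(cls, path) -> "ConservationTrack":
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                chrom, s, e, v = line.split()[:4]
                per_chrom.setdefault(chrom, []).append((int(s), int(e), float(v)))
        return cls(per_chrom)

    def write_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._data):
                starts, ends, scores = self._data[chrom]
                for s, e, x in zip(starts, ends, scores):
                    fh.write(f"{chrom}\t{s}\t{e}\t{x:.6g}\n")

    def sum_and_count(self, interval: GenomicInterval) -> tuple[float, int]:
        """Sum of per-base scores and number of scored bases in `interval`."""
        if interval.chrom not in self._data:
            return 0.0, 0
        starts, ends, scores = self._data[interval.chrom]
        i = np.searchsorted(ends, interval.start, side="right")
        total, n = 0.0, 0
        while i < len(starts) and starts[i] < interval.end:
            lo = max(interval.start, starts[i])
            hi = min(interval.end, ends[i])
            if hi > lo:
                total += scores[i] * (hi - lo)
                n += hi - lo
            i += 1
        return total, n


def region_conservation(
    track: ConservationTrack,
    intervals: Sequence[GenomicInterval],
    mask_intervals: Sequence[GenomicInterval] = (),
) -> float:
    """Mean per-base score over `intervals`, excluding masked bases
    (exonic regions of other genes) and bases without a score.
    NaN when no scoreable base remains."""
    usable = subtract_intervals(intervals, mask_intervals)
    total, n = 0.0, 0
    for iv in usable:
        s, c = track.sum_and_count(iv)
        total += s
        n += c
    return total / n if n else float("nan")


def conservation_by_group(
    per_gene_scores: pd.Series,
    expressed_sets: Mapping[str, set],
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Median conservation per condition gene set with a percentile
    bootstrap confidence interval over genes."""
    rng = np.random.default_rng(seed)
    lo_q, hi_q = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2
    rows = []
    for cond, genes in expressed_sets.items():
        vals = per_gene_scores.reindex(sorted(genes)).dropna().values
        if vals.size == 0:
            continue
        med = float(np.median(vals))
        boots = np.median(
            vals[rng.integers(0, vals.size, size=(n_boot, vals.size))], axis=1
        )
        unstable = vals.size < 10
        # conservative percentile selection (floor below, ceiling above):
        # the plain linear-interpolated percentile interval undercovers for
        # the median at these group sizes
        rows.append((cond, vals.size, med,
                     float(np.percentile(boots, lo_q, method="lower")),
                     float(np.percentile(boots, hi_q, method="higher")), unstable))
    return pd.DataFrame(
        rows, columns=["condition", "n_genes", "median", "ci_low", "ci_high", "unstable"]
    ).set_index("condition")


# ---------------------------------------------------------------------------
# Expression conservation index


@dataclass
class ECIndex:
    condition: str
    rho_between: float
    rho_within: float
    ec: float
    bootstrap_min: float
    bootstrap_max: float


def _mean_pairwise_rho(cols_a: np.ndarray, cols_b: np.ndarray) -> float:
    """Mean Spearman rho over cross-column pairings of two replicate blocks.

    Positionally matched pairs (replicate i vs replicate i) are skipped:
    replicate indices carry no biological pairing, and skipping them makes
    the index exactly 1 when one species' replicates are copies of the
    other's.  For exchangeable replicates the skipped subset is arbitrary,
    so the estimate is unchanged in expectation.
    """
    rhos = []
    for i in range(cols_a.shape[1]):
        for j in range(cols_b.shape[1]):
            if i == j:
                continue
            rhos.append(spearmanr(cols_a[:, i], cols_b[:, j]).statistic)
    return float(np.mean(rhos))


def _within_rho(block: np.ndarray) -> list[float]:
    return [
        spearmanr(block[:, i], block[:, j]).statistic
        for i, j in itertools.combinations(range(block.shape[1]), 2)
    ]


def expression_conservation_index(
    tpm_a: pd.DataFrame,
    tpm_b: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    condition: str = "",
    n_boot: int = 100,
    seed: int = 0,
    log: bool = True,
) -> ECIndex:
    """EC index for a gene category in one organ/stage condition.

    `tpm_a`/`tpm_b` hold the condition's replicate columns for the two
    species.  rho_between is the mean Spearman correlation (log2 TPM+1)
    over all cross-species replicate pairs; rho_within is the mean over
    all within-species replicate pairs, both species pooled; ec is their
    ratio.  Bootstrap resamples gene pairs with replacement and reports
    the min and max of the ec over `n_boot` replicates.
    """
    if tpm_a.shape[1] < 2 or tpm_b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per species")
    if len(pairs) < 20:
        raise ValueError("need >= 20 ortholog pairs")
    a = tpm_a.loc[[p[0] for p in pairs]].values.astype(float)
    b = tpm_b.loc[[p[1] for p in pairs]].values.astype(float)
    if log:
        a = np.log2(a + 1.0)
        b = np.log2(b + 1.0)

    def _ec(a_blk, b_blk):
        between = _mean_pairwise_rho(a_blk, b_blk)
        within = np.mean(_within_rho(a_blk) + _within_rho(b_blk))
        if within <= 0:
            return np.nan, between, within
        return between / within, between, within

    ec, between, within = _ec(a, b)
    if np.isnan(ec):
        logger.warning("within-species correlation <= 0; EC undefined")
    rng = np.random.default_rng(seed)
    boots = []
    n = len(pairs)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        e, _, _ = _ec(a[idx], b[idx])
        if not np.isnan(e):
            boots.append(e)
    return ECIndex(condition, float(between), float(within), float(ec),
                   float(np.min(boots)) if boots else float("nan"),
                   float(np.max(boots)) if boots else float("nan"))


# ---------------------------------------------------------------------------
# Relative profiles and expression divergence


def relative_profile_sum(cond_means: pd.Series | np.ndarray) -> np.ndarray:
    """Condition means normalized to sum to 1; undefined (error) for
    all-zero genes."""
    x = np.asarray(cond_means, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero gene has no relative profile")
    return x / total


def expression_divergence(profile_a: np.ndarray, profile_b: np.ndarray) -> float:
    """Euclidean distance between two relative expression profiles over the
    same conditions."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles over different condition sets")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def divergence_contributions(profile_a: np.ndarray, profile_b: np.ndarray) -> np.ndarray:
    """Per-condition share of squared divergence:
    contribution_c = (p_Ac - p_Bc)^2 / d^2; sums to 1 when d > 0."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    sq = (a - b) ** 2
    d2 = sq.sum()
    if d2 == 0:
        raise ValueError("d = 0: contributions undefined")
    return sq / d2


@dataclass
class DivergenceRecord:
    ref_gene: str
    target_gene: str
    distance: float
    avg_log2_expr: float
    contributions: np.ndarray


def divergence_records(
    cond_means_a: pd.DataFrame,
    cond_means_b: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
) -> list[DivergenceRecord]:
    """Per-pair expression divergence, average log2 expression, and
    per-condition contributions, over a common condition set."""
    if list(cond_means_a.columns) != list(cond_means_b.columns):
        raise ValueError("condition sets differ between species")
    out = []
    for a, b in pairs:
        xa = cond_means_a.loc[a].values
        xb = cond_means_b.loc[b].values
        if xa.sum() <= 0 or xb.sum() <= 0:
            continue
        pa, pb = relative_profile_sum(xa), relative_profile_sum(xb)
        d = expression_divergence(pa, pb)
        avg = float(np.mean(np.log2(np.concatenate([xa, xb]) + 1.0)))
        contrib = divergence_contributions(pa, pb) if d > 0 else np.full(len(pa), np.nan)
        out.append(DivergenceRecord(a, b, d, avg, contrib))
    return out


def residual_divergence(records: Sequence[DivergenceRecord]) -> pd.DataFrame:
    """OLS of divergence on average log2 expression; residual = observed -
    fitted.  Returns a table with distance, avg_log2_expr, fitted, residual."""
    if len(records) < 10:
        raise ValueError("need >= 10 records")
    x = np.array([r.avg_log2_expr for r in records])
    d = np.array([r.distance for r in records])
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor")
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, d, rcond=None)
    fitted = design @ coef
    return pd.DataFrame(
        {
            "ref_gene": [r.ref_gene for r in records],
            "target_gene": [r.target_gene for r in records],
            "distance": d,
            "avg_log2_expr": x,
            "fitted": fitted,
            "residual": d - fitted,
        }
    )


def mean_contributions(records: Sequence[DivergenceRecord], conditions: Sequence[str]) -> pd.Series:
    """Across-gene mean of per-condition divergence contributions
    (genes with d = 0 excluded)."""
    mat = np.array([r.contributions for r in records if not np.isnan(r.contributions).any()])
    if mat.size == 0:
        raise ValueError("no records with d > 0")
    return pd.Series(mat.mean(axis=0), index=list(conditions))


# ---------------------------------------------------------------------------
# Species-specific loci


def species_specific_loci(
    focal_reads: Mapping[str, int],
    projected_region_reads: Mapping[str, int | None],
    min_reads: int = 100,
) -> list[str]:
    """Loci transcribed in the focal species with a silent homologous region.

    A locus qualifies with >= `min_reads` total unique reads in the focal
    species and exactly 0 reads over its projected region in the other
    species; loci without a resolvable projection (None) are excluded.
    """
    out = []
    for gid, reads in focal_reads.items():
        other = projected_region_reads.get(gid)
        if other is None:
            continue
        if reads >= min_reads and other == 0:
            out.append(gid)
    return sorted(out)
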