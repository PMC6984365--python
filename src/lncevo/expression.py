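"""Expression-matrix handling: scaling normalization, transforms,
replicate aggregation, depth resampling, and expression summaries.

The central object is a genes x samples :class:`ExpressionMatrix` bound to
per-sample metadata (species, organ, developmental stage, replicate).
Values are raw unique-read counts or TPM; normalization rescales each
sample so the median TPM of a common set of stably ranked genes is
identical across samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ORGANS = ("brain", "kidney", "liver", "testes")

META_COLUMNS = ("species", "organ", "stage", "replicate")


def validate_meta(meta: pd.DataFrame) -> None:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata missing columns {missing}")
    if meta[list(META_COLUMNS)].duplicated().any():
        raise ValueError("duplicate (species, organ, stage, replicate)")


@dataclass
class ExpressionMatrix:
    """Genes x samples values with aligned sample metadata."""

    values: pd.DataFrame          # index: gene ids, columns: sample ids
    meta: pd.DataFrame            # index: sample ids
    value_kind: str = "tpm"       # "counts" | "tpm"

    def __post_init__(self):
        validate_meta(self.meta)
        if list(self.values.columns) != list(self.meta.index):
            self.meta = self.meta.loc[self.values.columns]
        if (self.values.values < 0).any():
            raise ValueError("negative expression values")
        if self.value_kind == "counts":
            v = self.values.values
            if not np.allclose(v, np.round(v)):
                raise ValueError("counts must be integral")

    def subset_samples(self, mask: pd.Series) -> "ExpressionMatrix":
        cols = self.meta.index[mask.loc[self.meta.index]]
        return ExpressionMatrix(self.values[cols], self.meta.loc[cols], self.value_kind)


# ---------------------------------------------------------------------------
# Scaling normalization


@dataclass
class NormalizationResult:
    matrix: pd.DataFrame
    coefficients: pd.Series       # per-sample multipliers
    selected_genes: list[str]     # the least rank-varying genes used


def scaling_normalize(
    tpm: pd.DataFrame,
    n_reference: int = 100,
    target: float | None = None,
) -> NormalizationResult:
    """Scale samples so a common gene set has identical median TPM.

    Genes are ranked within each sample by TPM; candidates are genes whose
    mean expression lies within the across-gene interquartile range
    (25–75%); the `n_reference` candidates with the lowest across-sample
    rank variance are selected.  Each sample is multiplied by a coefficient
    making the median TPM of the selected genes equal to `target`
    (default: the across-sample mean of the pre-scaling medians, which
    keeps the output on the input's TPM scale).

    Candidate means are computed on library-size-prescaled columns, so the
    gene selection — and hence the procedure — is invariant to rescaling
    any sample.  With the default target the output is defined up to one
    global factor that follows the input scale; pass a numeric `target`
    for strict scale invariance of the output matrix.
    """
    if tpm.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    ranks = tpm.rank(axis=0, method="average")
    rank_var = ranks.var(axis=1, ddof=1)
    # scale-free mean expression: per-sample rescaling must not move genes
    # in or out of the candidate window
    colsums = tpm.sum(axis=0)
    if (colsums == 0).any():
        raise ValueError("sample with all-zero expression")
    mean_expr = (tpm / colsums).mean(axis=1)
    q25, q75 = mean_expr.quantile([0.25, 0.75])
    candidates = mean_expr.index[(mean_expr >= q25) & (mean_expr <= q75)]
    if len(candidates) < n_reference:
        logger.warning("only %d candidate genes in the IQR; using all", len(candidates))
        selected = list(candidates)
    else:
        selected = list(rank_var.loc[candidates].nsmallest(n_reference, keep="first").index)
    medians = tpm.loc[selected].median(axis=0)
    if (medians == 0).any():
        bad = list(medians.index[medians == 0])
        raise ValueError(f"zero median of reference genes in samples {bad}")
    if target is None:
        target = medians.mean()
    coefficients = target / medians
    return NormalizationResult(tpm * coefficients, coefficients, selected)


def log_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(x + 1)."""
    if (matrix.values < 0).any():
        raise ValueError("negative values")
    return np.log2(matrix + 1.0)


# ---------------------------------------------------------------------------
# Aggregation


def condition_label(organ: str, stage) -> str:
    return f"{organ}|{stage}"


def condition_means(matrix: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Replicate-averaged values per (organ, stage) condition.

    Returns genes x conditions with columns labelled ``organ|stage`` in
    fixed organ order then ascending stage.
    """
    validate_meta(meta)
    cols = {}
    organs = [o for o in ORGANS if o in set(meta["organ"])]
    organs += sorted(set(meta["organ"]) - set(ORGANS))
    for organ in organs:
        for stage in sorted(set(meta.loc[meta["organ"] == organ, "stage"])):
            samples = meta.index[(meta["organ"] == organ) & (meta["stage"] == stage)]
            samples = [s for s in samples if s in matrix.columns]
            if not samples:
                logger.warning("condition %s|%s has no samples", organ, stage)
                continue
            cols[condition_label(organ, stage)] = matrix[samples].mean(axis=1)
    return pd.DataFrame(cols)


def max_expression_condition(cond_means: pd.DataFrame) -> pd.DataFrame:
    """Per-gene condition of maximum mean expression.

    Ties are broken by the fixed column order of `cond_means` (organ order
    brain, kidney, liver, testes, stages ascending) and flagged; all-zero
    genes are unassigned (NaN condition).
    """
    vals = cond_means.values
    out = []
    for i, gene in enumerate(cond_means.index):
        row = vals[i]
        if np.all(row == 0):
            out.append((gene, None, False))
            continue
        j = int(np.argmax(row))  # first max in column order
        tie = np.sum(row == row[j]) > 1
        out.append((gene, cond_means.columns[j], tie))
    return pd.DataFrame(out, columns=["gene_id", "condition", "tie"]).set_index("gene_id")


# ---------------------------------------------------------------------------
# Read resampling


def resample_reads_to_depth(
    counts: pd.DataFrame, meta: pd.DataFrame, seed: int
) -> pd.DataFrame:
    """Down-sample counts so every (organ, stage) condition within each
    species has the same total number of reads (the within-species minimum),
    drawing without replacement (multivariate hypergeometric across the
    flattened gene x replicate cells of the condition)."""
    validate_meta(meta)
    rng = np.random.default_rng(seed)
    out = counts.copy()
    for species in sorted(set(meta["species"])):
        sp_meta = meta[meta["species"] == species]
        conds = sp_meta.groupby(["organ", "stage"], sort=True)
        totals = {key: int(counts[list(grp.index)].values.sum()) for key, grp in conds}
        if not totals:
            continue
        target = min(totals.values())
        for key, grp in conds:
            samples = list(grp.index)
            block = counts[samples].values.astype(np.int64)
            total = int(block.sum())
            if total <= target:
                continue
            flat = block.ravel()
            drawn = rng.multivariate_hypergeometric(flat, target, method="marginals")
            out.loc[:, samples] = drawn.reshape(block.shape)
    return out


def detected_genes(
    counts: pd.DataFrame, gene_class: pd.Series, min_reads: int = 10
) -> pd.DataFrame:
    """Per-sample numbers of genes with >= `min_reads` reads, split by
    gene class.  Expects depth-homogenized counts."""
    detected = counts >= min_reads
    rows = {}
    for cls in sorted(set(gene_class)):
        genes = gene_class.index[gene_class == cls]
        rows[cls] = detected.loc[detected.index.intersection(genes)].sum(axis=0)
    return pd.DataFrame(rows).T


def downsample_counts_to_match(
    pc_counts: pd.DataFrame, lnc_counts: pd.DataFrame, seed: int
) -> pd.DataFrame:
    """Scale protein-coding counts so their per-sample mean matches the
    lncRNA mean, preserving relative abundances.

    Counts are multiplied by r = mean(lnc) / mean(pc) per sample and
    stochastically rounded (floor + Bernoulli on the fractional part), so
    the adjusted mean equals the lncRNA mean in expectation and zeros stay
    zero.  Samples where mean(pc) <= mean(lnc) are left unchanged.
    """
    rng = np.random.default_rng(seed)
    out = pc_counts.copy().astype(np.int64)
    for col in pc_counts.columns:
        pc_mean = pc_counts[col].mean()
        lnc_mean = lnc_counts[col].mean()
        if pc_mean <= lnc_mean:
            logger.warning("sample %s: pc mean %.3g <= lnc mean %.3g; unchanged",
                           col, pc_mean, lnc_mean)
            continue
        scaled = pc_counts[col].values * (lnc_mean / pc_mean)
        floor = np.floor(scaled)
        frac = scaled - floor
        out[col] = (floor + (rng.random(len(scaled)) < frac)).astype(np.int64)
    return out


# ---------------------------------------------------------------------------
# Expression specificity and markers


def tau_specificity(cond_means: pd.DataFrame) -> pd.Series:
    """Tissue-specificity index tau = sum(1 - x_i / x_max) / (n - 1) over
    conditions; 1 for single-condition expression, 0 for uniform.
    All-zero genes get NaN."""
    x = cond_means.values.astype(float)
    xmax = x.max(axis=1)
    n = x.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = (1.0 - x / xmax[:, None]).sum(axis=1) / (n - 1)
    tau[xmax == 0] = np.nan
    return pd.Series(tau, index=cond_means.index, name="tau")


def marker_genes(
    cond_means_a: pd.DataFrame,
    cond_means_b: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    tau_threshold: float = 0.8,
) -> list[tuple[str, str]]:
    """Orthologous pairs that are condition markers in both species.

    A pair qualifies when tau >= `tau_threshold` in both species and the
    condition of maximum expression is identical in both.
    """
    tau_a = tau_specificity(cond_means_a)
    tau_b = tau_specificity(cond_means_b)
    arg_a = max_expression_condition(cond_means_a)
    arg_b = max_expression_condition(cond_means_b)
    out = []
    for a, b in pairs:
        if a not in tau_a.index or b not in tau_b.index:
            continue
        ta, tb = tau_a[a], tau_b[b]
        if np.isnan(ta) or np.isnan(tb):
            continue
        if ta < tau_threshold or tb < tau_threshold:
            continue
        ca, cb = arg_a.loc[a, "condition"], arg_b.loc[b, "condition"]
        if ca is not None and ca == cb:
            out.append((a, b))
    return out


# ---------------------------------------------------------------------------
# TSV I/O


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_meta_tsv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    validate_meta(meta)
    return meta
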