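"""Chain-based homology and reciprocal-best-hit orthology between species.

Exon blocks of each reference gene are projected onto the target genome
through UCSC chain alignments (liftOver semantics, permissive 10% remap
threshold), filtered on the projected/reference size ratio, reduced to a
consensus chromosome/strand with a single-block rearrangement rescue,
clustered against target annotations by exonic overlap, scored by global
alignment of exonic sequences, and resolved to 1-to-1 orthologs by
reciprocal best hits on percent identity (best/second-best ratio > 1.1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from .gene_models import AnnotationSet, GeneModel, exon_blocks
from .intervals import GenomicInterval, merge_intervals

logger = logging.getLogger(__name__)

RODENT_BOUNDS = (0.33, 3.0)
CHICKEN_BOUNDS = (0.2, 5.0)


# ---------------------------------------------------------------------------
# Chain format


@dataclass
class ChainBlock:
    """One gapless aligned block: ref [r_start, r_end) <-> target [t_start, t_end).

    Target coordinates are stored on the + strand of the target chromosome;
    `t_strand` records the alignment orientation.
    """

    r_start: int
    r_end: int
    t_start: int
    t_end: int


@dataclass
class Chain:
    score: float
    r_chrom: str
    t_chrom: str
    t_strand: str  # '+' or '-'
    t_size: int
    blocks: list[ChainBlock] = field(default_factory=list)

    def ref_range(self) -> tuple[int, int]:
        return self.blocks[0].r_start, self.blocks[-1].r_end


class ChainMap:
    """A set of chains from one (reference) genome to another (target)."""

    def __init__(self, chains: Sequence[Chain]):
        self.chains = sorted(chains, key=lambda c: -c.score)
        self._by_chrom: dict[str, list[Chain]] = {}
        for c in self.chains:
            self._by_chrom.setdefault(c.r_chrom, []).append(c)

    def chains_for(self, chrom: str) -> list[Chain]:
        return self._by_chrom.get(chrom, [])


def read_chain(path) -> ChainMap:
    """Read a UCSC chain file.

    Header: ``chain score tName tSize tStrand tStart tEnd qName qSize
    qStrand qStart qEnd id``; here the chain's *target* line (tName) is the
    reference genome and qName the other genome, matching UCSC liftOver
    usage where chains are named ref-to-target.  Data lines are
    ``size dt dq`` with a bare ``size`` terminating the chain.  Query
    coordinates on the '-' strand are given in reversed-strand coordinates
    and converted here to forward-strand coordinates.
    """
    chains: list[Chain] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or line.startswith("#"):
            continue
        if not line.startswith("chain"):
            raise ValueError(f"expected chain header, got {line!r}")
        f = line.split()
        (score, r_chrom, _r_size, r_strand, r_start, _r_end,
         t_chrom, t_size, t_strand, t_start, _t_end) = (
            float(f[1]), f[2], int(f[3]), f[4], int(f[5]), int(f[6]),
            f[7], int(f[8]), f[9], int(f[10]), int(f[11]),
        )
        if r_strand != "+":
            raise ValueError("reference strand must be '+' in chain files")
        blocks: list[ChainBlock] = []
        r_pos, t_pos = r_start, t_start
        while i < len(lines):
            data = lines[i].strip()
            i += 1
            if not data:
                break
            parts = data.split()
            size = int(parts[0])
            blocks.append(_make_block(r_pos, t_pos, size, t_strand, int(f[8])))
            if len(parts) == 1:
                break
            dt, dq = int(parts[1]), int(parts[2])
            r_pos += size + dt
            t_pos += size + dq
        chains.append(Chain(score, r_chrom, t_chrom, t_strand, t_size, blocks))
    return ChainMap(chains)


def _make_block(r_pos: int, t_pos: int, size: int, t_strand: str, t_size: int) -> ChainBlock:
    if t_strand == "+":
        return ChainBlock(r_pos, r_pos + size, t_pos, t_pos + size)
    # '-' strand chain coordinates count from the reversed strand
    fwd_end = t_size - t_pos
    return ChainBlock(r_pos, r_pos + size, fwd_end - size, fwd_end)


def write_chain(chainmap: ChainMap, path, r_sizes: Mapping[str, int]) -> None:
    """Write chains in UCSC format (inverse of :func:`read_chain`)."""
    with open(path, "w") as fh:
        for cid, c in enumerate(chainmap.chains, start=1):
            r0, r1 = c.ref_range()
            if c.t_strand == "+":
                t0 = c.blocks[0].t_start
                t1 = c.blocks[-1].t_end
                t0_out, t1_out = t0, t1
            else:
                t0_out = c.t_size - c.blocks[0].t_end
                t1_out = c.t_size - c.blocks[-1].t_start
            fh.write(
                f"chain {c.score:g} {c.r_chrom} {r_sizes[c.r_chrom]} + {r0} {r1} "
                f"{c.t_chrom} {c.t_size} {c.t_strand} {t0_out} {t1_out} {cid}\n"
            )
            for j, b in enumerate(c.blocks):
                size = b.r_end - b.r_start
                if j == len(c.blocks) - 1:
                    fh.write(f"{size}\n\n")
                else:
                    nb = c.blocks[j + 1]
                    dt = nb.r_start - b.r_end
                    if c.t_strand == "+":
                        dq = nb.t_start - b.t_end
                    else:
                        dq = b.t_start - nb.t_end
                    fh.write(f"{size}\t{dt}\t{dq}\n")


# ---------------------------------------------------------------------------
# Interval projection

PROJ_STATUSES = ("ok", "unmapped", "ambiguous", "split", "size_fail",
                 "consensus_fail", "order_fail")


@dataclass
class BlockProjection:
    ref_block: GenomicInterval
    target_intervals: list[GenomicInterval]   # strand = projected gene strand
    fraction_remapped: float
    status: str
    chain_score: float = 0.0
    orientation: str = "+"                    # chain orientation used

    @property
    def target_span(self) -> GenomicInterval | None:
        if not self.target_intervals:
            return None
        t = self.target_intervals
        return GenomicInterval(t[0].chrom, min(x.start for x in t),
                               max(x.end for x in t), t[0].strand)


def _combine_strand(ref_strand: str, chain_strand: str) -> str:
    if ref_strand not in ("+", "-"):
        ref_strand = "+"
    return ref_strand if chain_strand == "+" else ("-" if ref_strand == "+" else "+")


def _project_through_chain(interval: GenomicInterval, chain: Chain) -> list[GenomicInterval]:
    """Target intervals carry the *projected gene* strand: the interval's
    strand composed with the chain orientation."""
    strand = _combine_strand(interval.strand, chain.t_strand)
    out = []
    for b in chain.blocks:
        lo = max(interval.start, b.r_start)
        hi = min(interval.end, b.r_end)
        if lo >= hi:
            continue
        if chain.t_strand == "+":
            t_lo = b.t_start + (lo - b.r_start)
            t_hi = b.t_start + (hi - b.r_start)
        else:
            t_hi = b.t_end - (lo - b.r_start)
            t_lo = b.t_end - (hi - b.r_start)
        out.append(GenomicInterval(chain.t_chrom, t_lo, t_hi, strand))
    return out


def _distinct_loci(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval],
                   min_gap: int = 1_000_000) -> bool:
    ca, cb = a[0].chrom, b[0].chrom
    if ca != cb:
        return True
    sa = min(x.start for x in a), max(x.end for x in a)
    sb = min(x.start for x in b), max(x.end for x in b)
    gap = max(sb[0] - sa[1], sa[0] - sb[1])
    return gap > min_gap


def project_interval(
    interval: GenomicInterval, chainmap: ChainMap, min_remap: float = 0.10
) -> BlockProjection:
    """Project a reference interval onto the target genome.

    Uses the highest-scoring chain covering the interval.  ``unmapped``
    when fewer than `min_remap` of the reference bases remap; ``ambiguous``
    when two or more chains remap overlapping reference bases (each
    >= `min_remap` of the interval) to distinct target loci — the signature
    of a recent duplication; ``split`` when qualifying chains to distinct
    loci cover disjoint parts of the interval — a breakpoint through the
    block.
    """
    candidates = []
    for chain in chainmap.chains_for(interval.chrom):
        tivs = _project_through_chain(interval, chain)
        if not tivs:
            continue
        mapped = sum(len(t) for t in tivs)
        frac = mapped / len(interval)
        ref_cov = merge_intervals(
            [GenomicInterval(interval.chrom, max(interval.start, b.r_start),
                             min(interval.end, b.r_end))
             for b in chain.blocks
             if max(interval.start, b.r_start) < min(interval.end, b.r_end)]
        )
        candidates.append((chain, tivs, frac, ref_cov))
    if not candidates:
        return BlockProjection(interval, [], 0.0, "unmapped")
    qualifying = [c for c in candidates if c[2] >= min_remap]
    if not qualifying:
        return BlockProjection(interval, [], max(c[2] for c in candidates), "unmapped")
    if len(qualifying) >= 2:
        best = qualifying[0]
        for other in qualifying[1:]:
            if not _distinct_loci(best[1], other[1]):
                continue
            shared = sum(
                a.overlap_len(b) for a in best[3] for b in other[3]
            )
            if shared > 0:
                return BlockProjection(interval, [], best[2], "ambiguous")
            return BlockProjection(interval, [], best[2], "split")
    chain, tivs, frac, _ = qualifying[0]
    return BlockProjection(interval, sorted(tivs, key=lambda t: t.start), frac, "ok",
                           chain.score, chain.t_strand)


def size_ratio_filter(
    projection: BlockProjection, bounds: tuple[float, float] = RODENT_BOUNDS
) -> BlockProjection:
    """Mark a projection ``size_fail`` unless target span / reference span
    lies within `bounds` (0.33–3 for rodent pairs, 0.2–5 with chicken)."""
    if projection.status != "ok":
        return projection
    span = projection.target_span
    ratio = len(span) / len(projection.ref_block)
    if not bounds[0] <= ratio <= bounds[1]:
        return BlockProjection(projection.ref_block, projection.target_intervals,
                               projection.fraction_remapped, "size_fail",
                               projection.chain_score, projection.orientation)
    return projection


# ---------------------------------------------------------------------------
# Gene-level resolution


@dataclass
class GeneProjection:
    gene_id: str
    blocks: list[BlockProjection]         # surviving ok blocks, ref order
    consensus_chrom: str | None
    consensus_strand: str | None
    status: str                           # "projected" or "discarded"
    reason: str = ""

    @property
    def target_region(self) -> GenomicInterval | None:
        ivs = [t for bp in self.blocks for t in bp.target_intervals]
        if not ivs:
            return None
        return GenomicInterval(self.consensus_chrom, min(t.start for t in ivs),
                               max(t.end for t in ivs), self.consensus_strand)


def _is_monotone(xs: Sequence[float], increasing: bool) -> bool:
    if increasing:
        return all(a < b for a, b in zip(xs, xs[1:]))
    return all(a > b for a, b in zip(xs, xs[1:]))


def resolve_gene_projection(
    gene_id: str, block_projections: Sequence[BlockProjection]
) -> GeneProjection:
    """Consensus chromosome/strand and collinearity resolution for one gene.

    The consensus is the target chromosome/strand carrying the majority of
    projected bases; blocks elsewhere are dropped (``consensus_fail``).
    Remaining blocks must be collinear (target midpoints monotone in
    reference order, orientation-corrected for '-' strand chains): a single
    offending block is dropped, two or more discard the gene
    (``order_fail``).  Ties in the consensus vote discard the gene.
    """
    ok = [bp for bp in block_projections if bp.status == "ok"]
    if not ok:
        return GeneProjection(gene_id, [], None, None, "discarded", "no_projected_blocks")
    votes: dict[tuple[str, str], int] = {}
    for bp in ok:
        key = (bp.target_intervals[0].chrom, bp.target_intervals[0].strand)
        votes[key] = votes.get(key, 0) + sum(len(t) for t in bp.target_intervals)
    ranked = sorted(votes.items(), key=lambda kv: -kv[1])
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return GeneProjection(gene_id, [], None, None, "discarded", "consensus_tie")
    (c_chrom, c_strand), _ = ranked[0]
    kept = [bp for bp in ok
            if (bp.target_intervals[0].chrom, bp.target_intervals[0].strand)
            == (c_chrom, c_strand)]
    if not kept:
        return GeneProjection(gene_id, [], None, None, "discarded", "no_consensus_blocks")

    kept = sorted(kept, key=lambda bp: bp.ref_block.start)
    mids = [(bp.target_span.start + bp.target_span.end) / 2 for bp in kept]
    # order direction follows the chain orientation, not the projected strand
    increasing = kept[0].orientation == "+"
    if len(kept) >= 2 and not _is_monotone(mids, increasing):
        # try removing exactly one block
        rescue = None
        for skip in range(len(kept)):
            rest = [m for j, m in enumerate(mids) if j != skip]
            if _is_monotone(rest, increasing):
                rescue = skip
                break
        if rescue is None:
            return GeneProjection(gene_id, [], c_chrom, c_strand, "discarded", "order_fail")
        kept = [bp for j, bp in enumerate(kept) if j != rescue]
    return GeneProjection(gene_id, kept, c_chrom, c_strand, "projected")


def project_gene(
    gene: GeneModel,
    chainmap: ChainMap,
    min_remap: float = 0.10,
    bounds: tuple[float, float] = RODENT_BOUNDS,
) -> GeneProjection:
    """Full per-gene projection: exon blocks -> chain projection ->
    size-ratio filter -> consensus/collinearity resolution."""
    bps = [
        size_ratio_filter(project_interval(blk, chainmap, min_remap), bounds)
        for blk in exon_blocks(gene)
    ]
    return resolve_gene_projection(gene.id, bps)


# ---------------------------------------------------------------------------
# Candidate clustering and alignment statistics


def cluster_candidates(
    gene_projections: Mapping[str, GeneProjection], target_ann: AnnotationSet
) -> list[tuple[set[str], set[str]]]:
    """Single-link clusters of (ref genes, target genes) connected by >=1 bp
    strand-aware overlap between projected exon blocks and target exon blocks."""
    import networkx as nx

    g = nx.Graph()
    for gid, proj in gene_projections.items():
        if proj.status != "projected":
            continue
        g.add_node(("ref", gid))
        for bp in proj.blocks:
            for tiv in bp.target_intervals:
                for tgt in target_ann.genes_with_exonic_overlap([tiv], stranded=True):
                    g.add_edge(("ref", gid), ("tgt", tgt.id))
    clusters = []
    for comp in nx.connected_components(g):
        refs = {n[1] for n in comp if n[0] == "ref"}
        tgts = {n[1] for n in comp if n[0] == "tgt"}
        if refs:
            clusters.append((refs, tgts))
    return clusters


@dataclass
class HomologyCandidate:
    ref_gene: str
    target_gene: str
    pct_aligned_ungapped: float
    pct_identity: float

    def __post_init__(self):
        if not (0 <= self.pct_aligned_ungapped <= 100 and 0 <= self.pct_identity <= 100):
            raise ValueError("percentages outside [0,100]")


def biopython_global_aligner():
    """Default pluggable aligner: affine-gap global alignment, returning the
    two aligned strings (with '-' gaps)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -0.5

    def align(a: str, b: str) -> tuple[str, str]:
        aln = aligner.align(a, b)[0]
        return str(aln[0]), str(aln[1])

    return align


def alignment_stats(
    ref_gene: str,
    target_gene: str,
    ref_seq: str,
    target_seq: str,
    aligner: Callable[[str, str], tuple[str, str]] | None = None,
) -> HomologyCandidate:
    """Align exonic sequences and report, relative to the reference exonic
    length, the percent of bases in gapless columns and the percent of
    identical bases."""
    if not ref_seq or not target_seq:
        raise ValueError("empty exonic sequence")
    aligner = aligner or biopython_global_aligner()
    a, b = aligner(ref_seq.upper(), target_seq.upper())
    ungapped = sum(1 for x, y in zip(a, b) if x != "-" and y != "-")
    ident = sum(1 for x, y in zip(a, b) if x != "-" and x == y)
    n = len(ref_seq)
    return HomologyCandidate(ref_gene, target_gene, 100.0 * ungapped / n, 100.0 * ident / n)


def best_hit(
    candidates: Sequence[HomologyCandidate], ratio_threshold: float = 1.1
) -> str | None:
    """Best target by percent identity; with several candidates the best is
    reported only when best/second-best identity > `ratio_threshold`."""
    if not candidates:
        return None
    if len(candidates) == 1:
        return candidates[0].target_gene
    ranked = sorted(candidates, key=lambda c: -c.pct_identity)
    top, second = ranked[0], ranked[1]
    if second.pct_identity <= 0:
        return top.target_gene
    if top.pct_identity / second.pct_identity > ratio_threshold:
        return top.target_gene
    return None


def reciprocal_best_hits(
    ref_to_target: Mapping[str, str | None], target_to_ref: Mapping[str, str | None]
) -> list[tuple[str, str]]:
    """Pairs (a, b) with best(a) = b and best(b) = a; a partial bijection."""
    pairs = []
    for a, b in ref_to_target.items():
        if b is not None and target_to_ref.get(b) == a:
            pairs.append((a, b))
    return sorted(pairs)


def three_species_families(
    pairwise_rbh: Mapping[tuple[str, str], Sequence[tuple[str, str]]]
) -> list[dict[str, str]]:
    """Single-link families over pairwise RBH edges across >=2 species pairs.

    `pairwise_rbh` maps (species_a, species_b) to RBH pairs of gene ids.
    Families with more than one gene of any species are discarded.
    Returns one {species: gene_id} dict per family.
    """
    import networkx as nx

    g = nx.Graph()
    for (sa, sb), pairs in pairwise_rbh.items():
        for a, b in pairs:
            g.add_edge((sa, a), (sb, b))
    families = []
    for comp in nx.connected_components(g):
        species = [n[0] for n in comp]
        if len(species) != len(set(species)):
            continue  # duplicate representative per species
        families.append({s: gid for s, gid in comp})
    return families


def conservation_class(
    projection: GeneProjection,
    target_unique_reads: int | None,
    rbh_partner: str | None,
    same_class: bool = False,
    min_reads: int = 10,
) -> str:
    """Ordered conservation class of a reference gene: the highest of
    unprojected < projected < projected_transcribed (>= `min_reads` unique
    reads over the projected region) < ortholog < ortholog_same_class."""
    if projection.status != "projected":
        return "unprojected"
    cls = "projected"
    if target_unique_reads is not None and target_unique_reads >= min_reads:
        cls = "projected_transcribed"
    if rbh_partner is not None:
        cls = "ortholog_same_class" if same_class else "ortholog"
    return cls
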