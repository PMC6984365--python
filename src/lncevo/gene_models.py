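"""Gene/transcript data model, GTF I/O, and derived regions.

A :class:`GeneModel` groups one or more :class:`TranscriptModel` isoforms
sharing a chromosome and strand.  Derived regions used downstream are the
exon blocks (union of exon coordinates across isoforms), the promoter
(400 bp upstream of the gene TSS by default) and the splice sites (the
first and last two bases of each intron).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .intervals import GenomicInterval, merge_intervals

logger = logging.getLogger(__name__)

GENE_CLASSES = ("protein_coding", "lncRNA", "other", "excluded")


class GtfParseError(ValueError):
    pass


@dataclass
class TranscriptModel:
    id: str
    gene_id: str
    exons: list[GenomicInterval]
    biotype: str = ""

    def __post_init__(self):
        self.exons = sorted(self.exons, key=lambda e: e.start)
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"transcript {self.id}: exons span multiple chrom/strand")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(f"transcript {self.id}: exons overlap or touch")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> int:
        """Genomic span, first exon start to last exon end."""
        return self.end - self.start

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def introns(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        ]

    @property
    def is_multiexonic(self) -> bool:
        return len(self.exons) > 1


@dataclass
class GeneModel:
    id: str
    transcripts: list[TranscriptModel]
    biotype: str = ""
    gene_class: str = "other"
    source: str = "reference"

    def __post_init__(self):
        if not self.transcripts:
            raise ValueError(f"gene {self.id}: no transcripts")
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"gene {self.id}: transcripts on multiple chrom/strand")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def span_interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def tss(self) -> int:
        """5'-most transcript start across isoforms on the gene strand."""
        if self.strand == "+":
            return self.start
        return self.end

    @property
    def is_multiexonic(self) -> bool:
        return any(t.is_multiexonic for t in self.transcripts)


class AnnotationSet:
    """Genes indexed by id with per-chromosome interval lookup."""

    def __init__(self, genes: Iterable[GeneModel] = ()):
        self.genes: dict[str, GeneModel] = {}
        for g in genes:
            self.add(g)
        self._index: dict[str, list[tuple[int, int, str]]] | None = None

    def add(self, gene: GeneModel) -> None:
        if gene.id in self.genes:
            raise ValueError(f"duplicate gene id {gene.id}")
        self.genes[gene.id] = gene
        self._index = None

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def _build_index(self):
        idx: dict[str, list[tuple[int, int, str]]] = {}
        for g in self.genes.values():
            idx.setdefault(g.chrom, []).append((g.start, g.end, g.id))
        for entries in idx.values():
            entries.sort()
        self._index = idx

    def overlapping_genes(
        self, interval: GenomicInterval, stranded: bool = False
    ) -> list[GeneModel]:
        """Genes whose span overlaps `interval` (optionally same strand)."""
        if self._index is None:
            self._build_index()
        out = []
        for s, e, gid in self._index.get(interval.chrom, []):
            if s >= interval.end:
                break
            if e > interval.start:
                g = self.genes[gid]
                if stranded and g.strand != interval.strand:
                    continue
                out.append(g)
        return out

    def genes_with_exonic_overlap(
        self, exons: Sequence[GenomicInterval], stranded: bool = False
    ) -> list[GeneModel]:
        """Genes with >=1 bp of exon overlap with any of `exons`."""
        hits: dict[str, GeneModel] = {}
        for ex in exons:
            for g in self.overlapping_genes(ex, stranded=stranded):
                if g.id in hits:
                    continue
                for blk in exon_blocks(g):
                    if blk.overlaps(ex, stranded=stranded):
                        hits[g.id] = g
                        break
        return list(hits.values())


# ---------------------------------------------------------------------------
# GTF I/O (Ensembl dialect). GTF is 1-based inclusive; internal coordinates
# are 0-based half-open.

def _parse_attributes(field: str, lineno: int) -> dict[str, str]:
    attrs = {}
    for chunk in field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            key, val = chunk.split(" ", 1)
        except ValueError:
            raise GtfParseError(f"line {lineno}: malformed attribute {chunk!r}")
        attrs[key] = val.strip().strip('"')
    return attrs


def read_gtf(path) -> AnnotationSet:
    """Read an Ensembl-dialect GTF into an :class:`AnnotationSet`.

    Only `exon` features are used to build transcripts; gene/transcript
    biotypes come from the `gene_biotype` / `transcript_biotype` attributes
    when present.  Exon records lacking a transcript_id are rejected and
    logged rather than aborting the parse.
    """
    tx_exons: dict[str, list[GenomicInterval]] = {}
    tx_gene: dict[str, str] = {}
    tx_biotype: dict[str, str] = {}
    gene_biotype: dict[str, str] = {}
    gene_source: dict[str, str] = {}
    gene_order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"line {lineno}: expected 9 fields, got {len(fields)}")
            chrom, _src, feature, start, end, _score, strand, _frame, attr_str = fields
            if feature != "exon":
                continue
            try:
                start_i = int(start) - 1  # to 0-based half-open
                end_i = int(end)
            except ValueError:
                raise GtfParseError(f"line {lineno}: non-integer coordinates")
            if start_i < 0 or end_i <= start_i:
                raise GtfParseError(f"line {lineno}: bad coordinates {start}..{end}")
            attrs = _parse_attributes(attr_str, lineno)
            if "transcript_id" not in attrs:
                logger.warning("line %d: exon without transcript_id, skipped", lineno)
                continue
            if "gene_id" not in attrs:
                raise GtfParseError(f"line {lineno}: exon without gene_id")
            tid = attrs["transcript_id"]
            gid = attrs["gene_id"]
            tx_exons.setdefault(tid, []).append(GenomicInterval(chrom, start_i, end_i, strand))
            tx_gene[tid] = gid
            if "transcript_biotype" in attrs:
                tx_biotype[tid] = attrs["transcript_biotype"]
            if "gene_biotype" in attrs:
                gene_biotype[gid] = attrs["gene_biotype"]
            if "gene_source" in attrs:
                gene_source[gid] = attrs["gene_source"]
            gene_biotype.setdefault(gid, "")
            if gid not in gene_order:
                gene_order.append(gid)

    genes_tx: dict[str, list[TranscriptModel]] = {}
    for tid, exons in tx_exons.items():
        gid = tx_gene[tid]
        genes_tx.setdefault(gid, []).append(
            TranscriptModel(tid, gid, exons, biotype=tx_biotype.get(tid, ""))
        )
    ann = AnnotationSet()
    for gid in gene_order:
        txs = sorted(genes_tx[gid], key=lambda t: t.id)
        ann.add(
            GeneModel(
                gid,
                txs,
                biotype=gene_biotype.get(gid, ""),
                source=gene_source.get(gid, "reference"),
            )
        )
    return ann


def write_gtf(ann: AnnotationSet, path) -> None:
    """Write exon records; inverse of :func:`read_gtf`."""
    with open(path, "w") as fh:
        for gene in sorted(ann, key=lambda g: (g.chrom, g.start, g.id)):
            for tx in gene.transcripts:
                for ex in tx.exons:
                    attrs = (
                        f'gene_id "{gene.id}"; transcript_id "{tx.id}"; '
                        f'gene_biotype "{gene.biotype}"; '
                        f'transcript_biotype "{tx.biotype}"; '
                        f'gene_source "{gene.source}";'
                    )
                    fh.write(
                        "\t".join(
                            [
                                ex.chrom,
                                "lncevo",
                                "exon",
                                str(ex.start + 1),
                                str(ex.end),
                                ".",
                                ex.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


def write_bed6(intervals: Sequence[GenomicInterval], path, names: Sequence[str] | None = None):
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"region_{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bed(path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            strand = f[5].strip() if len(f) >= 6 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


# ---------------------------------------------------------------------------
# Reference prefiltering and derived regions

DEFAULT_DROP_BIOTYPES = ("retained_intron", "processed_transcript")


def prefilter_reference(
    ann: AnnotationSet,
    max_span_bp: int = 2_500_000,
    drop_biotypes: Sequence[str] = DEFAULT_DROP_BIOTYPES,
) -> AnnotationSet:
    """Remove transcripts spanning more than `max_span_bp` and, for
    protein-coding genes, isoforms with the listed non-coding biotypes.
    Genes left without transcripts are dropped."""
    if max_span_bp <= 0:
        raise ValueError("max_span_bp must be positive")
    drop = set(drop_biotypes)
    out = AnnotationSet()
    for gene in ann:
        kept = [t for t in gene.transcripts if t.span <= max_span_bp]
        if gene.biotype == "protein_coding":
            kept = [t for t in kept if t.biotype not in drop]
        if kept:
            out.add(
                GeneModel(gene.id, kept, biotype=gene.biotype,
                          gene_class=gene.gene_class, source=gene.source)
            )
    return out


def exon_blocks(gene: GeneModel) -> list[GenomicInterval]:
    """Union of exon coordinates across all isoforms: minimal sorted set of
    disjoint intervals covering every exon base."""
    return merge_intervals(ex for tx in gene.transcripts for ex in tx.exons)


def exonic_length(gene: GeneModel) -> int:
    return sum(len(b) for b in exon_blocks(gene))


def promoter_region(gene: GeneModel, upstream_bp: int = 400) -> tuple[GenomicInterval, bool]:
    """Region of `upstream_bp` immediately upstream of the gene TSS.

    Returns (interval, truncated) where truncated flags clipping at the
    chromosome start (only possible on the + strand).
    """
    tss = gene.tss
    truncated = False
    if gene.strand == "+":
        start = tss - upstream_bp
        if start < 0:
            start = 0
            truncated = True
        return GenomicInterval(gene.chrom, start, tss, gene.strand), truncated
    return GenomicInterval(gene.chrom, tss, tss + upstream_bp, gene.strand), truncated


def splice_sites(transcript: TranscriptModel) -> list[GenomicInterval]:
    """First and last two bases of every intron (4 bp per intron);
    empty for monoexonic transcripts."""
    sites = []
    for intron in transcript.introns():
        sites.append(GenomicInterval(intron.chrom, intron.start, intron.start + 2, intron.strand))
        sites.append(GenomicInterval(intron.chrom, intron.end - 2, intron.end, intron.strand))
    return sites


def gene_splice_sites(gene: GeneModel) -> list[GenomicInterval]:
    return merge_intervals(
        s for tx in gene.transcripts for s in splice_sites(tx)
    ) if gene.is_multiexonic else []


def classify_promoter_type(gene: GeneModel, ann: AnnotationSet, window_bp: int = 1000) -> str:
    """Promoter architecture of `gene` relative to opposite-strand TSSs.

    ``bidirectional_pc`` if a protein-coding gene's TSS on the opposite
    strand lies within `window_bp`; ``bidirectional_other`` if only a
    non-coding TSS does; else ``unidirectional``.  Protein-coding takes
    precedence when both occur.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    tss = gene.tss
    found_other = False
    for other in ann:
        if other.id == gene.id or other.chrom != gene.chrom or other.strand == gene.strand:
            continue
        if abs(other.tss - tss) <= window_bp:
            if other.biotype == "protein_coding" or other.gene_class == "protein_coding":
                return "bidirectional_pc"
            found_other = True
    return "bidirectional_other" if found_other else "unidirectional"
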