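"""Synthetic multi-species fixtures with planted ground truth.

Generates, from a single seed, a pair of small genomes related by known
homology (substitutions plus planted duplications, deletions, inversions,
rearrangements, breakpoints and species-specific loci), chain alignment
maps consistent with that homology, gene annotations, organ x stage x
replicate expression matrices with negative-binomial noise, per-base
conservation tracks, and in-frame/neutral alignment pairs for training
the coding-potential model.  Every downstream module can therefore be
exercised against known truth without external data.

The defaults describe the emulated study design: two closely related
species, four organs (brain, kidney, liver, testes), three developmental
stages with three replicates each, low-abundance and testis-biased
lncRNAs, and conservation elevated on constrained exons, promoters and
splice sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gene_models import AnnotationSet, GeneModel, TranscriptModel, exon_blocks, exonic_length
from .intervals import GenomicInterval
from .orthology import Chain, ChainBlock, ChainMap
from .coding_potential import SENSE_CODONS, revcomp

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

# gene fates planted in the descendant genome
FATES = (
    "ortholog",
    "inverted",          # orthologous, on the '-' strand in the target
    "duplicate",         # extra dispersed copy -> ambiguous projection
    "deleted",           # absent from target -> unmapped
    "rearrange_rescue",  # one exon displaced -> single-block rescue
    "rearrange_fatal",   # two exon pairs swapped -> order_fail
    "consensus_rescue",  # one exon translocated to another chrom -> dropped
    "size_fail",         # large insertion inside the exon -> size ratio fail
    "split",             # breakpoint through the exon block
    "specific_a",        # annotated/transcribed in A only (sequence conserved)
    "specific_b",        # annotated/transcribed in B only
)


@dataclass
class SimulationConfig:
    seed: int = 0
    # genome / annotation
    n_pc: int = 280
    n_lnc: int = 320
    substitution_rate: float = 0.03
    duplicate_fraction: float = 0.04
    deleted_fraction: float = 0.03
    rescue_fraction: float = 0.03
    fatal_fraction: float = 0.02
    consensus_fraction: float = 0.02
    inverted_fraction: float = 0.04
    size_fail_fraction: float = 0.01
    split_fraction: float = 0.01
    specific_fraction: float = 0.04     # per species, lncRNAs only
    # expression
    organs: tuple = ("brain", "kidney", "liver", "testes")
    n_stages: int = 3
    n_replicates: int = 3
    dispersion: float = 0.05
    pc_mean: float = 60.0               # expected counts per sample
    lnc_scale: float = 0.1              # lncRNA abundance relative to pc
    testis_bias: float = 4.0            # fold-increase for testis-biased lncRNAs
    testis_bias_fraction: float = 0.5
    organ_effect_sd: float = 1.0
    divergence_sd: float = 0.4          # between-species log-scale divergence
    de_fraction: float = 0.3
    de_effect: float = 6.0              # max/min stage-mean fold change
    # conservation
    baseline_score: float = 0.07
    exon_boost: float = 0.42
    promoter_boost: float = 0.17
    splice_boost: float = 0.85
    lnc_exon_score: float = 0.094
    conserved_lnc_fraction: float = 0.3

    def validate(self):
        frac = (self.duplicate_fraction + self.deleted_fraction + self.rescue_fraction
                + self.fatal_fraction + self.consensus_fraction + self.inverted_fraction
                + self.size_fail_fraction + self.split_fraction + 2 * self.specific_fraction)
        if frac > 1:
            raise ValueError("event fractions sum to more than 1")
        for name in ("substitution_rate", "dispersion", "divergence_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    fate: dict[str, str]                      # per A-side gene id (or B for specific_b)
    ortholog_pairs: list[tuple[str, str]]     # planted recoverable 1-to-1
    duplicate_families: list[tuple[str, list[str]]]
    specific_a: list[str]
    specific_b: list[str]
    gene_class: dict[str, str]                # both species
    de_genes: dict[str, str]                  # gene -> profile shape (species A ids)
    conserved_lnc: set[str] = field(default_factory=set)
    expected_losses: list[str] = field(default_factory=list)  # orthologous but designed to fail


@dataclass
class SyntheticGenomes:
    config: SimulationConfig
    sequences: dict[str, dict[str, str]]      # species -> chrom -> sequence
    annotations: dict[str, AnnotationSet]     # species -> genes
    chain_ab: ChainMap                        # A -> B
    chain_ba: ChainMap                        # B -> A
    truth: GroundTruth

    def chrom_sizes(self, species: str) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences[species].items()}


# ---------------------------------------------------------------------------
# sequence helpers


def _random_seq(rng, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _mutate(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if hit.any():
        # substitute with one of the three other bases
        repl = _BASES[rng.integers(0, 4, size=int(hit.sum()))]
        cur = arr[hit]
        same = repl == cur
        while same.any():
            repl[same] = _BASES[rng.integers(0, 4, size=int(same.sum()))]
            same = repl == cur
        arr[hit] = repl
    return "".join(arr)


class _GenomeWriter:
    """Accumulates per-chromosome sequence and tracks the cursor."""

    def __init__(self):
        self.chroms: dict[str, list[str]] = {}
        self.pos: dict[str, int] = {}

    def append(self, chrom: str, seq: str) -> int:
        start = self.pos.get(chrom, 0)
        self.chroms.setdefault(chrom, []).append(seq)
        self.pos[chrom] = start + len(seq)
        return start

    def sequences(self) -> dict[str, str]:
        return {c: "".join(parts) for c, parts in self.chroms.items()}


class _ChainBuilder:
    """Collects gapless aligned runs into chains; merges contiguous runs."""

    def __init__(self):
        self.chains: list[Chain] = []
        self._main: list[ChainBlock] | None = None
        self._main_key: tuple | None = None

    def add_main(self, r_chrom, t_chrom, a_start, b_start, size):
        key = (r_chrom, t_chrom)
        if self._main is None or self._main_key != key:
            self.flush_main()
            self._main = []
            self._main_key = key
        blocks = self._main
        if blocks and blocks[-1].r_end == a_start and blocks[-1].t_end == b_start:
            blocks[-1] = ChainBlock(blocks[-1].r_start, a_start + size,
                                    blocks[-1].t_start, b_start + size)
        else:
            blocks.append(ChainBlock(a_start, a_start + size, b_start, b_start + size))

    def flush_main(self, score: float = 1e9, t_size: int = 0):
        if self._main:
            r_chrom, t_chrom = self._main_key
            self.chains.append(Chain(score, r_chrom, t_chrom, "+", t_size, self._main))
        self._main = None
        self._main_key = None

    def add_chain(self, r_chrom, t_chrom, t_strand, blocks, score):
        self.chains.append(Chain(score, r_chrom, t_chrom, t_strand, 0, list(blocks)))


def _invert_chain(chain: Chain, new_t_sizes: dict[str, int]) -> Chain:
    blocks = [
        ChainBlock(b.t_start, b.t_end, b.r_start, b.r_end) for b in chain.blocks
    ]
    blocks.sort(key=lambda b: b.r_start)
    return Chain(chain.score, chain.t_chrom, chain.r_chrom, chain.t_strand,
                 new_t_sizes.get(chain.r_chrom, 0), blocks)


def invert_chainmap(chainmap: ChainMap, t_sizes: dict[str, int]) -> ChainMap:
    """Swap reference and target roles of every chain."""
    return ChainMap([_invert_chain(c, t_sizes) for c in chainmap.chains])


# ---------------------------------------------------------------------------
# genome + annotation simulation


def _gene_structure(rng, gene_class: str, fate: str) -> tuple[list[int], list[int]]:
    """Exon and intron lengths for a gene, honouring fate constraints."""
    if fate in ("size_fail", "split"):
        n_exons = 1
    elif fate == "rearrange_fatal":
        n_exons = 4
    elif fate in ("rearrange_rescue", "consensus_rescue"):
        n_exons = int(rng.integers(3, 5))
    elif gene_class == "protein_coding":
        n_exons = int(rng.integers(2, 6))
    else:
        n_exons = int(rng.integers(1, 5))
    exon_lens = list(rng.integers(120, 320, size=n_exons))
    intron_lens = list(rng.integers(150, 450, size=max(0, n_exons - 1)))
    return [int(x) for x in exon_lens], [int(x) for x in intron_lens]


def _assign_fates(rng, cfg: SimulationConfig, classes: list[str]) -> list[str]:
    n = len(classes)
    fates = ["ortholog"] * n
    lnc_idx = [i for i, c in enumerate(classes) if c == "lncRNA"]
    pool = list(range(n))
    rng.shuffle(pool)

    def take(count, allowed=None):
        out = []
        for i in list(pool):
            if len(out) >= count:
                break
            if allowed is None or i in allowed:
                out.append(i)
                pool.remove(i)
        return out

    lnc_set = set(lnc_idx)
    n_spec = int(round(cfg.specific_fraction * n))
    for i in take(n_spec, lnc_set):
        fates[i] = "specific_a"
    for i in take(n_spec, lnc_set):
        fates[i] = "specific_b"
    for fate, frac in (
        ("duplicate", cfg.duplicate_fraction),
        ("deleted", cfg.deleted_fraction),
        ("rearrange_rescue", cfg.rescue_fraction),
        ("rearrange_fatal", cfg.fatal_fraction),
        ("consensus_rescue", cfg.consensus_fraction),
        ("inverted", cfg.inverted_fraction),
        ("size_fail", cfg.size_fail_fraction),
        ("split", cfg.split_fraction),
    ):
        count = max(1, int(round(frac * n))) if frac > 0 else 0
        for i in take(count):
            fates[i] = fate
    return fates


def simulate_genomes(config: SimulationConfig) -> SyntheticGenomes:
    """Generate the two-species fixture: sequences, annotations, chains, truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_pc + config.n_lnc
    classes = ["protein_coding"] * config.n_pc + ["lncRNA"] * config.n_lnc
    order = rng.permutation(n)
    classes = [classes[i] for i in order]
    fates = _assign_fates(rng, config, classes)

    ga, gb = _GenomeWriter(), _GenomeWriter()
    cb = _ChainBuilder()
    ann_a, ann_b = AnnotationSet(), AnnotationSet()
    truth = GroundTruth({}, [], [], [], [], {}, {})
    rate = config.substitution_rate
    A_CHR, B_CHR, B_CHR2 = "chrA1", "chrB1", "chrB2"

    # chrB2 gets a small lead-in so translocated material is not at pos 0
    gb.append(B_CHR2, _random_seq(rng, 1000))

    def spacer():
        s = _random_seq(rng, int(rng.integers(600, 1500)))
        a0 = ga.append(A_CHR, s)
        b0 = gb.append(B_CHR, _mutate(rng, s, rate))
        cb.add_main(A_CHR, B_CHR, a0, b0, len(s))

    def add_gene_annotation(ann, gid, chrom, strand, exon_ivs, gene_class, source="reference"):
        exons = [GenomicInterval(chrom, s, e, strand) for s, e in sorted(exon_ivs)]
        biotype = "protein_coding" if gene_class == "protein_coding" else "lincRNA"
        tx = TranscriptModel(f"{gid}.t1", gid, exons, biotype=biotype)
        ann.add(GeneModel(gid, [tx], biotype=biotype, gene_class=gene_class, source=source))

    for gi in range(n):
        spacer()
        gene_class = classes[gi]
        fate = fates[gi]
        gid_a = f"gA{gi:04d}"
        gid_b = f"gB{gi:04d}"
        exon_lens, intron_lens = _gene_structure(rng, gene_class, fate)
        # element list: exon0, intron0, exon1, ...
        elements = []
        for k, el in enumerate(exon_lens):
            elements.append(("exon", _random_seq(rng, el)))
            if k < len(intron_lens):
                elements.append(("intron", _random_seq(rng, intron_lens[k])))
        gene_seq = "".join(s for _, s in elements)

        a0 = ga.append(A_CHR, gene_seq)
        # A exon coordinates
        a_exons, off = [], 0
        for kind, s in elements:
            if kind == "exon":
                a_exons.append((a0 + off, a0 + off + len(s)))
            off += len(s)
        if fate != "specific_b":
            add_gene_annotation(ann_a, gid_a, A_CHR, "+", a_exons, gene_class)
            truth.fate[gid_a] = fate
            truth.gene_class[gid_a] = gene_class

        if fate in ("ortholog", "specific_a", "specific_b"):
            b_seq = _mutate(rng, gene_seq, rate)
            b0 = gb.append(B_CHR, b_seq)
            cb.add_main(A_CHR, B_CHR, a0, b0, len(gene_seq))
            b_exons = [(b0 + (s - a0), b0 + (e - a0)) for s, e in a_exons]
            if fate != "specific_a":
                add_gene_annotation(ann_b, gid_b, B_CHR, "+", b_exons, gene_class)
                truth.gene_class[gid_b] = gene_class
            if fate == "ortholog":
                truth.ortholog_pairs.append((gid_a, gid_b))
            elif fate == "specific_a":
                truth.specific_a.append(gid_a)
            else:
                truth.specific_b.append(gid_b)
                truth.fate[gid_b] = fate

        elif fate == "inverted":
            b_seq = revcomp(_mutate(rng, gene_seq, rate))
            b0 = gb.append(B_CHR, b_seq)
            cb.flush_main()
            cb.add_chain(A_CHR, B_CHR, "-",
                         [ChainBlock(a0, a0 + len(gene_seq), b0, b0 + len(gene_seq))],
                         score=1e6)
            b_exons = [
                (b0 + (a0 + len(gene_seq) - e), b0 + (a0 + len(gene_seq) - s))
                for s, e in a_exons
            ]
            add_gene_annotation(ann_b, gid_b, B_CHR, "-", b_exons, gene_class)
            truth.gene_class[gid_b] = gene_class
            truth.ortholog_pairs.append((gid_a, gid_b))

        elif fate == "duplicate":
            b_seq = _mutate(rng, gene_seq, rate)
            b0 = gb.append(B_CHR, b_seq)
            cb.add_main(A_CHR, B_CHR, a0, b0, len(gene_seq))
            b_exons = [(b0 + (s - a0), b0 + (e - a0)) for s, e in a_exons]
            add_gene_annotation(ann_b, gid_b, B_CHR, "+", b_exons, gene_class)
            # dispersed second copy on chrB2, its own chain
            gb.append(B_CHR2, _random_seq(rng, int(rng.integers(400, 900))))
            b2_seq = _mutate(rng, gene_seq, rate)
            b2 = gb.append(B_CHR2, b2_seq)
            cb.add_chain(A_CHR, B_CHR2, "+",
                         [ChainBlock(a0, a0 + len(gene_seq), b2, b2 + len(gene_seq))],
                         score=5e5)
            gid_b2 = f"{gid_b}dup"
            b2_exons = [(b2 + (s - a0), b2 + (e - a0)) for s, e in a_exons]
            add_gene_annotation(ann_b, gid_b2, B_CHR2, "+", b2_exons, gene_class)
            truth.gene_class[gid_b] = gene_class
            truth.gene_class[gid_b2] = gene_class
            truth.duplicate_families.append((gid_a, [gid_b, gid_b2]))

        elif fate == "deleted":
            pass  # B lacks the locus entirely; main chain gap (dt only)

        elif fate in ("rearrange_rescue", "rearrange_fatal"):
            # permute exon order in B; every exon gets its own chain
            n_ex = len(exon_lens)
            if fate == "rearrange_rescue":
                perm = list(range(n_ex))
                perm[1], perm[2] = perm[2], perm[1]  # B order: e0 e2 e1 ...
            else:
                perm = [1, 0, 3, 2]
            cb.flush_main()
            exon_seqs = [s for kind, s in elements if kind == "exon"]
            b_positions: dict[int, tuple[int, int]] = {}
            for j, ex_idx in enumerate(perm):
                if j > 0:
                    gb.append(B_CHR, _random_seq(rng, 200))  # unaligned introns
                b_seq = _mutate(rng, exon_seqs[ex_idx], rate)
                b0 = gb.append(B_CHR, b_seq)
                b_positions[ex_idx] = (b0, b0 + len(b_seq))
            for ex_idx, (bs, be) in b_positions.items():
                a_s, a_e = a_exons[ex_idx]
                cb.add_chain(A_CHR, B_CHR, "+", [ChainBlock(a_s, a_e, bs, be)], score=1e5)
            b_exons = sorted(b_positions.values())
            add_gene_annotation(ann_b, gid_b, B_CHR, "+", b_exons, gene_class)
            truth.gene_class[gid_b] = gene_class
            if fate == "rearrange_rescue":
                truth.ortholog_pairs.append((gid_a, gid_b))
            else:
                truth.expected_losses.append(gid_a)

        elif fate == "consensus_rescue":
            # all but one exon syntenic; the smallest exon translocated to
            # chrB2 so the consensus (projected-base majority) stays on chrB1
            moved = int(np.argmin(exon_lens))
            off = 0
            b_exons = []
            for kind, s in elements:
                if kind == "exon":
                    ex_no = a_exons.index((a0 + off, a0 + off + len(s)))
                    if ex_no == moved:
                        gb.append(B_CHR2, _random_seq(rng, 300))
                        b2 = gb.append(B_CHR2, _mutate(rng, s, rate))
                        cb.add_chain(A_CHR, B_CHR2, "+",
                                     [ChainBlock(a0 + off, a0 + off + len(s), b2, b2 + len(s))],
                                     score=1e5)
                        off += len(s)
                        continue
                b0 = gb.append(B_CHR, _mutate(rng, s, rate))
                cb.add_main(A_CHR, B_CHR, a0 + off, b0, len(s))
                if kind == "exon":
                    b_exons.append((b0, b0 + len(s)))
                off += len(s)
            add_gene_annotation(ann_b, gid_b, B_CHR, "+", b_exons, gene_class)
            truth.gene_class[gid_b] = gene_class
            truth.ortholog_pairs.append((gid_a, gid_b))

        elif fate == "size_fail":
            # B copy carries a large internal insertion: span ratio > 3
            half = len(gene_seq) // 2
            ins = _random_seq(rng, 4 * len(gene_seq))
            b0 = gb.append(B_CHR, _mutate(rng, gene_seq[:half], rate))
            cb.add_main(A_CHR, B_CHR, a0, b0, half)
            gb.append(B_CHR, ins)
            b1 = gb.append(B_CHR, _mutate(rng, gene_seq[half:], rate))
            cb.add_main(A_CHR, B_CHR, a0 + half, b1, len(gene_seq) - half)
            add_gene_annotation(ann_b, gid_b, B_CHR, "+",
                                [(b0, b1 + len(gene_seq) - half)], gene_class)
            truth.gene_class[gid_b] = gene_class
            truth.expected_losses.append(gid_a)

        elif fate == "split":
            # breakpoint through the single exon: halves on different chroms
            half = len(gene_seq) // 2
            b0 = gb.append(B_CHR, _mutate(rng, gene_seq[:half], rate))
            cb.add_main(A_CHR, B_CHR, a0, b0, half)
            cb.flush_main()
            gb.append(B_CHR2, _random_seq(rng, 300))
            b2 = gb.append(B_CHR2, _mutate(rng, gene_seq[half:], rate))
            cb.add_chain(A_CHR, B_CHR2, "+",
                         [ChainBlock(a0 + half, a0 + len(gene_seq), b2,
                                     b2 + len(gene_seq) - half)],
                         score=1e5)
            truth.expected_losses.append(gid_a)

        else:  # pragma: no cover
            raise AssertionError(fate)

    spacer()
    cb.flush_main()

    seqs = {"speciesA": ga.sequences(), "speciesB": gb.sequences()}
    sizes_a = {c: len(s) for c, s in seqs["speciesA"].items()}
    sizes_b = {c: len(s) for c, s in seqs["speciesB"].items()}
    for chain in cb.chains:
        chain.t_size = sizes_b[chain.t_chrom]
    chain_ab = ChainMap(cb.chains)
    chain_ba = invert_chainmap(chain_ab, sizes_a)
    # inverse chains need t_size of the A genome for '-' strand bookkeeping
    for chain in chain_ba.chains:
        chain.t_size = sizes_a[chain.t_chrom]

    return SyntheticGenomes(config, seqs, {"speciesA": ann_a, "speciesB": ann_b},
                            chain_ab, chain_ba, truth)


def exonic_sequence(gene: GeneModel, chrom_seq: str) -> str:
    """Spliced exon-block sequence on the gene strand."""
    seq = "".join(chrom_seq[b.start:b.end] for b in exon_blocks(gene))
    return revcomp(seq) if gene.strand == "-" else seq


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sequences):
            fh.write(f">{chrom}\n")
            s = sequences[chrom]
            for i in range(0, len(s), 80):
                fh.write(s[i:i + 80] + "\n")


# ---------------------------------------------------------------------------
# planted filter-violation fixture


@dataclass
class FilterFixture:
    annotation: AnnotationSet
    locus_evidence: dict
    region_sets: dict
    coding_flags: dict
    junction_ok: dict
    expected_failures: dict[str, str]   # gene id -> the one filter it must fail


def filter_violation_fixture(n_samples: int = 9) -> FilterFixture:
    """Annotation planting exactly one violation per lncRNA selection filter.

    Every planted gene passes all other filters; `expected_failures` maps
    each violator to the single filter it must fail.  A block of clean
    candidate loci that pass everything is included as well.
    """
    from .lncrna_filter import LocusEvidence

    ann = AnnotationSet()
    evidence: dict[str, LocusEvidence] = {}
    region_sets = {"unmappable": [], "retrogenes": [], "trna": [], "rna_repeats": []}
    coding_flags: dict[str, str] = {}
    junction_ok: dict[str, bool] = {}
    expected: dict[str, str] = {}
    chrom = "chr1"
    cursor = [100_000]

    def clean_evidence(gid):
        evidence[gid] = LocusEvidence(
            gene_id=gid,
            unique_reads_per_sample=np.full(n_samples, 20),
            sense_antisense_ratio_per_sample=np.full(n_samples, 0.5),
        )

    def add(gid, exon_lens, intron_lens=(), source="novel", biotype="lincRNA",
            strand="+", gap=60_000):
        start = cursor[0]
        exons = []
        pos = start
        for k, el in enumerate(exon_lens):
            exons.append(GenomicInterval(chrom, pos, pos + el, strand))
            pos += el
            if k < len(intron_lens):
                pos += intron_lens[k]
        cursor[0] = pos + gap
        tx = TranscriptModel(f"{gid}.t1", gid, exons, biotype=biotype)
        ann.add(GeneModel(gid, [tx], biotype=biotype, gene_class="other", source=source))
        coding_flags[gid] = "candidate_noncoding"
        clean_evidence(gid)
        if len(exon_lens) > 1:
            junction_ok[gid] = True
        return ann[gid]

    # a distant protein-coding gene (same strand) as the 5-kb anchor
    pc = add("pc_anchor", [900, 900], [500], source="reference", biotype="protein_coding")
    coding_flags["pc_anchor"] = "protein_coding"

    for i in range(8):
        add(f"clean{i}", [300, 300], [400])

    # one violation per filter
    g = add("viol_length", [480])                       # monoexonic < 500 bp
    expected[g.id] = "exonic_length"

    g = add("viol_distance", [120, 100], [300], gap=0)  # placed 4.9 kb from a pc gene
    # reposition: build a same-strand pc gene 4,900 bp downstream of it
    pos = g.end + 4_900
    tx = TranscriptModel("pc_near.t1", "pc_near",
                         [GenomicInterval(chrom, pos, pos + 800, "+"),
                          GenomicInterval(chrom, pos + 1200, pos + 2000, "+")],
                         biotype="protein_coding")
    ann.add(GeneModel("pc_near", [tx], biotype="protein_coding", source="reference"))
    coding_flags["pc_near"] = "protein_coding"
    cursor[0] = pos + 2000 + 60_000
    expected[g.id] = "intergenic_distance"

    g = add("viol_unmappable", [400, 400], [300])       # 6% of exonic bases unmappable
    region_sets["unmappable"].append(GenomicInterval(chrom, g.start, g.start + 48))
    expected[g.id] = "unmappable"

    g = add("viol_junction", [300, 300], [400])
    junction_ok[g.id] = False
    expected[g.id] = "junction_support"

    g = add("viol_retro", [350, 350], [300])            # 55% of span over a retrogene
    span = g.end - g.start
    region_sets["retrogenes"].append(
        GenomicInterval(chrom, g.start, g.start + int(0.55 * span)))
    expected[g.id] = "retrogene_overlap"

    g = add("viol_trna", [300, 300], [400])
    region_sets["trna"].append(GenomicInterval(chrom, g.start + 10, g.start + 80))
    expected[g.id] = "trna_overlap"

    g = add("viol_repeat", [350, 350], [300])           # 30% of span over RNA repeats
    span = g.end - g.start
    region_sets["rna_repeats"].append(
        GenomicInterval(chrom, g.start, g.start + int(0.30 * span)))
    expected[g.id] = "repeat_overlap"

    g = add("viol_reads", [300, 300], [400])            # 9 reads in total
    evidence[g.id].unique_reads_per_sample = np.concatenate(
        [np.ones(min(9, n_samples), dtype=int),
         np.zeros(max(0, n_samples - 9), dtype=int)])
    expected[g.id] = "min_unique_reads"

    g = add("viol_ratio", [300, 300], [400])            # sense/antisense < 1% everywhere
    evidence[g.id].sense_antisense_ratio_per_sample = np.full(n_samples, 0.005)
    expected[g.id] = "sense_antisense_ratio"

    # antisense-overlapping locus whose two expression estimates disagree:
    # Spearman rho = 0.85 (n = 9, sum d^2 = 18: swap ranks 1 and 4)
    g = add("viol_concordance", [300, 300], [400])
    full = np.arange(1.0, n_samples + 1)
    nonov = full.copy()
    nonov[0], nonov[3] = nonov[3], nonov[0]
    evidence[g.id].full_tpm = full
    evidence[g.id].nonoverlap_tpm = nonov
    expected[g.id] = "antisense_concordance"

    # coding-flag violation: classified protein-coding upstream
    g = add("viol_coding", [300, 300], [400])
    coding_flags[g.id] = "protein_coding"
    expected[g.id] = "noncoding"

    return FilterFixture(ann, evidence, region_sets, coding_flags, junction_ok, expected)


# ---------------------------------------------------------------------------
# expression simulation


@dataclass
class SyntheticExpression:
    counts: dict[str, pd.DataFrame]
    tpm: dict[str, pd.DataFrame]
    meta: dict[str, pd.DataFrame]


def _stage_profile(shape: str, n_stages: int, effect: float) -> np.ndarray:
    t = np.linspace(0, 1, n_stages)
    if shape == "up":
        return effect ** t
    if shape == "down":
        return effect ** (1 - t)
    # peak at the middle stage
    return effect ** (1 - np.abs(2 * t - 1))


def simulate_expression(
    config: SimulationConfig,
    genomes: SyntheticGenomes,
    divergence_sd: float | None = None,
) -> SyntheticExpression:
    """Replicate count and TPM matrices for both species.

    Per-gene condition means combine a log-normal baseline (lncRNAs scaled
    down by `lnc_scale`), per-organ preferences, a testis bias for a
    fraction of lncRNAs, and stage profiles for DE genes; species-B means
    diverge by a log-normal factor of sd `divergence_sd`.  Replicates are
    negative-binomial.  Species-specific loci get zero counts in the off
    species (enforced by the planted homology: the locus is annotated in
    one species only).
    """
    rng = np.random.default_rng(config.seed + 1)
    div_sd = config.divergence_sd if divergence_sd is None else divergence_sd
    truth = genomes.truth
    stages = list(range(1, config.n_stages + 1))
    conditions = [(o, s) for o in config.organs for s in stages]

    # pair mapping for sharing expression programs between orthologs
    b_of_a = dict(truth.ortholog_pairs)

    counts, tpms, metas = {}, {}, {}
    programs: dict[str, dict] = {}

    def gene_program(gid_a: str, gene_class: str) -> dict:
        base = config.pc_mean * rng.lognormal(0, 1.0)
        if gene_class != "protein_coding":
            base *= config.lnc_scale
            base = max(base, 2.0)  # keep loci detectable
        organ_mult = rng.lognormal(0, config.organ_effect_sd, size=len(config.organs))
        if gene_class != "protein_coding" and rng.random() < config.testis_bias_fraction:
            organ_mult[list(config.organs).index("testes")] *= config.testis_bias
        de_shape = None
        if rng.random() < config.de_fraction:
            de_shape = str(rng.choice(["up", "down", "peak"]))
        stage_mult = (
            _stage_profile(de_shape, config.n_stages, config.de_effect)
            if de_shape else np.ones(config.n_stages)
        )
        return {"base": base, "organ": organ_mult, "stage": stage_mult, "shape": de_shape}

    for species in ("speciesA", "speciesB"):
        ann = genomes.annotations[species]
        gene_ids = sorted(ann.genes)
        lengths = np.array([exonic_length(ann[g]) for g in gene_ids], dtype=float)
        sample_ids, meta_rows = [], []
        for organ, stage in conditions:
            for rep in range(1, config.n_replicates + 1):
                sid = f"{species}_{organ}_s{stage}_r{rep}"
                sample_ids.append(sid)
                meta_rows.append((sid, species, organ, stage, rep))
        meta = pd.DataFrame(
            meta_rows, columns=["sample_id", "species", "organ", "stage", "replicate"]
        ).set_index("sample_id")

        mu = np.zeros((len(gene_ids), len(conditions)))
        for i, gid in enumerate(gene_ids):
            gene_class = truth.gene_class.get(gid, "protein_coding")
            if species == "speciesA":
                prog = programs.setdefault(gid, gene_program(gid, gene_class))
                div = 1.0
            else:
                # share the program with the A ortholog where one exists
                a_id = "gA" + gid[2:6] if gid.startswith("gB") else None
                if a_id in programs:
                    prog = programs[a_id]
                else:
                    prog = programs.setdefault(gid, gene_program(gid, gene_class))
                div = None  # per-condition divergence drawn below
            for j, (organ, stage) in enumerate(conditions):
                m = (prog["base"]
                     * prog["organ"][list(config.organs).index(organ)]
                     * prog["stage"][stage - 1])
                if species == "speciesB" and div_sd > 0:
                    m *= rng.lognormal(0, div_sd)
                mu[i, j] = m
            # planted species-specific loci must clear the 100-read support
            # rule comfortably in the on species
            if gid in truth.specific_a or gid in truth.specific_b:
                total = mu[i].sum() * config.n_replicates
                if total < 300:
                    mu[i] *= 300 / total
        if species == "speciesA":
            truth.de_genes = {
                g: programs[g]["shape"] for g in gene_ids
                if g in programs and programs[g]["shape"]
            }

        # replicate NB counts
        mat = np.zeros((len(gene_ids), len(sample_ids)), dtype=np.int64)
        col = 0
        for j, _cond in enumerate(conditions):
            for _rep in range(config.n_replicates):
                m = mu[:, j]
                if config.dispersion > 0:
                    size = 1.0 / config.dispersion
                    lam = rng.gamma(size, m / size)
                    mat[:, col] = rng.poisson(lam)
                else:
                    mat[:, col] = rng.poisson(m)
                col += 1
        count_df = pd.DataFrame(mat, index=gene_ids, columns=sample_ids)
        rate = mat / lengths[:, None]
        tpm_df = pd.DataFrame(
            1e6 * rate / rate.sum(axis=0, keepdims=True), index=gene_ids, columns=sample_ids
        )
        counts[species], tpms[species], metas[species] = count_df, tpm_df, meta
    return SyntheticExpression(counts, tpms, metas)


# ---------------------------------------------------------------------------
# conservation simulation


def simulate_conservation(config: SimulationConfig, genomes: SyntheticGenomes,
                          species: str = "speciesA"):
    """Per-base conservation track for one species.

    Baseline score everywhere; exons, promoters and splice sites of
    constrained genes (all protein-coding genes plus a planted fraction of
    lncRNAs) are boosted to the configured levels; unconstrained lncRNA
    exons sit slightly above baseline.
    """
    from .evolution import ConservationTrack
    from .gene_models import gene_splice_sites, promoter_region

    rng = np.random.default_rng(config.seed + 2)
    ann = genomes.annotations[species]
    sizes = genomes.chrom_sizes(species)
    paint = {c: np.full(n, config.baseline_score) for c, n in sizes.items()}
    lnc = sorted(g.id for g in ann if g.gene_class == "lncRNA")
    n_cons = int(round(config.conserved_lnc_fraction * len(lnc)))
    conserved_lnc = set(rng.choice(lnc, size=n_cons, replace=False)) if n_cons else set()
    genomes.truth.conserved_lnc = conserved_lnc

    for gene in ann:
        constrained = gene.gene_class == "protein_coding" or gene.id in conserved_lnc
        exon_score = (config.exon_boost if constrained else config.lnc_exon_score)
        for blk in exon_blocks(gene):
            paint[gene.chrom][blk.start:blk.end] = exon_score
        if constrained:
            prom, _ = promoter_region(gene)
            paint[gene.chrom][prom.start:prom.end] = config.promoter_boost
            for ss in gene_splice_sites(gene):
                paint[gene.chrom][ss.start:ss.end] = config.splice_boost

    intervals = {}
    for chrom, arr in paint.items():
        runs = []
        changes = np.flatnonzero(np.diff(arr)) + 1
        bounds = np.concatenate([[0], changes, [len(arr)]])
        for s, e in zip(bounds[:-1], bounds[1:]):
            runs.append((int(s), int(e), float(arr[s])))
        intervals[chrom] = runs
    return ConservationTrack(intervals)


# ---------------------------------------------------------------------------
# CSF training data simulation


def _random_coding_seq(rng, n_codons: int) -> str:
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


_SYNONYMS: dict[str, list[str]] = {}


def _synonyms(codon: str) -> list[str]:
    if not _SYNONYMS:
        from Bio.Data.CodonTable import standard_dna_table

        table = standard_dna_table.forward_table
        by_aa: dict[str, list[str]] = {}
        for c in SENSE_CODONS:
            by_aa.setdefault(table[c], []).append(c)
        for c in SENSE_CODONS:
            _SYNONYMS[c] = [x for x in by_aa[standard_dna_table.forward_table[c]] if x != c]
    return _SYNONYMS[codon]


def _evolve_coding(rng, seq: str, rate: float, synonymous_bias: float = 0.85) -> str:
    """Codon-level evolution: substitutions prefer synonymous codons and
    never introduce stops, preserving the reading frame."""
    out = []
    for k in range(0, len(seq), 3):
        codon = seq[k:k + 3]
        if rng.random() < rate * 3:
            syn = _synonyms(codon)
            if syn and rng.random() < synonymous_bias:
                codon = syn[rng.integers(0, len(syn))]
            else:
                codon = SENSE_CODONS[rng.integers(0, len(SENSE_CODONS))]
        out.append(codon)
    return "".join(out)


def simulate_csf_training(
    config: SimulationConfig,
    n_pairs: int = 80,
    pair_len_codons: int = 200,
    coding_rate: float = 0.15,
    neutral_rate: float = 0.25,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Aligned (reference, informant) pairs under coding and neutral
    evolution.  Coding pairs evolve per codon with a synonymous bias and no
    in-frame stops; neutral pairs under uniform base substitution."""
    rng = np.random.default_rng(config.seed + 3)
    coding, noncoding = [], []
    for _ in range(n_pairs):
        ref = _random_coding_seq(rng, pair_len_codons)
        coding.append((ref, _evolve_coding(rng, ref, coding_rate)))
    for _ in range(n_pairs):
        ref = _random_seq(rng, pair_len_codons * 3)
        noncoding.append((ref, _mutate(rng, ref, neutral_rate)))
    return coding, noncoding
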