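"""Determinism, internal consistency, and planted structure of the
synthetic fixtures."""

import numpy as np
import pandas as pd
import pytest

from lncevo.gene_models import exon_blocks, read_gtf, write_gtf
from lncevo.orthology import project_gene, read_chain, write_chain
from lncevo.synthetic import (
    SimulationConfig,
    exonic_sequence,
    filter_violation_fixture,
    simulate_conservation,
    simulate_csf_training,
    simulate_expression,
    simulate_genomes,
    write_fasta,
)


@pytest.fixture(scope="module")
def small_config():
    return SimulationConfig(seed=5, n_pc=30, n_lnc=30)


@pytest.fixture(scope="module")
def small_genomes(small_config):
    return simulate_genomes(small_config)


class TestDeterminism:
    def test_identical_seed_identical_outputs(self, small_config, small_genomes):
        again = simulate_genomes(SimulationConfig(seed=5, n_pc=30, n_lnc=30))
        assert again.sequences == small_genomes.sequences
        assert set(again.annotations["speciesB"].genes) == set(
            small_genomes.annotations["speciesB"].genes)
        assert again.truth.ortholog_pairs == small_genomes.truth.ortholog_pairs
        e1 = simulate_expression(small_config, small_genomes)
        e2 = simulate_expression(small_config, again)
        pd.testing.assert_frame_equal(e1.counts["speciesA"], e2.counts["speciesA"])
        pd.testing.assert_frame_equal(e1.tpm["speciesB"], e2.tpm["speciesB"])

    def test_different_seed_differs(self, small_genomes):
        other = simulate_genomes(SimulationConfig(seed=6, n_pc=30, n_lnc=30))
        assert other.sequences != small_genomes.sequences

    def test_infeasible_fractions_rejected(self):
        with pytest.raises(ValueError):
            simulate_genomes(SimulationConfig(duplicate_fraction=0.9,
                                              deleted_fraction=0.9))


class TestEmittedFiles:
    def test_fasta_gtf_chain_round_trip(self, small_genomes, tmp_path):
        from lncevo.synthetic import write_fasta

        gtf = tmp_path / "a.gtf"
        write_gtf(small_genomes.annotations["speciesA"], gtf)
        ann = read_gtf(gtf)
        assert set(ann.genes) == set(small_genomes.annotations["speciesA"].genes)
        for gid in ann.genes:
            assert exon_blocks(ann[gid]) == exon_blocks(
                small_genomes.annotations["speciesA"][gid])

        chain = tmp_path / "ab.chain"
        write_chain(small_genomes.chain_ab, chain,
                    small_genomes.chrom_sizes("speciesA"))
        cm = read_chain(chain)
        assert len(cm.chains) == len(small_genomes.chain_ab.chains)

        fa = tmp_path / "a.fa"
        write_fasta(small_genomes.sequences["speciesA"], fa)
        from Bio import SeqIO

        recs = {r.id: str(r.seq) for r in SeqIO.parse(str(fa), "fasta")}
        assert recs == small_genomes.sequences["speciesA"]

    def test_annotated_exons_inside_chromosomes(self, small_genomes):
        for sp in ("speciesA", "speciesB"):
            sizes = small_genomes.chrom_sizes(sp)
            for gene in small_genomes.annotations[sp]:
                assert gene.end <= sizes[gene.chrom]


class TestPlantedFailureModes:
    def test_every_projection_failure_mode_is_planted(self, genomes):
        """The default fixture exercises unmapped, ambiguous, split,
        size_fail, consensus rescue, order_fail, and '-' strand chains."""
        from lncevo.orthology import project_interval, size_ratio_filter

        truth = genomes.truth
        ann = genomes.annotations["speciesA"]
        by_fate: dict[str, list[str]] = {}
        for gid, fate in truth.fate.items():
            by_fate.setdefault(fate, []).append(gid)

        def block_statuses(gid):
            out = []
            for blk in exon_blocks(ann[gid]):
                bp = size_ratio_filter(project_interval(blk, genomes.chain_ab))
                out.append(bp.status)
            return out

        assert all(set(block_statuses(g)) == {"unmapped"}
                   for g in by_fate["deleted"])
        assert all(set(block_statuses(g)) == {"ambiguous"}
                   for g in by_fate["duplicate"])
        assert all("split" in block_statuses(g) for g in by_fate["split"])
        assert all("size_fail" in block_statuses(g) for g in by_fate["size_fail"])
        for g in by_fate["rearrange_fatal"]:
            gp = project_gene(ann[g], genomes.chain_ab)
            assert gp.status == "discarded" and gp.reason == "order_fail"
        for g in by_fate["rearrange_rescue"]:
            gp = project_gene(ann[g], genomes.chain_ab)
            assert gp.status == "projected"
            assert len(gp.blocks) == len(exon_blocks(ann[g])) - 1
        for g in by_fate["consensus_rescue"]:
            gp = project_gene(ann[g], genomes.chain_ab)
            assert gp.status == "projected"
            assert gp.consensus_chrom == "chrB1"
        for g in by_fate["inverted"]:
            gp = project_gene(ann[g], genomes.chain_ab)
            assert gp.status == "projected" and gp.consensus_strand == "-"

    def test_zero_event_zero_divergence_identity(self):
        cfg = SimulationConfig(
            seed=9, n_pc=10, n_lnc=10, substitution_rate=0.0,
            duplicate_fraction=0, deleted_fraction=0, rescue_fraction=0,
            fatal_fraction=0, consensus_fraction=0, inverted_fraction=0,
            size_fail_fraction=0, split_fraction=0, specific_fraction=0,
        )
        g = simulate_genomes(cfg)
        # genomes are identical up to chromosome naming; every gene projects
        # fully and orthology recovers every pair
        assert len(g.chain_ab.chains) == 1
        from lncevo.pipeline import run_orthology

        res = run_orthology(g)
        assert set(res.pairs) == set(g.truth.ortholog_pairs)
        for gid, proj in res.projections.items():
            assert proj.status == "projected"
            assert all(bp.fraction_remapped == 1.0 for bp in proj.blocks)

    def test_exonic_sequences_similar_for_orthologs(self, small_genomes):
        a, b = small_genomes.truth.ortholog_pairs[0]
        sa = exonic_sequence(small_genomes.annotations["speciesA"][a],
                             small_genomes.sequences["speciesA"]["chrA1"])
        ann_b = small_genomes.annotations["speciesB"][b]
        sb = exonic_sequence(ann_b, small_genomes.sequences["speciesB"][ann_b.chrom])
        assert len(sa) == len(sb)
        ident = sum(1 for x, y in zip(sa, sb) if x == y) / len(sa)
        assert ident > 0.9  # substitution rate 0.03


class TestExpressionSimulation:
    def test_metadata_design(self, small_config, small_genomes):
        expr = simulate_expression(small_config, small_genomes)
        meta = expr.meta["speciesA"]
        assert set(meta["organ"]) == set(small_config.organs)
        assert sorted(set(meta["stage"])) == [1, 2, 3]
        assert len(meta) == 4 * 3 * small_config.n_replicates

    def test_tpm_columns_sum_to_a_million(self, small_config, small_genomes):
        expr = simulate_expression(small_config, small_genomes)
        sums = expr.tpm["speciesA"].sum(axis=0)
        assert np.allclose(sums, 1e6)

    def test_species_specific_loci_silent_in_off_species(self, small_config,
                                                         small_genomes):
        expr = simulate_expression(small_config, small_genomes)
        truth = small_genomes.truth
        ann_b = small_genomes.annotations["speciesB"]
        for gid in truth.specific_a:
            # the locus exists only in A's annotation; its B counts simply
            # do not exist, and its A support clears the 100-read rule
            assert gid not in ann_b
            assert expr.counts["speciesA"].loc[gid].sum() >= 100

    def test_poisson_limit_at_zero_dispersion(self, small_genomes):
        cfg = SimulationConfig(seed=5, n_pc=30, n_lnc=30, dispersion=0.0)
        expr = simulate_expression(cfg, small_genomes)
        counts = expr.counts["speciesA"]
        meta = expr.meta["speciesA"]
        # within one condition, variance/mean over replicates ~ 1 on average
        cols = meta.index[(meta["organ"] == "brain") & (meta["stage"] == 1)]
        sub = counts[list(cols)]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        keep = m > 5
        ratio = (v[keep] / m[keep]).mean()
        assert 0.6 < ratio < 1.6

    def test_testis_bias_visible_for_lncrnas(self, small_config, small_genomes):
        expr = simulate_expression(small_config, small_genomes)
        meta = expr.meta["speciesA"]
        counts = expr.counts["speciesA"]
        lnc = [g for g in counts.index
               if small_genomes.truth.gene_class.get(g) == "lncRNA"]
        testes = meta.index[meta["organ"] == "testes"]
        soma = meta.index[meta["organ"] != "testes"]
        t = counts.loc[lnc, list(testes)].mean(axis=1)
        s = counts.loc[lnc, list(soma)].mean(axis=1)
        # a planted fraction of lncRNAs is testis-biased, so the median
        # testes/soma ratio across lncRNAs exceeds 1
        assert np.median((t + 1) / (s + 1)) > 1.0


class TestConservationSimulation:
    def test_boosted_regions_score_higher(self, small_config, small_genomes):
        from lncevo.evolution import region_conservation

        track = simulate_conservation(small_config, small_genomes)
        ann = small_genomes.annotations["speciesA"]
        truth = small_genomes.truth
        pc_scores, lnc_scores = [], []
        for gene in ann:
            score = region_conservation(track, exon_blocks(gene))
            if gene.gene_class == "protein_coding":
                pc_scores.append(score)
            elif gene.id not in truth.conserved_lnc:
                lnc_scores.append(score)
        assert np.median(pc_scores) > np.median(lnc_scores)
        assert np.median(pc_scores) == pytest.approx(small_config.exon_boost)

    def test_zero_boost_erases_group_differences(self, small_genomes):
        from lncevo.evolution import region_conservation

        cfg = SimulationConfig(
            seed=5, n_pc=30, n_lnc=30, exon_boost=0.07, promoter_boost=0.07,
            splice_boost=0.07, lnc_exon_score=0.07, baseline_score=0.07,
        )
        track = simulate_conservation(cfg, small_genomes)
        ann = small_genomes.annotations["speciesA"]
        scores = [region_conservation(track, exon_blocks(g)) for g in ann]
        assert np.allclose(scores, 0.07)

    def test_track_covers_every_annotated_base(self, small_config, small_genomes):
        track = simulate_conservation(small_config, small_genomes)
        ann = small_genomes.annotations["speciesA"]
        for gene in list(ann)[:20]:
            for blk in exon_blocks(gene):
                _total, n = track.sum_and_count(blk)
                assert n == len(blk)


class TestCsfTrainingSimulation:
    def test_zero_rate_gives_identical_pairs(self):
        cfg = SimulationConfig(seed=3)
        coding, noncoding = simulate_csf_training(cfg, n_pairs=5,
                                                  coding_rate=0.0,
                                                  neutral_rate=0.0)
        assert all(a == b for a, b in coding)
        assert all(a == b for a, b in noncoding)

    def test_coding_pairs_have_no_inframe_stops(self):
        cfg = SimulationConfig(seed=3)
        coding, _ = simulate_csf_training(cfg, n_pairs=20)
        stops = {"TAA", "TAG", "TGA"}
        for ref, informant in coding:
            for seq in (ref, informant):
                codons = {seq[k:k + 3] for k in range(0, len(seq), 3)}
                assert not codons & stops

    def test_labels_separable_by_trained_model(self):
        # cross-validated accuracy of the window sign on held-out pairs
        from lncevo.coding_potential import csf_window_scan, train_csf_model

        cfg = SimulationConfig(seed=3)
        coding, noncoding = simulate_csf_training(cfg)
        model = train_csf_model(coding[:40], noncoding[:40])
        correct = total = 0
        for pair, want_positive in [(p, True) for p in coding[40:60]] + [
                (p, False) for p in noncoding[40:60]]:
            for w in csf_window_scan(pair, model)["+"]:
                correct += (w.score > 0) == want_positive
                total += 1
        assert correct / total >= 0.9


class TestFilterFixture:
    def test_every_filter_has_a_planted_violation(self):
        fx = filter_violation_fixture()
        from lncevo.lncrna_filter import FILTER_NAMES

        planted = set(fx.expected_failures.values())
        assert planted == set(FILTER_NAMES)
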