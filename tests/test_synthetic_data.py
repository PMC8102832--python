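import numpy as np
import pytest

from exomirnet.synthetic_data import (
    AXIS_MIRNA_SEQ,
    SynthConfig,
    generate_study,
    make_worked_fixture,
    planted_module_graph,
)
from exomirnet.target_screen import seed_of

_COMP = str.maketrans("ACGU", "UGCA")


class TestDeterminism:
    def test_same_config_same_seed_identical_bundles(self, tmp_path):
        cfg = SynthConfig(n_mirnas=60, n_genes=100, n_rescued_down=8, n_rescued_up=10,
                          n_consistent_down=2, n_consistent_up=6, seed=3)
        b1, t1 = generate_study(cfg)
        b2, t2 = generate_study(cfg)
        assert t1.planted_pairs == t2.planted_pairs
        assert b1.exo_counts.values.equals(b2.exo_counts.values)
        assert b1.utr_seqs == b2.utr_seqs
        (b1.write(tmp_path / "a"), b2.write(tmp_path / "b"))
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_different_seeds_differ(self):
        b1, _ = generate_study(SynthConfig(n_mirnas=60, n_genes=100, n_rescued_down=8,
                                           n_rescued_up=10, n_consistent_down=2,
                                           n_consistent_up=6, seed=3))
        b2, _ = generate_study(SynthConfig(n_mirnas=60, n_genes=100, n_rescued_down=8,
                                           n_rescued_up=10, n_consistent_down=2,
                                           n_consistent_up=6, seed=4))
        assert not b1.exo_counts.values.equals(b2.exo_counts.values)


class TestConfigValidation:
    def test_more_planted_than_mirnas_rejected(self):
        with pytest.raises(ValueError, match="planted"):
            generate_study(SynthConfig(n_mirnas=50, n_rescued_down=40, n_rescued_up=40))

    def test_sub_threshold_effect_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            SynthConfig(mrna_lfc=1.0).validate()

    def test_weak_planted_correlation_rejected(self):
        with pytest.raises(ValueError, match="0.6"):
            SynthConfig(corr_strength=0.5).validate()


class TestGroundTruthStructure:
    def test_default_planted_sizes(self, default_study):
        _, truth = default_study
        assert len(truth.reversed_down_mirnas) == 56
        assert len(truth.reversed_up_mirnas) == 60
        assert len(truth.consistent_demirs) == 36
        assert sum(d == "down" for d in truth.consistent_demirs.values()) == 6
        assert len(truth.planted_module) == 12
        assert len(truth.pathway_genes) == 9
        assert len(truth.pathway_genes | truth.planted_module) == 15

    def test_axis_is_a_planted_pair_in_the_module(self, default_study):
        _, truth = default_study
        assert truth.planted_axis in truth.planted_pairs
        assert truth.planted_axis[1] in truth.planted_module

    def test_pair_directions_oppose(self, default_study):
        _, truth = default_study
        for m, g in truth.planted_pairs:
            assert truth.consistent_demirs[m] != truth.gene_direction[g]


class TestSequences:
    def test_axis_utr_contains_8mer_by_substring_scan(self, default_study):
        bundle, truth = default_study
        axis_mirna, axis_gene = truth.planted_axis
        site = seed_of(bundle.mirna_seqs[axis_mirna]).translate(_COMP)[::-1] + "A"
        assert site in bundle.utr_seqs[axis_gene]
        assert site == "GCACUUUA"  # reverse complement of the axis seed, plus A

    def test_axis_mirna_uses_reference_sequence(self, default_study):
        bundle, truth = default_study
        assert bundle.mirna_seqs[truth.planted_axis[0]] == AXIS_MIRNA_SEQ

    def test_nontarget_utrs_free_of_strong_sites(self, small_study):
        bundle, truth = small_study
        planted_genes = {g for _, g in truth.planted_pairs}
        seeds = [seed_of(bundle.mirna_seqs[m]) for m in truth.consistent_demirs]
        r7s = [s.translate(_COMP)[::-1] for s in seeds]
        for g, utr in bundle.utr_seqs.items():
            if g not in planted_genes:
                assert not any(r7 in utr for r7 in r7s)


class TestDifferentialTables:
    def test_core_genes_sign_consistent_across_datasets(self, default_study):
        bundle, truth = default_study
        for recs in bundle.mrna_tables.values():
            for rec in recs:
                if rec.feature_id in truth.gene_direction and rec.feature_id in {
                    g for _, g in truth.planted_pairs
                }:
                    if abs(rec.log2fc) >= 2.0 and rec.p <= 0.01:
                        continue
                    pytest.fail(f"planted gene {rec.feature_id} below thresholds")

    def test_proteome_overlaps_transcriptome_core(self, default_study):
        bundle, truth = default_study
        mrna_genes = {r.feature_id for recs in bundle.mrna_tables.values() for r in recs}
        protein_planted = [r.feature_id for r in bundle.protein_table
                           if r.feature_id in truth.gene_direction]
        assert any(g in mrna_genes for g in protein_planted)
        assert any(g not in mrna_genes for g in protein_planted)


class TestCorrelationStructure:
    def test_planted_r_matches_strength_at_n_1000(self):
        cfg = SynthConfig(n_corr_samples=1000, seed=21)
        bundle, truth = generate_study(cfg)
        for m, g in sorted(truth.planted_pairs):
            x = bundle.mirna_expr.values.loc[m].to_numpy()
            y = bundle.gene_expr.values.loc[g].to_numpy()
            r = np.corrcoef(x, y)[0, 1]
            assert abs(r - (-cfg.corr_strength)) <= 0.05


class TestPlantedModuleGraph:
    def test_edge_probabilities_respected(self):
        nodes = [f"n{i}" for i in range(40)]
        module = nodes[:15]
        edges = planted_module_graph(nodes, module, p_in=1.0, p_out=0.0, rng=0)
        inside = {frozenset((a, b)) for a, b, _ in edges}
        assert len(inside) == 15 * 14 // 2
        assert all(a in module and b in module for a, b, _ in edges)


class TestWorkedFixtures:
    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            make_worked_fixture("nope")

    def test_fig3_component_sizes(self, fig3_fixture):
        assert len(fig3_fixture["demirs"]) == 36
        assert len(fig3_fixture["genes_up"]) == 42
        assert len(fig3_fixture["genes_down"]) == 196

    def test_hub_union_printed_list_sizes(self, hub_fixture):
        assert len(hub_fixture["pathway_genes"]) == 9
        assert len(hub_fixture["module_genes"]) == 12
        assert len(hub_fixture["mirnas"]) == 21
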