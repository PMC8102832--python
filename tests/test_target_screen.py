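import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exomirnet.de_screen import ConsistentDEmiR
from exomirnet.io_formats import DifferentialRecord
from exomirnet.synthetic_data import AXIS_MIRNA_SEQ
from exomirnet.target_screen import (
    SITE_WEIGHTS,
    SeedMatch,
    TargetPrediction,
    find_seed_sites,
    opposite_trend_filter,
    predict_targets,
    score_target,
    seed_of,
)

_COMP = str.maketrans("ACGU", "UGCA")


def _rc(s):
    return s.translate(_COMP)[::-1]


def brute_force_sites(mirna_seq, utr):
    """Independent position-by-position scan used as the oracle."""
    seed = mirna_seq[1:8]
    r7, r6 = _rc(seed), _rc(seed[:6])
    out = []
    for i in range(len(utr)):
        if utr[i : i + 7] == r7:
            if utr[i + 7 : i + 8] == "A":
                out.append(("8mer", i, i + 8))
            else:
                out.append(("7mer-m8", i, i + 7))
        if utr[i : i + 6] == r6 and not (i >= 1 and utr[i - 1 : i + 6] == r7):
            if utr[i + 6 : i + 7] == "A":
                out.append(("7mer-A1", i, i + 7))
            else:
                out.append(("6mer", i, i + 6))
    return sorted(out, key=lambda t: (t[1], t[0]))


def _rand_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


class TestSeedOf:
    def test_canonical_mature_mirna(self):
        assert seed_of("UAAAGUGCUUAUAGUGCAGGUAG") == "AAAGUGC"

    def test_positional_definition(self):
        assert seed_of("UUUUUUUU") == "UUUUUUU"

    def test_equals_brute_force_slice(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            s = _rand_rna(rng, 22)
            assert seed_of(s) == s[1:8]

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="8 nt"):
            seed_of("ACGUACG")


class TestFindSeedSites:
    def test_axis_8mer_site_detected(self):
        utr = "CCGG" + "GCACUUUA" + "GGCC"
        sites = find_seed_sites(AXIS_MIRNA_SEQ, utr)
        assert [s.site_type for s in sites] == ["8mer"]
        assert (sites[0].utr_start, sites[0].utr_end) == (4, 12)

    def test_no_complement_no_sites(self):
        assert find_seed_sites(AXIS_MIRNA_SEQ, "AAAAAAAAAA") == []

    def test_7mer_m8_without_flanking_a(self):
        sites = find_seed_sites(AXIS_MIRNA_SEQ, "GCACUUUG")
        assert [s.site_type for s in sites] == ["7mer-m8"]

    def test_7mer_a1_and_6mer(self):
        # r6 for the axis seed (AAAGUG) is CACUUU
        sites = find_seed_sites(AXIS_MIRNA_SEQ, "GGCACUUUAGG")
        # GCACUUU absent... G CACUUU A: r7=GCACUUU IS present at 1
        assert [s.site_type for s in sites] == ["8mer"]
        sites = find_seed_sites(AXIS_MIRNA_SEQ, "UUCACUUUAUU")
        assert [s.site_type for s in sites] == ["7mer-A1"]
        sites = find_seed_sites(AXIS_MIRNA_SEQ, "UUCACUUUUUU")
        assert [s.site_type for s in sites] == ["6mer"]

    def test_matches_exhaustive_oracle_on_random_draws(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            mirna = _rand_rna(rng, 22)
            utr = _rand_rna(rng, 200)
            got = [(s.site_type, s.utr_start, s.utr_end)
                   for s in find_seed_sites(mirna, utr)]
            assert got == brute_force_sites(mirna, utr)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGU", min_size=8, max_size=25),
           st.text(alphabet="ACGU", min_size=0, max_size=120))
    def test_property_matches_oracle(self, mirna, utr):
        got = [(s.site_type, s.utr_start, s.utr_end)
               for s in find_seed_sites(mirna, utr)]
        assert got == brute_force_sites(mirna, utr)


def _site(site_type):
    length = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}[site_type]
    return SeedMatch("m", "g", site_type, 0, length)


class TestScore:
    def test_single_8mer_clears_threshold(self):
        assert score_target([_site("8mer")]) == pytest.approx(0.9)

    def test_empty_site_list_scores_zero(self):
        assert score_target([]) == 0.0

    def test_hand_evaluated_combination(self):
        # 1 - (1 - 0.75)(1 - 0.3)
        assert score_target([_site("7mer-m8"), _site("6mer")]) == pytest.approx(0.825)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(list(SITE_WEIGHTS)), max_size=8),
           st.sampled_from(list(SITE_WEIGHTS)))
    def test_adding_a_site_never_lowers_score(self, types, extra):
        sites = [_site(t) for t in types]
        assert score_target(sites + [_site(extra)]) >= score_target(sites) - 1e-12

    def test_8mer_dominates_single_site_types(self):
        assert all(score_target([_site("8mer")]) >= score_target([_site(t)])
                   for t in SITE_WEIGHTS)


def _demir(mirna, direction):
    lfc = 2.0 if direction == "up" else -2.0
    return ConsistentDEmiR(
        mirna, direction,
        DifferentialRecord(mirna, "exosome_mirna", "e", lfc),
        DifferentialRecord(mirna, "tissue_mirna", "t", lfc, p=0.001),
    )


class TestPredictTargets:
    def test_unattainable_threshold_empty(self, small_study):
        bundle, truth = small_study
        mirnas = sorted(truth.consistent_demirs)
        assert predict_targets(mirnas, bundle.mirna_seqs, bundle.utr_seqs,
                               threshold=1.1) == []

    def test_missing_sequence_listed(self):
        with pytest.raises(ValueError, match="ghost-mir"):
            predict_targets(["ghost-mir"], {}, {"g": "ACGUACGU"})

    def test_planted_pairs_retained_and_clean_utrs_excluded(self, small_study):
        bundle, truth = small_study
        demirs = [_demir(m, d) for m, d in truth.consistent_demirs.items()]
        preds = predict_targets(demirs, bundle.mirna_seqs, bundle.utr_seqs)
        got = {(p.mirna_id, p.gene_id) for p in preds}
        assert truth.planted_pairs <= got
        planted_genes = {g for _, g in truth.planted_pairs}
        strong = {(p.mirna_id, p.gene_id) for p in preds
                  if any(s.site_type in ("8mer", "7mer-m8") for s in p.sites)}
        # strong-site predictions outside planted genes are impossible:
        # non-target UTRs are rejection-sampled free of 7mer-m8/8mer sites
        assert all(g in planted_genes for _, g in strong)

    def test_axis_pair_scores_above_threshold(self, small_study):
        bundle, truth = small_study
        demirs = [_demir(m, d) for m, d in truth.consistent_demirs.items()]
        preds = {(p.mirna_id, p.gene_id): p
                 for p in predict_targets(demirs, bundle.mirna_seqs, bundle.utr_seqs)}
        axis = preds[truth.planted_axis]
        assert axis.score >= 0.7
        assert any(s.site_type == "8mer" for s in axis.sites)


class TestOppositeTrendFilter:
    def test_fig3_layer_sizes(self, fig3_fixture):
        f = fig3_fixture
        cand = opposite_trend_filter(
            f["demirs"], f["predictions"], f["mrna_tables"], f["protein_table"]
        )
        assert cand.n_transcriptome == 233
        assert len(cand.all_genes) == 238
        assert cand.n_proteome == 8
        assert cand.n_both == 3
        assert len(cand.genes_up) == 42     # 40 transcripts + 2 proteome-only
        assert len(cand.genes_down) == 196  # 193 transcripts + 3 proteome-only

    def test_inclusion_exclusion_identity(self, fig3_fixture):
        f = fig3_fixture
        cand = opposite_trend_filter(
            f["demirs"], f["predictions"], f["mrna_tables"], f["protein_table"]
        )
        assert cand.n_transcriptome + cand.n_proteome - cand.n_both == len(cand.all_genes)

    def test_sign_inconsistent_gene_excluded(self):
        demirs = [_demir("m-down", "down")]
        preds = [TargetPrediction("m-down", "G1", 0.9, source="external")]
        tables = {
            f"ds{i}": [DifferentialRecord("G1", "mrna", f"ds{i}", 2.5, p=0.001)]
            for i in range(3)
        }
        tables["ds3"] = [DifferentialRecord("G1", "mrna", "ds3", -2.5, p=0.001)]
        cand = opposite_trend_filter(demirs, preds, tables, [])
        assert cand.all_genes == set()

    def test_min_support_relaxation(self):
        demirs = [_demir("m-down", "down")]
        preds = [TargetPrediction("m-down", "G1", 0.9, source="external")]
        tables = {
            "ds0": [DifferentialRecord("G1", "mrna", "ds0", 2.5, p=0.001)],
            "ds1": [DifferentialRecord("G1", "mrna", "ds1", 0.5, p=0.5)],
        }
        assert opposite_trend_filter(demirs, preds, tables, [], min_support="all").all_genes == set()
        assert opposite_trend_filter(demirs, preds, tables, [], min_support=1).genes_up == {"G1"}

    def test_direction_must_oppose_a_regulator(self):
        # gene up but only targeted by an up miRNA: not a candidate
        demirs = [_demir("m-up", "up")]
        preds = [TargetPrediction("m-up", "G1", 0.9, source="external")]
        tables = {"ds0": [DifferentialRecord("G1", "mrna", "ds0", 2.5, p=0.001)]}
        assert opposite_trend_filter(demirs, preds, tables, []).all_genes == set()

    def test_empty_predictions_warn(self):
        with pytest.warns(UserWarning, match="empty prediction"):
            cand = opposite_trend_filter([], [], {}, [])
        assert cand.all_genes == set()

    def test_candidates_oppose_at_least_one_regulator(self, small_study):
        bundle, truth = small_study
        demirs = [_demir(m, d) for m, d in truth.consistent_demirs.items()]
        preds = predict_targets(demirs, bundle.mirna_seqs, bundle.utr_seqs)
        cand = opposite_trend_filter(demirs, preds, bundle.mrna_tables,
                                     bundle.protein_table)
        dir_of = {d.mirna_id: d.direction for d in demirs}
        regulators = {}
        for p in preds:
            regulators.setdefault(p.gene_id, set()).add(dir_of[p.mirna_id])
        for g in cand.genes_up:
            assert "down" in regulators[g]
        for g in cand.genes_down:
            assert "up" in regulators[g]
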