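import numpy as np
import pandas as pd
import pytest

from drugfunnel.connectivity import score_compounds
from drugfunnel.errors import ConfigError
from drugfunnel.evidence import classify_evidence
from drugfunnel.synthetic import (
    ORA_CHANNELS,
    SimConfig,
    drug_names,
    gen_drug_target_map,
    gen_evidence_registry,
    gen_expression_dataset,
    gen_gene_universe,
    gen_geneset_collections,
    gen_rank_profiles,
    load_reference_fixture,
)


class TestSimConfig:
    def test_risk_larger_than_universe_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(n_genes=10, n_true_risk=11)

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(druggable_fraction=1.2)

    def test_from_dict_rejects_unknown_keys(self):
        with pytest.raises(ConfigError, match="unknown"):
            SimConfig.from_dict({"n_genez": 10})


class TestGeneUniverse:
    def test_counts_and_labels(self):
        universe, risk = gen_gene_universe(SimConfig(seed=1, n_genes=895, n_true_risk=318))
        assert len(universe) == 895
        assert len(set(universe)) == 895
        assert len(risk) == 318
        assert risk <= set(universe)

    def test_empty_planting(self):
        universe, risk = gen_gene_universe(SimConfig(n_genes=10, n_true_risk=0))
        assert len(universe) == 10 and risk == set()

    def test_saturation(self):
        universe, risk = gen_gene_universe(SimConfig(n_genes=50, n_true_risk=50))
        assert risk == set(universe)

    def test_deterministic_under_seed(self):
        cfg = SimConfig(seed=42, n_genes=100, n_true_risk=30)
        assert gen_gene_universe(cfg) == gen_gene_universe(cfg)
        other = gen_gene_universe(cfg.with_seed(43))
        assert other[1] != gen_gene_universe(cfg)[1]


class TestGenesetCollections:
    def test_structure(self, small_cfg):
        universe, risk = gen_gene_universe(small_cfg)
        collections = gen_geneset_collections(small_cfg, universe, risk)
        assert set(collections) == set(ORA_CHANNELS)
        for collection in collections.values():
            assert len(collection) == small_cfg.n_sets_per_channel
            enriched = [n for n in collection.sets if "_E" in n]
            assert len(enriched) == small_cfg.n_enriched_per_channel
            for members in collection.sets.values():
                assert members <= collection.annotation_universe

    def test_zero_sets_valid(self):
        cfg = SimConfig(n_genes=50, n_true_risk=10, n_sets_per_channel=0, n_enriched_per_channel=0)
        universe, risk = gen_gene_universe(cfg)
        collections = gen_geneset_collections(cfg, universe, risk)
        assert all(len(c) == 0 for c in collections.values())

    def test_infeasible_set_size_rejected(self):
        cfg = SimConfig(n_genes=5, n_true_risk=2, set_size_range=(10, 200), background_multiplier=1)
        universe, risk = gen_gene_universe(cfg)
        with pytest.raises(ConfigError, match="set_size_range"):
            gen_geneset_collections(cfg, universe, risk)

    def test_deterministic(self, small_cfg):
        universe, risk = gen_gene_universe(small_cfg)
        first = gen_geneset_collections(small_cfg, universe, risk)
        second = gen_geneset_collections(small_cfg, universe, risk)
        for channel in first:
            assert first[channel].sets == second[channel].sets


class TestExpressionDataset:
    def test_shape_and_labels(self):
        cfg = SimConfig(seed=2, n_genes=120, n_true_risk=0)
        universe, _ = gen_gene_universe(cfg)
        matrix = gen_expression_dataset(cfg, universe, set(), n_normal=61, n_tumor=69)
        assert matrix.values.shape == (120, 130)
        assert (matrix.groups == "tumor").sum() == 69

    def test_planted_shift(self):
        cfg = SimConfig(seed=2, n_genes=200, n_true_risk=50, effect_size=3.0, noise_sd=0.4)
        universe, risk = gen_gene_universe(cfg)
        up = set(sorted(risk)[:25])
        matrix = gen_expression_dataset(cfg, universe, up, n_normal=30, n_tumor=30)
        diff = matrix.samples_in("tumor").mean(axis=1) - matrix.samples_in("normal").mean(axis=1)
        assert diff.loc[sorted(up)].mean() == pytest.approx(3.0, abs=0.2)
        others = [g for g in universe if g not in up]
        assert diff.loc[others].mean() == pytest.approx(0.0, abs=0.2)

    def test_too_few_samples_rejected(self):
        cfg = SimConfig(n_genes=10, n_true_risk=0)
        universe, _ = gen_gene_universe(cfg)
        with pytest.raises(ConfigError, match=">= 2 samples"):
            gen_expression_dataset(cfg, universe, set(), n_normal=1, n_tumor=5)

    def test_up_genes_must_be_in_universe(self):
        cfg = SimConfig(n_genes=10, n_true_risk=0)
        universe, _ = gen_gene_universe(cfg)
        with pytest.raises(ConfigError, match="subset"):
            gen_expression_dataset(cfg, universe, {"ALIEN"}, n_normal=3, n_tumor=3)


class TestDrugTargetMap:
    def test_druggable_fraction_honored(self, small_cfg):
        universe, risk = gen_gene_universe(small_cfg)
        table = gen_drug_target_map(small_cfg, universe, risk)
        druggable = set(table["target"]) & risk
        expected = round(small_cfg.druggable_fraction * len(risk))
        assert len(druggable) == expected
        assert set(table["drug"]) == set(drug_names(small_cfg))

    def test_zero_fraction_gives_no_risk_targets(self, small_cfg):
        cfg = SimConfig(**{**small_cfg.__dict__, "druggable_fraction": 0.0})
        universe, risk = gen_gene_universe(cfg)
        table = gen_drug_target_map(cfg, universe, risk)
        assert set(table["target"]) & risk == set()
        assert (table.groupby("drug").size() >= 1).all()

    def test_pairs_unique(self, small_cfg):
        universe, risk = gen_gene_universe(small_cfg)
        table = gen_drug_target_map(small_cfg, universe, risk)
        assert not table.duplicated(["drug", "target"]).any()

    def test_first_drugs_are_approved_with_risk_target(self, small_cfg):
        universe, risk = gen_gene_universe(small_cfg)
        table = gen_drug_target_map(small_cfg, universe, risk)
        for drug in drug_names(small_cfg)[: small_cfg.correlated_compounds]:
            rows = table.loc[table["drug"] == drug]
            assert (rows["status"] == "approved").all()
            assert len(set(rows["target"]) & risk) >= 1


class TestRankProfiles:
    def test_reference_cell_lines_present(self, small_cfg):
        profile_set = gen_rank_profiles(small_cfg)
        cell_lines = {
            p.cell_line for p in profile_set.profiles if p.compound == profile_set.reference_name
        }
        assert cell_lines == {"A549", "MCF7", "PC3"}

    def test_rankings_are_bijections(self, small_cfg):
        profile_set = gen_rank_profiles(small_cfg)
        for profile in profile_set.profiles[:5]:
            ranks = np.sort(profile.ranking.to_numpy())
            np.testing.assert_array_equal(ranks, np.arange(1, len(profile) + 1))

    def test_zero_transposition_compound_identical_to_reference(self, small_cfg):
        profile_set = gen_rank_profiles(small_cfg)
        by_key = {(p.compound, p.cell_line): p for p in profile_set.profiles}
        reference = by_key[(profile_set.reference_name, "MCF7")]
        first = by_key[(profile_set.correlated_names[0], "MCF7")]
        pd.testing.assert_series_equal(first.ranking, reference.ranking, check_names=False)

    def test_identical_clone_attains_tau_100(self, small_cfg):
        profile_set = gen_rank_profiles(small_cfg)
        results = score_compounds(
            profile_set.profiles,
            profile_set.reference_name,
            q=100,
            background_compounds=profile_set.touchstone_names,
        ).set_index("compound")
        assert results.loc[profile_set.correlated_names[0], "tau"] == pytest.approx(100.0)

    def test_duplicate_compound_names_rejected(self, small_cfg):
        with pytest.raises(ConfigError, match="duplicate"):
            gen_rank_profiles(small_cfg, compounds=["a", "a"])

    def test_deterministic(self, small_cfg):
        first = gen_rank_profiles(small_cfg)
        second = gen_rank_profiles(small_cfg)
        for p1, p2 in zip(first.profiles, second.profiles):
            assert p1.compound == p2.compound
            assert (p1.ranking == p2.ranking).all()


class TestEvidenceRegistry:
    def test_every_drug_registered(self, small_cfg):
        drugs = drug_names(small_cfg)
        registry = gen_evidence_registry(small_cfg, drugs)
        assert registry.drugs() == sorted(drugs)
        levels = {classify_evidence(d, registry)[0] for d in drugs}
        assert levels <= {"Phase 1", "Phase 2", "Phase 3", "Phase 4", "preclinical", "none"}

    def test_empty_drugs_rejected(self, small_cfg):
        with pytest.raises(ConfigError):
            gen_evidence_registry(small_cfg, [])


class TestReferenceFixture:
    def test_candidate_table_shape(self, fixture_data):
        assert len(fixture_data.candidate_table) == 13
        assert len(fixture_data.top_genes) == 12

    def test_known_record(self, fixture_data):
        row = fixture_data.candidate_table.set_index("drug").loc["Clomifene"]
        assert row["score"] == pytest.approx(97.84)
        assert row["target"] == "ESR1"

    def test_scores_in_range(self, fixture_data):
        scores = fixture_data.candidate_table["score"]
        assert ((scores > -100) & (scores <= 100)).all()

    def test_thresholds(self, fixture_data):
        assert fixture_data.thresholds == {
            "fdr": 0.05, "logfc_min": 2.0, "score_min": 2, "tau_min": 80.0,
        }

    def test_evidence_registry_split(self, fixture_data):
        registry = fixture_data.evidence_registry()
        levels = [classify_evidence(d, registry)[0] for d in fixture_data.candidate_table["drug"]]
        assert sum(level.startswith("Phase") for level in levels) == 8
        assert levels.count("preclinical") == 2
        assert levels.count("none") == 3

    def test_indicator_universe_consistent(self, fixture_data):
        universe, indicators = fixture_data.channel_indicators()
        assert len(universe) == len(set(universe))
        assert set(fixture_data.top_genes) <= set(universe)
        for vec in indicators.values():
            assert list(vec.index) == universe

    def test_loader_is_deterministic(self):
        first = load_reference_fixture()
        second = load_reference_fixture()
        pd.testing.assert_frame_equal(first.candidate_table, second.candidate_table)
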