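"""Generator contracts: group sizes, determinism, the walk-time cap, and
calibration of planted expression/serum effects."""

import numpy as np
import pandas as pd
import pytest

from frailmark.simulate import (
    ConfigurationError, KBComposition, PlantedMarker, SerumSpec, SimConfig,
    generate_cohort, generate_expression, generate_knowledge_base, generate_serum,
)


def _corr(x, y):
    return float(np.corrcoef(np.asarray(x, float), np.asarray(y, float))[0, 1])


class TestCohort:
    def test_group_sizes_match_config(self, small_cohort):
        counts = small_cohort.groupby(["sex", "age_group"]).size()
        assert counts[("F", "old")] == 24
        assert counts[("M", "old")] == 28
        assert counts[("F", "young")] == 13
        assert counts[("M", "young")] == 13

    def test_empty_config_gives_empty_cohort(self):
        cfg = SimConfig(n_old_female=0, n_old_male=0, n_young_female=0, n_young_male=0, n_genes=5)
        assert len(generate_cohort(cfg)) == 0

    def test_same_seed_reproduces_cohort_exactly(self, small_config):
        pd.testing.assert_frame_equal(generate_cohort(small_config), generate_cohort(small_config))

    def test_young_participants_have_no_test_values(self, small_cohort):
        young = small_cohort[small_cohort["age_group"] == "young"]
        assert young[["walk400", "gait4", "chair5"]].isna().all().all()

    def test_walk_cap_is_exact_ceiling(self):
        cfg = SimConfig(n_old_female=200, n_old_male=0, n_young_female=0, n_young_male=0,
                        n_genes=5, walk_cap_seconds=330.0, seed=3)
        cohort = generate_cohort(cfg)
        walks = cohort["walk400"].dropna()
        assert (walks <= 330.0).all()
        assert (walks == 330.0).any()  # slow walkers sit exactly at the cap
        assert (cohort[["gait4", "chair5"]].dropna() > 0).all().all()

    def test_test_times_share_latent_factor(self, small_cohort):
        old = small_cohort[small_cohort["age_group"] == "old"]
        assert _corr(old["walk400"], old["gait4"]) > 0.2
        assert _corr(old["walk400"], old["chair5"]) > 0.2

    def test_invalid_counts_name_the_field(self):
        with pytest.raises(ConfigurationError, match="n_old_female"):
            SimConfig(n_old_female=-1)

    def test_fried_scores_within_range(self, small_cohort):
        assert small_cohort["fried_score"].between(0, 5).all()


class TestExpression:
    def test_matrix_dimensions(self, small_config, small_cohort, small_expression):
        assert small_expression.shape == (small_config.n_genes, len(small_cohort))

    def test_empty_cohort_gives_zero_columns(self):
        cfg = SimConfig(n_old_female=0, n_old_male=0, n_young_female=0, n_young_male=0, n_genes=7)
        expr = generate_expression(generate_cohort(cfg), cfg)
        assert expr.shape == (7, 0)

    def test_null_genes_have_small_correlations_at_large_n(self):
        cfg = SimConfig(n_old_female=1000, n_old_male=0, n_young_female=0, n_young_male=0,
                        n_genes=200, seed=5)
        cohort = generate_cohort(cfg)
        expr = generate_expression(cohort, cfg)
        y = cohort["gait4"]
        rs = np.array([_corr(expr.loc[g], y) for g in expr.index])
        # null sampling SD of r is ~1/sqrt(n-1) ~ 0.032; |r| < 0.1 is ~3 SD
        assert (np.abs(rs) < 0.1).mean() >= 0.99

    def test_planted_gene_hits_strong_target(self):
        cfg = SimConfig(n_old_female=1000, n_old_male=0, n_young_female=0, n_young_male=0,
                        n_genes=5, planted_markers=(PlantedMarker("G00000", "F", "chair5", 0.9),),
                        seed=6)
        cohort = generate_cohort(cfg)
        expr = generate_expression(cohort, cfg)
        r = _corr(expr.loc["G00000"], cohort["chair5"])
        assert r == pytest.approx(0.9, abs=0.05)

    def test_planted_calibration_within_3se(self):
        cfg = SimConfig(n_old_female=2000, n_old_male=0, n_young_female=0, n_young_male=0,
                        n_genes=6,
                        planted_markers=(
                            PlantedMarker("G00000", "F", "walk400", 0.6),
                            PlantedMarker("G00001", "F", "gait4", -0.75),
                        ),
                        seed=7)
        cohort = generate_cohort(cfg)
        expr = generate_expression(cohort, cfg)
        assert _corr(expr.loc["G00000"], cohort["walk400"]) == pytest.approx(0.6, abs=0.04)
        assert _corr(expr.loc["G00001"], cohort["gait4"]) == pytest.approx(-0.75, abs=0.04)

    def test_no_cross_sex_leakage(self):
        cfg = SimConfig(n_old_female=500, n_old_male=500, n_young_female=0, n_young_male=0,
                        n_genes=5, planted_markers=(PlantedMarker("G00000", "F", "gait4", 0.8),),
                        seed=8)
        cohort = generate_cohort(cfg)
        expr = generate_expression(cohort, cfg)
        males = cohort[cohort["sex"] == "M"].index
        r_m = _corr(expr.loc["G00000", males], cohort.loc[males, "gait4"])
        assert abs(r_m) < 0.15

    def test_unknown_planted_gene_rejected_by_config(self):
        with pytest.raises(ConfigurationError, match="n_genes"):
            SimConfig(n_genes=0, planted_markers=(PlantedMarker("X", "F", "gait4", 0.5),))


class TestSerum:
    def test_concentrations_positive_and_deterministic(self, small_config, small_cohort):
        s1 = generate_serum(small_cohort, small_config)
        s2 = generate_serum(small_cohort, small_config)
        assert (s1 > 0).all().all()
        pd.testing.assert_frame_equal(s1, s2)

    def test_null_marker_uncorrelated_with_tests(self):
        cfg = SimConfig(n_old_female=1000, n_old_male=0, n_young_female=0, n_young_male=0,
                        n_genes=5, serum_markers=(SerumSpec("S", sex_effect="none"),), seed=9)
        cohort = generate_cohort(cfg)
        serum = generate_serum(cohort, cfg)
        for test in ("walk400", "gait4", "chair5"):
            assert abs(_corr(serum["S"], cohort[test])) < 0.1

    def test_zero_shifts_give_equal_group_means(self):
        cfg = SimConfig(n_old_female=500, n_old_male=0, n_young_female=500, n_young_male=0,
                        n_genes=5, serum_markers=(SerumSpec("S"),), seed=10)
        cohort = generate_cohort(cfg)
        serum = generate_serum(cohort, cfg)
        old = serum.loc[cohort["age_group"] == "old", "S"]
        young = serum.loc[cohort["age_group"] == "young", "S"]
        assert np.log(old).mean() == pytest.approx(np.log(young).mean(), abs=0.1)

    def test_female_effect_is_female_specific(self):
        cfg = SimConfig(n_old_female=1000, n_old_male=1000, n_young_female=0, n_young_male=0,
                        n_genes=5,
                        serum_markers=(SerumSpec("S", sex_effect="F",
                                                 standardized_shift_per_tertile=1.0),),
                        seed=12)
        cohort = generate_cohort(cfg)
        serum = generate_serum(cohort, cfg)
        f = cohort["sex"] == "F"
        assert _corr(serum.loc[f, "S"], cohort.loc[f, "gait4"]) > 0.2
        assert abs(_corr(serum.loc[~f, "S"], cohort.loc[~f, "gait4"])) < 0.1


class TestKnowledgeBase:
    def test_all_pass_composition(self):
        comp = KBComposition(
            mean_records_per_gene=50.0,  # Poisson(50): zero-record genes vanishingly rare
            population={"Adult": 1.0}, sample_type={"Serum": 1.0},
            validity={"Early studies in humans": 1.0},
            conditions={"Sarcopenia": 1.0}, roles={"Risk factor": 1.0},
        )
        cfg = SimConfig(n_genes=30, kb_composition=comp, seed=13)
        kb, truth = generate_knowledge_base(cfg.gene_ids(), cfg)
        assert truth["n_qualified"] == 30
        assert truth["n_described"] == 30

    def test_empty_composition_gives_no_records(self):
        cfg = SimConfig(n_genes=10, kb_composition=KBComposition(mean_records_per_gene=0.0), seed=14)
        kb, truth = generate_knowledge_base(cfg.gene_ids(), cfg)
        assert len(kb) == 0 and truth["n_qualified"] == 0

    def test_empty_gene_list_rejected(self):
        cfg = SimConfig(n_genes=5)
        with pytest.raises(ConfigurationError):
            generate_knowledge_base([], cfg)

    def test_ground_truth_counts_self_consistent(self):
        cfg = SimConfig(n_genes=200, seed=15)
        kb, truth = generate_knowledge_base(cfg.gene_ids(), cfg)
        assert truth["n_described"] == len(set(kb["gene_symbol"]))
        assert set(truth["qualified_genes"]) <= set(truth["described_genes"])
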