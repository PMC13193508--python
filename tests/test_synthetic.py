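import numpy as np
import pandas as pd
import pytest

from hopikit.freelist import standardize_all
from hopikit.identification import score_table
from hopikit.lexicon import MACRO_CATEGORIES
from hopikit.salience import item_salience, top_k_salient
from hopikit.synthetic import (
    FixationSpec,
    GeneratorConfig,
    GroupSpec,
    MaskSpec,
    default_scenario,
    generate_fixation_table,
    generate_freelists,
    generate_identification_responses,
    generate_object_masks,
    rubric_probabilities,
)


def small_config(lexicon, seed=7, **group_kwargs):
    defaults = dict(
        n_respondents=30,
        weights={"plant": 0.3, "animal": 0.2, "human_nonliving": 0.5},
        mean_list_length=6.0,
        specific_plant_boost=1.0,
    )
    defaults.update(group_kwargs)
    prominence = {c: 1.0 for c in sorted(lexicon.macro_map) if lexicon.macro_of(c) in MACRO_CATEGORIES}
    return GeneratorConfig(
        seed=seed,
        lexicon=lexicon,
        prominence=prominence,
        groups={"g": GroupSpec(name="g", **defaults)},
        fixation=FixationSpec(group="g"),
    )


class TestConfigValidation:
    def test_weights_must_sum_to_one(self, scene_lexicon):
        with pytest.raises(ValueError, match="sum"):
            small_config(scene_lexicon, weights={"plant": 0.5, "animal": 0.2, "human_nonliving": 0.5})

    def test_lambda_incompatible_with_roster(self, scene_lexicon):
        with pytest.raises(ValueError, match="incompatible"):
            small_config(scene_lexicon, mean_list_length=1e6)

    def test_nonpositive_prominence_rejected(self, scene_lexicon):
        cfg = small_config(scene_lexicon)
        with pytest.raises(ValueError, match="prominence"):
            GeneratorConfig(
                seed=1,
                lexicon=scene_lexicon,
                prominence={**cfg.prominence, "tree": 0.0},
                groups=cfg.groups,
            )

    def test_roster_object_must_be_canonical(self, scene_lexicon):
        cfg = small_config(scene_lexicon)
        with pytest.raises(ValueError, match="canonical"):
            GeneratorConfig(
                seed=1,
                lexicon=scene_lexicon,
                prominence={**cfg.prominence, "martian": 1.0},
                groups=cfg.groups,
            )


class TestFreeLists:
    def test_fixed_seed_identical_output(self, scene_lexicon):
        a, _ = generate_freelists(small_config(scene_lexicon, seed=11))
        b, _ = generate_freelists(small_config(scene_lexicon, seed=11))
        assert a == b

    def test_different_seed_differs(self, scene_lexicon):
        a, _ = generate_freelists(small_config(scene_lexicon, seed=11))
        b, _ = generate_freelists(small_config(scene_lexicon, seed=12))
        assert a != b

    def test_degenerate_plant_weights_yield_only_plants(self, scene_lexicon):
        cfg = small_config(
            scene_lexicon, weights={"plant": 1.0, "animal": 0.0, "human_nonliving": 0.0}
        )
        lists, _ = generate_freelists(cfg)
        std = standardize_all(lists, scene_lexicon)
        assert all(item.macro_category == "plant" for sl in std for item in sl.items)

    def test_lists_have_valid_lengths_and_unique_canonicals(self, scene_lexicon):
        cfg = small_config(scene_lexicon)
        lists, _ = generate_freelists(cfg)
        std = standardize_all(lists, scene_lexicon)
        for sl in std:
            assert 1 <= sl.L <= len(cfg.prominence)
            assert len(set(sl.canonicals())) == sl.L  # PL sampling w/o replacement

    def test_aliases_standardize_back_to_roster(self, scenario, scene_lexicon):
        lists, _ = generate_freelists(scenario, groups=["expert"])
        std = standardize_all(lists, scene_lexicon)
        roster = set(scenario.roster)
        for sl in std:
            assert set(sl.canonicals()) <= roster
            assert all(item.flag != "unmapped" for item in sl.items)

    def test_salience_recovers_prominence_order(self, scene_lexicon):
        # graded prominence within one category -> salience should rank-match
        prominence = {}
        animals = scene_lexicon.objects_in("animal")
        for i, a in enumerate(animals):
            prominence[a] = 0.05 + i * 0.25
        cfg = GeneratorConfig(
            seed=5,
            lexicon=scene_lexicon,
            prominence=prominence,
            groups={
                "g": GroupSpec(
                    name="g",
                    n_respondents=400,
                    weights={"plant": 0.0, "animal": 1.0, "human_nonliving": 0.0},
                    mean_list_length=6.0,
                )
            },
        )
        lists, truth = generate_freelists(cfg)
        table = item_salience(standardize_all(lists, scene_lexicon), roster=cfg.roster)
        from scipy.stats import spearmanr

        rho, _ = spearmanr(
            [prominence[a] for a in animals], [table.loc[a, "salience"] for a in animals]
        )
        assert rho >= 0.9


class TestIdentification:
    def test_rubric_probability_family_mean(self):
        for m in (0.0, 0.3, 1.5, 2.55, 3.0):
            probs = rubric_probabilities(m)
            assert probs.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.dot(probs, np.arange(4)) == pytest.approx(m, abs=1e-12)

    def test_certain_success_scores_all_threes(self, scene_lexicon, scene_key):
        cfg = small_config(scene_lexicon)
        cfg.identification_group = "g"
        cfg.identification_means = {"spruce": 3.0}
        resp = generate_identification_responses(cfg, scene_key)
        assert (resp["level"] == 3).all()

    def test_uniform_rubric_mean_near_1_5(self, scene_lexicon, scene_key):
        # Binomial(3, 1/2) has mean 1.5; with n=10000 draws the standard
        # error of the mean is ~0.0087 so 0.03 is a ~3.5 sigma band
        cfg = small_config(scene_lexicon)
        cfg.groups["g"].n_respondents = 10_000
        cfg.identification_group = "g"
        cfg.identification_means = {"spruce": 1.5}
        resp = generate_identification_responses(cfg, scene_key)
        assert resp["level"].mean() == pytest.approx(1.5, abs=0.03)

    def test_missing_taxon_rejected(self, scene_lexicon, scene_key):
        cfg = small_config(scene_lexicon)
        cfg.identification_group = "g"
        cfg.identification_means = {"unicorn": 2.0}
        with pytest.raises(KeyError, match="unicorn"):
            generate_identification_responses(cfg, scene_key)


class TestFixations:
    def test_zero_weight_objects_never_fixated(self, scene_lexicon):
        cfg = small_config(
            scene_lexicon, weights={"plant": 0.5, "animal": 0.0, "human_nonliving": 0.5}
        )
        fx = generate_fixation_table(cfg)
        animals = set(scene_lexicon.objects_in("animal"))
        sub = fx[fx["object"].isin(animals)]
        assert (sub["n_fix"] == 0).all()
        assert sub["ttff_s"].isna().all()

    def test_viewing_time_cap_holds_per_respondent(self, scene_lexicon):
        cfg = small_config(scene_lexicon)
        cfg.fixation.duration_mean_s = 0.6  # push totals over the cap
        fx = generate_fixation_table(cfg)
        totals = fx.groupby("respondent")["tfd_s"].sum()
        assert (totals <= cfg.fixation.exposure_s).all()

    def test_ttff_within_exposure_window(self, scene_lexicon):
        fx = generate_fixation_table(small_config(scene_lexicon))
        assert (fx["ttff_s"].dropna() <= 30.0).all()
        assert (fx["ttff_s"].dropna() >= 0.0).all()

    def test_determinism(self, scene_lexicon):
        a = generate_fixation_table(small_config(scene_lexicon, seed=3))
        b = generate_fixation_table(small_config(scene_lexicon, seed=3))
        pd.testing.assert_frame_equal(a, b)


class TestMasks:
    def test_rectangle_ground_truth_is_analytic(self):
        specs = [MaskSpec("sq", "rectangle", (0, 0, 49, 49))]
        _, masks, truth = generate_object_masks(specs, (100, 100))
        assert truth["sq"] == 2500
        from hopikit.object_area import count_nonbackground_pixels

        assert count_nonbackground_pixels(masks[0][1]) == 2500

    def test_forced_overlap_detected_downstream(self):
        specs = [
            MaskSpec("a", "rectangle", (0, 0, 19, 19)),
            MaskSpec("b", "rectangle", (10, 10, 29, 29)),
        ]
        _, masks, _ = generate_object_masks(specs, (50, 50))
        from hopikit.object_area import compute_area_table

        table, _ = compute_area_table((50, 50), masks)
        assert table.loc["b", "overlap_pixels"] == 100

    def test_empty_roster_gives_blank_scene(self):
        scene, masks, truth = generate_object_masks([], (40, 30))
        assert masks == [] and truth == {}
        assert np.asarray(scene).sum() == 0

    def test_shape_exceeding_canvas_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            generate_object_masks([MaskSpec("big", "rectangle", (0, 0, 100, 10))], (50, 50))

    def test_ellipse_truth_matches_counter(self):
        specs = [MaskSpec("e", "ellipse", (5, 5, 44, 34))]
        _, masks, truth = generate_object_masks(specs, (60, 40))
        from hopikit.object_area import count_nonbackground_pixels

        assert count_nonbackground_pixels(masks[0][1]) == truth["e"]


class TestDefaultScenario:
    def test_mirrors_study_sample_sizes(self, scenario):
        n = {g.name: g.n_respondents for g in scenario.groups.values()}
        assert n == {
            "middle_school": 427,
            "naturparkschule": 388,
            "expert": 66,
            "pilot": 218,
            "eyetracking": 80,
        }
        assert len(scenario.roster) == 71

    def test_round_trip_top_k_contains_top_prominence_animals(self, scenario, scene_lexicon):
        lists, _ = generate_freelists(scenario, groups=["pilot"])
        table = item_salience(standardize_all(lists, scene_lexicon), roster=scenario.roster)
        top = top_k_salient(table, "animal", 3)
        by_prom = sorted(
            (o for o in scenario.roster if scene_lexicon.macro_of(o) == "animal"),
            key=lambda o: -scenario.prominence[o],
        )
        assert set(top.index) <= set(by_prom[:6])
        assert by_prom[0] in set(top.index)  # the most prominent animal surfaces

    def test_expert_lists_more_specific_than_students(self, scenario, scene_lexicon):
        from hopikit.salience import specificity_group_means, specificity_salience

        lists, _ = generate_freelists(scenario, groups=["expert", "middle_school"])
        means = specificity_group_means(
            specificity_salience(standardize_all(lists, scene_lexicon))
        )
        assert means.loc["expert", "specific"] > means.loc["middle_school", "specific"]
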