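"""Trait schema, plumage scoring, diagnostic selection, cohort keys."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vetkey import morphology as morph
from vetkey import synthetic as syn
from vetkey.morphology import (
    COHORTS,
    HYBRID,
    MALLARD,
    MEXICAN_DUCK,
    CohortKey,
    PlumageScore,
    TraitDef,
    TraitSchema,
)


def _record(schema, cohort="MA", sample_id="x", **levels):
    rec = {"sample_id": sample_id, "cohort": cohort}
    for t in schema.plumage_traits(cohort):
        rec[t.name] = levels.get(t.name, 0)
    return pd.Series(rec)


class TestSchema:
    def test_packaged_trait_counts(self, schema):
        assert len(schema.plumage_traits()) == 16
        assert len(schema.structural_traits()) == 7

    def test_green_head_maximum_ordinal(self, schema):
        assert schema["percent_green_in_head"].max_ordinal == 3

    def test_three_level_traits(self, schema):
        for name in ("rump", "central_tail_feather_curl", "undertail_covert_pattern"):
            assert schema[name].max_ordinal == 2

    def test_ordinal_gap_rejected(self):
        with pytest.raises(ValueError, match="consecutive"):
            TraitSchema(traits=[TraitDef(name="t", kind="plumage",
                                         levels=[(0, "a"), (2, "b")])])

    def test_duplicate_names_rejected(self):
        t = TraitDef(name="t", kind="plumage", levels=[(0, "a"), (1, "b")])
        with pytest.raises(ValueError, match="duplicate"):
            TraitSchema(traits=[t, t])

    def test_cohort_maxima(self, schema):
        # independent walk over the packaged table
        assert schema.max_ps("MA") == 21
        assert schema.max_ps("MI") == 21
        assert schema.max_ps("FI") == 15
        assert schema.max_ps("FA") == 11


class TestScoring:
    def test_all_null_adult_female_scores_zero(self, schema):
        s = morph.score_plumage(_record(schema, "FA"), schema)
        assert s.ps == 0 and s.n_missing == 0

    def test_adult_male_maximum_is_21(self, schema):
        levels = {t.name: t.max_ordinal for t in schema.plumage_traits("MA")}
        s = morph.score_plumage(_record(schema, "MA", **levels), schema)
        assert s.ps == 21

    def test_three_intermediate_traits_score_three(self, schema):
        s = morph.score_plumage(
            _record(schema, "MA", percent_green_in_head=1,
                    central_tail_feather_curl=1, rump=1), schema)
        assert s.ps == 3

    def test_missing_traits_contribute_zero_and_are_counted(self, schema):
        rec = _record(schema, "FA")
        rec["flank_feather_pattern"] = np.nan
        s = morph.score_plumage(rec, schema)
        assert s.ps == 0 and s.n_missing == 1

    def test_out_of_range_state_names_the_trait(self, schema):
        rec = _record(schema, "FA", flank_feather_pattern=5)
        with pytest.raises(ValueError, match="flank_feather_pattern"):
            morph.score_plumage(rec, schema)

    @given(st.data())
    @settings(max_examples=25, deadline=None)
    def test_ps_monotone_in_any_single_trait(self, data):
        schema = morph.load_trait_schema()
        cohort = data.draw(st.sampled_from(COHORTS))
        traits = schema.plumage_traits(cohort)
        levels = {t.name: data.draw(st.integers(0, t.max_ordinal)) for t in traits}
        rec = _record(schema, cohort, **levels)
        base = morph.score_plumage(rec, schema).ps
        bump = data.draw(st.sampled_from(traits))
        if levels[bump.name] < bump.max_ordinal:
            rec[bump.name] = levels[bump.name] + 1
            assert morph.score_plumage(rec, schema).ps >= base


class TestOrdination:
    def test_separable_classes_disjoint_on_pc1(self, schema):
        cfg = syn.default_config(1)
        cfg.trait_model.panel_sizes = {(MEXICAN_DUCK, "FA"): 40, (MALLARD, "FA"): 40}
        panel = syn.simulate_trait_panel(cfg, schema)
        scores, evr, used = morph.plumage_pca(panel, schema)
        pc1 = pd.Series(scores[:, 0], index=panel["true_trait_class"])
        a, b = pc1.loc[MEXICAN_DUCK], pc1.loc[MALLARD]
        assert a.max() < b.min() or b.max() < a.min()

    def test_identical_records_zero_variance(self, schema):
        panel = pd.DataFrame([_record(schema, "FA", sample_id=f"s{i}")
                              for i in range(5)])
        scores, evr, _ = morph.plumage_pca(panel, schema)
        assert np.allclose(evr, 0.0)

    def test_single_record_rejected(self, schema):
        panel = pd.DataFrame([_record(schema, "FA")])
        with pytest.raises(ValueError):
            morph.plumage_pca(panel, schema)


class TestStructuralAnova:
    def test_type_one_error_controlled_under_null(self, schema):
        rng = np.random.default_rng(0)
        alpha = 0.01
        false_hits = 0
        n_sims = 200
        for _ in range(n_sims):
            records = pd.DataFrame({
                "cohort": "MA",
                "tarsus_length": rng.normal(44, 1.0, 60),
            })
            labels = pd.Series(rng.permutation(np.repeat(["a", "b", "c"], 20)),
                               index=records.index)
            out = morph.structural_tests(records, labels, schema, alpha=alpha)
            anova = out[out["comparison"] == "anova"]
            false_hits += int(anova["significant"].any())
        assert false_hits / n_sims <= 0.05

    def test_large_shift_detected(self, schema):
        rng = np.random.default_rng(1)
        records = pd.DataFrame({
            "cohort": "MA",
            "mass": np.concatenate([rng.normal(950, 50, 30), rng.normal(1150, 50, 30)]),
        })
        labels = pd.Series(np.repeat([MEXICAN_DUCK, MALLARD], 30), index=records.index)
        out = morph.structural_tests(records, labels, schema, alpha=0.001)
        anova = out[(out["comparison"] == "anova") & (out["trait"] == "mass")]
        assert anova["significant"].all()

    def test_constant_trait_flagged(self, schema):
        records = pd.DataFrame({"cohort": "MA", "bill_length": np.full(20, 55.0)})
        labels = pd.Series(np.repeat(["a", "b"], 10), index=records.index)
        out = morph.structural_tests(records, labels, schema)
        row = out[(out["trait"] == "bill_length") & (out["comparison"] == "anova")]
        assert row["note"].iloc[0] == "constant trait"
        assert not row["significant"].iloc[0]


class TestDiagnosticSelection:
    def test_perfectly_separating_trait_selected_alone(self, schema):
        rng = np.random.default_rng(2)
        rows = []
        for i in range(40):
            cls = MEXICAN_DUCK if i < 20 else MALLARD
            rec = _record(schema, "FA", sample_id=f"s{i}")
            rec["speculum_color"] = 0 if cls == MEXICAN_DUCK else 1
            # other traits are pure noise
            for t in schema.plumage_traits("FA"):
                if t.name != "speculum_color":
                    rec[t.name] = int(rng.integers(0, t.max_ordinal + 1))
            rows.append(rec)
        records = pd.DataFrame(rows)
        labels = pd.Series([MEXICAN_DUCK] * 20 + [MALLARD] * 20, index=records.index)
        selected, axis = morph.select_diagnostic_traits(records, labels, "FA", schema)
        assert selected == ["speculum_color"]

    def test_selection_stable_under_appended_noise_traits(self, schema):
        cfg = syn.default_config(3)
        cfg.trait_model.panel_sizes = {(MEXICAN_DUCK, "FA"): 30, (MALLARD, "FA"): 30}
        panel = syn.simulate_trait_panel(cfg, schema)
        labels = panel["true_trait_class"]
        base_sel, _ = morph.select_diagnostic_traits(panel, labels, "FA", schema)
        noise_defs = [TraitDef(name=f"noise_{k}", kind="plumage",
                               levels=[(0, "a"), (1, "b")]) for k in range(2)]
        wide = TraitSchema(traits=schema.traits + noise_defs)
        rng = np.random.default_rng(4)
        stable = 0
        for rep in range(5):
            noisy = panel.copy()
            for d in noise_defs:
                noisy[d.name] = rng.integers(0, 2, len(noisy))
            sel, _ = morph.select_diagnostic_traits(noisy, labels, "FA", wide)
            stable += sel == base_sel
        assert stable >= 4  # pure-noise traits do not enter the subset

    def test_needs_two_classes(self, schema):
        panel = pd.DataFrame([_record(schema, "FA", sample_id=f"s{i}") for i in range(6)])
        labels = pd.Series([MEXICAN_DUCK] * 6, index=panel.index)
        with pytest.raises(ValueError, match="2 genetic classes"):
            morph.select_diagnostic_traits(panel, labels, "FA", schema)


@pytest.fixture(scope="module")
def calibrated(schema):
    cfg = syn.default_config(5)
    panel = syn.simulate_trait_panel(cfg, schema)
    scores = morph.score_panel(panel, schema).set_index("sample_id")
    labels = panel.set_index("sample_id")["true_trait_class"]
    keys = {c: morph.build_key(scores, labels, c, schema) for c in COHORTS}
    return panel, scores, labels, keys


class TestKeys:
    def test_mexican_duck_interval_capped_at_four_in_every_cohort(self, calibrated):
        _, _, _, keys = calibrated
        for cohort, key in keys.items():
            assert key.intervals[MEXICAN_DUCK] == (0, 4)

    def test_intervals_partition_the_ps_range(self, calibrated, schema):
        _, _, _, keys = calibrated
        for cohort, key in keys.items():
            covered = sorted(v for lo, hi in key.intervals.values()
                             for v in range(lo, hi + 1))
            assert covered == list(range(0, schema.max_ps(cohort) + 1))

    def test_overlapping_ranges_merge_classes(self, schema):
        scores = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(6)],
            "cohort": "FA",
            "ps": [0, 2, 6, 9, 8, 11],
            "n_missing": 0,
        }).set_index("sample_id")
        labels = pd.Series([MEXICAN_DUCK, MEXICAN_DUCK, HYBRID, HYBRID,
                            MALLARD, MALLARD], index=scores.index)
        key = morph.build_key(scores, labels, "FA", schema)
        assert morph.HYBRID_MALLARD in key.intervals

    def test_disjoint_ranges_give_three_classes(self, schema):
        scores = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(6)],
            "cohort": "FA",
            "ps": [0, 2, 6, 7, 10, 11],
            "n_missing": 0,
        }).set_index("sample_id")
        labels = pd.Series([MEXICAN_DUCK, MEXICAN_DUCK, HYBRID, HYBRID,
                            MALLARD, MALLARD], index=scores.index)
        key = morph.build_key(scores, labels, "FA", schema)
        assert key.intervals == {MEXICAN_DUCK: (0, 4), HYBRID: (5, 7),
                                 MALLARD: (8, 11)}

    @pytest.mark.parametrize("ps, expected", [
        (4, MEXICAN_DUCK), (0, MEXICAN_DUCK), (5, HYBRID),
    ])
    def test_boundary_classification(self, schema, ps, expected):
        key = CohortKey(cohort="FA", diagnostic_traits=[],
                        intervals={MEXICAN_DUCK: (0, 4), HYBRID: (5, 9),
                                   MALLARD: (10, 11)})
        score = PlumageScore("x", "FA", ps, [], 0)
        assert morph.classify(score, key) == expected

    def test_cohort_mismatch_rejected(self, schema):
        key = CohortKey(cohort="FA", diagnostic_traits=[],
                        intervals={MEXICAN_DUCK: (0, 4), HYBRID: (5, 11)})
        with pytest.raises(ValueError, match="cohort"):
            morph.classify(PlumageScore("x", "MA", 3, [], 0), key)

    def test_classification_monotone_in_ps(self, schema):
        key = CohortKey(cohort="FA", diagnostic_traits=[],
                        intervals={MEXICAN_DUCK: (0, 4), HYBRID: (5, 9),
                                   MALLARD: (10, 11)})
        rank = {MEXICAN_DUCK: 0, HYBRID: 1, MALLARD: 2}
        prev = -1
        for ps in range(0, 12):
            r = rank[morph.classify(PlumageScore("x", "FA", ps, [], 0), key)]
            assert r >= prev
            prev = r

    def test_key_rebuild_idempotent_on_classified_panel(self, calibrated, schema):
        _, scores, labels, keys = calibrated
        preds = morph.classify_panel(scores.reset_index(), keys)
        # where the key produced a definite class, rebuilding from those labels
        # reproduces the same intervals
        keys2 = {c: morph.build_key(scores, preds, c, schema) for c in COHORTS
                 if morph.HYBRID_MALLARD not in keys[c].intervals}
        for c, k2 in keys2.items():
            assert k2.intervals == keys[c].intervals


class TestEvaluation:
    def test_perfect_predictions(self):
        labels = pd.Series([MEXICAN_DUCK, MALLARD], index=["a", "b"])
        out = morph.evaluate_key(labels.copy(), labels)
        assert out["accuracy"] == 1.0

    def test_immature_male_accuracy_matches_configured_overflow(self, schema):
        cfg = syn.default_config(6)
        cfg.trait_model.panel_sizes = dict(cfg.trait_model.panel_sizes)
        cfg.trait_model.panel_sizes[(MEXICAN_DUCK, "MI")] = 600
        panel = syn.simulate_trait_panel(cfg, schema)
        scores = morph.score_panel(panel, schema).set_index("sample_id")
        labels = panel.set_index("sample_id")["true_trait_class"]
        keys = {c: morph.build_key(scores, labels, c, schema) for c in COHORTS}
        preds = morph.classify_panel(scores.reset_index(), keys)
        mi = scores.index[(scores["cohort"] == "MI") & (labels == MEXICAN_DUCK)]
        acc = (preds.loc[mi] == MEXICAN_DUCK).mean()
        # binomial(600, 0.97): 4 sigma ~ 0.028
        assert acc == pytest.approx(0.97, abs=0.03)

    def test_shuffled_labels_fall_to_prior_baseline(self, schema):
        cfg = syn.default_config(7)
        panel = syn.simulate_trait_panel(cfg, schema)
        scores = morph.score_panel(panel, schema).set_index("sample_id")
        labels = panel.set_index("sample_id")["true_trait_class"]
        keys = {c: morph.build_key(scores, labels, c, schema) for c in COHORTS}
        preds = morph.classify_panel(scores.reset_index(), keys)
        rng = np.random.default_rng(0)
        shuffled = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
        acc = morph.evaluate_key(preds, shuffled)["accuracy"]
        prior = (labels.value_counts(normalize=True) ** 2).sum()
        assert acc == pytest.approx(prior, abs=0.08)

    def test_disjoint_ids_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            morph.evaluate_key(pd.Series({"a": MALLARD}), pd.Series({"b": MALLARD}))


class TestReassessment:
    def test_all_null_specimens_reclassified_mexican_duck(self, schema):
        keys = {"FA": CohortKey(cohort="FA", diagnostic_traits=[],
                                intervals={MEXICAN_DUCK: (0, 4), HYBRID: (5, 11)})}
        rows = [_record(schema, "FA", sample_id=f"h{i}") for i in range(5)]
        hist = pd.DataFrame(rows)
        hist["original_label"] = HYBRID
        out = morph.reassess_specimens(hist, keys, schema)
        assert (out["key_class"] == MEXICAN_DUCK).all()

    def test_synthetic_historical_crosstab_matches_truth(self, schema):
        cfg = syn.default_config(8)
        cfg.trait_model.panel_sizes = {
            (MEXICAN_DUCK, "FA"): 30, (MALLARD, "FA"): 20, (HYBRID, "FA"): 10}
        panel = syn.simulate_trait_panel(cfg, schema)
        scores = morph.score_panel(panel, schema).set_index("sample_id")
        labels = panel.set_index("sample_id")["true_trait_class"]
        keys = {"FA": morph.build_key(scores, labels, "FA", schema)}
        hist = panel.copy()
        hist["original_label"] = "uncertain"  # mislabeled originals
        out = morph.reassess_specimens(hist, keys, schema)
        merged = out.set_index("sample_id").join(labels)
        # key classes agree with generator truth for the disjoint calibration
        agree = (merged["key_class"] == merged["true_trait_class"]) | (
            (merged["key_class"] == morph.HYBRID_MALLARD)
            & merged["true_trait_class"].isin([HYBRID, MALLARD]))
        assert agree.mean() > 0.95

    def test_empty_input_gives_empty_report(self, schema):
        out = morph.reassess_specimens(pd.DataFrame(columns=["cohort"]), {}, schema)
        assert len(out) == 0

    def test_missing_cohort_skipped(self, schema, caplog):
        keys = {"FA": CohortKey(cohort="FA", diagnostic_traits=[],
                                intervals={MEXICAN_DUCK: (0, 4), HYBRID: (5, 11)})}
        rec = _record(schema, "MA", sample_id="h0")
        hist = pd.DataFrame([rec])
        hist["original_label"] = HYBRID
        out = morph.reassess_specimens(hist, keys, schema)
        assert len(out) == 0
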