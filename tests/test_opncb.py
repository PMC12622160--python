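"""OPNCB: exclusion rules, permutation optimization, mode semantics,
routing, and plan serialization."""

import numpy as np
import pytest

from radharm.cohort import CohortTable
from radharm.opncb import (
    HarmonizationPlan,
    OpncbError,
    exclude_rare_protocols,
    exclude_unseen_test_protocols,
    fit_opncb,
    harmonize,
)
from radharm.screen import ScreenConfig, screen_features
from radharm.simulate import generate_cohort, null_config, small_config

from conftest import build_cohort


class TestRareProtocolExclusion:
    def test_level_with_two_scans_excluded(self):
        rows = [{"scan_id": f"S{i}", "KVP": "120"} for i in range(6)]
        rows += [{"scan_id": "S6", "KVP": "100"}, {"scan_id": "S7", "KVP": "100"}]
        rep = exclude_rare_protocols(build_cohort(rows), parameters=("KVP",))
        assert sorted(rep.excluded_ids) == ["S6", "S7"]
        assert len(rep.retained) == 6

    def test_no_exclusions_when_all_levels_full(self):
        rows = [{"scan_id": f"S{i}", "KVP": "120" if i < 3 else "100"}
                for i in range(6)]
        rep = exclude_rare_protocols(build_cohort(rows), parameters=("KVP",))
        assert rep.excluded == []

    def test_cascading_exclusion_reaches_fixed_point(self):
        """Hand-traced 10-scan fixture: removing KVP=80's two scans drops
        MANUFACTURER=C to two scans, which must then also fall."""
        rows = [
            # 6 solid scans: KVP=120, MANUFACTURER=A
            *[{"scan_id": f"S{i}", "KVP": "120", "MANUFACTURER": "A"}
              for i in range(6)],
            # two scans with rare KVP=80, manufacturer C
            {"scan_id": "S6", "KVP": "80", "MANUFACTURER": "C"},
            {"scan_id": "S7", "KVP": "80", "MANUFACTURER": "C"},
            # two more manufacturer-C scans with common KVP: C has 4 scans
            # initially, but only 2 once KVP=80 goes
            {"scan_id": "S8", "KVP": "120", "MANUFACTURER": "C"},
            {"scan_id": "S9", "KVP": "120", "MANUFACTURER": "C"},
        ]
        rep = exclude_rare_protocols(build_cohort(rows),
                                     parameters=("KVP", "MANUFACTURER"))
        assert sorted(rep.excluded_ids) == ["S6", "S7", "S8", "S9"]
        assert sorted(rep.retained) == [f"S{i}" for i in range(6)]

    def test_everything_excluded_is_error(self):
        rows = [{"scan_id": "S0", "KVP": "80"}, {"scan_id": "S1", "KVP": "100"}]
        with pytest.raises(OpncbError, match="every scan"):
            exclude_rare_protocols(build_cohort(rows), parameters=("KVP",))


def _aug_cohort(seed=0, n_features=12, scale=0.6):
    cfg = small_config(scale=scale, n_features=n_features)
    cohort, _ = generate_cohort(cfg, seed=seed)
    rep = exclude_rare_protocols(cohort)
    return cohort.subset(rep.retained)


class TestFitOpncb:
    def test_single_parameter_single_permutation(self):
        cohort = _aug_cohort(seed=1)
        plan = fit_opncb(cohort, parameters=("CE",), mode="collective",
                         screen_config=ScreenConfig(parameters=("CE",)))
        assert plan.parameter_order["ALL"] == ["CE"]
        assert len(plan.chains["ALL"]) == 1

    def test_two_parameter_order_matches_exhaustive_scoring(self):
        """The chosen order must equal the argmax of independently scoring
        both permutations end to end."""
        from radharm.opncb import _fit_chain, _score_harmonized

        cohort = _aug_cohort(seed=3)
        params = ("CE", "FOCAL_SPOT")
        cfg = ScreenConfig(parameters=params)
        scores = {}
        for perm in (("CE", "FOCAL_SPOT"), ("FOCAL_SPOT", "CE")):
            _, Y = _fit_chain(cohort, list(perm), None)
            scores[perm] = _score_harmonized(cohort, Y, params, cfg)
        best = max(sorted(scores), key=lambda p: scores[p])
        plan = fit_opncb(cohort, parameters=params, mode="collective",
                         screen_config=cfg)
        assert tuple(plan.parameter_order["ALL"]) == best
        assert plan.criterion_value == scores[best]

    def test_criterion_equals_independent_rescreen(self):
        cohort = _aug_cohort(seed=4)
        params = ("CE", "KVP")
        plan = fit_opncb(cohort, parameters=params, mode="covariate",
                         screen_config=ScreenConfig(parameters=params))
        h = harmonize(plan, cohort)
        rep = screen_features(h, ScreenConfig(parameters=params))
        assert plan.criterion_value == (~rep.dependent).sum()

    def test_single_level_parameter_skipped_with_log(self):
        cohort = _aug_cohort(seed=5)
        df = cohort.df.copy()
        df["KVP"] = "120"
        cohort = CohortTable(df, list(cohort.feature_names))
        plan = fit_opncb(cohort, parameters=("CE", "KVP"), mode="collective",
                         screen_config=ScreenConfig(parameters=("CE", "KVP")))
        assert plan.parameter_order["ALL"] == ["CE"]
        assert "KVP" in plan.skipped["ALL"]
        assert any("single level" in line for line in plan.log)

    def test_separate_mode_has_three_chains(self):
        cohort = _aug_cohort(seed=6, scale=1.0)
        plan = fit_opncb(cohort, parameters=("CE",), mode="separate",
                         screen_config=ScreenConfig(parameters=("CE",)))
        assert set(plan.chains) == {"EARLY", "AUG_BENIGN", "AUG_MALIGNANT"}

    def test_mode_ranking_on_biology_dependent_data(self):
        """With biology-dependent effects, the acquisition-independence
        criterion ranks separate >= covariate >= collective."""
        cohort = _aug_cohort(seed=7, scale=1.0, n_features=40)
        params = ("CE", "MANUFACTURER")
        cfg = ScreenConfig(parameters=params)
        vals = {m: fit_opncb(cohort, params, m, cfg).criterion_value
                for m in ("collective", "covariate", "separate")}
        assert vals["separate"] >= vals["covariate"] >= vals["collective"]
        assert vals["separate"] > vals["collective"]


class TestHarmonize:
    def test_empty_parameter_order_is_identity(self):
        cohort = _aug_cohort(seed=8)
        df = cohort.df.copy()
        for p in ("CE", "KVP", "FOCAL_SPOT", "MANUFACTURER"):
            df[p] = "only"
        constant = CohortTable(df, list(cohort.feature_names))
        plan = fit_opncb(constant, mode="collective")
        out = harmonize(plan, constant)
        np.testing.assert_array_equal(out.feature_matrix(),
                                      constant.feature_matrix())

    def test_separate_training_scan_uses_its_dataset_chain(self):
        cohort = _aug_cohort(seed=9, scale=1.0)
        params = ("CE",)
        plan = fit_opncb(cohort, parameters=params, mode="separate",
                         screen_config=ScreenConfig(parameters=params))
        dropped = {t[0] for t in plan.training_exclusions}
        kept = cohort.subset([s for s in cohort.scan_ids() if s not in dropped])
        h = harmonize(plan, kept)
        # transform the malignant subset through its chain alone
        mal = kept.select_dataset("AUG_MALIGNANT")
        Y = mal.feature_matrix()
        from radharm.combat import adjust_training
        for m in plan.chains["AUG_MALIGNANT"]:
            Y = adjust_training(m, Y, mal.df[m.batch_parameter].tolist())
        got = h.df[h.df.dataset_label == "AUG_MALIGNANT"][h.feature_names].to_numpy()
        np.testing.assert_allclose(got, Y, atol=1e-12)

    def test_covariate_and_separate_plans_differ_on_test_scans(self):
        cohort = _aug_cohort(seed=10, scale=1.0)
        params = ("CE", "FOCAL_SPOT")
        cfg = ScreenConfig(parameters=params)
        early = cohort.select_dataset("EARLY")
        test = early.subset(early.scan_ids()[:5])
        outs = {}
        for mode in ("covariate", "separate"):
            plan = fit_opncb(cohort, parameters=params, mode=mode,
                             screen_config=cfg)
            keep = exclude_unseen_test_protocols(test, plan).retained
            outs[mode] = harmonize(plan, test.subset(keep),
                                   is_test=True).feature_matrix()
        assert not np.allclose(outs["covariate"], outs["separate"])

    def test_plan_json_round_trip_preserves_behaviour(self):
        cohort = _aug_cohort(seed=11)
        plan = fit_opncb(cohort, parameters=("CE",), mode="covariate",
                         screen_config=ScreenConfig(parameters=("CE",)))
        plan2 = HarmonizationPlan.from_json(plan.to_json())
        assert plan2.to_json() == plan.to_json()
        a = harmonize(plan, cohort).feature_matrix()
        b = harmonize(plan2, cohort).feature_matrix()
        np.testing.assert_array_equal(a, b)


class TestUnseenTestProtocols:
    def test_unseen_manufacturer_excluded(self):
        cohort = _aug_cohort(seed=12)
        plan = fit_opncb(cohort, parameters=("MANUFACTURER",), mode="collective",
                         screen_config=ScreenConfig(parameters=("MANUFACTURER",)))
        test = build_cohort([
            {"scan_id": "T0", "MANUFACTURER": "A"},
            {"scan_id": "T1", "MANUFACTURER": "ZZZ"},
        ], n_features=cohort.n_features)
        rep = exclude_unseen_test_protocols(test, plan)
        assert rep.excluded_ids == ["T1"]
        assert rep.retained == ["T0"]
        assert rep.excluded[0][1] == "unseen_protocol"

    def test_subset_of_training_protocols_passes(self):
        cohort = _aug_cohort(seed=13)
        plan = fit_opncb(cohort, parameters=("CE",), mode="collective",
                         screen_config=ScreenConfig(parameters=("CE",)))
        test = build_cohort([{"scan_id": "T0", "CE": "no"}],
                            n_features=cohort.n_features)
        rep = exclude_unseen_test_protocols(test, plan)
        assert rep.excluded == []

    def test_separate_mode_routes_against_early_chain_levels(self):
        """A level trained only in the malignant chain is still unseen for
        test scans, which are routed through the early chain."""
        cfg = null_config(scale=1.0, n_features=8)
        cohort, _ = generate_cohort(cfg, seed=14)
        df = cohort.df.copy()
        # give KVP=85 to malignant scans only (enough of them to survive)
        mal = df.index[df.dataset_label == "AUG_MALIGNANT"][:30]
        df.loc[mal, "KVP"] = "85"
        cohort = CohortTable(df, list(cohort.feature_names))
        cohort = cohort.subset(exclude_rare_protocols(cohort).retained)
        plan = fit_opncb(cohort, parameters=("KVP",), mode="separate",
                         screen_config=ScreenConfig(parameters=("KVP",)))
        assert "85" in plan.trained_levels("AUG_MALIGNANT").get("KVP", set())
        assert "85" not in plan.trained_levels("EARLY").get("KVP", set())
        test = build_cohort([{"scan_id": "T0", "KVP": "85"},
                             {"scan_id": "T1", "KVP": "120"}],
                            n_features=cohort.n_features)
        rep = exclude_unseen_test_protocols(test, plan)
        assert rep.excluded_ids == ["T0"]
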