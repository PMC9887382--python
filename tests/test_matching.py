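"""Eligibility screening, propensity model and calliper matching.

The matching algorithm is pinned by an independently implemented
exhaustive best-first oracle on small random instances.
"""

import numpy as np
import pandas as pd
import pytest

from namdcast.matching import (
    MatchSet,
    PropensityModel,
    fit_propensity,
    match_within_calliper,
    screen_eligibility,
    standardized_mean_difference,
)
from namdcast.ehr_preprocess import age_band_midpoints
from tests.conftest import make_profiles, make_sham


class TestScreenEligibility:
    def test_above_upper_bound_ineligible(self):
        eligible, ineligible = screen_eligibility(make_profiles(1, va=[80]), 25, 70)
        assert len(eligible) == 0
        assert ineligible["reason"].iloc[0] == "va_above_70"

    def test_bounds_inclusive(self):
        eligible, ineligible = screen_eligibility(
            make_profiles(3, va=[25, 70, 24]), 25, 70
        )
        assert sorted(eligible["baseline_va"]) == [25, 70]
        assert ineligible["reason"].iloc[0] == "va_below_25"

    def test_empty_input(self):
        eligible, ineligible = screen_eligibility(make_profiles(1, va=[50]).iloc[:0])
        assert len(eligible) == 0 and len(ineligible) == 0

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            screen_eligibility(make_profiles(1, va=[50]), 70, 25)


class TestFitPropensity:
    def test_identical_groups_give_prevalence(self):
        profiles = make_profiles(40, seed=2)
        sham, _ = make_sham(0, seed=0)
        sham = pd.DataFrame(
            {
                "participant_id": [f"S{i}" for i in range(40)],
                "sex": profiles["sex"].to_numpy(),
                "age_band": profiles["age_band"].to_numpy(),
                "ethnicity": "white",
                "smoker": "yes",
                "baseline_va": profiles["baseline_va"].to_numpy(),
            }
        )
        model = fit_propensity(profiles, sham)
        assert np.allclose(model.subjects["propensity"], 0.5, atol=1e-4)
        assert model.logit_sd < 1e-3

    def test_parameter_recovery_at_n2000(self):
        """MLE recovers the generating coefficients within 3 SE."""
        rng = np.random.default_rng(42)
        n = 4000
        profiles = make_profiles(n, seed=1)
        age = age_band_midpoints(profiles)
        female = (profiles["sex"] == "female").astype(float).to_numpy()
        va = profiles["baseline_va"].to_numpy(dtype=float)
        truth = {"const": -1.0, "age": 0.02, "female": 0.5, "baseline_va": -0.01}
        eta = (
            truth["const"] + truth["age"] * age + truth["female"] * female
            + truth["baseline_va"] * va
        )
        member = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
        cohort = profiles[member]
        sham = (
            profiles[~member]
            .rename(columns={"patient_id": "participant_id"})
            .drop(columns=["centre", "index_year", "index_week", "study_eye"])
        )
        model = fit_propensity(cohort, sham)
        for name, value in truth.items():
            assert abs(model.params[name] - value) < 3 * model.bse[name], name

    def test_empty_group_rejected(self):
        profiles = make_profiles(5)
        with pytest.raises(ValueError):
            fit_propensity(profiles.iloc[:0], profiles)


def toy_model(cohort_logits, sham_logits):
    """PropensityModel built directly from logit values (no fitting)."""
    subjects = pd.DataFrame(
        {
            "subject_id": [f"P{i:02d}" for i in range(len(cohort_logits))]
            + [f"S{i:02d}" for i in range(len(sham_logits))],
            "group": ["cohort"] * len(cohort_logits) + ["sham"] * len(sham_logits),
            "logit": np.r_[cohort_logits, sham_logits],
        }
    )
    subjects["propensity"] = 1.0 / (1.0 + np.exp(-subjects["logit"]))
    return PropensityModel(params=pd.Series(dtype=float), bse=pd.Series(dtype=float),
                           subjects=subjects)


def oracle_best_first(model, calliper_mult=0.1):
    """Exhaustive best-first 1:1 matching: repeatedly admit the globally
    closest admissible free pair, ties broken lexicographically."""
    subj = model.subjects
    calliper = calliper_mult * subj["logit"].std(ddof=1)
    cohort = subj[subj["group"] == "cohort"]
    sham = subj[subj["group"] == "sham"]
    admissible = [
        (abs(c.logit - s.logit), c.subject_id, s.subject_id)
        for c in cohort.itertuples()
        for s in sham.itertuples()
        if abs(c.logit - s.logit) <= calliper
    ]
    pairs = []
    while admissible:
        best = min(admissible)
        pairs.append((best[1], best[2]))
        admissible = [
            t for t in admissible if t[1] != best[1] and t[2] != best[2]
        ]
    return sorted(pairs)


class TestMatchWithinCalliper:
    def test_identical_pair_matches_at_zero(self):
        result = match_within_calliper(toy_model([0.3, 1.0], [0.3, 9.0]))
        assert len(result.pairs) == 1
        assert result.pairs["delta_logit"].iloc[0] == 0.0

    def test_zero_calliper_keeps_exact_ties_only(self):
        result = match_within_calliper(
            toy_model([0.5, 0.6], [0.5, 0.6001]), calliper_mult=0.0
        )
        assert list(result.pairs["participant_id"]) == ["S00"]
        assert list(result.pairs["profile_id"]) == ["P00"]

    def test_zero_matches_is_valid(self):
        result = match_within_calliper(toy_model([0.0], [5.0]))
        assert len(result.pairs) == 0
        assert list(result.unmatched_profiles["reason"]) == ["no_neighbour_in_calliper"]

    @pytest.mark.parametrize("trial", range(4))
    def test_matches_exhaustive_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        for _ in range(50):
            nc, ns = rng.integers(1, 13, size=2)
            model = toy_model(rng.normal(0, 1, nc), rng.normal(0, 1, ns))
            result = match_within_calliper(model, calliper_mult=0.5)
            got = sorted(zip(result.pairs["profile_id"], result.pairs["participant_id"]))
            assert got == oracle_best_first(model, calliper_mult=0.5)
            assert (result.pairs["delta_logit"] <= result.calliper).all()

    def test_matchset_invariants_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            nc, ns = rng.integers(2, 40, size=2)
            model = toy_model(rng.normal(0, 1, nc), rng.normal(0, 1, ns))
            result = match_within_calliper(model)
            pairs, unmatched = result.pairs, result.unmatched_profiles
            assert pairs["profile_id"].is_unique
            assert pairs["participant_id"].is_unique
            assert len(pairs) <= min(nc, ns)
            all_ids = set(pairs["profile_id"]) | set(unmatched["profile_id"])
            assert len(all_ids) == nc
            assert (pairs["delta_logit"] <= result.calliper + 1e-12).all()

    def test_input_order_invariance(self):
        rng = np.random.default_rng(3)
        model = toy_model(rng.normal(0, 1, 15), rng.normal(0, 1, 15))
        shuffled = PropensityModel(
            params=model.params, bse=model.bse,
            subjects=model.subjects.sample(frac=1.0, random_state=1).reset_index(drop=True),
        )
        a = match_within_calliper(model).pairs
        b = match_within_calliper(shuffled).pairs
        assert sorted(zip(a["profile_id"], a["participant_id"])) == sorted(
            zip(b["profile_id"], b["participant_id"])
        )

    def test_matching_improves_balance(self):
        """On overlapping cohorts shifted in every propensity covariate,
        matching shrinks each covariate's standardised mean difference."""
        from namdcast.ehr_preprocess import AGE_BAND_MIDPOINT, AGE_BANDS

        def covs(frame):
            return {
                "age": frame["age_band"].map(AGE_BAND_MIDPOINT).to_numpy(float),
                "female": (frame["sex"] == "female").to_numpy(float),
                "va": frame["baseline_va"].to_numpy(float),
            }

        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            n = 500
            cohort = make_profiles(n, seed=seed, va=rng.integers(35, 86, n))
            cohort["sex"] = rng.choice(["female", "male"], n, p=[0.70, 0.30])
            cohort["age_band"] = rng.choice(
                AGE_BANDS, n, p=[0.05, 0.05, 0.10, 0.20, 0.25, 0.35]
            )
            sham_profiles = make_profiles(n, seed=seed + 1000,
                                          va=rng.integers(20, 71, n))
            sham_profiles["sex"] = rng.choice(["female", "male"], n, p=[0.50, 0.50])
            sham_profiles["age_band"] = rng.choice(
                AGE_BANDS, n, p=[0.20, 0.20, 0.20, 0.15, 0.15, 0.10]
            )
            sham = sham_profiles.rename(
                columns={"patient_id": "participant_id"}
            ).drop(columns=["centre", "index_year", "index_week", "study_eye"])
            model = fit_propensity(cohort, sham)
            result = match_within_calliper(model)
            assert len(result.pairs) > 20
            matched_c = cohort.set_index("patient_id").loc[result.pairs["profile_id"]]
            matched_s = sham.set_index("participant_id").loc[result.pairs["participant_id"]]
            before_c, before_s = covs(cohort), covs(sham)
            after_c, after_s = covs(matched_c), covs(matched_s)
            for name in ("age", "female", "va"):
                smd_before = standardized_mean_difference(before_c[name], before_s[name])
                smd_after = standardized_mean_difference(after_c[name], after_s[name])
                assert smd_after < smd_before, (seed, name)
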