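"""Eligibility rule, condition grouping, preventable flags, polar encoding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from claimseg import fixtures
from claimseg.cohort_features import (
    ConditionCrosswalk,
    EncodingScheme,
    ValidationError,
    flag_preventable,
    group_conditions,
    polar_encode,
    select_eligible,
)
from claimseg.synthetic_claims import generate_cohort


def _py(spends, ages=None):
    n = len(spends)
    return pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(n)],
        "age": ages if ages is not None else [40] * n,
        "annual_spend": spends,
    })


class TestSelectEligible:
    def test_top_five_of_hundred_distinct_spends(self):
        out = select_eligible(_py(list(range(1, 101))), quantile=0.05)
        assert sorted(out["annual_spend"]) == [96, 97, 98, 99, 100]

    def test_twenty_patients_selects_only_maximum(self):
        out = select_eligible(_py(list(range(1, 21))), quantile=0.05)
        assert out["annual_spend"].tolist() == [20]

    def test_matches_sort_and_slice_oracle(self):
        rng = np.random.default_rng(7)
        spends = rng.lognormal(8, 1.2, 1000)
        out = select_eligible(_py(spends), quantile=0.05)
        oracle = set(np.argsort(spends)[::-1][:50])
        assert set(int(p[1:]) for p in out["patient_id"]) == oracle

    def test_ties_at_threshold_all_included(self):
        spends = [1] * 95 + [50] * 5
        out = select_eligible(_py(spends), quantile=0.04)
        # threshold value 50 is tied across 5 patients; all kept
        assert len(out) == 5

    def test_age_filter_applies_before_quantile(self):
        spends = list(range(1, 41))
        ages = [18] * 20 + [40] * 20  # minors hold the low spends
        out = select_eligible(_py(spends, ages), quantile=0.05)
        assert (out["age"] >= 21).all()
        assert out["annual_spend"].tolist() == [40]

    def test_empty_and_degenerate_inputs_raise(self):
        with pytest.raises(ValidationError):
            select_eligible(_py([]), quantile=0.05)
        with pytest.raises(ValidationError, match="tie policy"):
            select_eligible(_py([5.0] * 10), quantile=0.05)
        with pytest.raises(ValidationError):
            select_eligible(_py([1, 2, 3]), quantile=1.5)


def _claims(rows):
    return pd.DataFrame(rows, columns=["patient_id", "service_date", "setting",
                                       "icd9", "paid_amount"])


class TestGroupConditions:
    crosswalk = ConditionCrosswalk(pd.DataFrame([
        {"code_prefix": "250", "category_id": "C1", "category_name": "Diabetes", "level": 2},
        {"code_prefix": "401", "category_id": "C2", "category_name": "Hypertension", "level": 2},
        {"code_prefix": "2500", "category_id": "C3", "category_name": "DiabetesNoComp", "level": 3},
    ]))

    def test_zero_claims_gives_all_zero_flags(self):
        flags, unmapped = group_conditions(_claims([]), self.crosswalk,
                                           patient_ids=["A"])
        assert flags.loc["A"].sum() == 0
        assert not unmapped

    def test_direct_lookup(self):
        claims = _claims([("A", "2014-01-01", "OP", "250.00", 10.0),
                          ("A", "2014-02-01", "OP", "401.9", 10.0)])
        flags, unmapped = group_conditions(claims, self.crosswalk)
        assert flags.loc["A", "cond_diabetes"] == 1
        assert flags.loc["A", "cond_hypertension"] == 1
        assert not unmapped

    def test_unmapped_codes_counted_not_fatal(self):
        claims = _claims([("A", "2014-01-01", "OP", "999.9", 10.0)])
        flags, unmapped = group_conditions(claims, self.crosswalk)
        assert flags.loc["A"].sum() == 0
        assert unmapped["999.9"] == 1

    def test_longest_prefix_wins_within_level(self):
        xw = ConditionCrosswalk(pd.DataFrame([
            {"code_prefix": "25", "category_id": "C1", "category_name": "Broad", "level": 2},
            {"code_prefix": "250", "category_id": "C2", "category_name": "Narrow", "level": 2},
        ]))
        assert xw.lookup("250.00") == "Narrow"
        assert xw.lookup("255.4") == "Broad"

    def test_duplicate_prefix_same_level_rejected(self):
        with pytest.raises(ValidationError, match="same level"):
            ConditionCrosswalk(pd.DataFrame([
                {"code_prefix": "250", "category_id": "C1", "category_name": "A", "level": 2},
                {"code_prefix": "250", "category_id": "C2", "category_name": "B", "level": 2},
            ]))

    def test_random_claims_match_naive_scan_oracle(self):
        rng = np.random.default_rng(0)
        xw = fixtures.default_crosswalk()
        codes = [f"{p}.{s}" for _, p in fixtures.CONDITIONS for s in range(3)]
        codes += ["777.7", "888.8"]  # unmapped
        pids = [f"P{i}" for i in range(30)]
        claims = _claims([
            (pids[rng.integers(30)], "2014-01-01", "OP",
             codes[rng.integers(len(codes))], 1.0)
            for _ in range(500)])
        flags, _ = group_conditions(claims, xw, patient_ids=pids)
        # independent double loop over patients and claims
        for pid in pids:
            sub = claims[claims["patient_id"] == pid]
            expect = set()
            for code in sub["icd9"]:
                for name, prefix in fixtures.CONDITIONS:
                    if code.startswith(prefix):
                        expect.add(name)
            got = {name for name, _ in fixtures.CONDITIONS
                   if flags.loc[pid, f"cond_{name.strip().lower().replace(' ', '_')}"]}
            assert got == expect


class TestFlagPreventable:
    def test_empty_map_gives_zeros(self):
        claims = _claims([("A", "2014-01-01", "ED", "646.1", 5.0)])
        out = flag_preventable(claims, pd.DataFrame(columns=["code", "setting"]))
        assert out.loc["A"].sum() == 0

    def test_two_of_three_ed_visits_flagged(self):
        flag = pd.DataFrame([{"code": "646.1", "setting": "ED"}])
        claims = _claims([
            ("A", "2014-01-05", "ED", "646.1", 5.0),
            ("A", "2014-02-05", "ED", "646.1", 5.0),
            ("A", "2014-03-05", "ED", "646.0", 5.0),
        ])
        out = flag_preventable(claims, flag)
        assert out.loc["A", "preventable_ed_visits"] == 2
        assert out.loc["A", "preventable_admissions"] == 0

    def test_ip_encounter_flagged_if_any_line_flagged(self):
        flag = pd.DataFrame([{"code": "250.1", "setting": "IP"}])
        claims = _claims([
            ("A", "2014-01-05", "IP", "250.1", 5.0),  # day 1, flagged
            ("A", "2014-01-05", "IP", "250.0", 5.0),  # day 2 of same admission
            ("A", "2014-03-05", "IP", "250.0", 5.0),  # second admission, unflagged
        ])
        out = flag_preventable(claims, flag)
        assert out.loc["A", "preventable_admissions"] == 1

    def test_random_cohort_matches_naive_scan(self):
        rng = np.random.default_rng(12)
        flag = fixtures.default_preventable_flags()
        flagged = set(flag["code"])
        codes = [f"{p}.{s}" for _, p in fixtures.CONDITIONS for s in (0, 1)]
        rows = []
        for i in range(400):
            pid = f"P{rng.integers(20)}"
            setting = ["IP", "ED", "OP"][rng.integers(3)]
            date = f"2014-01-{rng.integers(1, 29):02d}"
            rows.append((pid, date, setting, codes[rng.integers(len(codes))], 1.0))
        claims = _claims(rows)
        out = flag_preventable(claims, flag)
        for pid in out.index:
            sub = claims[claims["patient_id"] == pid]
            ip = sub[sub["setting"] == "IP"]
            expect_adm = len({d for d in ip["service_date"]
                              if (ip[ip["service_date"] == d]["icd9"]
                                  .isin(flagged)).any()})
            expect_ed = int(sub[(sub["setting"] == "ED")
                                & sub["icd9"].isin(flagged)].shape[0])
            assert out.loc[pid, "preventable_admissions"] == expect_adm
            assert out.loc[pid, "preventable_ed_visits"] == expect_ed


class TestPolarEncode:
    def test_binary_quarter_circle_convention(self, tiny_patient_years):
        scheme = EncodingScheme(binary=["cond_diabetes"])
        fm = polar_encode(tiny_patient_years, scheme)
        flags = tiny_patient_years["cond_diabetes"].to_numpy()
        np.testing.assert_allclose(fm.values[:, 0], 1 - flags)  # cos
        np.testing.assert_allclose(fm.values[:, 1], flags)      # sin

    def test_four_level_third_level_maps_to_minus_one(self):
        py = pd.DataFrame({"patient_id": ["A"], "eligibility": ["Expansion"]})
        scheme = EncodingScheme(categorical={
            "eligibility": ["TANF", "SSI", "Expansion", "Medicare-eligible"]})
        fm = polar_encode(py, scheme)
        np.testing.assert_allclose(fm.values[0], [-1.0, 0.0], atol=1e-12)

    def test_unseen_level_raises_with_names(self, tiny_patient_years):
        scheme = EncodingScheme(categorical={"eligibility": ["TANF", "SSI"]})
        with pytest.raises(ValidationError, match="eligibility.*Expansion"):
            polar_encode(tiny_patient_years, scheme)

    def test_utilization_rejected_from_scheme(self):
        with pytest.raises(ValidationError, match="ed_visits"):
            EncodingScheme(continuous=["ed_visits"])

    def test_no_utilization_in_column_meta(self, fixture6_features):
        sources = {m["source"] for m in fixture6_features.column_meta}
        assert not sources & {"admissions", "hospital_days", "ed_visits",
                              "preventable_admissions", "preventable_ed_visits",
                              "annual_spend"}

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_polar_pairs_on_unit_circle(self, seed):
        cohort = generate_cohort(fixtures.fixture6_spec(n_patients=60, seed=seed))
        scheme = EncodingScheme.default(cohort.spec.condition_names)
        fm = polar_encode(cohort.patient_years, scheme)
        roles = [m["role"] for m in fm.column_meta]
        for i, role in enumerate(roles):
            if role == "polar-cos":
                assert roles[i + 1] == "polar-sin"
                norm = fm.values[:, i] ** 2 + fm.values[:, i + 1] ** 2
                assert np.abs(norm - 1).max() < 1e-9

    def test_encoding_injective_over_variables(self, fixture6_cohort,
                                               fixture6_features):
        py = fixture6_cohort.patient_years
        scheme_vars = (["eligibility", "race_ethnicity", "female", "age"]
                       + [c for c in py.columns if c.startswith("cond_")])
        X = fixture6_features.values
        rng = np.random.default_rng(0)
        for _ in range(200):
            i, j = rng.integers(0, len(py), 2)
            differs = any(py.iloc[i][v] != py.iloc[j][v] for v in scheme_vars)
            if differs:
                assert not np.allclose(X[i], X[j])

    def test_zscored_age_unit_variance(self, fixture6_features):
        age_col = [m["name"] for m in fixture6_features.column_meta].index("age__z")
        z = fixture6_features.values[:, age_col]
        assert abs(z.std() - 1) < 1e-9
        assert abs(z.mean()) < 1e-9
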