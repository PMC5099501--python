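"""Linkage module: edit distance, similarity, insurance mapping, directory linkage."""

import string

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from planlink.linkage import (
    AttributeWeights,
    UndefinedScoreError,
    attribute_scores,
    build_specialty_map,
    calibrate_threshold,
    canonicalize,
    combined_score,
    jaccard,
    levenshtein,
    link_directories,
    match_insurance_names,
    name_similarity,
    split_state_suffix,
)

from conftest import make_directory
from oracles import calibrate_sweep_brute, levenshtein_dp


def _random_string(rng, max_len=30):
    n = int(rng.integers(0, max_len + 1))
    return "".join(rng.choice(list(string.ascii_lowercase + " '.-")) for _ in range(n))


class TestLevenshtein:
    @pytest.mark.parametrize("a,b,expected", [
        ("abc", "abc", 0),
        ("", "abc", 3),
        ("abc", "", 3),
        ("", "", 0),
        ("kitten", "sitting", 3),
    ])
    def test_known_values(self, a, b, expected):
        assert levenshtein(a, b) == expected

    def test_insurance_name_strings_match_dp_oracle(self):
        a, b = "United Healthcare Services, CA", "United Healthcare, CA"
        assert levenshtein(a, b) == levenshtein_dp(a, b)

    def test_matches_full_matrix_oracle_on_random_pairs(self, rng):
        for _ in range(500):
            a, b = _random_string(rng), _random_string(rng)
            assert levenshtein(a, b) == levenshtein_dp(a, b)

    def test_metric_properties(self, rng):
        """Symmetry and the triangle inequality on random triples."""
        for _ in range(200):
            a, b, c = (_random_string(rng, 15) for _ in range(3))
            assert levenshtein(a, b) == levenshtein(b, a)
            assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)

    @settings(derandomize=True, max_examples=200)
    @given(st.text(alphabet=string.ascii_lowercase + " '-", max_size=20),
           st.text(alphabet=string.ascii_lowercase + " '-", max_size=20))
    def test_oracle_equivalence_property(self, a, b):
        assert levenshtein(a, b) == levenshtein_dp(a, b)

    @settings(derandomize=True, max_examples=100)
    @given(st.text(max_size=25), st.text(max_size=25))
    def test_length_difference_lower_bound(self, a, b):
        d = levenshtein(a, b)
        assert abs(len(a) - len(b)) <= d <= max(len(a), len(b))


class TestNameSimilarity:
    def test_identical(self):
        assert name_similarity("smith", "smith") == 1.0

    def test_fully_different(self):
        assert name_similarity("abcd", "wxyz") == 0.0

    def test_normalization_against_oracle(self):
        d = levenshtein_dp("kitten", "sitting")
        assert name_similarity("kitten", "sitting") == pytest.approx(1 - d / 7)

    def test_both_empty_is_one(self):
        assert name_similarity("", "") == 1.0
        assert name_similarity(None, None) == 1.0

    def test_canonicalization_makes_case_and_punct_irrelevant(self):
        assert name_similarity("O'Brien", "obrien") == 1.0
        assert name_similarity("  Mary   Ann ", "mary ann") == 1.0


def test_canonicalize_keeps_state_comma():
    assert canonicalize("Aetna  Life, AR!") == "aetna life, ar"
    assert split_state_suffix("Aetna HMO, AR") == ("Aetna HMO", "AR")
    assert split_state_suffix("No State Plan") == ("No State Plan", None)


class TestInsuranceMapping:
    def test_state_code_must_match(self):
        """The same-state candidate wins even when a cross-state name is closer."""
        mapping, unmapped = match_insurance_names(
            ["Aetna Life Insurance, AR"], ["Aetna HMO, AR", "Aetna HMO, CA"],
            min_similarity=0.2)
        assert mapping == {"Aetna Life Insurance, AR": "Aetna HMO, AR"}
        assert unmapped == []

    def test_identity_on_identical_lists(self):
        names = ["Humana PPO, TX", "Cigna HMO, OH"]
        mapping, unmapped = match_insurance_names(names, list(names))
        assert mapping == {n: n for n in names}
        assert unmapped == []

    def test_disjoint_names_at_full_similarity_all_unmapped(self):
        mapping, unmapped = match_insurance_names(
            ["Aetna PPO, NY"], ["Wellcare HMO, NY"], min_similarity=1.0)
        assert mapping == {}
        assert unmapped == ["Aetna PPO, NY"]


class TestAttributeScores:
    def test_identical_records_score_all_ones(self):
        rec = {"first_name": "Ann", "middle_name": "B", "last_name": "Lee",
               "address": "1 Main St", "medical_school": "X", "graduation_year": 1999,
               "affiliated_hospitals": "H1;H2", "specialties": "Cardiology"}
        scores = attribute_scores(rec, dict(rec))
        assert all(v == 1.0 for v in scores.values())

    def test_graduation_year_is_exact_match(self):
        a = {"graduation_year": 1999, "first_name": "Ann"}
        b = {"graduation_year": 2000, "first_name": "Ann"}
        scores = attribute_scores(a, b)
        assert scores["graduation_year"] == 0.0
        assert scores["first_name"] == 1.0

    def test_hospital_jaccard(self):
        a = {"affiliated_hospitals": {"H1", "H2"}}
        b = {"affiliated_hospitals": {"H2", "H3"}}
        assert attribute_scores(a, b)["affiliated_hospitals"] == pytest.approx(1 / 3)
        assert jaccard({"H1", "H2"}, {"H2", "H3"}) == pytest.approx(1 / 3)

    def test_missing_fields_are_nan(self):
        scores = attribute_scores({"first_name": "Ann"}, {"first_name": None})
        assert np.isnan(scores["first_name"])


class TestCombinedScore:
    def test_all_ones_any_weights(self):
        w = AttributeWeights()
        scores = {a: 1.0 for a in w.weights}
        assert combined_score(scores, w) == pytest.approx(1.0)

    def test_equal_weights_half(self):
        w = AttributeWeights(weights={"first_name": 0.5, "last_name": 0.5})
        assert combined_score({"first_name": 1.0, "last_name": 0.0}, w) == pytest.approx(0.5)

    def test_missing_scores_renormalize(self):
        """(0.25*0.8 + 0.25*0.6) / 0.5 = 0.7 when the 0.5-weight field is absent."""
        w = AttributeWeights(weights={"first_name": 0.25, "last_name": 0.5,
                                      "address": 0.25})
        scores = {"first_name": 0.8, "last_name": np.nan, "address": 0.6}
        assert combined_score(scores, w) == pytest.approx(0.7)

    def test_all_missing_raises(self):
        w = AttributeWeights()
        with pytest.raises(UndefinedScoreError):
            combined_score({a: np.nan for a in w.weights}, w)


def _toy_dirs():
    rows = [
        {"npi": 1, "first_name": "Ann", "last_name": "Smith", "state": "NY",
         "site_id": "a"},
        {"npi": 2, "first_name": "Bob", "last_name": "Jones", "state": "NY",
         "site_id": "b"},
        {"npi": 3, "first_name": "Cal", "last_name": "Smith", "state": "CA",
         "site_id": "c"},
    ]
    dir_a = make_directory([{k: v for k, v in r.items() if k != "site_id"}
                            for r in rows])
    dir_b = make_directory(rows).rename(columns={"npi": "true_npi"})
    return dir_a, dir_b


class TestLinkDirectories:
    def test_exact_copy_gives_identity_mapping(self):
        dir_a, dir_b = _toy_dirs()
        links = link_directories(dir_a, dir_b, AttributeWeights(threshold=0.9))
        got = dict(zip(links.accepted["site_id"], links.accepted["npi"]))
        assert got == {"a": 1, "b": 2, "c": 3}

    def test_row_order_invariance(self, small_world):
        w = AttributeWeights(threshold=0.8)
        links1 = link_directories(small_world.cms_providers, small_world.site_providers, w)
        shuffled_a = small_world.cms_providers.sample(frac=1, random_state=1)
        shuffled_b = small_world.site_providers.sample(frac=1, random_state=2)
        links2 = link_directories(shuffled_a, shuffled_b, w)
        k1 = set(zip(links1.accepted["npi"], links1.accepted["site_id"]))
        k2 = set(zip(links2.accepted["npi"], links2.accepted["site_id"]))
        assert k1 == k2

    def test_raising_threshold_never_accepts_more(self, small_world):
        counts = []
        for thr in (0.6, 0.8, 0.9, 0.99):
            links = link_directories(small_world.cms_providers,
                                     small_world.site_providers,
                                     AttributeWeights(threshold=thr))
            counts.append(len(links.accepted))
        assert counts == sorted(counts, reverse=True)

    def test_threshold_one_accepts_only_perfect_clones(self, small_world):
        links = link_directories(small_world.cms_providers,
                                 small_world.site_providers,
                                 AttributeWeights(threshold=1.0))
        assert (links.accepted["score"] == 1.0).all()
        truth = set(zip(small_world.truth_links["npi"],
                        small_world.truth_links["site_id"]))
        accepted = set(zip(links.accepted["npi"], links.accepted["site_id"]))
        assert accepted <= truth

    def test_at_most_one_constraint(self, small_world):
        links = link_directories(small_world.cms_providers,
                                 small_world.site_providers,
                                 AttributeWeights(threshold=0.7))
        assert links.accepted["site_id"].is_unique
        assert (links.accepted["score"] >= 0.7).all()

    def test_blocking_sound_at_zero_noise(self, clean_world):
        """Unperturbed names: single-pass blocking loses no true pair."""
        links = link_directories(clean_world.cms_providers,
                                 clean_world.site_providers,
                                 AttributeWeights(threshold=0.99),
                                 blocking_key="last_initial_state")
        truth = set(zip(clean_world.truth_links["npi"],
                        clean_world.truth_links["site_id"]))
        scored = set(zip(links.scored_pairs["npi"], links.scored_pairs["site_id"]))
        assert truth <= scored
        accepted = set(zip(links.accepted["npi"], links.accepted["site_id"]))
        assert accepted == truth


class TestCalibrateThreshold:
    def test_perfectly_separated_scores(self):
        pairs = pd.DataFrame({
            "npi": [1, 2, 3, 4], "site_id": ["a", "b", "c", "d"],
            "score": [1.0, 1.0, 0.0, 0.0]})
        truth = pd.DataFrame({"npi": [1, 2], "site_id": ["a", "b"]})
        cal = calibrate_threshold(pairs, truth)
        assert cal.f1 == 1.0 and cal.precision == 1.0 and cal.recall == 1.0
        assert 0.0 < cal.threshold <= 1.0

    def test_matches_brute_force_sweep_on_overlapping_scores(self, rng):
        n = 300
        is_true = rng.random(n) < 0.5
        scores = np.where(is_true, rng.normal(0.8, 0.1, n), rng.normal(0.5, 0.15, n))
        scores = np.clip(scores, 0, 1)
        pairs = pd.DataFrame({"npi": np.arange(n), "site_id": [f"s{i}" for i in range(n)],
                              "score": scores})
        truth = pairs.loc[is_true, ["npi", "site_id"]]
        cal = calibrate_threshold(pairs, truth)
        t, f1, (prec, rec) = calibrate_sweep_brute(scores.tolist(), is_true.tolist())
        assert cal.threshold == pytest.approx(t)
        assert cal.f1 == pytest.approx(f1)
        assert (cal.precision, cal.recall) == pytest.approx((prec, rec))

    def test_empty_truth_raises(self):
        pairs = pd.DataFrame({"npi": [1], "site_id": ["a"], "score": [1.0]})
        with pytest.raises(ValueError):
            calibrate_threshold(pairs, pairs.iloc[0:0])


class TestSpecialtyMap:
    def test_strictly_more_than_min_occurrences(self):
        """A count equal to the floor is excluded; one above is kept."""
        raw = {"Cardiology": {"Cardiology & Heart Surgery"},
               "Dermatology": {"Cancer"}}
        smap = build_specialty_map({"Cardiology": 100, "Dermatology": 101}, raw,
                                   min_occurrences=100)
        assert smap.categories_for("Cardiology") is None
        assert smap.categories_for("Dermatology") == {"Cancer"}

    def test_empty_raw_entries(self):
        smap = build_specialty_map({"X": 500}, {})
        assert smap.entries == {}

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            build_specialty_map({"X": -1}, {})
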