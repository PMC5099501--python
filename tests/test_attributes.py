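"""Derived provider attributes: ratings, hospital scores, ranks, distances, cost."""

import math

import numpy as np
import pandas as pd
import pytest

from planlink.attributes import (
    average_rating,
    derive_all,
    haversine_miles,
    hospital_category_score,
    impute_hospital_ranks,
    provider_hospital_score,
    relative_cost,
    relative_costs,
)
from planlink.linkage import SpecialtyMap, build_specialty_map
from planlink.mappings import DEFAULT_SPECIALTY_CATEGORIES

from oracles import law_of_cosines_miles, relative_cost_brute


class TestAverageRating:
    @pytest.mark.parametrize("sources,expected", [
        ([(87.5, 4)], 87.5),
        ([(80.0, 2), (90.0, 2)], 85.0),
        ([(80.0, 3), (90.0, 1)], 82.5),
    ])
    def test_weighted_mean(self, sources, expected):
        assert average_rating(sources) == pytest.approx(expected)

    def test_zero_total_reviews_absent(self):
        assert math.isnan(average_rating([(80.0, 0)]))
        assert math.isnan(average_rating([]))

    def test_out_of_range_rating_rejected(self):
        with pytest.raises(ValueError):
            average_rating([(120.0, 1)])


_SMAP = SpecialtyMap(entries={
    "Cardiology": {"Heart"},
    "Internal Medicine": {"Heart", "Diabetes"},
})


class TestHospitalScores:
    def test_single_category(self):
        assert hospital_category_score({"Heart": 70.0}, "Cardiology", _SMAP) == 70.0

    def test_two_categories_averaged(self):
        score = hospital_category_score({"Heart": 70.0, "Diabetes": 90.0},
                                        "Internal Medicine", _SMAP)
        assert score == pytest.approx(80.0)

    def test_unmapped_specialty_absent(self):
        assert math.isnan(hospital_category_score({"Heart": 70.0}, "Podiatry", _SMAP))

    def test_hospital_lacking_mapped_categories_absent(self):
        assert math.isnan(hospital_category_score({"Cancer": 95.0}, "Cardiology", _SMAP))

    def test_max_over_affiliations(self):
        affs = [{"Heart": 80.0}, {"Heart": 60.0}]
        assert provider_hospital_score(affs, "Cardiology", _SMAP) == 80.0

    def test_single_affiliation(self):
        assert provider_hospital_score([{"Heart": 55.0}], "Cardiology", _SMAP) == 55.0

    def test_no_scorable_affiliation_absent(self):
        assert math.isnan(provider_hospital_score([{}], "Cardiology", _SMAP))

    def test_adding_affiliation_never_decreases(self):
        base = provider_hospital_score([{"Heart": 60.0}], "Cardiology", _SMAP)
        more = provider_hospital_score([{"Heart": 60.0}, {"Heart": 75.0}],
                                       "Cardiology", _SMAP)
        assert more >= base


class TestRankImputation:
    def test_bottom_median_of_large_list(self):
        """50 ranked of 1956: unranked all receive floor((51+1956)/2 + .5) = 1004."""
        df = pd.DataFrame({
            "hospital_id": [f"H{i}" for i in range(1956)],
            "rank": [i + 1 if i < 50 else np.nan for i in range(1956)],
        })
        ranks = impute_hospital_ranks(df)
        assert (ranks.iloc[50:] == 1004).all()
        assert (ranks.iloc[:50] == np.arange(1, 51)).all()

    def test_all_ranked_unchanged(self):
        df = pd.DataFrame({"hospital_id": list("abcde"), "rank": [3, 1, 4, 2, 5]})
        assert impute_hospital_ranks(df).tolist() == [3, 1, 4, 2, 5]

    def test_two_element_bottom_range_rounds_half_up(self):
        df = pd.DataFrame({"hospital_id": list("abc"), "rank": [1, np.nan, np.nan]})
        assert impute_hospital_ranks(df).tolist() == [1, 3, 3]

    def test_duplicate_ranks_rejected(self):
        df = pd.DataFrame({"hospital_id": list("abc"), "rank": [1, 1, np.nan]})
        with pytest.raises(ValueError):
            impute_hospital_ranks(df)


class TestHaversine:
    def test_identical_points_zero(self):
        assert haversine_miles(40.0, -75.0, 40.0, -75.0) == 0.0

    def test_symmetry(self, rng):
        for _ in range(20):
            lat1, lat2 = rng.uniform(-80, 80, 2)
            lon1, lon2 = rng.uniform(-170, 170, 2)
            assert haversine_miles(lat1, lon1, lat2, lon2) == pytest.approx(
                haversine_miles(lat2, lon2, lat1, lon1))

    def test_against_law_of_cosines_oracle(self, rng):
        d = haversine_miles(0.0, 0.0, 0.0, 1.0)
        assert d == pytest.approx(law_of_cosines_miles(0.0, 0.0, 0.0, 1.0), rel=1e-6)
        for _ in range(50):
            lat1, lat2 = rng.uniform(-60, 60, 2)
            lon1, lon2 = rng.uniform(-120, 120, 2)
            assert haversine_miles(lat1, lon1, lat2, lon2) == pytest.approx(
                law_of_cosines_miles(lat1, lon1, lat2, lon2), rel=1e-6, abs=1e-6)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            haversine_miles(91.0, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            haversine_miles(0.0, 181.0, 0.0, 0.0)


def _co_located(n, charge_fn, code="99213", nproc_fn=lambda i: 1):
    charges = pd.DataFrame([
        {"provider_id": i, "hcpcs_code": code, "avg_charged": charge_fn(i),
         "n_procedures": nproc_fn(i)} for i in range(n)])
    directory = pd.DataFrame({
        "npi": range(n), "specialty": "Cardiology",
        "lat": 40.0, "lon": -75.0})
    return charges, directory


class TestRelativeCost:
    def test_strictly_most_expensive_scores_100(self):
        charges, directory = _co_located(5, lambda i: 100.0 + 10 * i)
        costs = relative_costs(charges, directory)
        assert costs[4] == pytest.approx(100.0)
        assert costs[0] == pytest.approx(0.0)

    def test_alone_in_neighborhood_scores_100(self):
        charges, directory = _co_located(1, lambda i: 250.0)
        assert relative_cost(0, charges, directory) == pytest.approx(100.0)

    def test_procedure_weighted_average_across_codes(self):
        """Code A relative 100 with 3 procedures, code B relative 0 with 1 -> 75."""
        rows = [
            {"provider_id": 0, "hcpcs_code": "A", "avg_charged": 200.0, "n_procedures": 3},
            {"provider_id": 1, "hcpcs_code": "A", "avg_charged": 100.0, "n_procedures": 5},
            {"provider_id": 0, "hcpcs_code": "B", "avg_charged": 50.0, "n_procedures": 1},
            {"provider_id": 1, "hcpcs_code": "B", "avg_charged": 80.0, "n_procedures": 5},
        ]
        charges = pd.DataFrame(rows)
        directory = pd.DataFrame({"npi": [0, 1], "specialty": "X",
                                  "lat": [40.0, 40.0], "lon": [-75.0, -75.0]})
        assert relative_cost(0, charges, directory) == pytest.approx(75.0)

    def test_no_charges_absent(self):
        charges, directory = _co_located(2, lambda i: 100.0)
        assert math.isnan(relative_cost(99, charges, directory))

    def test_affine_invariance_within_neighborhood(self):
        charges, directory = _co_located(6, lambda i: 100.0 + 7.0 * i)
        base = relative_costs(charges, directory)
        scaled = charges.copy()
        scaled["avg_charged"] = 3.5 * scaled["avg_charged"] + 40.0
        rescored = relative_costs(scaled, directory)
        pd.testing.assert_series_equal(base, rescored)

    def test_agrees_with_brute_force_oracle(self, rng):
        """200 geolocated providers, 20 codes: exact agreement with all-pairs scan."""
        n, codes = 200, [f"C{j}" for j in range(20)]
        directory = pd.DataFrame({
            "npi": range(n),
            "specialty": rng.choice(["Cardio", "Derm"], size=n),
            "lat": rng.uniform(39.5, 40.5, n),
            "lon": rng.uniform(-75.5, -74.5, n),
        })
        rows = []
        for i in range(n):
            for c in rng.choice(codes, size=rng.integers(1, 4), replace=False):
                rows.append({"provider_id": i, "hcpcs_code": c,
                             "avg_charged": float(rng.uniform(50, 500)),
                             "n_procedures": int(rng.integers(1, 10))})
        charges = pd.DataFrame(rows)
        k, radius = 25, 30.0
        mine = relative_costs(charges, directory, k=k, radius_miles=radius)

        charge_tuples = list(charges.itertuples(index=False, name=None))
        dir_map = {r.npi: (r.specialty, r.lat, r.lon) for r in directory.itertuples()}
        for pid in mine.index:
            expected = relative_cost_brute(pid, charge_tuples, dir_map, k, radius)
            assert mine[pid] == pytest.approx(expected, abs=1e-9), f"provider {pid}"

    def test_radius_inf_and_large_k_is_global_minmax(self):
        charges, directory = _co_located(10, lambda i: 100.0 + i)
        directory["lat"] = np.linspace(30, 45, 10)   # spread far apart
        full = relative_costs(charges, directory, k=1000, radius_miles=1e9)
        assert full[9] == pytest.approx(100.0)
        assert full[0] == pytest.approx(0.0)
        assert full[5] == pytest.approx(100 * 5 / 9)

    def test_larger_k_never_shrinks_neighborhood(self):
        """With k covering everyone, extremes span the full 0-100 range."""
        charges, directory = _co_located(8, lambda i: 100.0 + i)
        small_k = relative_costs(charges, directory, k=2)
        large_k = relative_costs(charges, directory, k=100)
        # with k=2 each provider is compared against one peer only; with full k
        # the global cheapest must score 0 and the global priciest 100
        assert large_k[0] == 0.0 and large_k[7] == 100.0
        assert (small_k >= 0).all() and (small_k <= 100).all()


class TestDeriveAll:
    def test_zero_links_gives_empty_table(self, clean_world):
        w = clean_world
        smap = build_specialty_map(w.specialty_counts(), DEFAULT_SPECIALTY_CATEGORIES)
        attrs = derive_all(w.cms_providers, w.site_providers, w.hospitals,
                           w.hospital_scores, w.charges, w.referrals,
                           w.truth_links.iloc[0:0], smap, compute_cost=False)
        assert len(attrs) == 0

    def test_row_count_equals_accepted_links(self, clean_world):
        w = clean_world
        smap = build_specialty_map(w.specialty_counts(), DEFAULT_SPECIALTY_CATEGORIES)
        attrs = derive_all(w.cms_providers, w.site_providers, w.hospitals,
                           w.hospital_scores, w.charges, w.referrals,
                           w.truth_links, smap, compute_cost=True)
        assert len(attrs) == len(w.truth_links)
        # rating absent iff no reviews
        assert (attrs["user_rating"].isna() == (attrs["n_reviews"] == 0)).all()
        present = attrs["relative_cost"].dropna()
        assert ((present >= 0) & (present <= 100)).all()

    def test_rating_mean_tracks_generator_target(self):
        from planlink.config import NameNoise, WorldConfig
        from planlink.synthdata import generate_world
        cfg = WorldConfig(n_providers=10_000, n_plans=50, seed=17,
                          state_heterogeneity=0.0,
                          name_noise=NameNoise(max_edits=0, dropout=0.0,
                                               distractor_rate=0.0))
        w = generate_world(cfg)
        smap = build_specialty_map(w.specialty_counts(), DEFAULT_SPECIALTY_CATEGORIES)
        attrs = derive_all(w.cms_providers, w.site_providers, w.hospitals,
                           w.hospital_scores, w.charges, w.referrals,
                           w.truth_links, smap, compute_cost=False)
        assert abs(attrs["user_rating"].mean() - 82.0) <= 2.0

    def test_specialty_z_normalization(self, clean_world):
        w = clean_world
        smap = build_specialty_map(w.specialty_counts(), DEFAULT_SPECIALTY_CATEGORIES)
        attrs = derive_all(w.cms_providers, w.site_providers, w.hospitals,
                           w.hospital_scores, w.charges, w.referrals,
                           w.truth_links, smap, referral_norm="specialty_z",
                           compute_cost=False)
        by_spec = attrs.groupby("specialty")["num_referrals"].mean()
        assert (by_spec.abs() < 1e-9).all()
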