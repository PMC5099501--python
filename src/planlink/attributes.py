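"""Derived per-provider attributes.

Builds the provider attribute vector used by the plan-level analysis:

* ``user_rating`` — review-count-weighted mean patient rating (0-100)
  across the provider's linked review-site profiles; absent with zero
  reviews.
* ``num_referrals`` — inbound referral count (optionally z-scored within
  specialty, since referral volume is strongly specialty-dependent).
* ``castle_connolly`` — peer-nominated award flag.
* ``hospital_score`` — each affiliated hospital is scored as the mean of
  its ranking-category scores over the categories the provider's specialty
  maps to; the provider takes the maximum over affiliations; absent when
  the specialty is unmapped or no affiliation carries a mapped score.
* ``hospital_rank`` — best (smallest) rank among affiliated hospitals,
  after unranked hospitals are imputed the median of the bottom positions.
* ``relative_cost`` — 0-100 score comparing the provider's average billed
  charge per procedure code with same-specialty peers among the k nearest
  billers within a radius, min-max normalized per code (100 = most
  expensive) and procedure-count-weighted across the provider's codes.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .linkage import SpecialtyMap

logger = logging.getLogger(__name__)

EARTH_RADIUS_MILES = 3958.8


def average_rating(sources: list[tuple[float, int]]) -> float:
    """Review-count-weighted mean rating across source profiles.

    ``sources`` holds ``(mean_rating, n_reviews)`` per linked profile;
    returns NaN when the total review count is zero.
    """
    num = den = 0.0
    for rating, count in sources:
        if count == 0:
            continue
        if not 0.0 <= rating <= 100.0:
            raise ValueError(f"rating {rating} outside [0, 100]")
        num += rating * count
        den += count
    return num / den if den else float("nan")


def hospital_category_score(
    hospital_scores: dict[str, float], provider_specialty: str, smap: SpecialtyMap
) -> float:
    """Mean of the hospital's scores over the provider's mapped categories.

    NaN when the specialty is unmapped or the hospital carries none of the
    mapped categories.
    """
    cats = smap.categories_for(provider_specialty)
    if not cats:
        return float("nan")
    vals = [hospital_scores[c] for c in cats if c in hospital_scores]
    return float(np.mean(vals)) if vals else float("nan")


def provider_hospital_score(
    affiliations: list[dict[str, float]], provider_specialty: str, smap: SpecialtyMap
) -> float:
    """Maximum category score over the provider's affiliated hospitals."""
    scores = [hospital_category_score(h, provider_specialty, smap) for h in affiliations]
    scores = [s for s in scores if not math.isnan(s)]
    return max(scores) if scores else float("nan")


def impute_hospital_ranks(hospitals: pd.DataFrame) -> pd.Series:
    """Assign every unranked hospital the median of the bottom rank positions.

    With m ranked hospitals out of N, the unranked ones are treated as
    jointly occupying positions m+1..N and all receive the median of that
    range, (m+1+N)/2 rounded half-up.  Ranked hospitals keep their rank.
    Returns an integer Series indexed by ``hospital_id``.
    """
    ranks = hospitals["rank"]
    ranked = ranks.dropna()
    if ranked.duplicated().any():
        raise ValueError("duplicate hospital ranks")
    n, m = len(hospitals), len(ranked)
    imputed = math.floor((m + 1 + n) / 2 + 0.5) if m < n else 0   # half-up midpoint
    vals = [int(v) if not math.isnan(v) else imputed
            for v in ranks.to_numpy(dtype=float)]
    return pd.Series(vals, index=pd.Index(hospitals["hospital_id"], name="hospital_id"),
                     name="hospital_rank", dtype="int64")


def haversine_miles(lat1, lon1, lat2, lon2):
    """Great-circle distance in miles between coordinate pairs (degrees)."""
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    for lat in (lat1, lat2):
        if np.any((lat < -90) | (lat > 90)):
            raise ValueError("latitude outside [-90, 90]")
    for lon in (lon1, lon2):
        if np.any((lon < -180) | (lon > 180)):
            raise ValueError("longitude outside [-180, 180]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_MILES * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _per_code_charges(charges: pd.DataFrame) -> pd.DataFrame:
    """One row per (provider, code): procedure-weighted mean charge and total count."""
    df = charges.copy()
    df["_w"] = df["avg_charged"] * df["n_procedures"]
    g = df.groupby(["provider_id", "hcpcs_code"], sort=False).agg(
        _w=("_w", "sum"), n_procedures=("n_procedures", "sum"))
    g["avg_charged"] = g["_w"] / g["n_procedures"]
    return g.drop(columns="_w").reset_index()


def relative_costs(
    charges: pd.DataFrame,
    directory: pd.DataFrame,
    k: int = 1000,
    radius_miles: float = 30.0,
    id_col: str = "npi",
) -> pd.Series:
    """Relative cost with respect to area, for every provider with charges.

    For each of a provider's procedure codes, the comparison neighborhood is
    the k nearest same-specialty billers of that code within the radius
    (great-circle distance, ties broken by ascending provider identifier,
    the provider itself always included).  The provider's charge is min-max
    scaled to 0-100 within the neighborhood (100 when max = min), and the
    per-code values are combined weighted by the provider's procedure
    counts.  Providers lacking geolocation are skipped with a warning.

    Returns a float Series indexed by provider identifier.
    """
    geo = directory.set_index(id_col)[["specialty", "lat", "lon"]]
    per_code = _per_code_charges(charges)
    known = per_code["provider_id"].isin(geo.index)
    per_code = per_code[known]
    per_code = per_code.join(geo, on="provider_id")
    missing_geo = per_code["lat"].isna() | per_code["lon"].isna()
    if missing_geo.any():
        skipped = per_code.loc[missing_geo, "provider_id"].nunique()
        logger.warning("relative_costs: skipping %d providers lacking geolocation", skipped)
        per_code = per_code[~missing_geo]

    rel_num: dict = {}
    rel_den: dict = {}
    for (_spec, _code), grp in per_code.groupby(["specialty", "hcpcs_code"], sort=False):
        ids = grp["provider_id"].to_numpy()
        order = np.argsort(ids, kind="mergesort")      # id order for tie-breaking
        ids = ids[order]
        lat = grp["lat"].to_numpy()[order]
        lon = grp["lon"].to_numpy()[order]
        charge = grp["avg_charged"].to_numpy()[order]
        nproc = grp["n_procedures"].to_numpy()[order]
        g = len(ids)
        dist = haversine_miles(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
        within = dist <= radius_miles
        for i in range(g):
            mask = within[i]
            mask[i] = True                              # self always in
            idx = np.nonzero(mask)[0]
            if len(idx) > k:
                d = dist[i, idx]
                # k nearest; equidistant ties resolved by ascending id (idx order)
                sel = np.lexsort((idx, d))[:k]
                idx = idx[sel]
                if i not in idx:
                    idx = np.append(idx[:-1], i)
            lo, hi = charge[idx].min(), charge[idx].max()
            rel = 100.0 if hi == lo else 100.0 * (charge[i] - lo) / (hi - lo)
            pid = ids[i]
            rel_num[pid] = rel_num.get(pid, 0.0) + rel * nproc[i]
            rel_den[pid] = rel_den.get(pid, 0.0) + nproc[i]

    index = sorted(rel_num)
    vals = [rel_num[p] / rel_den[p] for p in index]
    return pd.Series(vals, index=pd.Index(index, name=id_col), name="relative_cost",
                     dtype=float)


def relative_cost(
    provider_id,
    charges: pd.DataFrame,
    directory: pd.DataFrame,
    k: int = 1000,
    radius_miles: float = 30.0,
    id_col: str = "npi",
) -> float:
    """Relative cost for one provider (NaN with no charge records)."""
    if not (charges["provider_id"] == provider_id).any():
        return float("nan")
    all_costs = relative_costs(charges, directory, k=k, radius_miles=radius_miles,
                               id_col=id_col)
    return float(all_costs.get(provider_id, float("nan")))


def derive_all(
    cms_providers: pd.DataFrame,
    site_providers: pd.DataFrame,
    hospitals: pd.DataFrame,
    hospital_scores: pd.DataFrame,
    charges: pd.DataFrame,
    referrals: pd.DataFrame,
    accepted_links: pd.DataFrame,
    smap: SpecialtyMap,
    k: int = 1000,
    radius_miles: float = 30.0,
    referral_norm: str = "none",
    compute_cost: bool = True,
) -> pd.DataFrame:
    """One attribute row per accepted link (site profile -> directory record).

    Ratings, review counts, award flags come from the site profile; state,
    specialty, geolocation and affiliations from the directory record.
    ``referral_norm`` is ``"none"`` (raw counts) or ``"specialty_z"``.
    """
    if referral_norm not in ("none", "specialty_z"):
        raise ValueError("referral_norm must be 'none' or 'specialty_z'")
    linked = accepted_links[["npi", "site_id"]].drop_duplicates("site_id")
    out = linked.merge(
        site_providers[["site_id", "rating", "n_reviews", "castle_connolly"]],
        on="site_id", how="left")
    out = out.merge(
        cms_providers[["npi", "state", "specialty", "hospital_ids"]],
        on="npi", how="left")
    out["n_reviews"] = out["n_reviews"].fillna(0).astype(int)
    out["user_rating"] = out["rating"].where(out["n_reviews"] > 0)
    bad = out["user_rating"].dropna()
    if len(bad) and ((bad < 0) | (bad > 100)).any():
        raise ValueError("rating outside [0, 100]")
    out["castle_connolly"] = out["castle_connolly"].fillna(False).astype(bool)

    if len(referrals):
        out = out.merge(referrals[["npi", "n_referrals"]], on="npi", how="left")
        out["num_referrals"] = out["n_referrals"].fillna(0.0).astype(float)
    else:
        out["num_referrals"] = 0.0

    # affiliations, exploded to (npi, hospital_id) with the provider specialty
    aff = out[["npi", "specialty", "hospital_ids"]].copy()
    aff["hospital_id"] = aff["hospital_ids"].fillna("").astype(str).str.split(";")
    aff = aff.explode("hospital_id")
    aff = aff[aff["hospital_id"].astype(bool)]

    # mean category score per (hospital, specialty) over mapped categories,
    # then max over a provider's affiliations
    smap_long = pd.DataFrame(
        [(s, c) for s, cats in smap.entries.items() for c in cats],
        columns=["specialty", "category"])
    if len(smap_long) and len(hospital_scores):
        hs = hospital_scores.merge(smap_long, on="category")
        hs = hs.groupby(["hospital_id", "specialty"], as_index=False)["score"].mean()
        scored_aff = aff.merge(hs, on=["hospital_id", "specialty"], how="inner")
        hosp_score = scored_aff.groupby("npi")["score"].max()
    else:
        hosp_score = pd.Series(dtype=float)
    out["hospital_score"] = out["npi"].map(hosp_score)

    rank_map = impute_hospital_ranks(hospitals)
    aff_rank = aff.merge(rank_map.rename("rank_i"), left_on="hospital_id",
                         right_index=True, how="inner")
    best_rank = aff_rank.groupby("npi")["rank_i"].min()
    out["hospital_rank"] = out["npi"].map(best_rank).astype("Int64")

    if compute_cost:
        cost = relative_costs(charges, cms_providers, k=k, radius_miles=radius_miles)
        out["relative_cost"] = out["npi"].map(cost)
    else:
        out["relative_cost"] = float("nan")

    attrs = out[[
        "npi", "site_id", "user_rating", "n_reviews", "num_referrals",
        "castle_connolly", "hospital_score", "hospital_rank", "relative_cost",
        "state", "specialty"]].copy()
    if referral_norm == "specialty_z" and len(attrs):
        def _z(s: pd.Series) -> pd.Series:
            sd = s.std(ddof=1)
            return (s - s.mean()) / sd if sd and sd > 0 else s * 0.0
        attrs["num_referrals"] = attrs.groupby("specialty")["num_referrals"].transform(_z)
    return attrs
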