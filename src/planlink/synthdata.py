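"""Synthetic provider/plan universe with ground-truth links and planted effects.

Emulates the five source families the analysis pipeline consumes —
a CMS-style provider directory, review-site provider profiles (perturbed
clones of the directory plus distractors), a hospital list with sparse
specialty rankings, HCPCS-style charge records with referral counts, and an
NCQA-style plan table with 0-100 quality scores — together with the exact
cross-source identity pairs and the planted statistical structure, so every
downstream stage can be evaluated against known truth.

Generative choices (no public data can be redistributed, so distributions
are chosen to match the published marginals of the emulated universe):

* patient ratings: truncated Gaussian on [0, 100] centered at 82;
  a configurable fraction of providers has zero reviews;
* referral counts: zero-inflated negative binomial (42% zeros by default,
  overall mean near 70 with median far below it, matching the
  mean/median asymmetry of real referral data);
* charges: log-normal per procedure code with a provider-level cost
  propensity and mild state effects;
* geolocation: uniform within synthetic per-state bounding boxes — enough
  for nearest-neighbor radius logic, no real geography;
* plan membership: each provider accepts 1-8 insurers (mean 1.7) within
  its state, weighted by plan popularity.

Planted associations are calibrated against the *realized* plan-level
aggregates (including the realized 0-100 relative-cost score, computed with
the same routine the attributes stage uses), so a planted target Pearson r
is exact up to downstream sampling error.  When ``state_heterogeneity`` is
positive, provider ratings and plan scores receive independent state-level
intercepts and the planted slope applies to the within-state-centered
aggregate: within-state correlations then sit at the target while the
pooled correlation is attenuated, reproducing the pooled-versus-stratified
pattern seen when a national analysis is localized.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .attributes import impute_hospital_ranks, relative_costs
from .config import ConfigError, NameNoise, PlantedEffect, WorldConfig
from .mappings import DEFAULT_CONDITIONS, RANKING_CATEGORIES

logger = logging.getLogger(__name__)

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"

FIRST_NAMES = [
    "James", "Mary", "Robert", "Patricia", "John", "Jennifer", "Michael", "Linda",
    "David", "Elizabeth", "William", "Barbara", "Richard", "Susan", "Joseph",
    "Jessica", "Thomas", "Sarah", "Charles", "Karen", "Christopher", "Lisa",
    "Daniel", "Nancy", "Matthew", "Betty", "Anthony", "Margaret", "Mark",
    "Sandra", "Donald", "Ashley", "Steven", "Kimberly", "Paul", "Emily",
    "Andrew", "Donna", "Joshua", "Michelle", "Kenneth", "Carol", "Kevin",
    "Amanda", "Brian", "Dorothy", "George", "Melissa", "Timothy", "Deborah",
]

LAST_NAMES = [
    "Smith", "Johnson", "Williams", "Brown", "Jones", "Garcia", "Miller",
    "Davis", "Rodriguez", "Martinez", "Hernandez", "Lopez", "Gonzalez",
    "Wilson", "Anderson", "Thomas", "Taylor", "Moore", "Jackson", "Martin",
    "Lee", "Perez", "Thompson", "White", "Harris", "Sanchez", "Clark",
    "Ramirez", "Lewis", "Robinson", "Walker", "Young", "Allen", "King",
    "Wright", "Scott", "Torres", "Nguyen", "Hill", "Flores", "Green",
    "Adams", "Nelson", "Baker", "Hall", "Rivera", "Campbell", "Mitchell",
    "Carter", "Roberts", "Gomez", "Phillips", "Evans", "Turner", "Diaz",
    "Parker", "Cruz", "Edwards", "Collins", "Reyes", "Stewart", "Morris",
    "Morales", "Murphy", "Cook", "Rogers", "Gutierrez", "Ortiz", "Morgan",
    "Cooper", "Peterson", "Bailey", "Reed", "Kelly", "Howard", "Ramos",
    "Kim", "Cox", "Ward", "Richardson",
]

STREETS = [
    "Oak Street", "Maple Avenue", "Cedar Lane", "Pine Road", "Elm Drive",
    "Washington Boulevard", "Lake View Drive", "Sunset Avenue", "Park Place",
    "Hillcrest Road", "River Road", "Highland Avenue", "Forest Lane",
    "Meadow Drive", "Spring Street", "Valley Road", "Church Street",
    "Main Street", "Second Avenue", "Broadway",
]

MEDICAL_SCHOOLS = [
    "Harborview School of Medicine", "Lakeside Medical College",
    "Summit University College of Medicine", "Riverbend School of Medicine",
    "Crestwood Medical University", "Northgate College of Medicine",
    "Eastfield School of Medicine", "Westbrook Medical College",
    "Pinehurst University School of Medicine", "Oakdale College of Medicine",
    "Grandview Medical School", "Silver Lake School of Medicine",
    "Stonebridge University College of Medicine", "Fairmont Medical College",
    "Clearwater School of Medicine", "Highland Medical University",
    "Redwood College of Medicine", "Bayshore School of Medicine",
    "Kingsport Medical College", "Ashford University School of Medicine",
]

CARRIERS = [
    "Aetna", "Cigna", "Humana", "United Healthcare", "Blue Shield", "Anthem",
    "Kaiser", "Centene", "Molina", "Wellcare", "Highmark", "Oscar",
]

HCPCS_CODES = [str(c) for c in range(99201, 99225)]

PLAN_SCORE_COLUMNS = [
    "overall_score", "consumer_satisfaction_score", "prevention_score",
    "treatment_score", "womens_reproductive_score", "mental_behavioral_score",
    "cancer_screening_score", "heart_disease_treatment_score",
    "children_adolescents_score", "diabetes_treatment_score",
]

#: Condition name -> (specialty set, plan score column), from the default map.
_CONDITION_INDEX = {c.name: c for c in DEFAULT_CONDITIONS}


@dataclass
class SyntheticWorld:
    """All generated tables plus ground truth for evaluation."""

    config: WorldConfig
    cms_providers: pd.DataFrame
    site_providers: pd.DataFrame
    hospitals: pd.DataFrame
    hospital_scores: pd.DataFrame
    plans: pd.DataFrame
    charges: pd.DataFrame
    referrals: pd.DataFrame
    populations: pd.DataFrame
    truth_links: pd.DataFrame          # npi, site_id
    memberships: pd.DataFrame          # plan_id, npi (ground-truth membership)
    truth_params: dict = field(default_factory=dict)

    def specialty_counts(self) -> dict[str, int]:
        return self.cms_providers["specialty"].value_counts().to_dict()

    _TABLES = ("cms_providers", "site_providers", "hospitals", "hospital_scores",
               "plans", "charges", "referrals", "populations", "truth_links",
               "memberships")

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False)
        with open(outdir / "truth_params.json", "w") as fh:
            json.dump(self.truth_params, fh, indent=2, default=float)

    @classmethod
    def read(cls, indir, config: WorldConfig | None = None) -> "SyntheticWorld":
        """Load a world from CSVs (user-supplied or previously written).

        ``truth_links``, ``memberships``, ``populations`` and
        ``truth_params.json`` are optional: absent files yield empty tables,
        so real (truth-free) data directories load the same way.
        """
        indir = Path(indir)
        tables = {}
        empties = {
            "truth_links": pd.DataFrame(columns=["npi", "site_id"]),
            "memberships": pd.DataFrame(columns=["plan_id", "npi"]),
            "populations": pd.DataFrame(columns=["state", "population"]),
            "hospital_scores": pd.DataFrame(columns=["hospital_id", "category",
                                                     "score"]),
            "referrals": pd.DataFrame(columns=["npi", "n_referrals"]),
        }
        for name in cls._TABLES:
            path = indir / f"{name}.csv"
            if path.exists():
                tables[name] = pd.read_csv(path)
            elif name in empties:
                tables[name] = empties[name]
            else:
                raise FileNotFoundError(f"required input table missing: {path}")
        params_path = indir / "truth_params.json"
        params = json.loads(params_path.read_text()) if params_path.exists() else {}
        return cls(config=config or WorldConfig(), truth_params=params, **tables)


def _state_boxes(states: list[str]) -> dict[str, tuple[float, float]]:
    """Synthetic non-overlapping bounding-box centers, one per state."""
    return {s: (30.0 + 2.6 * i, -120.0 + 4.8 * i) for i, s in enumerate(sorted(states))}


def _apply_edits(s: str, n_edits: int, rng: np.random.Generator) -> str:
    for _ in range(n_edits):
        op = int(rng.integers(0, 3)) if s else 1
        if op == 0:      # substitute
            i = int(rng.integers(0, len(s)))
            s = s[:i] + _ALPHABET[int(rng.integers(0, 26))] + s[i + 1:]
        elif op == 1:    # insert
            i = int(rng.integers(0, len(s) + 1))
            s = s[:i] + _ALPHABET[int(rng.integers(0, 26))] + s[i:]
        else:            # delete
            i = int(rng.integers(0, len(s)))
            s = s[:i] + s[i + 1:]
    return s


def perturb_directory(
    providers: pd.DataFrame,
    noise: NameNoise,
    seed: int,
    id_prefix: str = "S",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clone a directory into noisy site profiles plus distractor records.

    Each clone's string fields receive 0..max_edits random single-character
    edits (so edit distance to the original never exceeds the configured
    bound); dropout replaces a field with absent.  Distractors are synthesized
    by recombining field values across rows, so they resemble real records
    without corresponding to any.  Returns ``(site_table, truth_pairs)``.
    """
    noise.validate()
    rng = np.random.default_rng(seed)
    n = len(providers)
    clones = providers.copy().reset_index(drop=True)

    for fld in NameNoise.STRING_FIELDS:
        if fld not in clones.columns:
            continue
        max_e = noise.edits_for(fld)
        p_drop = noise.dropout_for(fld)
        vals = clones[fld].astype(object).tolist()
        for i in range(n):
            if p_drop and rng.random() < p_drop:
                vals[i] = None
                continue
            if max_e and isinstance(vals[i], str):
                k = int(rng.integers(0, max_e + 1))
                if k:
                    vals[i] = _apply_edits(vals[i], k, rng)
        clones[fld] = vals
    if "graduation_year" in clones.columns:
        p_drop = noise.dropout_for("graduation_year")
        if p_drop:
            drop = rng.random(n) < p_drop
            clones.loc[drop, "graduation_year"] = np.nan

    n_distract = int(round(noise.distractor_rate * n))
    if n_distract:
        base = rng.integers(0, n, size=n_distract)
        distract = providers.iloc[base].copy().reset_index(drop=True)
        # recombine non-geographic fields across rows
        for fld in ("first_name", "middle_name", "last_name", "address",
                    "medical_school", "graduation_year", "specialty"):
            if fld in distract.columns:
                distract[fld] = providers[fld].iloc[
                    rng.integers(0, n, size=n_distract)].to_numpy()
        distract["npi"] = -1
        site = pd.concat([clones, distract], ignore_index=True)
        is_clone = np.r_[np.ones(n, dtype=bool), np.zeros(n_distract, dtype=bool)]
    else:
        site = clones
        is_clone = np.ones(n, dtype=bool)

    order = rng.permutation(len(site))
    site = site.iloc[order].reset_index(drop=True)
    is_clone = is_clone[order]
    site.insert(0, "site_id", [f"{id_prefix}{i:07d}" for i in range(len(site))])
    truth = pd.DataFrame({
        "npi": site.loc[is_clone, "npi"].astype(np.int64).to_numpy(),
        "site_id": site.loc[is_clone, "site_id"].to_numpy(),
    })
    site = site.drop(columns=["npi"])
    return site, truth


def _plan_channel_aggregates(
    config: WorldConfig,
    memberships: pd.DataFrame,
    provider_tbl: pd.DataFrame,
    hospitals: pd.DataFrame,
    charges: pd.DataFrame,
    cms_providers: pd.DataFrame,
    n_plans: int,
) -> dict[str, np.ndarray]:
    """Realized plan-level aggregates used to calibrate planted effects."""
    m = memberships.merge(provider_tbl, on="npi", how="left")
    grp = m.groupby("plan_idx")
    out: dict[str, np.ndarray] = {}

    def _per_plan(series: pd.Series) -> np.ndarray:
        arr = np.full(n_plans, np.nan)
        arr[series.index.to_numpy()] = series.to_numpy(dtype=float)
        return arr

    out["mean_rating"] = _per_plan(grp["rating_obs"].mean())
    out["mean_referrals"] = _per_plan(grp["n_referrals"].mean())
    out["cc_ratio"] = _per_plan(grp["castle_connolly"].mean())

    if "mean_hospital_rank" in config.planted_effects:
        rank_map = impute_hospital_ranks(hospitals)
        aff = cms_providers[["npi", "hospital_ids"]].copy()
        aff["hospital_id"] = aff["hospital_ids"].str.split(";")
        aff = aff.explode("hospital_id")
        aff = aff.merge(rank_map.rename("rank_i"), left_on="hospital_id",
                        right_index=True, how="inner")
        best = aff.groupby("npi")["rank_i"].min()
        m2 = memberships.merge(best.rename("hrank"), left_on="npi",
                               right_index=True, how="left")
        out["mean_hospital_rank"] = _per_plan(m2.groupby("plan_idx")["hrank"].mean())

    if "mean_relative_cost" in config.planted_effects:
        cost = relative_costs(charges, cms_providers)
        m3 = memberships.merge(cost.rename("rcost"), left_on="npi",
                               right_index=True, how="left")
        out["mean_relative_cost"] = _per_plan(m3.groupby("plan_idx")["rcost"].mean())

    for cond_name in config.condition_effects:
        cond = _CONDITION_INDEX.get(cond_name)
        if cond is None:
            raise ConfigError(f"unknown condition {cond_name!r} in condition_effects")
        sub = m[m["specialty"].isin(cond.specialties)]
        out[f"condition:{cond_name}"] = _per_plan(sub.groupby("plan_idx")["rating_obs"].mean())
    return out


def _center(x: np.ndarray, state_idx: np.ndarray, within_state: bool) -> np.ndarray:
    """Center observed values; within-state mode also scales per state.

    Per-state standardization makes every state carry the planted
    within-state correlation regardless of how state-level shifts (or score
    truncation) change its local variance.  NaNs stay NaN.
    """
    out = np.full_like(x, np.nan, dtype=float)
    obs = ~np.isnan(x)
    if within_state:
        for s in np.unique(state_idx):
            sel = (state_idx == s) & obs
            if sel.any():
                centered = x[sel] - x[sel].mean()
                sd = centered.std()
                out[sel] = centered / sd if sd > 0 else centered
    elif obs.any():
        out[obs] = x[obs] - x[obs].mean()
    return out


def _planted_column(
    effects: dict[str, tuple[PlantedEffect, np.ndarray]],
    base_mean: float,
    base_sd: float,
    state_intercept: np.ndarray,
    rng: np.random.Generator,
    n: int,
    state_idx: np.ndarray,
    within_state: bool,
) -> np.ndarray:
    """Score column = mean + state intercept + planted signal + noise, clipped.

    Target-r effects are calibrated jointly against the realized channel
    values: with Z the (within-state-)standardized channel matrix on the
    rows where all channels are observed, the signal is Z G^{-1} r (G the
    sample channel correlation matrix) and the Gaussian noise is
    residualized against Z and rescaled, making the sample correlation of
    the column with each channel equal to its target exactly on those rows
    (before the [0, 100] clip, which is rare at the default scale).
    """
    eps = rng.standard_normal(n)
    y = np.zeros(n)
    extra_var = 0.0
    target: list[tuple[float, np.ndarray]] = []
    for name, (eff, x) in effects.items():
        x = np.asarray(x, dtype=float)
        if eff.target_r is not None:
            if np.nanstd(x) == 0:
                logger.warning("planted channel %r has zero variance; effect dropped",
                               name)
                continue
            target.append((eff.target_r, x))
        else:
            xc = _center(x, state_idx, within_state)
            sd = np.nanstd(xc)
            if sd > 0:
                y += (eff.slope / base_sd) * np.nan_to_num(xc, nan=0.0)
            if eff.noise_sd is not None:
                extra_var += (eff.noise_sd / base_sd) ** 2

    if target:
        X = np.column_stack([x for _, x in target])
        r = np.array([tr for tr, _ in target])
        obs = ~np.isnan(X).any(axis=1)
        m = int(obs.sum())
        if m < len(r) + 2:
            raise ConfigError("too few plans with observed channels for planted effects")
        cols, kept = [], []
        for j in range(X.shape[1]):
            col = _center(X[:, j], state_idx, within_state)[obs]
            col = col - col.mean()
            sd = col.std()
            if sd == 0:
                logger.warning("planted channel degenerate on observed rows; "
                               "effect dropped")
                continue
            cols.append(col / sd)
            kept.append(j)
        Z = np.column_stack(cols) if cols else np.empty((m, 0))
        r = r[kept]
    if target and Z.shape[1]:
        G = (Z.T @ Z) / m
        c = np.linalg.solve(G, r)
        s2 = float(r @ c)
        if s2 >= 1.0:
            raise ConfigError("planted target correlations jointly infeasible")
        e = eps[obs]
        A = np.column_stack([np.ones(m), Z])
        e = e - A @ np.linalg.lstsq(A, e, rcond=None)[0]
        norm = np.sqrt(float(e @ e) / m)
        e = e * (np.sqrt(1.0 - s2) / norm) if norm > 0 else e
        core = np.empty(n)
        core[obs] = Z @ c + e
        core[~obs] = eps[~obs]
        y += core
    else:
        y += eps * np.sqrt(1.0 + extra_var) if extra_var else eps

    col = base_mean + state_intercept + base_sd * y
    return np.clip(col, 0.0, 100.0)


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate the full synthetic universe; deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    het = config.state_heterogeneity

    states = sorted(config.states)
    n_states = len(states)
    pops = np.array([config.state_populations[s] for s in states], dtype=float)
    state_w = pops / pops.sum()
    boxes = _state_boxes(states)

    populations = pd.DataFrame({"state": states,
                                "population": pops.astype(np.int64)})

    # ---- hospitals -------------------------------------------------------
    nh = config.n_hospitals
    h_state_idx = rng.choice(n_states, size=nh, p=state_w)
    h_ids = [f"H{i:05d}" for i in range(nh)]
    n_ranked = int(round(config.frac_ranked_hospitals * nh))
    ranked_idx = rng.choice(nh, size=n_ranked, replace=False)
    ranks = np.full(nh, np.nan)
    ranks[ranked_idx] = rng.permutation(n_ranked) + 1
    hospitals = pd.DataFrame({
        "hospital_id": h_ids,
        "name": [f"{rng.choice(LAST_NAMES)} {kind} Hospital"
                 for kind in rng.choice(["General", "Memorial", "Regional", "University"],
                                        size=nh)],
        "state": [states[i] for i in h_state_idx],
        "rank": ranks,
    })
    score_rows = []
    for i in ranked_idx:
        quality = 100.0 - ranks[i] * (40.0 / max(n_ranked, 1))
        for cat in RANKING_CATEGORIES:
            if rng.random() < 0.6:
                score_rows.append((h_ids[i], cat,
                                   float(np.clip(quality + rng.normal(0, 5), 40, 100))))
    hospital_scores = pd.DataFrame(score_rows,
                                   columns=["hospital_id", "category", "score"])

    hospitals_by_state: dict[int, list[str]] = {
        s: hospitals.loc[h_state_idx == s, "hospital_id"].tolist()
        for s in range(n_states)}

    # ---- providers -------------------------------------------------------
    n = config.n_providers
    spec_names = list(config.specialties)
    spec_w = np.array([config.specialties[s] for s in spec_names], dtype=float)
    spec_w = spec_w / spec_w.sum()
    p_state_idx = rng.choice(n_states, size=n, p=state_w)
    specialty = rng.choice(spec_names, size=n, p=spec_w)
    lat0 = np.array([boxes[states[i]][0] for i in p_state_idx])
    lon0 = np.array([boxes[states[i]][1] for i in p_state_idx])
    lat = lat0 + rng.uniform(-1.0, 1.0, size=n)
    lon = lon0 + rng.uniform(-1.2, 1.2, size=n)

    middle_pool = list(_ALPHABET.upper())
    n_aff = rng.integers(1, 4, size=n)
    hospital_ids = []
    for i in range(n):
        pool = hospitals_by_state.get(p_state_idx[i]) or h_ids
        k = min(n_aff[i], len(pool))
        hospital_ids.append(";".join(sorted(rng.choice(pool, size=k, replace=False))))

    cms_providers = pd.DataFrame({
        "npi": np.arange(1_000_000_000, 1_000_000_000 + n, dtype=np.int64),
        "first_name": rng.choice(FIRST_NAMES, size=n),
        "middle_name": rng.choice(middle_pool, size=n),
        "last_name": rng.choice(LAST_NAMES, size=n),
        "address": [f"{int(num)} {st}" for num, st in
                    zip(rng.integers(100, 9999, size=n), rng.choice(STREETS, size=n))],
        "state": [states[i] for i in p_state_idx],
        "lat": lat,
        "lon": lon,
        "specialty": specialty,
        "hospital_ids": hospital_ids,
        "medical_school": rng.choice(MEDICAL_SCHOOLS, size=n),
        "graduation_year": rng.integers(1960, 2016, size=n),
    })

    # ---- latent provider attributes -------------------------------------
    state_rating_shift = rng.normal(0.0, het, size=n_states) if het > 0 else np.zeros(n_states)
    reviewed = rng.random(n) < config.frac_reviewed
    n_reviews = np.where(reviewed, 1 + rng.poisson(2.0, size=n), 0)
    rating = np.clip(
        rng.normal(config.rating_mean + state_rating_shift[p_state_idx],
                   config.rating_sd), 0.0, 100.0)
    rating_obs = np.where(reviewed, rating, np.nan)

    nonzero_ref = rng.random(n) >= config.frac_zero_referrals
    nb = rng.negative_binomial(0.5, 0.5 / (0.5 + 120.0), size=n)
    referral_counts = np.where(nonzero_ref, nb + 1, 0)
    referrals = pd.DataFrame({"npi": cms_providers["npi"], "n_referrals": referral_counts})

    castle = rng.random(n) < config.frac_castle_connolly

    # ---- charges ---------------------------------------------------------
    code_base = {c: np.log(60.0 + 25.0 * i) for i, c in enumerate(HCPCS_CODES)}
    cost_propensity = rng.standard_normal(n)
    state_cost = rng.normal(0.0, 0.08, size=n_states)
    charge_rows = []
    n_codes = 1 + np.minimum(rng.poisson(1.5, size=n), 4)
    for i in range(n):
        codes = rng.choice(HCPCS_CODES, size=n_codes[i], replace=False)
        for c in codes:
            amt = float(np.exp(code_base[c] + 0.35 * cost_propensity[i]
                               + state_cost[p_state_idx[i]] + rng.normal(0, 0.10)))
            charge_rows.append((cms_providers["npi"].iloc[i], c, round(amt, 2),
                                int(1 + rng.poisson(8))))
    charges = pd.DataFrame(charge_rows,
                           columns=["provider_id", "hcpcs_code", "avg_charged",
                                    "n_procedures"])

    # ---- plans and membership -------------------------------------------
    np_ = config.n_plans
    plan_state_idx = rng.choice(n_states, size=np_, p=state_w)
    categories = rng.choice(["private", "Medicare", "Medicaid"], size=np_,
                            p=[0.5, 0.3, 0.2])
    plan_types = rng.choice(["HMO", "PPO"], size=np_)
    plan_names = []
    seen: dict[str, int] = {}
    for i in range(np_):
        base = f"{rng.choice(CARRIERS)} {plan_types[i]}"
        seen[base] = seen.get(base, 0) + 1
        suffix = f" {seen[base]}" if seen[base] > 1 else ""
        plan_names.append(f"{base}{suffix}, {states[plan_state_idx[i]]}")

    plans_by_state: dict[int, np.ndarray] = {
        s: np.nonzero(plan_state_idx == s)[0] for s in range(n_states)}
    popularity: dict[int, np.ndarray] = {}
    for s, idx in plans_by_state.items():
        if len(idx):
            # mildly skewed popularity; too steep a tail starves small plans
            w = 1.0 / np.sqrt(1.0 + rng.permutation(len(idx)))
            popularity[s] = w / w.sum()

    n_ins = 1 + np.minimum(rng.poisson(config.mean_extra_insurers, size=n), 7)
    member_plan_idx: list[int] = []
    member_npi: list[int] = []
    insurer_strings: list[str] = []
    npis = cms_providers["npi"].to_numpy()
    for i in range(n):
        idx = plans_by_state.get(p_state_idx[i])
        if idx is None or len(idx) == 0:
            insurer_strings.append("")
            continue
        k = min(n_ins[i], len(idx))
        chosen = rng.choice(idx, size=k, replace=False, p=popularity[p_state_idx[i]])
        insurer_strings.append(";".join(plan_names[j] for j in sorted(chosen)))
        member_plan_idx.extend(int(j) for j in chosen)
        member_npi.extend([int(npis[i])] * k)
    memberships = pd.DataFrame({"plan_idx": member_plan_idx, "npi": member_npi})

    # ---- plan scores with planted structure ------------------------------
    provider_tbl = pd.DataFrame({
        "npi": npis, "rating_obs": rating_obs, "n_referrals": referral_counts,
        "castle_connolly": castle.astype(float), "specialty": specialty,
    })
    channels = _plan_channel_aggregates(config, memberships, provider_tbl,
                                        hospitals, charges, cms_providers, np_)
    within = het > 0

    def _intercepts() -> np.ndarray:
        """Per-column state intercepts, drawn exactly uncorrelated (in the
        realized sample of states) with the provider-rating shifts so the
        between-state term never couples plan scores to ratings."""
        if het <= 0:
            return np.zeros(np_)
        u = rng.normal(0.0, het, size=n_states)
        v = state_rating_shift - state_rating_shift.mean()
        if n_states > 2 and v.std() > 0:
            u = u - u.mean()
            u = u - (u @ v) / (v @ v) * v
            sd = u.std()
            if sd > 0:
                u = u * (het / sd)
        return u[plan_state_idx]

    sat_effects = {name: (eff, channels[name])
                   for name, eff in config.planted_effects.items()}
    consumer_satisfaction = _planted_column(
        sat_effects, config.satisfaction_mean, config.satisfaction_sd,
        _intercepts(), rng, np_, plan_state_idx, within)

    plan_scores: dict[str, np.ndarray] = {
        "consumer_satisfaction_score": consumer_satisfaction,
        "overall_score": np.clip(0.6 * consumer_satisfaction
                                 + 0.4 * rng.normal(78.0, 8.0, size=np_), 0, 100),
        "prevention_score": np.clip(rng.normal(75.0, 8.0, size=np_) + _intercepts(), 0, 100),
        "treatment_score": np.clip(rng.normal(75.0, 8.0, size=np_) + _intercepts(), 0, 100),
    }
    for cond in DEFAULT_CONDITIONS:
        eff = config.condition_effects.get(cond.name)
        if eff is not None:
            col = _planted_column({cond.name: (eff, channels[f"condition:{cond.name}"])},
                                  75.0, 8.0, _intercepts(), rng, np_,
                                  plan_state_idx, within)
        else:
            col = np.clip(rng.normal(75.0, 8.0, size=np_) + _intercepts(), 0, 100)
        plan_scores[cond.score_column] = col

    plans = pd.DataFrame({
        "plan_id": [f"P{i:05d}" for i in range(np_)],
        "plan_name": plan_names,
        "state": [states[i] for i in plan_state_idx],
        "category": categories,
        "plan_type": plan_types,
        **{c: np.round(plan_scores[c], 2) for c in PLAN_SCORE_COLUMNS},
    })

    # incomplete plans: null out a random subset of score columns
    n_incomplete = int(round(config.frac_incomplete_plans * np_))
    if n_incomplete:
        incomplete_idx = rng.choice(np_, size=n_incomplete, replace=False)
        for i in incomplete_idx:
            k = int(rng.integers(1, len(PLAN_SCORE_COLUMNS) + 1))
            cols = rng.choice(PLAN_SCORE_COLUMNS, size=k, replace=False)
            plans.loc[i, list(cols)] = np.nan

    # ---- site profiles ---------------------------------------------------
    site, truth_links = perturb_directory(
        cms_providers, config.name_noise, seed=int(rng.integers(0, 2**31)))
    per_npi = pd.DataFrame({
        "npi": npis, "rating": np.round(rating, 1), "n_reviews": n_reviews,
        "castle_connolly": castle, "insurers": insurer_strings,
    })
    site = site.merge(truth_links, on="site_id", how="left")
    site = site.merge(per_npi, on="npi", how="left")
    is_distractor = site["npi"].isna()
    nd = int(is_distractor.sum())
    if nd:
        d_rating = np.clip(rng.normal(config.rating_mean, config.rating_sd, size=nd), 0, 100)
        d_reviewed = rng.random(nd) < config.frac_reviewed
        site.loc[is_distractor, "rating"] = np.round(d_rating, 1)
        site.loc[is_distractor, "n_reviews"] = np.where(
            d_reviewed, 1 + rng.poisson(2.0, size=nd), 0)
        site.loc[is_distractor, "castle_connolly"] = rng.random(nd) < config.frac_castle_connolly
        d_ins = []
        for st in site.loc[is_distractor, "state"]:
            s = states.index(st)
            idx = plans_by_state.get(s)
            if idx is None or len(idx) == 0:
                d_ins.append("")
            else:
                j = rng.choice(idx, p=popularity[s])
                d_ins.append(plan_names[int(j)])
        site.loc[is_distractor, "insurers"] = d_ins
    site["n_reviews"] = site["n_reviews"].astype(int)
    site["castle_connolly"] = site["castle_connolly"].astype(bool)
    site["rating"] = site["rating"].where(site["n_reviews"] > 0)
    site = site.drop(columns=["npi"])

    memberships_out = pd.DataFrame({
        "plan_id": [f"P{i:05d}" for i in memberships["plan_idx"]],
        "npi": memberships["npi"],
    })

    truth_params = {
        "planted": {k: (v.target_r if v.target_r is not None else {"slope": v.slope})
                    for k, v in config.planted_effects.items()},
        "condition_planted": {k: v.target_r for k, v in config.condition_effects.items()},
        "realized": {
            name: _realized_r(channels[name], plan_scores["consumer_satisfaction_score"])
            for name in config.planted_effects if name in channels},
        "state_rating_shift": {states[i]: float(state_rating_shift[i])
                               for i in range(n_states)},
    }

    return SyntheticWorld(
        config=config, cms_providers=cms_providers, site_providers=site,
        hospitals=hospitals, hospital_scores=hospital_scores, plans=plans,
        charges=charges, referrals=referrals, populations=populations,
        truth_links=truth_links.sort_values("npi").reset_index(drop=True),
        memberships=memberships_out, truth_params=truth_params,
    )


def _realized_r(x: np.ndarray, y: np.ndarray) -> float:
    obs = ~np.isnan(x) & ~np.isnan(y)
    if obs.sum() < 3 or np.std(x[obs]) == 0 or np.std(y[obs]) == 0:
        return float("nan")
    return float(np.corrcoef(x[obs], y[obs])[0, 1])
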