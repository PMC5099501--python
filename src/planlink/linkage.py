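"""Fuzzy record linkage between provider directories.

Review-site provider profiles carry no shared key with a CMS-style
directory, so identity must be recovered from noisy attributes.  The
procedure implemented here:

1. canonicalize strings (case-fold, strip punctuation, collapse whitespace);
2. score candidate pairs attribute-by-attribute — Levenshtein-based
   similarity for name/address/school fields, exact match for graduation
   year, Jaccard overlap for affiliation and specialty sets;
3. combine per-attribute scores as a weighted mean, renormalizing weights
   over the attributes present on both sides (a missing field is
   non-evidence, not disagreement);
4. restrict candidates by a blocking key (default: last-name initial +
   state) for tractability;
5. accept pairs greedily in descending combined score subject to the
   at-most-one constraint on the site side and a score threshold.

The threshold can be calibrated against known true pairs by an exhaustive
F1 sweep (`calibrate_threshold`).  Insurance-plan name strings are mapped
across sources with the same normalized edit-distance similarity, with the
trailing state code compared exactly (cross-state mappings are forbidden).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

try:
    import edlib as _edlib
except ImportError:            # pure-Python dynamic programming still works
    _edlib = None

MATCH_ATTRIBUTES = (
    "first_name", "middle_name", "last_name", "address",
    "medical_school", "graduation_year", "affiliated_hospitals", "specialties",
)

#: Name fields dominate; school/address are supporting evidence.
DEFAULT_WEIGHTS = {
    "first_name": 0.2, "middle_name": 0.05, "last_name": 0.3, "address": 0.15,
    "medical_school": 0.1, "graduation_year": 0.05,
    "affiliated_hospitals": 0.075, "specialties": 0.075,
}

DEFAULT_THRESHOLD = 0.85


class UndefinedScoreError(ValueError):
    """All attribute scores missing: no basis for a combined score."""


@dataclass
class AttributeWeights:
    """Nonnegative per-attribute weights (normalized to sum 1) and a threshold."""

    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        unknown = set(self.weights) - set(MATCH_ATTRIBUTES)
        if unknown:
            raise ValueError(f"unknown matching attributes: {sorted(unknown)}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be nonnegative")
        total = sum(self.weights.values())
        if total <= 0:
            raise ValueError("weights must not all be zero")
        self.weights = {k: w / total for k, w in self.weights.items()}
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")


@dataclass
class LinkSet:
    """Scored candidate pairs and the accepted one-to-at-most-one mapping."""

    scored_pairs: pd.DataFrame    # id_a, id_b, per-attribute scores, score
    accepted: pd.DataFrame        # id_a, id_b, score, sorted by id_b
    threshold: float


@dataclass
class CalibrationResult:
    threshold: float
    precision: float
    recall: float
    f1: float


# ---------------------------------------------------------------------------
# string primitives

_PUNCT_RE = re.compile(r"[^\w\s,]")
_WS_RE = re.compile(r"\s+")


def canonicalize(s: str | None) -> str:
    """Case-fold, strip punctuation (commas kept for state codes), collapse whitespace."""
    if s is None or (isinstance(s, float) and np.isnan(s)):
        return ""
    return _canonicalize_cached(str(s))


@lru_cache(maxsize=200_000)
def _canonicalize_cached(s: str) -> str:
    s = _PUNCT_RE.sub("", s).casefold()
    return _WS_RE.sub(" ", s).strip()


def levenshtein(a: str, b: str) -> int:
    """Minimal single-character insert/delete/substitute count from ``a`` to ``b``.

    Delegates to the C-backed edlib aligner when available (it computes the
    same unit-cost edit distance); the two-row dynamic program below is the
    portable fallback.
    """
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    if _edlib is not None:
        try:
            return _edlib.align(a, b, task="distance")["editDistance"]
        except (TypeError, ValueError):    # e.g. alphabet too large
            pass
    if len(a) > len(b):          # iterate over the longer string, keep the row short
        a, b = b, a
    prev = list(range(len(a) + 1))
    for j, cb in enumerate(b, start=1):
        cur = [j]
        for i, ca in enumerate(a, start=1):
            cur.append(min(prev[i] + 1,                    # delete from a
                           cur[i - 1] + 1,                 # insert into a
                           prev[i - 1] + (ca != cb)))      # substitute
        prev = cur
    return prev[-1]


def name_similarity(a: str | None, b: str | None) -> float:
    """Normalized edit similarity ``1 - d/max(len)`` on canonicalized strings.

    Two empty strings are defined as similarity 1.0.
    """
    ca, cb = canonicalize(a), canonicalize(b)
    m = max(len(ca), len(cb))
    if m == 0:
        return 1.0
    return 1.0 - levenshtein(ca, cb) / m


_STATE_RE = re.compile(r",\s*([A-Za-z]{2})\s*$")


def split_state_suffix(name: str) -> tuple[str, str | None]:
    """Split ``"Aetna HMO, AR"`` into (``"Aetna HMO"``, ``"AR"``)."""
    m = _STATE_RE.search(name)
    if m:
        return name[: m.start()], m.group(1).upper()
    return name, None


def match_insurance_names(
    names_a: list[str], names_b: list[str], min_similarity: float = 0.5
) -> tuple[dict[str, str], list[str]]:
    """Map each name in ``names_a`` to its most similar name in ``names_b``.

    Similarity is computed on the canonicalized name body; the trailing
    two-letter state code must match exactly.  Names whose best same-state
    similarity falls below ``min_similarity`` are reported unmapped.
    Returns ``(mapping, unmapped)``.
    """
    if not 0.0 <= min_similarity <= 1.0:
        raise ValueError("min_similarity must be in [0, 1]")
    by_state: dict[str | None, list[tuple[str, str]]] = {}
    exact: dict[tuple[str | None, str], str] = {}
    for nb in names_b:
        body_b, st_b = split_state_suffix(nb)
        cb = canonicalize(body_b)
        by_state.setdefault(st_b, []).append((nb, cb))
        key = (st_b, cb)
        if key not in exact or nb < exact[key]:
            exact[key] = nb
    mapping: dict[str, str] = {}
    unmapped: list[str] = []
    for na in names_a:
        body_a, st_a = split_state_suffix(na)
        ca = canonicalize(body_a)
        hit = exact.get((st_a, ca))        # similarity 1.0 cannot be beaten
        if hit is not None:
            mapping[na] = hit
            continue
        best, best_sim = None, -1.0
        for nb, cb in by_state.get(st_a, ()):
            m = max(len(ca), len(cb))
            sim = 1.0 if m == 0 else 1.0 - levenshtein(ca, cb) / m
            if sim > best_sim or (sim == best_sim and best is not None and nb < best):
                best, best_sim = nb, sim
        if best is not None and best_sim >= min_similarity:
            mapping[na] = best
        else:
            unmapped.append(na)
    return mapping, unmapped


# ---------------------------------------------------------------------------
# record scoring

def _is_missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and np.isnan(v):
        return True
    if isinstance(v, str) and not v.strip():
        return True
    if isinstance(v, (set, frozenset, list, tuple)) and len(v) == 0:
        return True
    return False


def _as_set(v) -> frozenset:
    if isinstance(v, (set, frozenset)):
        return frozenset(v)
    if isinstance(v, (list, tuple)):
        return frozenset(v)
    return frozenset(str(v).split(";"))


def jaccard(a, b) -> float:
    sa, sb = _as_set(a), _as_set(b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


def attribute_scores(rec_a, rec_b) -> dict[str, float]:
    """Per-attribute similarity vector; missing fields score NaN.

    ``rec_a``/``rec_b`` are mappings (e.g. DataFrame rows) exposing the
    eight matching attributes.
    """
    out: dict[str, float] = {}
    for attr in MATCH_ATTRIBUTES:
        va, vb = rec_a.get(attr), rec_b.get(attr)
        if _is_missing(va) or _is_missing(vb):
            out[attr] = np.nan
        elif attr == "graduation_year":
            out[attr] = 1.0 if int(va) == int(vb) else 0.0
        elif attr in ("affiliated_hospitals", "specialties"):
            out[attr] = jaccard(va, vb)
        else:
            out[attr] = name_similarity(str(va), str(vb))
    return out


def combined_score(scores: dict[str, float], weights: AttributeWeights) -> float:
    """Weighted mean over non-missing scores, weights renormalized to sum 1."""
    num = den = 0.0
    for attr, s in scores.items():
        if np.isnan(s):
            continue
        w = weights.weights.get(attr, 0.0)
        num += w * s
        den += w
    if den == 0.0:
        raise UndefinedScoreError("all attribute scores missing")
    return num / den


# ---------------------------------------------------------------------------
# directory linkage

def _blocking_series(df: pd.DataFrame, blocking_key: str) -> pd.Series:
    if blocking_key in ("last_initial_state", "first_initial_state"):
        col = "last_name" if blocking_key.startswith("last") else "first_name"
        initial = df[col].fillna("").astype(str).str.strip().str.upper().str[:1]
        return blocking_key[0] + initial + "|" + df["state"].fillna("").astype(str)
    if blocking_key not in df.columns:
        raise KeyError(f"blocking key {blocking_key!r} not in directory columns")
    return df[blocking_key].astype(str)


def _record_view(df: pd.DataFrame) -> list[dict]:
    cols = [c for c in MATCH_ATTRIBUTES if c in df.columns]
    return [dict(zip(cols, row)) for row in df[cols].itertuples(index=False, name=None)]


DEFAULT_BLOCKING = ("last_initial_state", "first_initial_state")


def link_directories(
    dir_a: pd.DataFrame,
    dir_b: pd.DataFrame,
    weights: AttributeWeights | None = None,
    blocking_key: str | tuple[str, ...] = DEFAULT_BLOCKING,
    id_a: str = "npi",
    id_b: str = "site_id",
) -> LinkSet:
    """Score blocked candidate pairs and accept a one-to-at-most-one mapping.

    ``blocking_key`` may be a single key or several; with several, the
    candidate set is the union over blocking passes, which keeps recall high
    when noise corrupts the initial a single pass blocks on.  Acceptance is
    greedy in descending combined score; a pair whose b-side record is
    already matched is skipped; score ties break on the smaller
    ``(id_a, id_b)`` pair, making the output invariant to input row order.
    """
    weights = weights or AttributeWeights()
    keys = (blocking_key,) if isinstance(blocking_key, str) else tuple(blocking_key)
    recs_a, recs_b = _record_view(dir_a), _record_view(dir_b)
    ids_a, ids_b = dir_a[id_a].tolist(), dir_b[id_b].tolist()

    candidates: set[tuple[int, int]] = set()
    for key in keys:
        block_a = _blocking_series(dir_a, key)
        block_b = _blocking_series(dir_b, key)
        groups_a: dict[str, list[int]] = {}
        for i, k in enumerate(block_a):
            groups_a.setdefault(k, []).append(i)
        for j, k in enumerate(block_b):
            for i in groups_a.get(k, ()):
                candidates.add((i, j))

    rows = []
    for i, j in sorted(candidates):
        scores = attribute_scores(recs_a[i], recs_b[j])
        try:
            total = combined_score(scores, weights)
        except UndefinedScoreError:
            continue
        rows.append((ids_a[i], ids_b[j], *scores.values(), total))

    cols = [id_a, id_b, *MATCH_ATTRIBUTES, "score"]
    scored = pd.DataFrame(rows, columns=cols)

    accepted_rows = []
    if len(scored):
        order = scored.sort_values(
            ["score", id_a, id_b], ascending=[False, True, True], kind="mergesort"
        )
        taken_b: set = set()
        thr = weights.threshold
        for a, b, s in zip(order[id_a], order[id_b], order["score"]):
            if s < thr:
                break
            if b in taken_b:
                continue
            taken_b.add(b)
            accepted_rows.append((a, b, s))
    accepted = pd.DataFrame(accepted_rows, columns=[id_a, id_b, "score"])
    accepted = accepted.sort_values(id_b).reset_index(drop=True)
    return LinkSet(scored_pairs=scored.reset_index(drop=True),
                   accepted=accepted, threshold=weights.threshold)


def calibrate_threshold(
    scored_pairs: pd.DataFrame,
    truth_pairs: pd.DataFrame,
    id_a: str = "npi",
    id_b: str = "site_id",
    max_candidates: int = 2000,
) -> CalibrationResult:
    """Pick the score threshold maximizing F1 against known true pairs.

    Candidate thresholds are the distinct observed scores (quantile-thinned
    above ``max_candidates``).  A scored pair counts as predicted-positive at
    threshold t when its score >= t; recall is measured against all truth
    pairs, including any the blocking stage never scored.
    """
    if truth_pairs is None or len(truth_pairs) == 0:
        raise ValueError("calibration requires a nonempty truth set")
    truth = set(zip(truth_pairs[id_a], truth_pairs[id_b]))
    scores = scored_pairs["score"].to_numpy()
    is_true = np.fromiter(
        ((a, b) in truth for a, b in zip(scored_pairs[id_a], scored_pairs[id_b])),
        dtype=bool, count=len(scored_pairs),
    )
    candidates = np.unique(scores)
    if len(candidates) > max_candidates:
        qs = np.linspace(0, 1, max_candidates)
        candidates = np.unique(np.quantile(candidates, qs))

    n_truth = len(truth)
    best = CalibrationResult(threshold=1.0, precision=0.0, recall=0.0, f1=-1.0)
    for t in candidates:
        pred = scores >= t
        tp = int(np.sum(pred & is_true))
        fp = int(np.sum(pred & ~is_true))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / n_truth
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        # prefer the highest threshold at equal F1 (tightest acceptance)
        if f1 > best.f1 or (f1 == best.f1 and t > best.threshold):
            best = CalibrationResult(float(t), prec, rec, f1)
    return best


# ---------------------------------------------------------------------------
# specialty mapping

@dataclass
class SpecialtyMap:
    """Specialty -> hospital ranking categories, frequency-filtered."""

    entries: dict[str, set[str]]
    min_occurrences: int = 100

    def categories_for(self, specialty: str) -> set[str] | None:
        return self.entries.get(specialty)


def build_specialty_map(
    specialty_counts: dict[str, int],
    raw_entries: dict[str, set[str]],
    min_occurrences: int = 100,
) -> SpecialtyMap:
    """Keep only specialties occurring strictly more than ``min_occurrences`` times.

    Providers whose specialty is filtered out receive null hospital scores
    downstream.
    """
    if any(c < 0 for c in specialty_counts.values()):
        raise ValueError("specialty counts must be nonnegative")
    entries = {
        spec: set(cats)
        for spec, cats in raw_entries.items()
        if specialty_counts.get(spec, 0) > min_occurrences
    }
    return SpecialtyMap(entries=entries, min_occurrences=min_occurrences)
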