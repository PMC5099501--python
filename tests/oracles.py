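"""Independent brute-force oracles used to check the package's implementations.

Everything here is deliberately naive — full-matrix dynamic programming,
exhaustive enumeration, all-pairs distance scans — and shares no code with
the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def levenshtein_dp(a: str, b: str) -> int:
    """Full-matrix edit distance."""
    n, m = len(a), len(b)
    D = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        D[i][0] = i
    for j in range(m + 1):
        D[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i][j] = min(D[i - 1][j] + 1,
                          D[i][j - 1] + 1,
                          D[i - 1][j - 1] + (a[i - 1] != b[j - 1]))
    return D[n][m]


def pearson_closed_form(x, y) -> float:
    """r from explicit covariance / variance sums."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def _midranks(values) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def wilcoxon_exact_enum(differences) -> float:
    """Two-sided signed-rank p by enumerating all 2^n sign assignments."""
    d = [float(v) for v in differences if v != 0]
    n = len(d)
    ranks = _midranks([abs(v) for v in d])
    w_obs = sum(r for v, r in zip(d, ranks) if v > 0)
    ws = [sum(r for s, r in zip(signs, ranks) if s)
          for signs in itertools.product([0, 1], repeat=n)]
    lo = sum(w <= w_obs for w in ws) / len(ws)
    hi = sum(w >= w_obs for w in ws) / len(ws)
    return min(1.0, 2 * min(lo, hi))


def mannwhitney_exact_enum(group_a, group_b) -> float:
    """Two-sided Mann-Whitney p by enumerating rank assignments to group a."""
    a = [float(v) for v in group_a]
    b = [float(v) for v in group_b]
    n1 = len(a)
    pooled = a + b
    ranks = _midranks(pooled)
    u_obs = sum(ranks[:n1]) - n1 * (n1 + 1) / 2
    us = [sum(ranks[i] for i in comb) - n1 * (n1 + 1) / 2
          for comb in itertools.combinations(range(len(pooled)), n1)]
    lo = sum(u <= u_obs for u in us) / len(us)
    hi = sum(u >= u_obs for u in us) / len(us)
    return min(1.0, 2 * min(lo, hi))


_EARTH_R = 3958.8


def law_of_cosines_miles(lat1, lon1, lat2, lon2) -> float:
    """Spherical law of cosines great-circle distance (independent formula)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    c = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
    return _EARTH_R * math.acos(max(-1.0, min(1.0, c)))


def relative_cost_brute(provider_id, charges, directory, k, radius_miles):
    """All-pairs, explicit-sort relative cost for one provider.

    ``charges``: list of (provider_id, code, avg_charged, n_procedures);
    ``directory``: dict provider_id -> (specialty, lat, lon).
    Duplicate (provider, code) rows are combined by procedure-weighted mean.
    Returns NaN when the provider has no charge rows.
    """
    per: dict[tuple, list] = {}
    for pid, code, amt, nproc in charges:
        key = (pid, code)
        per.setdefault(key, [0.0, 0])
        per[key][0] += amt * nproc
        per[key][1] += nproc
    agg = {key: (tot / cnt, cnt) for key, (tot, cnt) in per.items()}

    my_codes = [(code, amt, cnt) for (pid, code), (amt, cnt) in agg.items()
                if pid == provider_id]
    if not my_codes:
        return float("nan")
    spec, lat, lon = directory[provider_id]

    num = den = 0.0
    for code, my_amt, my_cnt in my_codes:
        peers = []
        for (pid, c), (amt, _cnt) in agg.items():
            if c != code or pid == provider_id:
                continue
            pspec, plat, plon = directory[pid]
            if pspec != spec:
                continue
            d = law_of_cosines_miles(lat, lon, plat, plon)
            if d <= radius_miles:
                peers.append((d, pid, amt))
        peers.sort()
        neighborhood = [my_amt] + [amt for _d, _pid, amt in peers[: k - 1]]
        lo, hi = min(neighborhood), max(neighborhood)
        rel = 100.0 if hi == lo else 100.0 * (my_amt - lo) / (hi - lo)
        num += rel * my_cnt
        den += my_cnt
    return num / den


def calibrate_sweep_brute(scores, labels):
    """Best-F1 threshold by sweeping every distinct score (ties -> highest t)."""
    best_t, best_f1, best_pr = 1.0, -1.0, (0.0, 0.0)
    n_true = sum(labels)
    for t in sorted(set(scores)):
        tp = sum(1 for s, y in zip(scores, labels) if s >= t and y)
        fp = sum(1 for s, y in zip(scores, labels) if s >= t and not y)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / n_true if n_true else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        if f1 > best_f1 or (f1 == best_f1 and t > best_t):
            best_t, best_f1, best_pr = t, f1, (prec, rec)
    return best_t, best_f1, best_pr
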