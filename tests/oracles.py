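"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive (O(n*m) scans, exhaustive window
enumeration, full combinatorial enumeration) and shares no code with the
package paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
import scipy.stats as ss


def _overlap(a, b) -> bool:
    return a[0] == b[0] and min(a[2], b[2]) - max(a[1], b[1]) >= 1


def brute_merge(triples: list[tuple]) -> list[tuple]:
    """Union of (chrom,start,end) triples by repeated pairwise coalescing."""
    items = [list(t) for t in triples]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                if _overlap(items[i], items[j]):
                    items[i] = [items[i][0], min(items[i][1], items[j][1]),
                                max(items[i][2], items[j][2])]
                    del items[j]
                    changed = True
                    break
            if changed:
                break
    return sorted(tuple(t) for t in items)


def brute_subtract(a: list[tuple], b: list[tuple]) -> list[tuple]:
    return sorted(x for x in a if not any(_overlap(x, y) for y in b))


def brute_label(merged: list[tuple], a: list[tuple], b: list[tuple]) -> list[str]:
    out = []
    for m in merged:
        in_a = any(_overlap(m, x) for x in a)
        in_b = any(_overlap(m, x) for x in b)
        out.append("common" if in_a and in_b else ("a_only" if in_a else "b_only"))
    return out


def brute_classify(query: list[tuple], promoters, dtres, enhancers) -> list[str]:
    out = []
    for q in query:
        if any(_overlap(q, p) for p in promoters):
            out.append("promoter")
        elif any(_overlap(q, d) for d in dtres):
            out.append("dTRE")
        elif any(_overlap(q, e) for e in enhancers):
            out.append("enhancer")
        else:
            out.append("remote")
    return out


# ---- HSE scanner oracle ------------------------------------------------


def _unit_core(seq: str, p: int) -> str:
    return seq[p + 1:p + 4]


def brute_scan_hre(seq: str, min_units: int = 3) -> set[tuple]:
    """All maximal alternating-pentamer runs as (start, end, phase, n_units).

    Exhaustive: every (start, k, first-core) window is checked unit by unit,
    then non-maximal windows are discarded.
    """
    seq = seq.upper()
    n = len(seq)
    hits = set()
    for first in ("GAA", "TTC"):
        other = "TTC" if first == "GAA" else "GAA"
        for start in range(0, n - 5 * min_units + 1):
            k = 0
            while start + 5 * (k + 1) <= n:
                want = first if k % 2 == 0 else other
                if _unit_core(seq, start + 5 * k) != want:
                    break
                k += 1
            if k < min_units:
                continue
            # maximality: no matching unit immediately left or right
            left_ok = start - 5 < 0 or _unit_core(seq, start - 5) != other
            want_next = first if k % 2 == 0 else other
            right_ok = (start + 5 * (k + 1) > n
                        or _unit_core(seq, start + 5 * k) != want_next)
            if left_ok and right_ok:
                phase = "GAA-first" if first == "GAA" else "TTC-first"
                hits.add((start, start + 5 * k, phase, k))
    return hits


# ---- rank-test oracles -------------------------------------------------


def enum_mann_whitney_p(x, y) -> float:
    """Two-sided permutation p for the U statistic by full enumeration."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = ss.rankdata(pooled)
    n1, n = len(x), len(pooled)
    mu = n1 * (n - n1) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
        total += 1
    return count / total


def enum_spearman_p(x, y) -> float:
    """Two-sided exact permutation p for Spearman rho."""
    xr = ss.rankdata(x)
    yr = ss.rankdata(y)
    rho_obs = abs(np.corrcoef(xr, yr)[0, 1])
    count = total = 0
    for perm in itertools.permutations(yr):
        rho = abs(np.corrcoef(xr, np.asarray(perm))[0, 1])
        if rho >= rho_obs - 1e-12:
            count += 1
        total += 1
    return count / total
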