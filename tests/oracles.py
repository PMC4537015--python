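"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive -- exhaustive enumeration, direct
textbook formulas, substring scans -- and shares no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def mannwhitney_exact_p(a, b) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all group labelings.

    Assumes no ties.  U counts pairs where an ``a`` value exceeds a ``b``
    value; the two-sided p doubles the smaller tail (equivalently, by the
    symmetry of the tie-free null, sums labelings at least as extreme about
    the mean n_a*n_b/2), capped at 1.
    """
    a, b = list(a), list(b)
    combined = a + b
    n, k = len(combined), len(a)
    mu = k * (n - k) / 2.0

    def u_stat(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y)

    u_obs = u_stat(a, b)
    count = total = 0
    for idx in itertools.combinations(range(n), k):
        ga = [combined[i] for i in idx]
        gb = [combined[i] for i in range(n) if i not in idx]
        u = u_stat(ga, gb)
        total += 1
        if abs(u - mu) >= abs(u_obs - mu):
            count += 1
    return min(1.0, count / total)


def bh_stepup(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values, direct step-up definition."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adjusted[i] = running_min
    return adjusted


def quartile_type7(values, q: float) -> float:
    """Linear-interpolation quantile: position 1 + (n-1)q between order
    statistics (the "type 7" convention)."""
    v = sorted(float(x) for x in values)
    h = (len(v) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def quartile_separation(values_a, values_b) -> bool:
    q1a = quartile_type7(values_a, 0.25)
    q3a = quartile_type7(values_a, 0.75)
    q1b = quartile_type7(values_b, 0.25)
    q3b = quartile_type7(values_b, 0.75)
    return q1a > q3b or q1b > q3a


_RC = {"A": "U", "U": "A", "C": "G", "G": "C"}


def naive_seed_sites(mirna: str, utr: str) -> set[tuple[str, int]]:
    """All (site_type, 1-based start) pairs by brute-force substring scan.

    Finds every overlapping occurrence of each of the four patterns, then
    keeps only the most specific type per seed locus (the position of the
    core 6mer), mirroring the published nesting rule by construction from
    the pattern definitions alone.
    """
    rc = lambda s: "".join(_RC[c] for c in reversed(s))
    six = rc(mirna[1:7])
    m8 = rc(mirna[1:8])
    patterns = {"6mer": six, "7mer-A1": six + "A", "7mer-m8": m8, "8mer": m8 + "A"}
    # core (0-based) -> {type: pattern start (0-based)}
    loci: dict[int, dict[str, int]] = {}
    for stype, pat in patterns.items():
        for i in range(len(utr) - len(pat) + 1):
            if utr[i : i + len(pat)] == pat:
                core = i + 1 if stype in ("7mer-m8", "8mer") else i
                loci.setdefault(core, {})[stype] = i
    out = set()
    for core, found in loci.items():
        for stype in ("8mer", "7mer-m8", "7mer-A1", "6mer"):
            if stype in found:
                out.add((stype, found[stype] + 1))
                break
    return out


def naive_are_runs(utr: str) -> list[tuple[int, int]]:
    """Maximal overlapping-AUUUA runs as (1-based start, pentamer count),
    built by chaining occurrences whose starts differ by 4."""
    positions = [i for i in range(len(utr) - 4) if utr[i : i + 5] == "AUUUA"]
    runs = []
    i = 0
    while i < len(positions):
        j = i
        while j + 1 < len(positions) and positions[j + 1] == positions[j] + 4:
            j += 1
        runs.append((positions[i] + 1, j - i + 1))
        i = j + 1
    return runs
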