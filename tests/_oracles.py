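"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from the definitions (loops,
enumeration, math.comb) and shares no code path with the package.
"""

from __future__ import annotations

import itertools
import math
import statistics

PAIRS = {("G", "C"): -3.0, ("C", "G"): -3.0,
         ("A", "T"): -2.0, ("T", "A"): -2.0,
         ("G", "T"): -1.0, ("T", "G"): -1.0}
MIN_LOOP = 3


# --- junk rules ------------------------------------------------------------

def junk_oracle(seq, min_N=2, runs=(("A", 7), ("C", 8), ("G", 6), ("T", 7)),
                tandems=((2, 10), (3, 6), (4, 5))):
    """Substring-search re-statement of the junk rules."""
    if seq.count("N") >= min_N:
        return True
    for base, threshold in runs:
        if base * threshold in seq:
            return True
    for k, copies in tandems:
        for start in range(len(seq) - k + 1):
            motif = seq[start:start + k]
            if motif * copies in seq:
                return True
    return False


# --- nested structure enumeration ------------------------------------------

def enumerate_structures(seq):
    """All nested structures (as frozensets of index pairs) with loops >= 3."""
    n = len(seq)
    memo = {}

    def rec(i, j):
        if (i, j) in memo:
            return memo[(i, j)]
        if j - i < MIN_LOOP:
            memo[(i, j)] = [frozenset()]
            return memo[(i, j)]
        out = list(rec(i + 1, j))
        for k in range(i + MIN_LOOP + 1, j + 1):
            if (seq[i], seq[k]) in PAIRS:
                for left in rec(i + 1, k - 1):
                    base = left | {(i, k)}
                    for right in rec(k + 1, j):
                        out.append(base | right)
        memo[(i, j)] = out
        return out

    return rec(0, n - 1)


def structure_energy(seq, pairs):
    return sum(PAIRS[(seq[i], seq[j])] for i, j in pairs)


def best_fold_by_enumeration(seq):
    """(minimum energy, maximal pair count among minimum-energy structures)."""
    best_e = 0.0
    best_np = 0
    for pairs in enumerate_structures(seq):
        e = structure_energy(seq, pairs)
        if e < best_e - 1e-9:
            best_e, best_np = e, len(pairs)
        elif abs(e - best_e) <= 1e-9:
            best_np = max(best_np, len(pairs))
    return best_e, best_np


# --- end-shift / mismatch read matching ------------------------------------

def match_oracle(read, ref, max_shift5=3, max_shift3=3, max_mm=1):
    """Exhaustive check whether *read* matches *ref* under the allowances."""
    for s in range(-max_shift5, max_shift5 + 1):
        t = len(read) - len(ref) - s
        if abs(t) > max_shift3:
            continue
        lo, hi = max(0, s), min(len(read), len(ref) + s)
        if hi <= lo:
            continue
        mm = sum(1 for i in range(lo, hi) if read[i] != ref[i - s])
        if mm <= max_mm:
            return True
    return False


# --- hypergeometric enrichment ---------------------------------------------

def hypergeom_tail(k, N, K, n):
    """Exact upper-tail P(X >= k) via integer binomials."""
    denom = math.comb(N, n)
    total = 0
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / denom


# --- Spearman --------------------------------------------------------------

def _ranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for idx in order[i:j + 1]:
            ranks[idx] = avg
        i = j + 1
    return ranks


def _pearson(x, y):
    mx, my = sum(x) / len(x), sum(y) / len(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def spearman_oracle(x, y):
    """(rs, exact two-sided permutation p) by full enumeration."""
    rx, ry = _ranks(list(x)), _ranks(list(y))
    r_obs = _pearson(rx, ry)
    count = total = 0
    for perm in itertools.permutations(ry):
        r = _pearson(rx, list(perm))
        if abs(r) >= abs(r_obs) - 1e-12:
            count += 1
        total += 1
    return r_obs, count / total


# --- geNorm ----------------------------------------------------------------

def genorm_m_oracle(quantities):
    """M per gene from the definition; ``quantities``: {gene: [per-sample q]}."""
    genes = list(quantities)
    m = {}
    for g in genes:
        sds = []
        for h in genes:
            if h == g:
                continue
            ratios = [math.log2(a / b)
                      for a, b in zip(quantities[g], quantities[h])]
            sds.append(statistics.stdev(ratios))
        m[g] = sum(sds) / len(sds)
    return m


def genorm_v_oracle(quantities, ranking):
    """V_{n/n+1} per n from the definition (geometric-mean NFs)."""
    n_samples = len(next(iter(quantities.values())))

    def nf(genes):
        out = []
        for s in range(n_samples):
            prod = 1.0
            for g in genes:
                prod *= quantities[g][s]
            out.append(prod ** (1.0 / len(genes)))
        return out

    v = {}
    for n in range(2, len(ranking)):
        a = nf(ranking[:n])
        b = nf(ranking[:n + 1])
        logs = [math.log2(x / y) for x, y in zip(a, b)]
        v[n] = statistics.stdev(logs)
    return v
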