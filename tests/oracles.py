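"""Independent brute-force oracles used by the test suite.

Each oracle is a deliberately naive re-derivation of a quantity the
package computes by a different route: exhaustive dynamic programming
over alignment states, exhaustive subset enumeration for rarefaction,
and exhaustive partition search for synteny conflict resolution.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

from panoen._aligner import ALPHABET, BLOSUM62

NEG = (-10 ** 9, 0, 0)


def brute_force_align(a: str, b: str, gap_open: int = 11, gap_extend: int = 1):
    """Optimal (score, matches, columns) of a free-end-gap affine
    alignment, by memoized recursion over (i, j, last-column-state)."""
    S = {(x, y): int(BLOSUM62[ALPHABET.index(x), ALPHABET.index(y)])
         for x in set(a) for y in set(b)}
    n, m = len(a), len(b)

    @lru_cache(maxsize=None)
    def best_end(i: int, j: int, state: str):
        if state == "M":
            if i < 1 or j < 1:
                return NEG
            d = S[(a[i - 1], b[j - 1])]
            mt = 1 if a[i - 1] == b[j - 1] else 0
            opts = [best_end(i - 1, j - 1, s) for s in "MEF"]
            if i == 1 or j == 1:
                opts.append((0, 0, 0))
            bb = max(opts)
            if bb[0] <= -10 ** 8:
                return NEG
            return (bb[0] + d, bb[1] + mt, bb[2] - 1)
        if state == "E":
            if j < 1:
                return NEG
            om = best_end(i, j - 1, "M")
            oe = best_end(i, j - 1, "E")
            cands = []
            if om[0] > -10 ** 8:
                cands.append((om[0] - gap_open - gap_extend, om[1], om[2] - 1))
            if oe[0] > -10 ** 8:
                cands.append((oe[0] - gap_extend, oe[1], oe[2] - 1))
            return max(cands) if cands else NEG
        if i < 1:
            return NEG
        om = best_end(i - 1, j, "M")
        of = best_end(i - 1, j, "F")
        cands = []
        if om[0] > -10 ** 8:
            cands.append((om[0] - gap_open - gap_extend, om[1], om[2] - 1))
        if of[0] > -10 ** 8:
            cands.append((of[0] - gap_extend, of[1], of[2] - 1))
        return max(cands) if cands else NEG

    ends = [best_end(n, j, "M") for j in range(1, m + 1)]
    ends += [best_end(i, m, "M") for i in range(1, n)]
    score, matches, neg_cols = max(ends)
    return score, matches, -neg_cols


def brute_force_rarefaction(values: np.ndarray, x: int,
                            core_thr: int = 2, pan_thr: int = 1):
    """(sum of core, sum of pan, count) over all strain subsets of size x."""
    S = values.shape[1]
    core_sum = pan_sum = count = 0
    for cols in itertools.combinations(range(S), x):
        sub = values[:, list(cols)]
        core_sum += int((sub >= core_thr).all(axis=1).sum())
        pan_sum += int((sub >= pan_thr).any(axis=1).sum())
        count += 1
    return core_sum, pan_sum, count


def brute_force_conflict_partition(strains, agree, min_join=2):
    """Best total pairwise agreement over all partitions with <=1 member
    per strain per group, joining only at >= min_join agreement."""
    n = len(strains)
    best = [-1, None]

    def score_of(groups):
        tot = 0
        for g in groups:
            for i, a in enumerate(g):
                for b in g[i + 1:]:
                    tot += agree[a][b]
        return tot

    def recurse(k, groups):
        if k == n:
            sc = score_of(groups)
            if sc > best[0]:
                best[0] = sc
                best[1] = [sorted(g) for g in groups]
            return
        for g in groups:
            if any(strains[x] == strains[k] for x in g):
                continue
            if sum(agree[x][k] for x in g) >= min_join:
                g.append(k)
                recurse(k + 1, groups)
                g.pop()
        groups.append([k])
        recurse(k + 1, groups)
        groups.pop()

    recurse(0, [])
    return best[0], best[1]


def pairwise_nt_divergence(a: str, b: str) -> float:
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    n = min(arr_a.size, arr_b.size)
    return float((arr_a[:n] != arr_b[:n]).mean())
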