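"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation paths they check: the LZ76
oracle tests substring reproducibility by naive character-by-character
scanning, and the Mann-Whitney oracle enumerates every rank assignment.
"""

from __future__ import annotations

import itertools
import math


def _occurs(word, text) -> bool:
    """Naive scan: does ``word`` occur in ``text``? (no str.find)"""
    lw, lt = len(word), len(text)
    for start in range(lt - lw + 1):
        if all(text[start + i] == word[i] for i in range(lw)):
            return True
    return False


def lz76_oracle(symbols) -> int:
    """LZ76 word count by definition: close a word when the current word
    stops being reproducible from the extended prior history."""
    s = list(symbols)
    n = len(s)
    count = 0
    h = 0
    while h < n:
        j = h + 1
        # extend while s[h:j] occurs somewhere in s[0:j-1]
        while j < n and _occurs(s[h:j], s[: j - 1]):
            j += 1
        count += 1
        h = j
    return count


def mannwhitney_exact_p(x, y) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all rank splits.

    Assumes no ties.  The p-value is the probability, under random
    assignment of the pooled values to the two groups, of a U at least
    as extreme (two-sided, by distance from the mean) as observed.
    """
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    observed_u = sum(1 for xi in x for yj in y if xi > yj)
    mu = n1 * n2 / 2.0
    pooled = sorted(x + y)
    total = math.comb(n1 + n2, n1)
    extreme = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        chosen = set(combo)
        u = sum(
            1
            for i in combo
            for j in range(n1 + n2)
            if j not in chosen and pooled[i] > pooled[j]
        )
        if abs(u - mu) >= abs(observed_u - mu) - 1e-12:
            extreme += 1
    return extreme / total


def u_distribution(n1, n2):
    """Exact Mann-Whitney U distribution (no ties) by enumerating every
    assignment of pooled ranks to the first group."""
    counts = {}
    half = n1 * (n1 - 1) // 2
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = sum(combo) - half
        counts[u] = counts.get(u, 0) + 1
    total = math.comb(n1 + n2, n1)
    return counts, total


def exact_two_sided_p(n1, n2, observed_u):
    counts, total = u_distribution(n1, n2)
    mu = n1 * n2 / 2.0
    extreme = sum(c for u, c in counts.items()
                  if abs(u - mu) >= abs(observed_u - mu) - 1e-12)
    return extreme / total


def best_alignment_bruteforce(corr):
    """Exhaustive search over all permutations maximizing sum |corr|."""
    import numpy as np

    corr = np.asarray(corr)
    k = corr.shape[0]
    best_perm, best_score = None, -np.inf
    for perm in itertools.permutations(range(k)):
        score = sum(abs(corr[i, perm[i]]) for i in range(k))
        if score > best_score:
            best_perm, best_score = perm, score
    return list(best_perm), best_score
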