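"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive everything from first principles with plain
Python loops — no numpy vectorization, no scipy, and no imports from the
scoring internals they check — so agreement with the package is a real
cross-validation, not a tautology.
"""

from __future__ import annotations

from collections import Counter
from itertools import combinations


def brute_force_pileup(reads, locus_length):
    """Per-position depth and base lists from (ref_start, base_calls) pairs."""
    depth = [0] * locus_length
    bases: list[list[str]] = [[] for _ in range(locus_length)]
    for ref_start, calls in reads:
        for offset, base in enumerate(calls):
            pos = ref_start + offset
            if pos < 0 or pos >= locus_length:
                continue
            depth[pos] += 1
            if base != "-":
                bases[pos].append(base.upper())
    return depth, bases


def brute_force_call(
    reads,
    sequence,
    window_length=50,
    min_depth=3.0,
    min_usable_windows=9,
    window_identity=99.0,
):
    """Recompute the ternary locus call entirely from scratch.

    reads: iterable of (ref_start, base_calls) with '-' for deleted
    positions.  Returns (call, depth, n_usable, n_passed).
    """
    L = len(sequence)
    depth, bases = brute_force_pileup(reads, L)
    n_windows = L // window_length

    n_usable = 0
    n_passed = 0
    for w in range(n_windows):
        lo, hi = w * window_length, (w + 1) * window_length
        usable = all(depth[p] >= 1 for p in range(lo, hi))
        matches = 0
        for p in range(lo, hi):
            if not bases[p]:
                continue
            counts = Counter(bases[p])
            top = max(counts.values())
            ref = sequence[p].upper()
            # ties break toward the reference base
            if counts.get(ref, 0) == top:
                matches += 1
        identity = 100.0 * matches / window_length
        if usable:
            n_usable += 1
            if identity >= window_identity:
                n_passed += 1

    span = n_windows * window_length
    mean_depth = sum(depth[:span]) / span if span else 0.0

    if n_windows < min_usable_windows:
        call = "uncallable"
    elif (
        mean_depth >= min_depth
        and n_usable >= min_usable_windows
        and n_usable > 0
        and n_passed == n_usable
    ):
        call = "positive"
    else:
        call = "negative"
    return call, mean_depth, n_usable, n_passed


def exact_mannwhitney(x, y):
    """Exhaustive two-sided Mann-Whitney U for tie-free samples.

    Enumerates every C(n+m, n) assignment of the pooled values to the first
    group; p is the fraction of assignments whose U is at least as far from
    the null mean nm/2 as the observed U.  Returns (U_observed, p).
    """
    x, y = list(x), list(y)
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free input"
    n, m = len(x), len(y)

    def u_stat(group_a, group_b):
        return sum(1 for a in group_a for b in group_b if a > b)

    u_obs = u_stat(x, y)
    center = n * m / 2.0
    observed_dev = abs(u_obs - center)

    hits = 0
    total = 0
    indices = range(n + m)
    for combo in combinations(indices, n):
        chosen = set(combo)
        a = [pooled[i] for i in indices if i in chosen]
        b = [pooled[i] for i in indices if i not in chosen]
        total += 1
        if abs(u_stat(a, b) - center) >= observed_dev - 1e-12:
            hits += 1
    return u_obs, hits / total
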