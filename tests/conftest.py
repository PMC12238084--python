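"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results by exhaustive / naive
methods (plain DP over an unrolled monomer, recursive alignment enumeration,
sliding Hamming counts) so the vectorized implementations are checked
against a different computation path.
"""

from __future__ import annotations

import random
from functools import lru_cache

import pytest

from repeatprobe.repeatscan import AlignmentWeights


def wraparound_score_oracle(seg: str, mon: str, w: AlignmentWeights | None = None) -> int:
    """Brute-force wraparound score: global-in-segment alignment against the
    monomer unrolled enough times, with free endpoints on the monomer axis."""
    w = w or AlignmentWeights()
    K = len(seg) // len(mon) + 3
    T = mon * K
    n, m = len(seg), len(T)
    NEG = -(10**9)
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [NEG] * (m + 1)
        cur[0] = prev[0] - w.indel_penalty
        for j in range(0, m + 1):
            best = cur[j]
            if j > 0:
                eq = seg[i - 1] == T[j - 1] and seg[i - 1] in "ACGT"
                sub = w.match_reward if eq else -w.mismatch_penalty
                best = max(best, prev[j - 1] + sub)
            best = max(best, prev[j] - w.indel_penalty)
            if j > 0:
                best = max(best, cur[j - 1] - w.indel_penalty)
            cur[j] = best
        prev = cur
    return max(prev)


def nw_identity_oracle(a: str, b: str) -> float:
    """Recursive enumeration maximizing (score, matches, -columns) under
    unit weights; identity = 100 * matches / columns."""

    @lru_cache(maxsize=None)
    def go(i: int, j: int):
        if i == 0 and j == 0:
            return (0, 0, 0)
        best = None
        if i > 0 and j > 0:
            s, m, c = go(i - 1, j - 1)
            eq = a[i - 1] == b[j - 1] and a[i - 1] in "ACGT"
            cand = (s + (1 if eq else -1), m + (1 if eq else 0), c - 1)
            best = cand
        if i > 0:
            s, m, c = go(i - 1, j)
            cand = (s - 1, m, c - 1)
            best = cand if best is None or cand > best else best
        if j > 0:
            s, m, c = go(i, j - 1)
            cand = (s - 1, m, c - 1)
            best = cand if best is None or cand > best else best
        return best

    s, m, c = go(len(a), len(b))
    return 100.0 * m / (-c) if c else 100.0


def sliding_hamming_hits(seq: str, probe: str, min_identity: float) -> list[int]:
    """Naive forward-strand scan: positions with identity strictly above
    min_identity under the ungapped Hamming model (N never matches)."""
    L = len(probe)
    out = []
    for i in range(len(seq) - L + 1):
        matches = sum(
            1
            for a, b in zip(seq[i : i + L], probe)
            if a == b and a in "ACGT"
        )
        if 100.0 * matches > min_identity * L:
            out.append(i)
    return out


def random_seq(rng: random.Random, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


@pytest.fixture()
def rng() -> random.Random:
    return random.Random(20260920)
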