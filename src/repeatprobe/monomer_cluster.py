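"""Greedy identity clustering of consensus monomers (CD-HIT semantics).

Monomers are sorted by descending length and assigned first-fit to the first
existing representative whose global alignment identity reaches the
threshold; otherwise they found a new cluster.  Identity is computed from an
optimal global (Needleman-Wunsch) alignment under unit weights
(match +1, mismatch -1, gap -1); among equal-score alignments the one with
the most matches, then the fewest columns, defines the identity, making the
value deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ClusterParams:
    identity_threshold: float = 75.0  # inclusive for membership
    consider_reverse_complement: bool = True
    consider_rotations: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.identity_threshold <= 100:
            raise ValueError("identity_threshold must lie in (0, 100]")


@dataclass
class MonomerCluster:
    representative_id: str
    representative: str
    members: list[tuple[str, float]] = field(default_factory=list)  # (id, identity%)


def _nw_identity(a: str, b: str) -> float:
    """Identity percent from the canonical optimal global alignment.

    DP maximizes the lexicographic objective (score, matches, -columns),
    packed into one integer so rows vectorize with numpy.
    """
    n, m = len(a), len(b)
    L = max(n, m)
    # composite = score*A + matches*B + (colcap - columns); pick radixes wide
    # enough that the lower fields never borrow from the higher ones
    colcap = 2 * L + 1
    B = 4 * L + 4
    A = (L + 2) * B * colcap
    ca = np.frombuffer(a.encode(), dtype=np.uint8)
    cb = np.frombuffer(b.encode(), dtype=np.uint8)
    gap = -A - 1  # score -1, matches 0, one column
    # row DP over b (vector axis)
    prev = np.empty(m + 1, dtype=np.int64)
    prev[0] = colcap  # zero columns consumed => field starts at colcap... see decode
    prev[1:] = colcap + np.arange(1, m + 1, dtype=np.int64) * gap
    valid = cb != ord("N")
    for i in range(1, n + 1):
        eq = (cb == ca[i - 1]) & valid & (ca[i - 1] != ord("N"))
        diag_add = np.where(eq, A + B - 1, -A - 1)
        cur = np.empty(m + 1, dtype=np.int64)
        cur[0] = prev[0] + gap
        best = np.maximum(prev[:-1] + diag_add, prev[1:] + gap)
        # horizontal gap chain: prefix max with linear decay
        off = np.arange(1, m + 1, dtype=np.int64) * (-gap)
        tmp = np.maximum.accumulate(np.concatenate(([cur[0]], best + off)))
        cur[1:] = tmp[1:] - off
        prev = cur
    val = int(prev[m])
    # decode (score, matches, columns)
    smin = -(n + m)  # least possible score
    shifted = val - smin * A
    score = shifted // A + smin
    rem = val - score * A
    matches = rem // B
    cols = colcap - (rem - matches * B)
    if cols <= 0:
        return 100.0
    return 100.0 * matches / cols


def global_identity(a: str, b: str, params: ClusterParams | None = None) -> float:
    """Global alignment identity percent between two sequences.

    With ``consider_reverse_complement`` (default), the maximum over both
    orientations of ``b`` is returned; with ``consider_rotations``, also the
    maximum over all cyclic rotations of the shorter sequence.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    params = params or ClusterParams()
    a, b = a.upper(), b.upper()

    def best_for(bb: str) -> float:
        if not params.consider_rotations:
            return _nw_identity(a, bb)
        if len(a) <= len(bb):
            rots = [a[i:] + a[:i] for i in range(len(a))]
            return max(_nw_identity(r, bb) for r in rots)
        rots = [bb[i:] + bb[:i] for i in range(len(bb))]
        return max(_nw_identity(a, r) for r in rots)

    ident = best_for(b)
    if params.consider_reverse_complement:
        ident = max(ident, best_for(reverse_complement(b)))
    return ident


def greedy_cluster(
    monomers: list[tuple[str, str]], params: ClusterParams | None = None
) -> list[MonomerCluster]:
    """Cluster (id, sequence) monomers greedily.

    Longest-first (ties: input order); each monomer joins the first existing
    cluster whose representative identity >= threshold, else founds one.
    """
    if not monomers:
        raise ValueError("monomers must be non-empty")
    params = params or ClusterParams()
    order = sorted(range(len(monomers)), key=lambda i: (-len(monomers[i][1]), i))
    clusters: list[MonomerCluster] = []
    for i in order:
        mid, seq = monomers[i]
        placed = False
        for cl in clusters:
            ident = global_identity(seq, cl.representative, params)
            if ident >= params.identity_threshold:
                cl.members.append((mid, round(ident, 2)))
                placed = True
                break
        if not placed:
            clusters.append(
                MonomerCluster(representative_id=mid, representative=seq,
                               members=[(mid, 100.0)])
            )
    return clusters
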