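"""Tandem repeat array detection, scoring, de-overlap and filtering.

The scoring model is wraparound dynamic programming: a genomic segment is
aligned globally against an unbounded head-to-tail concatenation of a monomer,
with alignment columns that re-enter monomer column 1 after the last one.
This is the classic tandem-repeat scoring model; scores use integer
match/mismatch/indel weights (default +2 / -7 / -7).

Detection is a deterministic two-stage procedure:

1. exact k-mer seeding (default k=13): every position whose k-mer re-occurs
   at distance ``d`` (1 <= d <= max_period) upstream votes for period ``d``;
   votes at the same distance are chained into candidate intervals;
2. each candidate is rescored by wraparound alignment against a
   traceback-refined column-majority consensus; candidates below the minimum
   score are discarded.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

#: sentinel code for N / unknown bases; never matches anything, itself included
N_CODE = 4


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0 C=1 G=2 T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class AlignmentWeights:
    """Integer alignment weights; penalties are stored positive."""

    match_reward: int = 2
    mismatch_penalty: int = 7
    indel_penalty: int = 7

    def __post_init__(self) -> None:
        if min(self.match_reward, self.mismatch_penalty, self.indel_penalty) < 0:
            raise ValueError("alignment weights must be non-negative")


@dataclass(frozen=True)
class DetectionParams:
    """Tandem repeat detection thresholds.

    ``prob_match`` / ``prob_indel`` are the percent match / indel rates the
    candidate model tolerates; in this detector they only set the allowed gap
    between successive exact seeds of a candidate chain, the binding filter
    being ``min_score``.
    """

    weights: AlignmentWeights = field(default_factory=AlignmentWeights)
    min_score: int = 50
    max_period: int = 2000
    prob_match: float = 80.0
    prob_indel: float = 10.0
    seed_kmer: int = 13

    def __post_init__(self) -> None:
        if self.min_score <= 0:
            raise ValueError("min_score must be positive")
        if self.max_period < 1:
            raise ValueError("max_period must be >= 1")
        if not 0 < self.prob_match <= 100:
            raise ValueError("prob_match must lie in (0, 100]")
        if not 0 <= self.prob_indel < 100:
            raise ValueError("prob_indel must lie in [0, 100)")
        if self.seed_kmer < 2:
            raise ValueError("seed_kmer must be >= 2")


@dataclass(frozen=True)
class FilterParams:
    """Array retention thresholds: period >= min_period, copies >= min_copies,
    percent matches strictly > min_pct_match."""

    min_period: int = 10
    min_copies: float = 50.0
    min_pct_match: float = 70.0

    def __post_init__(self) -> None:
        if self.min_period < 1:
            raise ValueError("min_period must be >= 1")
        if self.min_copies < 1:
            raise ValueError("min_copies must be >= 1")
        if not 0 <= self.min_pct_match <= 100:
            raise ValueError("min_pct_match must lie in [0, 100]")


@dataclass(frozen=True)
class AlignmentResult:
    score: int
    matches: int
    mismatches: int
    indels: int
    copy_number: float


@dataclass(frozen=True)
class TandemRepeatArray:
    """A located tandem repeat array with its consensus monomer."""

    chrom: str
    start: int
    end: int
    period: int
    copy_number: float
    pct_match: float
    pct_indel: float
    score: int
    consensus: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("start must be < end")
        if len(self.consensus) != self.period:
            raise ValueError("consensus length must equal period")

    @property
    def span(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# wraparound alignment
# ---------------------------------------------------------------------------


def _substitution_row(seg_code: int, mon: np.ndarray, w: AlignmentWeights) -> np.ndarray:
    eq = (mon == seg_code) & (mon != N_CODE) & (seg_code != N_CODE)
    return np.where(eq, w.match_reward, -w.mismatch_penalty).astype(np.int64)


def _wraparound_matrix(seg: np.ndarray, mon: np.ndarray, w: AlignmentWeights) -> np.ndarray:
    """Full DP matrix D of shape (n+1, p).

    D[i, j] = best score consuming seg[:i], the alignment currently sitting
    just after monomer column j.  Row 0 is all zero (free phase start); the
    within-row cyclic deletion chain is solved exactly by a prefix-max scan
    over the doubled column axis (one wrap suffices: a second full cycle of
    deletions can never raise the score).
    """
    n, p = len(seg), len(mon)
    c = w.indel_penalty
    D = np.empty((n + 1, p), dtype=np.int64)
    D[0] = 0
    jcost = np.arange(p, dtype=np.int64) * c
    for i in range(1, n + 1):
        prev = D[i - 1]
        sub = _substitution_row(seg[i - 1], mon, w)
        v = np.maximum(np.roll(prev, 1) + sub, prev - c)
        # cyclic left-moves: D[i,j] = max_t V[(j-t) mod p] - t*c, t in [0, j+p]
        a = v + jcost
        b = np.concatenate([a, a + p * c])
        m = np.maximum.accumulate(b)
        D[i] = m[p:] - (jcost + p * c)
    return D


def wraparound_align(
    segment: str, monomer: str, weights: AlignmentWeights | None = None
) -> AlignmentResult:
    """Align ``segment`` against tandem copies of ``monomer``; return the
    optimal score and the match/mismatch/indel counts of one optimal
    traceback.

    ``copy_number`` is the number of monomer columns consumed divided by the
    period, to one decimal.  N bases never match (they score as mismatches).

    Raises ``ValueError`` on empty input.
    """
    if not segment or not monomer:
        raise ValueError("segment and monomer must be non-empty")
    w = weights or AlignmentWeights()
    seg = encode(segment)
    mon = encode(monomer)
    n, p = len(seg), len(mon)
    c = w.indel_penalty
    D = _wraparound_matrix(seg, mon, w)
    j = int(np.argmax(D[n]))
    i = n
    matches = mismatches = indels = cols = 0
    left_run = 0
    while i > 0:
        jp = (j - 1) % p
        is_match = seg[i - 1] == mon[j] and seg[i - 1] != N_CODE
        sub = w.match_reward if is_match else -w.mismatch_penalty
        if D[i, j] == D[i - 1, jp] + sub:
            if is_match:
                matches += 1
            else:
                mismatches += 1
            cols += 1
            i, j = i - 1, jp
            left_run = 0
        elif D[i, j] == D[i - 1, j] - c:
            indels += 1
            i = i - 1
            left_run = 0
        elif left_run < p - 1 and D[i, j] == D[i, jp] - c:
            indels += 1
            cols += 1
            j = jp
            left_run += 1
        else:  # pragma: no cover - defensive; D is internally consistent
            raise RuntimeError("traceback inconsistency in wraparound alignment")
    score = int(D[n].max())
    return AlignmentResult(
        score=score,
        matches=matches,
        mismatches=mismatches,
        indels=indels,
        copy_number=round(cols / p, 1),
    )


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def _kmer_codes(seq: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of all k-mers and a validity mask (no N inside)."""
    n = len(seq) - k + 1
    codes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for t in range(k):
        window = seq[t : t + n]
        codes = codes * 4 + np.minimum(window, 3)
        valid &= window != N_CODE
    return codes, valid


def _seed_votes(seq: np.ndarray, k: int, max_period: int) -> tuple[np.ndarray, np.ndarray]:
    """(positions, distances) where the k-mer at pos re-occurs ``d`` bp back.

    Only the distance to the *most recent* previous occurrence is voted,
    which concentrates votes on the fundamental period of an array.
    """
    if len(seq) < k + 1:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    codes, valid = _kmer_codes(seq, k)
    idx = np.nonzero(valid)[0]
    if len(idx) < 2:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    order = np.argsort(codes[idx], kind="stable")
    pos_sorted = idx[order]
    code_sorted = codes[idx][order]
    same = code_sorted[1:] == code_sorted[:-1]
    dist = pos_sorted[1:] - pos_sorted[:-1]
    keep = same & (dist >= 1) & (dist <= max_period)
    pos = pos_sorted[1:][keep]
    d = dist[keep]
    o = np.argsort(pos, kind="stable")
    return pos[o], d[o]


def _candidate_intervals(
    pos: np.ndarray, dist: np.ndarray, k: int, seq_len: int, params: DetectionParams
) -> list[tuple[int, int, int]]:
    """Chain same-distance votes into candidate (start, end, period) triples."""
    cands: list[tuple[int, int, int]] = []
    # gap tolerance scales with period and with the tolerated divergence
    for d in np.unique(dist):
        p = pos[dist == d]
        dd = int(d)
        tol = max(3 * dd, 150)
        run_start = p[0]
        prev = p[0]
        nvotes = 1
        for x in p[1:]:
            if x - prev <= tol:
                prev = x
                nvotes += 1
            else:
                if nvotes >= 2 or dd <= params.seed_kmer:
                    cands.append((max(int(run_start) - dd, 0), min(int(prev) + params.seed_kmer, seq_len), dd))
                run_start = prev = x
                nvotes = 1
        if nvotes >= 2 or dd <= params.seed_kmer:
            cands.append((max(int(run_start) - dd, 0), min(int(prev) + params.seed_kmer, seq_len), dd))
    cands.sort(key=lambda t: (t[0], t[1], t[2]))
    return cands


def _collapse_internal_period(consensus: str) -> str:
    """Collapse an exactly self-periodic consensus to its fundamental unit."""
    p = len(consensus)
    for q in range(1, p // 2 + 1):
        if p % q == 0 and consensus == consensus[:q] * (p // q):
            return consensus[:q]
    return consensus


def _majority_consensus(seg: np.ndarray, mon: np.ndarray, w: AlignmentWeights) -> str:
    """Column-majority consensus from a wraparound traceback of seg vs mon."""
    p = len(mon)
    D = _wraparound_matrix(seg, mon, w)
    c = w.indel_penalty
    counts = np.zeros((p, 4), dtype=np.int64)
    i = len(seg)
    j = int(np.argmax(D[i]))
    left_run = 0
    while i > 0:
        jp = (j - 1) % p
        sub = (
            w.match_reward
            if (seg[i - 1] == mon[j] and seg[i - 1] != N_CODE)
            else -w.mismatch_penalty
        )
        if D[i, j] == D[i - 1, jp] + sub:
            if seg[i - 1] != N_CODE:
                counts[j, seg[i - 1]] += 1
            i, j = i - 1, jp
            left_run = 0
        elif D[i, j] == D[i - 1, j] - c:
            i -= 1
            left_run = 0
        elif left_run < p - 1 and D[i, j] == D[i, jp] - c:
            j = jp
            left_run += 1
        else:  # pragma: no cover
            raise RuntimeError("traceback inconsistency")
    bases = "ACGT"
    out = []
    for j in range(p):
        if counts[j].sum() == 0:
            out.append(bases[int(mon[j])] if mon[j] != N_CODE else "A")
        else:
            out.append(bases[int(np.argmax(counts[j]))])
    return "".join(out)


def _score_candidate(
    chrom: str, seq: np.ndarray, start: int, end: int, period: int, params: DetectionParams
) -> TandemRepeatArray | None:
    seg = seq[start:end]
    if len(seg) < period or len(seg) < 2:
        return None
    if np.count_nonzero(seg == N_CODE) > 0.2 * len(seg):
        return None
    bases = "ACGT" + "N"
    initial = "".join(bases[b] for b in seg[:period])
    if "N" in initial:
        initial = initial.replace("N", "A")
    cons = _majority_consensus(seg, encode(initial), params.weights)
    cons = _collapse_internal_period(cons)
    seg_str = "".join(bases[b] for b in seg)
    res = wraparound_align(seg_str, cons, params.weights)
    if res.score < params.min_score or len(cons) > params.max_period:
        return None
    aligned = res.matches + res.mismatches + res.indels
    if aligned == 0 or res.copy_number < 1:
        return None
    return TandemRepeatArray(
        chrom=chrom,
        start=start,
        end=end,
        period=len(cons),
        copy_number=res.copy_number,
        pct_match=round(100.0 * res.matches / aligned, 1),
        pct_indel=round(100.0 * res.indels / aligned, 1),
        score=res.score,
        consensus=cons,
    )


def _dedupe_candidates(
    cands: list[tuple[int, int, int]]
) -> list[list[tuple[int, int, int]]]:
    """Group candidates whose intervals overlap; one array -> one group."""
    groups: list[list[tuple[int, int, int]]] = []
    cur: list[tuple[int, int, int]] = []
    cur_end = -1
    for s, e, d in cands:
        if cur and s < cur_end:
            cur.append((s, e, d))
            cur_end = max(cur_end, e)
        else:
            if cur:
                groups.append(cur)
            cur = [(s, e, d)]
            cur_end = e
    if cur:
        groups.append(cur)
    return groups


def detect_tandem_repeats(
    genome: dict[str, str], params: DetectionParams | None = None
) -> list[TandemRepeatArray]:
    """Detect tandem repeat arrays in a {chrom: sequence} mapping.

    Deterministic; arrays within a chromosome are sorted by start.
    Chromosomes shorter than ``2 * seed_kmer`` are skipped with a notice.
    """
    params = params or DetectionParams()
    out: list[TandemRepeatArray] = []
    for chrom, seq_str in genome.items():
        if not seq_str:
            raise ValueError(f"chromosome {chrom!r} has empty sequence")
        if len(seq_str) < params.seed_kmer + 1:
            logger.info("skipping %s: too short to seed (< seed_kmer + 1 bp)", chrom)
            continue
        seq = encode(seq_str)
        pos, dist = _seed_votes(seq, params.seed_kmer, params.max_period)
        if len(pos) == 0:
            continue
        cands = _candidate_intervals(pos, dist, params.seed_kmer, len(seq), params)
        arrays: list[TandemRepeatArray] = []
        for group in _dedupe_candidates(cands):
            # smallest candidate period first: harmonics (2d, 3d...) of the
            # same array lose to the fundamental
            group.sort(key=lambda t: (t[2], t[0], -(t[1] - t[0])))
            start = min(s for s, _, _ in group)
            end = max(e for _, e, _ in group)
            arr = None
            for _, _, d in group:
                arr = _score_candidate(chrom, seq, start, end, d, params)
                if arr is not None:
                    break
            if arr is not None:
                arrays.append(arr)
        arrays.sort(key=lambda a: (a.start, a.end))
        out.extend(arrays)
    return out


# ---------------------------------------------------------------------------
# de-overlap and filtering
# ---------------------------------------------------------------------------


def resolve_overlaps(arrays: list[TandemRepeatArray]) -> list[TandemRepeatArray]:
    """Greedy best-first interval selection per chromosome.

    Arrays are taken in descending score (ties: longer span, smaller start,
    input order); an array is kept iff it overlaps no already-kept array.
    The result preserves genomic order.
    """
    order = sorted(
        range(len(arrays)),
        key=lambda i: (-arrays[i].score, -arrays[i].span, arrays[i].start, i),
    )
    kept: dict[str, list[tuple[int, int]]] = {}
    kept_idx: list[int] = []
    for i in order:
        a = arrays[i]
        ivs = kept.setdefault(a.chrom, [])
        if any(a.start < e and s < a.end for s, e in ivs):
            continue
        ivs.append((a.start, a.end))
        kept_idx.append(i)
    kept_idx.sort()
    return [arrays[i] for i in kept_idx]


def filter_arrays(
    arrays: list[TandemRepeatArray], params: FilterParams | None = None
) -> list[TandemRepeatArray]:
    """Retain arrays with period >= min_period, copy_number >= min_copies and
    pct_match strictly > min_pct_match; order preserved."""
    params = params or FilterParams()
    return [
        a
        for a in arrays
        if a.period >= params.min_period
        and a.copy_number >= params.min_copies
        and a.pct_match > params.min_pct_match
    ]
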