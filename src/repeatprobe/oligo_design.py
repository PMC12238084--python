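"""Oligo probe design from cluster representative monomers.

Candidate probes are all fixed-length windows over the cyclic monomer (so
windows may span the tandem junction — every candidate is a true substring
of an infinite tandem array of its monomer).  Candidates are screened on GC
content, homopolymer runs and a simple hairpin-stem test, then ranked by
closeness of their melting temperature to the pool median, which favours a
thermodynamically uniform probe set.

Melting temperatures come from the nearest-neighbour model of
``Bio.SeqUtils.MeltingTemp`` (default thermodynamic table, default salt);
only the relative ranking matters for selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from Bio.SeqUtils import MeltingTemp, gc_fraction

from repeatprobe.monomer_cluster import reverse_complement

TELOMERE_MOTIF = "TTTAGGG"  # plant (Arabidopsis-type) telomeric monomer


@dataclass(frozen=True)
class DesignConstraints:
    length_range: tuple[int, int] = (40, 45)
    gc_range: tuple[float, float] = (30.0, 70.0)
    max_homopolymer: int = 6
    max_hairpin_stem: int = 8
    per_cluster_limit: int = 1

    def __post_init__(self) -> None:
        if self.length_range[0] > self.length_range[1] or self.length_range[0] < 1:
            raise ValueError("invalid length range")
        if not (0 <= self.gc_range[0] <= self.gc_range[1] <= 100):
            raise ValueError("invalid gc range")


@dataclass(frozen=True)
class Candidate:
    sequence: str
    source_cluster: str
    start: int  # start offset within the (cyclic) monomer
    gc_percent: float
    tm_celsius: float


@dataclass(frozen=True)
class OligoProbe:
    probe_id: str
    sequence: str
    source_cluster: str
    gc_percent: float
    tm_celsius: float
    channel: str = "unassigned"  # TAMRA | FAM | unassigned


@dataclass(frozen=True)
class ProbeCocktail:
    name: str
    channel: str
    members: tuple[str, ...]


def gc_percent(seq: str) -> float:
    return round(100.0 * gc_fraction(seq), 2)


def melting_temp(seq: str) -> float:
    return round(float(MeltingTemp.Tm_NN(seq)), 3)


def tile_candidates(
    representative: str, constraints: DesignConstraints | None = None,
    cluster_id: str = "cluster",
) -> list[Candidate]:
    """All windows of each allowed length over the cyclic representative.

    The monomer is conceptually concatenated with itself, so there are
    ``len(representative)`` distinct junction-cyclic start positions per
    window length; monomers shorter than the window are tandem-expanded.
    """
    if not representative:
        raise ValueError("representative must be non-empty")
    constraints = constraints or DesignConstraints()
    lo, hi = constraints.length_range
    p = len(representative)
    reps = hi // p + 2
    context = representative * reps
    out: list[Candidate] = []
    for length in range(lo, hi + 1):
        for start in range(p):
            s = context[start : start + length]
            out.append(
                Candidate(
                    sequence=s,
                    source_cluster=cluster_id,
                    start=start,
                    gc_percent=gc_percent(s),
                    tm_celsius=melting_temp(s),
                )
            )
    return out


def max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for i in range(1, len(seq)):
        run = run + 1 if seq[i] == seq[i - 1] else 1
        best = max(best, run)
    return best if seq else 0


def longest_hairpin_stem(seq: str) -> int:
    """Length of the longest substring whose reverse complement also occurs
    in the sequence (a proxy for self-complementary hairpin stems)."""
    n = len(seq)
    rc = reverse_complement(seq)
    best = 0
    # O(n^2) longest common substring of seq and rc via DP row
    prev = [0] * (n + 1)
    for i in range(1, n + 1):
        cur = [0] * (n + 1)
        for j in range(1, n + 1):
            if seq[i - 1] == rc[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def passes_screens(c: Candidate, constraints: DesignConstraints) -> bool:
    if not set(c.sequence) <= set("ACGT"):
        return False
    if not constraints.gc_range[0] <= c.gc_percent <= constraints.gc_range[1]:
        return False
    if max_homopolymer_run(c.sequence) > constraints.max_homopolymer:
        return False
    if longest_hairpin_stem(c.sequence) >= constraints.max_hairpin_stem:
        return False
    return True


def select_probes(
    candidates: Iterable[Candidate], constraints: DesignConstraints | None = None
) -> list[Candidate]:
    """Screen and rank candidates; keep per_cluster_limit per cluster.

    Survivors are ranked by |Tm - pool median Tm| (pool = survivors of the
    same cluster), ties broken by start offset, then length, then sequence.
    Clusters with no survivor simply contribute no probe.
    """
    constraints = constraints or DesignConstraints()
    by_cluster: dict[str, list[Candidate]] = {}
    for c in candidates:
        if passes_screens(c, constraints):
            by_cluster.setdefault(c.source_cluster, []).append(c)
    out: list[Candidate] = []
    for cluster in by_cluster:
        pool = by_cluster[cluster]
        tms = sorted(c.tm_celsius for c in pool)
        k = len(tms)
        median = tms[k // 2] if k % 2 else (tms[k // 2 - 1] + tms[k // 2]) / 2
        ranked = sorted(
            pool,
            key=lambda c: (abs(c.tm_celsius - median), c.start, len(c.sequence), c.sequence),
        )
        seen: set[str] = set()
        picked = []
        for c in ranked:
            if c.sequence in seen:
                continue
            seen.add(c.sequence)
            picked.append(c)
            if len(picked) >= constraints.per_cluster_limit:
                break
        out.extend(picked)
    return out


def _is_telomeric(monomer: str) -> bool:
    m = monomer.upper()
    if len(m) != len(TELOMERE_MOTIF):
        return False
    for motif in (TELOMERE_MOTIF, reverse_complement(TELOMERE_MOTIF)):
        doubled = motif * 2
        if m in doubled:
            return True
    return False


def name_probe(
    index: int,
    hit_counts_by_chrom: dict[str, int] | None = None,
    monomer: str | None = None,
    dispersal_cutoff: float = 0.30,
) -> str:
    """Probe naming: "C{chrom}-{i}" when one chromosome holds the plurality
    of in-silico hits, "Co-{i}" when hits are dispersed (no chromosome holds
    >= 30% of them), "Tel-{i}" for telomeric-motif monomers, "U-{i}" when no
    localization is available."""
    if monomer is not None and _is_telomeric(monomer):
        return f"Tel-{index}"
    if not hit_counts_by_chrom:
        return f"U-{index}"
    total = sum(hit_counts_by_chrom.values())
    if total == 0:
        return f"U-{index}"
    top_chrom, top = max(
        hit_counts_by_chrom.items(), key=lambda kv: (kv[1], kv[0])
    )
    if top / total < dispersal_cutoff:
        return f"Co-{index}"
    label = "".join(ch for ch in top_chrom if ch.isdigit()) or top_chrom
    label = str(int(label)) if label.isdigit() else label
    return f"C{label}-{index}"


def compose_cocktails(
    probes: Iterable[OligoProbe],
    channel_assignment: dict[str, str] | Iterable[tuple[str, str]],
    names: dict[str, str] | None = None,
) -> list[ProbeCocktail]:
    """One cocktail per channel; member order follows the assignment order.

    ``names`` optionally maps channel -> cocktail name (default
    "Multiplex #k" in first-seen channel order).  Unknown probe ids error.
    """
    known = {p.probe_id for p in probes}
    members: dict[str, list[str]] = {}
    pairs = channel_assignment.items() if hasattr(channel_assignment, "items") else channel_assignment
    for pid, channel in pairs:
        if pid not in known:
            raise ValueError(f"unknown probe id in channel assignment: {pid!r}")
        for ch, mm in members.items():
            if pid in mm and ch != channel:
                raise ValueError(f"probe {pid!r} assigned to multiple channels")
        members.setdefault(channel, [])
        if pid in members[channel]:
            raise ValueError(f"probe {pid!r} assigned twice")
        members[channel].append(pid)
    out = []
    for k, (channel, mm) in enumerate(members.items(), start=1):
        name = (names or {}).get(channel, f"Multiplex #{k}")
        out.append(ProbeCocktail(name=name, channel=channel, members=tuple(mm)))
    return out
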