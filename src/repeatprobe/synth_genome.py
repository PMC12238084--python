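"""Synthetic chromosomes with planted tandem repeat arrays.

Stands in for a multi-gigabase assembly: i.i.d. background at a configurable
GC content, with tandem arrays of stated period, copy number, substitution
divergence and indel rate planted at known (truth-BED-recorded) intervals.
Generation is fully reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ChromSpec:
    name: str
    length: int
    gc: float = 0.4

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("chromosome length must be positive")
        if not 0 <= self.gc <= 1:
            raise ValueError("gc must lie in [0, 1]")


@dataclass(frozen=True)
class PlantSpec:
    """One tandem array to plant: monomer repeated ``copies`` times, then
    per-base substitutions (prob ``divergence``) and 1-bp indels
    (prob ``indel_rate``) applied."""

    monomer: str
    copies: int
    divergence: float = 0.0
    indel_rate: float = 0.0
    chrom: str | None = None
    position: int | str = "random"

    def __post_init__(self) -> None:
        if not self.monomer:
            raise ValueError("monomer must be non-empty")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if not 0 <= self.divergence <= 0.5:
            raise ValueError("divergence must lie in [0, 0.5]")
        if not 0 <= self.indel_rate <= 0.5:
            raise ValueError("indel_rate must lie in [0, 0.5]")


@dataclass(frozen=True)
class TruthRecord:
    chrom: str
    start: int
    end: int
    monomer: str
    copies: int
    identity: float  # realized percent identity of the mutated array


@dataclass(frozen=True)
class RecoveryReport:
    recall: float
    precision: float
    vacuous_precision: bool = False  # no detections: precision reported as 1.0


def _random_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _mutate_array(
    rng: np.random.Generator, arr: np.ndarray, divergence: float, indel_rate: float
) -> tuple[np.ndarray, float]:
    """Substitutions first, then 1-bp indels (insertions copy a random base).

    Returns the mutated array and the realized identity percent, counting
    each substitution and each indel event as one non-identity column.
    """
    n = len(arr)
    out = arr.copy()
    n_sub = 0
    if divergence > 0:
        mask = rng.random(n) < divergence
        n_sub = int(mask.sum())
        if n_sub:
            shift = rng.integers(1, 4, size=n_sub).astype(np.uint8)
            out[mask] = (out[mask] + shift) % 4
    n_indel = 0
    if indel_rate > 0:
        events = np.nonzero(rng.random(n) < indel_rate)[0]
        n_indel = len(events)
        if n_indel:
            is_ins = rng.random(n_indel) < 0.5
            pieces: list[np.ndarray] = []
            prev = 0
            for pos, ins in zip(events, is_ins):
                if ins:
                    pieces.append(out[prev : pos + 1])
                    pieces.append(np.array([rng.integers(0, 4)], dtype=np.uint8))
                    prev = pos + 1
                else:
                    pieces.append(out[prev:pos])
                    prev = pos + 1
            pieces.append(out[prev:])
            out = np.concatenate(pieces)
    identity = 100.0 * max(n - n_sub - n_indel, 0) / n
    return out, identity


def generate_genome(
    chrom_specs: list[ChromSpec],
    plant_specs: list[PlantSpec],
    seed: int,
    max_attempts: int = 200,
) -> tuple[str, str]:
    """Generate (FASTA text, truth BED text).

    All randomness flows from one seeded generator, so identical inputs give
    byte-identical outputs.  Planted intervals never overlap; random
    placement is retried up to ``max_attempts`` times before erroring.
    """
    rng = np.random.default_rng(seed)
    chroms = {c.name: _random_background(rng, c.length, c.gc) for c in chrom_specs}
    occupied: dict[str, list[tuple[int, int]]] = {c.name: [] for c in chrom_specs}
    truths: list[TruthRecord] = []

    for spec in plant_specs:
        mono = np.frombuffer(spec.monomer.upper().encode(), dtype=np.uint8)
        codes = np.zeros(len(mono), dtype=np.uint8)
        for i, b in enumerate(_BASES):
            codes[mono == b] = i
        arr = np.tile(codes, spec.copies)
        arr, identity = _mutate_array(rng, arr, spec.divergence, spec.indel_rate)
        name = spec.chrom if spec.chrom is not None else chrom_specs[0].name
        if name not in chroms:
            raise ValueError(f"unknown chromosome {name!r} in plant spec")
        seq = chroms[name]
        if len(arr) > len(seq):
            raise ValueError(f"plant of monomer {spec.monomer[:12]}... does not fit")
        if spec.position == "random":
            placed = False
            for _ in range(max_attempts):
                start = int(rng.integers(0, len(seq) - len(arr) + 1))
                iv = (start, start + len(arr))
                if all(iv[0] >= e or s >= iv[1] for s, e in occupied[name]):
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    f"could not place plant of monomer {spec.monomer[:12]}... "
                    f"on {name} after {max_attempts} attempts"
                )
        else:
            start = int(spec.position)
            iv = (start, start + len(arr))
            if iv[1] > len(seq):
                raise ValueError("fixed-position plant extends past chromosome end")
            if not all(iv[0] >= e or s >= iv[1] for s, e in occupied[name]):
                raise ValueError("fixed-position plant overlaps an earlier plant")
        seq[start : start + len(arr)] = arr
        occupied[name].append((start, start + len(arr)))
        truths.append(
            TruthRecord(
                chrom=name,
                start=start,
                end=start + len(arr),
                monomer=spec.monomer.upper(),
                copies=spec.copies,
                identity=round(identity, 2),
            )
        )

    lines = []
    for c in chrom_specs:
        lines.append(f">{c.name} synthetic gc={c.gc} seed={seed}")
        s = chroms[c.name]
        text = _BASES[s].tobytes().decode("ascii")
        for i in range(0, len(text), 80):
            lines.append(text[i : i + 80])
    fasta = "\n".join(lines) + "\n"

    bed_lines = []
    for i, t in enumerate(sorted(truths, key=lambda t: (t.chrom, t.start))):
        bed_lines.append(
            f"{t.chrom}\t{t.start}\t{t.end}\tplant{i + 1};period={len(t.monomer)};"
            f"copies={t.copies};identity={t.identity}\t0\t+"
        )
    bed = "\n".join(bed_lines) + ("\n" if bed_lines else "")
    return fasta, bed


def parse_truth_bed(text: str) -> list[TruthRecord]:
    """Read a truth BED produced by :func:`generate_genome`."""
    out = []
    for line in text.splitlines():
        if not line.strip():
            continue
        chrom, start, end, name, _score, _strand = line.split("\t")
        meta = dict(kv.split("=") for kv in name.split(";")[1:])
        out.append(
            TruthRecord(
                chrom=chrom,
                start=int(start),
                end=int(end),
                monomer="N" * int(meta.get("period", 1)),
                copies=int(meta.get("copies", 1)),
                identity=float(meta.get("identity", 100.0)),
            )
        )
    return out


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def evaluate_recovery(
    truths: list[TruthRecord],
    detected,
    min_reciprocal_overlap: float = 0.5,
) -> RecoveryReport:
    """Match detected arrays to planted truth intervals.

    A truth is recovered iff some detected array reciprocally overlaps it by
    at least ``min_reciprocal_overlap``; each detected array consumes at most
    one truth (greedy by descending overlap).  With no detections, precision
    is vacuously 1.0 and flagged.
    """
    pairs = []
    for ti, t in enumerate(truths):
        for di, d in enumerate(detected):
            if d.chrom != t.chrom:
                continue
            ov = _reciprocal_overlap((t.start, t.end), (d.start, d.end))
            if ov >= min_reciprocal_overlap:
                pairs.append((ov, ti, di))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_t: set[int] = set()
    used_d: set[int] = set()
    for ov, ti, di in pairs:
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
    recall = len(used_t) / len(truths) if truths else 1.0
    if not detected:
        return RecoveryReport(recall=0.0 if truths else 1.0, precision=1.0,
                              vacuous_precision=True)
    matched_d = sum(
        1
        for di, d in enumerate(detected)
        if any(
            d.chrom == t.chrom
            and _reciprocal_overlap((t.start, t.end), (d.start, d.end))
            >= min_reciprocal_overlap
            for t in truths
        )
    )
    return RecoveryReport(recall=recall, precision=matched_d / len(detected))
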