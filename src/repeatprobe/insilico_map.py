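"""Electronic localization: probe-vs-genome scanning, locus calling, idiograms.

Short oligo probes (30-50 nt) are scanned with an ungapped sliding-identity
model on both strands; a window is a hit when its identity strictly exceeds
the minimum (default 80%).  Multi-kilobase probes (e.g. a 45S rDNA plasmid)
are fragmented into overlapping windows, each scanned as an oligo, and
overlapping hits merged per site.  Hits are assigned to fixed chromosome bins
(default 1 Mb, anchored at coordinate 0); a bin becomes a called locus when
its hit count strictly exceeds the count threshold (oligo class, default
>30) or its per-megabase density strictly exceeds the density threshold
(plasmid class, default >1/Mb).  Idiograms are emitted as self-contained SVG
plus a TSV twin of the plotted marks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from repeatprobe.monomer_cluster import reverse_complement
from repeatprobe.repeatscan import N_CODE, encode


@dataclass(frozen=True)
class MapParams:
    min_identity: float = 80.0  # strict >
    bin_size: int = 1_000_000
    count_threshold: int = 30  # strict >
    density_threshold: float = 1.0  # hits per Mb, strict >
    probe_class: str = "oligo"  # "oligo" | "plasmid"
    plasmid_window: int = 500
    plasmid_step: int = 250

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if self.count_threshold < 0 or self.density_threshold < 0:
            raise ValueError("thresholds must be >= 0")
        if self.probe_class not in ("oligo", "plasmid"):
            raise ValueError("probe_class must be 'oligo' or 'plasmid'")


@dataclass(frozen=True)
class MatchHit:
    chrom: str
    position: int  # forward-strand window start, 0-based
    strand: str  # "+" | "-"
    identity: float
    probe_id: str
    length: int


@dataclass(frozen=True)
class LocusCall:
    chrom: str
    bin_start: int
    bin_end: int
    count: int
    probe_id: str
    rule: str  # "count" | "density"


def _strand_hits(
    seq: np.ndarray, probe: np.ndarray, min_identity: float
) -> tuple[np.ndarray, np.ndarray]:
    """(positions, identities) of windows with identity strictly above the
    threshold, under the ungapped Hamming model; N never matches."""
    L = len(probe)
    n = len(seq) - L + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    matches = np.zeros(n, dtype=np.int32)
    for t in range(L):
        matches += (seq[t : t + n] == probe[t]) & (probe[t] != N_CODE) & (
            seq[t : t + n] != N_CODE
        )
    # identity > min_identity  <=>  100*matches > min_identity*L (exact)
    keep = 100.0 * matches > min_identity * L
    pos = np.nonzero(keep)[0]
    return pos, 100.0 * matches[pos] / L


def scan_probe(
    genome: dict[str, str], probe_id: str, sequence: str,
    params: MapParams | None = None,
) -> list[MatchHit]:
    """Scan an oligo probe over every chromosome, both strands.

    Hits are windows of probe length whose ungapped identity strictly
    exceeds ``min_identity``; positions are forward-strand window starts.
    Chromosomes shorter than the probe are skipped.
    """
    params = params or MapParams()
    seq_u = sequence.upper()
    if not seq_u or not set(seq_u) <= set("ACGT"):
        raise ValueError(f"probe {probe_id!r} must be non-empty A/C/G/T")
    fwd = encode(seq_u)
    rev = encode(reverse_complement(seq_u))
    hits: list[MatchHit] = []
    for chrom, s in genome.items():
        if len(s) < len(seq_u):
            continue
        seq = encode(s)
        chrom_hits = []
        p, ident = _strand_hits(seq, fwd, params.min_identity)
        chrom_hits += [(int(x), "+", float(v)) for x, v in zip(p, ident)]
        p, ident = _strand_hits(seq, rev, params.min_identity)
        chrom_hits += [(int(x), "-", float(v)) for x, v in zip(p, ident)]
        chrom_hits.sort(key=lambda h: (h[0], h[1]))
        hits += [
            MatchHit(chrom, pos, strand, round(iv, 2), probe_id, len(seq_u))
            for pos, strand, iv in chrom_hits
        ]
    return hits


def scan_long_probe(
    genome: dict[str, str], probe_id: str, long_sequence: str,
    params: MapParams | None = None,
) -> list[MatchHit]:
    """Scan a plasmid-scale probe by windowed fragmentation.

    The sequence is cut into ``plasmid_window``-length fragments every
    ``plasmid_step`` bp; each fragment is scanned as an oligo and
    overlapping hits on the same chromosome/strand are merged into one hit
    per site (position = region start, identity = best fragment identity,
    length = merged span).
    """
    params = params or MapParams()
    if params.probe_class != "plasmid":
        params = MapParams(
            min_identity=params.min_identity, bin_size=params.bin_size,
            count_threshold=params.count_threshold,
            density_threshold=params.density_threshold, probe_class="plasmid",
            plasmid_window=params.plasmid_window, plasmid_step=params.plasmid_step,
        )
    seq = long_sequence.upper()
    w, step = params.plasmid_window, params.plasmid_step
    if len(seq) < w:
        raise ValueError("long sequence shorter than plasmid_window")
    frags = [seq[i : i + w] for i in range(0, len(seq) - w + 1, step)]
    raw: list[MatchHit] = []
    for frag in frags:
        raw += scan_probe(genome, probe_id, frag, params)
    merged: list[MatchHit] = []
    by_key: dict[tuple[str, str], list[MatchHit]] = {}
    for h in raw:
        by_key.setdefault((h.chrom, h.strand), []).append(h)
    for (chrom, strand), hh in sorted(by_key.items()):
        hh.sort(key=lambda h: h.position)
        cur_s, cur_e, cur_i = hh[0].position, hh[0].position + hh[0].length, hh[0].identity
        for h in hh[1:]:
            if h.position <= cur_e:
                cur_e = max(cur_e, h.position + h.length)
                cur_i = max(cur_i, h.identity)
            else:
                merged.append(MatchHit(chrom, cur_s, strand, cur_i, probe_id, cur_e - cur_s))
                cur_s, cur_e, cur_i = h.position, h.position + h.length, h.identity
        merged.append(MatchHit(chrom, cur_s, strand, cur_i, probe_id, cur_e - cur_s))
    merged.sort(key=lambda h: (h.chrom, h.position, h.strand))
    return merged


def bin_and_call(
    hits: list[MatchHit], chrom_lengths: dict[str, int],
    params: MapParams | None = None,
) -> list[LocusCall]:
    """Assign hits to fixed bins and call loci per probe.

    Oligo class: bins with count strictly > count_threshold; plasmid class:
    bins with count / (bin span in Mb) strictly > density_threshold.
    Adjacent called bins of the same probe merge, keeping the summed count.
    """
    params = params or MapParams()
    counts: dict[tuple[str, str, int], int] = {}
    for h in hits:
        if h.chrom not in chrom_lengths:
            raise ValueError(f"hit on undeclared chromosome {h.chrom!r}")
        if h.position + h.length > chrom_lengths[h.chrom]:
            raise ValueError(
                f"hit at {h.chrom}:{h.position} extends past declared length"
            )
        b = h.position // params.bin_size
        counts[(h.probe_id, h.chrom, b)] = counts.get((h.probe_id, h.chrom, b), 0) + 1
    called: list[LocusCall] = []
    for (probe, chrom, b), cnt in sorted(counts.items()):
        bin_start = b * params.bin_size
        bin_end = min(bin_start + params.bin_size, chrom_lengths[chrom])
        if params.probe_class == "oligo":
            ok = cnt > params.count_threshold
            rule = "count"
        else:
            ok = cnt / ((bin_end - bin_start) / 1e6) > params.density_threshold
            rule = "density"
        if ok:
            called.append(LocusCall(chrom, bin_start, bin_end, cnt, probe, rule))
    # merge adjacent called bins per probe/chrom
    merged: list[LocusCall] = []
    for lc in called:
        prev = merged[-1] if merged else None
        if (
            prev
            and prev.probe_id == lc.probe_id
            and prev.chrom == lc.chrom
            and prev.bin_end == lc.bin_start
            and prev.rule == lc.rule
        ):
            merged[-1] = LocusCall(
                lc.chrom, prev.bin_start, lc.bin_end, prev.count + lc.count,
                lc.probe_id, lc.rule,
            )
        else:
            merged.append(lc)
    return merged


# ---------------------------------------------------------------------------
# idiogram rendering
# ---------------------------------------------------------------------------

_DEFAULT_COLORS = [
    "#d62728", "#2ca02c", "#1f77b4", "#ff7f0e", "#9467bd",
    "#8c564b", "#e377c2", "#17becf", "#bcbd22", "#7f7f7f",
]


def render_idiogram(
    loci: list[LocusCall],
    chrom_lengths: dict[str, int],
    channel_colors: dict[str, str] | None = None,
    width_per_chrom: int = 80,
    height: int = 420,
) -> tuple[str, str]:
    """Render chromosomes as vertical bars with one colored mark per locus.

    Returns (SVG text, marks TSV text).  Mark vertical placement is
    proportional: y / bar_height = bin midpoint / chromosome length.
    Deterministic layout; unknown chromosomes in ``loci`` error.
    """
    for lc in loci:
        if lc.chrom not in chrom_lengths:
            raise ValueError(f"locus on unknown chromosome {lc.chrom!r}")
        if lc.bin_end > chrom_lengths[lc.chrom]:
            raise ValueError("locus outside its chromosome")
    if any(v <= 0 for v in chrom_lengths.values()):
        raise ValueError("chromosome lengths must be positive")
    chroms = list(chrom_lengths)
    max_len = max(chrom_lengths.values())
    top, bar_h, bar_w = 40, height - 90, 18
    probes = sorted({lc.probe_id for lc in loci})
    colors = dict(channel_colors or {})
    for i, pr in enumerate(probes):
        colors.setdefault(pr, _DEFAULT_COLORS[i % len(_DEFAULT_COLORS)])
    svg = [
        f'<svg xmlns="http://www.w3.org/2000/svg" '
        f'width="{width_per_chrom * len(chroms) + 160}" height="{height}">',
        '<style>text{font-family:sans-serif;font-size:11px}</style>',
    ]
    marks_rows = ["chrom\tprobe\tbin_start\tbin_end\tcount\tx\ty\tbar_top\tbar_height"]
    for ci, chrom in enumerate(chroms):
        x = 40 + ci * width_per_chrom
        h = bar_h * chrom_lengths[chrom] / max_len
        svg.append(
            f'<rect x="{x}" y="{top}" width="{bar_w}" height="{h:.2f}" rx="8" '
            f'fill="#e8e8e8" stroke="#555"/>'
        )
        svg.append(f'<text x="{x}" y="{top + h + 16:.2f}">{chrom}</text>')
        for lc in loci:
            if lc.chrom != chrom:
                continue
            mid = (lc.bin_start + lc.bin_end) / 2
            y = top + h * mid / chrom_lengths[chrom]
            svg.append(
                f'<rect x="{x - 2}" y="{y - 2:.3f}" width="{bar_w + 4}" height="4" '
                f'fill="{colors[lc.probe_id]}"/>'
            )
            marks_rows.append(
                f"{chrom}\t{lc.probe_id}\t{lc.bin_start}\t{lc.bin_end}\t{lc.count}"
                f"\t{x - 2}\t{y:.3f}\t{top}\t{h:.2f}"
            )
    for i, pr in enumerate(probes):
        lx = 40 + len(chroms) * width_per_chrom + 10
        ly = top + 16 * i
        svg.append(f'<rect x="{lx}" y="{ly}" width="10" height="10" fill="{colors[pr]}"/>')
        svg.append(f'<text x="{lx + 14}" y="{ly + 9}">{pr}</text>')
    svg.append("</svg>")
    return "\n".join(svg) + "\n", "\n".join(marks_rows) + "\n"
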