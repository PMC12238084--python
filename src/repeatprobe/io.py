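"""File-format plumbing: FASTA (gzip-transparent, via Biopython), TSV, BED."""

from __future__ import annotations

import gzip
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from repeatprobe.insilico_map import LocusCall, MatchHit
from repeatprobe.oligo_design import OligoProbe
from repeatprobe.repeatscan import TandemRepeatArray

ARRAY_TSV_HEADER = "chrom\tstart\tend\tperiod\tcopy_number\tpct_match\tpct_indel\tscore\tconsensus"


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly gzipped) FASTA into an ordered {id: sequence} dict."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(records: dict[str, str], path: str | Path,
                descriptions: dict[str, str] | None = None) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description=(descriptions or {}).get(name, ""))
        for name, seq in records.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def arrays_to_tsv(arrays: list[TandemRepeatArray]) -> str:
    rows = [ARRAY_TSV_HEADER]
    rows += [
        f"{a.chrom}\t{a.start}\t{a.end}\t{a.period}\t{a.copy_number}"
        f"\t{a.pct_match}\t{a.pct_indel}\t{a.score}\t{a.consensus}"
        for a in arrays
    ]
    return "\n".join(rows) + "\n"


def arrays_from_tsv(text: str) -> list[TandemRepeatArray]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0] != ARRAY_TSV_HEADER:
        raise ValueError("bad array TSV header")
    out = []
    for ln in lines[1:]:
        c, s, e, p, cn, pm, pi, sc, cons = ln.split("\t")
        out.append(
            TandemRepeatArray(c, int(s), int(e), int(p), float(cn), float(pm),
                              float(pi), int(sc), cons)
        )
    return out


def arrays_to_bed(arrays: list[TandemRepeatArray]) -> str:
    """BED6; name = array id, score = alignment score capped at 1000."""
    rows = []
    for i, a in enumerate(arrays, start=1):
        rows.append(
            f"{a.chrom}\t{a.start}\t{a.end}\tTR{i};period={a.period}"
            f"\t{min(a.score, 1000)}\t+"
        )
    return "\n".join(rows) + ("\n" if rows else "")


def hits_to_tsv(hits: list[MatchHit]) -> str:
    rows = ["chrom\tpos0\tstrand\tidentity\tprobe"]
    rows += [
        f"{h.chrom}\t{h.position}\t{h.strand}\t{h.identity}\t{h.probe_id}"
        for h in hits
    ]
    return "\n".join(rows) + "\n"


def loci_to_bed(loci: list[LocusCall]) -> str:
    """BED; name = probe id, score = hit count."""
    rows = [
        f"{lc.chrom}\t{lc.bin_start}\t{lc.bin_end}\t{lc.probe_id}\t{lc.count}\t+"
        for lc in loci
    ]
    return "\n".join(rows) + ("\n" if rows else "")


def probes_to_tsv(probes: list[OligoProbe]) -> str:
    rows = ["probe_id\tsequence\tsource_cluster\tgc_percent\ttm_celsius\tchannel"]
    rows += [
        f"{p.probe_id}\t{p.sequence}\t{p.source_cluster}\t{p.gc_percent}"
        f"\t{p.tm_celsius}\t{p.channel}"
        for p in probes
    ]
    return "\n".join(rows) + "\n"


def probes_to_fasta(probes: list[OligoProbe], path: str | Path) -> None:
    write_fasta(
        {p.probe_id: p.sequence for p in probes},
        path,
        descriptions={
            p.probe_id: f"cluster={p.source_cluster} gc={p.gc_percent} "
                        f"tm={p.tm_celsius} channel={p.channel}"
            for p in probes
        },
    )
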