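"""End-to-end pipeline: scan -> de-overlap -> filter -> cluster -> design ->
map -> call loci -> idiogram, with a JSON manifest of every stage.

Re-running with an identical config (and seed, if the genome is simulated)
reproduces byte-identical outputs; the manifest carries no timestamps for
that reason (timing goes to the log only).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from repeatprobe import io as rio
from repeatprobe.insilico_map import MapParams, bin_and_call, render_idiogram, scan_probe
from repeatprobe.monomer_cluster import ClusterParams, greedy_cluster
from repeatprobe.oligo_design import (
    DesignConstraints,
    OligoProbe,
    name_probe,
    select_probes,
    tile_candidates,
)
from repeatprobe.repeatscan import (
    DetectionParams,
    FilterParams,
    detect_tandem_repeats,
    filter_arrays,
    resolve_overlaps,
)

logger = logging.getLogger(__name__)

STAGES = (
    "scan", "resolve", "filter", "cluster", "design", "map", "call", "idiogram",
)


@dataclass
class PipelineConfig:
    fasta: str
    outdir: str
    detection: DetectionParams = field(default_factory=DetectionParams)
    filter: FilterParams = field(default_factory=FilterParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    design: DesignConstraints = field(default_factory=DesignConstraints)
    map: MapParams = field(default_factory=MapParams)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs: dict = {"fasta": raw["fasta"], "outdir": raw["outdir"],
                        "seed": raw.get("seed", 0)}
        sub = {
            "detection": DetectionParams, "filter": FilterParams,
            "cluster": ClusterParams, "design": DesignConstraints,
            "map": MapParams,
        }
        for key, klass in sub.items():
            if key in raw:
                d = dict(raw[key])
                if key == "design":
                    for rk in ("length_range", "gc_range"):
                        if rk in d:
                            d[rk] = tuple(d[rk])
                kwargs[key] = klass(**d)
        return cls(**kwargs)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"pipeline stage {stage!r} failed: {message}")
        self.stage = stage


def _sha(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; return (and write) the run manifest.

    Each stage record lists inputs, outputs, parameters and item counts.
    Any stage error aborts with the stage name; outputs of completed stages
    are preserved on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {
        "fasta": str(config.fasta), "outdir": str(config.outdir),
        "seed": config.seed,
        "detection": asdict(config.detection), "filter": asdict(config.filter),
        "cluster": asdict(config.cluster), "design": asdict(config.design),
        "map": asdict(config.map),
    }, "stages": []}

    def record(stage: str, outputs: dict[str, str], counts: dict[str, int]) -> None:
        manifest["stages"].append(
            {"stage": stage, "order": len(manifest["stages"]) + 1,
             "outputs": outputs, "counts": counts}
        )
        logger.info("[%s] %s", stage, counts)

    def run_stage(stage: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as e:
            raise StageError(stage, str(e)) from e
        logger.info("[%s] done in %.1fs", stage, time.perf_counter() - t0)
        return result

    # scan
    def _scan():
        genome = rio.read_fasta(config.fasta)
        if not genome:
            raise ValueError("empty genome FASTA")
        return genome, detect_tandem_repeats(genome, config.detection)

    genome, arrays = run_stage("scan", _scan)
    text = rio.arrays_to_tsv(arrays)
    (outdir / "arrays_raw.tsv").write_text(text)
    record("scan", {"arrays_raw.tsv": _sha(text)},
           {"chromosomes": len(genome), "arrays": len(arrays)})

    # resolve overlaps
    deov = run_stage("resolve", lambda: resolve_overlaps(arrays))
    text = rio.arrays_to_tsv(deov)
    (outdir / "arrays_deoverlapped.tsv").write_text(text)
    record("resolve", {"arrays_deoverlapped.tsv": _sha(text)}, {"arrays": len(deov)})

    # filter
    kept = run_stage("filter", lambda: filter_arrays(deov, config.filter))
    text = rio.arrays_to_tsv(kept)
    bed = rio.arrays_to_bed(kept)
    (outdir / "arrays_filtered.tsv").write_text(text)
    (outdir / "arrays_filtered.bed").write_text(bed)
    record("filter", {"arrays_filtered.tsv": _sha(text), "arrays_filtered.bed": _sha(bed)},
           {"arrays": len(kept)})

    # cluster
    def _cluster():
        monomers = [(f"TR{i + 1}", a.consensus) for i, a in enumerate(kept)]
        if not monomers:
            raise ValueError("no arrays survived filtering; nothing to cluster")
        return greedy_cluster(monomers, config.cluster)

    clusters = run_stage("cluster", _cluster)
    cl_rows = ["cluster\trepresentative\tmember\tidentity"]
    for ci, cl in enumerate(clusters, start=1):
        for mid, ident in cl.members:
            cl_rows.append(f"cl{ci}\t{cl.representative_id}\t{mid}\t{ident}")
    text = "\n".join(cl_rows) + "\n"
    (outdir / "clusters.tsv").write_text(text)
    rio.write_fasta(
        {f"cl{ci}": cl.representative for ci, cl in enumerate(clusters, start=1)},
        outdir / "representatives.fa",
    )
    record("cluster", {"clusters.tsv": _sha(text)}, {"clusters": len(clusters)})

    # design
    def _design():
        picked = []
        for ci, cl in enumerate(clusters, start=1):
            cands = tile_candidates(cl.representative, config.design, f"cl{ci}")
            picked.extend(select_probes(cands, config.design))
        return picked

    selected = run_stage("design", _design)

    # map (probes named after localization, so scanning precedes naming)
    def _map():
        hits_by_cluster = {}
        for c in selected:
            hits_by_cluster[c.source_cluster] = scan_probe(
                genome, c.source_cluster, c.sequence, config.map
            )
        return hits_by_cluster

    hits_by_cluster = run_stage("map", _map)

    probes: list[OligoProbe] = []
    cluster_reps = {f"cl{ci}": cl.representative
                    for ci, cl in enumerate(clusters, start=1)}
    for idx, c in enumerate(selected, start=1):
        counts: dict[str, int] = {}
        for h in hits_by_cluster[c.source_cluster]:
            counts[h.chrom] = counts.get(h.chrom, 0) + 1
        pid = name_probe(idx, counts, monomer=cluster_reps[c.source_cluster])
        probes.append(
            OligoProbe(pid, c.sequence, c.source_cluster, c.gc_percent, c.tm_celsius)
        )
    text = rio.probes_to_tsv(probes)
    (outdir / "probes.tsv").write_text(text)
    rio.probes_to_fasta(probes, outdir / "probes.fa")
    record("design", {"probes.tsv": _sha(text)}, {"probes": len(probes)})

    all_hits = []
    id_of = {c.source_cluster: p.probe_id for c, p in zip(selected, probes)}
    for cl_id, hh in hits_by_cluster.items():
        for h in hh:
            all_hits.append(h.__class__(h.chrom, h.position, h.strand, h.identity,
                                        id_of[cl_id], h.length))
    all_hits.sort(key=lambda h: (h.probe_id, h.chrom, h.position, h.strand))
    text = rio.hits_to_tsv(all_hits)
    (outdir / "hits.tsv").write_text(text)
    record("map", {"hits.tsv": _sha(text)}, {"hits": len(all_hits)})

    # call loci
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    loci = run_stage("call", lambda: bin_and_call(all_hits, chrom_lengths, config.map))
    bed = rio.loci_to_bed(loci)
    (outdir / "loci.bed").write_text(bed)
    record("call", {"loci.bed": _sha(bed)}, {"loci": len(loci)})

    # idiogram
    svg, marks = run_stage(
        "idiogram", lambda: render_idiogram(loci, chrom_lengths)
    )
    (outdir / "idiogram.svg").write_text(svg)
    (outdir / "idiogram_marks.tsv").write_text(marks)
    record("idiogram", {"idiogram.svg": _sha(svg), "idiogram_marks.tsv": _sha(marks)},
           {"marks": len(marks.splitlines()) - 1})

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
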