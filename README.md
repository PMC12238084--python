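# repeatprobe

Repeat-based oligo-FISH probe design and in-silico karyotyping for plant
genomes.

Cytogeneticists identifying chromosomes in large, repeat-rich plant genomes
(the motivating case is *Artemisia argyi*, a ~8 Gb allotetraploid medicinal
herb) need fluorescent probes that paint reproducible banding patterns.
A proven route is to mine the assembly for tandem repeats, design short
labelled oligos from the repeat monomers, and predict where each probe will
light up by counting its genome matches per chromosome bin ("electronic
localization"). `repeatprobe` implements that entire computational route as
a reusable library and CLI:

1. **repeatscan** — tandem repeat discovery with wraparound dynamic
   programming (match/mismatch/indel = +2/−7/−7; minimum score 50, maximum
   period 2000), greedy de-overlapping, and filtering to arrays with period
   ≥ 10 bp, copy number ≥ 50 and percent matches > 70.
2. **monomer_cluster** — greedy CD-HIT-style clustering of consensus
   monomers at ≥ 75% global-alignment identity.
3. **oligo_design** — candidate oligos (default 40–45 nt) tiled over the
   cyclic monomer, screened on GC/homopolymer/hairpin, ranked by melting
   temperature uniformity, named by their predicted chromosome
   (`C8-21`-style), and pooled into fluorophore cocktails (TAMRA/FAM
   multiplexes).
4. **insilico_map** — ungapped both-strand probe scanning (identity > 80%),
   1-Mb bin locus calling (> 30 hits per bin, or > 1 hit/Mb for
   plasmid-scale probes such as 45S rDNA), and SVG idiogram rendering.
5. **karyo_compare** — signal-site catalogs, cross-accession mismatch
   percentages, pooled-t and mean-ratio summary statistics.
6. **synth_genome** — seeded synthetic chromosomes with planted, truth-BED
   recorded tandem arrays for end-to-end validation.

The core scoring model: an array spanning segment *S* is scored against
monomer *m* by maximizing

```
score = 2·matches − 7·mismatches − 7·indels
```

over all alignments of *S* against unbounded tandem copies of *m*, with DP
columns that wrap from the last monomer position back to the first. See
`docs/methods.md` for the full model, parameter rationale and limitations.

## Worked example

Simulate a 300-kb chromosome with four diverged planted satellite arrays,
then run the whole pipeline:

```python
import numpy as np
from repeatprobe.synth_genome import ChromSpec, PlantSpec, generate_genome
from repeatprobe.pipeline import PipelineConfig, run_pipeline

rng = np.random.default_rng(42)
plants = []
for _ in range(4):
    period = int(rng.integers(15, 80))
    mono = "".join("ACGT"[b] for b in rng.integers(0, 4, period))
    plants.append(PlantSpec(mono, int(rng.integers(60, 120)), 0.03, 0.002, "chr1"))

fasta, truth_bed = generate_genome([ChromSpec("chr1", 300_000, 0.42)], plants, seed=42)
open("toy.fa", "w").write(fasta)

manifest = run_pipeline(PipelineConfig(fasta="toy.fa", outdir="out"))
print({s["stage"]: s["counts"] for s in manifest["stages"]})
```

prints

```
{'scan': {'chromosomes': 1, 'arrays': 7}, 'resolve': {'arrays': 7},
 'filter': {'arrays': 4}, 'cluster': {'clusters': 4},
 'design': {'probes': 3}, 'map': {'hits': 80}, 'call': {'loci': 1},
 'idiogram': {'marks': 1}}
```

Seven raw arrays are detected (the four plants plus three low-copy
background repeats), all are disjoint, the copy/period/match filter keeps
exactly the four planted arrays, and each surviving cluster that passes the
composition screens yields one probe. `out/probes.tsv` then holds the
designed probes:

```
probe_id  sequence                                     source_cluster  gc_percent  tm_celsius  channel
C1-1      TCTTCTCAGGATATATTTGCGCTGCACCCAGAGGTGCTCCTC   cl1             52.38       68.674      unassigned
C1-2      TGCCTAGAAGTGTGTGATCGTGCCTAGAAGTGTGTGATCGTG   cl3             50.0        67.746      unassigned
U-3       GGAGAAACGGCGATGGGGAGAAACGGCGATGGGGAGAAACGGC  cl4             62.79       73.908      unassigned
```

`C1-1` means "first probe, hits concentrated on chromosome 1" (here there is
only one chromosome); `U-3`'s cluster produced no locus-forming hit pattern,
so it stays unplaced. One 1-Mb bin exceeds the 30-hit calling threshold and
appears as the single locus in `out/loci.bed` and as one mark in
`out/idiogram.svg`.

The same pipeline is scriptable from the shell:

```
repeatprobe simulate --spec sim.yaml --out-prefix toy
repeatprobe scan --fasta toy.fa --min-score 50 --max-period 2000 --out arrays.tsv
repeatprobe filter --in arrays.tsv --min-period 10 --min-copies 50 --min-pct-match 70 --out kept.tsv
repeatprobe cluster --in monomers.fa --identity 75 --out reps.fa --report clusters.tsv
repeatprobe design --reps reps.fa --len 40:45 --out probes.fa
repeatprobe map --fasta toy.fa --probes probes.fa --min-identity 80 --bin 1000000 --out loci.bed --svg idiogram.svg
repeatprobe karyo-compare --ref qcxa.tsv --query wals9.tsv
repeatprobe tstat --g1 95.68,1.36,10 --g2 55.23,8.27,10
```

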