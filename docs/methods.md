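# Methods

`repeatprobe` re-creates, as desk-scale software, the computational arm of a
repeat-based oligo-FISH karyotyping workflow: tandem repeat discovery in a
genome assembly, reduction of repeat monomers to a non-redundant set, design
of short labelled oligo probes from those monomers, electronic localization
of the probes back onto chromosomes, and arithmetic comparison of the
resulting karyotype signal catalogs between accessions.

## Tandem repeat model and scoring

A tandem repeat array is a genomic interval that aligns well against an
unbounded head-to-tail concatenation of a short monomer. Scoring uses
wraparound dynamic programming: the alignment matrix has one column per
monomer position and re-enters column 1 after the last column, so alignments
freely span unit junctions and the number of copies is unbounded. Weights
are integer match/mismatch/indel = +2/−7/−7; the alignment is global in the
genomic segment and free at both ends on the monomer axis (arbitrary phase).
The implementation solves the cyclic within-row deletion recurrence exactly
with a prefix-max scan over a doubled column axis (one wrap suffices: a
second full cycle of deletions can never improve the score, as each deletion
costs a non-negative penalty). `N` bases never match anything, including
`N`. Reported per-array statistics come from one optimal traceback with a
fixed move preference (substitution, then segment-gap, then monomer-gap),
so they are deterministic; `copy_number` is monomer columns consumed divided
by the period, to one decimal.

The wraparound DP is property-tested against an independent brute-force
oracle (plain alignment against the monomer unrolled with slack copies, free
endpoints on the text axis) on hundreds of random instances up to 100 bp.

## Detection

Full probabilistic candidate selection of classical tandem-repeat finders is
not re-derivable from published parameter lists alone, so detection here is
a transparent two-stage procedure in which the score threshold is the
binding criterion:

1. **Seeding.** Every position whose exact 13-mer re-occurs at distance
   `d` (1 ≤ d ≤ 2000) immediately upstream votes for period `d`; only the
   most recent previous occurrence is used, which concentrates votes on the
   fundamental period. Votes at the same distance are chained into candidate
   intervals when the gap between successive votes is at most
   `max(3d, 150)` bp — wide enough that a 10%-diverged array (where only a
   few percent of 13-mers survive intact in adjacent copies) almost never
   fragments.
2. **Rescoring.** Each candidate interval is aligned once against a
   provisional monomer (the first in-phase copy), its column-majority
   consensus is read off the traceback, an exactly self-periodic consensus
   is collapsed to its fundamental unit, and the interval is realigned
   against that consensus for the final score and statistics. Overlapping
   candidates (harmonics at 2d, 3d, …) are grouped; the smallest-period
   candidate reaching the minimum score (≥ 50, inclusive) represents the
   group, so one planted array yields one reported array.

Arrays with more than 20% `N` content are dropped. Candidate intervals run
from one period before the first vote to one k-mer past the last vote;
boundaries are therefore accurate to a few bases on clean arrays, which is
far inside the 50%-reciprocal-overlap criterion used for evaluation.

Downstream, `resolve_overlaps` is greedy best-first interval selection
(descending score; ties: longer span, smaller start, input order) — a
deterministic O(n log n) reconstruction of "keep the best of any overlapping
set". `filter_arrays` retains arrays with period ≥ 10 (inclusive), copy
number ≥ 50 (inclusive) and percent matches strictly > 70, exactly as those
inequalities are printed; the de-overlap → filter order is the pipeline
default.

## Monomer clustering

Non-redundancy follows greedy-incremental (CD-HIT-style) clustering:
monomers sorted longest-first, first-fit assignment to the first existing
representative at ≥ 75% identity (inclusive), otherwise a new cluster.
Identity is defined from an optimal global alignment under unit weights
(match +1, mismatch −1, gap −1) as 100 × matches / alignment columns; among
equal-score alignments the one with the most matches, then fewest columns,
is used, making the value well-defined and symmetric. The DP maximizes the
lexicographic triple (score, matches, −columns) packed into one integer so
rows vectorize; it is tested against a recursive enumeration oracle.
Reverse-complement orientation is always considered (satellite monomers have
no canonical strand); cyclic-rotation scanning is off by default to mirror
standard CD-HIT behaviour, with an opt-in flag that maximizes identity over
all rotations of the shorter sequence.

## Oligo design

Candidates are every window of each allowed length (default 40–45 nt,
configurable down to 30 and up to 50) over the cyclic monomer, so windows
may span the tandem junction and every candidate is a genuine substring of a
real array of that monomer. Screens: GC within 30–70%, homopolymer runs
≤ 6 nt, and longest self-reverse-complement substring < 8 nt (a simple,
testable hairpin-stem proxy rather than full secondary-structure folding).
Survivors are ranked by closeness of their nearest-neighbour melting
temperature (Biopython `Tm_NN`, default table and salt — only the relative
ranking matters) to the surviving pool's median, favouring a thermally
uniform probe set; one probe per cluster by default.

Probe naming reconstructs the field convention from electronic
localization: `C{chrom}-{i}` when one chromosome carries the plurality of
hits, `Co-{i}` when no chromosome reaches 30% of hits (dispersed), `Tel-{i}`
when the monomer is a rotation of the plant telomeric repeat TTTAGGG or its
complement, `U-{i}` when no localization exists. The plurality/30% cutoffs
are this package's own documented choices; naming is injective within a run.
Cocktail composition groups probes by fluorophore channel (TAMRA/FAM) in
assignment order.

## Electronic localization

For 30–50 nt oligos an ungapped sliding-identity scan of both strands
replaces a heuristic local aligner: at > 80% identity over ≤ 50 nt, gapped
alignment adds no sensitivity, and the scan is deterministic and exactly
oracle-testable. Identity is matching positions ÷ probe length; the
threshold is strict (identity > 80%), evaluated in exact integer arithmetic
so the 36/45 = 80.0% boundary case is excluded and 37/45 is included.
Plasmid-scale probes (e.g. a 45S rDNA clone) are fragmented into 500-bp
windows every 250 bp, each scanned as an oligo, with overlapping hits merged
per site.

"Chromosome positions" are fixed non-overlapping bins anchored at
coordinate 0 (default 1 Mb; the granularity is configurable because no
standard defines it). A bin is a called locus when its hit count is
strictly > 30 (oligo rule) or its density strictly > 1 hit/Mb (plasmid
rule); adjacent called bins merge with summed counts. Locus calls are per
probe by default; a combine mode sums a named probe set before calling.
Idiograms are emitted as self-contained SVG (one proportional vertical bar
per chromosome, one colored mark per locus at its bin midpoint) plus a TSV
twin of the plotted marks so layouts are machine-checkable.

## Karyotype comparison and summary statistics

A signal site is keyed by (chromosome label, arm, region, probe); a
reference site is matched when a query site shares the key and a compatible
intensity, where "absent on one homolog" never corroborates. The key is
configurable (region can be dropped for coarse matching) because
"correspondence" between cytogenetic catalogs has no published formal
definition. Mismatch percentages are rounded half-up to one decimal.

Group comparisons use the pooled-variance two-sample t statistic from
(mean, SD, n) summaries — pooled rather than Welch by default because the
published pollen-fertility statistic (15.26 at n = 10 per group) is
reproduced exactly by the pooled formula; Welch is available by flag. Ratios
of group means are reported at full precision and rounded half-up to one
decimal. Several other printed t values in the source material do not
reproduce from their printed summaries under either formula (presumably
unrounded-source effects); the package computes, it does not transcribe.

## Synthetic genomes

The generator emulates exactly what the pipeline assumes about real
assemblies: i.i.d. background at a configurable GC, plus planted tandem
arrays (monomer × copies) with per-base substitutions and 1-bp indels
(insertions copy a random base; applying indels after substitutions keeps
truth-interval bookkeeping exact). One seeded NumPy generator drives
everything, so identical specs give byte-identical FASTA/BED; the seed is
recorded in FASTA headers. The standard evaluation condition is a 2-Mb
chromosome with 30 plants of period 10–200 bp, 50–200 copies and ≤ 10%
substitution divergence; the default indel rate is 0.2% per base, a
realistic order for satellite arrays. What the simulator does **not**
emulate: interspersed transposons, nested/higher-order repeat structure,
segmental duplications, assembly gaps and polyploid homologs — so passing
recovery tests demonstrate correctness of the detection machinery under the
stated repeat model, not performance on an 8-Gb allotetraploid assembly.

Recovery scoring: a truth interval is recovered iff some detected array
reciprocally overlaps it by ≥ 50%; each detected array may consume one
truth (greedy by overlap). Empty detection reports recall 0 and a flagged,
vacuous precision of 1.0.

## Numerical and degenerate-input choices

- Coordinates 0-based half-open internally and in BED; 1-based in prose.
- All tie-breaks are total orders (documented per function), so every
  result is reproducible bit-for-bit; the pipeline manifest carries no
  timestamps for the same reason.
- Chromosomes too short to carry a single seed pair (< k+1 bp) are skipped
  with a notice, not an error; all-`N` chromosomes yield nothing.
- Score/threshold comparisons follow the printed inequalities exactly:
  score ≥ 50, period ≥ 10, copies ≥ 50, matches > 70, identity > 80,
  count > 30, density > 1/Mb.
- Problem sizes in the test-suite (2-Mb genomes, 30 plants, 5 seeds;
  500-instance DP oracle sweeps at ≤ 100 bp) were chosen as the smallest
  scales at which the detector's behaviour is statistically meaningful.

## Known limitations

- The detector is not a bit-exact re-implementation of Tandem Repeats
  Finder; very low-scoring or highly indel-rich arrays that TRF's
  probabilistic model would chain may be fragmented or missed. The declared
  filters (copies ≥ 50, period ≥ 10) make this immaterial downstream.
- Monomer-phase ambiguity means a reported consensus may be any rotation of
  the "textbook" monomer; rotation-aware clustering handles the redundancy
  when enabled.
- The hairpin screen is a substring heuristic, not a thermodynamic folder.
- Electronic localization is ungapped; probes targeting indel-rich repeat
  families will undercount relative to a gapped aligner.
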