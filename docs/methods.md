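# Methods

This note records the models, statistical assumptions, defaults and design
choices behind stormkit, and what its synthetic validation does and does
not demonstrate about real libraries.

## Coordinate and format conventions

All coordinates are 0-based half-open internally (BED-native). GTF is
converted to 1-based closed on write. FASTQ is gzipped with a zeroed
timestamp and no embedded filename so fixed-seed runs are byte-identical.
Synthetic quality strings are constant ("I"): no metric in the toolkit
consumes base qualities, and a realistic quality model would add noise
without adding validation power.

## The synthetic-library generator

The generator's job is to reproduce the *statistical* structure of a
plate-based total-RNA library well enough that every downstream metric can
be validated against known truth.

**Transcriptome.** A random genome with `n_genes` non-overlapping
single-exon genes (one transcript each; the GTF still carries the full
gene/transcript/exon hierarchy). Gene lengths are uniform on a
configurable range (default 200–2000 bp) and a configurable fraction of
each chromosome is intergenic (default 0.5). Nothing in scope exercises
splicing, so multi-exon structure would only complicate coordinate
arithmetic without exercising more code paths.

**Annotations.** TE loci (150–600 bp elements) are placed in intergenic
space with per-family bp quotas proportional to the requested family
weights (the last element of each family is clipped so realised fractions
track the weights to placement granularity). Enhancers and R-loop regions
are placed in the remaining intergenic space; all placed elements are
mutually non-overlapping. Family labels use the standard
repeat-annotation vocabulary (LINE/L1, LINE/L2, SINE/Alu, LTR/ERV1, …).

**Cells and molecules.** Per-gene molecule counts are negative binomial
with mean `mean_molecules` per gene and `Var = μ + μ²/dispersion` (the
standard scRNA-seq overdispersion form; `dispersion = inf` gives the
Poisson limit). Each molecule draws an independent UMI from the declared
base distribution. Spike-in molecule counts are Poisson at each species'
expected copies per cell.

**Reads.** Each molecule receives `1 + Poisson(mean_reads_per_molecule −
1)` read pairs; duplicates share the molecule's fragment and UMI, so
UMI-saturation behaves like an amplified library. Fragments are uniform
within the transcript (or 3'-biased via a Beta(3,1) offset when
`frag_bias="three_prime"`). Spike-in molecules are emitted unfragmented,
mirroring their addition after the fragmentation step. R1 is
`[UMI][linker][cDNA]` from the fragment's 5' end in molecule orientation;
R2 is cDNA from the fragment's 3' end on the opposite strand.

**Artifact planting.** Every read is independently reassigned to an
artifact class with the requested probabilities (so class counts are
exactly binomial):

* *genomic background* — the read is re-placed uniformly in intergenic
  space with a fresh molecule and UMI, and a 15-A run (configurable) is
  planted immediately downstream of the recorded alignment end
  (strand-aware), reproducing the poly-A-flanked background signature of
  spurious priming;
* *strand invasion* — the read keeps its cell and UMI but its 5' end is
  moved to an invasion site inside a random gene whose upstream k bases
  are overwritten with the TSO tail. Sites are drawn from a small
  per-gene pool (default 2) rather than per read: invasion is a
  sequence-driven event that recurs at the same complementary sites, and
  one-site-per-read planting would litter transcript space with TSO
  k-mers that false-flag ordinary reads;
* *internal poly-A* — a transcript-internal read with a planted
  downstream A-run (off by default).

Signatures are planted into a **copy** of the genome *before* any read
sequence is extracted, and that planted genome is written with the
library, so parsers and detectors round-trip exactly against the emitted
FASTA/SAM.

**What the generator does not emulate** — and therefore what passing
tests do *not* show about real data: sequencing error, GC and priming
bias, rRNA carry-through, multi-mapping reads (every truth alignment is
unique), isoform complexity, and doublets. Recovery tolerances achieved
here (e.g. background within a few percent relative) are upper bounds on
real-data accuracy, not estimates of it.

## UMI collision model

Collisions are counted at the level of distinct (gene, UMI) pairs within
a cell after exact within-gene deduplication; no error-tolerant UMI
merging is attempted (directional collapsing interacts with sequencing
error models that are out of scope). The closed form treats genes
independently: a pair in gene g collides with probability
`1 − Π_{h≠g}(1 − q)^{m_h}`, `q = 4^{−L}`, averaged over pairs with gene g
weighted by its molecule count `m_g`. This is a birthday-type
approximation: it is exact per pair when each gene's molecules draw UMIs
i.i.d., and the Monte-Carlo framework — which draws per-molecule UMIs,
collapses within genes, and replays the observed-rate computation — is
the reference whenever exactness matters (and the only route for
non-uniform base compositions, e.g. A-biased or WW-constrained designs).
The residual analytic-vs-MC discrepancy is the ratio/weighting bias from
random within-gene deduplication; at L=2 with genes {3,2,4} it measures
~10⁻³, inside the Monte-Carlo 3-SE band at 50,000 replicates.

When comparing Monte-Carlo and analytic rates where the true rate is
minuscule (16-bp UMIs), the empirical SE can be exactly zero; checks use
`max(empirical SE, sqrt(p(1−p)/reps))`, a conservative binomial floor.

Saturation uses `E[distinct] = N(1 − (1 − 1/N)^M)` with `M` total reads
per gene, verified against exhaustive enumeration at N=4. With PCR
duplication, observed/expected ratios sit below 1 by construction — the
same depression seen in under-saturated real libraries.

## Spike-ins

Expected copies follow from the mix chemistry:
`copies = conc[amol/µL] × 10⁻¹⁸ × N_A × dilution × volume[µL]`. The
added volume is a required field with no default — a silently assumed
volume would corrupt every sensitivity estimate. A 20-species synthetic
mix spanning a 2-fold geometric concentration ladder ships for tests; real
vendor tables are user-supplied TSV.

The copy-number fit is OLS of `log2(observed + c)` on `log2(expected +
c)` with the **same** pseudocount on both axes (default `c = 1`). The
symmetric transform is deliberate: a perfect library (observed ==
expected) must fit to slope exactly 1 and R² exactly 1, which no
asymmetric pseudocount can satisfy; with `c = 0` a pure fold change moves
only the intercept. Adjusted `R² = 1 − (1 − R²)(n − 1)/(n − 2)` requires
≥ 3 species.

Sensitivity is the fraction of species expected at ≥ `copy_threshold`
copies (default 1.0) observed at ≥ `detect_threshold` units (default 1
UMI; pass read counts for a read-level call — which unit real pipelines
use varies, so it is configurable rather than asserted).

## Artifact metrics

Background classification uses ≥ 1 bp overlap precedence: transcript
(exons *and* introns — pre-mRNA is genuine signal in total RNA) →
R-loop-excluded (reads in RNA:DNA-hybrid regions may be genuine RNA and
are excluded from the background call, not counted toward it) →
background, sub-labelled TE-intergenic vs unannotated. Labels partition
the unique-read set by construction.

Poly-A flanks: the window (default 20 bp) 3' of the read — downstream of
`end` scanned for A on the plus strand, upstream of `start` scanned for T
on the minus strand — is searched with a two-pointer longest-run scan for
a run of ≥ `min_run` (default 10) bases tolerating ≤ `max_mismatch`
(default 1) interruptions; windows truncate at chromosome edges.

Strand invasion compares the genomic k-mer (default k = 7) immediately
upstream (strand-aware) of the 5' end of UMI-bearing R1 alignments with
the last k bases of the TSO tail, at ≤ `max_mismatch` (default 1). With
these defaults a random 7-mer false-flags at 22/4⁷ ≈ 0.13%, which bounds
the floor of the per-cell fractions; k and the mismatch budget are
exposed because published pipelines differ.

## Regulatory profiles

Gene-body coverage rescales each transcript (≥ `min_length`, default
500 bp) to 100 bins 5'→3' in transcript orientation, averages per-bin
depth over transcripts, then normalises to mean 1; the bin CV is the
evenness diagnostic. TE reads are assigned uniquely to the
maximal-overlap locus (ties to the lexicographically first name —
multi-mapping-aware TE quantification is out of scope), and family scores
divide the read-fraction by the genomic bp fraction (copy-number mode
available; bp is the default because element length differences are part
of the footprint being compared). Locus-level comparison CPM-normalises
both count vectors before the log2(·+1) OLS because pseudobulk and bulk
depths differ by construction.

eRNA detection counts UMIs (read fallback) in enhancer ± 500 bp by strand
relative to the element midpoint; divergent orientation is defined
against the midpoint because enhancer files carry midpoints, not TSS
pairs. `min_umis = 1` by default — the weakest defensible presence call,
configurable upward. The metaprofile asymmetry score is the fraction of
flanking coverage concordant with divergent initiation (plus-strand
downstream + minus-strand upstream over total); symmetric divergent
transcription scores ≈ 1, unstranded signal ≈ 0.5.

## Subsampling and fusion weighting

Subsampling is without replacement at read level (multivariate
hypergeometric over features), matching BAM downsampling; binomial
thinning is an option. CV (not variance) is the robustness statistic so
that transcript-length bins with different expression levels are
comparable. Detection rates for empty length bins are reported missing,
never zero.

Fusion support is FFPM = fragments/total × 10⁶. Weighted single-cell
detection divides the raw proportion of cells by the relative bulk
support `s_f = FFPM(sc strategy)/FFPM(reference)` and caps at 1; capping
(rather than renormalising across technologies) keeps each fusion's
weighted value interpretable as a proportion, and fusions with zero
reference-strategy support are flagged unweightable instead of dropped.

## Validation problem sizes

The shipped tests and the acceptance script use: a ~100k-read emitted
library (60 genes, 20 cells, 15% background / 2% invasion) for artifact
recovery; 50,000 Monte-Carlo replicates across UMI lengths {1, 2, 6, 8,
16} and gene counts {2, 5, 10, 50, 200} for the collision framework; 200
enhancers (50 transcribed) on a sparse ~12 Mb genome for eRNA recovery —
sized so that ±2 kb windows of distinct enhancers rarely overlap, which
isolates detector behaviour from annotation-density effects; 50,000
sampled reads for TE scores; 500 loci for the pseudobulk/bulk comparison
at a mean locus depth of 200 counts (locus-level log-log agreement is
counting-noise-limited below ~100 counts per locus); and 3,000 replicates
for subsampling moments. These sizes put Monte-Carlo bands well inside
the tolerances being checked while keeping the whole suite to a couple of
minutes.
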