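# stormkit

Quality-control, simulation and regulatory-element profiling toolkit for
**single-cell total RNA-seq** libraries of the STORM-seq family
(random-hexamer primed, ribo-reduced, plate-based, paired-end, with a UMI
added at template switching).

Total-RNA protocols are judged on things ordinary scRNA-seq QC does not
measure: how much genomic DNA leaks into the library, whether the
template-switching oligo (TSO) creates chimeric "strand invasion" reads,
whether a short UMI space causes inter-gene UMI collisions, whether
single spike-in molecules are actually detected, and whether non-coding
signal — transposable-element (TE) families and loci, bidirectionally
transcribed enhancer RNAs (eRNAs) — is represented faithfully. stormkit
implements those metrics as a library plus a `storm-kit` CLI, together with
a synthetic-library generator that emits truth-labelled FASTQ/SAM so every
metric can be validated against known ground truth without any external
dataset.

Audience: developers and users of plate-based total-RNA single-cell
protocols, and anyone benchmarking scRNA-seq chemistries at the read level.

## What it computes

**UMI diagnostics** (`stormkit.umistats`) — per-cell sequence logos
(diversity / prevalence / top-UMI-per-cell, with per-position information
content in bits); observed inter-gene collision rates over distinct
(gene, UMI) pairs; the expected collision rate as a function of UMI length
L and gene detection, both in closed form

    P(pair in gene g collides) = 1 − Π_{h≠g} (1 − 4^{−L})^{m_h}

(averaged over pairs; `m_h` molecules in gene h) and by Monte-Carlo
simulation that replays the observed-rate computation on simulated
molecules; and UMI saturation, `E[distinct] = N(1 − (1 − 1/N)^M)` with
`N = 4^L`.

**Spike-in sensitivity** (`stormkit.spikein`) — expected copies per cell
from the mix chemistry (`conc × 10⁻¹⁸ × N_A × dilution × volume`), OLS
fits of observed vs expected copy number on the log2 scale with adjusted
R², and single-molecule detection sensitivity (fraction of ≥ 1-copy
species detected).

**Artifact metrics** (`stormkit.artifacts`) — genomic-background
classification (reads outside transcript space, TE-aware, R-loop-excluded),
poly-A flank flagging for internal priming (strand-aware interrupted-run
search), and strand-invasion detection (genomic k-mer upstream of the
read 5' end vs the TSO tail).

**Regulatory profiles** (`stormkit.regprofiles`) — length-normalised
gene-body coverage; TE family observed/expected scores
(`score = read fraction / genomic bp fraction`); locus-level
pseudobulk-vs-bulk comparison (log2 CPM+1, OLS R²); eRNA detection with
bidirectionality calls, divergent metaprofiles with an asymmetry score,
and enhancer sharing across cells.

**Robustness** (`stormkit.robustness`) — replicated read subsampling
(multivariate hypergeometric), detection rates by transcript length,
abundance CV across replicates, gene-detection saturation curves, FFPM
(fusion fragments per million) and FFPM-weighted fusion detection across
library strategies.

**Read structure** (`stormkit.readstruct`) — declarative UMI/linker/cDNA
parsing with presets for 6/8/16-bp and WW-constrained UMI designs, and
reversible synthetic cell-barcode injection ("synthbar") so plate-based
per-well FASTQs can flow through droplet-style aligners.

**Synthetic data** (`stormkit.synthdata`) — generates genome + GTF +
BED annotation tracks, negative-binomial per-cell molecule counts,
Poisson spike-ins, and paired FASTQ with a truth SAM; artifact reads are
planted at requested rates with their sequence signatures written into the
emitted genome.

## Worked example

```python
from stormkit import synthdata as sd, artifacts as art, umistats as us
from stormkit.readstruct import ReadStructure

model = sd.build_transcriptome(n_genes=50, length_range=(200, 2000),
                               intergenic_fraction=0.75, seed=1)
bundle = sd.build_annotations(model, {"LINE/L1": 0.4, "SINE/Alu": 0.6},
                              n_rloops=10, seed=2)
truth = sd.simulate_cells(model, n_cells=8, mean_molecules=30,
                          dispersion=2.0, seed=3)
lib = sd.emit_library(truth, ReadStructure(umi_length=8),
                      sd.ArtifactRates(gdna_fraction=0.1), "demo", seed=4)
print("reads:", len(lib.reads))

aln = art.load_alignments(lib.truth_sam)
report = art.classify_background(aln, model.transcript_intervals(),
                                 bundle.te, bundle.rloops)
print(f"background fraction: {report.background_fraction:.4f}")

table = us.UmiTable.from_truth_reads(lib.reads)
cell = table.cells[0]
obs = us.observed_collision_rate(table, cell)
mols = truth.molecules
mols = mols[(mols.cell == cell) & (mols.source == "transcript")]
counts = mols.groupby("feature").size().to_numpy()
est = us.expected_collision_rate(8, counts, "monte_carlo", reps=5000, seed=5)
print(f"{cell}: observed collision {obs:.5f}, expected {est.rate:.5f} "
      f"(95% CI {est.ci_low:.5f}-{est.ci_high:.5f})")
```

prints

```
reads: 24727
background fraction: 0.0969
cell0000: observed collision 0.03242, expected 0.02708 (95% CI 0.02694-0.02723)
```

Reading the numbers: the generator planted 10% genomic-background reads
and the classifier recovers 9.7% (a little is absorbed by R-loop
exclusion and chance transcript overlap). With 8-bp UMIs and ~30
molecules per gene over 50 genes, about 2.7% of (gene, UMI) pairs are
expected to collide by chance; this cell's observed 3.2% is within the
cell-to-cell spread of that expectation (the CI shown is for the
Monte-Carlo mean, not a single-cell prediction band). Note the expected
rate takes **molecule** counts — feeding read counts (which include PCR
duplicates) would overstate the expectation.

The same operations are exposed on the command line:

```sh
storm-kit simulate --n-cells 8 --n-genes 50 --gdna-frac 0.1 --seed 1 --outdir demo
storm-kit artifacts background --sam demo/truth.sam \
    --transcripts-bed tx.bed --te-bed te.bed --out background.tsv
storm-kit umi collision --table umis.tsv --out collision.tsv
```

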