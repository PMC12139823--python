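"""Synthetic total-RNA single-cell libraries with per-read ground truth.

This module builds everything a desk test of the toolkit needs without any
download: a random transcriptome (FASTA + GTF), annotation tracks (TE loci
with family labels, enhancers, R-loop regions; BED6), per-cell molecule
counts with UMIs, and finally paired FASTQ plus a truth SAM in which every
read is placed at its source coordinates and labelled with its cell, UMI,
molecule and artifact class.

Statistical structure emulated:

* per-gene molecule counts are negative binomial with variance
  mu + mu^2/dispersion (the standard scRNA-seq overdispersion form);
  ``dispersion=inf`` gives the Poisson limit;
* spike-in molecules are Poisson at the expected copy number from the mix
  design, and are emitted unfragmented (spike-ins enter after
  fragmentation);
* PCR duplicates share their molecule's fragment and UMI;
* artifact reads (genomic background with planted downstream poly-A runs,
  strand-invasion reads whose 5' flank is the TSO tail, internal poly-A
  priming) are injected at requested rates, and their sequence signatures
  are planted into a copy of the genome *before* read sequences are
  extracted, so detectors and parsers round-trip exactly.

Coordinates are 0-based half-open internally; GTF is converted on write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .artifacts import ALIGNMENT_COLUMNS
from .intervals import IntervalSet
from .readstruct import ALPHABET, ReadStructure
from .seqio import FastqRecord, FastqWriter, revcomp, write_fasta
from .spikein import SpikeInDesign

_BASE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)

#: declared TE family vocabulary (BED name column carries the family).
TE_FAMILIES = ("LINE/L1", "LINE/L2", "SINE/Alu", "SINE/MIR",
               "LTR/ERV1", "LTR/ERVK", "LTR/ERVL", "DNA/hAT")

DEFAULT_TSO_TAIL = "AAGCAGTGGTATCAACGCAGAGTGGG"

ARTIFACT_CLASSES = ("none", "gdna_background", "strand_invasion",
                    "internal_polyA")


def _decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def _random_umis(rng: np.random.Generator, n: int, length: int,
                 weights: Mapping[str, float] | None) -> list[str]:
    if weights is None:
        p = None
    else:
        p = np.array([weights.get(b, 0.0) for b in ALPHABET], dtype=float)
        if not np.isclose(p.sum(), 1.0):
            raise ValueError("umi_weights must sum to 1")
    idx = rng.choice(4, size=(n, length), p=p)
    mat = _BASE_LUT[idx]
    return [_decode(row) for row in mat]


# ---------------------------------------------------------------------------
# transcriptome
# ---------------------------------------------------------------------------

@dataclass
class TranscriptomeModel:
    """A synthetic genome with single-transcript genes.

    ``genes``: DataFrame with gene_id, chrom, start, end, strand, length and
    an ``exons`` column (list of (start, end); one exon per gene here).
    ``sequences``: chrom -> mutable uint8 array of ASCII bases.
    """

    genes: pd.DataFrame
    sequences: dict[str, np.ndarray]
    seed: int

    def __post_init__(self):
        g = self.genes
        if g["gene_id"].duplicated().any():
            raise ValueError("gene ids are not unique")
        for row in g.itertuples():
            clen = len(self.sequences[row.chrom])
            if not (0 <= row.start < row.end <= clen):
                raise ValueError(
                    f"gene {row.gene_id} [{row.start},{row.end}) outside "
                    f"chromosome bounds [0,{clen})"
                )

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def sequence(self, chrom: str) -> str:
        return _decode(self.sequences[chrom])

    def genome_dict(self) -> dict[str, str]:
        return {c: _decode(s) for c, s in self.sequences.items()}

    def transcript_intervals(
        self, extra_contigs: Mapping[str, int] | None = None
    ) -> IntervalSet:
        """All transcript spans (introns included) as an IntervalSet.

        ``extra_contigs`` (e.g. spike-in contig lengths) are added as
        full-length transcript intervals.
        """
        rows = [(r.chrom, r.start, r.end, r.gene_id, 0, r.strand)
                for r in self.genes.itertuples()]
        for name, length in (extra_contigs or {}).items():
            rows.append((name, 0, length, name, 0, "+"))
        return IntervalSet.from_tuples(rows)

    def intergenic_segments(self) -> list[tuple[str, int, int]]:
        """Maximal intervals not covered by any gene, per chromosome."""
        out = []
        for chrom, length in self.chrom_lengths.items():
            sub = self.genes[self.genes["chrom"] == chrom].sort_values("start")
            cursor = 0
            for row in sub.itertuples():
                if row.start > cursor:
                    out.append((chrom, cursor, row.start))
                cursor = max(cursor, row.end)
            if cursor < length:
                out.append((chrom, cursor, length))
        return out

    # -- I/O --------------------------------------------------------------
    def write_fasta(self, path: str | Path) -> Path:
        return write_fasta(path, self.genome_dict())

    def write_gtf(self, path: str | Path, source: str = "stormkit") -> Path:
        """GTF (1-based, closed intervals) with gene/transcript/exon lines."""
        path = Path(path)
        with open(path, "w") as fh:
            for row in self.genes.itertuples():
                attrs = (f'gene_id "{row.gene_id}"; '
                         f'transcript_id "{row.gene_id}.t1";')
                for feature in ("gene", "transcript"):
                    fh.write("\t".join([
                        row.chrom, source, feature, str(row.start + 1),
                        str(row.end), ".", row.strand, ".", attrs,
                    ]) + "\n")
                for es, ee in row.exons:
                    fh.write("\t".join([
                        row.chrom, source, "exon", str(es + 1), str(ee),
                        ".", row.strand, ".", attrs,
                    ]) + "\n")
        return path


def build_transcriptome(n_genes: int,
                        length_range: tuple[int, int] = (200, 2000),
                        intergenic_fraction: float = 0.5,
                        seed: int = 0,
                        n_chroms: int = 1) -> TranscriptomeModel:
    """Random genome with ``n_genes`` non-overlapping single-exon genes.

    Genes alternate with intergenic gaps sized so that the requested
    fraction of each chromosome is intergenic; strands are random.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = length_range
    if lo > hi:
        raise ValueError(f"invalid length_range: min {lo} > max {hi}")
    if lo < 50:
        raise ValueError("minimum transcript length is 50 bp")
    if not (0 <= intergenic_fraction < 1):
        raise ValueError("intergenic_fraction must be in [0, 1)")

    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, n_genes)
    strands = rng.choice(list("+-"), n_genes)
    chrom_of = np.arange(n_genes) % n_chroms

    gene_rows = []
    sequences: dict[str, np.ndarray] = {}
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        idx = np.where(chrom_of == ci)[0]
        gene_bp = int(lengths[idx].sum())
        total = max(int(np.ceil(gene_bp / (1 - intergenic_fraction))),
                    gene_bp + len(idx) + 1)
        intergenic = total - gene_bp
        gaps = rng.multinomial(intergenic, np.full(len(idx) + 1,
                                                   1 / (len(idx) + 1)))
        cursor = 0
        for j, gi in enumerate(idx):
            cursor += int(gaps[j])
            start, end = cursor, cursor + int(lengths[gi])
            gene_rows.append({
                "gene_id": f"gene{gi + 1:04d}", "chrom": chrom,
                "start": start, "end": end, "strand": strands[gi],
                "length": int(lengths[gi]), "exons": [(start, end)],
            })
            cursor = end
        sequences[chrom] = _BASE_LUT[rng.integers(0, 4, total)].copy()

    genes = pd.DataFrame(gene_rows)
    return TranscriptomeModel(genes, sequences, seed)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

@dataclass
class AnnotationBundle:
    """TE, enhancer and R-loop interval tracks over a model's genome."""

    te: IntervalSet
    enhancers: IntervalSet
    rloops: IntervalSet
    enhancer_midpoints: pd.Series = field(default_factory=pd.Series)

    def te_family_bp(self) -> pd.Series:
        df = self.te.df
        widths = df["end"] - df["start"]
        return widths.groupby(df["name"]).sum()

    def write_beds(self, outdir: str | Path,
                   prefix: str = "annotations") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        return {
            "te": self.te.to_bed(outdir / f"{prefix}.te.bed"),
            "enhancers": self.enhancers.to_bed(
                outdir / f"{prefix}.enhancers.bed"),
            "rloops": self.rloops.to_bed(outdir / f"{prefix}.rloops.bed"),
        }


class _SpaceAllocator:
    """Allocate non-overlapping sub-intervals from free segments."""

    def __init__(self, segments: Sequence[tuple[str, int, int]]):
        self.segments = [list(s) for s in segments]

    def allocate(self, length: int, rng: np.random.Generator,
                 what: str) -> tuple[str, int, int]:
        capacities = np.array(
            [max(0, s[2] - s[1] - length + 1) for s in self.segments],
            dtype=float)
        total = capacities.sum()
        if total <= 0:
            raise ValueError(
                f"insufficient intergenic space to place {what} of "
                f"{length} bp; shrink the element or raise "
                f"intergenic_fraction"
            )
        i = rng.choice(len(self.segments), p=capacities / total)
        chrom, s, e = self.segments[i]
        start = int(s + rng.integers(0, e - s - length + 1))
        end = start + length
        # split the segment around the allocation
        self.segments.pop(i)
        if start - s > 0:
            self.segments.insert(i, [chrom, s, start])
        if e - end > 0:
            self.segments.insert(i + 1, [chrom, end, e])
        return chrom, start, end


def build_annotations(model: TranscriptomeModel,
                      family_weights: Mapping[str, float],
                      n_enhancers: int = 0,
                      n_rloops: int = 0,
                      seed: int = 0,
                      te_fraction_of_intergenic: float = 0.25,
                      te_length_range: tuple[int, int] = (150, 600),
                      enhancer_length: int = 300,
                      rloop_length_range: tuple[int, int] = (300, 1200),
                      ) -> AnnotationBundle:
    """Place TE loci (bp per family ~ family_weights), enhancers, R-loops.

    All elements are placed in intergenic space, mutually non-overlapping.
    TE quotas are hit near-exactly by clipping each family's last element,
    so realised family bp fractions track the weights to placement
    granularity.
    """
    weights = dict(family_weights)
    if not np.isclose(sum(weights.values()), 1.0):
        raise ValueError("family_weights must sum to 1")
    rng = np.random.default_rng(seed)
    alloc = _SpaceAllocator(model.intergenic_segments())
    intergenic_bp = sum(e - s for _, s, e in model.intergenic_segments())

    te_rows = []
    total_te_bp = int(te_fraction_of_intergenic * intergenic_bp)
    tlo, thi = te_length_range
    for fam, w in weights.items():
        remaining = int(round(w * total_te_bp))
        while remaining >= 50:
            length = int(min(rng.integers(tlo, thi + 1), remaining))
            if length < 50:
                length = remaining
            chrom, s, e = alloc.allocate(length, rng, f"TE ({fam})")
            te_rows.append((chrom, s, e, fam, 0, rng.choice(list("+-"))))
            remaining -= length

    enh_rows = []
    for i in range(n_enhancers):
        chrom, s, e = alloc.allocate(enhancer_length, rng, "enhancer")
        enh_rows.append((chrom, s, e, f"enh{i + 1:04d}", 0, "."))

    rl_rows = []
    rlo, rhi = rloop_length_range
    for i in range(n_rloops):
        length = int(rng.integers(rlo, rhi + 1))
        chrom, s, e = alloc.allocate(length, rng, "R-loop")
        rl_rows.append((chrom, s, e, f"rloop{i + 1:04d}", 0, "."))

    te = IntervalSet.from_tuples(te_rows)
    enhancers = IntervalSet.from_tuples(enh_rows)
    rloops = IntervalSet.from_tuples(rl_rows)
    midpoints = pd.Series(
        ((enhancers.df["start"] + enhancers.df["end"]) // 2).to_numpy(),
        index=enhancers.df["name"], dtype=int, name="midpoint")
    return AnnotationBundle(te, enhancers, rloops, midpoints)


# ---------------------------------------------------------------------------
# cells and molecules
# ---------------------------------------------------------------------------

@dataclass
class ArtifactRates:
    """Requested per-read artifact fractions (each in [0,1], sum <= 1)."""

    gdna_fraction: float = 0.0
    strand_invasion_fraction: float = 0.0
    internal_polyA_fraction: float = 0.0

    def __post_init__(self):
        vals = (self.gdna_fraction, self.strand_invasion_fraction,
                self.internal_polyA_fraction)
        if any(not (0 <= v <= 1) for v in vals):
            raise ValueError("artifact fractions must be in [0, 1]")
        if sum(vals) > 1:
            raise ValueError(f"artifact fractions sum to {sum(vals)} > 1")

    @property
    def probabilities(self) -> np.ndarray:
        p = np.array([self.gdna_fraction, self.strand_invasion_fraction,
                      self.internal_polyA_fraction])
        return np.concatenate([[1 - p.sum()], p])


@dataclass
class MoleculeTruth:
    """Ground truth linking molecules (and later reads) to their sources."""

    model: TranscriptomeModel
    gene_counts: pd.DataFrame          # genes x cells
    molecules: pd.DataFrame            # molecule_id, cell, source, feature, umi
    umi_length: int
    spikein: SpikeInDesign | None = None
    reads: pd.DataFrame | None = None  # filled by emit_library

    @property
    def cells(self) -> list[str]:
        return list(self.gene_counts.columns)

    def spike_counts(self) -> pd.DataFrame:
        """Species x cell molecule counts from the truth."""
        spikes = self.molecules[self.molecules["source"] == "spikein"]
        table = (spikes.groupby(["feature", "cell"]).size().unstack(
            fill_value=0).reindex(columns=self.cells, fill_value=0))
        if self.spikein is not None:
            table = table.reindex(self.spikein.species["id"], fill_value=0)
        return table

    def artifact_fractions(self) -> pd.Series:
        if self.reads is None:
            raise ValueError("no reads emitted yet")
        return (self.reads["artifact_class"].value_counts(normalize=True)
                .reindex(ARTIFACT_CLASSES, fill_value=0.0))


def simulate_cells(model: TranscriptomeModel,
                   n_cells: int,
                   mean_molecules: float = 2.0,
                   dispersion: float = 2.0,
                   spikein: SpikeInDesign | None = None,
                   umi_length: int = 8,
                   umi_weights: Mapping[str, float] | None = None,
                   gene_weights: np.ndarray | None = None,
                   seed: int = 0) -> MoleculeTruth:
    """Draw per-cell molecule counts and assign every molecule a UMI.

    ``mean_molecules`` is the negative-binomial mean *per gene*
    (variance = mu + mu^2/dispersion); ``dispersion=inf`` gives Poisson
    counts. ``gene_weights`` rescales per-gene means while conserving the
    per-cell total (heterogeneous expression). Spike-in molecule counts are
    Poisson at each species' expected copies per cell.
    """
    if umi_length < 1:
        raise ValueError("umi_length must be >= 1")
    if not np.isinf(dispersion) and dispersion <= 0:
        raise ValueError("dispersion must be > 0 (or inf for Poisson)")
    rng = np.random.default_rng(seed)
    genes = model.genes["gene_id"].to_numpy()
    n_genes = len(genes)

    mu = np.full(n_genes, float(mean_molecules))
    if gene_weights is not None:
        w = np.asarray(gene_weights, dtype=float)
        mu = mean_molecules * n_genes * w / w.sum()

    cells = [f"cell{i:04d}" for i in range(n_cells)]
    if np.isinf(dispersion):
        counts = rng.poisson(mu[:, None], size=(n_genes, n_cells))
    else:
        p = dispersion / (dispersion + mu)
        counts = rng.negative_binomial(dispersion, p[:, None],
                                       size=(n_genes, n_cells))
    gene_counts = pd.DataFrame(counts, index=genes, columns=cells)

    mol_cell, mol_feature, mol_source = [], [], []
    for ci, cell in enumerate(cells):
        nz = np.nonzero(counts[:, ci])[0]
        for gi in nz:
            k = counts[gi, ci]
            mol_cell.extend([cell] * k)
            mol_feature.extend([genes[gi]] * k)
        mol_source.extend(["transcript"] * int(counts[:, ci].sum()))
        if spikein is not None:
            expect = spikein.expected_copies()
            spike_n = rng.poisson(expect.to_numpy())
            for sid, k in zip(expect.index, spike_n):
                mol_cell.extend([cell] * int(k))
                mol_feature.extend([sid] * int(k))
                mol_source.extend(["spikein"] * int(k))

    n_mol = len(mol_cell)
    molecules = pd.DataFrame({
        "molecule_id": np.arange(n_mol),
        "cell": mol_cell,
        "source": mol_source,
        "feature": mol_feature,
        "umi": _random_umis(rng, n_mol, umi_length, umi_weights),
    })
    return MoleculeTruth(model, gene_counts, molecules, umi_length, spikein)


# ---------------------------------------------------------------------------
# library emission
# ---------------------------------------------------------------------------

@dataclass
class EmittedLibrary:
    """Paths and in-memory state of an emitted synthetic library."""

    fastq_r1: Path
    fastq_r2: Path
    truth_sam: Path
    truth_table: Path
    genome_fasta: Path
    genome: dict[str, str]       # planted genome (artifact signatures applied)
    reads: pd.DataFrame
    tso_tail: str
    structure: ReadStructure


def emit_library(truth: MoleculeTruth,
                 structure: ReadStructure,
                 rates: ArtifactRates,
                 outdir: str | Path,
                 read_len: int = 76,
                 frag_bias: str = "uniform",
                 frag_length_range: tuple[int, int] = (150, 400),
                 mean_reads_per_molecule: float = 2.0,
                 polya_run: int = 15,
                 tso_tail: str = DEFAULT_TSO_TAIL,
                 tso_k: int = 7,
                 invasion_sites_per_gene: int = 2,
                 seed: int = 0,
                 gzip_fastq: bool = True) -> EmittedLibrary:
    """Emit paired FASTQ + truth SAM for a simulated cell population.

    R1 carries [UMI][linker][cDNA] per ``structure`` (R2 is pure cDNA from
    the fragment's other end). Each read is independently converted to an
    artifact class with the probabilities in ``rates``; artifact sequence
    signatures (poly-A runs, TSO tails) are planted into a copy of the
    genome before sequences are extracted, and the planted genome is
    written alongside the library so detectors see a consistent reference.
    """
    if frag_bias not in ("uniform", "three_prime"):
        raise ValueError("frag_bias must be 'uniform' or 'three_prime'")
    prefix = structure.umi_length + len(structure.linker)
    if read_len <= prefix:
        raise ValueError(
            f"read_len {read_len} must exceed UMI+linker length {prefix}"
        )
    rates.probabilities  # validates sum <= 1
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    model = truth.model
    genome = {c: s.copy() for c, s in model.sequences.items()}

    # spike-in contigs (deterministic sequences keyed off this seed)
    spike_lengths: dict[str, int] = {}
    if truth.spikein is not None:
        srng = np.random.default_rng(seed + 1)
        for row in truth.spikein.species.itertuples():
            genome[row.id] = _BASE_LUT[
                srng.integers(0, 4, int(row.length_bp))].copy()
            spike_lengths[row.id] = int(row.length_bp)

    genes = model.genes.set_index("gene_id")
    cdna_len = read_len - prefix
    flo, fhi = frag_length_range

    # --- fragments per molecule -----------------------------------------
    mols = truth.molecules
    n_mol = len(mols)
    frag = np.zeros((n_mol, 2), dtype=int)
    frag_chrom = np.empty(n_mol, dtype=object)
    frag_strand = np.empty(n_mol, dtype=object)
    gene_start = genes["start"]
    gene_end = genes["end"]
    gene_strand = genes["strand"]
    for i, row in enumerate(mols.itertuples()):
        if row.source == "spikein":
            frag_chrom[i] = row.feature
            frag_strand[i] = "+"
            frag[i] = (0, spike_lengths[row.feature])
            continue
        gs, ge = int(gene_start[row.feature]), int(gene_end[row.feature])
        strand = gene_strand[row.feature]
        glen = ge - gs
        flen = int(min(rng.integers(flo, fhi + 1), glen))
        room = glen - flen
        if frag_bias == "uniform":
            off5 = int(rng.integers(0, room + 1))
        else:  # offset of the fragment 5' end in transcript coordinates,
            # concentrated toward the 3' end
            off5 = int(round(rng.beta(3, 1) * room))
        if strand == "+":
            fs = gs + off5
        else:
            fs = ge - off5 - flen
        frag_chrom[i] = row.chrom if hasattr(row, "chrom") else genes.loc[
            row.feature, "chrom"]
        frag_strand[i] = strand
        frag[i] = (fs, fs + flen)

    # --- reads -----------------------------------------------------------
    if mean_reads_per_molecule < 1:
        raise ValueError("mean_reads_per_molecule must be >= 1")
    reads_per_mol = 1 + rng.poisson(mean_reads_per_molecule - 1, n_mol)
    read_mol = np.repeat(np.arange(n_mol), reads_per_mol)
    n_reads = len(read_mol)
    classes = rng.choice(4, size=n_reads, p=rates.probabilities)

    intergenic = model.intergenic_segments()
    ig_caps = np.array(
        [max(0, e - s - cdna_len - polya_run - 1) for _, s, e in intergenic],
        dtype=float)
    if rates.gdna_fraction > 0 and ig_caps.sum() <= 0:
        raise ValueError("insufficient intergenic space for gDNA reads")

    mol_cells = mols["cell"].to_numpy()
    mol_umis = mols["umi"].to_numpy()
    mol_features = mols["feature"].to_numpy()
    gene_ids = genes.index.to_numpy()

    rows = []       # read_id, cell, molecule_id, class, umi, chrom, s, e, strand, feature
    plants = []     # (chrom, pos, bytes) applied before sequence extraction
    extra_mols = []
    invasion_sites: dict[str, list[int]] = {}

    next_mol = n_mol
    for ri in range(n_reads):
        mi = read_mol[ri]
        cls = ARTIFACT_CLASSES[classes[ri]]
        cell = mol_cells[mi]
        if cls == "none":
            chrom, strand = frag_chrom[mi], frag_strand[mi]
            fs, fe = frag[mi]
            c = min(cdna_len, fe - fs)
            if strand == "+":
                s, e = fs, fs + c
            else:
                s, e = fe - c, fe
            rows.append((ri, cell, mi, cls, mol_umis[mi], chrom, s, e,
                         strand, mol_features[mi]))
        elif cls == "gdna_background":
            seg = int(rng.choice(len(intergenic), p=ig_caps / ig_caps.sum()))
            chrom, gs_, ge_ = intergenic[seg]
            strand = "+" if rng.random() < 0.5 else "-"
            lo_pos = gs_ + (polya_run if strand == "-" else 0)
            hi_pos = ge_ - cdna_len - (polya_run if strand == "+" else 0)
            s = int(rng.integers(lo_pos, max(lo_pos + 1, hi_pos)))
            e = s + cdna_len
            umi = _random_umis(rng, 1, truth.umi_length, None)[0]
            extra_mols.append((next_mol, cell, "gdna", "", umi))
            if strand == "+":
                plants.append((chrom, e, b"A" * polya_run))
            else:
                plants.append((chrom, s - polya_run, b"T" * polya_run))
            rows.append((ri, cell, next_mol, cls, umi, chrom, s, e,
                         strand, ""))
            next_mol += 1
        elif cls == "strand_invasion":
            gid = gene_ids[int(rng.integers(0, len(gene_ids)))]
            gs, ge = int(gene_start[gid]), int(gene_end[gid])
            strand = gene_strand[gid]
            chrom = genes.loc[gid, "chrom"]
            c = min(cdna_len, ge - gs - tso_k)
            tail = tso_tail[-tso_k:]
            # invasion recurs at a small pool of complementary sites per
            # gene; reusing them keeps planted TSO k-mers from littering
            # transcript space with false 5'-flank matches
            pool = invasion_sites.setdefault(gid, [])
            if len(pool) < invasion_sites_per_gene:
                if strand == "+":
                    p5 = int(rng.integers(max(gs, tso_k),
                                          max(max(gs, tso_k) + 1, ge - c)))
                    plants.append((chrom, p5 - tso_k, tail.encode()))
                else:
                    clen = len(genome[chrom])
                    p5 = int(rng.integers(
                        gs + c, max(gs + c + 1, min(ge, clen - tso_k))))
                    plants.append((chrom, p5, revcomp(tail).encode()))
                pool.append(p5)
            else:
                p5 = pool[int(rng.integers(0, len(pool)))]
            s, e = (p5, p5 + c) if strand == "+" else (p5 - c, p5)
            rows.append((ri, cell, mi, cls, mol_umis[mi], chrom, s, e,
                         strand, gid))
        else:  # internal_polyA: transcript read with a planted downstream A run
            gid = mol_features[mi]
            if mols["source"].iloc[mi] == "spikein":
                gid = gene_ids[int(rng.integers(0, len(gene_ids)))]
            gs, ge = int(gene_start[gid]), int(gene_end[gid])
            strand = gene_strand[gid]
            chrom = genes.loc[gid, "chrom"]
            c = min(cdna_len, ge - gs)
            if strand == "+":
                s = int(rng.integers(gs, max(gs + 1, ge - c)))
                e = s + c
                plants.append((chrom, e, b"A" * polya_run))
            else:
                e = int(rng.integers(gs + c, max(gs + c + 1, ge)))
                s = e - c
                plants.append((chrom, max(0, s - polya_run),
                               b"T" * min(polya_run, s)))
            rows.append((ri, cell, mi, cls, mol_umis[mi], chrom, s, e,
                         strand, gid))

    # --- plant artifact signatures, then extract sequences ---------------
    for chrom, pos, payload in plants:
        arr = genome[chrom]
        end = min(len(arr), pos + len(payload))
        if pos < 0:
            payload = payload[-pos:]
            pos = 0
        arr[pos:end] = np.frombuffer(payload[:end - pos], dtype=np.uint8)

    genome_str = {c: _decode(s) for c, s in genome.items()}

    reads = pd.DataFrame(rows, columns=[
        "read_index", "cell", "molecule_id", "artifact_class", "umi",
        "chrom", "start", "end", "strand", "feature"])
    reads["read_id"] = [f"sk{int(i):08d}" for i in reads["read_index"]]

    if extra_mols:
        truth.molecules = pd.concat([
            truth.molecules,
            pd.DataFrame(extra_mols, columns=[
                "molecule_id", "cell", "source", "feature", "umi"]),
        ], ignore_index=True)
    truth.reads = reads

    suffix = ".fastq.gz" if gzip_fastq else ".fastq"
    fq1 = outdir / f"library_R1{suffix}"
    fq2 = outdir / f"library_R2{suffix}"
    frag_by_mol = {mi: frag[mi] for mi in range(n_mol)}

    with FastqWriter(fq1) as w1, FastqWriter(fq2) as w2:
        for row in reads.itertuples():
            seq = genome_str[row.chrom][row.start:row.end]
            cdna1 = seq if row.strand == "+" else revcomp(seq)
            r1 = row.umi + structure.linker + cdna1
            w1.write(FastqRecord(row.read_id, r1, "I" * len(r1)))
            # R2 from the fragment's 3' end (same span as R1 for artifact reads)
            mi = row.molecule_id
            if row.artifact_class == "none" and mi in frag_by_mol:
                fs, fe = frag_by_mol[mi]
                fchrom = row.chrom
                flen2 = min(read_len, fe - fs)
                if row.strand == "+":
                    r2 = revcomp(genome_str[fchrom][fe - flen2:fe])
                else:
                    r2 = genome_str[fchrom][fs:fs + flen2]
            else:
                r2 = revcomp(cdna1)
            w2.write(FastqRecord(row.read_id, r2, "I" * len(r2)))

    # --- truth SAM --------------------------------------------------------
    sam_path = outdir / "truth.sam"
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in genome_str.items()],
    }
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as sam:
        for row in reads.itertuples():
            rec = pysam.AlignedSegment(sam.header)
            rec.query_name = row.read_id
            rec.reference_name = row.chrom
            rec.reference_start = int(row.start)
            rec.mapping_quality = 60
            rec.flag = 0 if row.strand == "+" else 16
            span = int(row.end - row.start)
            rec.cigarstring = f"{span}M"
            seq = genome_str[row.chrom][row.start:row.end]
            rec.query_sequence = seq
            rec.query_qualities = pysam.qualitystring_to_array("I" * span)
            rec.set_tag("CB", str(row.cell))
            rec.set_tag("UB", str(row.umi))
            rec.set_tag("XC", str(row.artifact_class))
            rec.set_tag("XM", int(row.molecule_id))
            if row.feature:
                rec.set_tag("XG", str(row.feature))
            rec.set_tag("NH", 1)
            sam.write(rec)

    table_path = outdir / "truth_table.tsv"
    reads.drop(columns=["read_index"]).to_csv(table_path, sep="\t",
                                              index=False)
    fasta_path = write_fasta(outdir / "genome.fa", genome_str)

    return EmittedLibrary(fq1, fq2, sam_path, table_path, fasta_path,
                          genome_str, reads, tso_tail, structure)


# ---------------------------------------------------------------------------
# focused samplers for regulatory-element metrics
# ---------------------------------------------------------------------------

def simulate_enhancer_reads(bundle: AnnotationBundle,
                            transcribed: Sequence[str],
                            cells: Sequence[str],
                            mean_reads_per_side: float = 2.0,
                            max_offset: int = 300,
                            read_len: int = 50,
                            umi_length: int = 8,
                            seed: int = 0) -> pd.DataFrame:
    """Plant divergent eRNA transcription at a subset of enhancers.

    Each transcribed enhancer gets, per cell, >= 1 plus-strand read starting
    downstream of its midpoint and >= 1 minus-strand read ending upstream of
    it (counts 1 + Poisson(mean - 1) per side) — the bidirectional signature
    of active enhancers. Returns an alignment frame; untranscribed
    enhancers receive no reads.
    """
    rng = np.random.default_rng(seed)
    mids = bundle.enhancer_midpoints
    unknown = set(transcribed) - set(mids.index)
    if unknown:
        raise KeyError(f"unknown enhancer ids: {sorted(unknown)}")
    chrom_of = bundle.enhancers.df.set_index("name")["chrom"]

    rows = []
    for cell in cells:
        for eid in transcribed:
            mid = int(mids[eid])
            chrom = chrom_of[eid]
            n_plus = 1 + rng.poisson(max(0.0, mean_reads_per_side - 1))
            n_minus = 1 + rng.poisson(max(0.0, mean_reads_per_side - 1))
            for _ in range(n_plus):
                s = mid + int(rng.integers(0, max_offset))
                rows.append((cell, chrom, s, s + read_len, "+",
                             _random_umis(rng, 1, umi_length, None)[0],
                             True, eid))
            for _ in range(n_minus):
                e = mid - int(rng.integers(0, max_offset))
                rows.append((cell, chrom, max(0, e - read_len), e, "-",
                             _random_umis(rng, 1, umi_length, None)[0],
                             True, eid))
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


def sample_te_reads(te: IntervalSet, n_reads: int,
                    family_fractions: Mapping[str, float] | None = None,
                    read_len: int = 50, cell: str = "pseudobulk",
                    seed: int = 0) -> pd.DataFrame:
    """Draw reads from TE loci.

    With ``family_fractions=None`` the probability of a locus is
    proportional to its bp (the null under which every family's
    observed/expected score is 1). Passing explicit per-family read
    fractions plants over/under-expression: a family given twice its bp
    fraction scores 2.
    """
    df = te.df
    widths = (df["end"] - df["start"]).to_numpy(dtype=float)
    fam = df["name"].to_numpy()
    if family_fractions is None:
        probs = widths / widths.sum()
    else:
        fam_bp = pd.Series(widths).groupby(pd.Series(fam)).sum()
        fr = pd.Series(family_fractions, dtype=float)
        fr = fr / fr.sum()
        probs = np.array([
            fr.get(f, 0.0) * w / fam_bp[f] for f, w in zip(fam, widths)
        ])
        probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    loci = rng.choice(len(df), size=n_reads, p=probs)
    rows = []
    for li in loci:
        row = df.iloc[li]
        span = row["end"] - row["start"]
        rl = min(read_len, span)
        s = int(row["start"] + rng.integers(0, span - rl + 1))
        rows.append((cell, row["chrom"], s, s + rl,
                     rng.choice(list("+-")), "", True, row["name"]))
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


def simulate_locus_counts(n_loci: int = 500, depth_sc: float = 200.0,
                          depth_bulk: float = 200.0, sigma: float = 1.5,
                          seed: int = 0) -> tuple[pd.Series, pd.Series]:
    """Two independent Poisson samplings of one log-normal expression truth.

    Emulates single-cell pseudobulk and bulk libraries measuring the same
    locus-level TE expression; their log-log agreement is bounded only by
    counting noise.
    """
    rng = np.random.default_rng(seed)
    lam = rng.lognormal(0.0, sigma, n_loci)
    lam = lam / lam.mean()
    idx = pd.Index([f"locus{i + 1:04d}" for i in range(n_loci)], name="locus")
    sc = pd.Series(rng.poisson(lam * depth_sc), index=idx, name="pseudobulk")
    bulk = pd.Series(rng.poisson(lam * depth_bulk), index=idx, name="bulk")
    return sc, bulk
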