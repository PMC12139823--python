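"""Read-level artifact metrics for total-RNA single-cell libraries.

Three artifact classes matter for random-primed total RNA-seq:

* **genomic background** — reads from contaminating genomic DNA. A uniquely
  mapped read is called background when it overlaps neither annotated
  transcript space (exons *and* introns — pre-mRNA is genuine signal in
  total RNA) nor a known R-loop region (reads there may be genuine RNA and
  are excluded from the call rather than counted as background).
* **internal poly-A priming** — oligo(dT) priming of genomic poly-A tracks;
  flagged when the genomic window 3' of a read contains a long A run
  (T run on the minus strand).
* **strand invasion** — the template-switching oligo anneals to an internal
  complementary site, so the read's 5' end abuts genomic sequence matching
  the TSO tail.

Alignments are carried as a plain DataFrame (:data:`ALIGNMENT_COLUMNS`),
loadable from a tagged SAM/BAM via :func:`load_alignments`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .intervals import IntervalSet
from .seqio import revcomp

#: canonical in-memory alignment table: 0-based half-open coordinates,
#: ``unique`` marks uniquely-mapping reads, ``feature`` an optional gene id.
ALIGNMENT_COLUMNS = ["cell", "chrom", "start", "end", "strand", "umi",
                     "unique", "feature"]

BACKGROUND_LABELS = ("transcript", "te_intergenic", "unannotated",
                     "rloop_excluded")


@dataclass
class AlignmentRecord:
    """Minimal strand-aware alignment with cell/UMI tags."""

    cell: str
    chrom: str
    start: int
    end: int
    strand: str
    umi: str = ""
    unique: bool = True
    feature: str | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"start >= end ({self.start} >= {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


def load_alignments(path: str | Path, cell_tag: str = "CB",
                    umi_tag: str = "UB") -> pd.DataFrame:
    """Read a tagged SAM/BAM into the alignment table.

    Unmapped and secondary records are skipped; uniqueness is taken from the
    NH tag when present (NH == 1), else MAPQ >= 30.
    """
    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            nh = rec.get_tag("NH") if rec.has_tag("NH") else None
            rows.append((
                rec.get_tag(cell_tag) if rec.has_tag(cell_tag) else "",
                rec.reference_name,
                rec.reference_start,
                rec.reference_end,
                "-" if rec.is_reverse else "+",
                rec.get_tag(umi_tag) if rec.has_tag(umi_tag) else "",
                (nh == 1) if nh is not None else rec.mapping_quality >= 30,
                rec.get_tag("XG") if rec.has_tag("XG") else None,
            ))
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


def as_alignment_frame(records) -> pd.DataFrame:
    """Coerce a DataFrame or iterable of AlignmentRecord into the table."""
    if isinstance(records, pd.DataFrame):
        missing = set(ALIGNMENT_COLUMNS) - set(records.columns)
        if missing:
            raise ValueError(f"alignment frame missing columns {sorted(missing)}")
        return records
    return pd.DataFrame(
        [(r.cell, r.chrom, r.start, r.end, r.strand, r.umi, r.unique,
          r.feature) for r in records],
        columns=ALIGNMENT_COLUMNS,
    )


@dataclass
class BackgroundReport:
    """Per-read background labels and per-cell background fractions."""

    labels: pd.Series           # aligned to the input frame's index
    per_cell: pd.DataFrame      # cell, unique_reads, background_reads, fraction

    @property
    def background_fraction(self) -> float:
        """Pooled background fraction over all unique reads."""
        total = self.per_cell["unique_reads"].sum()
        return float(self.per_cell["background_reads"].sum() / total)


def classify_background(alignments, transcripts: IntervalSet,
                        te: IntervalSet,
                        rloops: IntervalSet | None = None) -> BackgroundReport:
    """Partition uniquely-mapping reads into background classes.

    Order of precedence per read: transcript overlap -> ``transcript``;
    else R-loop overlap -> ``rloop_excluded`` (not background); else
    background, sub-labelled ``te_intergenic`` when overlapping a TE
    interval and ``unannotated`` otherwise. Per-cell background fraction is
    background reads / unique reads.
    """
    if transcripts is None or len(transcripts) == 0:
        raise ValueError("cannot classify background with an empty "
                         "transcript annotation set")
    frame = as_alignment_frame(alignments)
    frame = frame[frame["unique"]]
    rloops = rloops if rloops is not None else IntervalSet()

    labels = []
    for row in frame.itertuples():
        if transcripts.overlaps(row.chrom, row.start, row.end):
            labels.append("transcript")
        elif rloops.overlaps(row.chrom, row.start, row.end):
            labels.append("rloop_excluded")
        elif te.overlaps(row.chrom, row.start, row.end):
            labels.append("te_intergenic")
        else:
            labels.append("unannotated")
    labels = pd.Series(labels, index=frame.index, name="label")

    is_bg = labels.isin(["te_intergenic", "unannotated"])
    per_cell = (
        pd.DataFrame({"cell": frame["cell"], "background": is_bg})
        .groupby("cell")
        .agg(unique_reads=("background", "size"),
             background_reads=("background", "sum"))
        .reset_index()
    )
    per_cell["fraction"] = (per_cell["background_reads"]
                            / per_cell["unique_reads"])
    return BackgroundReport(labels, per_cell)


def _longest_base_run(window: str, base: str, max_mismatch: int) -> int:
    """Longest stretch containing <= max_mismatch non-``base`` characters."""
    best = left = mismatches = 0
    for right, ch in enumerate(window):
        if ch != base:
            mismatches += 1
        while mismatches > max_mismatch:
            if window[left] != base:
                mismatches -= 1
            left += 1
        best = max(best, right - left + 1)
    return best


def polya_flank(record: AlignmentRecord, genome: dict[str, str],
                window: int = 20, min_run: int = 10,
                max_mismatch: int = 1) -> bool:
    """Is the genomic window 3' of the read an (interrupted) poly-A run?

    Strand-aware: for a plus-strand read the window is downstream of
    ``end`` and scanned for A; for a minus-strand read it is upstream of
    ``start`` in reference coordinates and scanned for T. Windows are
    truncated at chromosome boundaries.
    """
    if record.chrom not in genome:
        raise KeyError(f"chromosome {record.chrom!r} absent from genome")
    seq = genome[record.chrom]
    if record.strand == "+":
        flank = seq[record.end:record.end + window]
        base = "A"
    else:
        flank = seq[max(0, record.start - window):record.start]
        base = "T"
    run = _longest_base_run(flank.upper(), base, max_mismatch)
    # an interrupted run must still contain >= min_run matching bases
    return run >= min_run and flank.upper().count(base) >= min_run - max_mismatch


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass
class StrandInvasionReport:
    flags: pd.Series
    per_cell: pd.DataFrame

    @property
    def invasion_fraction(self) -> float:
        total = self.per_cell["considered_reads"].sum()
        return float(self.per_cell["invasion_reads"].sum() / total)


def strand_invasion(alignments, genome: dict[str, str], tso_tail: str,
                    k: int = 7, max_mismatch: int = 1) -> StrandInvasionReport:
    """Flag reads whose genomic 5' flank matches the TSO tail.

    A read is flagged when the genomic k-mer immediately upstream
    (strand-aware) of its 5' end matches the last ``k`` bases of
    ``tso_tail`` with at most ``max_mismatch`` mismatches — the signature
    left when the TSO invades an internal complementary site. Only
    UMI-bearing 5' (R1) alignments should be passed in; the per-cell
    fraction is over the reads considered.
    """
    if k > len(tso_tail):
        raise ValueError(f"k={k} exceeds TSO tail length {len(tso_tail)}")
    tail = tso_tail[-k:].upper()
    tail_rc = revcomp(tail)
    frame = as_alignment_frame(alignments)

    flags = []
    for row in frame.itertuples():
        seq = genome.get(row.chrom)
        if seq is None:
            raise KeyError(f"chromosome {row.chrom!r} absent from genome")
        if row.strand == "+":
            upstream = seq[max(0, row.start - k):row.start].upper()
            hit = len(upstream) == k and _hamming(upstream, tail) <= max_mismatch
        else:
            upstream = seq[row.end:row.end + k].upper()
            hit = len(upstream) == k and _hamming(upstream, tail_rc) <= max_mismatch
        flags.append(hit)
    flags = pd.Series(flags, index=frame.index, name="strand_invasion")

    per_cell = (
        pd.DataFrame({"cell": frame["cell"], "flag": flags})
        .groupby("cell")
        .agg(considered_reads=("flag", "size"), invasion_reads=("flag", "sum"))
        .reset_index()
    )
    per_cell["fraction"] = (per_cell["invasion_reads"]
                            / per_cell["considered_reads"])
    return StrandInvasionReport(flags, per_cell)
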