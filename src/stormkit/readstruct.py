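"""Declarative read-structure parsing and synthetic cell-barcode injection.

STORM-seq-style paired-end libraries carry the UMI (and optionally a fixed
linker) at the start of one mate, with cDNA filling the remainder; the other
mate is pure cDNA. Plate-based protocols have no cell barcode in the read
itself — each well is its own FASTQ pair — so aligners that expect droplet
style barcodes (e.g. STARsolo) need a synthetic barcode prepended to every
read. :func:`inject_barcodes` does exactly that, reversibly, and
:func:`collate_cells` merges the per-well files into one pair plus a
whitelist.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .seqio import FastqRecord, FastqWriter, read_fastq

ALPHABET = "ACGT"

#: IUPAC codes used in UMI patterns. N = any base, W = A/T (weak).
PATTERN_BASES = {"N": "ACGT", "W": "AT", "S": "CG", "A": "A", "C": "C",
                 "G": "G", "T": "T"}


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class ReadStructure:
    """Layout of UMI / linker / cDNA within a read pair.

    Parameters
    ----------
    umi_length : length of the UMI in bp (>= 1).
    linker : fixed sequence between UMI and cDNA ("" for none).
    umi_read : which mate carries the UMI ("R1" or "R2").
    barcode_length : length of a synthetic cell barcode preceding the UMI
        (0 before injection; set to the barcode length to parse injected
        files).
    umi_pattern : optional IUPAC pattern (e.g. "NNNNNNNNWW") describing
        per-position composition constraints; overrides ``umi_length``.
    max_linker_mismatch : mismatches tolerated when matching the linker.
    """

    umi_length: int = 8
    linker: str = ""
    umi_read: str = "R1"
    barcode_length: int = 0
    umi_pattern: str | None = None
    max_linker_mismatch: int = 1

    def __post_init__(self):
        if self.umi_pattern is not None:
            object.__setattr__(self, "umi_length", len(self.umi_pattern))
            bad = set(self.umi_pattern) - set(PATTERN_BASES)
            if bad:
                raise ValueError(f"unknown UMI pattern codes: {sorted(bad)}")
        if self.umi_length < 1:
            raise ValueError("umi_length must be >= 1")
        if self.umi_read not in ("R1", "R2"):
            raise ValueError("umi_read must be 'R1' or 'R2'")
        if self.barcode_length < 0:
            raise ValueError("barcode_length must be >= 0")

    @property
    def prefix_length(self) -> int:
        """Bases before cDNA on the UMI-bearing mate."""
        return self.barcode_length + self.umi_length + len(self.linker)

    @property
    def w_positions(self) -> tuple[int, ...]:
        if self.umi_pattern is None:
            return ()
        return tuple(i for i, c in enumerate(self.umi_pattern) if c == "W")

    def with_barcode(self, barcode_length: int) -> "ReadStructure":
        return ReadStructure(
            umi_length=self.umi_length, linker=self.linker,
            umi_read=self.umi_read, barcode_length=barcode_length,
            umi_pattern=self.umi_pattern,
            max_linker_mismatch=self.max_linker_mismatch,
        )

    def umi_base_weights(self) -> np.ndarray:
        """(L, 4) per-position base probabilities implied by the pattern."""
        out = np.zeros((self.umi_length, 4))
        pattern = self.umi_pattern or "N" * self.umi_length
        for i, code in enumerate(pattern):
            allowed = PATTERN_BASES[code]
            for b in allowed:
                out[i, ALPHABET.index(b)] = 1.0 / len(allowed)
        return out


#: Named presets for the library structures handled by the toolkit. The
#: linker/TSO bases vary by kit lot and are therefore configuration, not
#: constants.
PRESETS: dict[str, ReadStructure] = {
    "storm": ReadStructure(umi_length=8),
    "vasa-like-6bp": ReadStructure(umi_length=6),
    "sstotal-like-16bp": ReadStructure(umi_length=16),
    "ss3x-like-8bp-ww": ReadStructure(umi_pattern="NNNNNNNNWW"),
}


@dataclass
class ParsedRead:
    """Result of applying a :class:`ReadStructure` to one read pair."""

    read_id: str
    umi: str
    barcode: str
    cdna1_seq: str
    cdna1_qual: str
    cdna2_seq: str
    cdna2_qual: str
    passed: bool
    fail_reason: str | None = None


def _core_name(name: str) -> str:
    base = name.split()[0]
    if base.endswith(("/1", "/2")):
        base = base[:-2]
    return base


def parse_read_pair(r1: FastqRecord, r2: FastqRecord,
                    structure: ReadStructure) -> ParsedRead:
    """Extract barcode/UMI/cDNA from a mate pair.

    Linker mismatches beyond ``structure.max_linker_mismatch`` and reads too
    short to contain the declared prefix are fail-flagged (never silently
    dropped); a mate-id mismatch is a hard error because it indicates
    desynchronised input files.
    """
    if _core_name(r1.name) != _core_name(r2.name):
        raise ValueError(
            f"mate id mismatch: {r1.name!r} vs {r2.name!r}"
        )
    umi_rec, cdna_rec = (r1, r2) if structure.umi_read == "R1" else (r2, r1)

    def result(umi="", bc="", passed=False, reason=None, c1=("", ""), c2=None):
        c2 = (cdna_rec.sequence, cdna_rec.quality) if c2 is None else c2
        a, b = (c1, c2) if structure.umi_read == "R1" else (c2, c1)
        return ParsedRead(_core_name(r1.name), umi, bc, a[0], a[1], b[0], b[1],
                          passed, reason)

    if len(umi_rec.sequence) <= structure.prefix_length:
        return result(reason="too_short")

    seq, qual = umi_rec.sequence, umi_rec.quality
    off = structure.barcode_length
    barcode = seq[:off]
    umi = seq[off:off + structure.umi_length]
    off += structure.umi_length
    if structure.linker:
        seen = seq[off:off + len(structure.linker)]
        if hamming(seen, structure.linker) > structure.max_linker_mismatch:
            return result(umi=umi, bc=barcode, reason="linker_mismatch")
        off += len(structure.linker)
    return result(umi=umi, bc=barcode, passed=True,
                  c1=(seq[off:], qual[off:]))


# ---------------------------------------------------------------------------
# synthetic cell barcodes
# ---------------------------------------------------------------------------

@dataclass
class BarcodeAssignment:
    """Well/file -> synthetic cell barcode mapping.

    Barcodes must be unique, equal length, over {A,C,G,T}, and pairwise
    Hamming distance >= ``min_distance`` so that single sequencing errors
    cannot convert one cell into another.
    """

    barcodes: dict[str, str]
    min_distance: int = 2
    length: int = field(init=False)

    def __post_init__(self):
        if not self.barcodes:
            raise ValueError("empty barcode assignment")
        values = list(self.barcodes.values())
        lengths = {len(b) for b in values}
        if len(lengths) != 1:
            raise ValueError(f"barcodes have mixed lengths: {sorted(lengths)}")
        self.length = lengths.pop()
        if len(set(values)) != len(values):
            raise ValueError("duplicate barcode in assignment")
        bad = [b for b in values if set(b) - set(ALPHABET)]
        if bad:
            raise ValueError(f"barcodes outside ACGT alphabet: {bad}")
        for a, b in itertools.combinations(values, 2):
            if hamming(a, b) < self.min_distance:
                raise ValueError(
                    f"barcodes {a} and {b} are within Hamming distance "
                    f"{self.min_distance}"
                )

    @classmethod
    def generate(cls, wells: Sequence[str], length: int = 8,
                 min_distance: int = 2, seed: int = 0) -> "BarcodeAssignment":
        """Draw random well barcodes satisfying the distance constraint."""
        rng = np.random.default_rng(seed)
        chosen: list[str] = []
        attempts = 0
        while len(chosen) < len(wells):
            cand = "".join(ALPHABET[i] for i in rng.integers(0, 4, length))
            if all(hamming(cand, c) >= min_distance for c in chosen):
                chosen.append(cand)
            attempts += 1
            if attempts > 10000 * len(wells):
                raise RuntimeError(
                    "could not generate enough barcodes; increase length"
                )
        return cls(dict(zip(wells, chosen)), min_distance=min_distance)

    def write_whitelist(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text("".join(f"{b}\n" for b in self.barcodes.values()))
        return path


def prepend_barcode(fastq_in: str | Path, fastq_out: str | Path,
                    barcode: str, quality_char: str = "I") -> int:
    """Prefix every read with ``barcode`` (and a matching quality run).

    All other bytes are unchanged, so the operation is exactly reversible
    with :func:`strip_barcode`. Returns the number of records written.
    """
    with FastqWriter(fastq_out) as out:
        for rec in read_fastq(fastq_in):
            out.write(FastqRecord(rec.name, barcode + rec.sequence,
                                  quality_char * len(barcode) + rec.quality))
        return out.n_written


def strip_barcode(fastq_in: str | Path, fastq_out: str | Path,
                  barcode_length: int) -> int:
    """Inverse of :func:`prepend_barcode`."""
    with FastqWriter(fastq_out) as out:
        for rec in read_fastq(fastq_in):
            out.write(FastqRecord(rec.name, rec.sequence[barcode_length:],
                                  rec.quality[barcode_length:]))
        return out.n_written


def inject_barcodes(
    pairs: Mapping[str, tuple[str | Path, str | Path]],
    assignment: BarcodeAssignment,
    outdir: str | Path,
    structure: ReadStructure | None = None,
    suffix: str = ".barcoded.fastq",
) -> dict[str, tuple[Path, Path]]:
    """Inject each well's barcode into its UMI-bearing mate.

    ``pairs`` maps well id -> (R1 path, R2 path). The barcode goes onto the
    mate named by ``structure.umi_read`` (default R1); the other mate is
    copied through unchanged. Errors (missing wells, duplicate barcodes) are
    raised before any output is written.
    """
    structure = structure or ReadStructure()
    missing = [w for w in pairs if w not in assignment.barcodes]
    if missing:
        raise KeyError(f"wells missing from barcode assignment: {missing}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: dict[str, tuple[Path, Path]] = {}
    for well, (r1, r2) in pairs.items():
        bc = assignment.barcodes[well]
        o1 = outdir / f"{well}_R1{suffix}"
        o2 = outdir / f"{well}_R2{suffix}"
        if structure.umi_read == "R1":
            prepend_barcode(r1, o1, bc)
            _copy_fastq(r2, o2)
        else:
            _copy_fastq(r1, o1)
            prepend_barcode(r2, o2, bc)
        out[well] = (o1, o2)
    return out


def _copy_fastq(src: str | Path, dst: str | Path) -> int:
    with FastqWriter(dst) as out:
        for rec in read_fastq(src):
            out.write(rec)
        return out.n_written


def collate_cells(
    pairs: Mapping[str, tuple[str | Path, str | Path]],
    assignment: BarcodeAssignment,
    out_r1: str | Path,
    out_r2: str | Path,
    whitelist: str | Path,
    structure: ReadStructure | None = None,
) -> dict[str, int]:
    """Barcode-inject and merge per-well FASTQ pairs into one pair.

    Record order within each well is preserved; wells are concatenated in
    assignment order. Empty wells are legal (their barcode still appears in
    the whitelist with zero reads). Returns per-well read counts.
    """
    import warnings

    structure = structure or ReadStructure()
    absent = [str(p) for pr in pairs.values() for p in pr
              if not Path(p).exists()]
    if absent:
        raise FileNotFoundError(f"missing input FASTQ file(s): {absent}")
    missing = [w for w in pairs if w not in assignment.barcodes]
    if missing:
        raise KeyError(f"wells missing from barcode assignment: {missing}")

    counts: dict[str, int] = {}
    with FastqWriter(out_r1) as w1, FastqWriter(out_r2) as w2:
        for well in assignment.barcodes:
            if well not in pairs:
                continue
            r1, r2 = pairs[well]
            bc = assignment.barcodes[well]
            n = 0
            for rec1, rec2 in zip(read_fastq(r1), read_fastq(r2)):
                if structure.umi_read == "R1":
                    rec1 = FastqRecord(rec1.name, bc + rec1.sequence,
                                       "I" * len(bc) + rec1.quality)
                else:
                    rec2 = FastqRecord(rec2.name, bc + rec2.sequence,
                                       "I" * len(bc) + rec2.quality)
                w1.write(rec1)
                w2.write(rec2)
                n += 1
            if n == 0:
                warnings.warn(f"well {well!r} contributed zero reads")
            counts[well] = n
    assignment.write_whitelist(whitelist)
    return counts
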