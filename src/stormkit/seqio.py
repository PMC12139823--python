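"""Sequence-file I/O helpers.

FASTQ is read with :class:`pysam.FastxFile` (transparent gzip support) and
written by a minimal text writer. Gzipped output is produced with ``mtime=0``
and no embedded filename so that fixed-seed runs are byte-identical — plain
``gzip.open`` stamps the current time into the header, which would break the
determinism guarantees of the synthetic-library generator.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterator

import pysam

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class FastqRecord:
    name: str
    sequence: str
    quality: str

    def __post_init__(self):
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"sequence/quality length mismatch for read {self.name!r}"
            )


def open_text_maybe_gzip(path: str | Path, mode: str = "wt") -> IO:
    """Open for writing; '.gz' suffix selects deterministic gzip."""
    path = Path(path)
    if path.suffix == ".gz":
        raw = open(path, mode.replace("t", "") + "b" if "r" not in mode else "rb")
        return gzip.GzipFile(filename="", mode=mode.replace("t", ""), fileobj=raw, mtime=0)  # type: ignore[return-value]
    return open(path, mode)


class FastqWriter:
    """Write FASTQ records, gzipped deterministically when path ends in .gz."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        if self.path.suffix == ".gz":
            self._raw = open(self.path, "wb")
            self._fh: IO = gzip.GzipFile(
                filename="", mode="wb", fileobj=self._raw, mtime=0
            )
            self._binary = True
        else:
            self._fh = open(self.path, "w")
            self._raw = None
            self._binary = False
        self.n_written = 0

    def write(self, rec: FastqRecord) -> None:
        entry = f"@{rec.name}\n{rec.sequence}\n+\n{rec.quality}\n"
        if self._binary:
            self._fh.write(entry.encode())
        else:
            self._fh.write(entry)
        self.n_written += 1

    def close(self) -> None:
        self._fh.close()
        if self._raw is not None:
            self._raw.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def read_fastq(path: str | Path) -> Iterator[FastqRecord]:
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            name = entry.name
            if entry.comment:
                name = f"{name} {entry.comment}"
            yield FastqRecord(name, entry.sequence, entry.quality or "")


def count_fastq_records(path: str | Path) -> int:
    return sum(1 for _ in read_fastq(path))


def write_fasta(path: str | Path, sequences: dict[str, str], width: int = 80) -> Path:
    path = Path(path)
    with open_text_maybe_gzip(path, "wt") as fh:
        write = (lambda s: fh.write(s.encode())) if path.suffix == ".gz" else fh.write
        for name, seq in sequences.items():
            write(f">{name}\n")
            for i in range(0, len(seq), width):
                write(seq[i:i + width] + "\n")
    return path


def read_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            out[entry.name] = entry.sequence
    return out
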