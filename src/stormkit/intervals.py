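"""Genomic interval sets with fast overlap queries.

All coordinates are 0-based, half-open (BED-native). GTF output converts on
write. Backed by one :class:`intervaltree.IntervalTree` per chromosome; each
stored interval carries an arbitrary ``data`` payload (typically the row index
or a label such as a TE family).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from intervaltree import IntervalTree

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class IntervalSet:
    """A collection of stranded, labelled genomic intervals."""

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame(columns=BED6_COLUMNS)
        df = df.copy().reset_index(drop=True)
        for col in ("name", "score", "strand"):
            if col not in df.columns:
                df[col] = {"name": ".", "score": 0, "strand": "."}[col]
        if not df.empty:
            bad = df["start"] >= df["end"]
            if bad.any():
                raise ValueError(
                    f"{int(bad.sum())} interval(s) have start >= end"
                )
        self.df = df[BED6_COLUMNS]
        self._trees: dict[str, IntervalTree] = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            self._trees[str(chrom)] = IntervalTree.from_tuples(
                zip(sub["start"], sub["end"], sub.index)
            )

    # -- construction -----------------------------------------------------
    @classmethod
    def from_bed(cls, path: str | Path) -> "IntervalSet":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=BED6_COLUMNS, usecols=range(6),
            dtype={"chrom": str, "start": int, "end": int, "name": str},
        )
        return cls(df)

    @classmethod
    def from_tuples(cls, rows: Iterable[tuple]) -> "IntervalSet":
        """Rows of (chrom, start, end[, name[, score[, strand]]])."""
        recs = []
        for row in rows:
            row = list(row) + [".", 0, "."][len(row) - 3:]
            recs.append(dict(zip(BED6_COLUMNS, row)))
        return cls(pd.DataFrame(recs, columns=BED6_COLUMNS))

    # -- queries ----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __bool__(self) -> bool:
        return len(self) > 0

    def overlapping(self, chrom: str, start: int, end: int) -> list[int]:
        """Row indices of intervals intersecting [start, end) by >= 1 bp."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.overlap(start, end))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps(start, end))

    def best_overlap(self, chrom: str, start: int, end: int) -> int | None:
        """Index of the interval with maximal intersection length.

        Ties broken by lexicographically smallest name, then lowest index
        (deterministic unique assignment).
        """
        hits = self.overlapping(chrom, start, end)
        if not hits:
            return None
        best, best_key = None, None
        for i in hits:
            row = self.df.iloc[i]
            ov = min(end, row["end"]) - max(start, row["start"])
            key = (-ov, str(row["name"]), i)
            if best_key is None or key < best_key:
                best, best_key = i, key
        return best

    def total_bp(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())

    def iter_rows(self) -> Iterator[pd.Series]:
        for _, row in self.df.iterrows():
            yield row

    # -- I/O --------------------------------------------------------------
    def to_bed(self, path: str | Path) -> Path:
        path = Path(path)
        self.df.to_csv(path, sep="\t", header=False, index=False)
        return path
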