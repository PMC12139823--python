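"""Per-cell UMI diagnostics: sequence logos, inter-gene collisions, saturation.

A UMI of length L over {A,C,G,T} has N = 4^L possible sequences. When many
molecules per cell share that space, the same UMI can appear on molecules of
*different* genes purely by chance (an inter-gene collision, a birthday
problem), and repeated draws within one gene saturate the space (expected
distinct UMIs after M molecules is N(1 - (1 - 1/N)^M)). Both effects grow as
L shrinks, which is why collision rates fall as UMIs lengthen from 6 bp
through 8 bp to 16 bp.

Collisions are counted at the level of distinct (gene, UMI) pairs after
exact within-gene deduplication — no error-tolerant UMI merging. The
analytic expectation treats genes independently (a standard birthday-type
approximation); the Monte-Carlo framework, which draws per-molecule UMIs and
replays the observed-rate computation, is the reference when exactness
matters and is the only route for non-uniform base compositions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .readstruct import ALPHABET, ReadStructure

_CODE = {b: i for i, b in enumerate(ALPHABET)}


def _encode_umis(umis: Sequence[str]) -> np.ndarray:
    """(n, L) integer base codes; validates a single length and alphabet."""
    lengths = {len(u) for u in umis}
    if len(lengths) != 1:
        raise ValueError(f"mixed UMI lengths: {sorted(lengths)}")
    arr = np.frombuffer("".join(umis).encode(), dtype=np.uint8)
    arr = arr.reshape(len(umis), lengths.pop())
    codes = np.full(arr.shape, -1, dtype=np.int64)
    for base, code in _CODE.items():
        codes[arr == ord(base)] = code
    if (codes < 0).any():
        raise ValueError("UMIs contain characters outside ACGT")
    return codes


class UmiTable:
    """Per-cell gene -> UMI read counts (columns: cell, gene, umi, reads)."""

    def __init__(self, df: pd.DataFrame):
        required = {"cell", "gene", "umi", "reads"}
        if not required <= set(df.columns):
            raise ValueError(f"UmiTable needs columns {sorted(required)}")
        df = df.reset_index(drop=True).copy()
        if (df["reads"] < 1).any():
            raise ValueError("read counts must be >= 1")
        lengths = df["umi"].str.len().unique()
        if len(lengths) > 1:
            raise ValueError(f"mixed UMI lengths: {sorted(lengths)}")
        self.df = df
        self.umi_length = int(lengths[0]) if len(lengths) else 0

    # -- construction -----------------------------------------------------
    @classmethod
    def from_tsv(cls, path: str | Path) -> "UmiTable":
        return cls(pd.read_csv(path, sep="\t"))

    @classmethod
    def from_alignments(cls, frame: pd.DataFrame) -> "UmiTable":
        """Collapse an alignment frame (gene-assigned, UMI-tagged reads)."""
        sub = frame[(frame["feature"].notna()) & (frame["feature"] != "")
                    & (frame["umi"] != "")]
        grouped = (sub.groupby(["cell", "feature", "umi"]).size()
                   .reset_index(name="reads")
                   .rename(columns={"feature": "gene"}))
        return cls(grouped)

    @classmethod
    def from_truth_reads(cls, reads: pd.DataFrame) -> "UmiTable":
        """From a generator truth table, non-artifact transcript reads only."""
        sub = reads[reads["artifact_class"] == "none"]
        return cls.from_alignments(sub)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.df.to_csv(path, sep="\t", index=False)
        return path

    # -- helpers ----------------------------------------------------------
    @property
    def cells(self) -> list[str]:
        return sorted(self.df["cell"].unique())

    def for_cell(self, cell: str) -> pd.DataFrame:
        if cell not in set(self.df["cell"]):
            raise KeyError(f"unknown cell id {cell!r}")
        return self.df[self.df["cell"] == cell]


# ---------------------------------------------------------------------------
# sequence logos
# ---------------------------------------------------------------------------

LOGO_MODES = ("diversity", "prevalence", "top_per_cell")


@dataclass
class LogoMatrix:
    """L x 4 base-frequency matrix with per-position information content."""

    frequencies: pd.DataFrame      # index 0..L-1, columns A,C,G,T
    mode: str
    information_bits: np.ndarray   # per position, in [0, 2]
    n_sequences: int

    def plot(self, ax=None):
        """Stacked-bar logo rendering (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(0.6 * len(self.frequencies), 2.4))
        heights = self.frequencies.to_numpy() * self.information_bits[:, None]
        bottom = np.zeros(len(self.frequencies))
        colors = {"A": "#109648", "C": "#255C99", "G": "#F7B32B",
                  "T": "#D62839"}
        for base in ALPHABET:
            h = heights[:, ALPHABET.index(base)]
            ax.bar(self.frequencies.index, h, bottom=bottom,
                   color=colors[base], label=base)
            bottom += h
        ax.set_ylim(0, 2)
        ax.set_ylabel("bits")
        ax.set_xlabel("UMI position")
        ax.legend(ncol=4, fontsize=8)
        return ax


def _logo_from_weighted(umis: Sequence[str], weights: np.ndarray,
                        mode: str) -> LogoMatrix:
    codes = _encode_umis(umis)
    L = codes.shape[1]
    freq = np.zeros((L, 4))
    for pos in range(L):
        freq[pos] = np.bincount(codes[:, pos], weights=weights, minlength=4)
    freq /= freq.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    table = pd.DataFrame(freq, columns=list(ALPHABET))
    return LogoMatrix(table, mode, ic, len(umis))


def umi_logo(table: UmiTable, mode: str = "diversity",
             cell: str | None = None) -> LogoMatrix:
    """Base-frequency logo over the table (optionally one cell).

    Modes: ``diversity`` — each distinct UMI per cell counted once;
    ``prevalence`` — UMIs weighted by read count; ``top_per_cell`` — the
    single most-read UMI per cell (ties broken lexicographically).
    """
    if mode not in LOGO_MODES:
        raise ValueError(f"mode must be one of {LOGO_MODES}")
    df = table.for_cell(cell) if cell is not None else table.df
    if df.empty:
        raise ValueError("no UMIs in scope")

    if mode == "diversity":
        distinct = df.drop_duplicates(["cell", "umi"])
        return _logo_from_weighted(list(distinct["umi"]),
                                   np.ones(len(distinct)), mode)
    if mode == "prevalence":
        per = df.groupby(["cell", "umi"], as_index=False)["reads"].sum()
        return _logo_from_weighted(list(per["umi"]),
                                   per["reads"].to_numpy(float), mode)
    # top_per_cell: highest read count per cell, lexicographic tie-break
    per = df.groupby(["cell", "umi"], as_index=False)["reads"].sum()
    per = per.sort_values(["cell", "reads", "umi"],
                          ascending=[True, False, True])
    top = per.drop_duplicates("cell", keep="first")
    return _logo_from_weighted(list(top["umi"]), np.ones(len(top)), mode)


def random_umis(n: int, structure_or_length: ReadStructure | int,
                seed: int = 0) -> list[str]:
    """Draw UMIs from a structure's per-position composition (or uniform)."""
    if isinstance(structure_or_length, ReadStructure):
        weights = structure_or_length.umi_base_weights()
    else:
        weights = np.full((int(structure_or_length), 4), 0.25)
    rng = np.random.default_rng(seed)
    L = weights.shape[0]
    cols = [rng.choice(4, size=n, p=weights[pos]) for pos in range(L)]
    codes = np.stack(cols, axis=1)
    lut = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
    return [lut[row].tobytes().decode() for row in codes]


# ---------------------------------------------------------------------------
# inter-gene collisions
# ---------------------------------------------------------------------------

def observed_collision_rate(table: UmiTable, cell: str) -> float:
    """Fraction of distinct (gene, UMI) pairs whose UMI recurs in >= 1
    other gene of the same cell. Defined as 0 with fewer than two genes."""
    df = table.for_cell(cell)
    pairs = df.drop_duplicates(["gene", "umi"])
    if pairs["gene"].nunique() < 2:
        return 0.0
    genes_per_umi = pairs.groupby("umi")["gene"].nunique()
    colliding = pairs["umi"].map(genes_per_umi) >= 2
    return float(colliding.sum() / len(pairs))


@dataclass
class CollisionEstimate:
    """An expected inter-gene collision rate with its uncertainty."""

    rate: float
    method: str
    umi_length: int
    reps: int
    seed: int | None
    ci_low: float
    ci_high: float
    se: float

    def __post_init__(self):
        if not (self.ci_low - 1e-12 <= self.rate <= self.ci_high + 1e-12):
            raise ValueError("confidence interval does not contain the rate")


def analytic_collision_rate(L: int, per_gene_counts: Sequence[int]) -> float:
    """Closed-form expected rate for uniform UMIs.

    A (gene g, UMI) pair collides with probability
    1 - prod_{h != g} (1 - q)^{m_h}, q = 4^-L (each of the m_h molecules of
    another gene independently misses the UMI with probability 1 - q);
    the rate averages this over all pairs, weighting gene g by m_g.
    """
    m = np.asarray(per_gene_counts, dtype=float)
    if (m < 1).any():
        raise ValueError("per-gene molecule counts must be >= 1")
    q = 4.0 ** -L
    M = m.sum()
    p_collide = 1.0 - (1.0 - q) ** (M - m)
    return float((m * p_collide).sum() / M)


def _draw_umi_codes(rng: np.random.Generator, shape: tuple[int, ...], L: int,
                    umi_weights: Mapping[str, float] | None) -> np.ndarray:
    space = 4 ** L
    if umi_weights is None:
        return rng.integers(0, space, size=shape, dtype=np.int64)
    p = np.array([umi_weights.get(b, 0.0) for b in ALPHABET], dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("umi_weights must sum to 1")
    digits = rng.choice(4, size=shape + (L,), p=p)
    powers = 4 ** np.arange(L, dtype=np.int64)
    return (digits * powers).sum(axis=-1)


def monte_carlo_collision_rate(
    L: int, per_gene_counts: Sequence[int], reps: int, seed: int = 0,
    umi_weights: Mapping[str, float] | None = None,
) -> tuple[float, float, np.ndarray]:
    """Simulate molecule UMIs and replay the observed-rate computation.

    Per replicate, every gene's molecules draw i.i.d. UMIs from the base
    distribution; within-gene duplicates collapse to distinct (gene, UMI)
    pairs, and the observed rate is computed exactly as
    :func:`observed_collision_rate` defines it. Returns (mean, SE,
    per-replicate rates). Fully vectorised over replicates.
    """
    m = np.asarray(per_gene_counts, dtype=np.int64)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if (m < 1).any():
        raise ValueError("per-gene molecule counts must be >= 1")
    rng = np.random.default_rng(seed)
    G, M = len(m), int(m.sum())
    space = 4 ** L

    umis = _draw_umi_codes(rng, (reps, M), L, umi_weights)
    gene_of = np.repeat(np.arange(G, dtype=np.int64), m)
    rep_of = np.repeat(np.arange(reps, dtype=np.int64), M)

    # distinct (rep, gene, umi) triples
    code = (rep_of * G + np.tile(gene_of, reps)) * space + umis.ravel()
    pairs = np.unique(code)
    pair_rep = pairs // (G * space)
    pair_umi = pairs % space

    # collision: same (rep, umi) in >= 2 genes
    ru = pair_rep * space + pair_umi
    _, inverse, counts = np.unique(ru, return_inverse=True,
                                   return_counts=True)
    colliding = counts[inverse] >= 2

    n_pairs = np.bincount(pair_rep, minlength=reps)
    n_collide = np.bincount(pair_rep, weights=colliding.astype(float),
                            minlength=reps)
    rates = n_collide / n_pairs
    mean = float(rates.mean())
    se = float(rates.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
    return mean, se, rates


def expected_collision_rate(
    L: int, per_gene_counts: Sequence[int], method: str = "analytic",
    reps: int = 1000, seed: int | None = 0,
    umi_weights: Mapping[str, float] | None = None,
) -> CollisionEstimate:
    """Expected inter-gene collision rate for UMI length ``L``.

    ``method='analytic'`` uses the closed form (uniform base composition
    only); ``method='monte_carlo'`` simulates ``reps`` replicates and
    reports a normal-approximation 95% CI. Non-uniform ``umi_weights``
    require the Monte-Carlo route.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    uniform = umi_weights is None or np.allclose(
        [umi_weights.get(b, 0.0) for b in ALPHABET], 0.25)
    if method == "analytic":
        if not uniform:
            raise ValueError(
                "analytic method supports uniform UMIs only; use "
                "method='monte_carlo' for non-uniform base weights"
            )
        rate = analytic_collision_rate(L, per_gene_counts)
        return CollisionEstimate(rate, "analytic", L, 0, None, rate, rate,
                                 0.0)
    if method != "monte_carlo":
        raise ValueError("method must be 'analytic' or 'monte_carlo'")
    mean, se, _ = monte_carlo_collision_rate(L, per_gene_counts, reps,
                                             seed or 0, umi_weights)
    return CollisionEstimate(mean, "monte_carlo", L, reps, seed,
                             mean - 1.96 * se, mean + 1.96 * se, se)


# ---------------------------------------------------------------------------
# saturation
# ---------------------------------------------------------------------------

def expected_distinct_umis(N: int, M: int) -> float:
    """E[# distinct UMIs] after M uniform draws from N sequences."""
    return N * (1.0 - (1.0 - 1.0 / N) ** M)


def umi_saturation(table: UmiTable, cell: str) -> tuple[pd.DataFrame, float]:
    """Observed vs expected distinct UMIs per gene for one cell.

    For each gene with M total reads: expected distinct = N(1-(1-1/N)^M)
    with N = 4^L, saturation = observed distinct / N, and the
    observed/expected ratio. Returns (per-gene table, cell median ratio).
    Low saturation with a depressed ratio is the signature of biased UMI
    usage that inflates inter-gene collisions.
    """
    df = table.for_cell(cell)
    N = 4 ** table.umi_length
    per_gene = df.groupby("gene").agg(
        total_reads=("reads", "sum"),
        observed_distinct=("umi", "nunique"),
    ).reset_index()
    per_gene["expected_distinct"] = [
        expected_distinct_umis(N, int(mr)) for mr in per_gene["total_reads"]
    ]
    per_gene["saturation"] = per_gene["observed_distinct"] / N
    per_gene["obs_exp_ratio"] = (per_gene["observed_distinct"]
                                 / per_gene["expected_distinct"])
    median = float(per_gene["obs_exp_ratio"].median())
    return per_gene, median
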