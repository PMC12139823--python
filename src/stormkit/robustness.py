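"""Subsampling robustness simulation and FFPM-weighted fusion detection.

Simulating many "experiments" by repeatedly subsampling one cell's reads to
a fixed depth separates what a protocol detects from how much it was
sequenced: detection rates by transcript length, the coefficient of
variation of abundance estimates across replicates, and genes-per-cell
saturation curves all come from the same primitive. Subsampling is without
replacement at read level (multivariate hypergeometric over features),
matching what read-level downsampling of a BAM does; binomial thinning is
available as an option.

Fusion support is normalised as FFPM (fusion fragments per million) and
single-cell fusion detection proportions are weighted by the relative bulk
FFPM of the single-cell protocol's library strategy versus a reference
strategy, so polyA-based and total-RNA protocols become comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class SubsampleResult:
    """Replicate x feature count matrix from repeated downsampling."""

    counts: pd.DataFrame          # rows: replicate, columns: features
    target_depth: int
    achieved_depth: np.ndarray    # per replicate
    seed: int
    truncated: bool               # depth exceeded the available total

    @property
    def n_reps(self) -> int:
        return len(self.counts)


def subsample(counts: pd.Series, depth: int, reps: int,
              seed: int = 0, method: str = "hypergeometric",
              ) -> SubsampleResult:
    """Repeatedly draw ``depth`` reads without replacement from one cell.

    Each replicate is an independent multivariate-hypergeometric draw over
    the per-feature read counts (``method='binomial'`` thins each feature
    independently at rate depth/total instead). If ``depth`` exceeds the
    available total, every replicate is the full count vector and the
    result is flagged truncated.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    vec = counts.to_numpy(dtype=np.int64)
    total = int(vec.sum())
    rng = np.random.default_rng(seed)

    truncated = depth > total
    if truncated:
        import warnings

        warnings.warn(
            f"requested depth {depth} exceeds available {total} reads; "
            "returning the full count vector for every replicate"
        )
        mat = np.tile(vec, (reps, 1))
    elif method == "hypergeometric":
        mat = np.stack([
            rng.multivariate_hypergeometric(vec, depth) for _ in range(reps)
        ])
    elif method == "binomial":
        rate = depth / total if total else 0.0
        mat = rng.binomial(vec[None, :], rate, size=(reps, len(vec)))
    else:
        raise ValueError("method must be 'hypergeometric' or 'binomial'")

    frame = pd.DataFrame(mat, columns=counts.index)
    return SubsampleResult(frame, depth, mat.sum(axis=1), seed, truncated)


def detection_by_length(result: SubsampleResult, lengths: pd.Series,
                        bins: Sequence[float],
                        min_count: int = 1) -> pd.DataFrame:
    """Per length-bin detection rates, per replicate and summarised.

    A feature is detected in a replicate when its count >= ``min_count``;
    the rate is detected / features-in-bin. Bins with no features are
    reported with NaN rates (undefined, not zero).
    """
    missing = result.counts.columns.difference(lengths.index)
    if len(missing):
        raise ValueError(f"features without a length: {list(missing)[:5]}")
    lengths = lengths.reindex(result.counts.columns)
    bin_of = pd.cut(lengths, bins=list(bins), include_lowest=True)

    rows = []
    for interval in bin_of.cat.categories:
        feats = bin_of.index[bin_of == interval]
        for rep in range(result.n_reps):
            if len(feats) == 0:
                rows.append((str(interval), rep, np.nan, 0))
                continue
            detected = (result.counts.loc[rep, feats] >= min_count).sum()
            rows.append((str(interval), rep, detected / len(feats),
                         len(feats)))
    out = pd.DataFrame(rows, columns=["length_bin", "replicate",
                                      "detection_rate", "n_features"])
    return out


def summarize_detection(per_rep: pd.DataFrame) -> pd.DataFrame:
    return (per_rep.groupby("length_bin", sort=False)
            .agg(mean_rate=("detection_rate", "mean"),
                 var_rate=("detection_rate", "var"),
                 n_features=("n_features", "first"))
            .reset_index())


def abundance_cv(result: SubsampleResult) -> pd.Series:
    """Coefficient of variation (sd/mean) per feature across replicates.

    CV is scale-free, so robustness can be compared across expression
    levels and transcript-length bins. Features with zero mean are NaN
    (missing, not infinitely variable).
    """
    if result.n_reps < 2:
        raise ValueError("abundance CV needs >= 2 replicates")
    mean = result.counts.mean(axis=0)
    sd = result.counts.std(axis=0, ddof=1)
    cv = sd / mean
    cv[mean == 0] = np.nan
    return cv.rename("cv")


def gene_detection_curve(cells: pd.DataFrame, depths: Sequence[int],
                         reps: int = 10, seed: int = 0,
                         min_count: int = 1) -> pd.DataFrame:
    """Median (and IQR) genes detected per cell along a depth ladder.

    ``cells`` is a feature x cell count matrix. At each depth every cell is
    subsampled ``reps`` times; a gene counts as detected at >= ``min_count``
    reads. Cells with fewer total reads than the target depth contribute
    their full vector (flagged by :func:`subsample`).
    """
    depths = list(depths)
    if depths != sorted(depths):
        raise ValueError("depth ladder must be sorted ascending")
    import warnings

    rows = []
    for di, depth in enumerate(depths):
        per_cell = []
        for ci, cell in enumerate(cells.columns):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = subsample(cells[cell], depth, reps,
                                seed=seed + 1009 * di + ci)
            per_cell.extend((res.counts >= min_count).sum(axis=1).tolist())
        arr = np.array(per_cell)
        rows.append((depth, float(np.median(arr)),
                     float(np.percentile(arr, 25)),
                     float(np.percentile(arr, 75))))
    return pd.DataFrame(rows, columns=["depth", "median_genes",
                                       "q25_genes", "q75_genes"])


# ---------------------------------------------------------------------------
# fusion support
# ---------------------------------------------------------------------------

def ffpm(fusion_fragments: float, total_fragments: float) -> float:
    """Fusion fragments per million sequenced fragments."""
    if total_fragments <= 0:
        raise ValueError("total fragment count must be > 0")
    if fusion_fragments < 0:
        raise ValueError("fusion fragment count must be >= 0")
    return fusion_fragments / total_fragments * 1e6


@dataclass
class FusionSupport:
    fusion: str
    raw_proportion: float
    relative_support: float
    weighted_proportion: float
    weightable: bool


def weighted_fusion_detection(sc_detection: pd.Series,
                              bulk_ffpm: pd.DataFrame,
                              sc_strategy: str,
                              reference_strategy: str,
                              ) -> pd.DataFrame:
    """Weight single-cell fusion detection by relative bulk read support.

    For each fusion f, s_f = FFPM(sc protocol's library strategy) /
    FFPM(reference strategy) measures how much easier the fusion is to see
    under the single-cell protocol's chemistry; the detection proportion is
    divided by s_f and capped at 1. Fusions with s_f = 0 (or missing
    reference support) are flagged unweightable rather than silently
    dropped.
    """
    for col in (sc_strategy, reference_strategy):
        if col not in bulk_ffpm.columns:
            raise KeyError(f"bulk FFPM table lacks strategy column {col!r}")
    missing = sc_detection.index.difference(bulk_ffpm.index)
    if len(missing):
        raise KeyError(f"fusions without bulk FFPM: {list(missing)}")
    if (bulk_ffpm[[sc_strategy, reference_strategy]] < 0).any().any():
        raise ValueError("FFPM values must be >= 0")

    rows = []
    for fusion, raw in sc_detection.items():
        num = float(bulk_ffpm.loc[fusion, sc_strategy])
        den = float(bulk_ffpm.loc[fusion, reference_strategy])
        if den <= 0:
            raise ValueError(
                f"reference FFPM must be > 0 (fusion {fusion})"
            )
        s = num / den
        if s > 0:
            rows.append((fusion, float(raw), s, min(1.0, float(raw) / s),
                         True))
        else:
            rows.append((fusion, float(raw), s, np.nan, False))
    return pd.DataFrame(rows, columns=[
        "fusion", "raw_proportion", "relative_support",
        "weighted_proportion", "weightable"])
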