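"""ERCC-style spike-in copy-number expectations, fits, and sensitivity.

Spike-in transcripts added at known concentrations calibrate two things:
whether observed molecule counts scale linearly with input copy number
(:func:`fit_copy_number`), and how often a transcript present at >= 1 copy
per cell is actually seen (:func:`single_molecule_sensitivity`). Expected
copies follow directly from the mix chemistry::

    copies = conc[amol/uL] * 1e-18 mol * N_A * dilution * volume[uL]

with Avogadro's number N_A = 6.02214076e23.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

AVOGADRO = 6.02214076e23
ATTO = 1e-18


@dataclass
class SpikeInDesign:
    """A spike-in mix: per-species length and stock concentration.

    ``species`` is a DataFrame with columns ``id`` (unique), ``length_bp``
    and ``amol_per_uL``. The added ``volume_uL`` is a required field with no
    default: expected copies are meaningless without it and a silently wrong
    default would corrupt every downstream sensitivity number.
    """

    species: pd.DataFrame
    dilution: float
    volume_uL: float

    def __post_init__(self):
        df = self.species.reset_index(drop=True).copy()
        required = {"id", "length_bp", "amol_per_uL"}
        if not required <= set(df.columns):
            raise ValueError(f"design table needs columns {sorted(required)}")
        if df["id"].duplicated().any():
            raise ValueError("duplicate spike-in species ids")
        if (df["amol_per_uL"] <= 0).any():
            raise ValueError("concentrations must be > 0")
        if (df["length_bp"] < 1).any():
            raise ValueError("species lengths must be >= 1 bp")
        if not (0 < self.dilution <= 1):
            raise ValueError("dilution must be in (0, 1]")
        if self.volume_uL <= 0:
            raise ValueError("volume must be > 0")
        self.species = df

    @classmethod
    def from_tsv(cls, path: str | Path, dilution: float,
                 volume_uL: float) -> "SpikeInDesign":
        return cls(pd.read_csv(path, sep="\t"), dilution, volume_uL)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.species.to_csv(path, sep="\t", index=False)
        return path

    def expected_copies(self) -> pd.Series:
        """Expected molecules per cell for every species."""
        copies = (self.species["amol_per_uL"] * ATTO * AVOGADRO
                  * self.dilution * self.volume_uL)
        return pd.Series(copies.to_numpy(), index=self.species["id"],
                         name="expected_copies")


def synthetic_mix(n_species: int = 20, seed: int = 0,
                  top_amol_per_uL: float = 30.0,
                  fold_step: float = 2.0) -> pd.DataFrame:
    """A synthetic spike-in mix spanning a geometric concentration ladder.

    Mimics the design of commercial mixes (species across ~6 logs of
    concentration, lengths 250-2000 bp) without shipping any vendor table.
    """
    rng = np.random.default_rng(seed)
    conc = top_amol_per_uL / fold_step ** np.arange(n_species)
    lengths = rng.integers(250, 2001, n_species)
    return pd.DataFrame({
        "id": [f"SYN-{i + 1:04d}" for i in range(n_species)],
        "length_bp": lengths,
        "amol_per_uL": conc,
    })


def expected_copies(design: SpikeInDesign) -> pd.Series:
    """Functional alias for :meth:`SpikeInDesign.expected_copies`."""
    return design.expected_copies()


@dataclass
class SpikeInFit:
    """OLS fit of observed on expected copy number (log2 scale)."""

    slope: float
    intercept: float
    r_squared: float
    adjusted_r_squared: float
    n_species: int
    excluded: list

    def summary(self) -> str:
        return (
            f"spike-in fit over {self.n_species} species: "
            f"slope={self.slope:.4f} intercept={self.intercept:.4f} "
            f"R2={self.r_squared:.4f} adjR2={self.adjusted_r_squared:.4f}"
        )


def fit_copy_number(observed: pd.Series, expected: pd.Series,
                    pseudocount: float = 1.0) -> SpikeInFit:
    """OLS of log2(observed + c) on log2(expected + c).

    The same pseudocount ``c`` (default 1.0) is applied to both axes so a
    perfect library (observed == expected) fits to slope exactly 1 and
    R^2 exactly 1; with ``pseudocount=0`` a pure fold change shifts only the
    intercept. Species with expected <= 0 are excluded and reported.

    adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - 2); requires n >= 3.
    """
    obs, exp = observed.align(expected, join="inner")
    usable = exp > 0
    excluded = list(exp.index[~usable])
    obs, exp = obs[usable], exp[usable]
    n = len(obs)
    if n < 3:
        raise ValueError(
            f"need >= 3 species with expected > 0, got {n} "
            f"(excluded: {excluded})"
        )
    if pseudocount == 0 and (obs <= 0).any():
        raise ValueError("pseudocount=0 requires strictly positive observed counts")
    y = np.log2(obs.to_numpy(dtype=float) + pseudocount)
    x = np.log2(exp.to_numpy(dtype=float) + pseudocount)
    if np.allclose(x, x[0]):
        raise ValueError("expected copies are constant; fit undefined")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue ** 2)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return SpikeInFit(float(res.slope), float(res.intercept), r2, float(adj),
                      n, excluded)


def single_molecule_sensitivity(observed: pd.Series, expected: pd.Series,
                                copy_threshold: float = 1.0,
                                detect_threshold: int = 1) -> float:
    """Fraction of >= ``copy_threshold``-copy species that were detected.

    ``detect_threshold`` is in observed units (UMIs by default; pass read
    counts to reproduce a read-level call).
    """
    obs, exp = observed.align(expected, join="inner")
    eligible = exp >= copy_threshold
    n_elig = int(eligible.sum())
    if n_elig == 0:
        raise ValueError(
            f"no species with expected >= {copy_threshold} copies"
        )
    detected = int((obs[eligible] >= detect_threshold).sum())
    return detected / n_elig


def sensitivity_per_cell(counts: pd.DataFrame, expected: pd.Series,
                         copy_threshold: float = 1.0,
                         detect_threshold: int = 1) -> pd.Series:
    """Per-cell sensitivities for a species x cell count matrix."""
    out = {
        cell: single_molecule_sensitivity(
            counts[cell], expected, copy_threshold, detect_threshold)
        for cell in counts.columns
    }
    return pd.Series(out, name="sensitivity")
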