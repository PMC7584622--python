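"""Position-frequency and information-content statistics over the pocket.

Builds a per-position residue count matrix over a reference-numbered
region (default 100–175, the PctA active pocket) and computes sequence-
logo information content,

    IC(j) = log2(20) - H(j),    H(j) = -sum_a f_a(j) log2 f_a(j),

with gaps excluded from the frequencies (their fraction is reported
alongside) and an optional small-sample correction
e(n) = 19 / (2 ln 2 · n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GAP, AlignedFamily
from .reference_map import ColumnMap, ReferencePocketModel

RESIDUES = tuple("ACDEFGHIKLMNPQRSTVWY")
_RES_INDEX = {aa: i for i, aa in enumerate(RESIDUES)}


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Residue counts per reference position.

    ``counts`` has shape (n_positions, 20); gap and 'X' tallies are kept
    separately so residue frequencies are over informative letters only.
    """

    positions: tuple[int, ...]
    counts: np.ndarray
    gap_counts: np.ndarray
    x_counts: np.ndarray
    n_rows: int

    def frequencies(self) -> np.ndarray:
        """Per-position residue frequencies (gaps and X excluded).

        Positions with no informative residues yield NaN rows.
        """
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(totals > 0, self.counts / totals, np.nan)
        return freq

    def gap_fraction(self) -> np.ndarray:
        return self.gap_counts / self.n_rows

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(RESIDUES))
        df.insert(0, "position", self.positions)
        df["gap"] = self.gap_counts
        df["X"] = self.x_counts
        return df


def compute_pfm(family: AlignedFamily, cmap: ColumnMap,
                region: tuple[int, int] = (100, 175)) -> PositionFrequencyMatrix:
    """Tally residues at the retained columns of a reference region."""
    lo, hi = region
    positions = [p for p in range(lo, hi + 1) if p in cmap.refpos_to_col]
    if not positions:
        raise ValueError(f"region {region} is not covered by the column map")
    cols = np.array([cmap.refpos_to_col[p] - 1 for p in positions])
    counts = np.zeros((len(positions), 20), dtype=np.int64)
    gaps = np.zeros(len(positions), dtype=np.int64)
    xs = np.zeros(len(positions), dtype=np.int64)
    for _, row in family.rows:
        for j, c in enumerate(cols):
            aa = row[c]
            if aa == GAP:
                gaps[j] += 1
            elif aa == "X":
                xs[j] += 1
            else:
                counts[j, _RES_INDEX[aa]] += 1
    return PositionFrequencyMatrix(
        positions=tuple(positions), counts=counts,
        gap_counts=gaps, x_counts=xs, n_rows=len(family),
    )


def information_content(pfm: PositionFrequencyMatrix,
                        small_sample_correction: bool = False) -> np.ndarray:
    """Per-position information content in bits.

    All-gap positions are reported as NaN.  The small-sample correction
    subtracts e(n) = 19/(2 ln 2 · n) where n is the number of
    informative residues at the position; it is off by default since the
    screened families here number in the thousands of rows.
    """
    freq = pfm.frequencies()
    with np.errstate(invalid="ignore", divide="ignore"):
        logf = np.where(freq > 0, np.log2(np.where(freq > 0, freq, 1.0)), 0.0)
    entropy = -np.nansum(freq * logf, axis=1)
    ic = math.log2(20) - entropy
    n_informative = pfm.counts.sum(axis=1)
    ic = np.where(n_informative > 0, ic, np.nan)
    if small_sample_correction:
        with np.errstate(divide="ignore"):
            e_n = np.where(n_informative > 0,
                           19.0 / (2.0 * math.log(2) * n_informative), np.nan)
        ic = ic - e_n
    return ic


def top_conserved(pfm: PositionFrequencyMatrix, m: int) -> list[int]:
    """The m positions ranked by max single-residue frequency.

    Ties are broken by ascending reference position; all-gap positions
    rank last.
    """
    freq = pfm.frequencies()
    with np.errstate(invalid="ignore"):
        peak = np.nanmax(np.nan_to_num(freq, nan=-1.0), axis=1)
    order = sorted(range(len(pfm.positions)), key=lambda j: (-peak[j], pfm.positions[j]))
    return [pfm.positions[j] for j in order[:m]]
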