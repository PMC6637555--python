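"""Theoretical fragment spectra and the boolean bin-vector representation.

A spectrum (theoretical or experimental) is reduced to a sparse boolean
vector over m/z bins of width equal to the fragment tolerance: bin i is set
iff some peak falls in [i*w, (i+1)*w). The spectrum dot product then counts
shared set bins. Theoretical spectra contain singly-protonated b and y ions
only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .config import FixedModification
from .formats_io import Spectrum
from .masses import PROTON, RESIDUE_MASSES, WATER


@dataclass(frozen=True)
class BinnedSpectrum:
    """Sparse encoding of a boolean peak vector: sorted unique bin indices."""

    bins: np.ndarray  # int64, strictly increasing, >= 0
    bin_width: float

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")

    def __len__(self) -> int:
        return len(self.bins)

    def to_dense(self) -> np.ndarray:
        """Dense boolean vector up to the highest set bin (for checks)."""
        n = int(self.bins[-1]) + 1 if len(self.bins) else 0
        dense = np.zeros(n, dtype=bool)
        dense[self.bins] = True
        return dense


def _residue_mass(aa: str, mods: tuple[FixedModification, ...]) -> float:
    m = RESIDUE_MASSES[aa]
    for mod in mods:
        if mod.target_residue == aa:
            m += mod.delta_mass
    return m


def fragment_mzs(sequence: str, mods: tuple[FixedModification, ...] = ()) -> list[float]:
    """Singly-protonated b1..b(L-1) and y1..y(L-1) ion m/z values, ascending.

    b_i is the N-terminal prefix of i residues plus a proton; y_i is the
    C-terminal suffix of i residues plus water and a proton. A length-1
    peptide has no internal bond and yields an empty list.
    """
    L = len(sequence)
    if L < 2:
        return []
    residue = [_residue_mass(aa, mods) for aa in sequence]
    mzs: list[float] = []
    acc = PROTON
    for i in range(L - 1):  # b ions
        acc += residue[i]
        mzs.append(acc)
    acc = WATER + PROTON
    for i in range(L - 1, 0, -1):  # y ions
        acc += residue[i]
        mzs.append(acc)
    mzs.sort()
    return mzs


def binarize(mzs: Iterable[float], bin_width: float) -> BinnedSpectrum:
    """Map m/z values to bins by floor(mz / bin_width); duplicates collapse."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    arr = np.asarray(list(mzs), dtype=np.float64)
    if arr.size == 0:
        return BinnedSpectrum(np.empty(0, dtype=np.int64), bin_width)
    if np.any(arr < 0):
        raise ValueError("m/z values must be >= 0")
    bins = np.unique(np.floor(arr / bin_width).astype(np.int64))
    return BinnedSpectrum(bins, bin_width)


def binned_fragments(
    sequence: str, bin_width: float, mods: tuple[FixedModification, ...] = ()
) -> np.ndarray:
    """Bin indices of a peptide's b/y fragments (the theoretical vector)."""
    return binarize(fragment_mzs(sequence, mods), bin_width).bins


def binarize_experimental(
    spectrum: Spectrum, bin_width: float, top_n: int | None = None
) -> BinnedSpectrum:
    """Binarize an experimental peak list.

    If ``top_n`` is given, only the top_n most intense peaks are kept
    before binning; ties are broken deterministically by (intensity
    descending, m/z ascending).
    """
    peaks = spectrum.peaks
    if top_n is not None:
        if top_n < 1:
            raise ValueError("top_n must be >= 1 or None")
        peaks = sorted(peaks, key=lambda p: (-p[1], p[0]))[:top_n]
    return binarize((mz for mz, _ in peaks), bin_width)


@dataclass(frozen=True)
class TheoreticalSpectrum:
    """A peptide's binned b/y fragment vector with its precursor mass."""

    sequence: str
    precursor_neutral_mass: float
    binned: BinnedSpectrum
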