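"""Spectrum dot product scoring and candidate retrieval.

The score of a peptide-spectrum match is the dot product of the two
boolean bin vectors — the number of m/z bins set in both the experimental
and the theoretical spectrum. Candidates are the contiguous run of the
mass-sorted index within the precursor tolerance, found by binary search.

Two scoring drivers are provided:

* ``score_spectrum_alg1`` — the two-pass reference: collect the whole
  candidate window first, then score each candidate.
* ``score_spectrum_micsdp`` — the fused single pass: one binary search,
  then each candidate is scored as it streams by, keeping only a bounded
  top-k buffer. Its output is identical to the reference on every input;
  the unit of work is one whole spectrum, so spectra can be dispatched to
  workers independently.
"""

from __future__ import annotations

import bisect
import threading
from dataclasses import dataclass

import numpy as np

from .config import SearchConfig
from .digestion import IndexEntry, PeptideIndex
from .formats_io import Spectrum
from .theoretical import BinnedSpectrum, binarize_experimental

#: Instrumentation counters (e.g. how often a full candidate list was
#: materialized); used by tests and the CLI, never by scoring decisions.
INSTRUMENTATION = {"candidate_list_materializations": 0}
_instr_lock = threading.Lock()


def reset_instrumentation() -> None:
    with _instr_lock:
        for key in INSTRUMENTATION:
            INSTRUMENTATION[key] = 0


def _count(key: str) -> None:
    with _instr_lock:
        INSTRUMENTATION[key] += 1


@dataclass(frozen=True)
class PSM:
    """A ranked peptide-spectrum match."""

    spectrum_id: str
    source_index: int
    peptide: IndexEntry
    precursor_neutral_mass: float
    sdp_score: int
    rank: int

    @property
    def peptide_sequence(self) -> str:
        return self.peptide.sequence

    @property
    def protein_accession(self) -> str:
        return ";".join(self.peptide.protein_accessions)

    @property
    def peptide_mass(self) -> float:
        return self.peptide.neutral_mass


@dataclass(frozen=True)
class CandidateWindow:
    """Half-open range [lo, hi) into the mass-sorted index (H, size K)."""

    lo: int
    hi: int

    def __len__(self) -> int:
        return self.hi - self.lo


def sdp(c: BinnedSpectrum, t: BinnedSpectrum) -> int:
    """Spectrum dot product: size of the bin-set intersection.

    Equals sum(c_i * t_i) over the dense boolean vectors. Both spectra
    must be binned at the same width.
    """
    if c.bin_width != t.bin_width:
        raise ValueError(
            f"bin width mismatch: {c.bin_width} vs {t.bin_width}"
        )
    return _sdp_bins(c.bins, t.bins)


def _sdp_bins(a: np.ndarray, b: np.ndarray) -> int:
    return int(np.intersect1d(a, b, assume_unique=True).size)


def candidate_window(index: PeptideIndex, query_mass: float, tol: float) -> CandidateWindow:
    """Maximal index range with |mass - query_mass| <= tol (binary search)."""
    if tol < 0:
        raise ValueError("tolerance must be >= 0")
    lo = int(np.searchsorted(index.masses, query_mass - tol, side="left"))
    hi = int(np.searchsorted(index.masses, query_mass + tol, side="right"))
    return CandidateWindow(lo, hi)


def rank_psms(
    scored: list[tuple[IndexEntry, int]],
    k: int,
    spectrum: Spectrum,
) -> list[PSM]:
    """Rank scored candidates into at most k PSMs.

    Ordering: score descending; ties broken by smaller |peptide mass −
    precursor neutral mass|, then lexicographic sequence. Zero scores
    carry no match evidence and are dropped.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    neutral = spectrum.precursor_neutral_mass
    keyed = sorted(
        ((-score, abs(e.neutral_mass - neutral), e.sequence, e, score)
         for e, score in scored if score > 0),
        key=lambda item: item[:3],
    )[:k]
    return [
        PSM(spectrum.spectrum_id, spectrum.source_index, e, neutral, score, rank)
        for rank, (_, _, _, e, score) in enumerate(keyed, start=1)
    ]


def score_spectrum_alg1(
    spectrum: Spectrum,
    index: PeptideIndex,
    config: SearchConfig,
    window: CandidateWindow | None = None,
) -> list[PSM]:
    """Two-pass reference scorer.

    Pass 1 materializes the full candidate window H; pass 2 scores every
    candidate with the dot product; the scored list is then ranked.
    """
    c = binarize_experimental(spectrum, config.fragment_tolerance_da, config.top_n_peaks)
    if window is None:
        window = candidate_window(
            index, spectrum.precursor_neutral_mass, config.precursor_tolerance_da
        )
    candidates = [(i, index.entries[i]) for i in range(window.lo, window.hi)]
    _count("candidate_list_materializations")
    scored = [
        (entry, _sdp_bins(c.bins, index.theoretical_bins(i, config.fragment_tolerance_da)))
        for i, entry in candidates
    ]
    return rank_psms(scored, config.top_k, spectrum)


def score_spectrum_micsdp(
    spectrum: Spectrum,
    index: PeptideIndex,
    config: SearchConfig,
    window: CandidateWindow | None = None,
) -> list[PSM]:
    """Fused single-pass scorer.

    One binary search bounds the candidate range; candidates are then
    streamed, each scored immediately, and only a top-k buffer (sorted,
    bounded by k entries) is kept — the candidate list is never
    materialized, so per-spectrum memory is O(N + k) rather than O(K).
    Output is field-for-field identical to :func:`score_spectrum_alg1`.
    """
    c = binarize_experimental(spectrum, config.fragment_tolerance_da, config.top_n_peaks)
    if window is None:
        window = candidate_window(
            index, spectrum.precursor_neutral_mass, config.precursor_tolerance_da
        )
    neutral = spectrum.precursor_neutral_mass
    top: list[tuple[int, float, str, IndexEntry, int]] = []  # bounded by k
    for i in range(window.lo, window.hi):
        score = _sdp_bins(c.bins, index.theoretical_bins(i, config.fragment_tolerance_da))
        if score <= 0:
            continue
        entry = index.entries[i]
        key = (-score, abs(entry.neutral_mass - neutral), entry.sequence, entry, score)
        if len(top) == config.top_k:
            if key[:3] >= top[-1][:3]:
                continue
            top.pop()
        bisect.insort(top, key, key=lambda item: item[:3])
    return [
        PSM(spectrum.spectrum_id, spectrum.source_index, e, neutral, score, rank)
        for rank, (_, _, _, e, score) in enumerate(top, start=1)
    ]


SCORERS = {"alg1": score_spectrum_alg1, "micsdp": score_spectrum_micsdp}
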