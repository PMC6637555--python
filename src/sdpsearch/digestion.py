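"""In-silico enzymatic digestion and monoisotopic peptide masses.

Proteins are cut by an enzyme's cleavage rule (Expasy conventions:
trypsin cuts C-terminal to K/R unless proline follows, LysC C-terminal to
K, AspN N-terminal to D). Peptides with up to ``max_missed`` skipped sites
are emitted, de-duplicated by sequence into a mass-sorted index that
candidate retrieval binary-searches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import FixedModification, SearchConfig
from .formats_io import ProteinRecord
from .masses import NONSTANDARD_RESIDUES, RESIDUE_MASSES, WATER

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnzymeRule:
    """A site-specific cleavage rule.

    Exactly one of ``cleave_after`` (C-terminal rule) / ``cleave_before``
    (N-terminal rule) is non-empty; ``restrict_next`` blocks cleavage when
    the residue immediately after the site matches (trypsin's proline rule).
    """

    name: str
    cleave_after: frozenset[str] = frozenset()
    cleave_before: frozenset[str] = frozenset()
    restrict_next: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if bool(self.cleave_after) == bool(self.cleave_before):
            raise ValueError("exactly one of cleave_after/cleave_before must be non-empty")


ENZYMES: dict[str, EnzymeRule] = {
    "trypsin": EnzymeRule("trypsin", cleave_after=frozenset("KR"), restrict_next=frozenset("P")),
    "lysc": EnzymeRule("lysc", cleave_after=frozenset("K")),
    "aspn": EnzymeRule("aspn", cleave_before=frozenset("D")),
}


@dataclass(frozen=True)
class Peptide:
    """A digested peptide with provenance and neutral monoisotopic mass."""

    sequence: str
    protein_accession: str
    start: int
    missed_cleavages: int
    neutral_mass: float


def peptide_mass(sequence: str, mods: tuple[FixedModification, ...] = ()) -> float:
    """Neutral monoisotopic mass: residues + one water + fixed mods.

    Raises on an empty sequence or any residue outside the standard 20.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    mass = WATER
    for aa in sequence:
        try:
            mass += RESIDUE_MASSES[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r} in {sequence!r}") from None
    for mod in mods:
        mass += sequence.count(mod.target_residue) * mod.delta_mass
    return mass


def cleavage_sites(sequence: str, rule: EnzymeRule) -> list[int]:
    """Positions where the backbone is cut (index of the residue that
    starts the next fragment). Termini are not included."""
    sites: list[int] = []
    n = len(sequence)
    if rule.cleave_after:
        for i in range(n - 1):
            if sequence[i] in rule.cleave_after and sequence[i + 1] not in rule.restrict_next:
                sites.append(i + 1)
    else:
        for i in range(1, n):
            if sequence[i] in rule.cleave_before:
                sites.append(i)
    return sites


def digest(
    protein: ProteinRecord,
    rule: EnzymeRule,
    max_missed: int = 2,
    min_len: int = 6,
    max_len: int = 50,
    mods: tuple[FixedModification, ...] = (),
) -> list[Peptide]:
    """All peptides of ``protein`` under ``rule`` with up to ``max_missed``
    missed cleavages, filtered to [min_len, max_len].

    A peptide with k missed cleavages is the concatenation of k+1 adjacent
    fully-cleaved fragments. Peptides containing non-standard residues
    (B/J/O/U/X/Z or anything else outside the 20-letter alphabet) are
    skipped with a warning. Output is ordered by (start, length).
    """
    seq = protein.sequence
    bounds = [0] + cleavage_sites(seq, rule) + [len(seq)]
    peptides: list[Peptide] = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for k in range(min(max_missed, n_frag - 1 - i) + 1):
            sub = seq[bounds[i]:bounds[i + k + 1]]
            if not (min_len <= len(sub) <= max_len):
                continue
            if not set(sub) <= RESIDUE_MASSES.keys():
                bad = sorted(set(sub) - RESIDUE_MASSES.keys())
                level = logging.WARNING if set(bad) <= NONSTANDARD_RESIDUES else logging.ERROR
                log.log(level, "skipping peptide %s from %s: non-standard residue(s) %s",
                        sub, protein.accession, ",".join(bad))
                continue
            peptides.append(
                Peptide(sub, protein.accession, bounds[i], k, peptide_mass(sub, mods))
            )
    return peptides


@dataclass(frozen=True)
class IndexEntry:
    """One scored entry of the index: a distinct peptide sequence with all
    of its protein provenances (accession, start, missed_cleavages)."""

    sequence: str
    neutral_mass: float
    occurrences: tuple[tuple[str, int, int], ...]

    @property
    def protein_accessions(self) -> tuple[str, ...]:
        return tuple(sorted({acc for acc, _, _ in self.occurrences}))


@dataclass
class PeptideIndex:
    """Mass-sorted, sequence-deduplicated peptide index.

    ``masses`` is ascending; candidate retrieval binary-searches it.
    Theoretical fragment bin vectors are computed lazily and memoized per
    entry for one fragment bin width.
    """

    entries: list[IndexEntry]
    masses: np.ndarray
    mods: tuple[FixedModification, ...] = ()
    _bin_cache: dict[int, np.ndarray] = field(default_factory=dict, repr=False)
    _bin_width: float | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.entries)

    def theoretical_bins(self, i: int, bin_width: float) -> np.ndarray:
        from .theoretical import binned_fragments

        if self._bin_width != bin_width:
            self._bin_cache.clear()
            self._bin_width = bin_width
        bins = self._bin_cache.get(i)
        if bins is None:
            bins = binned_fragments(self.entries[i].sequence, bin_width, self.mods)
            self._bin_cache[i] = bins
        return bins


def build_peptide_index(proteins: list[ProteinRecord], config: SearchConfig) -> PeptideIndex:
    """Digest every protein and build the mass-sorted index.

    Identical sequences collapse to one entry carrying all provenances;
    entries are sorted by (mass, sequence) — sequence uniqueness makes the
    order total — with occurrences ordered by (accession, start).
    """
    rule = ENZYMES[config.enzyme]
    by_seq: dict[str, list[tuple[str, int, int]]] = {}
    mass_of: dict[str, float] = {}
    for protein in proteins:
        for pep in digest(
            protein, rule, config.max_missed_cleavages,
            config.min_peptide_length, config.max_peptide_length, config.fixed_mods,
        ):
            by_seq.setdefault(pep.sequence, []).append(
                (pep.protein_accession, pep.start, pep.missed_cleavages)
            )
            mass_of[pep.sequence] = pep.neutral_mass
    entries = [
        IndexEntry(seq, mass_of[seq], tuple(sorted(occ)))
        for seq, occ in by_seq.items()
    ]
    entries.sort(key=lambda e: (e.neutral_mass, e.sequence))
    masses = np.array([e.neutral_mass for e in entries], dtype=np.float64)
    return PeptideIndex(entries, masses, mods=config.fixed_mods)
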