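"""Search configuration shared by every stage of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .masses import CARBAMIDOMETHYL


@dataclass(frozen=True)
class FixedModification:
    """A fixed (always-applied) mass shift on one residue type."""

    target_residue: str
    delta_mass: float

    def __post_init__(self) -> None:
        if len(self.target_residue) != 1 or not self.target_residue.isalpha():
            raise ValueError(f"target_residue must be one letter, got {self.target_residue!r}")
        if not (self.delta_mass == self.delta_mass and abs(self.delta_mass) != float("inf")):
            raise ValueError("delta_mass must be finite")

    @classmethod
    def parse(cls, text: str) -> "FixedModification":
        """Parse a ``"residue:+delta"`` string, e.g. ``"C:+57.021464"``."""
        residue, _, delta = text.partition(":")
        return cls(residue.strip().upper(), float(delta))


#: Fixed carbamidomethylation of cysteine — the default modification set.
DEFAULT_MODS: tuple[FixedModification, ...] = (
    FixedModification("C", CARBAMIDOMETHYL),
)


@dataclass
class SearchConfig:
    """Parameters of one database search.

    Defaults follow a common LTQ/trypsin setup: 3 Da precursor tolerance,
    0.5 Da fragment tolerance, fixed carbamidomethylation of cysteine.
    The fragment tolerance doubles as the m/z bin width of the boolean
    spectrum vectors.
    """

    enzyme: str = "trypsin"
    max_missed_cleavages: int = 2
    min_peptide_length: int = 6
    max_peptide_length: int = 50
    fixed_mods: tuple[FixedModification, ...] = DEFAULT_MODS
    precursor_tolerance_da: float = 3.0
    fragment_tolerance_da: float = 0.5
    top_n_peaks: int | None = None
    top_k: int = 10
    algorithm: str = "micsdp"
    default_precursor_charge: int = 2
    n_workers: int = 1
    queue_capacity: int = 2
    chunk_target_size: int = 32
    imbalance_threshold: float = 0.08
    alpha: float = 0.5
    seed: int = 1

    def validate(self) -> None:
        if self.enzyme not in ("trypsin", "aspn", "lysc"):
            raise ValueError(f"unknown enzyme {self.enzyme!r}")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if not (1 <= self.min_peptide_length <= self.max_peptide_length):
            raise ValueError("need 1 <= min_peptide_length <= max_peptide_length")
        if self.precursor_tolerance_da <= 0 or self.fragment_tolerance_da <= 0:
            raise ValueError("tolerances must be > 0")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.algorithm not in ("alg1", "micsdp"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")
        if self.queue_capacity < 2:
            raise ValueError("queue_capacity must be >= 2 (double buffering)")
        if self.chunk_target_size < 1:
            raise ValueError("chunk_target_size must be >= 1")
        if self.default_precursor_charge < 1:
            raise ValueError("default_precursor_charge must be >= 1")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.imbalance_threshold <= 0:
            raise ValueError("imbalance_threshold must be > 0")

    def with_(self, **kwargs) -> "SearchConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)
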