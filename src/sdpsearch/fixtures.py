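"""Deterministic synthetic data: proteomes, spectra with known ground
truth, and scheduler workloads.

The generator stands in for real human-sample spectra files: random
proteins are digested, a subset of the resulting peptides is "spiked"
into MGF spectra built from their own b/y fragments with a configurable
missing-fragment fraction, uniform-m/z noise peaks and a bounded
precursor m/z error. The same spec and seed always produce byte-identical
files, and every generated file is a valid input to the readers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import SearchConfig
from .digestion import ENZYMES, digest
from .formats_io import ProteinRecord
from .masses import PROTON
from .theoretical import fragment_mzs

AA = "ACDEFGHIKLMNPQRSTVWY"

#: m/z range in which uniform noise peaks are drawn (Da).
NOISE_MZ_RANGE = (100.0, 1500.0)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic dataset.

    Defaults describe a small but non-trivial benchmark: 40 random
    proteins, 200 spiked spectra with 5 noise peaks each, 30% of the b/y
    fragments missing and precursor m/z errors within ±0.5 Da — well
    inside the default 3 Da precursor tolerance at charges 2–3.
    """

    n_proteins: int = 40
    protein_length: tuple[int, int] = (80, 160)
    enzyme: str = "trypsin"
    n_spike_spectra: int = 200
    noise_peaks: int = 5
    missing_fragment_fraction: float = 0.3
    precursor_mz_error_da: tuple[float, float] = (-0.5, 0.5)
    charges: tuple[int, ...] = (2, 3)
    seed: int = 1

    def __post_init__(self) -> None:
        if min(self.n_proteins, self.n_spike_spectra, self.noise_peaks) < 0:
            raise ValueError("counts must be >= 0")
        if not 0.0 <= self.missing_fragment_fraction <= 1.0:
            raise ValueError("missing_fragment_fraction must lie in [0, 1]")
        if self.protein_length[0] < 1 or self.protein_length[0] > self.protein_length[1]:
            raise ValueError("bad protein_length range")


def make_proteome(
    spec: FixtureSpec, out_dir: str | os.PathLike, config: SearchConfig | None = None
) -> tuple[Path, list[ProteinRecord], list]:
    """Generate random proteins, write them as FASTA and return the
    digestion truth table.

    Residues are drawn uniformly over the 20-letter alphabet. The truth
    table holds every peptide the configured digestion yields (written as
    ``peptides.tsv`` next to the FASTA).
    """
    config = config or SearchConfig(enzyme=spec.enzyme)
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    proteins: list[ProteinRecord] = []
    for i in range(spec.n_proteins):
        length = int(rng.integers(spec.protein_length[0], spec.protein_length[1] + 1))
        seq = "".join(AA[j] for j in rng.integers(0, len(AA), size=length))
        proteins.append(ProteinRecord(f"SYN{i:04d}", "synthetic protein", seq))

    fasta_path = out_dir / "proteome.fasta"
    with open(fasta_path, "w", encoding="ascii", newline="\n") as fh:
        for p in proteins:
            fh.write(f">{p.accession} {p.description}\n")
            for j in range(0, len(p.sequence), 60):
                fh.write(p.sequence[j:j + 60] + "\n")

    rule = ENZYMES[config.enzyme]
    truth = [
        pep
        for p in proteins
        for pep in digest(
            p, rule, config.max_missed_cleavages,
            config.min_peptide_length, config.max_peptide_length, config.fixed_mods,
        )
    ]
    with open(out_dir / "peptides.tsv", "w", encoding="ascii", newline="\n") as fh:
        fh.write("protein_accession\tstart\tmissed_cleavages\tsequence\tneutral_mass\n")
        for pep in truth:
            fh.write(
                f"{pep.protein_accession}\t{pep.start}\t{pep.missed_cleavages}\t"
                f"{pep.sequence}\t{pep.neutral_mass:.5f}\n"
            )
    return fasta_path, proteins, truth


def make_spectra(
    truth_peptides: list,
    spec: FixtureSpec,
    out_dir: str | os.PathLike,
    config: SearchConfig | None = None,
) -> tuple[Path, dict[str, str]]:
    """Write an MGF of spiked spectra and return the spectrum→peptide map.

    Each spectrum is built from one distinct peptide sequence: its b/y
    m/z values with a fraction removed at random, plus uniform noise
    peaks; the precursor m/z is (mass + z·proton)/z perturbed within the
    configured error range. Intensities are uniform in (0, 1] (scoring
    ignores them). The truth map is also written as ``spectra_truth.tsv``.
    """
    config = config or SearchConfig(enzyme=spec.enzyme)
    rng = np.random.default_rng(spec.seed + 1)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    candidates = sorted({pep.sequence: pep for pep in truth_peptides}.values(),
                        key=lambda p: p.sequence)
    if spec.n_spike_spectra > len(candidates):
        raise ValueError(
            f"requested {spec.n_spike_spectra} spiked spectra but only "
            f"{len(candidates)} distinct peptides are available"
        )
    chosen_idx = rng.choice(len(candidates), size=spec.n_spike_spectra, replace=False)
    lo_err, hi_err = spec.precursor_mz_error_da

    mgf_path = out_dir / "spectra.mgf"
    truth_map: dict[str, str] = {}
    with open(mgf_path, "w", encoding="ascii", newline="\n") as fh:
        for si, ci in enumerate(chosen_idx):
            pep = candidates[int(ci)]
            title = f"spike_{si:04d}"
            truth_map[title] = pep.sequence
            charge = int(spec.charges[int(rng.integers(0, len(spec.charges)))])
            mz_err = float(rng.uniform(lo_err, hi_err))
            precursor_mz = (pep.neutral_mass + charge * PROTON) / charge + mz_err

            frags = fragment_mzs(pep.sequence, config.fixed_mods)
            keep = rng.random(len(frags)) >= spec.missing_fragment_fraction
            mzs = [m for m, k in zip(frags, keep) if k]
            mzs += list(rng.uniform(*NOISE_MZ_RANGE, size=spec.noise_peaks))
            peaks = sorted((m, float(1.0 - rng.random())) for m in mzs)

            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={title}\n")
            fh.write(f"PEPMASS={precursor_mz:.6f}\n")
            fh.write(f"CHARGE={charge}+\n")
            for mz, inten in peaks:
                fh.write(f"{mz:.5f} {inten:.5f}\n")
            fh.write("END IONS\n")

    with open(out_dir / "spectra_truth.tsv", "w", encoding="ascii", newline="\n") as fh:
        fh.write("spectrum_id\tpeptide_sequence\n")
        for title, seq in truth_map.items():
            fh.write(f"{title}\t{seq}\n")
    return mgf_path, truth_map


@dataclass(frozen=True)
class ScheduleWorkload:
    """Simulated chunk costs plus the true worker speeds behind them."""

    chunk_costs: np.ndarray
    worker_speeds: tuple[float, ...]


def make_schedule_workload(
    n_chunks: int,
    worker_speeds: list[float],
    seed: int,
    jitter_sigma: float = 0.1,
) -> ScheduleWorkload:
    """Per-chunk costs with lognormal jitter around unit cost.

    With ``jitter_sigma`` 0 every chunk costs exactly 1, so a perfectly
    proportional split is optimal.
    """
    if n_chunks < 0:
        raise ValueError("n_chunks must be >= 0")
    if any(s <= 0 for s in worker_speeds):
        raise ValueError("worker speeds must be > 0")
    rng = np.random.default_rng(seed)
    if jitter_sigma > 0:
        costs = rng.lognormal(mean=0.0, sigma=jitter_sigma, size=n_chunks)
    else:
        costs = np.ones(n_chunks)
    return ScheduleWorkload(costs, tuple(worker_speeds))


def make_fixture_set(
    spec: FixtureSpec, out_dir: str | os.PathLike, config: SearchConfig | None = None
) -> dict[str, object]:
    """Generate the full fixture set (FASTA + MGF + truth tables)."""
    config = config or SearchConfig(enzyme=spec.enzyme)
    fasta_path, proteins, truth = make_proteome(spec, out_dir, config)
    mgf_path, truth_map = make_spectra(truth, spec, out_dir, config)
    return {
        "fasta": fasta_path,
        "mgf": mgf_path,
        "proteins": proteins,
        "peptides": truth,
        "truth_map": truth_map,
    }
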