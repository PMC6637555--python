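"""Input/output: FASTA protein databases, MGF spectra, TSV result reports.

FASTA parsing is delegated to Biopython and MGF parsing to pyteomics; this
module only enforces the package's contracts on top of them (unique
accessions, sorted peaks, stable spectrum ordering).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from itertools import count as _count
from typing import Sequence

from Bio import SeqIO
from pyteomics import mgf as _mgf

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


class FormatError(ValueError):
    """Raised for malformed or contract-violating input files."""


@dataclass(frozen=True)
class ProteinRecord:
    """One database protein: accession, free-text description, sequence."""

    accession: str
    description: str
    sequence: str


@dataclass
class Spectrum:
    """One experimental MS/MS scan.

    Peaks are (m/z, intensity) pairs sorted ascending by m/z; intensities
    are carried for peak filtering but ignored by the boolean SDP score.
    ``source_index`` is the 0-based position in the input file and fixes a
    reproducible global ordering of results.
    """

    spectrum_id: str
    precursor_mz: float
    precursor_charge: int
    peaks: list[tuple[float, float]]
    source_index: int

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise FormatError(f"{self.spectrum_id}: precursor_mz must be > 0")
        if self.precursor_charge < 1:
            raise FormatError(f"{self.spectrum_id}: precursor_charge must be >= 1")
        self.peaks = sorted(self.peaks)

    @property
    def precursor_neutral_mass(self) -> float:
        from .masses import PROTON

        return (self.precursor_mz - PROTON) * self.precursor_charge


def read_fasta(path: str | os.PathLike) -> list[ProteinRecord]:
    """Read a FASTA protein database.

    The accession is the first whitespace-delimited token of the header;
    the rest is kept as the description. Sequences are uppercased and
    multi-line records concatenated. Duplicate accessions and empty
    sequences are errors.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = rec.id
        sequence = str(rec.seq).upper()
        if not sequence:
            raise FormatError(f"record {accession!r} has an empty sequence")
        if accession in seen:
            raise FormatError(f"duplicate accession {accession!r} in {path}")
        seen.add(accession)
        description = rec.description[len(rec.id):].strip()
        records.append(ProteinRecord(accession, description, sequence))
    return records


def read_mgf(path: str | os.PathLike, default_charge: int = 2) -> list[Spectrum]:
    """Read an MGF file into a list of :class:`Spectrum` in file order.

    Blocks without a CHARGE line get ``default_charge``. A block without
    PEPMASS, or with a malformed peak line, is an error naming the block.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    spectra: list[Spectrum] = []
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        it = iter(reader)
        for i in _count():
            try:
                block = next(it)
            except StopIteration:
                break
            except Exception as exc:
                raise FormatError(f"MGF block {i}: malformed line ({exc})") from exc
            params = block["params"]
            title = str(params.get("title", "")).strip() or f"spectrum_{i}"
            if "pepmass" not in params:
                raise FormatError(f"MGF block {i} ({title!r}): missing PEPMASS")
            pepmass = params["pepmass"]
            precursor_mz = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            charge_field = params.get("charge")
            charge = int(charge_field[0]) if charge_field else default_charge
            mzs = block.get("m/z array")
            intens = block.get("intensity array")
            peaks: list[tuple[float, float]] = []
            if mzs is not None and len(mzs):
                if intens is None or len(intens) != len(mzs):
                    raise FormatError(f"MGF block {i} ({title!r}): malformed peak list")
                peaks = [(float(m), float(h)) for m, h in zip(mzs, intens)]
            spectra.append(Spectrum(title, precursor_mz, charge, peaks, source_index=i))
    return spectra


REPORT_COLUMNS = (
    "spectrum_id",
    "peptide_sequence",
    "protein_accession",
    "peptide_mass",
    "precursor_neutral_mass",
    "sdp_score",
    "rank",
)


def write_psm_report(psms: Sequence, path: str | os.PathLike) -> None:
    """Write ranked PSMs as a TSV report.

    Masses are printed to 5 decimal places; SDP scores are integers.
    Rows are written in the order given (callers rank and merge first).
    """
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for p in psms:
            fh.write(
                f"{p.spectrum_id}\t{p.peptide_sequence}\t{p.protein_accession}\t"
                f"{p.peptide_mass:.5f}\t{p.precursor_neutral_mass:.5f}\t"
                f"{int(p.sdp_score)}\t{int(p.rank)}\n"
            )


@dataclass(frozen=True)
class ReportRow:
    """A parsed row of the PSM report (used for round-trip checks)."""

    spectrum_id: str
    peptide_sequence: str
    protein_accession: str
    peptide_mass: float
    precursor_neutral_mass: float
    sdp_score: int
    rank: int


def read_psm_report(path: str | os.PathLike) -> list[ReportRow]:
    """Parse a report written by :func:`write_psm_report`."""
    rows: list[ReportRow] = []
    with open(path, encoding="ascii") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != REPORT_COLUMNS:
            raise FormatError(f"unexpected report header in {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            rows.append(
                ReportRow(f[0], f[1], f[2], float(f[3]), float(f[4]), int(f[5]), int(f[6]))
            )
    return rows
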