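"""Protein databases, in-silico Trypsin/P digestion, peptide masses and sequons.

Coordinates are 1-based inclusive throughout, following the proteomics
site-reporting convention (an N-glycosite at "N123" means the asparagine is
the 123rd residue of the mature database sequence).
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from pyteomics import mass as _pyt_mass

__all__ = [
    "CANONICAL_RESIDUES",
    "WATER_MONO_DA",
    "DEAMIDATION_18O_SHIFT_DA",
    "ProteinRecord",
    "Peptide",
    "Sequon",
    "MassTable",
    "FastaError",
    "read_fasta",
    "write_fasta",
    "digest_trypsin_p",
    "observable_peptide_count",
    "find_sequons",
    "canonical_sequon_positions",
    "peptide_mass",
]

#: The 20 canonical amino-acid letters accepted in database sequences.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Monoisotopic mass of H2O in Da.
WATER_MONO_DA = 18.010565

#: Mass added per asparagine deamidated by PNGase F in heavy water (H2^18O):
#: Asn -> Asp with incorporation of ^18O. This printed constant is the
#: signature that distinguishes formerly N-glycosylated peptides from
#: spontaneous (light-oxygen, +0.984 Da) deamidation.
DEAMIDATION_18O_SHIFT_DA = 2.9890

#: Light-oxygen (H2^16O) deamidation shift, Da; useful for building decoys.
DEAMIDATION_16O_SHIFT_DA = 0.984016

# Standard monoisotopic residue masses, restricted to the canonical alphabet.
_STD_RESIDUE_MASSES: dict[str, float] = {
    aa: _pyt_mass.std_aa_mass[aa] for aa in sorted(CANONICAL_RESIDUES)
}


class FastaError(ValueError):
    """Raised for malformed FASTA input or invalid database sequences."""


@dataclass(frozen=True)
class ProteinRecord:
    """One database protein (e.g. a TAIR10 entry such as AT3G32980)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("protein record with empty id")
        if not self.sequence:
            raise FastaError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - CANONICAL_RESIDUES
        if bad:
            raise FastaError(
                f"protein {self.id!r}: non-canonical residue(s) "
                f"{''.join(sorted(bad))!r} in sequence"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Peptide:
    """An in-silico tryptic peptide with 1-based inclusive coordinates."""

    protein_id: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int
    mono_mass: float


@dataclass(frozen=True)
class Sequon:
    """An N-glycosylation consensus motif N-X-S/T (X != P) at a given Asn."""

    protein_id: str
    position: int  # 1-based index of the Asn
    triplet: str
    canonical: bool


def _default_residue_masses() -> dict[str, float]:
    return dict(_STD_RESIDUE_MASSES)


@dataclass(frozen=True)
class MassTable:
    """Monoisotopic masses used for peptide mass arithmetic.

    ``deam_18O_shift`` defaults to the 2.9890 Da heavy-water deamidation
    signature; it is a field (not a constant baked into formulas) so that
    alternative values, e.g. the value derived from atomic masses
    (~2.98826 Da), can be swapped in.
    """

    residue_masses: Mapping[str, float] = field(
        default_factory=_default_residue_masses
    )
    water_mass: float = WATER_MONO_DA
    deam_18O_shift: float = DEAMIDATION_18O_SHIFT_DA

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.residue_masses.values()):
            raise ValueError("residue masses must all be positive")
        if self.water_mass <= 0:
            raise ValueError("water mass must be positive")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA (plain or gzip) into validated records.

    The header token before the first whitespace becomes the record id; the
    remainder is the description. Duplicate ids, empty files, non-FASTA
    content and non-canonical residues are rejected with a FastaError.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:  # type: ignore[operator]
        lines = handle.read().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise FastaError(
                f"{path}: line {lineno} is not FASTA "
                f"(expected '>' header first): {line[:40]!r}"
            )
        break
    else:
        raise FastaError(f"{path}: empty FASTA file")

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with opener(path, "rt") as handle:  # type: ignore[operator]
        for rec in SeqIO.parse(handle, "fasta"):
            desc = rec.description[len(rec.id):].strip()
            if rec.id in seen:
                raise FastaError(f"{path}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
            records.append(
                ProteinRecord(
                    id=rec.id, sequence=str(rec.seq).upper(), description=desc
                )
            )
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as plain FASTA, 60 residues per line."""
    with open(path, "w") as out:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            out.write(header + "\n")
            for i in range(0, len(rec.sequence), 60):
                out.write(rec.sequence[i : i + 60] + "\n")


def _cleavage_boundaries(sequence: str) -> list[int]:
    """0-based segment boundaries under Trypsin/P: cut after every K or R."""
    bounds = [0]
    n = len(sequence)
    for i, aa in enumerate(sequence):
        if aa in "KR" and i + 1 < n:
            bounds.append(i + 1)
    bounds.append(n)
    return bounds


def digest_trypsin_p(
    protein: ProteinRecord,
    max_missed: int = 2,
    masses: MassTable | None = None,
) -> list[Peptide]:
    """In-silico digest under the Trypsin/P rule.

    Trypsin/P cleaves C-terminal to every K and R with NO proline exception
    (unlike classic trypsin, K|P and R|P bonds are cut). Returns all peptides
    carrying 0..max_missed internal missed cleavages, sorted by (start, end).
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    masses = masses or MassTable()
    seq = protein.sequence
    bounds = _cleavage_boundaries(seq)
    n_seg = len(bounds) - 1
    peptides: list[Peptide] = []
    for i in range(n_seg):
        for m in range(max_missed + 1):
            j = i + m
            if j >= n_seg:
                break
            s, e = bounds[i], bounds[j + 1]
            sub = seq[s:e]
            peptides.append(
                Peptide(
                    protein_id=protein.id,
                    start=s + 1,
                    end=e,
                    sequence=sub,
                    missed_cleavages=m,
                    mono_mass=peptide_mass(sub, 0, masses),
                )
            )
    return peptides


def observable_peptide_count(
    protein: ProteinRecord, min_len: int = 7, max_len: int = 30
) -> int:
    """Number of fully cleaved tryptic peptides of observable length.

    This is the iBAQ denominator: 0-missed-cleavage peptides whose length
    falls in [min_len, max_len] (the mass range routinely observed by LC-MS).
    """
    bounds = _cleavage_boundaries(protein.sequence)
    return sum(
        1
        for s, e in zip(bounds, bounds[1:])
        if min_len <= e - s <= max_len
    )


def find_sequons(protein: ProteinRecord) -> list[Sequon]:
    """Locate every canonical N-glycosylation sequon N-X-S/T (X != P).

    Overlapping sequons are all reported. An Asn within two residues of the
    C-terminus has no complete triplet and therefore cannot be canonical.
    """
    seq = protein.sequence
    out: list[Sequon] = []
    for p in range(len(seq) - 2):
        if seq[p] == "N" and seq[p + 1] != "P" and seq[p + 2] in "ST":
            out.append(
                Sequon(
                    protein_id=protein.id,
                    position=p + 1,
                    triplet=seq[p : p + 3],
                    canonical=True,
                )
            )
    return out


def canonical_sequon_positions(protein: ProteinRecord) -> frozenset[int]:
    """1-based Asn positions that start a canonical sequon."""
    return frozenset(s.position for s in find_sequons(protein))


def peptide_mass(
    sequence: str, n_deamidated: int = 0, masses: MassTable | None = None
) -> float:
    """Neutral monoisotopic mass of a peptide with k heavy deamidations.

    mass = sum(residue masses) + water + k * deam_18O_shift. Each deamidated
    Asn must exist in the sequence.
    """
    masses = masses or MassTable()
    if not sequence:
        raise ValueError("empty peptide sequence")
    if n_deamidated < 0:
        raise ValueError("n_deamidated must be >= 0")
    if n_deamidated > sequence.count("N"):
        raise ValueError(
            f"n_deamidated={n_deamidated} exceeds Asn count "
            f"{sequence.count('N')} in {sequence!r}"
        )
    rm = masses.residue_masses
    try:
        total = sum(rm[aa] for aa in sequence)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} in {sequence!r}") from exc
    return total + masses.water_mass + n_deamidated * masses.deam_18O_shift
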