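"""Call N-glycosites from peptide evidence via the heavy-water deamidation signature.

PNGase F deglycosylation performed in H2^18O converts each formerly
glycosylated Asn to Asp with a +2.9890 Da mass increment. A peptide whose
observed mass delta matches k x 2.9890 Da (within a ppm tolerance of its
theoretical mass) for k >= 1 annotated deamidations is accepted as an
N-glycopeptide; light-oxygen deamidation (+0.984 Da) and unmodified
survivors of the lectin enrichment fail the match and are rejected.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .proteome_model import (
    MassTable,
    ProteinRecord,
    canonical_sequon_positions,
    digest_trypsin_p,
    peptide_mass,
)

__all__ = [
    "EvidenceRecord",
    "GlycositeCall",
    "SignatureResult",
    "MotifFrequencyMatrix",
    "ProteinIndex",
    "read_evidence",
    "write_evidence",
    "validate_signature",
    "map_to_protein",
    "call_glycosites",
    "motif_census",
    "tally_identifications",
]

logger = logging.getLogger(__name__)

EVIDENCE_COLUMNS = [
    "peptide_sequence",
    "deamidated_positions",
    "mass_delta_da",
    "genotype",
    "treatment",
    "replicate",
    "intensity",
]


@dataclass(frozen=True)
class EvidenceRecord:
    """One observed (glyco)peptide measurement in one sample/replicate."""

    peptide_sequence: str
    deamidated_positions: tuple[int, ...]  # 1-based indices within the peptide
    mass_delta_da: float  # observed minus theoretical unmodified mass
    genotype: str
    treatment: str
    replicate: int
    intensity: float

    def __post_init__(self) -> None:
        for p in self.deamidated_positions:
            if not (1 <= p <= len(self.peptide_sequence)):
                raise ValueError(
                    f"deamidated position {p} outside peptide "
                    f"{self.peptide_sequence!r}"
                )
            if self.peptide_sequence[p - 1] != "N":
                raise ValueError(
                    f"deamidated position {p} in {self.peptide_sequence!r} "
                    f"is {self.peptide_sequence[p - 1]!r}, not Asn"
                )
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")


@dataclass(frozen=True)
class SignatureResult:
    accepted: bool
    k: int
    reason: str = ""


@dataclass(frozen=True)
class GlycositeCall:
    """A validated N-glycosylation site in protein coordinates."""

    protein_id: str
    protein_position: int  # 1-based Asn index in the protein
    peptide_sequence: str
    canonical: bool
    n_deamidations_on_peptide: int
    unique: bool  # peptide maps to exactly one database protein


@dataclass
class MotifFrequencyMatrix:
    """Per-offset residue relative frequencies around called glycosites."""

    flank: int
    frequencies: pd.DataFrame  # rows = offsets -flank..+flank, cols = residues
    n_canonical: int
    n_noncanonical: int

    @property
    def n_total(self) -> int:
        return self.n_canonical + self.n_noncanonical


def _parse_positions(text: object) -> tuple[int, ...]:
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return ()
    s = str(text).strip()
    if not s:
        return ()
    return tuple(int(tok) for tok in s.split(";"))


def read_evidence(path: str | Path) -> pd.DataFrame:
    """Read an evidence TSV into a frame with parsed deamidation positions."""
    df = pd.read_csv(path, sep="\t", dtype={"deamidated_positions": str})
    missing = [c for c in EVIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: evidence table missing columns {missing}")
    df = df.copy()
    df["deamidated_positions"] = df["deamidated_positions"].map(_parse_positions)
    df["replicate"] = df["replicate"].astype(int)
    df["intensity"] = df["intensity"].astype(float)
    if (df["intensity"] < 0).any():
        bad = int((df["intensity"] < 0).idxmax())
        raise ValueError(f"{path}: negative intensity at row {bad}")
    return df


def write_evidence(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["deamidated_positions"] = out["deamidated_positions"].map(
        lambda pos: ";".join(str(p) for p in pos)
    )
    out.to_csv(path, sep="\t", index=False)


def validate_signature(
    peptide_sequence: str,
    deamidated_positions: Sequence[int],
    mass_delta_da: float,
    masses: MassTable | None = None,
    tol_ppm: float = 10.0,
) -> SignatureResult:
    """Accept a peptide as an N-glycopeptide iff its mass delta matches
    k x deam_18O_shift within tol_ppm of the theoretical peptide mass.

    k is the number of annotated deamidated Asn; k = 0 is rejected outright
    (nothing to attribute the delta to).
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    masses = masses or MassTable()
    k = len(deamidated_positions)
    if k == 0:
        return SignatureResult(False, 0, "no deamidation annotated")
    theoretical = peptide_mass(peptide_sequence, 0, masses)
    tol_da = tol_ppm * 1e-6 * theoretical
    resid = abs(mass_delta_da - k * masses.deam_18O_shift)
    if resid <= tol_da:
        return SignatureResult(True, k, "")
    return SignatureResult(
        False, k, f"delta off signature by {resid:.4f} Da (> {tol_da:.4f})"
    )


class ProteinIndex:
    """Maps peptide sequences back to protein coordinates.

    Indexes every tryptic peptide with <= max_missed missed cleavages of
    every database protein; unindexed sequences fall back to an exhaustive
    substring scan so that unusual (e.g. >2 missed cleavage) peptides still
    map. A peptide matching more than one protein is non-unique.
    """

    def __init__(self, proteins: Iterable[ProteinRecord], max_missed: int = 2):
        self.proteins: dict[str, ProteinRecord] = {}
        self._peptides: dict[str, list[tuple[str, int]]] = {}
        self._canonical: dict[str, frozenset[int]] = {}
        for prot in proteins:
            if prot.id in self.proteins:
                raise ValueError(f"duplicate protein id {prot.id!r}")
            self.proteins[prot.id] = prot
            self._canonical[prot.id] = canonical_sequon_positions(prot)
            for pep in digest_trypsin_p(prot, max_missed):
                self._peptides.setdefault(pep.sequence, []).append(
                    (prot.id, pep.start)
                )
        self._fallback_cache: dict[str, list[tuple[str, int]]] = {}

    def locate(self, peptide_sequence: str) -> list[tuple[str, int]]:
        """All (protein_id, 1-based start) of exact occurrences."""
        hits = self._peptides.get(peptide_sequence)
        if hits is not None:
            return hits
        cached = self._fallback_cache.get(peptide_sequence)
        if cached is None:
            cached = []
            for pid, prot in self.proteins.items():
                pos = prot.sequence.find(peptide_sequence)
                while pos != -1:
                    cached.append((pid, pos + 1))
                    pos = prot.sequence.find(peptide_sequence, pos + 1)
            self._fallback_cache[peptide_sequence] = cached
        return cached

    def is_canonical(self, protein_id: str, position: int) -> bool:
        return position in self._canonical[protein_id]


def map_to_protein(
    peptide_sequence: str,
    deamidated_positions: Sequence[int],
    index: ProteinIndex,
) -> list[GlycositeCall]:
    """Map deamidated peptide positions to protein-coordinate site calls.

    The canonical flag comes from the protein-level sequon scan, so a sequon
    whose X/S/T residues lie in the next tryptic peptide (e.g. a peptide
    ending ...NK with downstream VS) is still classified correctly. Peptides
    occurring in more than one protein produce one call per protein, all
    flagged non-unique.
    """
    hits = index.locate(peptide_sequence)
    unique = len({pid for pid, _ in hits}) == 1
    calls: list[GlycositeCall] = []
    for pid, start in hits:
        for p in deamidated_positions:
            pos = start + p - 1
            calls.append(
                GlycositeCall(
                    protein_id=pid,
                    protein_position=pos,
                    peptide_sequence=peptide_sequence,
                    canonical=index.is_canonical(pid, pos),
                    n_deamidations_on_peptide=len(deamidated_positions),
                    unique=unique,
                )
            )
    return calls


def call_glycosites(
    evidence: pd.DataFrame,
    index: ProteinIndex,
    masses: MassTable | None = None,
    tol_ppm: float = 10.0,
) -> tuple[pd.DataFrame, dict]:
    """Validate every evidence row and map accepted rows to protein sites.

    Returns (calls, audit): ``calls`` has one row per (evidence row, mapped
    protein, deamidated position) with sample annotations carried along;
    ``audit`` counts accepted/rejected/unmapped rows. Unmapped accepted
    peptides are logged and excluded from site tallies.
    """
    masses = masses or MassTable()
    sig_cache: dict[tuple[str, int], tuple[bool, float]] = {}
    map_cache: dict[tuple[str, tuple[int, ...]], list[GlycositeCall]] = {}

    rows: list[dict] = []
    n_rejected = 0
    n_unmapped = 0
    n_accepted = 0
    for row in evidence.itertuples(index=False):
        pos = tuple(row.deamidated_positions)
        k = len(pos)
        key = (row.peptide_sequence, k)
        cached = sig_cache.get(key)
        if cached is None:
            theo = peptide_mass(row.peptide_sequence, 0, masses)
            cached = (k >= 1, theo)
            sig_cache[key] = cached
        ok_k, theo = cached
        accepted = (
            ok_k
            and abs(row.mass_delta_da - k * masses.deam_18O_shift)
            <= tol_ppm * 1e-6 * theo
        )
        if not accepted:
            n_rejected += 1
            continue
        n_accepted += 1
        mkey = (row.peptide_sequence, pos)
        calls = map_cache.get(mkey)
        if calls is None:
            calls = map_to_protein(row.peptide_sequence, pos, index)
            map_cache[mkey] = calls
        if not calls:
            n_unmapped += 1
            logger.warning(
                "accepted glycopeptide %r not found in any database protein",
                row.peptide_sequence,
            )
            continue
        for call in calls:
            rows.append(
                {
                    "protein_id": call.protein_id,
                    "protein_position": call.protein_position,
                    "peptide_sequence": call.peptide_sequence,
                    "deamidated_positions": pos,
                    "canonical": call.canonical,
                    "n_deamidations": call.n_deamidations_on_peptide,
                    "unique": call.unique,
                    "genotype": row.genotype,
                    "treatment": row.treatment,
                    "replicate": row.replicate,
                    "intensity": row.intensity,
                    "mass_delta_da": row.mass_delta_da,
                }
            )
    calls_df = pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "protein_position",
            "peptide_sequence",
            "deamidated_positions",
            "canonical",
            "n_deamidations",
            "unique",
            "genotype",
            "treatment",
            "replicate",
            "intensity",
            "mass_delta_da",
        ],
    )
    audit = {
        "n_evidence_rows": int(len(evidence)),
        "n_accepted": n_accepted,
        "n_rejected": n_rejected,
        "n_unmapped": n_unmapped,
    }
    return calls_df, audit


def motif_census(
    calls: pd.DataFrame,
    proteins: Mapping[str, ProteinRecord],
    flank: int = 2,
) -> MotifFrequencyMatrix:
    """Residue relative frequencies around unique called (protein, position) sites.

    Windows truncated at protein termini contribute only their existing
    offsets (per-offset denominators). Canonical/noncanonical counts refer
    to unique sites, matching how motif totals are reported.
    """
    offsets = list(range(-flank, flank + 1))
    residues = sorted("ACDEFGHIKLMNPQRSTVWY")
    counts = pd.DataFrame(0, index=offsets, columns=residues, dtype=float)
    n_canon = 0
    n_noncanon = 0
    if len(calls):
        sites = calls.drop_duplicates(["protein_id", "protein_position"])
        for row in sites.itertuples(index=False):
            prot = proteins[row.protein_id]
            n_canon += bool(row.canonical)
            n_noncanon += not row.canonical
            for off in offsets:
                idx = row.protein_position - 1 + off
                if 0 <= idx < len(prot.sequence):
                    counts.loc[off, prot.sequence[idx]] += 1
    denom = counts.sum(axis=1)
    freqs = counts.div(denom.replace(0, np.nan), axis=0).fillna(0.0)
    freqs.index.name = "offset"
    return MotifFrequencyMatrix(
        flank=flank,
        frequencies=freqs,
        n_canonical=n_canon,
        n_noncanonical=n_noncanon,
    )


def tally_identifications(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts of N-glycosites, N-glycopeptides and N-glycoproteins per group.

    A glycosite is a unique (protein, position); a glycopeptide a unique
    accepted (sequence, deamidation positions) combination; a glycoprotein a
    protein with >= 1 called site. Each is counted once per
    (genotype, treatment) group regardless of replicate multiplicity. The
    final row tallies the whole experiment.
    """
    def _count(df: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "n_glycosites": df.drop_duplicates(
                    ["protein_id", "protein_position"]
                ).shape[0],
                "n_glycopeptides": df.drop_duplicates(
                    ["peptide_sequence", "deamidated_positions"]
                ).shape[0],
                "n_glycoproteins": df["protein_id"].nunique(),
            }
        )

    if calls.empty:
        return pd.DataFrame(
            columns=[
                "genotype",
                "treatment",
                "n_glycosites",
                "n_glycopeptides",
                "n_glycoproteins",
            ]
        )
    per_group = (
        calls.groupby(["genotype", "treatment"], sort=True)
        .apply(_count, include_groups=False)
        .reset_index()
    )
    total = _count(calls)
    total_row = pd.DataFrame(
        [{"genotype": "all", "treatment": "all", **total.to_dict()}]
    )
    return pd.concat([per_group, total_row], ignore_index=True)
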