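"""Synthetic proteome + glycopeptide evidence with ground truth.

Emulates the statistical structure of a lectin-enriched, PNGase F/H2^18O
label-free N-glycoproteomics experiment on a 3 genotypes (WT and two
glycan-maturation mutants) x 2 treatments (control, 200 mM NaCl) x 3
replicates design:

* random protein sequences with planted canonical (N-X-S/T, X != P) and
  noncanonical glycosites;
* each site reported through its fully-cleaved tryptic covering peptide,
  with the k x 2.9890 Da heavy-deamidation mass delta plus ppm-scale noise;
* log-normal peptide intensities: log2 I = protein baseline + peptide
  ionization offset + genotype offset + treatment effect (for the
  salt-responsive fraction) + measurement noise;
* intensity-dependent logistic dropout, with a detection-odds multiplier
  per genotype loosely emulating the better lectin enrichment of
  high-mannose (mutant) glycoproteins;
* a configurable rate of light-oxygen deamidation decoy rows (+0.984 Da)
  standing in for spontaneous deamidation / O-glycopeptide contaminants.

Randomness is drawn from one pseudo-random stream per (protein), (protein,
peptide) and (protein, peptide, sample), all derived from the master seed,
so enlarging the proteome never perturbs already-generated proteins.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .glycosite_caller import write_evidence
from .proteome_model import (
    DEAMIDATION_16O_SHIFT_DA,
    DEAMIDATION_18O_SHIFT_DA,
    MassTable,
    ProteinRecord,
    peptide_mass,
    write_fasta,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "log2_sd_from_cv",
    "dropout_midpoint_for_rate",
    "simulate_proteome",
    "simulate_evidence",
    "simulate_study",
]

_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_NON_P = np.array([a for a in _ALPHABET if a != "P"])
_NON_ST = np.array([a for a in _ALPHABET if a not in "ST"])


def log2_sd_from_cv(cv: float) -> float:
    """Log2-scale SD of a log-normal variable with coefficient of variation cv."""
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if cv == 0:
        return 0.0
    return float(np.sqrt(np.log1p(cv**2)) / np.log(2))


def dropout_midpoint_for_rate(
    rate: float, baseline_log2_mean: float = 20.0, slope: float = 0.25
) -> float:
    """Logistic-dropout midpoint giving dropout probability `rate` at the
    baseline mean intensity (detection p = 1 - rate there)."""
    if not 0 < rate < 1:
        raise ValueError("rate must be in (0, 1)")
    return baseline_log2_mean - float(np.log((1 - rate) / rate)) / slope


def _default_detection_odds() -> dict[str, float]:
    # mutants carry high-mannose N-glycans that lectins (ConA) bind better
    return {"WT": 1.0, "mns1mns2": 1.3, "cgl1": 1.3}


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults are the study conditions being emulated."""

    seed: int
    n_proteins: int = 300
    length_range: tuple[int, int] = (120, 600)
    sites_lambda: float = 2.0  # Poisson mean, clipped to [1, 4] sites/protein
    noncanonical_fraction: float = 0.1
    genotypes: tuple[str, ...] = ("WT", "mns1mns2", "cgl1")
    treatments: tuple[str, ...] = ("control", "NaCl")  # (control, treated)
    n_replicates: int = 3
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.0
    responsive_fraction: float = 0.2  # per genotype
    log2fc_range: tuple[float, float] = (0.8, 3.0)  # |log2FC|, sign random
    cv: float = 0.15
    dropout_midpoint: float | None = None  # None = no dropout
    dropout_slope: float = 0.25  # gentle intensity dependence (log2 units^-1)
    genotype_detection_odds: dict[str, float] = field(
        default_factory=_default_detection_odds
    )
    mass_noise_ppm: float = 2.0
    decoy_rate: float = 0.05
    peptide_log2_sd: float = 0.8
    genotype_log2_sd: float = 0.25
    deam_shift: float = DEAMIDATION_18O_SHIFT_DA
    decoy_shift: float = DEAMIDATION_16O_SHIFT_DA
    #: sites are only planted where the covering fully-cleaved tryptic
    #: peptide has at least this many residues (search engines do not report
    #: shorter peptides, and sub-7mers are rarely proteotypic)
    min_peptide_length: int = 7

    def __post_init__(self) -> None:
        for name in ("noncanonical_fraction", "responsive_fraction", "decoy_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2 to exercise the filter")
        if len(self.treatments) != 2:
            raise ValueError("exactly two treatments (control, treated) expected")

    @property
    def control_label(self) -> str:
        return self.treatments[0]

    @property
    def treated_label(self) -> str:
        return self.treatments[1]

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["length_range"] = list(self.length_range)
        data["log2fc_range"] = list(self.log2fc_range)
        data["genotypes"] = list(self.genotypes)
        data["treatments"] = list(self.treatments)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("length_range", "log2fc_range", "genotypes", "treatments"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class GroundTruth:
    """What the generator planted, for recovery scoring.

    sites: one row per planted glycosite (protein_id, position, canonical).
    labels: per (protein, genotype) true response (responsive, true_log2fc,
        true_label in {increased, decreased, unchanged}).
    peptides: per true glycopeptide (protein_id, peptide_sequence,
        deamidated_positions, k, true_mass_delta, peptide_start).
    """

    sites: pd.DataFrame
    labels: pd.DataFrame
    peptides: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        self.sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
        self.labels.to_csv(outdir / "truth_labels.tsv", sep="\t", index=False)
        pep = self.peptides.copy()
        pep["deamidated_positions"] = pep["deamidated_positions"].map(
            lambda pos: ";".join(str(p) for p in pos)
        )
        pep.to_csv(outdir / "truth_peptides.tsv", sep="\t", index=False)


def _rng(*entropy: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _is_canonical_window(seq: np.ndarray, p0: int) -> bool:
    """p0 is the 0-based Asn index; sequence given as a char array."""
    return (
        p0 + 2 < len(seq)
        and seq[p0] == "N"
        and seq[p0 + 1] != "P"
        and seq[p0 + 2] in ("S", "T")
    )


def _plant_sites(
    seq: np.ndarray, rng: np.random.Generator, cfg: SimConfig
) -> list[tuple[int, bool]]:
    """Plant 1-4 glycosites; returns [(1-based position, canonical)]."""
    n_sites = int(np.clip(rng.poisson(cfg.sites_lambda), 1, 4))
    lo, hi = 5, len(seq) - 7  # keep full windows + margin inside the protein
    for _ in range(200):
        positions = np.sort(rng.choice(np.arange(lo, hi), n_sites, replace=False))
        if n_sites == 1 or np.min(np.diff(positions)) >= 4:
            break
    else:
        raise RuntimeError("could not place non-overlapping sites")
    sites: list[tuple[int, bool]] = []
    for p0 in positions:
        canonical = rng.random() >= cfg.noncanonical_fraction
        seq[p0] = "N"
        if canonical:
            seq[p0 + 1] = rng.choice(_NON_P)
            seq[p0 + 2] = rng.choice(("S", "T"))
        elif rng.random() < 0.5:
            seq[p0 + 1] = "P"  # X = Pro breaks the sequon
            seq[p0 + 2] = rng.choice(("S", "T"))
        else:
            seq[p0 + 1] = rng.choice(_NON_P)
            seq[p0 + 2] = rng.choice(_NON_ST)
        assert _is_canonical_window(seq, p0) == canonical
        sites.append((int(p0) + 1, bool(canonical)))
    return sites


def _segment_length_at(seq: np.ndarray, position: int) -> int:
    """Length of the fully-cleaved tryptic segment containing `position` (1-based)."""
    p0 = position - 1
    start = p0
    while start > 0 and seq[start - 1] not in ("K", "R"):
        start -= 1
    end = p0
    n = len(seq)
    while end < n - 1 and seq[end] not in ("K", "R"):
        end += 1
    return end - start + 1


def simulate_proteome(
    cfg: SimConfig,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Random proteins with planted sequons; deterministic given the seed.

    A protein draw is resampled (bounded retries) when any planted site's
    covering tryptic peptide would fall below the reportable minimum length.
    """
    proteins: list[ProteinRecord] = []
    site_rows: list[dict] = []
    for i in range(cfg.n_proteins):
        rng = _rng(cfg.seed, 0, i)
        for _attempt in range(100):
            length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
            seq = rng.choice(_ALPHABET, size=length)
            sites = _plant_sites(seq, rng, cfg)
            if all(
                _segment_length_at(seq, pos) >= cfg.min_peptide_length
                for pos, _ in sites
            ):
                break
        else:
            raise RuntimeError(
                "could not generate a protein whose glycopeptides reach "
                f"min_peptide_length={cfg.min_peptide_length}"
            )
        pid = f"SYN{i:05d}"
        proteins.append(
            ProteinRecord(
                id=pid,
                sequence="".join(seq),
                description=f"synthetic protein {i}",
            )
        )
        for pos, canonical in sites:
            site_rows.append(
                dict(protein_id=pid, position=pos, canonical=canonical)
            )
    sites_df = pd.DataFrame(site_rows, columns=["protein_id", "position", "canonical"])
    return proteins, sites_df


def _covering_peptides(
    protein: ProteinRecord, site_positions: Sequence[int]
) -> list[tuple[str, int, tuple[int, ...]]]:
    """Group sites by their fully-cleaved tryptic covering peptide.

    Returns [(peptide_sequence, 1-based start, relative deamidated
    positions)] with sites sharing a segment merged into one multi-site
    peptide.
    """
    seq = protein.sequence
    bounds = [0]
    for i, aa in enumerate(seq):
        if aa in "KR" and i + 1 < len(seq):
            bounds.append(i + 1)
    bounds.append(len(seq))
    out: dict[int, list[int]] = {}
    seg_of: dict[int, int] = {}
    for pos in site_positions:
        idx = np.searchsorted(bounds, pos - 1, side="right") - 1
        out.setdefault(idx, []).append(pos)
        seg_of[idx] = idx
    results = []
    for idx, positions in sorted(out.items()):
        s, e = bounds[idx], bounds[idx + 1]
        rel = tuple(sorted(p - s for p in positions))  # 1-based within peptide
        results.append((seq[s:e], s + 1, rel))
    return results


def _detection_prob(
    log2_intensity: float, genotype: str, cfg: SimConfig
) -> float:
    if cfg.dropout_midpoint is None:
        return 1.0
    z = cfg.dropout_slope * (log2_intensity - cfg.dropout_midpoint)
    p = 1.0 / (1.0 + np.exp(-z))
    odds = p / (1.0 - p + 1e-300) * cfg.genotype_detection_odds.get(genotype, 1.0)
    return float(odds / (1.0 + odds))


def simulate_evidence(
    cfg: SimConfig,
    proteins: list[ProteinRecord],
    sites: pd.DataFrame,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the evidence table and ground-truth labels for a proteome."""
    masses = MassTable(deam_18O_shift=cfg.deam_shift)
    sigma = log2_sd_from_cv(cfg.cv)
    log2_up_threshold = float(np.log2(1.5))
    samples = [
        (g_idx, t_idx, rep)
        for g_idx in range(len(cfg.genotypes))
        for t_idx in range(2)
        for rep in range(1, cfg.n_replicates + 1)
    ]
    sites_by_protein = {
        pid: grp["position"].tolist() for pid, grp in sites.groupby("protein_id")
    }

    evidence_rows: list[dict] = []
    label_rows: list[dict] = []
    peptide_rows: list[dict] = []
    for i, protein in enumerate(proteins):
        rng_p = _rng(cfg.seed, 1, i)
        baseline = rng_p.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd)
        geno_offsets = rng_p.normal(0.0, cfg.genotype_log2_sd, len(cfg.genotypes))
        responsive = rng_p.random(len(cfg.genotypes)) < cfg.responsive_fraction
        magnitudes = rng_p.uniform(*cfg.log2fc_range, len(cfg.genotypes))
        signs = rng_p.choice((-1.0, 1.0), len(cfg.genotypes))
        log2fc = np.where(responsive, signs * magnitudes, 0.0)
        for g_idx, genotype in enumerate(cfg.genotypes):
            fc = float(log2fc[g_idx])
            if not responsive[g_idx]:
                true_label = "unchanged"
            elif fc >= log2_up_threshold:
                true_label = "increased"
            elif fc <= -log2_up_threshold:
                true_label = "decreased"
            else:  # |log2FC| below the fold threshold: responsive but sub-threshold
                true_label = "unchanged"
            label_rows.append(
                dict(
                    protein_id=protein.id,
                    genotype=genotype,
                    responsive=bool(responsive[g_idx]),
                    true_log2fc=fc,
                    true_label=true_label,
                )
            )

        covering = _covering_peptides(protein, sites_by_protein.get(protein.id, []))
        for j, (pep_seq, pep_start, rel_pos) in enumerate(covering):
            k = len(rel_pos)
            theo = peptide_mass(pep_seq, 0, masses)
            peptide_rows.append(
                dict(
                    protein_id=protein.id,
                    peptide_sequence=pep_seq,
                    deamidated_positions=rel_pos,
                    k=k,
                    true_mass_delta=k * cfg.deam_shift,
                    peptide_start=pep_start,
                )
            )
            rng_pep = _rng(cfg.seed, 2, i, j)
            pep_offset = rng_pep.normal(0.0, cfg.peptide_log2_sd)
            is_decoy_source = rng_pep.random() < cfg.decoy_rate
            for s_idx, (g_idx, t_idx, rep) in enumerate(samples):
                genotype = cfg.genotypes[g_idx]
                treatment = cfg.treatments[t_idx]
                rng_s = _rng(cfg.seed, 3, i, j, s_idx)
                mu = baseline + pep_offset + geno_offsets[g_idx]
                if t_idx == 1:
                    mu += log2fc[g_idx]
                log2_int = mu + (rng_s.normal(0.0, sigma) if sigma > 0 else 0.0)
                detected = rng_s.random() < _detection_prob(log2_int, genotype, cfg)
                if detected:
                    delta = k * cfg.deam_shift
                    if cfg.mass_noise_ppm > 0:
                        delta += rng_s.normal(0.0, cfg.mass_noise_ppm * 1e-6 * theo)
                    evidence_rows.append(
                        dict(
                            peptide_sequence=pep_seq,
                            deamidated_positions=rel_pos,
                            mass_delta_da=delta,
                            genotype=genotype,
                            treatment=treatment,
                            replicate=rep,
                            intensity=float(2.0**log2_int),
                        )
                    )
                if is_decoy_source:
                    # light-oxygen deamidation contaminant of the same peptide
                    rng_d = _rng(cfg.seed, 4, i, j, s_idx)
                    d_int = mu - 2.0 + rng_d.normal(0.0, max(sigma, 0.1))
                    delta = k * cfg.decoy_shift
                    if cfg.mass_noise_ppm > 0:
                        delta += rng_d.normal(0.0, cfg.mass_noise_ppm * 1e-6 * theo)
                    evidence_rows.append(
                        dict(
                            peptide_sequence=pep_seq,
                            deamidated_positions=rel_pos,
                            mass_delta_da=delta,
                            genotype=genotype,
                            treatment=treatment,
                            replicate=rep,
                            intensity=float(2.0**d_int),
                        )
                    )

    evidence = pd.DataFrame(
        evidence_rows,
        columns=[
            "peptide_sequence",
            "deamidated_positions",
            "mass_delta_da",
            "genotype",
            "treatment",
            "replicate",
            "intensity",
        ],
    )
    truth = GroundTruth(
        sites=sites,
        labels=pd.DataFrame(
            label_rows,
            columns=[
                "protein_id",
                "genotype",
                "responsive",
                "true_log2fc",
                "true_label",
            ],
        ),
        peptides=pd.DataFrame(
            peptide_rows,
            columns=[
                "protein_id",
                "peptide_sequence",
                "deamidated_positions",
                "k",
                "true_mass_delta",
                "peptide_start",
            ],
        ),
    )
    return evidence, truth


def simulate_study(
    cfg: SimConfig, outdir: str | Path | None = None
) -> tuple[list[ProteinRecord], pd.DataFrame, GroundTruth]:
    """Full synthetic bundle; optionally written to disk (FASTA + TSVs + config)."""
    proteins, sites = simulate_proteome(cfg)
    evidence, truth = simulate_evidence(cfg, proteins, sites)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(proteins, outdir / "proteome.fasta")
        write_evidence(evidence, outdir / "evidence.tsv")
        truth.write(outdir)
        cfg.to_yaml(outdir / "sim_config.yaml")
    return proteins, evidence, truth
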