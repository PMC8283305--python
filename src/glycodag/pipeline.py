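"""End-to-end orchestration: evidence -> site calls -> quantification -> DAGs.

All tabular outputs are TSV (UTF-8, header row, empty field = missing) so
runs can be diffed bit-for-bit; a JSON manifest records the configuration,
package version and row counts in/out of every stage.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .differential_abundance import (
    LABEL_DECREASED,
    LABEL_INCREASED,
    LABEL_UNCHANGED,
    Thresholds,
    dag_table,
    overlap_analysis,
    presence_absence,
    replicate_qc,
)
from .glycosite_caller import (
    ProteinIndex,
    call_glycosites,
    motif_census,
    read_evidence,
)
from .proteome_model import MassTable, read_fasta
from .quantification import (
    ibaq,
    peptide_condition_abundance,
    peptide_table,
    protein_abundance_unique_mean,
    protein_replicate_abundance,
)
from .glycosite_caller import tally_identifications

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "summary_table", "export_sets"]

logger = logging.getLogger(__name__)


class PipelineValidationError(ValueError):
    """Invalid input or configuration (CLI exit code 2)."""


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of the pipeline, with the published defaults.

    max_missed=2, tol_ppm=10, min_reps=2, up/down=1.5/0.67 (inclusive) and
    alpha=0.05 are the search/acceptance settings of the study design being
    reproduced; everything is overridable.
    """

    fasta: str = ""
    evidence: str = ""
    outdir: str = ""
    genotypes: tuple[str, ...] = ()  # empty = accept whatever the evidence has
    control_label: str = "control"
    treated_label: str = "NaCl"
    max_missed: int = 2
    tol_ppm: float = 10.0
    min_reps: int = 2
    up: float = 1.5
    down: float = 0.67
    alpha: float = 0.05
    inclusive_thresholds: bool = True
    quant_method: str = "unique_mean"  # or "ibaq"
    test: str = "welch"  # or "student"
    flank: int = 2
    qc_floor: float = 0.6
    deam_shift: float = 2.9890
    ibaq_min_len: int = 7
    ibaq_max_len: int = 30

    def __post_init__(self) -> None:
        if self.quant_method not in ("unique_mean", "ibaq"):
            raise PipelineValidationError(
                f"unknown quant_method {self.quant_method!r}"
            )
        if self.test not in ("welch", "student"):
            raise PipelineValidationError(f"unknown test {self.test!r}")

    def thresholds(self) -> Thresholds:
        return Thresholds(
            up=self.up,
            down=self.down,
            alpha=self.alpha,
            inclusive=self.inclusive_thresholds,
        )

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["genotypes"] = list(self.genotypes)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "genotypes" in data:
            data["genotypes"] = tuple(data["genotypes"])
        return cls(**data)


@dataclass
class PipelineResult:
    config: PipelineConfig
    calls: pd.DataFrame
    audit: dict
    motif_frequencies: pd.DataFrame
    motif_counts: dict
    tally: pd.DataFrame
    peptides: pd.DataFrame
    dag_proteins: pd.DataFrame
    dag_peptides: pd.DataFrame
    presence: pd.DataFrame
    qc: pd.DataFrame
    overlap: pd.DataFrame
    summary: pd.DataFrame
    sets: dict = field(default_factory=dict)


def _validate_design(evidence: pd.DataFrame, cfg: PipelineConfig) -> None:
    labels = set(evidence["treatment"].unique())
    allowed = {cfg.control_label, cfg.treated_label}
    if not labels <= allowed:
        bad = labels - allowed
        row = int(evidence.index[evidence["treatment"].isin(bad)][0])
        raise PipelineValidationError(
            f"unknown treatment label(s) {sorted(bad)} (first at evidence row "
            f"{row}); expected {sorted(allowed)}"
        )
    if cfg.genotypes:
        genos = set(evidence["genotype"].unique())
        if not genos <= set(cfg.genotypes):
            bad = genos - set(cfg.genotypes)
            row = int(evidence.index[evidence["genotype"].isin(bad)][0])
            raise PipelineValidationError(
                f"unknown genotype label(s) {sorted(bad)} (first at evidence "
                f"row {row}); expected {sorted(cfg.genotypes)}"
            )


def summary_table(
    dag_proteins: pd.DataFrame, dag_peptides: pd.DataFrame
) -> pd.DataFrame:
    """Per-genotype quantified/regulated counts at peptide and protein level.

    "Quantified" = ids with a numeric ratio (quantifiable in both
    conditions); regulated counts split increased/decreased.
    """
    quant_labels = [LABEL_INCREASED, LABEL_DECREASED, LABEL_UNCHANGED]

    def _counts(dag: pd.DataFrame, prefix: str) -> pd.DataFrame:
        quant = dag[dag["label"].isin(quant_labels)]
        g = quant.groupby("genotype")
        out = pd.DataFrame(
            {
                f"{prefix}_quantified": g.size(),
                f"{prefix}_increased": g["label"].apply(
                    lambda s: int((s == LABEL_INCREASED).sum())
                ),
                f"{prefix}_decreased": g["label"].apply(
                    lambda s: int((s == LABEL_DECREASED).sum())
                ),
            }
        )
        return out

    pep = _counts(dag_peptides, "peptides")
    prot = _counts(dag_proteins, "proteins")
    out = pep.join(prot, how="outer").fillna(0).astype(int)
    out.index.name = "genotype"
    return out.sort_index().reset_index()


def export_sets(
    dag_proteins: pd.DataFrame,
    overlap: pd.DataFrame,
    outdir: str | Path | None = None,
) -> dict[str, list[str]]:
    """Plain id lists per (genotype, direction) and per Venn region.

    Suitable for upload to external GO/KEGG/STRING services. Ids are unique
    and lexicographically sorted; empty categories still yield (empty)
    entries so the interface is stable.
    """
    sets: dict[str, list[str]] = {}
    genotypes = sorted(dag_proteins["genotype"].unique()) if len(dag_proteins) else []
    for geno in genotypes:
        sub = dag_proteins[dag_proteins["genotype"] == geno]
        for direction, lab in (
            ("increased", LABEL_INCREASED),
            ("decreased", LABEL_DECREASED),
        ):
            ids = sorted(sub.loc[sub["label"] == lab, "protein_id"].unique())
            sets[f"{geno}_{direction}"] = ids
    for row in overlap.itertuples(index=False):
        name = "overlap_" + row.genotypes.replace("&", "_")
        ids = sorted(i for i in row.exclusive_ids.split(";") if i)
        sets[name] = ids
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, ids in sets.items():
            (outdir / f"{name}.txt").write_text(
                "".join(f"{i}\n" for i in ids)
            )
    return sets


def _regulated_sets(dag_proteins: pd.DataFrame) -> dict[str, set[str]]:
    reg = dag_proteins[dag_proteins["label"].isin([LABEL_INCREASED, LABEL_DECREASED])]
    return {
        geno: set(grp["protein_id"])
        for geno, grp in reg.groupby("genotype")
    }


def run_pipeline(cfg: PipelineConfig, write: bool = True) -> PipelineResult:
    """Execute call-sites -> quantify -> differential -> report.

    Idempotent for fixed inputs and configuration: all outputs are fully
    determined by (fasta, evidence, config).
    """
    proteins = read_fasta(cfg.fasta)
    protein_map = {p.id: p for p in proteins}
    evidence = read_evidence(cfg.evidence)
    if len(evidence):
        _validate_design(evidence, cfg)
    else:
        logger.warning("evidence table %s is empty; outputs will be empty", cfg.evidence)

    masses = MassTable(deam_18O_shift=cfg.deam_shift)
    index = ProteinIndex(proteins, max_missed=cfg.max_missed)
    calls, audit = call_glycosites(evidence, index, masses, cfg.tol_ppm)
    logger.info(
        "glycosite calling: %d evidence rows -> %d accepted, %d rejected, %d unmapped",
        audit["n_evidence_rows"], audit["n_accepted"], audit["n_rejected"],
        audit["n_unmapped"],
    )
    motif = motif_census(calls, protein_map, flank=cfg.flank)
    tally = tally_identifications(calls)

    peptides = peptide_table(calls)
    pep_cond = peptide_condition_abundance(peptides, cfg.min_reps)
    if cfg.quant_method == "ibaq":
        prot_rep = ibaq(
            peptides, protein_map, cfg.min_reps, cfg.ibaq_min_len, cfg.ibaq_max_len
        )
        prot_cond = (
            prot_rep.groupby(["protein_id", "genotype", "treatment"], sort=False)[
                "abundance"
            ]
            .mean()
            .reset_index()
        )
    else:
        prot_cond = protein_abundance_unique_mean(peptides, cfg.min_reps)
        prot_rep = protein_replicate_abundance(peptides, cfg.min_reps)
    logger.info(
        "quantification (%s): %d peptide-group rows, %d protein-condition rows",
        cfg.quant_method, len(pep_cond), len(prot_cond),
    )

    thresholds = cfg.thresholds()
    dag_prot = dag_table(
        prot_cond,
        prot_rep,
        cfg.control_label,
        cfg.treated_label,
        thresholds,
        cfg.test,
        id_col="protein_id",
    )
    # peptide-level classification: replicate values are the observed
    # intensities of the accepted peptide itself
    obs = peptides[peptides["intensity"] > 0].merge(
        pep_cond[["peptide_key", "genotype", "treatment"]].drop_duplicates(),
        on=["peptide_key", "genotype", "treatment"],
    )
    pep_rep = obs.rename(columns={"intensity": "abundance"})[
        ["peptide_key", "genotype", "treatment", "replicate", "abundance"]
    ]
    dag_pep = dag_table(
        pep_cond.rename(columns={"abundance": "abundance"})[
            ["peptide_key", "genotype", "treatment", "abundance"]
        ],
        pep_rep,
        cfg.control_label,
        cfg.treated_label,
        thresholds,
        cfg.test,
        id_col="peptide_key",
    )
    presence = presence_absence(dag_prot, id_col="protein_id")
    qc = replicate_qc(peptides, floor=cfg.qc_floor)
    overlap = overlap_analysis(_regulated_sets(dag_prot)) if len(dag_prot) else (
        pd.DataFrame(
            columns=[
                "genotypes", "n_genotypes", "n_intersection", "n_exclusive",
                "intersection_ids", "exclusive_ids",
            ]
        )
    )
    summary = summary_table(dag_prot, dag_pep)
    sets = export_sets(
        dag_prot,
        overlap,
        Path(cfg.outdir) / "sets" if (write and cfg.outdir) else None,
    )

    result = PipelineResult(
        config=cfg,
        calls=calls,
        audit=audit,
        motif_frequencies=motif.frequencies,
        motif_counts={
            "canonical": motif.n_canonical,
            "noncanonical": motif.n_noncanonical,
        },
        tally=tally,
        peptides=peptides,
        dag_proteins=dag_prot,
        dag_peptides=dag_pep,
        presence=presence,
        qc=qc,
        overlap=overlap,
        summary=summary,
        sets=sets,
    )
    if write and cfg.outdir:
        _write_outputs(result)
    return result


def _config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_outputs(result: PipelineResult) -> None:
    outdir = Path(result.config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    calls = result.calls.copy()
    if len(calls):
        calls["deamidated_positions"] = calls["deamidated_positions"].map(
            lambda pos: ";".join(str(p) for p in pos)
        )
    calls.to_csv(outdir / "glycosite_calls.tsv", sep="\t", index=False)
    result.motif_frequencies.to_csv(outdir / "motif_frequencies.csv")
    result.tally.to_csv(outdir / "identification_tally.tsv", sep="\t", index=False)
    result.dag_proteins.to_csv(outdir / "dag_proteins.tsv", sep="\t", index=False)
    result.dag_peptides.to_csv(outdir / "dag_peptides.tsv", sep="\t", index=False)
    result.presence.to_csv(outdir / "presence_absence.tsv", sep="\t", index=False)
    result.qc.to_csv(outdir / "replicate_qc.tsv", sep="\t", index=False)
    result.overlap.to_csv(outdir / "overlap.tsv", sep="\t", index=False)
    result.summary.to_csv(outdir / "summary_table.tsv", sep="\t", index=False)

    manifest = {
        "package": "glycodag",
        "version": __version__,
        "config": dataclasses.asdict(result.config),
        "config_hash": _config_hash(result.config),
        "stage_counts": {
            **result.audit,
            "n_calls": int(len(result.calls)),
            "n_peptide_rows": int(len(result.peptides)),
            "n_dag_proteins": int(len(result.dag_proteins)),
            "n_dag_peptides": int(len(result.dag_peptides)),
            "n_presence_rows": int(len(result.presence)),
            "motif_counts": result.motif_counts,
        },
        "coordinate_convention": "1-based inclusive protein coordinates",
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=list) + "\n"
    )
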