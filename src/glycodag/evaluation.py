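"""End-to-end benchmark studies against generator ground truth.

Each study simulates a full synthetic experiment, writes it to disk, runs
the complete pipeline on the files, and scores the output against what the
generator planted: false-positive rate under the null, sensitivity and
specificity with planted effects, and exactness in the noise-free limit.
"""
from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .differential_abundance import LABEL_DECREASED, LABEL_INCREASED
from .pipeline import PipelineConfig, PipelineResult, run_pipeline
from .synthetic_data import (
    GroundTruth,
    SimConfig,
    dropout_midpoint_for_rate,
    simulate_study,
)

__all__ = [
    "run_study",
    "null_false_positive_rate",
    "recovery_metrics",
    "zero_noise_exactness",
]

_REGULATED = (LABEL_INCREASED, LABEL_DECREASED)


def run_study(
    sim: SimConfig, workdir: str | Path | None = None, **pipeline_kwargs
) -> tuple[PipelineResult, GroundTruth]:
    """Simulate a study to disk and run the full pipeline on the files."""
    if workdir is None:
        with tempfile.TemporaryDirectory() as tmp:
            return run_study(sim, tmp, **pipeline_kwargs)
    workdir = Path(workdir)
    _, _, truth = simulate_study(sim, workdir)
    cfg = PipelineConfig(
        fasta=str(workdir / "proteome.fasta"),
        evidence=str(workdir / "evidence.tsv"),
        outdir="",
        **pipeline_kwargs,
    )
    result = run_pipeline(cfg, write=False)
    return result, truth


def null_false_positive_rate(
    seed: int, n_proteins: int = 2000, cv: float = 0.15
) -> dict:
    """Fraction of (protein, genotype) tests labeled regulated when no
    protein truly responds (responsive fraction 0)."""
    sim = SimConfig(seed=seed, n_proteins=n_proteins, responsive_fraction=0.0, cv=cv)
    result, _ = run_study(sim)
    dag = result.dag_proteins
    tested = dag[dag["ratio"].notna()]
    n = len(tested)
    n_fp = int(tested["label"].isin(_REGULATED).sum())
    return {
        "fraction_regulated": n_fp / n if n else 0.0,
        "n_tests": n,
        "nominal_alpha": 0.05,
        "binomial_3se": 3 * np.sqrt(0.05 * 0.95 / n) if n else np.nan,
    }


def recovery_metrics(
    seed: int,
    n_proteins: int = 500,
    responsive_fraction: float = 0.2,
    log2_effect: float = 2.0,  # 4-fold
    cv: float = 0.1,
    dropout_rate: float = 0.05,
) -> dict:
    """End-to-end sensitivity/specificity of DAG calls vs planted effects.

    Sensitivity requires the correct direction (a truly increased protein
    labeled decreased counts as a miss); truly unchanged pairs that end up
    unquantified or presence-only count as non-regulated (correct) for
    specificity.
    """
    sim = SimConfig(
        seed=seed,
        n_proteins=n_proteins,
        responsive_fraction=responsive_fraction,
        log2fc_range=(log2_effect, log2_effect),
        cv=cv,
        dropout_midpoint=dropout_midpoint_for_rate(dropout_rate)
        if dropout_rate > 0
        else None,
    )
    result, truth = run_study(sim)
    pred = {
        (r.protein_id, r.genotype): r.label
        for r in result.dag_proteins.itertuples(index=False)
    }
    tp = fn = tn = fp = 0
    for row in truth.labels.itertuples(index=False):
        label = pred.get((row.protein_id, row.genotype), "unquantified")
        if row.true_label in _REGULATED:
            if label == row.true_label:
                tp += 1
            else:
                fn += 1
        else:
            if label in _REGULATED:
                fp += 1
            else:
                tn += 1
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
        "n_responsive": tp + fn,
        "n_null": tn + fp,
    }


def zero_noise_exactness(seed: int, n_proteins: int = 150) -> dict:
    """In the noise-free limit the pipeline must reproduce the ground truth
    exactly: every evidence row accepted, the called site set identical to
    the planted one (including canonical flags), no presence/absence
    exclusives, and the regulated summary equal to a recount of true labels.
    """
    sim = SimConfig(
        seed=seed,
        n_proteins=n_proteins,
        cv=0.0,
        mass_noise_ppm=0.0,
        decoy_rate=0.0,
        dropout_midpoint=None,
    )
    result, truth = run_study(sim)

    called = set(
        map(
            tuple,
            result.calls.drop_duplicates(["protein_id", "protein_position"])[
                ["protein_id", "protein_position", "canonical"]
            ].itertuples(index=False),
        )
    )
    planted = set(map(tuple, truth.sites.itertuples(index=False)))

    truth_counts = (
        truth.labels.groupby("genotype")["true_label"]
        .value_counts()
        .unstack(fill_value=0)
    )
    summary = result.summary.set_index("genotype")
    summary_matches = True
    for geno in truth_counts.index:
        want_up = int(truth_counts.loc[geno].get("increased", 0))
        want_down = int(truth_counts.loc[geno].get("decreased", 0))
        got_up = int(summary.loc[geno, "proteins_increased"])
        got_down = int(summary.loc[geno, "proteins_decreased"])
        if (got_up, got_down) != (want_up, want_down):
            summary_matches = False
    all_quantified = bool(
        (summary["proteins_quantified"] == n_proteins).all()
    )
    return {
        "all_rows_accepted": result.audit["n_rejected"] == 0
        and result.audit["n_unmapped"] == 0,
        "sites_exact": called == planted,
        "n_sites_called": len(called),
        "n_sites_planted": len(planted),
        "presence_lists_empty": len(result.presence) == 0,
        "summary_matches_truth": summary_matches,
        "all_proteins_quantified": all_quantified,
    }
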