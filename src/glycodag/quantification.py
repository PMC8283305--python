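"""Peptide-to-protein label-free quantification.

Two aggregation routes are produced side by side:

* ``unique_mean`` — the abundance of each glycoprotein in a condition is the
  arithmetic mean, over its unique (proteotypic) glycopeptides, of the
  peptide's mean intensity across observed replicates; a single-peptide
  protein inherits that peptide's profile directly.
* ``ibaq`` — intensity-based absolute quantification: summed accepted
  peptide intensity per sample divided by the protein's count of observable
  fully-cleaved tryptic peptides (length 7-30).

A glycopeptide is quantifiable within a (genotype, treatment) group only if
it was observed in at least ``min_reps`` independent replicates there (the
replicate-acceptance rule); the decision is made group-wise, so a peptide
can be quantifiable under control and not under salt. Missing intensities
are treated as absence, never imputed as zeros.
"""
from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .proteome_model import ProteinRecord, observable_peptide_count

__all__ = [
    "peptide_key",
    "peptide_table",
    "replicate_filter",
    "peptide_condition_abundance",
    "protein_abundance_unique_mean",
    "protein_replicate_abundance",
    "ibaq",
]

logger = logging.getLogger(__name__)

GROUP_COLS = ["genotype", "treatment"]


def peptide_key(sequence: str, deamidated_positions: tuple[int, ...]) -> str:
    """Deamidation-position-resolved peptide identity."""
    return sequence + "|" + ";".join(str(p) for p in deamidated_positions)


def peptide_table(calls: pd.DataFrame) -> pd.DataFrame:
    """Collapse site-level calls to one row per (peptide, protein, sample).

    Multi-site peptides appear once per sample here; the ``unique`` flag
    (peptide maps to exactly one database protein) is carried along because
    only unique peptides enter protein abundance.
    """
    if calls.empty:
        return pd.DataFrame(
            columns=[
                "peptide_key",
                "peptide_sequence",
                "protein_id",
                "unique",
                "genotype",
                "treatment",
                "replicate",
                "intensity",
            ]
        )
    df = calls.copy()
    df["peptide_key"] = [
        peptide_key(s, p)
        for s, p in zip(df["peptide_sequence"], df["deamidated_positions"])
    ]
    df = df.drop_duplicates(
        ["peptide_key", "protein_id", "genotype", "treatment", "replicate"]
    )
    return df[
        [
            "peptide_key",
            "peptide_sequence",
            "protein_id",
            "unique",
            "genotype",
            "treatment",
            "replicate",
            "intensity",
        ]
    ].reset_index(drop=True)


def replicate_filter(peptides: pd.DataFrame, min_reps: int = 2) -> pd.DataFrame:
    """Group-wise replicate-acceptance rule.

    Returns one row per (peptide_key, protein_id, genotype, treatment) with
    ``n_observed`` (replicates with intensity > 0) and ``accepted``
    (n_observed >= min_reps). Adding an observation can only turn rejected
    into accepted, never the reverse.
    """
    if min_reps < 1:
        raise ValueError("min_reps must be >= 1")
    if peptides.empty:
        return pd.DataFrame(
            {
                "peptide_key": pd.Series(dtype=str),
                "protein_id": pd.Series(dtype=str),
                "genotype": pd.Series(dtype=str),
                "treatment": pd.Series(dtype=str),
                "n_observed": pd.Series(dtype=int),
                "accepted": pd.Series(dtype=bool),
            }
        )
    obs = peptides[peptides["intensity"] > 0]
    counts = (
        obs.groupby(["peptide_key", "protein_id", *GROUP_COLS], sort=False)
        .size()
        .rename("n_observed")
        .reset_index()
    )
    counts["accepted"] = counts["n_observed"] >= min_reps
    return counts


def peptide_condition_abundance(
    peptides: pd.DataFrame, min_reps: int = 2
) -> pd.DataFrame:
    """Condition-level peptide abundance: mean over observed replicates.

    Only peptides passing the replicate rule in that group are retained.
    """
    accepted = replicate_filter(peptides, min_reps)
    accepted = accepted[accepted["accepted"]]
    obs = peptides[peptides["intensity"] > 0]
    means = (
        obs.groupby(["peptide_key", "protein_id", "unique", *GROUP_COLS], sort=False)[
            "intensity"
        ]
        .mean()
        .rename("abundance")
        .reset_index()
    )
    out = means.merge(
        accepted[["peptide_key", "protein_id", *GROUP_COLS, "n_observed"]],
        on=["peptide_key", "protein_id", *GROUP_COLS],
        how="inner",
    )
    return out


def protein_abundance_unique_mean(
    peptides: pd.DataFrame, min_reps: int = 2
) -> pd.DataFrame:
    """Condition-level protein abundance by unique-peptide averaging.

    The mean is over the protein's accepted unique peptides of their
    replicate-mean intensities; shared (non-proteotypic) peptides never
    contribute. Proteins with no accepted unique peptide in a condition are
    simply absent from the result for that condition.
    """
    pep = peptide_condition_abundance(peptides, min_reps)
    pep = pep[pep["unique"]]
    if pep.empty:
        return pd.DataFrame(
            columns=["protein_id", *GROUP_COLS, "abundance", "n_peptides"]
        )
    out = (
        pep.groupby(["protein_id", *GROUP_COLS], sort=False)
        .agg(abundance=("abundance", "mean"), n_peptides=("abundance", "size"))
        .reset_index()
    )
    return out


def protein_replicate_abundance(
    peptides: pd.DataFrame, min_reps: int = 2
) -> pd.DataFrame:
    """Replicate-level protein abundance (unique-peptide mean per replicate).

    For each replicate, the protein's abundance is the mean intensity of its
    accepted unique peptides observed in that replicate. These replicate
    values feed the significance test; the condition-level ratio itself uses
    ``protein_abundance_unique_mean``.
    """
    accepted = replicate_filter(peptides, min_reps)
    accepted = accepted[accepted["accepted"]]
    obs = peptides[(peptides["intensity"] > 0) & peptides["unique"]]
    obs = obs.merge(
        accepted[["peptide_key", "protein_id", *GROUP_COLS]],
        on=["peptide_key", "protein_id", *GROUP_COLS],
        how="inner",
    )
    if obs.empty:
        return pd.DataFrame(
            columns=["protein_id", *GROUP_COLS, "replicate", "abundance"]
        )
    out = (
        obs.groupby(["protein_id", *GROUP_COLS, "replicate"], sort=False)["intensity"]
        .mean()
        .rename("abundance")
        .reset_index()
    )
    return out


def ibaq(
    peptides: pd.DataFrame,
    proteins: Mapping[str, ProteinRecord],
    min_reps: int = 2,
    min_len: int = 7,
    max_len: int = 30,
) -> pd.DataFrame:
    """iBAQ protein abundance per sample.

    iBAQ = (sum of accepted unique peptide intensities in the sample) /
    (number of theoretically observable fully-cleaved tryptic peptides of
    length [min_len, max_len]). Proteins with no observable peptide are
    excluded with a warning.
    """
    accepted = replicate_filter(peptides, min_reps)
    accepted = accepted[accepted["accepted"]]
    obs = peptides[(peptides["intensity"] > 0) & peptides["unique"]]
    obs = obs.merge(
        accepted[["peptide_key", "protein_id", *GROUP_COLS]],
        on=["peptide_key", "protein_id", *GROUP_COLS],
        how="inner",
    )
    if obs.empty:
        return pd.DataFrame(
            columns=["protein_id", *GROUP_COLS, "replicate", "abundance"]
        )
    sums = (
        obs.groupby(["protein_id", *GROUP_COLS, "replicate"], sort=False)["intensity"]
        .sum()
        .rename("summed_intensity")
        .reset_index()
    )
    denoms: dict[str, int] = {}
    for pid in sums["protein_id"].unique():
        n_obs = observable_peptide_count(proteins[pid], min_len, max_len)
        if n_obs == 0:
            logger.warning(
                "protein %s has no observable %d-%dmer tryptic peptide; "
                "excluded from iBAQ",
                pid,
                min_len,
                max_len,
            )
        denoms[pid] = n_obs
    sums["observable_count"] = sums["protein_id"].map(denoms)
    sums = sums[sums["observable_count"] > 0].copy()
    sums["abundance"] = sums["summed_intensity"] / sums["observable_count"]
    return sums[
        ["protein_id", *GROUP_COLS, "replicate", "abundance"]
    ].reset_index(drop=True)
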