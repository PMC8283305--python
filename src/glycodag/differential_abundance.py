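"""Salt-response ratios, significance and DAG classification.

Per genotype, each glycoprotein (or glycopeptide) quantifiable in both the
control and salt-treated condition receives a treated/control abundance
ratio, an SD over replicate-level ratios, and a two-sided p-value from a
two-sample test on log2 replicate abundances (Welch's t by default). A
protein is classified ``increased`` when ratio >= 1.5 and p < 0.05,
``decreased`` when ratio <= 0.67 and p < 0.05, else ``unchanged``
(thresholds, alpha and inclusivity configurable). Proteins quantifiable in
exactly one condition are routed to the qualitative presence/absence lists
instead of the ratio table; no multiple-testing correction is applied by
default, but a Benjamini-Hochberg FDR column is emitted alongside.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Thresholds",
    "compute_ratio",
    "classify",
    "dag_table",
    "presence_absence",
    "replicate_qc",
    "overlap_analysis",
]

LABEL_INCREASED = "increased"
LABEL_DECREASED = "decreased"
LABEL_UNCHANGED = "unchanged"
LABEL_ONLY_TREATED = "present_only_treated"
LABEL_ONLY_CONTROL = "present_only_control"
LABEL_ABSENT = "absent"


@dataclass(frozen=True)
class Thresholds:
    """Fold-change and significance thresholds for DAG classification."""

    up: float = 1.5
    down: float = 0.67
    alpha: float = 0.05
    inclusive: bool = True  # ratio >= up / <= down vs strict > / <


def compute_ratio(
    control_reps: np.ndarray,
    treated_reps: np.ndarray,
    control_abundance: float,
    treated_abundance: float,
    test: str = "welch",
) -> tuple[float, float, float]:
    """Treated/control ratio, replicate-ratio SD, and p-value.

    The ratio divides the condition-level abundances; the p-value comes from
    a two-sided two-sample test on log2 replicate abundances (``welch`` or
    ``student``); ratio_sd is the SD (ddof=1) of per-replicate ratios
    treated_r / mean(control). With zero variance on both sides the t
    statistic is undefined: p is 0.0 if the group means differ and 1.0 if
    they are identical (the noise-free limit).
    """
    control_reps = np.asarray(control_reps, dtype=float)
    treated_reps = np.asarray(treated_reps, dtype=float)
    if control_reps.size == 0 or treated_reps.size == 0:
        raise ValueError("both conditions need >= 1 replicate observation")
    if control_abundance <= 0:
        raise ValueError("control abundance must be > 0 to form a ratio")
    ratio = treated_abundance / control_abundance
    if treated_reps.size > 1:
        ratio_sd = float(np.std(treated_reps / np.mean(control_reps), ddof=1))
    else:
        ratio_sd = float("nan")
    log_c = np.log2(control_reps)
    log_t = np.log2(treated_reps)
    if np.ptp(log_c) == 0 and np.ptp(log_t) == 0:
        p = 0.0 if log_c.mean() != log_t.mean() else 1.0
    elif control_reps.size < 2 or treated_reps.size < 2:
        p = float("nan")
    else:
        p = float(
            stats.ttest_ind(log_t, log_c, equal_var=(test == "student")).pvalue
        )
    return float(ratio), ratio_sd, p


def classify(ratio: float, p_value: float, thresholds: Thresholds = Thresholds()) -> str:
    """Apply the fold-change x significance rule to one ratio."""
    t = thresholds
    sig = (p_value < t.alpha) if np.isfinite(p_value) else False
    if t.inclusive:
        up_hit, down_hit = ratio >= t.up, ratio <= t.down
    else:
        up_hit, down_hit = ratio > t.up, ratio < t.down
    if up_hit and sig:
        return LABEL_INCREASED
    if down_hit and sig:
        return LABEL_DECREASED
    return LABEL_UNCHANGED


def _quantifiable_map(condition_abundance: pd.DataFrame) -> dict:
    return {
        (r.protein_id, r.genotype, r.treatment): r.abundance
        for r in condition_abundance.itertuples(index=False)
    }


def dag_table(
    condition_abundance: pd.DataFrame,
    replicate_abundance: pd.DataFrame,
    control_label: str = "control",
    treated_label: str = "NaCl",
    thresholds: Thresholds = Thresholds(),
    test: str = "welch",
    id_col: str = "protein_id",
) -> pd.DataFrame:
    """Per-(id, genotype) differential abundance table.

    ``condition_abundance`` and ``replicate_abundance`` are the long frames
    produced by the quantification module (columns: id_col, genotype,
    treatment, [replicate,] abundance); ``id_col`` lets the same machinery
    classify glycopeptides (peptide_key) and glycoproteins (protein_id).
    Ids quantifiable in both conditions get ratio/p/label; the rest get the
    qualitative presence labels.
    """
    cond = _quantifiable_map(
        condition_abundance.rename(columns={id_col: "protein_id"})
    )
    reps: dict[tuple, np.ndarray] = {}
    ra = replicate_abundance.rename(columns={id_col: "protein_id"})
    for (pid, geno, trt), grp in ra.groupby(
        ["protein_id", "genotype", "treatment"], sort=False
    ):
        reps[(pid, geno, trt)] = grp["abundance"].to_numpy()

    ids = sorted({pid for pid, _, _ in cond})
    genotypes = sorted({g for _, g, _ in cond})
    rows = []
    for pid, geno in itertools.product(ids, genotypes):
        in_c = (pid, geno, control_label) in cond
        in_t = (pid, geno, treated_label) in cond
        if not in_c and not in_t:
            continue
        if in_c and in_t:
            ratio, sd, p = compute_ratio(
                reps[(pid, geno, control_label)],
                reps[(pid, geno, treated_label)],
                cond[(pid, geno, control_label)],
                cond[(pid, geno, treated_label)],
                test=test,
            )
            label = classify(ratio, p, thresholds)
            rows.append(
                dict(
                    protein_id=pid,
                    genotype=geno,
                    ratio=ratio,
                    ratio_sd=sd,
                    p_value=p,
                    label=label,
                )
            )
        else:
            rows.append(
                dict(
                    protein_id=pid,
                    genotype=geno,
                    ratio=np.nan,
                    ratio_sd=np.nan,
                    p_value=np.nan,
                    label=LABEL_ONLY_TREATED if in_t else LABEL_ONLY_CONTROL,
                )
            )
    out = pd.DataFrame(
        rows,
        columns=["protein_id", "genotype", "ratio", "ratio_sd", "p_value", "label"],
    )
    # optional FDR column for users; never used by the classification itself
    out["p_adj_bh"] = np.nan
    for geno, grp in out.groupby("genotype"):
        mask = grp["p_value"].notna()
        if mask.any():
            p = grp.loc[mask, "p_value"].to_numpy()
            out.loc[grp.index[mask], "p_adj_bh"] = stats.false_discovery_control(p)
    out = out.rename(columns={"protein_id": id_col})
    return out.sort_values([id_col, "genotype"]).reset_index(drop=True)


def presence_absence(dag: pd.DataFrame, id_col: str = "protein_id") -> pd.DataFrame:
    """Qualitative "exclusively detected" lists per genotype.

    An id quantifiable (per the replicate rule) in exactly one condition is
    exclusively detected there; ids quantified in both conditions are
    excluded from the qualitative comparison.
    """
    mask = dag["label"].isin([LABEL_ONLY_TREATED, LABEL_ONLY_CONTROL])
    return (
        dag.loc[mask, [id_col, "genotype", "label"]]
        .sort_values(["genotype", "label", id_col])
        .reset_index(drop=True)
    )


def replicate_qc(
    peptides: pd.DataFrame,
    floor: float = 0.6,
    min_shared: int = 3,
) -> pd.DataFrame:
    """Pairwise Pearson correlation of log2 peptide intensities per group.

    For each (genotype, treatment) and each replicate pair, r is computed
    over peptides observed (intensity > 0) in both replicates; pairs with
    fewer than ``min_shared`` shared peptides are reported with r = NaN.
    Pairs with r below ``floor`` are flagged.
    """
    rows = []
    obs = peptides[peptides["intensity"] > 0]
    for (geno, trt), grp in obs.groupby(["genotype", "treatment"], sort=True):
        wide = grp.pivot_table(
            index="peptide_key", columns="replicate", values="intensity",
            aggfunc="first",
        )
        reps = sorted(wide.columns)
        for a, b in itertools.combinations(reps, 2):
            both = wide[[a, b]].dropna()
            if len(both) < min_shared:
                r = float("nan")
            else:
                r = float(
                    stats.pearsonr(
                        np.log2(both[a].to_numpy()), np.log2(both[b].to_numpy())
                    ).statistic
                )
            rows.append(
                dict(
                    genotype=geno,
                    treatment=trt,
                    replicate_a=a,
                    replicate_b=b,
                    n_shared=len(both),
                    pearson_r=r,
                    flagged=bool(np.isnan(r) or r < floor),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "genotype",
            "treatment",
            "replicate_a",
            "replicate_b",
            "n_shared",
            "pearson_r",
            "flagged",
        ],
    )


def overlap_analysis(sets_by_genotype: dict[str, set[str]]) -> pd.DataFrame:
    """Venn-style region counts and memberships over per-genotype DAG sets.

    Every non-empty combination of genotypes defines a region: ids belonging
    to exactly those genotypes' sets. Ids within a region are sorted for
    deterministic output.
    """
    genotypes = sorted(sets_by_genotype)
    rows = []
    for r in range(1, len(genotypes) + 1):
        for combo in itertools.combinations(genotypes, r):
            inside = set.intersection(*(sets_by_genotype[g] for g in combo))
            outside = set.union(
                set(), *(sets_by_genotype[g] for g in genotypes if g not in combo)
            )
            exclusive = inside - outside
            rows.append(
                dict(
                    genotypes="&".join(combo),
                    n_genotypes=r,
                    n_intersection=len(inside),
                    n_exclusive=len(exclusive),
                    intersection_ids=";".join(sorted(inside)),
                    exclusive_ids=";".join(sorted(exclusive)),
                )
            )
    return pd.DataFrame(rows)
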