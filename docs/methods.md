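# Methods

## The identification model

N-glycans attach to Asn within the sequon N-X-S/T (X ≠ P). Enzymatic
deglycosylation with PNGase F converts the glycosylated Asn to Asp; carried
out in heavy water (H₂¹⁸O) the reaction incorporates ¹⁸O, so each formerly
glycosylated Asn raises the peptide's monoisotopic mass by 2.9890 Da. This
is the discriminating signature: spontaneous deamidation in normal water
adds only +0.984016 Da, and O-glycopeptides or unmodified peptides that
survive lectin enrichment carry no shift at all.

`validate_signature` accepts an evidence row iff

|Δm − k·2.9890| ≤ tol_ppm · 10⁻⁶ · M_peptide,  k ≥ 1,

where k is the number of annotated deamidated Asn, Δm the observed mass
delta and M the theoretical unmodified monoisotopic mass. The tolerance is
relative (ppm) because instrument mass error scales with m/z; the default
10 ppm is the precursor tolerance such evidence is searched with. Acceptance
is monotone in the tolerance. Note 2.9890 Da is the conventional printed
constant; the value derived from atomic masses is ≈ 2.98826 Da. The
difference (0.7 mDa) is far below any realistic tolerance; the constant is a
`MassTable` field and can be swapped.

Peptide masses are sums of standard monoisotopic residue masses (from
pyteomics) plus one water (18.010565 Da) plus k × shift. Digestion follows
Trypsin/P — cleave C-terminal to every K and R with **no** proline
exception — with up to `max_missed` (default 2) internal missed cleavages.
Coordinates are 1-based inclusive everywhere.

Accepted peptides are mapped back to proteins through an index of all
tryptic peptides (≤ max_missed) of the database, with an exhaustive
substring fallback for out-of-rule peptides. The canonical/noncanonical
flag of a called site comes from the protein-level sequon scan, not the
peptide, so a sequon whose S/T lies in the next tryptic peptide is
classified correctly. Peptides matching more than one protein are flagged
non-unique: they count toward site/peptide/protein identification tallies
but are excluded from all protein quantification. Noncanonical sites are
kept and flagged, never discarded — they are part of the motif census
(per-offset residue frequencies over unique sites, window ±2 by default,
termini handled by per-offset denominators).

## Quantification

A glycopeptide is quantifiable in a (genotype, treatment) group iff it has
intensity > 0 in ≥ `min_reps` (default 2) replicates; the decision is
group-wise. Missing intensities are absence, never imputed.

Protein abundance, two routes:

* **unique_mean** (default): condition-level abundance = arithmetic mean
  over the protein's accepted unique peptides of their replicate-mean
  intensities; a single-peptide protein inherits that peptide directly.
  Replicate-level protein abundance (for the significance test) is the mean
  over accepted unique peptides observed in that replicate.
* **ibaq**: per sample, summed accepted unique-peptide intensity divided by
  the count of fully-cleaved tryptic peptides of length 7–30 (the standard
  "observable" definition). Proteins with no observable peptide are
  excluded with a warning.

Both are homogeneous of degree 1 in intensities and invariant to replicate
or peptide ordering. The differential analysis defaults to unique_mean
because the reported ratio ± SD semantics are peptide-derived; the switch
is `PipelineConfig.quant_method`.

## Differential abundance

For each (protein, genotype) quantifiable in both conditions:

* ratio = treated / control condition-level abundance;
* ratio_sd = SD (ddof = 1) of per-replicate ratios treated_r / mean(control)
  — the "± SD" convention adopted here, since replicate-level ratios are
  the only well-defined dispersion for a 3 vs 3 unpaired design;
* p from a two-sided two-sample test on log2 replicate abundances. Welch's
  t is the default (unequal variances are the norm in label-free data);
  Student's t is available via config. No multiple-testing correction is
  applied to the classification (per-protein p < 0.05, as is conventional
  in this literature); a Benjamini–Hochberg column is emitted for users.

Classification: increased iff ratio ≥ 1.5 and p < α; decreased iff
ratio ≤ 0.67 and p < α (α = 0.05). Comparisons are inclusive by default
(configurable to strict). Proteins passing the replicate rule in exactly
one condition are routed to the presence/absence lists
(present_only_treated / present_only_control) and never to the ratio table,
which avoids division by a missing abundance.

Degenerate inputs: when both groups have zero variance on the log scale
(the noise-free limit of the simulator, or truly identical replicates) the
t statistic is undefined; `compute_ratio` then reports p = 0 if the group
means differ and p = 1 if they are identical. This is the limit of the test
as within-group variance → 0 and makes the noise-free pipeline exactly
reproduce planted labels. With exactly one observation on either side the
p-value is NaN and the protein is never called regulated.

Replicate QC computes pairwise Pearson r of log2 intensities over peptides
observed in both replicates of a pair (≥ 3 shared required, else NaN);
pairs below a configurable floor (default 0.6) are flagged. Overlap
analysis reports intersection and exclusive membership for every
combination of genotypes, with deterministic (sorted) id ordering.

## The synthetic-data generator

`SimConfig` defaults define the emulated study: 3 genotypes (WT, mns1mns2,
cgl1) × 2 treatments (control, NaCl) × 3 replicates; protein lengths
uniform 120–600; 1–4 planted sites per protein (Poisson λ = 2 clipped);
10% noncanonical sites; baseline log2 intensity N(20, 2); 20% of
(protein, genotype) pairs salt-responsive with |log2FC| uniform on
[0.8, 3] and random sign; measurement CV 0.15 (log2 SD = √ln(1+CV²)/ln 2);
2 ppm mass noise; 5% of peptides also emit light-deamidation decoy rows.

Structure of a simulated intensity:
log2 I = baseline(protein) + ionization offset(peptide, SD 0.8)
+ genotype offset(SD 0.25) + treatment effect (responsive proteins only)
+ N(0, σ_CV). The peptide offset models peptide-specific ionization
efficiency (why iBAQ and unique_mean disagree in rank), the genotype offset
models non-salt-related abundance differences, and both cancel from
within-genotype ratios.

Dropout is logistic in log2 intensity: p(detect) = σ(slope·(x − midpoint)),
default slope 0.25 (weak intensity dependence, typical of label-free
missingness within the quantified dynamic range) and midpoint `None` (off);
`dropout_midpoint_for_rate(r)` places the midpoint so the marginal dropout
at baseline intensity is r. Mutant genotypes get a 1.3× detection-odds
multiplier, loosely emulating the better lectin enrichment of high-mannose
glycoproteins — a detection effect only, not an abundance effect.

Sites are only planted where the covering fully-cleaved tryptic peptide has
≥ 7 residues, the conventional minimum reportable peptide length; shorter
peptides are rarely proteotypic and real evidence tables do not contain
them. Randomness uses one stream per (protein), (protein, peptide) and
(protein, peptide, sample), all derived from the master seed, so outputs
are byte-reproducible and enlarging the proteome never perturbs existing
proteins.

What the generator does **not** emulate: chromatography and spectral
realism, charge states, retention time, O-glycopeptides (represented only
by decoy rows), shared peptides between proteins (random sequences make
collisions negligible), match-between-runs, and the compressed replicate
correlations of real data — simulated QC r values are ≈ 0.99 at default
CV, whereas real label-free replicates typically fall in 0.6–0.95. Passing
tests therefore demonstrate the correctness of the pipeline's logic and
its statistical calibration under the stated model, not robustness to every
pathology of real LC-MS data.

## Benchmark studies and problem sizes

`glycodag.evaluation` runs three end-to-end studies (also exercised by the
test suite and `scripts/acceptance.py`):

* **null**: 2,000 proteins, no true effects, CV 0.15 — the fraction of
  tests labeled regulated is the empirical size of the combined
  fold + significance rule. Because regulation requires both p < 0.05 and a
  ≥ 1.5-fold observed ratio, the empirical rate is far below the nominal
  5% (≈ 0.05% at these settings).
* **recovery**: 500 proteins, 4-fold effects on 20% per genotype, CV 0.1,
  5% dropout — end-to-end sensitivity (direction-matched) and specificity
  against generator truth.
* **zero-noise**: CV = 0, no dropout, no mass noise, no decoys — site
  calls, presence lists and the regulated summary must equal ground truth
  exactly.

These sizes keep each study in the tens of seconds on one CPU while leaving
the binomial uncertainty of the measured rates well below the margins being
checked.

## Known limitations

* Mapping considers tryptic peptides with ≤ `max_missed` cleavages plus a
  substring fallback; semi-tryptic or non-specific peptides are unmapped
  (logged, excluded from tallies).
* The presence/absence comparison inherits the replicate rule; with 2 of 3
  required, a protein observed once per condition is "absent" in both.
* iBAQ here divides by observable-peptide count over *all* tryptic
  peptides of the protein, while only glycopeptides are measured after
  enrichment; iBAQ values are therefore comparable across samples within a
  protein, not across proteins — one reason unique_mean is the default for
  ratios.
* No normalization across runs is applied (none is assumed by the upstream
  design); systematic run-level intensity shifts would propagate to ratios.
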