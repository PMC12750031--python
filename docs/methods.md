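# Methods

This note documents the scoring model implemented in emakit, its
assumptions, the tunable parameters, the synthetic-data generator, and the
design choices made where the design was genuinely open.

## Structure model and PDB dialect

Structures are chain → residue → atom hierarchies with coordinates in Å and
the B-factor channel carrying pLDDT (0–100) in predicted models. The PDB
reader accepts single-model files with `ATOM` records only: HETATM and
occupancy are ignored, altlocs other than blank/'A' are dropped, and
insertion codes or non-increasing residue numbering are rejected with the
offending line number. This is the clean numbering of CASP-style
submissions; the parser is deliberately strict so that silent
misinterpretation cannot propagate into scores. The writer emits
fixed-column ATOM/TER/END with B-factors at two decimals and errors on
coordinates beyond ±9999.999 Å. mmCIF, ligands and nucleic acids are out of
scope.

Residue correspondence between model and target requires identical author
residue indices; index-matched residues with different names are flagged on
the mapping rather than silently remapped. Chain mapping first groups chains
by residue-name sequence (the same grouping that defines the stoichiometry
signature, a canonically ordered multiset of sequence classes with copy
counts). Classes with one copy map directly. Within a class of *n* copies,
every permutation (for n ≤ 4) is evaluated by its own whole-complex Kabsch
superposition on shared CA atoms and the assignment with the lowest CA RMSD
wins; above 4 copies a greedy assignment under a provisional superposition
is used. Evaluating each candidate under its own superposition matters: a
cost computed under a single provisional transform is biased toward the
provisional pairing and fails on relabeled homodimers.

## LDDT family

Parameters: inclusion radius 15 Å, thresholds {0.5, 1, 2, 4} Å,
intra-residue pairs excluded — the standard choices of the local distance
difference test. A check passes iff |d_model − d_reference| < t (strict);
the global score is passed checks over total checks, and per-atom /
per-residue scores pool the checks of all pairs touching that atom or
residue. An atom or residue with no contacts is *undefined* (`None`), never
zero. Pairs whose atoms are missing from the model fail every threshold, so
incomplete models score lower rather than being quietly truncated.
Per-residue LDDT is the fraction over the residue's pair set, not the mean
of its per-atom fractions; per-atom→per-residue *averaging* exists only in
the pLDDT module, where regraining prescribes it.

The `interchain_only` flag restricts the contact set to pairs spanning two
chains (iLDDT). The `augmented` flag adds *model-only* contacts: pairs
within the inclusion radius in the model alone whose atoms both map to
reference atoms (and are therefore covered by experimental data). Model-only
contacts are counted as unpreserved at every threshold — a pure penalty for
contacts the model hallucinates. We considered scoring them by comparing the
model distance with the true (out-of-radius) reference distance instead, but
near the radius boundary that lets some hallucinated contacts *pass*, which
contradicts the variant's purpose and breaks the invariant that the
augmented score never exceeds the standard one; the pure-penalty reading
keeps both exact. No stereochemistry checks or side-chain naming symmetry
corrections are applied (the synthetic fixtures are backbone-only).

Interface residues are those with any atom within 5 Å (heavy-atom,
configurable) of another chain; the threshold is a package default, not a
community-fixed constant. Superposition RMSD uses the Kabsch least-squares
fit on mapped CA atoms (≥ 3 pairs required).

## pLDDT self-assessment

pLDDT is read from B-factors; a vector is classified `native_per_atom` iff
any residue carries non-identical atom values. Values on a 0–1 scale are
rejected with a pointer to the `rescale_fraction` flag rather than guessed.
Regraining: per-residue = unweighted mean over the residue's atoms; per-atom
= broadcast of the residue value. Accuracy is the RMSD between predicted and
realized LDDT on the 0–100 scale over keys defined in both (undefined LDDT
keys excluded); a mean-absolute-deviation alternative is available behind
`metric="mad"` since the two were observed to rank predictors
near-identically. Ranking uses per-target two-pass Z on negated RMSD over
all five models per target. The five per-model RMSDs are averaged per
predictor before the Z by default (`mean_then_z`); Z-scoring each model slot
separately and summing (`z_per_model`) is provided because the pooling order
is a genuinely open choice.

## CASP Z-scores

`two_pass_z` implements the standard two-pass scheme: mean/sd over all
values; values below mean − k·sd dropped (k = 2 by default, 3 for the
model-selection cross-check); mean/sd recomputed on survivors; Z =
(v − mean)/sd with negatives clamped to 0; sd = 0 (or a single value) yields
all-zero Z; missing predictors contribute exactly 0. The sample (ddof = 1)
standard deviation is used; this is configurable since nothing pins it down.
Note a structural property of the screen: with n values, no single point can
lie more than √(n−1) sample standard deviations below the mean, so the
exclusion pass can only ever fire when there are enough values (n ≥ 6 for
k = 2); tests of outlier screening therefore use a dozen predictors. The
QMODE1/2 ranking score uses the *single-pass* Z exactly as its formula is
written (`two_pass=False`), while self-assessment and the QMODE3 cross-check
use the two-pass form.

## QMODE1/2 evaluation

Filters: models whose stoichiometry signature differs from the target's are
excluded; predictors must return ≥ 80% of expected data points on ≥ 80% of
targets (thresholds computed as ⌈fraction·total⌉, e.g. 240 of 300 models,
104 000 of 130 000 interface residues, 33 of 41 targets); targets are
dropped unless at least one pool model reaches 0.6 on the channel's
viability metric (TM-score for SCORE, QS-score for QSCORE/Local), boundary
inclusive.

Per-target statistics use only the models a predictor actually scored
(pairwise-complete; skipped models shrink the pair count, nothing is
imputed). Correlations need ≥ 3 pairs and defined variance; the ROC AUC
needs both classes; undefined statistics are simply absent and contribute 0
through the missing-prediction rule. For QMODE1 the AUC binarizes the
reference metric at 0.6 (the same convention as the viability threshold;
configurable) since no community-fixed label rule exists. For QMODE2 the AUC
is the true-interface classification AUC, which does not depend on the
accuracy reference metric; it enters each metric's RS identically, and the
standalone identification ranking (mean per-target AUC) is reported
separately. The top-1 loss is best_ref − ref[argmax predicted], ties in the
predicted score broken by lexicographically smallest model id; loss is
negated before the Z so that lower loss ranks higher — the only orientation
under which adding its Z to a reward-style score is coherent.

Reference metrics are split by channel: SCORE against oligo-GDTTS and
TM-score, QSCORE against QS-score and DockQ-wave, Local against LDDT, CAD,
PatchQS and PatchDockQ. Of these only the LDDT family is computed natively;
the others are consumed from external score-table TSVs, as they have
canonical implementations elsewhere. The AC consensus baseline scores a
model by its mean pairwise similarity to every other pool model; it inherits
consensus behavior — right when the majority is near-native, wrong when a
decoy cluster dominates — and both regimes are exercised in tests as
documented behavior, not universal truths.

## QMODE3 evaluation

Per category (monomer/homomer/heteromer) the criterion set is LDDT,
TM-score, QS-global, QS-best, RMSD, oligo-GDTHA, oligo-GDTTS, plus iLDDT,
IPS, ICS, DockQ-ave and DockQ-wave for oligomers; RMSD, IPS and ICS are
carried in score tables but excluded from the weighted penalty. RMSD is the
only lower-better metric and is negated before sorting.

Ranking error: pool scores and the five selected scores are each sorted
best-first and the absolute slot-wise gaps summed. Because the true slot
value is always at least as good as the selected slot value (order
statistics), the absolute value equals the signed sum for higher-better
metrics; it is kept for safety with lower-better ones and guarantees RE ≥ 0.
Selections shorter than five are rejected by default; with
`allow_short=True` each empty slot is charged the gap between the slot's
true score and the pool's worst score.

Covariance: estimated from all (target, model) rows of the category — not
just selected models — in two passes; rows whose squared Mahalanobis
distance from the pass-1 mean exceeds the χ² quantile at d degrees of
freedom (0.975 by default, configurable — "severe outlier" is not a fixed
community constant) are screened before the final estimate. Note the screen
trims the distribution's tail, so on clean Gaussian data the pass-2
variances sit a few percent below the population values; comparisons should
be made screened-vs-screened. Σ⁻¹ is the Moore–Penrose pseudo-inverse, with
an optional ridge (ε = 1e-8·trace/d) for near-singular Σ from duplicated or
near-perfectly correlated criteria; a warning is emitted when the condition
number exceeds 1e12. Per-category covariance is the default; per-target
covariance can be had by building per-target tables.

Penalties P_w = RE Σ⁻¹ REᵀ are min–max normalized across predictors per
target (best 0, worst 1; all-equal → all 0) and **averaged** over each
predictor's submitted targets — the mean, unlike the sum, is invariant to
how many targets a predictor skipped, which realizes the
no-extra-penalty-for-missing-targets rule (predictors must still cover 80%
of targets to be ranked). The cross-check ranks predictors by equal-weight
two-pass Z (k = 3) on negated REs per (criterion, target). The
best-selection analysis reports, per target, the 1-based competition rank
(tied values share the best rank) of the best model any predictor selected,
under TM-score or DockQ-ave.

## Synthetic data

Targets are helical backbone traces (CA, N, C, O per residue; α-helix
geometry: 2.3 Å radius, 1.5 Å rise, 100° turn) with random residue-name
sequences per chain class, stacked so neighbouring chains touch at a
4.5 ± 0.45 Å gap — every chain forms an inter-chain contact within 5 Å.
Model pools apply per-chain rigid jitter (≤ 1 Å translation, ≤ 5° rotation,
scaled by min(σ, 1) so a σ = 0 model is bit-identical to the target) plus
isotropic Gaussian coordinate noise of per-model σ; a redundancy fraction
clones the first σ across part of the pool to emulate the tightly redundant
regimes of large sampled pools. pLDDT is written as 100·exp(−d/2 Å) of each
atom's realized displacement — a monotone proxy chosen for simplicity; tests
rely only on its monotonicity, never on the functional form. Synthetic score
tables draw a latent per-model quality and express every similarity metric
as a noisy monotone transform of it (RMSD as a decreasing one), reproducing
the strong inter-criterion correlation of real structural scores. Synthetic
predictors observe true scores through Gaussian noise of per-predictor
fidelity (σ = 0 is an oracle; σ = ∞ shuffles, a permutation null).

What the generator does *not* emulate: physically realistic decoys,
side-chain packing and naming symmetries, partially resolved references,
alternative stoichiometries beyond deliberate test edits, and the long-tail
error structure of real prediction pools. Passing tests therefore establish
the correctness and calibration of the *evaluation machinery*, not claims
about real-world predictor performance.

## Problem sizes and numerics

The test suite and the acceptance script run on deliberately small problems:
LDDT oracle checks on 12–15-residue two-chain fixtures; parameter recovery
on 20 seeds of 20 targets × 200 models × 5 predictors, where the
weighted-penalty ranking recovers the fidelity ladder and agrees with the
Z cross-check at mean Spearman ≈ 0.93–0.95. Tolerances: LDDT matches the
brute-force oracle to 1e-12; penalty affine invariance holds to 1e-8;
degenerate inputs (zero spread, one-class labels, empty contact sets,
monomer interfaces) return all-zero Z, NaN markers, errors and empty sets
respectively, as documented on each function.

## Known limitations

No mmCIF input, no insertion codes, no chain-mapping beyond sequence-class +
RMSD assignment (the full quaternary-structure mapping problem is out of
scope), no native TM-score/GDT/QS/DockQ/CAD implementations (external
tables), and the augmented-LDDT numeric treatment of model-only contacts is
this package's documented reading rather than a community-fixed formula.
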