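# emakit

A toolkit for **estimation-of-model-accuracy (EMA) evaluation** of predicted
protein structures and complexes, in the style of CASP-type community
assessments. It is written for assessors and method developers who need to
(a) score predicted models against reference structures with the LDDT
family, (b) evaluate how well models estimate their own local accuracy
(pLDDT), (c) rank quality-assessment predictors that score other groups'
models, and (d) evaluate *model selection* — picking the five best models
out of a large sampled pool.

## What it computes

**LDDT family.** LDDT (local distance difference test) is the
superposition-free fraction of reference interatomic distances preserved in
a model within tolerance thresholds (0.5/1/2/4 Å inside a 15 Å inclusion
radius, intra-residue pairs excluded), reported per atom, per residue and
globally. Variants: inter-chain-only contacts (iLDDT) and a
*contact-augmented* variant that additionally charges the model for contacts
present only in the model — a pure penalty for hallucinated interfaces.

**pLDDT self-assessment.** Models carry predicted LDDT (0–100) in the
B-factor column, per residue or per atom. Accuracy is the RMSD between
predicted and realized LDDT after "regraining" (per-residue = mean of a
residue's atom values; per-atom = broadcast of the residue value);
predictors are ranked by summed per-target CASP Z-scores.

**Predictor rankings (QMODE1/2).** Per reference metric *r*, predictor *p*
and target *t*, the per-target Pearson *P*, Spearman *S*, ROC AUC *R* and
top-1 loss *L* are converted into per-target Z-scores across predictors
(negatives clamped to 0, missing targets contributing exactly 0) and summed:

    RS(r, p) = 0.5·P + 0.5·S + R + L      (global estimates; L negated before Z)
    RS(r, p) = 0.5·P + 0.5·S + R          (local interface estimates)

with supporting machinery for the stoichiometry filter, the 80%-of-points /
80%-of-targets participation rule, target viability screens, interface-residue
ground truth, and the all-vs-all consensus (AC) baseline.

**Model-selection penalty (QMODE3).** For each structural criterion the
ranking error of a top-5 selection is

    RE = Σ_{k=1..5} |S_true(k) − S_pred(k)|

with both lists sorted best-first, so any selection among tied top models is
perfect (robust to pool redundancy). Correlated criteria are combined with
the Mahalanobis form **P_w = RE Σ⁻¹ REᵀ**, where Σ is the per-category
criterion covariance estimated in two passes with a Mahalanobis outlier
screen. Penalties are min–max normalized per target and averaged; an
equal-weight two-pass Z-score ranking cross-checks the result.

A synthetic-data module generates toy multimeric targets, perturbed model
pools with controllable quality distributions, and predictors of
controllable fidelity, so every stage runs with no external data.

## Worked example

```bash
python examples/01_lddt_scoring.py
```

prints, for a toy homodimer and a ten-model noise ladder:

```
model      sigma   LDDT  iLDDT  augLDDT  RMSD/Å
model_000    0.0  1.000  1.000    1.000    0.00
model_002    0.5  0.830  0.794    0.814    0.80
model_004    1.0  0.658  0.660    0.632    1.54
model_006    2.0  0.425  0.404    0.396    3.30
model_008    4.0  0.245  0.253    0.228    6.49
```

The unperturbed model scores exactly 1.0; LDDT decays with coordinate noise;
the augmented variant never exceeds the standard one. The other examples
rank synthetic self-assessors (`02`), global quality estimators with the
consensus baseline (`03`), and top-5 model selectors with the
covariance-weighted penalty and its Z cross-check (`04`).

A thin CLI wraps the same library:

```bash
emakit simulate --outdir run --seed 1
emakit qmode3 --submissions run/qmode3_submissions.tsv \
              --scores run/score_table.tsv --outdir run/q3
```

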