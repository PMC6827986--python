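# chemoscreen

Pan-solid-tumor chemosensitivity biomarker screening from pharmacogenomic
cell-line panels, with clinical survival validation.

## The problem

Conventional cytotoxic chemotherapy remains standard of care for most solid
tumors, yet response is heterogeneous and there are few biomarkers telling a
clinician which patients will benefit. One route to such a biomarker is to
mine public cell-line panels — each pairing a transcriptome with drug-response
summaries (AUC or ln IC50, lower = more sensitive) for dozens of
chemotherapeutics — for transcripts whose expression tracks sensitivity
consistently across *independent* databases and across whole *classes* of
drugs (alkylating agents, anti-metabolites, anti-tumor antibiotics,
microtubule/cytoskeleton inhibitors, topoisomerase inhibitors), and then to
test the candidate in patient cohorts. `chemoscreen` implements that whole
workflow as a tested, reusable library with a synthetic-data generator
standing in for the real panels and cohorts, so every stage is verifiable
without downloads.

## The method

1. **Correlation screen.** For every gene *g* and drug *d* within a panel,
   the sample Pearson coefficient
   *r* = cov(expr_g, resp_d) / (σ_g σ_d)
   is computed over pairwise-complete cell lines, with the two-sided p-value
   from *t* = *r*·√((n−2)/(1−r²)) ~ t(n−2). Because lower response values
   mean more sensitive, **r ≤ −0.2 marks sensitization** and r ≥ +0.2
   resistance. Pairs with n < 10 or constant input are emitted flagged
   invalid, never dropped.
2. **Consensus selection.** Per gene × class × database, the fraction of the
   class's drugs passing the signed threshold is computed (|r| = 0.2
   inclusive); a database passes if that fraction exceeds 50% (strict); a
   gene is nominated for a class/direction if **≥ 2 databases pass**.
   Databases reporting both AUC and ln IC50 are collapsed to one vote.
   Pan-class candidates are genes nominated for sensitivity in ≥ 4 of the 5
   classes.
3. **Concordance.** A candidate's expression is correlated across the cell
   lines shared between panels (names matched after case/punctuation
   normalization), and summarized per tissue lineage (n, mean, SD).
4. **Clinical validation.** Patients are dichotomized at the median tumor
   expression of the candidate (computed on the analyzed subset); groups are
   compared with the Kaplan–Meier product-limit estimator, the log-rank
   (Mantel–Cox) test, and a Mantel–Haenszel hazard ratio
   HR = (O_low/E_low)/(O_high/E_high), so HR > 1 means low expression is the
   riskier group. Analyses run on all patients and on the
   chemotherapy-treated subset. Responder cohorts (e.g. pathologic complete
   response) are compared by Welch's t-test on z-scored expression.
5. **Synthetic data.** A generator plants sensitizing/resistance genes with
   chosen effect sizes into multi-panel screens, and treatment-interaction
   hazard effects into survival cohorts, writing the same text formats the
   readers consume plus a machine-readable truth sidecar.

## Worked example

```python
import chemoscreen as cs

panels, truth = cs.generate_screen_panels(cs.SyntheticScreenConfig(seed=1))
screen = cs.screen_datasets(panels)
fractions = cs.compute_class_fractions(screen, truth.drug_classes)
consensus = cs.consensus_select(fractions)
counts = cs.flag_multiclass_genes(consensus)
sens = counts[counts.direction == "SENSITIVITY"]
print(sens.sort_values("n_classes", ascending=False).head(3).to_string(index=False))

cohort, _ = cs.generate_clinical_cohort(cs.SyntheticClinicalConfig(
    n_patients=200, gamma=1.0, seed=1))
comp = cs.validate_cohort(cohort, subset_chemo_only=True)
print(f"chemo-only: n_high={comp.n_high} n_low={comp.n_low} "
      f"chisq={comp.logrank_chisq:.2f} p={comp.p:.3g} HR={comp.hr:.2f}")
```

prints

```
     gene_id   direction  n_classes
PLANTED_SENS SENSITIVITY          4
      G00054 SENSITIVITY          1
chemo-only: n_high=55 n_low=55 chisq=23.85 p=1.04e-06 HR=2.57
```

The planted sensitizer (`PLANTED_SENS`, β = 1.5 across the four DNA-damage
classes) is the unique pan-class hit in this replicate; a single null gene
clears the bar in one class only. At 60 lines per panel, some replicates do
see null genes reach the pan-class bar through chance co-expression with the
driver (see `docs/methods.md` on this small-sample effect). In the matched
treated cohort, low expression carries ~2.6-fold higher hazard with a
strongly significant log-rank test, mirroring the intended
"benefit only under chemotherapy" pattern.

There is also a CLI: `chemoscreen simulate|screen|consensus|concordance|validate|all
--config config.yaml --out DIR --seed N`, where the YAML config lists either
dataset/cohort file paths or a `simulate:` section, plus thresholds
(defaults: r threshold 0.2, fraction 0.5, min databases 2, min n 10). Every
run writes stage TSVs and a manifest sufficient to reproduce it.

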