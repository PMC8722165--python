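# metaquad

Metabolic quadrant subtyping of tumor expression cohorts.

Bulk tumors reprogram two central metabolic axes — glycolysis and
cholesterol biosynthesis — and the joint activity of the two stratifies
patients in ways that single pathways do not: tumors high on both axes tend
to be more aggressive, carry more genomic instability, and shape a
different immune microenvironment than metabolically quiescent tumors.
`metaquad` implements the full analysis pipeline for this stratification on
merged multi-cohort expression data, for computational biologists who want
to run it on their own cohorts or study its statistical behavior on
simulated ones:

1. **Batch correction** of merged cohorts (parametric empirical-Bayes
   location/scale adjustment, i.e. ComBat) with a PCA-silhouette check.
2. **Consensus clustering** of pathway genes (1000 resampling reps, 80%
   item subsampling, hierarchical/euclidean/average linkage) with
   CDF/delta-area selection of the cluster count, to extract the robustly
   co-expressed glycolytic and cholesterogenic gene modules.
3. **Quadrant subtyping**: per sample, the glycolytic score
   *s<sub>g</sub>* = median<sub>g∈M_g</sub> Z<sub>gs</sub> and
   cholesterogenic score *s<sub>c</sub>* = median<sub>g∈M_c</sub>
   Z<sub>gs</sub>, with

   | label | rule |
   |---|---|
   | quiescent | s<sub>g</sub> ≤ 0 and s<sub>c</sub> ≤ 0 |
   | glycolytic | s<sub>g</sub> > 0 and s<sub>c</sub> ≤ 0 |
   | cholesterogenic | s<sub>g</sub> ≤ 0 and s<sub>c</sub> > 0 |
   | mixed | s<sub>g</sub> > 0 and s<sub>c</sub> > 0 |

4. **Characterization**: ssGSEA signature scoring, anchor-gene (PDK1-3)
   Pearson screening with hypergeometric over-representation, CIBERSORT-style
   nu-SVR immune deconvolution with permutation significance, Kaplan-Meier /
   log-rank / multivariable Cox survival analysis, and alteration-frequency
   Fisher tests with Benjamini-Hochberg adjustment.

A first-class **synthetic cohort generator** reproduces the statistical
structure this analysis assumes — planted co-expression modules, quadrant
latent activities, cohort batch effects, proportional-hazards survival,
subtype-linked copy-number losses, Dirichlet immune mixtures — with a
ground-truth channel, so every stage is testable end-to-end without any
external download.

## Worked example

`examples/01_simulate_and_subtype.py` simulates the default three-cohort
study (2,097 genes × 760 samples), batch-corrects it, and assigns subtypes:

```
cohort: 2097 genes x 760 samples, batches {'cohortA': 400, 'cohortC': 195, 'cohortB': 165}

subtype proportions (%):
label
quiescent          31.1
glycolytic         22.5
cholesterogenic    20.8
mixed              25.7

agreement with simulated truth: 0.967
```

The proportions are the share of samples in each quadrant; the agreement
line compares assigned labels with the generator's latent truth —
misassignments happen only for samples whose latent activities sit near a
quadrant boundary. The other scripts in `examples/` each demonstrate one
capability (batch correction, module extraction, signature scores and the
PDK screen, immune deconvolution, survival and copy-number contrasts) and
print a line explaining what their numbers mean. For instance,
`examples/06_survival_and_alterations.py`:

```
log-rank across 4 subtypes: chi2 = 36.2 (df 3), P = 6.74e-08
mixed vs quiescent adjusted HR = 1.81 [1.42, 2.30], P = 1.84e-06  (planted HR: 2.0)
RB1 deletion: mixed 25.0% vs quiescent 12.6%  (q = 0.0146)
LRP1B deletion: mixed 30.0% vs quiescent 10.4%  (q = 4e-05)
```

## Command line

Every stage is also exposed as a thin CLI over the library:

```bash
metaquad simulate --out data/ --seed 1
metaquad correct --in data/expression.tsv --out corrected.tsv --report pca.json
metaquad cluster --in corrected.tsv --sets data/pathways.gmt --reps 1000 --seed 1 --out consensus/
metaquad subtype --in corrected.tsv --modules consensus/modules.gmt --out subtypes.tsv
metaquad run --config run.yaml        # the whole pipeline, with a manifest
```

Expression input is a genes × samples TSV with a `#cohort` second header
row (or a sidecar sample/cohort TSV); gene sets are GMT; clinical and
variant tables are TSV (MAF-lite columns `gene`, `sample`, `variant_class`;
CNV calls as integers in [-2, 2]).

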