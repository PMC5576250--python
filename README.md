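# putarget

Positive–unlabelled machine learning for drug-target prioritisation from
gene–disease association evidence.

## The problem

Most drug programmes that fail in the clinic fail for lack of efficacy,
which usually traces back to a weak link between the chosen target and the
disease. `putarget` asks the converse question: can the strength and shape
of a gene's disease-association evidence *predict* whether it is (or will
become) a viable drug target?

The catch is that only positives are ever observed. Genes with drugs on the
market or in active development are known targets; every other gene is
merely *unlabelled* — a mix of true negatives and future targets. This is
the positive–unlabelled (PU) learning setting. `putarget` takes the
pragmatic route of treating the unlabelled set as negative, and counters
the resulting classifier instability with bootstrap aggregation.

## The method

1. **Feature matrix.** Evidence records (gene, disease, data type, score ∈
   [0, 1]) are filtered — indirect ontology-propagated associations
   removed, the leaky `known_drug` and `literature` channels dropped,
   `animal_model` records below 0.4 discarded — and averaged per gene and
   data type across diseases, giving one row per gene over five features:
   `affected_pathway`, `animal_model`, `genetic_association`,
   `rna_expression`, `somatic_mutation`.
2. **PU labels.** A gene is positive iff a development-stage table places
   it at an active stage (Preclinical … Launched); for multi-programme
   genes the most advanced stage is kept. Genes with only
   suspended/discontinued/withdrawn programmes stay unlabelled.
3. **Working set.** All *P* positives plus *P* randomly sampled unlabelled
   genes form a balanced working set, split 80/20 into train and test
   (stratified); the remaining unlabelled genes form the prediction set.
4. **Bagged classifiers.** SVM (RBF), single-hidden-layer neural network
   and gradient boosting (exponential/AdaBoost loss) are each bagged over
   100 bootstrap resamples with majority voting or mean-probability
   aggregation; random forests bag internally and are used as-is.
   Hyperparameters are tuned by 4×4 nested cross-validation, so
   performance estimates never touch the rows used for tuning.
5. **Prediction and validation.** The selected model (the bagged NN by
   default) ranks the prediction set by target probability; genes above a
   stringent 0.9 cut-off are nominated as novel targets and validated
   against an external (e.g. literature-derived) gene list with a
   two-sided Fisher's exact test, alongside a permutation null built from
   random gene sets of the same sizes.

Because the original evidence and pipeline databases are licensed, the
package ships a synthetic-data generator (`putarget.synthetic_data`) with
the same statistical structure — sparse zero-inflated-Beta scores, signal
concentrated in `animal_model` / `rna_expression` / `genetic_association`,
and SCAR-sampled positive labels — plus the ground truth needed for
property testing.

## Worked example

```python
from putarget import *

cfg = SyntheticConfig(n_genes=2000, true_target_fraction=0.1,
                      labelled_fraction=0.5, seed=42)
records, truth = generate_evidence(cfg)
matrix = build_feature_matrix(records, universe=truth.index)
stages = generate_stage_table(truth, seed=43)
labels = assign_labels(stages, matrix.index)
part = make_working_split(labels, SplitConfig(seed=44))

train, test = part == "train", part == "test"
model = fit_bagged(
    BaseLearnerSpec("feedforward_nn_1hidden", {"size": 5, "decay": 0.01}),
    matrix[train], labels.loc[train, "label"],
    BaggingConfig(n_bags=100, seed=45),
)
report, cm = evaluate_on_test(model, matrix[test], labels.loc[test, "label"],
                              train_ids=matrix[train].index)
print(report.rounded(3))
```

prints

```
{'misclassification_error': 0.147, 'accuracy': 0.853, 'auc': 0.969,
 'sensitivity_recall': 0.824, 'specificity': 0.882, 'precision': 0.875,
 'f1': 0.848}
```

i.e. on a 34-gene held-out test set the bagged network recovers 14 of 17
positives (sensitivity 0.824) while keeping 15 of 17 unlabelled genes
negative (specificity 0.882). Note that in the PU setting the "false
positives" partly hide true targets, so the apparent FPR overestimates the
real one. Applying the 0.9 probability cut-off to the 1,826 prediction-set
genes nominates 41 novel targets, and information-gain importance on the
working set ranks the three signal channels first:

```
animal_model           0.203
genetic_association    0.236
rna_expression         0.253
affected_pathway       0.032
somatic_mutation       0.016
```

The same analysis runs end to end from the shell:

```bash
putarget run-all --seed 7 --out run/     # synthetic inputs by default
putarget simulate --out data --n-genes 2000 --seed 1
putarget build-features --evidence data/evidence.jsonl --out features.tsv
putarget label-and-split --features features.tsv --stages data/stages.tsv --out parts.tsv
```

`run-all` writes the feature matrix, partitions, test metrics and confusion
matrix, the ranked prediction table, importance and decision-tree reports,
the stage-wise logistic-regression analysis, the enrichment report and a
manifest of derived seeds.

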