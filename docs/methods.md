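# Methods

## Setting and model

The package frames target discovery as binary classification from
positive–unlabelled (PU) data. Observed positives are genes with at least
one drug programme at an active development stage; all other genes are
unlabelled and treated as the negative class during training. Under the
SCAR assumption (observed positives are selected completely at random from
the true positives), a classifier trained this way ranks genes in the same
order as one trained on true labels, but absolute error rates against the
PU labels are biased: hidden positives inside the "negative" class inflate
the apparent false-positive rate. The test suite asserts this
overestimation property directly on synthetic data with known truth.

The design matrix has one row per gene and five columns, the pan-disease
mean association score per evidence channel (`affected_pathway`,
`animal_model`, `genetic_association`, `rna_expression`,
`somatic_mutation`). Three filters precede averaging, in this order:
excluded channels are dropped (`known_drug` restates the label,
`literature` is reserved for external validation), indirect
ontology-propagated associations are removed to avoid double counting, and
`animal_model` records with score < 0.4 are discarded. The 0.4 filter is
applied at the record level *before* averaging — the filter reads
most naturally as a per-association confidence cut — with a post-aggregation
variant available (`FeatureConfig.record_level_filter=False`) for
sensitivity analysis. The mean is taken only over diseases retaining at
least one qualifying record; gene × channel combinations with no surviving
evidence are encoded as 0, consistent with a matrix whose values
overwhelmingly sit at or near zero. Rows exist for every gene with at
least one retained record, plus any gene in an optional universe list
(added as all-zero rows).

## Labels, partitions

Stage precedence is Preclinical < Clinical Trial < Phase I < Phase II <
Phase III < Pre-registration < Registered < Launched; a multi-programme
gene keeps its most advanced stage. Suspended, discontinued and withdrawn
programmes never confer a positive label (the vocabulary for failed
categories is configurable). The balanced working set takes all P
positives and P unlabelled genes sampled without replacement — reuse would
leak rows between partitions — and is split 80/20 into train and test.
The split is stratified by label with the test share floored per class:
2,842 working genes yield exactly 2,274 train and 568 test rows, and the
two classes stay balanced in both parts. Remaining unlabelled genes form
the prediction set.

## Bagging layer

Each of `n_bags` (default 100) base models is fitted on a joint
with-replacement resample of the n training rows (a resample missing a
class is redrawn; with balanced training sets this is vanishingly rare).
Aggregation is either the mean of per-bag positive-class probabilities
(default) or the positive vote fraction. The vote rule alone cannot serve
the stringent 0.9 probability cut-off or ROC analysis, which is why the
continuous mean-probability aggregate is the default; the vote fraction is
retained as an alternative. A predicted class is 1 iff the aggregate
strictly exceeds the threshold, so exact ties (a 50/50 vote at threshold
0.5) resolve to non-target — the conservative direction for nominating
targets. Random forests skip the outer bagging entirely (one forest on the
full training data), since the forest bags internally.

Base learners come from scikit-learn: `RandomForestClassifier`,
`SVC(kernel="rbf", probability=True)`, `MLPClassifier` with exactly one
hidden layer (lbfgs solver, 500 iterations — adequate for 5-dimensional
inputs), `GradientBoostingClassifier(loss="exponential")` (the AdaBoost
loss), and `DecisionTreeClassifier`. Hyperparameters are exposed under the
field's usual names (`decay` for the network's L2 penalty, `cost` for the
SVM's C, `interaction_depth` for boosting depth).

## Model selection

Nested cross-validation uses stratified 4-fold loops inside and outside by
default. For each outer fold the inner loop scores every grid point by
mean misclassification error (the tuning measure is configurable; ties
break to the earlier grid point), the winner is refitted on the full outer
training portion and scored once on the outer test fold. Outer test rows
are structurally invisible to tuning; the tests verify the outer folds
partition the data and that a one-point grid reduces the procedure to a
plain k-fold evaluation. Default grids: RF trees {250, 500, 1000} ×
features-per-split {1, 2, 3}; NN size {1, 3, 5, 8} × decay {0, 0.01, 0.1};
SVM gamma {0.1, 0.5, 1, 2} × cost {0.5, 1, 2, 4}; GBM trees {100, 300,
1000} × depth {1, 2, 3}. A grid point that fails to fit is skipped with a
warning; all points failing is fatal.

The Monte Carlo stability analysis asks how much the arbitrary choice of
"negatives" moves the results: each iteration re-draws the unlabelled half
of the working set from the full unlabelled pool, rebuilds the 80/20
split, refits and records test accuracy and AUC. The library default is
200 iterations — enough to estimate a standard deviation of order 0.02 —
with the full-scale 10,000 available by configuration.

## Evaluation

Confusion-matrix metrics follow the standard definitions; a metric whose
denominator is zero is reported as `None`, never silently as 0. AUC is the
area under the ROC curve via scikit-learn, equal to the midrank
Mann–Whitney statistic normalised by n₁·n₀ (the tests pin this equality
against an exhaustive pairwise-comparison oracle). Metrics are stored at
full precision and rounded to 3 decimals only for display.

The stage analysis regresses the correct-prediction indicator (a label-1
gene predicted 1 at threshold 0.5) on stage indicators with Preclinical as
reference, reporting Wald p-values; under separation or non-convergence
the fit falls back to BFGS and per-stage likelihood-ratio tests. The
failed-programme contrast is the same regression with a two-level
grouping.

## Interpretation

Feature importance is computed without removing any feature, by two filter
methods on a discretised copy of each column: the chi-squared statistic of
the bin × label table (no continuity correction) and the information gain
H(label) − H(label | bin) in bits. Discretisation uses equal-frequency
bins (default 5) on the non-zero values with all zeros collapsed into one
bin — with mostly-zero features, plain quantile binning would put the
zeros everywhere. Constant features score 0 with a warning. The
inspection tree is a depth-3 CART fit from scikit-learn; the report lists
each node's split, majority class, per-class counts and the percentage of
observations reaching it, and the tests check count conservation and that
leaf percentages total 100.

## External validation

The overlap between the nominated targets and an external gene list is
tested over a fixed universe (default 19,000, roughly the protein-coding
genome; the parameter is explicit because the right universe depends on
the input corpus) after excluding all training and test genes from both
sets. Significance is the two-sided Fisher's exact test under the
minimum-likelihood convention (scipy); effect size is the sample odds
ratio (a·d)/(b·c), flagged rather than crashed when bc = 0. The
permutation null draws both sets independently and uniformly at random
with sizes fixed — equivalent under the null to permuting labels — and
reuses an exact-p cache keyed by the overlap count, which makes thousands
of permutations cheap.

## Synthetic data

The generator emulates the structure the analysis assumes rather than any
real corpus: for every gene × disease × channel triple a record exists
with an activation probability depending on class and channel, and its
score is Beta-distributed — a zero-inflated Beta model producing the
sparse, near-zero-heavy matrix the method expects. Signal lives in
`animal_model`, `rna_expression`, `genetic_association` (and in
`known_drug`, which deliberately leaks the label so the feature builder's
exclusion matters). Defaults: 2,000 genes, 50 i.i.d. diseases (no
ontology structure — indirect associations are removed downstream anyway),
true-target fraction 0.08 (close to the 1,421/18,104 regime), labelled
fraction 0.5, target activation 0.15 vs background 0.08, target scores
Beta(1.5, 3) vs background Beta(1, 4), indirect fraction 0.3. These
choices put a bagged network at test AUC ≈ 0.9 against PU labels —
moderately easier than real evidence data, which is noisier and
batch-structured in ways the generator does not model (no disease
ontology, no per-source score structure, no correlated evidence across
channels). Passing tests therefore demonstrate correctness of the
machinery and the PU properties, not field performance.

Stage tables give every observed positive one uniform active stage plus a
second with probability 0.3; a configurable fraction (default 0.1) of the
other genes receives a failed-programme stage. The literature list samples
genes without replacement with weight `enrichment_factor` for true targets
and 1 otherwise.

## Numerical and reproducibility choices

All randomness flows through `numpy.random.default_rng` with explicit
seeds; the pipeline fans a single global seed out to per-stage seeds via
`SeedSequence.spawn`, recorded in the manifest, so each stage is
independently reproducible. Feature matrices round-trip through TSV
exactly (`%.17g`). Problem sizes in the test suite (hundreds to a few
thousand genes, 2–10 bags, 4-fold loops, 50–2,000 permutations) are chosen
so the full suite runs in well under a minute while leaving every
statistical assertion comfortable margins; the paper-scale settings
(100 bags, 10,000 iterations/permutations, 18,104 genes) remain the
library defaults or documented flags.

## Known limitations

- SCAR is assumed, not tested; label noise that correlates with evidence
  strength would bias both the model and the stability analysis.
- The unlabelled-as-negative device biases probability calibration, so the
  0.9 cut-off is a ranking device, not a calibrated posterior.
- The generator's independence assumptions (i.i.d. diseases, independent
  channels given the class) understate the correlation structure of real
  evidence; recovery results on synthetic data are upper bounds.
- `SVC(probability=True)` calibrates probabilities by internal
  cross-validation, which is comparatively slow at large n; benchmark runs
  at full scale should budget for it.
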