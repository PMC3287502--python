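# Methods

## Problem setting

The package operates on collections of binary gene-expression classifier
signatures: per-model probe lists submitted for one clinical endpoint, plus
a labeled expression matrix (samples × probes) on which models can be
trained and cross-validated. The goal is a single minimized signature with
preserved or improved cross-validated predictive power, together with
meta-analytic summaries (overlap, consensus, between-endpoint partition)
and a network-topology comparison of the signature before and after
minimization.

## Performance indices

All indices derive from the confusion counts TP, TN, FP, FN of a binary
prediction:

- `mcc = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN))`, in [−1, 1].
  When any marginal factor is zero the coefficient is undefined; we return
  0 (the standard convention) so the elimination loop stays total.
- `index1 = TP·TN/((TP+FP)(TN+FP))`. The second factor is implemented
  exactly as stated even though `(TN+FN)` may look more natural; a
  `variant="fn"` switch provides the alternative. Zero denominators yield 0
  with a warning.
- `index2 = TN/(TN+FP) + TP/(TP+FP)`, i.e. specificity + precision, in
  [0, 2]; an empty denominator drops that term with a warning.
- accuracy, sensitivity, specificity as usual; an empty class makes the
  corresponding rate 0 with a warning rather than an error.
- `MCC-robustness = mean(MCC) / sd(MCC)` across CV repeats, with the sample
  (n−1) standard deviation. A zero SD makes the ratio infinite; because the
  sentinel can only be resolved relative to the other models being
  weighed, the scalar function returns `inf` and
  `resolve_robustness_weights` maps it, per policy, to the smallest finite
  weight in the batch (default) or to a large finite cap. Assigning the
  *smallest* weight to a perfectly stable classifier is deliberate
  fidelity to the source procedure, not a statistical recommendation; the
  cap policy is the alternative for users who prefer the intuitive
  reading.

## Cross-validation protocol

`evaluate_cv` runs stratified k-fold CV (default k = 5) repeated r times
(default r = 10). Within one repeat the held-out predictions of the k folds
are pooled into a single confusion table before any index is computed, so
each repeat contributes exactly one value per metric. Pooling keeps the
confusion table populated when positives are rare (a 25% positive fraction
at n = 60 leaves only 3 positives per fold); the alternative — averaging
per-fold MCC — is noisier and frequently undefined in small folds.

Fold assignment for repeat j uses an integer seed drawn from
`SeedSequence(entropy=seed, spawn_key=(j,))`, which makes the repeat stream
*prefix-stable*: reducing `repeats` from 10 to 5 leaves the first five
repeats' folds unchanged, so scaled-down runs are nested inside full runs.

The default classifier is a linear-kernel SVM with C = 1 (no tuning, no
class reweighting); a small registry accepts alternatives. No
hyperparameter search runs inside CV.

## MFS: backward stepwise elimination

Configuration: fitting index (`mcc`, `index1`, `index2`), a
`criteria_value` threshold that gates only the emission of intermediate
signatures, a minimum size (default 5), fold/repeat counts, a seed, probe
weights, and the visiting order.

Per iteration i:

1. Score the current feature set with the fitting index, using a CV seed
   derived deterministically from (run seed, i). This evaluation is
   recorded as a candidate.
2. Visit each probe (default order: ascending merged weight, so the
   least-supported probes are challenged first; ties lexicographic;
   `input_order` preserves the given order). Re-evaluate the index without
   the probe **under the same derived seed**, so the comparison reflects
   the removal and not fold noise. If the new value is strictly lower the
   probe is restored; otherwise the removal is permanent, the current value
   updates, and the new state is recorded as a candidate. A failed
   evaluation (degenerate candidate set) restores the probe with a
   warning.
3. If the iteration's final value exceeds `criteria_value`, the state is
   emitted as an intermediate signature.
4. Terminate when the set did not shrink during the iteration or its size
   is at most `min_size` (checked at the next iteration start, which also
   covers inputs that are already small enough).

The **best model** is the candidate with the maximal index value — ties
prefer the smaller set, then the earlier record — and is reported
regardless of `criteria_value`. Because the first candidate is the starting
set, the best value can never fall below the starting evaluation.

Within an iteration the accepted values form a non-decreasing sequence and
every iteration's feature set is a subset of its predecessor's; the whole
procedure is a pure function of (dataset, features, config).

`prepare_mfs_input` builds the wrapper's input from signature collections:
the consensus set at `min_support`, restricted to probes present in the
dataset (absent probes are reported), with probe weights from the weighted
merge. Model weights are MCC-robustness values when every model carries
`mcc_mean`/`mcc_sd` metadata, else uniform. A single input signature passes
through unchanged.

## AGC batch centering

Array-generation based gene centering subtracts, per probe and per batch,
that batch's probe mean (optionally median). It is idempotent, leaves
within-batch variances and all labels untouched, and with a single batch
reduces to global gene centering. It is applied as a fixed dataset-level
preprocessing *before* any CV split, mirroring its role as background-noise
removal; note the leakage caveat that centering sees all samples of a
batch, including ones later held out.

## PPI topology

The network is undirected and unweighted; probes map to zero or more nodes.
A probe pair is *absent* (no mapped node), *disconnected* (no path), or
linked at the BFS hop distance; with multiple mapped nodes the minimum over
node combinations is taken, and two probes on the same node get distance 0.
Summaries count pairs per distance level (reported as levels 1–6 plus a
">6" bucket), absent and disconnected pairs — the three outcomes always
partition the pair set — and the average distance over linked pairs.
Distances are computed with networkx BFS; tests check them against an
independent Floyd–Warshall oracle.

## Synthetic cohorts

`generate_dataset` draws class-conditional Gaussian intensities:
informative probes shift their mean by `effect_size` pooled SDs between
classes, redundant probes are ρ-correlated copies of informative ones,
noise probes are class-independent, and per-(batch, probe) offsets emulate
array-generation effects. Defaults (n = 130, positive fraction 0.25)
echo a realistically imbalanced training cohort of roughly 33 positives in
130 samples. `generate_signature_collection` mocks submitted signatures:
each model includes each signal probe with probability `hit_rate` and each
noise probe with probability `noise_rate`.

What the generator does **not** emulate: heavy-tailed microarray noise,
probe-level intensity-dependent variance, correlated noise blocks, and
annotation ambiguity. Passing tests therefore demonstrate algorithmic
correctness and behaviour under idealized Gaussian signal, not expected
performance on real cohorts.

## Known limitations

- **Winner's curse at small n.** At n = 60 with 10 pure-noise probes, the
  most spuriously endpoint-correlated noise probes (|r| ≈ 0.2–0.3) raise
  the cross-validated index of this specific cohort; a wrapper that
  maximizes that index retains them. In the planted-recovery experiment the
  acceptance script reports mean noise retention around 20–30% alongside
  planted recall around 90%: the retained noise is mostly *empirically*
  informative in-sample, an irreducible property of index-maximizing
  selection at this sample size rather than a defect of the elimination
  rule (comparing removals against the iteration-start value instead of
  the running value was evaluated and changes the retention only
  marginally).
- The strict "restore only on strictly lower" rule makes removal the
  default under exact ties; with a stochastic index, exact ties are rare
  and most redundancy stripping comes from removals that wobble the index
  upward.
- Probe→gene mapping implements a simple rule set (drop pseudogenes and
  hypothetical genes, collapse alias groups to the first-listed symbol,
  exclude — or take the first of — multi-gene probes, with an ambiguity
  report); no probabilistic disambiguation is attempted.
- ARFF support is the dense dialect only (numeric features, nominal binary
  class last, optional string `sample_id` first and nominal `batch`);
  sparse ARFF and missing values are rejected at load.

## Problem sizes used in the shipped experiments

Unit and property tests run at n ≤ 130 samples and ≤ 25 probes; the
planted-recovery experiment uses 10 runs at n = 60 with 1–3 informative and
10 noise probes under the full 5-fold × 10-repeat protocol; the BFS oracle
comparison uses 100 random graphs of up to 50 nodes. These sizes exercise
every code path while keeping a complete run of the suite and the
acceptance script in the low tens of seconds.
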