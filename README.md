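# sigmin

Meta-analysis and minimization of gene-expression classifier signatures.

When many analysis teams build classifiers for the same clinical endpoint
(e.g. pathologic complete response or ER status in breast cancer), they
produce dozens of probe-list signatures with similar predictive power but
little overlap. `sigmin` implements a workflow that turns such a collection
into one small, robust signature:

1. **Similarity analysis** — pairwise overlap matrices, probe support
   (frequency) tables, and a *consensus set*: probes identified by at least
   `min_support` signatures (default 2).
2. **MCC-robustness weighting** — each signature weighs in with
   MCC&#772;/σ<sub>MCC</sub>, its mean repeated-CV Matthews correlation
   coefficient divided by the standard deviation across repeats, so stable,
   strong models count more; each consensus probe's weight is the sum over
   signatures containing it.
3. **MFS (Minimize Feature's Size)** — iterative backward stepwise
   elimination. Per iteration the current set is scored by a fitting index
   (mean MCC over 10 repeats of stratified 5-fold CV by default; `index1`
   and `index2` are alternatives); each probe is then tentatively dropped
   and the index re-evaluated *under the same fold seeds*. A strictly lower
   index restores the probe; an equal or higher one makes the removal
   permanent — equality removing the probe is what strips redundant
   features. Iterations stop when the set no longer shrinks or reaches a
   minimum size; the best-scoring visited set is recorded unconditionally.
4. **Validation** — internal repeated CV, external validation on an
   independent cohort, and cross-endpoint prediction (scoring one
   endpoint's model against the other endpoint's labels).
5. **PPI topology** — all-pairs BFS shortest paths of signature probes on a
   protein-interaction network; each pair is *absent*, *disconnected*, or a
   *k-th level neighbor*; comparing the level counts and average linked
   distance before/after minimization shows whether the network topology of
   the signature survived.

The central index, for TP/TN/FP/FN confusion counts, is

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with `index1 = TP·TN / ((TP+FP)(TN+FP))` and
`index2 = TN/(TN+FP) + TP/(TP+FP)` as auxiliary fitting indices.

The elimination wrapper is also exposed scikit-learn style:
`MFSSelector(...).fit(X, y)` with `support_`, `best_score_`, `transform`,
composing with sklearn pipelines; `AGCCenterer` provides array-generation
gene centering (per-probe, per-batch mean centering) as a transformer.

A seeded synthetic-cohort generator (`FixtureSpec`, `generate_dataset`,
`generate_signature_collection`) provides ground-truth fixtures: informative
probes with a chosen class-mean gap in pooled-SD units, correlated redundant
probes, pure noise probes, batch offsets, and mock submitted signatures.

## Worked example

```python
from sigmin import (
    ClassifierSpec, FixtureSpec, MFSConfig, SignatureCollectionSpec,
    evaluate_cv, generate_dataset, generate_signature_collection,
    prepare_mfs_input, run_mfs,
)

ds, truth = generate_dataset(FixtureSpec(seed=7))           # 130 samples
coll = generate_signature_collection(truth, SignatureCollectionSpec(seed=8))
features, weights, _ = prepare_mfs_input(coll, ds, min_support=2)
print(f"consensus input: {len(features)} probes from {len(coll)} signatures")

cfg = MFSConfig(seed=9, weights=weights, min_size=2, criteria_value=0.3)
result = run_mfs(ds, features, cfg)
print(f"minimized signature ({len(result.best_features)} probes):",
      sorted(result.best_features))
print(f"fitting index (mean CV MCC): {result.best_value:.3f}  "
      f"stopped: {result.termination_reason}")

cv = evaluate_cv(ds, list(result.best_features), ClassifierSpec(), seed=10)
print(f"internal 5F-CV x10: MCC {cv.mcc.mean:.3f} (SD {cv.mcc.sd:.3f}), "
      f"ACC {cv.acc.mean:.3f}, SEN {cv.sen.mean:.3f}, SPE {cv.spe.mean:.3f}")
```

prints

```
consensus input: 16 probes from 20 signatures
minimized signature (7 probes): ['inf_000', 'inf_001', 'inf_002', 'inf_003', 'inf_004', 'noise_003', 'noise_016']
fitting index (mean CV MCC): 0.992  stopped: no_decrease
internal 5F-CV x10: MCC 0.992 (SD 0.015), ACC 0.997, SEN 0.988, SPE 1.000
```

The 20 mock signatures nominated 16 consensus probes; elimination shrank
them to 7 while the cross-validated MCC stayed at 0.99. All five planted
informative probes survive; the two surviving noise probes are ones that
happen to correlate with the endpoint in this cohort — at this sample size
an index-maximizing wrapper keeps them, which is exactly the caveat the
synthetic ground truth makes visible.

The same workflow is available from the shell:

```sh
sigmin simulate --seed 7 --out demo/
sigmin mfs --data demo/dataset.arff --signatures demo/signatures.tsv \
    --min-support 2 --index mcc --criteria 0.3 --seed 9 --out demo/out/
sigmin --help   # similarity, preprocess, validate, crosspredict, ppi, run
```

Datasets are read/written as dense ARFF (numeric probe attributes, nominal
binary class attribute last) or TSV; signature tables as TSV (one row per
model with semicolon-joined probes, or one row per model/probe pair).

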