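# qsmiles

QSAR modeling of *experimental situations* rather than molecules.  An
experimental situation — which nanoparticle, at what size, for how long, on
which cell line, measured as which half-maximal concentration endpoint — is
written as a **quasi-SMILES**: a string of bracketed condition codes such as

```
[Ag][nm20][24h][EC50][A549]
```

The package learns a **correlation weight** CW(code) for every code by Monte
Carlo optimization and predicts the (log-scale) endpoint from the **optimal
descriptor**, the sum of the weights of a record's codes:

```
DCW(T, N) = Σ CW(code)           endpoint ≈ C0 + C1 · DCW(T, N)
```

`T` is the rare-code threshold (codes seen in fewer than `T` active-training
records are *blocked* — their weight is pinned to 0); `N` is the number of
optimization epochs.  `(C0, C1)` is an ordinary least-squares fit on the
active training set.

It is aimed at nano-QSAR practitioners who have heterogeneous toxicity
databases (here: EC50/IC50/LC50 cytotoxicity of metal and metal-oxide
nanoparticles on A549, THP-1, MCF-7, Caco2 and HepG2 cells) and want a
model that answers "how would changing the experiment change the endpoint?"

## What is inside

* **Structured splits** — records are dealt into an *active training* set
  (weights are fitted to it), a *passive training* set (guards against
  split-specific overfit), a *calibration* set (hosts the ideality terms)
  and an untouched *validation* set, ≈25% each.
* **Target functions** — stochastic hill-climbing maximizes either

  `TF1 = r_AT + r_PT − |r_AT − r_PT| · 0.1`

  (Pearson correlations on the two training sets), or the
  ideality-augmented

  `TF2 = TF1 + (IIC + CII) · 0.3`

  where the *index of ideality of correlation* (IIC; Pearson r attenuated
  by the imbalance of positive- and negative-residual mean absolute
  errors) and the *correlation intensity index* (CII; one minus the summed
  positive leave-one-out improvements of R²) are evaluated on the
  calibration set.
* **Statistics** — R², CCC, IIC, CII, leave-one-out Q², RMSE, MAE, Fisher F
  for observed/predicted series.
* **Applicability domain** — per-code statistical defects `d` measure how
  inconsistently a code is distributed across the three training subsets; a
  record with defect sum `Dj = Σ d` above twice the training mean is out of
  domain.
* **Interpretation** — codes whose weights keep one sign across repeated
  optimizations are endpoint *promoters* (always positive) or *reducers*
  (always negative).
* **Synthetic data** — a generator with known additive ground truth
  emulating the five-slot structure of the real records, so every estimator
  property is testable offline.
* A 102-record reference dataset (with its original split, descriptor,
  prediction and defect columns) and the matching per-code weight/defect
  table ship as fixtures.

## Worked example

```python
import qsmiles as q

ds = q.load_reference_dataset()            # 102 records, labels A/P/C/V
res = q.optimize(ds, q.OptimizationConfig(tf_kind="TF2", seed=4))

for lab in ("A", "P", "C", "V"):
    sub = ds.subset(lab)
    obs = [r.endpoint for r in sub]
    preds = [q.predict(res.params, res.weights, r.qs) for r in sub]
    s = q.set_statistics(obs, [p.value for p in preds], dcw=[p.dcw for p in preds])
    print(f"{lab}: n={s.n} R2={s.r2:.4f} IIC={s.iic:.4f} RMSE={s.rmse:.3f}")
```

prints

```
A: n=26 R2=0.9597 IIC=0.9796 RMSE=0.182
P: n=25 R2=0.7360 IIC=0.6355 RMSE=0.463
C: n=25 R2=0.6889 IIC=0.8295 RMSE=0.397
V: n=26 R2=0.8357 IIC=0.4821 RMSE=0.277
```

— a model fitted only on the active set that transfers to the untouched
validation set (R² 0.84, RMSE 0.28 log units for this seed).  The
applicability domain on the bundled per-code defects:

```python
table = q.load_reference_code_table()
defects = q.DefectTable.from_mapping(dict(zip(table["code"], table["defect"])))
ad = q.assess(ds, defects)
print(ad.threshold, ad.out_of_domain_ids())
```

```
2.406 [21, 22]
```

flags exactly the two records whose codes (a rarely measured particle, an
endpoint kind confined to one subset) the training data cannot vouch for.
A single prediction:

```python
p = q.predict(res.params, res.weights, q.parse_quasi_smiles("[Ag][nm20][24h][EC50][A549]"))
print(round(p.dcw, 4), round(p.value, 4))   # -0.059 -3.6254
```

The same workflow is available from the shell:

```sh
qsmiles simulate --seed 3 --n 200 --out ds.tsv --truth-out truth.json
qsmiles split    --seed 1 --dataset ds.tsv --out labeled.tsv
qsmiles train    --seed 2 --dataset labeled.tsv --tf tf2 \
                 --weights-out w.json --model-out m.json --trace-out trace.csv
qsmiles predict  --dataset labeled.tsv --weights w.json --model m.json --out pred.tsv
qsmiles domain   --dataset labeled.tsv --out ad.tsv
```

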