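# vaxhes

Spatio-temporal forecasting of childhood vaccine hesitancy at ZIP-code
resolution from insurance-claims panels.

## The problem

Refusal of mandatory childhood vaccines (MMR, HepB, IPV, DTaP) clusters
in space and drifts in time, but hesitancy data at fine spatial
resolution is scarce: the natural source — all-payer claims databases —
is restricted, and at ZIP-by-quarter resolution the signal is sparse
(tens of refusal events per cell). `vaxhes` is for epidemiologists and
public-health data scientists who need to (a) derive a hesitancy panel
from claims-like records, (b) forecast next-quarter hesitancy for ZIP
codes *whose hesitancy history was never observed*, and (c) decide which
ZIP codes are worth buying labels for under a budget.

Hesitancy is measured as h_i(t), the fraction of unique children aged ≤ 6
in ZIP i with at least one vaccine-refusal claim (ICD-10-CM Z28.x) in
quarter t. The forecaster combines:

* a **spatial module** M_s — stacked order-1 Weisfeiler–Leman
  message-passing layers (out_i = W₁x_i + W₂ Σ_j w(i,j) x_j + b) over a
  weighted ZIP graph (activity-based contacts, geographic adjacency, or
  inverse centroid distance), mapping each quarter's demographic claim
  features nc(t) to a per-ZIP estimate ŷ(t);
* a **temporal module** M_t — a per-ZIP residual LSTM over the ŷ series,
  whose output at step t predicts h(t+1).

The two modules are trained with separate Adam optimizers on separate
MAPE + L2 losses; evaluation is cold-start (an unlabeled ZIP's hesitancy
is never read — only its features and the graph).

Also included: weighted Moran's I and the isolation index, a Poisson
Kulldorff scan for connected high-hesitancy clusters with Monte-Carlo
p-values, budgeted active learning over ZIP codes, reference baselines
(linear-with-neighbours, MLP, GNN-GRU, GCN-LSTM, single-module
ablations), and a synthetic generator producing claims, geographies,
contact networks and panels with the statistical structure the method
assumes — so the entire pipeline is testable without restricted data.

## Worked example

```python
from vaxhes import (HesitancySTL, SimConfig, TrainSplit)
from vaxhes.benchmarks import make_study, desk_spatial, desk_temporal, desk_train

study = make_study(SimConfig(N=100, TS=12, seed=0))   # synthetic benchmark
split = TrainSplit.random(100, frac_labeled=0.7, seed=0)
model = HesitancySTL(study.panel, study.ga, split,
                     spatial=desk_spatial(), temporal=desk_temporal(),
                     train=desk_train(seed=0))
result = model.fit()
print(result.summary())
```

```
Spatio-Temporal Hesitancy Model Results
===============================================
nodes: 100   labeled |K|: 70   eval: 30
timesteps: 12   last training step T: 11   target: T+1
spatial: 2 x GraphConv(32)   temporal: LSTM(8)
epochs: 2500   lr: 0.002   weight_decay: 0.0005   seed: 0
final loss1: 0.13419   final loss2: 0.18821
-----------------------------------------------
eval MAPE: 0.2727   MAE: 0.0470   MSE: 0.00419
eval RMSE: 0.0648   R2: 0.6241   n: 30
```

The eval rows are the 30 ZIP codes whose hesitancy series the model never
saw: their next-quarter refusal fractions are predicted with a mean
absolute error of about five percentage points, explaining about 62% of
the cross-ZIP variance (eval R² ≈ 0.62). `result.predict(nodes,
horizon=4)` rolls the forecast four quarters ahead closed-loop;
`vaxhes.morans_i` / `isolation_index` / `kulldorff_scan` characterize a
quarter's spatial field; `vaxhes.al_loop` grows a labeled set under a
query budget.

A command-line interface mirrors the library:

```bash
vaxhes simulate --n 100 --ts 12 --seed 0 --out study/
vaxhes train --panel study/panel --graph study/graph_ga.csv --seed 0 --out run/
vaxhes stats --panel study/panel --graph study/graph_ga.csv --morans-i --isolation --scan --mc 999 --seed 0
vaxhes active-learn --panel study/panel --graph study/graph_ga.csv --init-size 10 --budget 10 --seed 0 --out al/
vaxhes benchmark --panel study/panel --graph study/graph_ga.csv --models stl,lrn,mlp,gnn_only,lstm_only --seeds 0,1,2 --out table.csv
```

All runs are deterministic given `--seed`.

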