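# Methods

## Problem

Vaccine hesitancy for mandatory childhood vaccines is tracked here as the
fraction `h_i(t)` of unique children aged six or below in ZIP code `i`
with at least one vaccine-refusal claim (ICD-10-CM category Z28) during
quarter `t`, out of the `p_i(t)` unique children with any claim in that
quarter. The package forecasts `h_i(T+1)` for ZIP codes whose hesitancy
history is *never observed* (cold start), using only their demographic
claim features, the histories of a labeled subset of ZIP codes, and a
weighted ZIP-to-ZIP graph.

## Data model

A claims extract is aggregated to a panel:

* `nc[N, X, TS]` — per ZIP and quarter, unique-child counts overall and
  per one-hot demographic category (gender, race, Hispanic indicator,
  payer line of business), min-max normalized per column within each
  quarter;
* `h[N, TS]` — refusal fractions (kept as raw fractions by default; a
  switch applies per-quarter min-max to `h` as well);
* `p[N, TS]` — unique-child counts, with a mask marking empty cells
  (`p = 0`), which are excluded from every loss and metric.

Quarters are calendar quarters. Age is age at date of service,
"six or below" inclusive. Z28 matching is prefix-based on the
three-character category, so any subcode (e.g. Z28.21) counts. Unknown or
missing categories keep their own one-hot column. ZIPs with total
population at or below a cutoff (default 1000) are dropped, and graphs
must be subset to the same ZIP ordering — the panel and graph carry a
shared ordered ZIP list that is validated at model construction.

Three graph variants are built over that ordering: the aggregated contact
graph `Ga` (summed activity-weighted person-level contacts; intra-ZIP
contacts dropped, no self-loops), the geographic adjacency graph `Gb1`
(unit weights), and the inverse-centroid-distance graph `Gb2` (fully
connected). Edge weights are min-max normalized over realized edges only;
a constant-weight graph maps to 1 everywhere so adjacency graphs keep
their connectivity.

## Model

The forecaster couples two modules trained with **separate Adam
optimizers** and separate losses; no gradient flows between them.

**Spatial module** `M_s`: a stack of order-1 Weisfeiler–Leman
message-passing layers,

    out_i = W_self x_i + W_neigh Σ_j w(i,j) x_j + b,

with ReLU and dropout between layers, none after the last, and a linear
head mapping to one scalar per node. One shared module is applied to
every quarter's feature matrix, producing the estimate series
`ŷ_i(1..T)`. Message passing always runs on the full graph, so unlabeled
nodes' features inform their neighbours and vice versa.

**Temporal module** `M_t`: a per-node LSTM over the scalar `ŷ` series
with a residual connection — the recurrent stack emits a *correction*
added to its input, so an uninformative `M_t` degrades to persistence of
the spatial estimate instead of noise. Outputs are aligned one step
ahead: the output at input step `t` is the prediction of `h(t+1)`, so the
output at the final observed step is a genuine forecast. (The
reconstruction alignment is selectable.) Longer horizons roll the model
forward closed-loop, feeding each prediction back as the next input.

**Losses.** Both modules minimize MAPE plus an optional explicit L2 term,
with Adam weight decay on top:

    loss1 = MAPE(h_K(t), ŷ_K(t)) + λ L2(M_s)
    loss2 = MAPE(h_K(t+1), o_K(t)) + λ L2(M_t)

Each epoch takes one batch-gradient Adam step for `M_s` over the mean of
the per-quarter losses, then one step for `M_t` on the detached,
training-mode (dropout-active) `ŷ` series. Training on the dropout-noised
series matters: the temporal module must not calibrate itself to
memorized in-sample spatial estimates it will never see for cold-start
nodes. A per-timestep update mode (`ms_update="per_step"`) is available.

MAPE denominators are floored: `|h|` is replaced by `max(|h|, eps)`.
Reported metrics use `eps = 1e-3` throughout. The *training* floor
defaults to `1e-2` (`TrainConfig.mape_eps`): quarterly refusal fractions
are legitimately zero or near-zero in small cells, and a 1e-3 floor lets
those cells contribute relative errors in the hundreds, which both
destabilizes the gradient and pushes the MAPE-optimal solution far below
the conditional mean. Desk-scale benchmark runs raise it to 0.15 (the
typical hesitancy scale of the synthetic panels) for the same reason.

Parameters of both modules are Polyak-averaged over the final 25% of
epochs (`TrainConfig.tail_average`); with full-batch training this
removes most seed-to-seed wobble at no cost.

**Defaults** mirror the reference configuration: 2 message-passing layers,
hidden 256 (desk-scale experiments use 32), 50% dropout (desk: 60% after
observing stronger neighbourhood memorization at small N), LSTM hidden 32
(desk: 8), lr 5e-4 (desk: 2e-3), weight decay 5e-4, 15000 epochs (desk:
2500). Hidden sizes, depths, dropout, λ and the update mode are all
configurable.

## Evaluation

Metrics on the held-out nodes at the target step: MAPE, MSE, RMSE, MAE
and R², over observed cells only. Baselines share the split and panel:

* `lrn` — OLS on `[nc_i(T), Σ_{j∈N(i)∩K} h_j(T) w(i,j)]`;
* `mlp` — feedforward net on flattened feature history;
* `gnn_gru` — the framework with a GRU temporal module;
* `gcn_lstm` — spatial layers swapped for symmetric-normalized
  convolution with self-loops (shared self/neighbour weights);
* `gnn_only` — spatial module alone; its T+1 forecast reuses the last
  feature step (features-persist assumption);
* `lstm_only` — temporal module trained on labeled nodes' observed `h`
  series and **applied to the eval nodes' own observed histories**. This
  deliberately breaks the cold-start contract (it is the only model that
  reads eval-node hesitancy) and is reported as the reference ablation in
  that easier information regime.

## Spatial statistics

* **Moran's I** with the unweighted mean and a hollow weight matrix;
  errors on constant fields and edgeless graphs.
* **Isolation index** `Σ_i (h_i p_i / Σ_j h_j p_j) h_i`, the
  hesitant-population-share-weighted average of hesitancy.
* **Kulldorff Poisson scan** on a graph: cases `c_i = round(h_i p_i)`;
  candidate zones are hop-count-ordered neighbourhood prefixes around
  every seed node up to half the total population (the graph analogue of
  distance-ordered circles); `LLR = c ln(c/e) + (C−c) ln((C−c)/(C−e))`
  for `c > e`, else 0; Monte-Carlo significance by multinomial
  redistribution of the `C` cases with probabilities `p_i / P`, ranking
  each reported cluster's LLR against the replicate maxima (exact for the
  primary cluster, conservative for secondaries); overlapping secondary
  clusters are removed greedily in LLR order.

## Active learning

Starting from an initial set (uniform random by default; `scattered` =
greedy max-min over shortest paths with edge length `1/w`, seeded at a
diameter endpoint; `closer` = greedy heaviest-edge growth), the loop
repeats `B` times: retrain from scratch at a reduced epoch count, score
every unlabeled node by the euclidean norm of (its forecast minus the
vector of training labels at the target step), query the argmax (ties to
the lowest index). The norm scoring favours candidates whose predicted
hesitancy is far from the bulk of observed labels — output-space
diversity; a min-distance variant is selectable.

## Synthetic data

The generator emulates the statistical structure of a claims-derived
panel, not any real geography:

* random planar centroids with Delaunay adjacency (connected by
  construction);
* gravity-law ZIP-to-ZIP contact targets (`pop_i pop_j / d²` on Delaunay
  neighbours plus thinned long-range pairs), split into person-level
  contact edges whose aggregation reproduces the targets exactly;
* demographic composition per field as SAR-smoothed latent Gaussian
  fields (`(I − ρW)⁻¹` over the row-normalized contact graph) passed
  through a softmax, drifting in time as a stationary AR(1) with
  coefficient `share_ar = 0.9` — neighbouring ZIPs have similar, slowly
  changing claimant mixes;
* a latent logit rate: base rate + centered composition effect
  (`beta` on the Hispanic, Medicaid and other/unknown-race shares) +
  a small AR(1) SAR-smoothed fluctuation + a linear trend. The
  composition effect is centered per quarter so the panel-wide level is
  governed by `base_rate` and `trend` alone;
* children per cell `p_i(t) ~ Poisson(lognormal pop)`, refusals binomial,
  per-child demographic draws multinomial from the cell's shares; claims
  records (1–4 per child per quarter, one Z28-coded claim for refusers)
  reproduce `p` and `h` exactly under the ETL.

Default conditions: `N=100, TS=12, rho=0.6, base_rate=0.10,
beta=(2.5, −1.2, 1.8), trend=0.05, noise_sd=0.03, share_ar=0.9,
pop ~ lognormal(5.9, 0.35)` (median ≈ 350 children per ZIP-quarter).
These were chosen to match the qualitative properties of the motivating
claims data — strong positive spatial autocorrelation (Moran's I ≈ 0.5),
a rising trend, composition-driven cross-ZIP differences observed almost
noiselessly through claim counts, and refusal outcomes observed sparsely
(tens of events per cell), so each cell's quarterly rate is individually
noisy. That last asymmetry is what the architecture exploits: features
and the graph recover the latent rate, while pure history models face the
binomial noise.

What the generator does **not** emulate: real ZIP geography or
population shares, seasonality, reporting artefacts, coverage changes,
claim-cost structure, or correlation between population size and
demographic composition. Passing tests show the pipeline recovers planted
structure of this kind; they do not certify performance on any real
claims system.

## Numerical choices

* Neural layers and reverse-mode autodiff are implemented in-package on
  numpy (float64): GraphConv/GCN layers, LSTM/GRU cells with combined
  gate matrices (forget bias 1), inverted dropout, Glorot init, Adam.
  Training is deterministic given `TrainConfig.seed`; one Generator
  drives init and dropout.
* Spatial training batches all quarters into one `[T, N, X]` tensor pass.
* Min-max normalizations map constant columns to 0 (features) or keep
  constant edge weights at 1 (graphs); re-normalizing a normalized graph
  is a no-op.
* Scan zone enumeration is O(N²) zones with vectorized LLR; Monte-Carlo
  replicates reuse the zone membership matrix.
* Degenerate inputs raise: empty labeled sets, constant fields,
  zero-case scans, horizons < 1, coincident centroids, divergent latent
  fields.

## Desk-scale experiment sizes

All shipped experiments run on one CPU: benchmark `N=100, TS=12` with
2500 epochs and hidden sizes 32/8; graph-variant comparison at `N=60`;
active learning at `N=150` with 80-epoch retrains inside the query loop
and 500-epoch final fits; scan recovery at `N=60` with 199 Monte-Carlo
replicates. The reproduction script (`scripts/acceptance.py`) uses the
same sizes.

## Known limitations

* MAPE-trained models under-predict wide-spread targets; the training
  floor mitigates but does not remove this.
* The `lstm_only` ablation sees eval-node histories (by design, as the
  reference regime); under low observation noise it can rival or beat
  the cold-start models — orderings between them are regime-dependent.
* Monte-Carlo p-values for secondary scan clusters are conservative.
* The hand-rolled autodiff engine favours clarity over speed; large-N
  or deep configurations are CPU-bound.
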