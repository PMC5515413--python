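# halflife-xfer

Predicting **in-tissue protein half-lives from cellular properties**.

Proteome-dynamics experiments measure protein turnover far more easily in
cell culture (SILAC) than in living tissue (¹⁵N or heavy-water labeling), so
for most proteins only the cellular half-life is known. This package
implements a transfer model that learns, from the proteins measured in both
compartments, how tissue half-life relates to cellular half-life and other
cellular properties — and then predicts tissue half-lives for proteins
observed only in cell culture.

## The method

For the *common* proteins (measured in both compartments), fit the ordinary
least-squares line between tissue and cellular half-life (raw hours),

```
Y = m·X + w
```

and partition proteins by their relative deviation from the line,
`d = (Y − (mX + w)) / (mX + w)`, into three clusters: **C1** (`d > 0.10`),
**C2** (`|d| ≤ 0.10`, the strongly correlated core), **C3** (`d < −0.10`).
Each cluster *c* gets its own multivariate linear predictor

```
Ŷ = w_cell·X + w_PL·PL + w_PA·PA + w_ID·ID + w_MR·MR + w_TR·TR + w_TL·TL + w_c
```

over the cellular half-life and the log-transformed protein length (PL),
abundance (PA), intrinsically-disordered-segment count (ID), mRNA level
(MR), and transcription/translation rates (TR, TL). The intercept `w_c` is
fixed from the cluster's own regression; the seven weights, box-bounded in
(0, 1), are trained by a real-valued **genetic algorithm** minimizing the
summed relative error `Σ |Ŷ − Y| / Y` over a random one-third of the
cluster. The held-out two-thirds are scored by the **percentage of error**
`PE = |Ŷ − Y| / Y` at 5/10/20/30% thresholds, in two feature modes: ACH
(all properties) and PCH (only properties positively correlated with the
tissue half-life; the rest get weight exactly 0).

Proteins measured only in cell culture are routed to a cluster by a small
feedforward **neural network** (one hidden layer, 24 logistic units, class
priors applied) over the same seven properties, predicted by that cluster's
model, and given a zero-mean Gaussian noise draw calibrated to the
cluster's tissue half-life spread. Cell half-lives beyond the assay's
quantifiable range (> 200 h) are filtered first, and the minority of
proteins with *shorter* half-life in tissue than in culture is set aside
from model fitting and routed through the same trained machinery.

A seedable synthetic-data generator produces datasets with this exact
structure (three deviation bands around a known line, auxiliary properties
with configurable signed correlations, cell-only and shorter-in-tissue
subgroups), so every stage is testable against known generating truth.

## Worked example

```python
from halflife_xfer import (assign_clusters, fit_cluster_regression,
                           fit_global_regression, generate, liverlike_preset)

dataset, truth = generate(liverlike_preset(seed=1))   # 366 common proteins
fit = fit_global_regression(dataset)
asn = assign_clusters(dataset, fit, band_width=0.10)
print(fit.slope, fit.intercept, asn.sizes)
```

Running `python examples/02_band_clustering.py` (which adds the per-cluster
fits) prints:

```
global line: Y = 0.5118 * X + 148.33 h (r = 0.392, n = 366)
cluster sizes: {'C1': 135, 'C2': 67, 'C3': 164}
  C1: w_c =   213.78 h, slope = 0.8876, within-cluster r = 0.722
  C2: w_c =   144.99 h, slope = 0.5670, within-cluster r = 0.982
  C3: w_c =    87.03 h, slope = 0.3517, within-cluster r = 0.590
```

The refitted line recovers the generating slope/intercept (0.60863,
141.29 h) within sampling error; the band sizes scatter around the
generating 130/67/169; and the within-band core C2 shows a far stronger
tissue~cell correlation (0.98) than the full cloud (0.39) — the
observation the clustering is designed to exploit. `examples/03` to
`examples/05` continue with GA training (the C2 cell-half-life weight
comes out near the C2 regression slope), PE tables (C2 predicts best),
classifier training, and noise-injected prediction of cell-only proteins.

The `halflife-xfer` CLI exposes the same stages
(`simulate | cluster | train | classify-train | classify | predict | run`).

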