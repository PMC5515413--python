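"""End-to-end run: predict tissue half-lives for cell-culture-only proteins.

The pipeline simulates a cohort where 40% of proteins lack a tissue
measurement, trains everything on the common majority, removes cell
half-lives beyond the assay's >200 h quantifiable range, routes each
uncommon protein to a band with the classifier, predicts with that
band's linear model, and adds zero-mean Gaussian noise calibrated to the
band's tissue half-life spread.
"""

import numpy as np

from halflife_xfer import RunConfig, liverlike_preset, run_pipeline

cfg = RunConfig(generator=liverlike_preset(uncommon_fraction=0.4,
                                           shorter_fraction=0.1),
                seed=1)
report = run_pipeline(cfg)

print(f"records: {report['n_records']} "
      f"({report['n_common']} common, {report['n_uncommon']} cell-only)")
print(f"removed for cell half-life > 200 h: {report['n_removed_long_cell']}")
print(f"shorter-in-tissue subgroup set aside: {report['n_shorter_in_tissue']}")
print(f"model cohort cluster sizes: {report['cluster_sizes']}")
print(f"noise sd per cluster (h): "
      + ", ".join(f"{c}: {s:.0f}" for c, s in report['noise']['sds'].items()))

preds = report["_predictions"]
print(f"\npredicted {len(preds)} uncommon proteins; first three:")
for p in preds[:3]:
    print(f"  {p.protein_id}: {p.assigned_cluster}, "
          f"deterministic {p.predicted_halflife_deterministic:7.1f} h, "
          f"with noise {p.predicted_halflife_noisy:7.1f} h")
dets = np.array([p.predicted_halflife_deterministic for p in preds])
print(f"predicted tissue half-life median {np.median(dets):.1f} h")
print("-> per-band predictions fall on three lines; the noise draw restores")
print("   the biological scatter seen around each band's regression line.")
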