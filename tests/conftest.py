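import dataclasses

import numpy as np
import pytest

from halflife_xfer import (GeneratorConfig, ProteinRecord, RegressionFit,
                           generate, liverlike_preset)
from halflife_xfer.datamodel import feature_matrix


def make_record(pid="P1", cell=50.0, tissue=170.0, **overrides) -> ProteinRecord:
    base = dict(protein_id=pid, cell_halflife=cell, tissue_halflife=tissue,
                length=300, abundance=1000.0, disorder_count=2,
                mrna_level=40.0, transcription_rate=5.0, translation_rate=12.0)
    base.update(overrides)
    return ProteinRecord(**base)


def true_line_fit(cfg: GeneratorConfig) -> RegressionFit:
    """The generator's own line wrapped as a reference fit."""
    return RegressionFit(slope=cfg.slope_true, intercept=cfg.intercept_true,
                         n=0, pearson_r=float("nan"), p_value=float("nan"))


ZERO_CORR = {k: 0.0 for k in ("length", "abundance", "disorder_count",
                              "mrna_level", "transcription_rate",
                              "translation_rate")}


def exact_linear_cluster(n=90, weights=None, intercept=141.28857, seed=3):
    """Records whose tissue half-life follows the multivariate linear
    model exactly (independent features, no noise) — GA recovery truth."""
    if weights is None:
        weights = np.array([0.6, 0.3, 0.25, 0.15, 0.4, 0.2, 0.35])
    ds, _ = generate(liverlike_preset(seed=seed, n_proteins=n,
                                      property_correlations=dict(ZERO_CORR)))
    feats = feature_matrix(ds.records)
    ys = feats @ np.asarray(weights) + intercept
    recs = [dataclasses.replace(r, tissue_halflife=float(y))
            for r, y in zip(ds.records, ys)]
    return recs, np.asarray(weights, dtype=float), intercept


@pytest.fixture(scope="session")
def liverlike():
    """One liver-like synthetic dataset shared across read-only tests."""
    ds, truth = generate(liverlike_preset(seed=42))
    return ds, truth
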