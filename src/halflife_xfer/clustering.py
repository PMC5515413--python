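"""Tissue~cell half-life regression, residual-band clustering, and
per-cluster property correlations.

The global ordinary-least-squares line Y = m*X + w (tissue on cell
half-life, raw hours) defines a relative deviation per protein,

    d = (Y - (m*X + w)) / (m*X + w),

and the common proteins partition into three bands: C1 above +10%
deviation, C2 within +/-10% (the strongly correlated core), C3 below
-10%. Each band then gets its own OLS refit whose intercept is the fixed
offset of that cluster's multivariate predictor, and a per-cluster
Pearson correlation profile of every transformed property against the
tissue half-life decides the reduced "positively-correlated" (PCH)
feature subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datamodel import (Dataset, FEATURE_NAMES, InsufficientDataError,
                        ProteinRecord, TransformConfig, feature_matrix)

CLUSTERS = ("C1", "C2", "C3")


class DegenerateLineError(ValueError):
    """Fitted value m*X + w is non-positive for some protein."""


@dataclass(frozen=True)
class RegressionFit:
    """Bivariate OLS fit of tissue on cell half-life."""

    slope: float
    intercept: float
    n: int
    pearson_r: float
    p_value: float

    def predict(self, cell_halflife) -> np.ndarray:
        return self.slope * np.asarray(cell_halflife, dtype=float) + self.intercept


@dataclass
class ClusterAssignment:
    """Band partition of the common proteins around a reference line."""

    labels: dict[str, str]           # protein_id -> C1/C2/C3
    deviations: dict[str, float]     # protein_id -> relative deviation d
    band_width: float
    reference_fit: RegressionFit

    def members(self, cluster: str) -> list[str]:
        return [pid for pid, lab in self.labels.items() if lab == cluster]

    @property
    def sizes(self) -> dict[str, int]:
        return {c: len(self.members(c)) for c in CLUSTERS}


@dataclass
class CorrelationProfile:
    """Per-cluster Pearson correlation of each transformed property with
    the tissue half-life; ``pch_mask[c][i]`` is True iff property i is
    positively correlated in cluster c (and hence kept in PCH mode)."""

    correlations: dict[str, dict[str, float]]
    pch_mask: dict[str, np.ndarray]
    excluded: dict[str, list[str]] = field(default_factory=dict)


def _xy(records: list[ProteinRecord]) -> tuple[np.ndarray, np.ndarray]:
    common = [r for r in records if r.is_common]
    x = np.array([r.cell_halflife for r in common])
    y = np.array([r.tissue_halflife for r in common])
    return x, y


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    if len(x) < 3:
        raise InsufficientDataError(
            f"need at least 3 points with both half-lives, got {len(x)}")
    res = stats.linregress(x, y)
    return RegressionFit(slope=float(res.slope), intercept=float(res.intercept),
                         n=len(x), pearson_r=float(res.rvalue),
                         p_value=float(res.pvalue))


def fit_global_regression(dataset: Dataset) -> RegressionFit:
    """OLS of tissue on cell half-life over all common proteins (raw hours)."""
    return _ols(*_xy(dataset.records))


def relative_deviation(record: ProteinRecord, fit: RegressionFit) -> float:
    """Signed relative deviation of a protein from the regression line."""
    if not record.is_common:
        raise InsufficientDataError(
            f"protein {record.protein_id} has no tissue half-life")
    pred = fit.slope * record.cell_halflife + fit.intercept
    if pred <= 0:
        raise DegenerateLineError(
            f"fitted value {pred:.4g} h <= 0 for protein {record.protein_id}")
    return (record.tissue_halflife - pred) / pred


def _band_label(d: float, band_width: float) -> str:
    # ties |d| == band_width fall in C2 ("between" read as inclusive)
    if d > band_width:
        return "C1"
    if d < -band_width:
        return "C3"
    return "C2"


def assign_clusters(dataset: Dataset, fit: RegressionFit,
                    band_width: float = 0.10,
                    denominator: str = "fitted") -> ClusterAssignment:
    """Partition common proteins into the three deviation bands.

    ``denominator`` selects what d is relative to: the fitted value
    (default, deviation *from the line*) or the observed tissue
    half-life.
    """
    if denominator not in ("fitted", "observed"):
        raise ValueError("denominator must be 'fitted' or 'observed'")
    labels, deviations = {}, {}
    for rec in dataset.common:
        pred = fit.slope * rec.cell_halflife + fit.intercept
        if pred <= 0:
            raise DegenerateLineError(
                f"fitted value {pred:.4g} h <= 0 for protein {rec.protein_id}")
        denom = pred if denominator == "fitted" else rec.tissue_halflife
        d = (rec.tissue_halflife - pred) / denom
        labels[rec.protein_id] = _band_label(d, band_width)
        deviations[rec.protein_id] = d
    asn = ClusterAssignment(labels, deviations, band_width, fit)
    for c, size in asn.sizes.items():
        if size == 0:
            warnings.warn(f"cluster {c} is empty under band width {band_width}")
    return asn


def fit_cluster_regression(dataset: Dataset, assignment: ClusterAssignment,
                           cluster: str) -> RegressionFit:
    """OLS restricted to one band; its intercept is that cluster's fixed
    offset w_c in the multivariate predictor."""
    ids = set(assignment.members(cluster))
    members = [r for r in dataset.common if r.protein_id in ids]
    if len(members) < 3:
        raise InsufficientDataError(
            f"cluster {cluster} has {len(members)} member(s); need >= 3")
    return _ols(*_xy(members))


def correlation_profile(dataset: Dataset, assignment: ClusterAssignment,
                        transform: TransformConfig = TransformConfig()
                        ) -> CorrelationProfile:
    """Pearson correlation of each transformed property with the tissue
    half-life, per cluster; positive entries define the PCH mask.

    A zero-variance property within a cluster has no defined correlation:
    it is reported as excluded from PCH with a warning.
    """
    correlations: dict[str, dict[str, float]] = {}
    masks: dict[str, np.ndarray] = {}
    excluded: dict[str, list[str]] = {}
    for c in CLUSTERS:
        ids = set(assignment.members(c))
        members = [r for r in dataset.common if r.protein_id in ids]
        if len(members) < 3:
            raise InsufficientDataError(
                f"cluster {c} has {len(members)} member(s); need >= 3")
        feats = feature_matrix(members, transform)
        y = np.array([r.tissue_halflife for r in members])
        corr_c: dict[str, float] = {}
        mask = np.zeros(len(FEATURE_NAMES), dtype=bool)
        dropped: list[str] = []
        for j, name in enumerate(FEATURE_NAMES):
            col = feats[:, j]
            if np.ptp(col) == 0 or np.ptp(y) == 0:
                corr_c[name] = float("nan")
                dropped.append(name)
                warnings.warn(
                    f"property {name} has zero variance in cluster {c}; "
                    "excluded from PCH")
                continue
            r = float(stats.pearsonr(col, y).statistic)
            corr_c[name] = r
            mask[j] = r > 0
        correlations[c] = corr_c
        masks[c] = mask
        if dropped:
            excluded[c] = dropped
    return CorrelationProfile(correlations, masks, excluded)


__all__ = ["CLUSTERS", "RegressionFit", "ClusterAssignment",
           "CorrelationProfile", "DegenerateLineError",
           "fit_global_regression", "relative_deviation", "assign_clusters",
           "fit_cluster_regression", "correlation_profile"]
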