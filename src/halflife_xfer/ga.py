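"""Per-cluster multivariate linear predictor trained by a genetic algorithm.

Each cluster c predicts the tissue half-life of a protein as

    Y_hat = w . f + w_c

where f is the transformed feature 7-vector (cell half-life in hours,
then log-scale length, abundance, disorder count, mRNA level,
transcription and translation rates), every active weight is box-bounded
in the open interval (0, 1), and the intercept w_c is *fixed* from the
cluster's own tissue~cell regression — it is never optimized.

Training minimizes the summed relative error over a randomly chosen
one-third of the cluster,

    E(w) = sum_s |Y_hat_s - Y_s| / Y_s,

with a real-valued genetic algorithm (tournament selection, blend
crossover, annealed Gaussian mutation, elitism, clipping to the box).
Internally the mean (sum / n_train) is used as fitness — the argmin is
identical and the value is comparable across cluster sizes; the raw sum
is reported alongside.

Two feature modes exist: ACH uses all seven properties; PCH zeroes the
weights of properties negatively correlated with the tissue half-life
in that cluster (they stay exactly 0 throughout the GA).

Held-out performance is summarized as the fraction of the remaining
two-thirds whose percentage of error PE = |Y_hat - Y| / Y falls within
5, 10, 20 and 30%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datamodel import (Dataset, DomainError, FEATURE_NAMES,
                        InsufficientDataError, ProteinRecord, TransformConfig,
                        feature_matrix)
from .clustering import CLUSTERS, ClusterAssignment

PE_THRESHOLDS = (0.05, 0.10, 0.20, 0.30)

_EPS = 1e-6  # open-interval nudge: weights clipped to [eps, 1 - eps]


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings (real-valued encoding, box (0,1))."""

    population_size: int = 50
    generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    mutation_sd: float = 0.1
    mutation_sd_final: float = 0.005
    tournament_size: int = 3
    elitism: int = 2
    seed: int = 0

    def validate(self):
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise DomainError(f"{name} must lie in [0, 1], got {v}")
        if self.population_size < 10:
            raise DomainError("population_size must be >= 10")
        if self.elitism < 1:
            raise DomainError("elitism must be >= 1")


@dataclass
class ClusterModel:
    """Trained weights for one cluster in one feature mode."""

    cluster: str
    weights: np.ndarray            # length 7, canonical feature order
    intercept_wc: float
    mode: str                      # "ACH" or "PCH"
    pch_mask: np.ndarray           # active-weight flags (all True for ACH)
    train_ids: tuple[str, ...]
    seed: int
    objective_mean: float = math.nan
    objective_sum: float = math.nan
    trace: list[float] = field(default_factory=list)  # best mean objective/gen
    transform: TransformConfig = TransformConfig()


@dataclass
class EvaluationTable:
    """Held-out PE-threshold fractions per cluster and feature mode."""

    fractions: dict[str, dict[str, dict[float, float]]]
    n_eval: dict[str, int]
    thresholds: tuple[float, ...] = PE_THRESHOLDS


def predict_linear(features, model: ClusterModel) -> float:
    """Weighted feature sum plus the cluster's fixed intercept (hours)."""
    vals = np.asarray(getattr(features, "values", features), dtype=float)
    if vals.shape[-1] != len(model.weights):
        raise DomainError(
            f"feature/weight length mismatch: {vals.shape[-1]} vs "
            f"{len(model.weights)}")
    return float(vals @ model.weights + model.intercept_wc)


def objective(weights, features: np.ndarray, targets: np.ndarray,
              intercept_wc: float, reduce: str = "sum") -> float:
    """Relative-error objective sum_s |Y_hat - Y| / Y over a training set."""
    targets = np.asarray(targets, dtype=float)
    if targets.size == 0:
        raise InsufficientDataError("empty training set")
    if np.any(targets <= 0):
        raise DomainError("all target tissue half-lives must be positive")
    w = np.atleast_2d(np.asarray(weights, dtype=float))
    preds = w @ features.T + intercept_wc           # (pop, n)
    rel = np.abs(preds - targets) / targets
    out = rel.sum(axis=1) if reduce == "sum" else rel.mean(axis=1)
    return float(out[0]) if np.asarray(weights).ndim == 1 else out


def split_training(cluster_members: list[ProteinRecord], seed: int
                   ) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Random one-third training sample; remainder is held out."""
    n = len(cluster_members)
    if n < 6:
        raise InsufficientDataError(
            f"cluster has {n} member(s); need >= 6 to split 1/3 vs 2/3")
    n_train = round(n / 3)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    train = [cluster_members[i] for i in idx[:n_train]]
    test = [cluster_members[i] for i in idx[n_train:]]
    return train, test


def _minimize_ga(features: np.ndarray, targets: np.ndarray, intercept: float,
                 active: np.ndarray, cfg: GAConfig
                 ) -> tuple[np.ndarray, float, list[float]]:
    """Core real-valued GA over the active weight coordinates."""
    rng = np.random.default_rng(cfg.seed)
    n_dim = int(active.sum())
    pop = rng.uniform(_EPS, 1 - _EPS, size=(cfg.population_size, n_dim))

    f_act = features[:, active]

    def fitness(p):
        preds = p @ f_act.T + intercept
        return (np.abs(preds - targets) / targets).mean(axis=1)

    fit = fitness(pop)
    trace: list[float] = []
    # mutation scale anneals geometrically for fine convergence late on
    decay = (cfg.mutation_sd_final / cfg.mutation_sd) ** (
        1.0 / max(cfg.generations - 1, 1))
    sd = cfg.mutation_sd
    for _ in range(cfg.generations):
        order = np.argsort(fit)
        elite = pop[order[: cfg.elitism]].copy()

        # tournament selection
        n_off = cfg.population_size - cfg.elitism
        cand = rng.integers(0, cfg.population_size,
                            size=(n_off, cfg.tournament_size))
        parents = pop[cand[np.arange(n_off), np.argmin(fit[cand], axis=1)]]

        # BLX-alpha crossover on consecutive pairs: children sampled from
        # the parents' interval expanded by 30% on each side, so the
        # population does not contract prematurely
        children = parents.copy()
        do_cx = rng.random(n_off // 2) < cfg.crossover_rate
        a, b = children[0::2][: n_off // 2], children[1::2][: n_off // 2]
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        span = hi - lo
        lo_x, hi_x = lo - 0.3 * span, hi + 0.3 * span
        mixed_a = rng.uniform(size=a.shape) * (hi_x - lo_x) + lo_x
        mixed_b = rng.uniform(size=b.shape) * (hi_x - lo_x) + lo_x
        a[do_cx], b[do_cx] = mixed_a[do_cx], mixed_b[do_cx]

        # mutation: mostly Gaussian perturbation (annealed scale), but a
        # fifth of mutated genes are redrawn uniformly over the box to
        # keep an escape route from local valleys of the piecewise-
        # linear objective
        mut = rng.random(children.shape) < cfg.mutation_rate
        gauss = children + rng.normal(0.0, sd, size=children.shape)
        fresh = rng.uniform(_EPS, 1 - _EPS, size=children.shape)
        use_fresh = rng.random(children.shape) < 0.2
        children = np.where(mut, np.where(use_fresh, fresh, gauss), children)
        np.clip(children, _EPS, 1 - _EPS, out=children)
        sd *= decay

        pop = np.vstack([elite, children])
        fit = fitness(pop)
        trace.append(float(fit.min()))

    best = pop[np.argmin(fit)]
    w = np.zeros(len(active))
    w[active] = best
    return w, float(fit.min()), trace


def train_cluster_model(cluster_members: list[ProteinRecord],
                        intercept_wc: float, mode: str = "ACH",
                        pch_mask: np.ndarray | None = None,
                        ga_config: GAConfig = GAConfig(),
                        transform: TransformConfig = TransformConfig(),
                        cluster: str = "C2") -> ClusterModel:
    """GA-train one cluster's weights on a random one-third split.

    In PCH mode ``pch_mask`` (from the cluster's correlation profile)
    fixes negatively-correlated properties at weight 0.
    """
    ga_config.validate()
    if mode not in ("ACH", "PCH"):
        raise DomainError(f"mode must be 'ACH' or 'PCH', got {mode!r}")
    if mode == "PCH":
        if pch_mask is None:
            raise DomainError("PCH mode requires a pch_mask")
        active = np.asarray(pch_mask, dtype=bool)
    else:
        active = np.ones(len(FEATURE_NAMES), dtype=bool)
    if not active.any():
        raise InsufficientDataError("no active features to optimize")

    train, _ = split_training(cluster_members, seed=ga_config.seed)
    feats = feature_matrix(train, transform)
    targets = np.array([r.tissue_halflife for r in train])
    if np.any(targets <= 0):
        raise DomainError("all training tissue half-lives must be positive")

    w, best_mean, trace = _minimize_ga(feats, targets, intercept_wc,
                                       active, ga_config)
    return ClusterModel(
        cluster=cluster, weights=w, intercept_wc=intercept_wc, mode=mode,
        pch_mask=active, train_ids=tuple(r.protein_id for r in train),
        seed=ga_config.seed, objective_mean=best_mean,
        objective_sum=best_mean * len(train), trace=trace,
        transform=transform)


def percentage_error(predicted: float, observed: float) -> float:
    """PE = |predicted - observed| / observed (scale-invariant)."""
    if observed <= 0:
        raise DomainError(f"observed half-life must be positive, got {observed}")
    return abs(predicted - observed) / observed


def pe_fractions(pes, thresholds=PE_THRESHOLDS) -> dict[float, float]:
    pes = np.asarray(list(pes), dtype=float)
    return {t: float(np.mean(pes <= t)) for t in thresholds}


def evaluate_pe_table(models: dict[str, dict[str, ClusterModel]],
                      assignment: ClusterAssignment, dataset: Dataset,
                      thresholds=PE_THRESHOLDS) -> EvaluationTable:
    """Held-out PE-threshold fractions for every trained cluster x mode.

    ``models`` maps cluster -> mode -> ClusterModel; each model is
    evaluated on its cluster's members outside its own training third.
    """
    by_id = {r.protein_id: r for r in dataset.common}
    fractions: dict[str, dict[str, dict[float, float]]] = {}
    n_eval: dict[str, int] = {}
    for c in CLUSTERS:
        if c not in models:
            continue
        member_ids = assignment.members(c)
        for mode, model in models[c].items():
            held = [by_id[pid] for pid in member_ids
                    if pid not in set(model.train_ids) and pid in by_id]
            if not held:
                import warnings
                warnings.warn(f"cluster {c} mode {mode}: empty evaluation set")
                continue
            feats = feature_matrix(held, model.transform)
            preds = feats @ model.weights + model.intercept_wc
            pes = [percentage_error(p, r.tissue_halflife)
                   for p, r in zip(preds, held)]
            fractions.setdefault(c, {})[mode] = pe_fractions(pes, thresholds)
            n_eval[c] = len(held)
    return EvaluationTable(fractions, n_eval, tuple(thresholds))


__all__ = ["PE_THRESHOLDS", "GAConfig", "ClusterModel", "EvaluationTable",
           "predict_linear", "objective", "split_training",
           "train_cluster_model", "percentage_error", "pe_fractions",
           "evaluate_pe_table"]
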