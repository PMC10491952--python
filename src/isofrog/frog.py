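"""Stochastic trans-dimensional feature-subset search (random-frog style).

A single chain walks over feature subsets of the task.  Each iteration
samples a candidate cardinality Q' from a truncated normal centred on the
current cardinality Q0 (standard deviation alpha*Q0, support
[Q0 - alpha*Q0, Q0 + alpha*Q0] intersected with [1, p]), builds a candidate
subset of exactly Q' features, scores both subsets by 3-fold
cross-validated AUC of the MdiPLS predictor, and accepts the candidate with
probability 1 if it improves the AUC, otherwise with probability at most
omega.  After N iterations the selection probability of feature i is
sp_i = N_i / N where N_i counts the iterations whose accepted subset
contained i — a Monte-Carlo measure of feature importance.

No detailed-balance correction is attempted; the chain is a heuristic
search in the spirit of reversible-jump MCMC, not a calibrated sampler.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import DataError, FeatureSubset, PredictionTask, apply_feature_subset
from .evaluation import auc, evaluable_units, stratified_gene_folds
from .mdipls import MdiplsConfig, clip_components, fit, predict

logger = logging.getLogger(__name__)

__all__ = [
    "FrogParams",
    "FrogResult",
    "sample_cardinality",
    "rank_features",
    "propose_subset",
    "cv_auc",
    "acceptance_probability",
    "run_frog",
]


@dataclass
class FrogParams:
    """Chain parameters.

    n_iterations: N, total iterations (the published recommendation is 2000
        for full-scale data; small synthetic problems converge much faster).
    q_init: Q, cardinality of the random initial subset.
    alpha: spread factor of the cardinality proposal.
    mu: expansion factor of the candidate pool when growing.
    omega: ceiling of the acceptance probability for worse candidates.
    inner_cv_folds: folds of the AUC evaluation inside the chain.
    cache_auc0: reuse the incumbent's AUC from the previous iteration
        instead of re-evaluating it on the iteration's folds (faster, but
        the comparison then mixes fold draws).
    """

    n_iterations: int = 2000
    q_init: int = 2
    alpha: float = 0.3
    mu: float = 10.0
    omega: float = 0.1
    inner_cv_folds: int = 3
    rng_seed: int = 0
    cache_auc0: bool = False

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.q_init < 1:
            raise ValueError("q_init must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.mu < 1:
            raise ValueError("mu must be >= 1")
        if not 0 <= self.omega <= 1:
            raise ValueError("omega must be in [0, 1]")
        if self.inner_cv_folds < 2:
            raise ValueError("inner_cv_folds must be >= 2")


@dataclass
class FrogResult:
    """Per-feature selection counts and probabilities over the N iterations."""

    feature_ids: list[str]
    selection_counts: np.ndarray      # integer N_i
    n_iterations: int
    trajectory: pd.DataFrame | None = field(default=None)

    @property
    def selection_probabilities(self) -> np.ndarray:
        return self.selection_counts / self.n_iterations

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "n_selected": self.selection_counts.astype(int),
                "selection_probability": self.selection_probabilities,
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def sample_cardinality(
    q0: int, alpha: float, p: int, rng: np.random.Generator
) -> int:
    """Draw the candidate cardinality: Q' = round(u) with
    u ~ Normal(q0, alpha*q0) re-drawn (rejection, not clipping) until it
    lies in [q0 - h, q0 + h], h = max(1, alpha*q0), then clamped to [1, p].

    The interval is enforced on the real-valued draw before rounding, and
    its half-width is floored at one feature.  Both choices keep the chain
    irreducible over cardinalities: restricting the rounded integer to
    [q0 - alpha*q0, q0 + alpha*q0] would leave q0 as the only reachable
    value whenever alpha*q0 < 1, freezing small chains (and making
    cardinality 1 an absorbing trap), which defeats the trans-dimensional
    jumps the search relies on.  The proposal spread itself stays alpha*q0,
    so as alpha -> 0 the cardinality still pins to q0, and for
    alpha*q0 >= 1 the support is exactly the nominal interval.
    """
    if not 1 <= q0 <= p:
        raise ValueError(f"q0={q0} outside [1, {p}]")
    half = max(1.0, alpha * q0)
    lo = q0 - half
    hi = q0 + half
    u = float(q0)
    for _ in range(1000):
        u = rng.normal(q0, alpha * q0)
        if lo <= u <= hi:
            break
    else:
        u = float(q0)
    return int(np.clip(np.rint(u), 1, p))


def rank_features(
    subset: FeatureSubset, task: PredictionTask, config: MdiplsConfig
) -> list[int]:
    """Order the subset's features by importance in a fitted MdiPLS model.

    Importance of feature j = |b_j| of the model fitted on the task
    restricted to the subset.  Descending by importance, ties broken by
    ascending column index for determinism.
    """
    if len(subset) == 1:
        return list(subset.indices)
    sub_task = apply_feature_subset(task, subset)
    cfg = clip_components(config, len(subset))
    try:
        model = fit(sub_task, cfg)
    except Exception as exc:  # propagate with subset context
        raise RuntimeError(f"MdiPLS fit failed on subset {subset.indices}") from exc
    importance = np.abs(model.b)
    cols = np.asarray(subset.indices)
    order = np.lexsort((cols, -importance))
    return [int(cols[i]) for i in order]


def propose_subset(
    v0: FeatureSubset,
    q_new: int,
    mu: float,
    task: PredictionTask,
    config: MdiplsConfig,
    rng: np.random.Generator,
) -> FeatureSubset:
    """Build a candidate subset of exactly ``min(q_new, p)`` features.

    Same cardinality: the incumbent is returned unchanged.  Shrinking: keep
    the top q_new features of the incumbent by model importance.  Growing:
    pool the incumbent with ``min(ceil(mu*(q_new-|v0|)), p-|v0|)`` features
    drawn uniformly from outside it, then keep the pool's top q_new.
    """
    p = task.n_features
    if not 1 <= q_new <= p:
        raise ValueError(f"q_new={q_new} outside [1, {p}]")
    q0 = len(v0)
    if q_new == q0:
        return v0
    if q_new < q0:
        ranked = rank_features(v0, task, config)
        return FeatureSubset(ranked[:q_new])
    outside = np.setdiff1d(np.arange(p), np.asarray(v0.indices))
    n_draw = min(int(np.ceil(mu * (q_new - q0))), len(outside))
    drawn = rng.choice(outside, size=n_draw, replace=False)
    pooled = FeatureSubset(list(v0.indices) + [int(i) for i in drawn])
    ranked = rank_features(pooled, task, config)
    return FeatureSubset(ranked[:q_new])


def cv_auc(
    subset: FeatureSubset,
    task: PredictionTask,
    folds: int,
    config: MdiplsConfig,
    seed: int,
) -> float:
    """Cross-validated AUC of MdiPLS on the task restricted to a subset.

    Genes are split into label-stratified folds; each fold's model is fitted
    on the remaining genes' task (isoforms follow their genes) and scores
    that fold's evaluable units (SIG isoforms plus max-aggregated MIGs).
    Held-out predictions are pooled over folds into one AUC.
    """
    if len(subset) == 0:
        raise DataError("empty feature subset")
    sub = apply_feature_subset(task, subset)
    cfg = clip_components(config, len(subset))
    all_scores: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []
    for train_idx, test_idx in stratified_gene_folds(task.yg, folds, seed):
        train_genes = [sub.gene_ids[i] for i in train_idx]
        test_genes = [sub.gene_ids[i] for i in test_idx]
        train_task = sub.restrict_genes(train_genes)
        model = fit(train_task, cfg)
        test_map = sub.mapping.restrict_genes(test_genes)
        iso_idx = sub.iso_index
        test_isos = test_map.isoforms
        X_test = sub.Xiso[[iso_idx[t] for t in test_isos]]
        # model.column_means are the training-row means in sub-task
        # coordinates, so held-out sub-task rows center correctly
        scores = predict(model, X_test)
        label_of = {g: sub.label_of_gene(g) for g in test_genes}
        units = evaluable_units(scores, test_isos, test_map, label_of)
        s, y = units["pooled"]
        all_scores.append(s)
        all_labels.append(y)
    return auc(np.concatenate(all_scores), np.concatenate(all_labels))


def acceptance_probability(auc0: float, auc_new: float, omega: float) -> float:
    """P' = 1 if the candidate improves the AUC; otherwise
    P' = omega * (AUC' + 0.001) / (AUC0 + 0.001), which never exceeds omega.
    The 0.001 offsets guard against AUC0 = 0."""
    if not (0 <= auc0 <= 1 and 0 <= auc_new <= 1):
        raise ValueError("AUC values must lie in [0, 1]")
    if not 0 <= omega <= 1:
        raise ValueError("omega must be in [0, 1]")
    if auc_new > auc0:
        return 1.0
    return omega * (auc_new + 0.001) / (auc0 + 0.001)


def run_frog(
    task: PredictionTask,
    params: FrogParams,
    config: MdiplsConfig | None = None,
    keep_trajectory: bool = False,
) -> FrogResult:
    """Run the chain for N iterations and tally selection probabilities.

    The recorded subset of each iteration is the incumbent *after* the
    accept/reject step, so counts reflect the chain's state.  Within one
    iteration the incumbent and the candidate are scored on the same folds
    (per-iteration fold seed derived from the master seed), making the
    comparison fair.  Fully reproducible from ``params.rng_seed``.
    """
    config = config or MdiplsConfig()
    p = task.n_features
    rng = np.random.default_rng(params.rng_seed)
    q = min(params.q_init, p)
    v0 = FeatureSubset(rng.choice(p, size=q, replace=False))

    counts = np.zeros(p, dtype=np.int64)
    traj: list[dict] = []
    auc0_cached: float | None = None
    for it in range(params.n_iterations):
        fold_seed = int(rng.integers(2**31))
        q_new = sample_cardinality(len(v0), params.alpha, p, rng)
        v_new = propose_subset(v0, q_new, params.mu, task, config, rng)
        if params.cache_auc0 and auc0_cached is not None:
            auc0 = auc0_cached
        else:
            auc0 = cv_auc(v0, task, params.inner_cv_folds, config, fold_seed)
        if v_new is v0 or v_new.indices == v0.indices:
            auc_new = auc0
        else:
            auc_new = cv_auc(v_new, task, params.inner_cv_folds, config, fold_seed)
        p_accept = acceptance_probability(auc0, auc_new, params.omega)
        accepted = rng.uniform() < p_accept
        if accepted:
            v0 = v_new
            auc0_cached = auc_new
        else:
            auc0_cached = auc0
        counts[list(v0.indices)] += 1
        logger.debug(
            "frog iter %d: |V0|=%d auc0=%.4f auc'=%.4f accepted=%s",
            it, len(v0), auc0, auc_new, accepted,
        )
        if keep_trajectory:
            traj.append(
                {"iteration": it, "cardinality": len(v0), "auc0": auc0,
                 "auc_new": auc_new, "accepted": int(accepted)}
            )
    return FrogResult(
        feature_ids=list(task.col_ids),
        selection_counts=counts,
        n_iterations=params.n_iterations,
        trajectory=pd.DataFrame(traj) if keep_trajectory else None,
    )
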