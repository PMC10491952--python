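"""Evaluation: ranking metrics, group-aware cross-validation, per-feature
relevance testing, and the end-to-end pipeline driver.

Isoform-level ground truth is unavailable for multi-isoform genes, so
evaluation uses two kinds of units: held-out SIG isoforms scored against
their gene's label, and held-out MIGs scored by the *maximum* prediction
score among their isoforms against the gene label.  "Pooled" metrics use
the union of both unit sets, each unit exactly once.

The outer cross-validation keeps every gene of one homolog group (duplicated
genes) in the same fold, so near-identical expression profiles cannot leak
between training and test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .data_model import (
    AnnotationTable,
    DataError,
    ExpressionMatrix,
    FeatureSubset,
    GeneIsoformMap,
    PredictionTask,
    apply_feature_subset,
    build_task,
)
from .mdipls import MdiplsConfig, clip_components, fit, predict, scores_to_probabilities

__all__ = [
    "GroupFoldPlan",
    "EvalReport",
    "group_kfold",
    "auc",
    "auprc",
    "mig_gene_scores",
    "evaluable_units",
    "feature_relevance_ttest",
    "run_pipeline",
    "summarize_reports",
]


# ---------------------------------------------------------------------------
# Fold construction


@dataclass
class GroupFoldPlan:
    """Fold assignment per gene; all genes of one homolog group share a fold."""

    fold_of: dict[str, int]
    n_folds: int

    def fold_genes(self, fold: int) -> list[str]:
        return [g for g, f in self.fold_of.items() if f == fold]


def group_kfold(
    genes: list[str],
    groups: dict[str, str] | None,
    k: int,
    seed: int = 0,
) -> GroupFoldPlan:
    """Assign genes to ``k`` folds without splitting homolog groups.

    Genes absent from ``groups`` form singleton groups.  Groups are packed
    greedily, largest first, into the currently smallest fold (ties broken
    deterministically after a seeded shuffle of equal-sized groups).
    """
    if k < 2:
        raise DataError("k must be >= 2")
    groups = groups or {}
    members: dict[str, list[str]] = {}
    for g in genes:
        members.setdefault(groups.get(g, f"__singleton__{g}"), []).append(g)
    if len(members) < k:
        raise DataError(f"only {len(members)} groups for {k} folds")
    rng = np.random.default_rng(seed)
    order = list(members)
    rng.shuffle(order)
    order.sort(key=lambda gid: -len(members[gid]))  # stable: shuffled ties
    sizes = [0] * k
    fold_of: dict[str, int] = {}
    for gid in order:
        target = int(np.argmin(sizes))
        for g in members[gid]:
            fold_of[g] = target
        sizes[target] += len(members[gid])
    return GroupFoldPlan(fold_of, k)


def stratified_gene_folds(
    labels: np.ndarray, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Label-stratified k-fold over gene indices (used by the inner CV)."""
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**32))
    X_dummy = np.zeros((len(labels), 1))
    return [(tr, te) for tr, te in skf.split(X_dummy, labels)]


# ---------------------------------------------------------------------------
# Metrics


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with half credit for ties:
    (#concordant + 0.5 * #tied) / (n_pos * n_neg), computed from midranks."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("AUC requires both classes")
    ranks = stats.rankdata(scores)
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve by step-wise summation:
    sum over descending score thresholds of (R_i - R_{i-1}) * P_i, i.e.
    precision at each recall change — no trapezoid interpolation."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise DataError("AUPRC requires at least one positive")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], (labels[order] == 1).astype(float)
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # thresholds = last index of each distinct score value
    distinct = np.r_[s[1:] != s[:-1], True]
    tp, fp = tp[distinct], fp[distinct]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    recall_prev = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - recall_prev) * precision))


def mig_gene_scores(
    scores: np.ndarray, iso_ids: list[str], mapping: GeneIsoformMap
) -> dict[str, float]:
    """Gene-level score of each MIG = max over its isoforms' scores."""
    idx = {t: i for i, t in enumerate(iso_ids)}
    out: dict[str, float] = {}
    for gene in mapping.migs:
        rows = [idx[t] for t in mapping.isoforms_of[gene] if t in idx]
        if not rows:
            raise DataError(f"MIG {gene} has no scored isoforms")
        out[gene] = float(np.max(np.asarray(scores)[rows]))
    return out


def evaluable_units(
    scores: np.ndarray,
    iso_ids: list[str],
    mapping: GeneIsoformMap,
    label_of: dict[str, int],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Assemble (scores, labels) per evaluation level.

    'sig': SIG isoforms vs their gene labels; 'mig': max-aggregated MIG
    genes vs gene labels; 'pooled': union of both.
    """
    idx = {t: i for i, t in enumerate(iso_ids)}
    scores = np.asarray(scores, dtype=float)
    sig_s, sig_y = [], []
    for gene in mapping.sigs:
        iso = mapping.isoforms_of[gene][0]
        if iso in idx:
            sig_s.append(scores[idx[iso]])
            sig_y.append(label_of[gene])
    mig = mig_gene_scores(scores, iso_ids, mapping) if mapping.migs else {}
    mig_s = [mig[g] for g in mapping.migs]
    mig_y = [label_of[g] for g in mapping.migs]
    return {
        "sig": (np.asarray(sig_s), np.asarray(sig_y)),
        "mig": (np.asarray(mig_s), np.asarray(mig_y)),
        "pooled": (
            np.asarray(sig_s + mig_s),
            np.asarray(sig_y + mig_y),
        ),
    }


def feature_relevance_ttest(task: PredictionTask) -> pd.DataFrame:
    """Welch two-sample t-test of positive- vs negative-gene expression per
    feature, Benjamini-Hochberg adjusted across features.

    Returns a frame with columns feature_id, t, p, q.
    """
    pos = task.Xg[task.yg == 1]
    neg = task.Xg[task.yg == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise DataError("each class needs >= 2 genes for the t-test")
    t, p = stats.ttest_ind(pos, neg, axis=0, equal_var=False)
    p = np.nan_to_num(p, nan=1.0)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"feature_id": task.col_ids, "t": t, "p": p, "q": q}
    )


# ---------------------------------------------------------------------------
# Pipeline driver


@dataclass
class EvalReport:
    """Per-fold metrics of one GO term's cross-validated run."""

    term_id: str
    per_fold: pd.DataFrame  # fold, sig_auc, sig_auprc, mig_auc, mig_auprc, pooled_auc, pooled_auprc
    predictions: pd.DataFrame  # isoform_id, fold, score, probability
    selected_features: dict[int, list[str]] = field(default_factory=dict)

    def means(self) -> pd.Series:
        cols = [c for c in self.per_fold.columns if c != "fold"]
        return self.per_fold[cols].mean()


def _fold_metrics(units: dict[str, tuple[np.ndarray, np.ndarray]]) -> dict[str, float]:
    out: dict[str, float] = {}
    for level, (s, y) in units.items():
        try:
            out[f"{level}_auc"] = auc(s, y)
            out[f"{level}_auprc"] = auprc(s, y)
        except DataError:
            out[f"{level}_auc"] = np.nan
            out[f"{level}_auprc"] = np.nan
    return out


def run_pipeline(
    gene_expr: ExpressionMatrix,
    iso_expr: ExpressionMatrix,
    mapping: GeneIsoformMap,
    annotations: AnnotationTable,
    term_id: str,
    frog_params=None,
    config: MdiplsConfig | None = None,
    k_outer: int = 5,
    groups: dict[str, str] | None = None,
    seed: int = 0,
    select_features: bool = True,
) -> EvalReport:
    """Outer k-fold cross-validated run of the full pipeline for one term.

    Per fold: a training task is built from the training genes only (its
    column centering, feature selection and model fit never see held-out
    genes); the stochastic feature-importance search and the threshold scan
    pick the feature subset; MdiPLS is fitted on the training task restricted
    to that subset; held-out isoforms are scored with the fitted model.
    ``select_features=False`` skips the selection steps and uses all
    features (the all-features ablation).
    """
    from .frog import FrogParams, run_frog
    from .sfs import select_subset

    config = config or MdiplsConfig()
    if frog_params is None:
        frog_params = FrogParams()

    plan = group_kfold(list(gene_expr.row_ids), groups, k_outer, seed=seed)
    ss = np.random.SeedSequence(seed)
    fold_seeds = [int(s) for s in ss.generate_state(k_outer) % (2**31)]

    iso_index = iso_expr.row_index()
    rows = []
    pred_rows = []
    selected_features: dict[int, list[str]] = {}
    for fold in range(k_outer):
        test_genes = set(plan.fold_genes(fold))
        train_genes = [g for g in gene_expr.row_ids if g not in test_genes]
        train_map = mapping.restrict_genes(train_genes)
        train_task = build_task(
            gene_expr.restrict_rows(train_genes),
            iso_expr.restrict_rows(train_map.isoforms),
            train_map,
            annotations,
            term_id,
        )
        if select_features:
            params = FrogParams(
                n_iterations=frog_params.n_iterations,
                q_init=frog_params.q_init,
                alpha=frog_params.alpha,
                mu=frog_params.mu,
                omega=frog_params.omega,
                inner_cv_folds=frog_params.inner_cv_folds,
                rng_seed=fold_seeds[fold],
                cache_auc0=frog_params.cache_auc0,
            )
            frog_result = run_frog(train_task, params, config)
            scan = select_subset(
                frog_result, train_task, config,
                folds=frog_params.inner_cv_folds, seed=fold_seeds[fold],
            )
            subset = scan.chosen_subset
        else:
            subset = FeatureSubset(range(train_task.n_features))
        selected_features[fold] = [train_task.col_ids[i] for i in subset]

        sub_task = apply_feature_subset(train_task, subset)
        model = fit(sub_task, clip_components(config, len(subset)))

        test_map = mapping.restrict_genes(sorted(test_genes))
        test_isos = test_map.isoforms
        col_pos = [iso_expr.col_ids.index(c) for c in sub_task.col_ids]
        X_test = iso_expr.values[
            np.ix_([iso_index[t] for t in test_isos], col_pos)
        ]
        # model means are in training-task coordinates = raw means of the
        # training isoform rows, so raw held-out rows center correctly
        scores = predict(model, X_test)
        probs = scores_to_probabilities(scores, standardize=len(scores) > 1)

        label_of = {
            g: (1 if g in annotations.annotated_genes(term_id) else 0)
            for g in test_genes
        }
        units = evaluable_units(scores, test_isos, test_map, label_of)
        rows.append({"fold": fold, **_fold_metrics(units)})
        for iso, s, p in zip(test_isos, scores, probs):
            pred_rows.append(
                {"isoform_id": iso, "fold": fold, "score": float(s),
                 "probability": float(p)}
            )

    return EvalReport(
        term_id=term_id,
        per_fold=pd.DataFrame(rows),
        predictions=pd.DataFrame(pred_rows),
        selected_features=selected_features,
    )


def summarize_reports(reports: list[EvalReport]) -> pd.DataFrame:
    """Per-term mean metrics plus a grand-mean row (arithmetic mean over
    terms of the per-term means)."""
    per_term = pd.DataFrame(
        [{"term_id": r.term_id, **r.means().to_dict()} for r in reports]
    )
    grand = per_term.drop(columns="term_id").mean()
    grand["term_id"] = "__grand_mean__"
    return pd.concat([per_term, grand.to_frame().T], ignore_index=True)
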