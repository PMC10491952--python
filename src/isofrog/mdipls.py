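"""Modified domain-invariant partial least squares (MdiPLS).

Domain-invariant PLS (diPLS) extracts latent variables whose scores have
matched variance across a labelled source domain (genes) and an unlabelled
target domain (isoforms): each weight vector ``w`` minimizes

    || X_src - y_src w^T ||_F^2  +  lambda * | var(t_src) - var(t_tgt) |

with ``t = X w`` the latent scores.  Mean centering of both matrices aligns
the domain means, the variance penalty aligns the spread, so a regression
fitted on gene labels transfers to isoforms.

The modification adds labelled isoforms to the source side: isoforms of
single-isoform genes (SIGs) inherit their gene's label outright, isoforms of
negative multi-isoform genes (MIGs) are negative, and for each positive MIG
a multiple-instance loop selects the single isoform whose projection is
closest to the positive-SIG reference and labels it positive.  The selected
rows are stacked under the gene matrix, which realises the extra PLS term
algebraically (two Frobenius terms sharing ``w`` equal one stacked term).

After ``n_k`` rounds of weight extraction and deflation, the regression
vector is ``b = W (P^T W)^{-1} q`` and isoform scores are ``y_pred = Xiso b``
(higher = more likely to carry the function).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_model import ExpressionMatrix, PredictionTask

__all__ = [
    "MdiplsConfig",
    "MdiplsModel",
    "MilState",
    "fit_weight_vector",
    "mil_update",
    "fit",
    "predict",
    "scores_to_probabilities",
    "save_model",
    "load_model",
]


class FitError(RuntimeError):
    """Raised when a model cannot be fitted on the given task."""


@dataclass
class MdiplsConfig:
    """Hyper-parameters of the MdiPLS predictor.

    n_components: dimension n_k of the latent-variable space.
    lambda_reg:   penalty weight of the domain-variance regularizer.
    max_mil_iterations: cap on the positive-isoform re-selection loop.
    mil_enabled:  if False the model is plain diPLS on the gene matrix
                  alone (no isoform rows stacked, no relabeling loop).
    """

    n_components: int = 5
    lambda_reg: float = 1.0
    max_mil_iterations: int = 100
    mil_enabled: bool = True

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        if self.max_mil_iterations < 1:
            raise ValueError("max_mil_iterations must be >= 1")


@dataclass
class MilState:
    """The augmented labelled-isoform training set after the MIL loop."""

    iso_ids: list[str]        # rows of X_ts, aligned
    X_ts: np.ndarray          # stacked labelled isoform rows (task coordinates)
    y_ts: np.ndarray
    selected: dict[str, str]  # positive-MIG gene id -> chosen isoform id
    n_iterations: int
    converged: bool


@dataclass
class MdiplsModel:
    """A fitted MdiPLS latent space and regression vector."""

    W: np.ndarray             # n_f x n_k weight matrix, unit-norm columns
    P: np.ndarray             # n_f x n_k loadings
    q: np.ndarray             # n_k inner coefficients
    b: np.ndarray             # n_f regression vector
    column_means: np.ndarray  # isoform-domain column means for centering
    config: MdiplsConfig
    col_ids: list[str] = field(default_factory=list)
    selected_positive_isoforms: dict[str, str] = field(default_factory=dict)
    train_scores: np.ndarray | None = None   # per-component source scores t_k
    train_response_pred: np.ndarray | None = None  # sum_k t_k q_k
    train_X: np.ndarray | None = None        # pre-deflation source stack

    @property
    def n_features(self) -> int:
        return len(self.b)


def clip_components(config: MdiplsConfig, n_features: int) -> MdiplsConfig:
    """Cap n_components at the task's feature count (small feature subsets
    cannot support the full latent dimension)."""
    if config.n_components <= n_features:
        return config
    return MdiplsConfig(
        n_components=n_features,
        lambda_reg=config.lambda_reg,
        max_mil_iterations=config.max_mil_iterations,
        mil_enabled=config.mil_enabled,
    )


def fit_weight_vector(
    X_source: np.ndarray,
    y_source: np.ndarray,
    X_target: np.ndarray,
    lambda_reg: float,
) -> np.ndarray:
    """One latent direction of the domain-regularized PLS objective.

    The absolute value in ``lambda * |var(t_src) - var(t_tgt)|`` makes the
    objective piecewise smooth.  On each branch the stationary point is the
    regularized linear system

        (y'y I + lambda * s * D) w = X_src' y,   s in {+1, -1},

    where ``D`` is the difference of the two domain covariance matrices.
    Both branch solutions are computed and the one with the lower true
    objective value is kept, then normalized to unit Euclidean norm.
    """
    X_source = np.asarray(X_source, dtype=float)
    X_target = np.asarray(X_target, dtype=float)
    y_source = np.asarray(y_source, dtype=float).ravel()
    if lambda_reg < 0:
        raise FitError("lambda_reg must be >= 0")
    if X_source.shape[0] != y_source.shape[0]:
        raise FitError("X_source rows must match y_source length")
    if X_source.shape[1] != X_target.shape[1]:
        raise FitError("source and target must share the feature axis")
    if not np.any(X_source):
        raise FitError("X_source is identically zero")

    xy = X_source.T @ y_source
    yy = float(y_source @ y_source)
    if yy <= 0:
        raise FitError("y_source is identically zero")

    if lambda_reg == 0:
        w = xy
    else:
        n_s = max(X_source.shape[0] - 1, 1)
        n_t = max(X_target.shape[0] - 1, 1)
        D = X_source.T @ X_source / n_s - X_target.T @ X_target / n_t
        D = 0.5 * (D + D.T)
        p = X_source.shape[1]
        best_w, best_obj = None, np.inf
        for sign in (1.0, -1.0):
            A = yy * np.eye(p) + lambda_reg * sign * D
            try:
                cand = np.linalg.solve(A, xy)
            except np.linalg.LinAlgError:
                cand = np.linalg.lstsq(A, xy, rcond=None)[0]
            obj = (
                np.linalg.norm(X_source - np.outer(y_source, cand)) ** 2
                + lambda_reg * abs(float(cand @ D @ cand))
            )
            if obj < best_obj:
                best_w, best_obj = cand, obj
        w = best_w

    norm = np.linalg.norm(w)
    if norm < 1e-14:
        raise FitError(
            "degenerate weight vector (response orthogonal to features); "
            "try fewer components"
        )
    return w / norm


def _initial_stack(task: PredictionTask) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Labelled isoform rows before any MIL selection: all SIG isoforms
    (inheriting gene labels) and all isoforms of negative MIGs (label 0)."""
    iso_idx = task.iso_index
    ids: list[str] = []
    labels: list[float] = []
    for gene in task.mapping.sigs:
        iso = task.mapping.isoforms_of[gene][0]
        ids.append(iso)
        labels.append(task.label_of_gene(gene))
    for gene in task.mapping.migs:
        if task.label_of_gene(gene) == 0:
            for iso in task.mapping.isoforms_of[gene]:
                ids.append(iso)
                labels.append(0.0)
    rows = np.array([iso_idx[i] for i in ids], dtype=int)
    X = task.Xiso[rows] if len(rows) else np.empty((0, task.n_features))
    return ids, X, np.asarray(labels, dtype=float)


def mil_update(task: PredictionTask, config: MdiplsConfig) -> MilState:
    """Select the most likely positive isoform of each positive MIG.

    Iterates: fit a weight vector on the current augmented stack; project
    positive-SIG isoform rows onto it to form the reference distribution;
    score every positive-MIG isoform by the absolute distance between its
    projection and the reference mean; keep the minimum-distance isoform per
    positive MIG (replacing, not appending to, the previous selection).
    Stops at a fixed point or after ``max_mil_iterations``.
    """
    base_ids, X_base, y_base = _initial_stack(task)
    iso_idx = task.iso_index
    pos_migs = [g for g in task.mapping.migs if task.label_of_gene(g) == 1]

    if not pos_migs:
        return MilState(base_ids, X_base, y_base, {}, 1, True)

    pos_sig_rows = np.array(
        [
            iso_idx[task.mapping.isoforms_of[g][0]]
            for g in task.mapping.sigs
            if task.label_of_gene(g) == 1
        ],
        dtype=int,
    )
    use_gene_reference = pos_sig_rows.size == 0
    if use_gene_reference:
        warnings.warn(
            "no positive SIGs: falling back to positive gene rows for the "
            "MIL reference distribution",
            stacklevel=2,
        )
        ref_matrix = task.Xg[task.yg == 1]
    else:
        ref_matrix = task.Xiso[pos_sig_rows]

    cand_rows = {g: np.array([iso_idx[i] for i in task.mapping.isoforms_of[g]])
                 for g in pos_migs}

    selected: dict[str, str] = {}
    converged = False
    iteration = 0
    for iteration in range(1, config.max_mil_iterations + 1):
        if selected:
            sel_rows = np.array([iso_idx[i] for i in selected.values()], dtype=int)
            X_stack = np.vstack([task.Xg, X_base, task.Xiso[sel_rows]])
            y_stack = np.concatenate([task.yg, y_base, np.ones(len(sel_rows))])
        else:
            X_stack = np.vstack([task.Xg, X_base])
            y_stack = np.concatenate([task.yg, y_base])
        w0 = fit_weight_vector(X_stack, y_stack, task.Xiso, config.lambda_reg)
        ref_mean = float(np.mean(ref_matrix @ w0))
        proj = task.Xiso @ w0
        new_selected: dict[str, str] = {}
        for gene in pos_migs:
            rows = cand_rows[gene]
            dist = np.abs(proj[rows] - ref_mean)
            best = rows[int(np.argmin(dist))]
            new_selected[gene] = task.iso_ids[best]
        if new_selected == selected:
            converged = True
            selected = new_selected
            break
        selected = new_selected
    if not converged and iteration >= config.max_mil_iterations:
        warnings.warn(
            f"MIL selection did not converge within {config.max_mil_iterations} "
            "iterations; using the last selection",
            stacklevel=2,
        )

    sel_rows = np.array([iso_idx[i] for i in selected.values()], dtype=int)
    ids = base_ids + [task.iso_ids[r] for r in sel_rows]
    X_ts = np.vstack([X_base, task.Xiso[sel_rows]])
    y_ts = np.concatenate([y_base, np.ones(len(sel_rows))])
    return MilState(ids, X_ts, y_ts, selected, iteration, converged)


def fit(task: PredictionTask, config: MdiplsConfig | None = None) -> MdiplsModel:
    """Fit MdiPLS on a prediction task.

    With ``mil_enabled`` the labelled-isoform stack from :func:`mil_update`
    is appended below the gene matrix; the stacked matrix and response are
    then deflated component by component.  The isoform matrix is deflated in
    parallel with its own scores against the shared loading, keeping both
    domains in the same residual space.
    """
    config = config or MdiplsConfig()
    n_f = task.n_features
    if config.n_components > n_f:
        raise FitError(
            f"n_components={config.n_components} exceeds n_features={n_f}"
        )

    selected: dict[str, str] = {}
    if config.mil_enabled:
        state = mil_update(task, config)
        selected = dict(state.selected)
        X = np.vstack([task.Xg, state.X_ts])
        y = np.concatenate([task.yg, state.y_ts])
    else:
        X = task.Xg.copy()
        y = task.yg.copy()

    X0 = X.copy()
    X = X.copy()
    y = y.astype(float).copy()
    Xiso = task.Xiso.copy()

    n_k = config.n_components
    W = np.empty((n_f, n_k))
    P = np.empty((n_f, n_k))
    q = np.empty(n_k)
    T = np.empty((X.shape[0], n_k))
    for k in range(n_k):
        w = fit_weight_vector(X, y, Xiso, config.lambda_reg)
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-14:
            raise FitError(f"zero-variance scores at component {k + 1}; "
                           "reduce n_components")
        p_k = X.T @ t / tt
        q_k = float(y @ t) / tt
        t_iso = Xiso @ w
        X = X - np.outer(t, p_k)
        y = y - t * q_k
        Xiso = Xiso - np.outer(t_iso, p_k)
        W[:, k] = w
        P[:, k] = p_k
        q[k] = q_k
        T[:, k] = t

    PtW = P.T @ W
    cond = np.linalg.cond(PtW)
    if not np.isfinite(cond) or cond > 1e12:
        raise FitError(
            "P'W numerically singular; reduce n_components"
        )
    b = W @ np.linalg.solve(PtW, q)

    return MdiplsModel(
        W=W,
        P=P,
        q=q,
        b=b,
        column_means=task.iso_col_means.copy(),
        config=config,
        col_ids=list(task.col_ids),
        selected_positive_isoforms=selected,
        train_scores=T,
        train_response_pred=T @ q,
        train_X=X0,
    )


def predict(model: MdiplsModel, Xiso: ExpressionMatrix | np.ndarray) -> np.ndarray:
    """Isoform prediction scores ``(Xiso - column_means) @ b``.

    Accepts an :class:`ExpressionMatrix` or a plain array in the same
    coordinates the model was trained from; rows are centered with the
    model's stored training column means.
    """
    values = Xiso.values if isinstance(Xiso, ExpressionMatrix) else np.asarray(Xiso, float)
    if values.ndim == 1:
        values = values[None, :]
    if values.shape[1] != model.n_features:
        raise FitError(
            f"expected {model.n_features} feature columns, got {values.shape[1]}"
        )
    return (values - model.column_means) @ model.b


def scores_to_probabilities(
    scores: np.ndarray, standardize: bool = False
) -> np.ndarray:
    """Two-class softmax on logits ``(s, -s)``: p = exp(s) / (exp(s) + exp(-s)).

    Equivalently a logistic map ``sigmoid(2s)``; p > 0.5 exactly when s > 0,
    and s = 0 maps to 0.5.  With ``standardize=True`` scores are first
    shifted/scaled to zero mean and unit variance, which fixes the scale of
    the probabilities when raw score magnitudes are arbitrary.
    """
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if standardize:
        sd = s.std()
        s = (s - s.mean()) / sd if sd > 0 else s - s.mean()
    # numerically stable sigmoid(2s)
    out = np.empty_like(s, dtype=float)
    pos = s >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-2.0 * s[pos]))
    ez = np.exp(2.0 * s[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# Serialization: one JSON file holding every model component.


def save_model(model: MdiplsModel, path: str | Path) -> None:
    payload = {
        "W": model.W.tolist(),
        "P": model.P.tolist(),
        "q": model.q.tolist(),
        "b": model.b.tolist(),
        "column_means": model.column_means.tolist(),
        "col_ids": model.col_ids,
        "selected_positive_isoforms": model.selected_positive_isoforms,
        "config": {
            "n_components": model.config.n_components,
            "lambda_reg": model.config.lambda_reg,
            "max_mil_iterations": model.config.max_mil_iterations,
            "mil_enabled": model.config.mil_enabled,
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> MdiplsModel:
    payload = json.loads(Path(path).read_text())
    return MdiplsModel(
        W=np.asarray(payload["W"], float),
        P=np.asarray(payload["P"], float),
        q=np.asarray(payload["q"], float),
        b=np.asarray(payload["b"], float),
        column_means=np.asarray(payload["column_means"], float),
        config=MdiplsConfig(**payload["config"]),
        col_ids=list(payload["col_ids"]),
        selected_positive_isoforms=dict(payload["selected_positive_isoforms"]),
    )
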