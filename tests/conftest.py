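"""Shared fixtures: small random tasks and reference (oracle) implementations."""

from __future__ import annotations

import numpy as np
import pytest

from isofrog.data_model import GeneIsoformMap, PredictionTask
from isofrog.simulate import SimConfig, generate
from isofrog.data_model import build_task


def make_sig_task(
    rng: np.random.Generator,
    n_g: int = 50,
    n_f: int = 10,
    pos_frac: float = 0.4,
) -> PredictionTask:
    """A random task where every gene is a SIG whose isoform row is an
    independent random profile (useful for gene-level oracle checks where
    the isoform matrix only matters through the domain regularizer)."""
    Xg = rng.normal(size=(n_g, n_f))
    Xiso = rng.normal(size=(n_g, n_f))
    n_pos = max(1, int(round(pos_frac * n_g)))
    yg = np.zeros(n_g)
    yg[rng.choice(n_g, size=n_pos, replace=False)] = 1
    genes = [f"g{i}" for i in range(n_g)]
    isos = [f"g{i}.1" for i in range(n_g)]
    mapping = GeneIsoformMap.from_pairs(list(zip(genes, isos)))
    return PredictionTask(
        term_id="GO:RAND",
        gene_ids=genes,
        iso_ids=isos,
        col_ids=[f"e{j}" for j in range(n_f)],
        Xg=Xg - Xg.mean(axis=0),
        Xiso=Xiso - Xiso.mean(axis=0),
        yg=yg,
        mapping=mapping,
        gene_col_means=Xg.mean(axis=0),
        iso_col_means=Xiso.mean(axis=0),
    )


def make_planted_task(seed: int = 0, **overrides) -> tuple[PredictionTask, object]:
    """Default planted synthetic task plus its ground truth."""
    cfg = SimConfig(rng_seed=seed, **overrides)
    Xg, Xiso, mapping, ann, truth = generate(cfg)
    task = build_task(Xg, Xiso, mapping, ann, cfg.term_id)
    return task, truth


# ---------------------------------------------------------------------------
# Independent oracles (never share code with the implementation they check)


def nipals_pls1(X: np.ndarray, y: np.ndarray, n_comp: int) -> np.ndarray:
    """Textbook NIPALS PLS1 regression vector for a univariate response."""
    X = np.asarray(X, float).copy()
    y = np.asarray(y, float).copy()
    n_f = X.shape[1]
    W = np.empty((n_f, n_comp))
    P = np.empty((n_f, n_comp))
    q = np.empty(n_comp)
    for k in range(n_comp):
        w = X.T @ y
        w = w / np.linalg.norm(w)
        t = X @ w
        tt = float(t @ t)
        p = X.T @ t / tt
        qk = float(y @ t) / tt
        X = X - np.outer(t, p)
        y = y - t * qk
        W[:, k] = w
        P[:, k] = p
        q[k] = qk
    return W @ np.linalg.solve(P.T @ W, q)


def auc_pair_counting(scores: np.ndarray, labels: np.ndarray) -> float:
    """Exhaustive concordant/tied pair enumeration."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def auprc_threshold_enumeration(scores: np.ndarray, labels: np.ndarray) -> float:
    """Step-wise precision-at-recall-change summation over every distinct
    score value used as a cutoff (predict positive if score >= cutoff)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    area = 0.0
    recall_prev = 0.0
    for cut in sorted(set(scores), reverse=True):
        pred = scores >= cut
        tp = int(((labels == 1) & pred).sum())
        precision = tp / int(pred.sum())
        recall = tp / n_pos
        area += (recall - recall_prev) * precision
        recall_prev = recall
    return area


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Hand-rolled Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def planted_task():
    return make_planted_task(seed=7)
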