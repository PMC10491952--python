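"""Threshold scan over selection probabilities — extraction of the final
feature subset V*.

After the stochastic search assigns each feature a selection probability,
candidate cutoffs are the distinct probability values themselves: these are
exactly the points where the surviving set changes, so the scan is
exhaustive over distinct subsets.  Each cutoff's subset (features with
sp >= cutoff) is scored by cross-validated AUC on shared folds, and the
cutoff with the highest AUC wins; ties go to the larger cutoff (fewer
features).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import DataError, FeatureSubset, PredictionTask
from .frog import FrogResult, cv_auc
from .mdipls import MdiplsConfig

__all__ = ["ThresholdScan", "candidate_thresholds", "select_subset"]


@dataclass
class ThresholdScan:
    """Result of one threshold scan."""

    table: pd.DataFrame          # threshold, n_features, auc, chosen
    chosen_threshold: float
    chosen_subset: FeatureSubset

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def candidate_thresholds(result: FrogResult) -> list[float]:
    """Ascending distinct selection-probability values usable as cutoffs.

    Survival rule is sp >= threshold, so the maximum sp value is the last
    usable cutoff (it keeps the top feature set) and no cutoff leaves an
    empty subset.  Zero is not a cutoff: features the chain never selected
    cannot enter the final subset.
    """
    sp = result.selection_probabilities
    if not np.any(sp > 0):
        raise DataError("no feature ever selected; increase n_iterations")
    return [float(v) for v in np.unique(sp[sp > 0])]


def select_subset(
    result: FrogResult,
    task: PredictionTask,
    config: MdiplsConfig | None = None,
    folds: int = 3,
    seed: int = 0,
) -> ThresholdScan:
    """Scan all candidate cutoffs and pick the subset with the best AUC.

    The same CV folds (one shared seed) are used for every cutoff so the
    comparison is free of fold-resampling noise.  Ties break toward the
    larger cutoff, i.e. the smaller subset.
    """
    config = config or MdiplsConfig()
    sp = result.selection_probabilities
    rows = []
    best: tuple[float, float, FeatureSubset] | None = None
    for thr in candidate_thresholds(result):
        idx = np.flatnonzero(sp >= thr)
        subset = FeatureSubset(idx)
        try:
            score = cv_auc(subset, task, folds, config, seed)
        except Exception as exc:
            raise RuntimeError(f"CV failed at threshold {thr}") from exc
        rows.append({"threshold": thr, "n_features": len(subset), "auc": score})
        if best is None or score >= best[0]:  # >= : later (larger) cutoff wins ties
            best = (score, thr, subset)
    table = pd.DataFrame(rows)
    table["chosen"] = (table["threshold"] == best[1]).astype(int)
    return ThresholdScan(table, best[1], best[2])
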