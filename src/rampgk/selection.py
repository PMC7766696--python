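"""Backward elimination of residue-type rows, scored by CV sensitivity.

At each level every remaining residue row is tentatively dropped, the
full pipeline (column slice -> fold split -> clean training folds ->
train -> test) is scored by mean cross-validated sensitivity, and the
drop with the highest score is made permanent.  The search runs to
``max_levels`` and the best level (highest sensitivity; earliest on
ties) is selected afterwards, since sensitivity beyond the peak can
only be confirmed by continuing past it.

Fold assignments are fixed by the run seed, so every candidate within a
level — and every level — is compared on identical splits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .cleaning import CleaningConfig
from .evaluation import cross_validate_features
from .model import ModelConfig
from .ram import FeatureTable, encode_dataset
from .sequence_io import Dataset


@dataclass(frozen=True)
class SelectionLevel:
    level: int
    eliminated: Optional[str]  # None for the level-0 baseline
    sensitivity: float
    remaining: tuple[str, ...]


@dataclass
class SelectionTrace:
    """Per-level record of the elimination path; level 0 is the baseline."""

    levels: list[SelectionLevel]

    @property
    def baseline_sensitivity(self) -> float:
        return self.levels[0].sensitivity

    @property
    def best_level(self) -> int:
        sens = [lv.sensitivity for lv in self.levels]
        return int(np.argmax(sens))  # argmax takes the earliest on ties

    @property
    def best_subset(self) -> tuple[str, ...]:
        return self.levels[self.best_level].remaining

    @property
    def eliminated_sequence(self) -> tuple[str, ...]:
        return tuple(lv.eliminated for lv in self.levels[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": [lv.level for lv in self.levels],
                "eliminated": [lv.eliminated or "" for lv in self.levels],
                "sensitivity": [lv.sensitivity for lv in self.levels],
                "n_remaining": [len(lv.remaining) for lv in self.levels],
            }
        )

    def to_dict(self) -> dict:
        return {
            "levels": [
                {
                    "level": lv.level,
                    "eliminated": lv.eliminated,
                    "sensitivity": lv.sensitivity,
                    "remaining": list(lv.remaining),
                }
                for lv in self.levels
            ],
            "best_level": self.best_level,
            "best_subset": list(self.best_subset),
        }


def _cv_sensitivity(table, labels, retained, cleaning_config, model_config,
                    folds, seed) -> float:
    sub = table.select_rows(retained)
    report = cross_validate_features(
        sub, labels,
        cleaning_config=cleaning_config,
        model_config=model_config,
        folds=folds,
        seed=seed,
    )
    return report.mean_metrics["sensitivity"]


def eliminate_features(
    table: FeatureTable,
    labels,
    cleaning_config: Optional[CleaningConfig] = None,
    model_config: Optional[ModelConfig] = None,
    folds: int = 6,
    seed: int = 0,
    max_levels: int = 19,
    n_jobs: int = 1,
) -> SelectionTrace:
    """Run backward elimination on an already-encoded feature table.

    Candidate evaluations within a level are independent and may run in
    parallel (``n_jobs``); the chosen path does not depend on execution
    order.  Within-level sensitivity ties break toward the residue
    earliest in alphabet order.
    """
    remaining = list(table.schema.retained)
    if not 0 <= max_levels <= len(remaining) - 1:
        raise ValueError(
            f"max_levels must be in [0, {len(remaining) - 1}], got {max_levels}"
        )
    labels = np.asarray(labels, dtype=int)

    baseline = _cv_sensitivity(
        table, labels, tuple(remaining), cleaning_config, model_config, folds, seed
    )
    levels = [
        SelectionLevel(
            level=0, eliminated=None, sensitivity=baseline,
            remaining=tuple(remaining),
        )
    ]
    for level in range(1, max_levels + 1):
        candidates = list(remaining)  # alphabet order preserved
        scores = Parallel(n_jobs=n_jobs)(
            delayed(_cv_sensitivity)(
                table,
                labels,
                tuple(r for r in remaining if r != cand),
                cleaning_config,
                model_config,
                folds,
                seed,
            )
            for cand in candidates
        )
        best = int(np.argmax(scores))  # earliest (alphabet order) wins ties
        eliminated = candidates[best]
        remaining.remove(eliminated)
        levels.append(
            SelectionLevel(
                level=level,
                eliminated=eliminated,
                sensitivity=float(scores[best]),
                remaining=tuple(remaining),
            )
        )
    return SelectionTrace(levels=levels)


def backward_eliminate(
    dataset: Dataset,
    n: int = 6,
    cleaning_config: Optional[CleaningConfig] = None,
    model_config: Optional[ModelConfig] = None,
    folds: int = 6,
    seed: int = 0,
    max_levels: int = 19,
    n_jobs: int = 1,
) -> SelectionTrace:
    """Encode a dataset with the full alphabet and run backward elimination."""
    table, labels = encode_dataset(dataset, n=n)
    return eliminate_features(
        table,
        labels,
        cleaning_config=cleaning_config,
        model_config=model_config,
        folds=folds,
        seed=seed,
        max_levels=max_levels,
        n_jobs=n_jobs,
    )
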