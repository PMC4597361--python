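"""Outcome-class assignment with a gray zone, and dataset-role bookkeeping.

A sample is *positive* when the event (recurrence, or death-with-tumor for
the RNA-seq setting) occurred within ``event_window`` years, *negative* when
it stayed event-free with follow-up of at least ``free_window`` years, and
*gray* otherwise. Gray samples are excluded from fitting, thresholds and
AUC but kept for Kaplan-Meier plots. Both window comparisons are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateCohortError, ValidationError
from .io import ExpressionMatrix, PhenotypeTable

POSITIVE = "positive"
NEGATIVE = "negative"
GRAY = "gray"

DEFAULT_EVENT_WINDOW = 5.0
DEFAULT_FREE_WINDOW = 7.0


@dataclass
class ClassLabels:
    """Sample id → {positive, negative, gray}."""

    labels: pd.Series

    def __post_init__(self) -> None:
        bad = set(self.labels) - {POSITIVE, NEGATIVE, GRAY}
        if bad:
            raise ValidationError(f"invalid class labels {sorted(bad)}")
        if self.labels.index.has_duplicates:
            raise ValidationError("duplicated sample id in class labels")

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, sample_id: str) -> str:
        return self.labels[sample_id]

    def counts(self) -> dict[str, int]:
        c = self.labels.value_counts()
        return {k: int(c.get(k, 0)) for k in (POSITIVE, NEGATIVE, GRAY)}

    def ids(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])


def assign_outcome_classes(
    pheno: PhenotypeTable,
    event_window: float = DEFAULT_EVENT_WINDOW,
    free_window: float = DEFAULT_FREE_WINDOW,
) -> ClassLabels:
    """Label every sample positive / negative / gray from outcome and follow-up.

    The mapping is total: event within ``event_window`` → positive; event-free
    with follow-up ≥ ``free_window`` → negative; everything else gray.
    """
    if event_window > free_window:
        raise ValidationError("event_window must not exceed free_window")
    event = pheno.table["event_observed"].to_numpy()
    time = pheno.table["time_years"].to_numpy(dtype=float)
    lab = np.full(len(pheno), GRAY, dtype=object)
    lab[event & (time <= event_window)] = POSITIVE
    lab[~event & (time >= free_window)] = NEGATIVE
    return ClassLabels(pd.Series(lab, index=pheno.table.index.copy(), name="label"))


def non_gray_subset(matrix: ExpressionMatrix, labels: ClassLabels):
    """Drop gray samples; return the sub-matrix and binary labels (positive=1).

    Raises :class:`DegenerateCohortError` when either outcome class is absent
    after the gray zone is removed, since sensitivity/specificity/AUC are
    undefined in that case.
    """
    missing = [s for s in matrix.sample_ids if s not in labels.labels.index]
    if missing:
        raise ValidationError(f"labels missing for samples {missing[:3]}")
    keep = [s for s in matrix.sample_ids if labels[s] != GRAY]
    y = np.array([1 if labels[s] == POSITIVE else 0 for s in keep], dtype=np.int64)
    if len(keep) == 0 or y.sum() == 0 or y.sum() == len(y):
        raise DegenerateCohortError(
            "cohort lacks positives or negatives after gray-zone exclusion"
        )
    return matrix.subset_samples(keep), y


@dataclass
class CohortSplit:
    """Datasets bound to pipeline roles: training, filtration-1..m, validation."""

    training: tuple[ExpressionMatrix, ClassLabels]
    filtration: list[tuple[ExpressionMatrix, ClassLabels]] = field(default_factory=list)
    validation: tuple[ExpressionMatrix, ClassLabels] | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for role, matrix, _ in self.roles():
            ids = set(matrix.sample_ids)
            overlap = seen & ids
            if overlap:
                raise ValidationError(
                    f"sample ids overlap across roles (e.g. {sorted(overlap)[:3]})"
                )
            seen |= ids

    def roles(self):
        """Yield (role_name, matrix, labels) in pipeline order."""
        yield "training", self.training[0], self.training[1]
        for k, (m, l) in enumerate(self.filtration, start=1):
            yield f"filtration_{k}", m, l
        if self.validation is not None:
            yield "validation", self.validation[0], self.validation[1]

    @property
    def role_names(self) -> list[str]:
        return [r for r, _, _ in self.roles()]

    @property
    def train_filtration_names(self) -> list[str]:
        return [r for r in self.role_names if r != "validation"]
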