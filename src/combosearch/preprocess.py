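"""Probeset filtration and training-frozen per-probeset normalization.

Both stages look only at the training cohort with the gray zone excluded.
The filter drops probesets that (a) carry no gene symbol, (b) stay below a
linear expression level of 128 (log2 scale 7) in every non-gray training
sample, or (c) have a linear max/min ratio below 2. Each retained probeset
is then standardized by its non-gray training mean and standard deviation;
the same shift/scale pair is applied unchanged to filtration and validation
data — normalization is never re-fitted outside training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohorts import GRAY, ClassLabels
from .errors import DegenerateProbesetError, PipelineError, ValidationError
from .io import ExpressionMatrix

DEFAULT_MIN_LINEAR_EXPR = 128.0
DEFAULT_MIN_RATIO = 2.0


@dataclass
class NormalizationParams:
    """Per-probeset (shift, scale) frozen from the training cohort.

    ``shift`` is the training mean of the log2 expression and ``scale`` the
    training standard deviation (denominator n−ddof, ddof=1 by default).
    """

    shift: pd.Series
    scale: pd.Series
    ddof: int = 1

    def __post_init__(self) -> None:
        if not self.shift.index.equals(self.scale.index):
            raise ValidationError("shift and scale indexed by different probesets")
        if np.any(self.scale.to_numpy() <= 0):
            bad = self.scale.index[self.scale.to_numpy() <= 0][0]
            raise DegenerateProbesetError(f"non-positive scale for probeset {bad!r}")

    @property
    def probeset_ids(self) -> list[str]:
        return list(self.shift.index)


def _non_gray_training(train: ExpressionMatrix, labels: ClassLabels) -> pd.DataFrame:
    keep = [s for s in train.sample_ids if labels[s] != GRAY]
    if not keep:
        raise ValidationError("no non-gray training samples")
    return train.values[keep]


def filter_probesets(
    train: ExpressionMatrix,
    labels: ClassLabels,
    min_linear_expr: float = DEFAULT_MIN_LINEAR_EXPR,
    min_ratio: float = DEFAULT_MIN_RATIO,
) -> list[str]:
    """Return training probesets surviving the three filtration rules, in input order.

    A probeset is dropped iff it has no gene symbol, or its maximum linear
    expression over all non-gray training samples is below ``min_linear_expr``
    ("constantly low"), or its linear max/min ratio is below ``min_ratio``
    ("low change"). The ratio is computed on the log2 values as
    ``2**(max − min)``, avoiding re-exponentiation error.
    """
    sub = _non_gray_training(train, labels).to_numpy()
    vmax = sub.max(axis=1)
    vmin = sub.min(axis=1)
    log_thr = math.log2(min_linear_expr)
    log_ratio = np.exp2(vmax - vmin)
    survivors = [
        ps
        for i, ps in enumerate(train.probeset_ids)
        if ps in train.annotation
        and vmax[i] >= log_thr
        and log_ratio[i] >= min_ratio
    ]
    if not survivors:
        raise PipelineError("probeset filtration left an empty universe")
    return survivors


def compute_normalization(
    train: ExpressionMatrix,
    labels: ClassLabels,
    retained: list[str],
    ddof: int = 1,
) -> NormalizationParams:
    """Mean/SD of each retained probeset over non-gray training samples."""
    sub = _non_gray_training(train, labels)
    if sub.shape[1] < 2:
        raise ValidationError("need at least 2 non-gray training samples")
    sub = sub.loc[list(retained)]
    shift = sub.mean(axis=1)
    scale = sub.std(axis=1, ddof=ddof)
    return NormalizationParams(shift=shift, scale=scale, ddof=ddof)


def apply_normalization(
    matrix: ExpressionMatrix,
    params: NormalizationParams,
    inverse: bool = False,
) -> ExpressionMatrix:
    """Standardize (or de-standardize) a matrix with training-frozen parameters.

    The matrix is restricted to the probesets covered by ``params``; a
    requested probeset missing from the matrix raises ``KeyError``. The same
    parameters are applied to every dataset — filtration and validation data
    are deliberately *not* re-centered on themselves.
    """
    missing = [p for p in params.probeset_ids if p not in matrix.values.index]
    if missing:
        raise KeyError(f"probesets missing from matrix: {missing[:3]}")
    sub = matrix.values.loc[params.probeset_ids]
    if inverse:
        out = sub.mul(params.scale, axis=0).add(params.shift, axis=0)
    else:
        out = sub.sub(params.shift, axis=0).div(params.scale, axis=0)
    return ExpressionMatrix(out, matrix.platform, matrix.annotation)
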