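"""Threshold sets governing which classifiers count as informative."""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError


@dataclass(frozen=True)
class ThresholdSet:
    """AUC (and optionally sensitivity/specificity) acceptance thresholds.

    ``auc_train_min`` applies to the training cohort, ``auc_filtration_min``
    to each filtration cohort separately. When ``enforce_balance`` is set,
    ``sens_min``/``spec_min`` are additionally required at the fixed decision
    threshold on the training and every filtration cohort — the "balanced"
    filter that prevents one-sided operating points. Validation metrics never
    participate in thresholding. All comparisons are non-strict (>=).
    """

    auc_train_min: float = 0.75
    auc_filtration_min: float = 0.70
    sens_min: float = 0.65
    spec_min: float = 0.65
    enforce_balance: bool = False

    def __post_init__(self) -> None:
        for name in ("auc_train_min", "auc_filtration_min", "sens_min", "spec_min"):
            v = getattr(self, name)
            if not 0.5 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0.5, 1]")

    def with_balance(self, enforce: bool = True) -> "ThresholdSet":
        return ThresholdSet(
            self.auc_train_min,
            self.auc_filtration_min,
            self.sens_min,
            self.spec_min,
            enforce,
        )

    def passes(self, aucs, sensitivities, specificities) -> bool:
        """Check the train∪filtration metric vectors (training first)."""
        if aucs[0] < self.auc_train_min:
            return False
        if any(a < self.auc_filtration_min for a in aucs[1:]):
            return False
        if self.enforce_balance:
            if any(s < self.sens_min for s in sensitivities):
                return False
            if any(s < self.spec_min for s in specificities):
                return False
        return True
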