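"""Model/Results front-end for the informative-combination search.

:class:`InformativePairSearch` is constructed from a cohort split (plus
optional phenotype tables for survival read-outs). Construction performs the
training-only preparation — probeset filtration and frozen normalization —
so the model object carries the exact feature universe and scaling that
every later evaluation reuses. ``fit()`` runs the exhaustive pair cascade
(and optionally the greedy growth to larger tuples) and returns a
:class:`PairSearchResults` with the scored tuples, validation summary
statistics and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classifier import DEFAULT_C_GRID, DEFAULT_DECISION_THRESHOLD
from .cohorts import CohortSplit
from .errors import ValidationError
from .io import scored_tuples_frame, write_scored_tuples
from .metrics import kaplan_meier, logrank_test
from .preprocess import (
    DEFAULT_MIN_LINEAR_EXPR,
    DEFAULT_MIN_RATIO,
    apply_normalization,
    compute_normalization,
    filter_probesets,
)
from .search import (
    SearchContext,
    ThresholdSet,
    balanced_filter,
    build_k_tuples,
    exhaustive_pair_search,
    unique_gene_view,
)
from .stats import rank_correlation, summarize_validation, test_mean_auc_above_random


class InformativePairSearch:
    """Exhaustive SVM pair search over a training/filtration/validation split.

    Parameters
    ----------
    split : CohortSplit
        Raw (log2-scale) cohorts with class labels. Filtration and
        normalization are derived from the training cohort only and frozen.
    thresholds : ThresholdSet, optional
        AUC / sensitivity / specificity acceptance thresholds (defaults
        0.75 / 0.70 / 0.65).
    c_grid : sequence of float
        Soft-margin penalty grid, default (1, 16, 256).
    phenotypes : dict, optional
        role → PhenotypeTable, enabling Kaplan-Meier / log-rank read-outs.

    Examples
    --------
    >>> model = InformativePairSearch(split)          # doctest: +SKIP
    >>> res = model.fit(balanced=True)                # doctest: +SKIP
    >>> print(res.summary())                          # doctest: +SKIP
    """

    def __init__(
        self,
        split: CohortSplit,
        thresholds: ThresholdSet | None = None,
        c_grid=DEFAULT_C_GRID,
        decision_threshold: float = DEFAULT_DECISION_THRESHOLD,
        min_linear_expr: float = DEFAULT_MIN_LINEAR_EXPR,
        min_ratio: float = DEFAULT_MIN_RATIO,
        ddof: int = 1,
        phenotypes=None,
    ):
        self.raw_split = split
        self.thresholds = thresholds or ThresholdSet()
        self.c_grid = tuple(c_grid)
        self.decision_threshold = decision_threshold
        self.phenotypes = phenotypes or {}

        train_matrix, train_labels = split.training
        self.universe = filter_probesets(
            train_matrix, train_labels, min_linear_expr, min_ratio
        )
        self.normalization = compute_normalization(
            train_matrix, train_labels, self.universe, ddof=ddof
        )
        norm = lambda m: apply_normalization(m, self.normalization)
        self.split = CohortSplit(
            training=(norm(train_matrix), train_labels),
            filtration=[(norm(m), l) for m, l in split.filtration],
            validation=(
                (norm(split.validation[0]), split.validation[1])
                if split.validation is not None
                else None
            ),
        )
        self.annotation = dict(train_matrix.annotation)
        self._context = SearchContext(self.split)

    @classmethod
    def from_frames(
        cls,
        training,
        filtration,
        validation,
        annotation: dict[str, str],
        labeller,
        **kwargs,
    ) -> "InformativePairSearch":
        """Build from (values DataFrame, PhenotypeTable) pairs per role.

        ``labeller`` maps a PhenotypeTable to ClassLabels (e.g.
        ``assign_outcome_classes``); phenotype tables are retained for
        survival read-outs.
        """
        from .io import ExpressionMatrix

        def bundle(values, pheno):
            return ExpressionMatrix(values, annotation=annotation), labeller(pheno)

        roles = {"training": bundle(*training), "validation": bundle(*validation)}
        filt = [bundle(*fv) for fv in filtration]
        phenos = {"training": training[1], "validation": validation[1]}
        for i, fv in enumerate(filtration, start=1):
            phenos[f"filtration_{i}"] = fv[1]
        split = CohortSplit(
            training=roles["training"], filtration=filt, validation=roles["validation"]
        )
        return cls(split, phenotypes=phenos, **kwargs)

    def fit(
        self,
        balanced: bool = False,
        max_size: int = 2,
        thresholds_per_size: dict[int, ThresholdSet] | None = None,
        n_jobs: int = 1,
        progress: bool = False,
    ) -> "PairSearchResults":
        """Run the exhaustive pair cascade (and optional growth to larger tuples).

        ``balanced`` applies the sensitivity/specificity floors to the pair
        stage; sizes ≥ 3 always enforce them (as the extension procedure
        does). Output is deterministic for any ``n_jobs``.
        """
        pairs = exhaustive_pair_search(
            self.universe,
            self._context,
            self.thresholds,
            self.c_grid,
            self.decision_threshold,
            n_jobs=n_jobs,
            progress=progress,
        )
        pairs_balanced = balanced_filter(pairs, self.thresholds)
        selected = pairs_balanced if balanced else pairs
        by_size = {2: selected}
        if max_size > 2:
            per_size = dict(thresholds_per_size or {})
            per_size.setdefault(2, self.thresholds)
            by_size = build_k_tuples(
                selected,
                self.universe,
                self._context,
                per_size,
                max_size,
                self.c_grid,
                self.decision_threshold,
            )
        n_pairs = len(self.universe) * (len(self.universe) - 1) // 2
        return PairSearchResults(
            model=self,
            by_size=by_size,
            all_pairs=pairs,
            balanced_pairs=pairs_balanced,
            n_pairs_evaluated=n_pairs,
        )


class PairSearchResults:
    """Scored tuples plus validation statistics from a fitted search.

    Attributes
    ----------
    by_size : dict
        size → list of ScoredTuple (size 2 is the selected pair list).
    all_pairs, balanced_pairs : list
        Pair cascade output before / after the sensitivity-specificity filter.
    """

    def __init__(self, model, by_size, all_pairs, balanced_pairs, n_pairs_evaluated):
        self.model = model
        self.by_size = by_size
        self.all_pairs = all_pairs
        self.balanced_pairs = balanced_pairs
        self.n_pairs_evaluated = n_pairs_evaluated

    @property
    def pairs(self):
        return self.by_size[2]

    def tuples(self, size: int = 2):
        return self.by_size[size]

    def to_frame(self, size: int = 2) -> pd.DataFrame:
        return scored_tuples_frame(self.by_size[size], self.model.annotation)

    def save(self, path, size: int = 2) -> None:
        write_scored_tuples(self.by_size[size], path, self.model.annotation)

    def gene_level(self, size: int = 2):
        return unique_gene_view(self.by_size[size], self.model.annotation)

    def validation_report(self, size: int = 2):
        return summarize_validation(self.by_size[size])

    def validation_auc_test(self, size: int = 2):
        aucs = [st.per_dataset["validation"].auc for st in self.by_size[size]]
        return test_mean_auc_above_random(aucs)

    def ranking_correlation(self, size: int = 2):
        sts = self.by_size[size]
        return rank_correlation(
            [st.mean_auc_tf for st in sts],
            [st.per_dataset["validation"].auc for st in sts],
        )

    def survival_groups(self, scored, role: str = "validation"):
        """Kaplan-Meier curves and log-rank test for one tuple's risk groups.

        All samples of the cohort are used — the gray zone included — split
        by the frozen classifier's decision at its fixed threshold.
        """
        pheno = self.model.phenotypes.get(role)
        if pheno is None:
            raise ValidationError(f"no phenotype table for role {role!r}")
        matrix = dict((r, m) for r, m, _ in self.model.split.roles())[role]
        X = matrix.values.loc[list(scored.probesets)].to_numpy().T
        clf = scored.classifier
        scores = X @ clf.weights + clf.bias
        groups = np.where(
            scores > clf.decision_threshold, "predicted_recurrence", "predicted_free"
        )
        order = [s for s in matrix.sample_ids]
        times = pheno.table.loc[order, "time_years"].to_numpy()
        events = pheno.table.loc[order, "event_observed"].to_numpy()
        curves = kaplan_meier(times, events, groups)
        stat, p = logrank_test(times, events, groups)
        return curves, (stat, p)

    def summary(self, size: int = 2, top: int = 10) -> str:
        """Plain-text results table in the spirit of a regression summary."""
        sts = self.by_size[size]
        thr = self.model.thresholds
        lines = []
        title = "Informative combination search results"
        lines.append(title)
        lines.append("=" * len(title))
        lines.append(f"probeset universe          {len(self.model.universe)}")
        lines.append(f"pairs evaluated            {self.n_pairs_evaluated}")
        lines.append(
            "thresholds                 "
            f"AUC {thr.auc_train_min:.2f} train / {thr.auc_filtration_min:.2f} "
            f"filtration; sens/spec {thr.sens_min:.2f}"
        )
        lines.append(f"C grid                     {tuple(self.model.c_grid)}")
        lines.append(f"informative pairs          {len(self.all_pairs)}")
        lines.append(f"after balanced filter      {len(self.balanced_pairs)}")
        if size != 2:
            lines.append(f"tuples of size {size}          {len(sts)}")
        if len(sts) >= 2:
            rep = summarize_validation(sts)
            t, p = test_mean_auc_above_random(rep.frame["auc"].to_numpy())
            lines.append("")
            lines.append(
                f"validation AUC             mean {rep.mean_auc:.3f} "
                f"(95% CI {rep.ci_low:.3f}-{rep.ci_high:.3f}), "
                f"median {rep.median_auc:.3f}"
            )
            lines.append(f"H0 mean AUC = 0.5          t = {t:.2f}, p = {p:.3g}")
        if sts:
            lines.append("")
            lines.append("top combinations (mean train∪filtration AUC):")
            header = f"{'probesets':<28}{'genes':<24}{'meanAUC':>8}{'valAUC':>8}{'C':>6}"
            lines.append(header)
            lines.append("-" * len(header))
            for st in sts[:top]:
                genes = ",".join(
                    self.model.annotation.get(p, "-") for p in st.probesets
                )
                val = st.per_dataset.get("validation")
                val_auc = f"{val.auc:.3f}" if val else "-"
                lines.append(
                    f"{','.join(st.probesets):<28}{genes:<24}"
                    f"{st.mean_auc_tf:>8.3f}{val_auc:>8}"
                    f"{st.classifier.C if st.classifier else float('nan'):>6.0f}"
                )
        return "\n".join(lines)
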