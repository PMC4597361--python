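"""Exhaustive informative-pair search, balanced filtering, and greedy extension.

The cascade evaluates every unordered probeset pair: a soft-margin linear
SVM is fitted on the training cohort per penalty-grid value and the pair is
kept only when the AUC thresholds hold on the training *and* every
filtration cohort — independent cohorts whose job is to discard pairs that
pass on training alone through overfitting or the sheer number of candidate
classifiers. Survivors are ranked by their mean train∪filtration AUC, the
quantity that also drives the greedy extension of pairs into triples,
quadruples and quintuples.

Search output is a deterministic function of (universe order, split,
thresholds, C grid): parallel execution chunks the pair list into fixed-size
blocks whose results are merged in block order and re-sorted, so any worker
count produces identical output.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from joblib import Parallel, delayed

from .classifier import (
    DEFAULT_C_GRID,
    DEFAULT_DECISION_THRESHOLD,
    LinearClassifier,
    select_over_C_datasets,
)
from .cohorts import CohortSplit, non_gray_subset
from .errors import ValidationError
from .metrics import DatasetMetrics
from .thresholds import ThresholdSet

__all__ = [
    "DatasetMetrics",
    "ScoredTuple",
    "SearchContext",
    "ThresholdSet",
    "evaluate_tuple",
    "exhaustive_pair_search",
    "balanced_filter",
    "extend_tuples",
    "greedy_optimize",
    "build_k_tuples",
    "unique_gene_view",
]

_CHUNK = 2048  # pairs per work unit; fixed so output is worker-count invariant


@dataclass
class ScoredTuple:
    """A probeset tuple that passed the cascade, with its frozen classifier.

    ``per_dataset`` maps every role in the split to (AUC, sensitivity,
    specificity); ``mean_auc_tf`` is the arithmetic mean of the training and
    filtration AUCs — the ranking criterion. Validation metrics are reported
    but never used for thresholding.
    """

    probesets: tuple[str, ...]
    classifier: LinearClassifier | None
    per_dataset: dict[str, DatasetMetrics]
    mean_auc_tf: float

    @property
    def size(self) -> int:
        return len(self.probesets)

    def metrics(self, role: str) -> DatasetMetrics:
        return self.per_dataset[role]


def _sort_key(st: ScoredTuple):
    return (-st.mean_auc_tf, st.probesets)


class SearchContext:
    """Pre-extracted numpy views of a normalized cohort split.

    Holds, per role, the (probesets × non-gray samples) value matrix and the
    binary labels, plus the probeset → row index. Building it once per search
    keeps the per-pair cost to array slicing and SVM fits.
    """

    def __init__(self, split: CohortSplit):
        train = split.training[0]
        self.universe: list[str] = train.probeset_ids
        self.index = {ps: i for i, ps in enumerate(self.universe)}
        self.annotation = train.annotation
        self.datasets: list[tuple[str, np.ndarray, np.ndarray]] = []
        for role, matrix, labels in split.roles():
            if matrix.probeset_ids != self.universe:
                if set(matrix.probeset_ids) < set(self.universe):
                    raise ValidationError(
                        f"{role} matrix does not cover the training probeset universe"
                    )
                matrix = matrix.subset_probesets(self.universe)
            sub, y = non_gray_subset(matrix, labels)
            M = np.ascontiguousarray(sub.values.to_numpy(dtype=np.float64))
            self.datasets.append((role, M, y))

    def tuple_datasets(self, rows: tuple[int, ...]):
        idx = np.asarray(rows, dtype=np.intp)
        return [
            (role, np.ascontiguousarray(M[idx].T), y)
            for role, M, y in self.datasets
        ]

    def rows_for(self, probesets) -> tuple[int, ...]:
        return tuple(self.index[p] for p in probesets)


def _as_context(split_or_ctx) -> SearchContext:
    if isinstance(split_or_ctx, SearchContext):
        return split_or_ctx
    return SearchContext(split_or_ctx)


def _evaluate_rows(
    ctx: SearchContext,
    rows: tuple[int, ...],
    thresholds: ThresholdSet,
    c_grid,
    decision_threshold: float,
) -> ScoredTuple | None:
    probesets = tuple(ctx.universe[r] for r in rows)
    res = select_over_C_datasets(
        ctx.tuple_datasets(rows), thresholds, c_grid, decision_threshold, probesets
    )
    if res is None:
        return None
    clf, per, mean_tf = res
    return ScoredTuple(
        probesets=probesets, classifier=clf, per_dataset=per, mean_auc_tf=mean_tf
    )


def evaluate_tuple(
    probesets,
    split,
    thresholds: ThresholdSet,
    c_grid=DEFAULT_C_GRID,
    decision_threshold: float = DEFAULT_DECISION_THRESHOLD,
) -> ScoredTuple | None:
    """Score one probeset tuple against the cascade; ``None`` means rejection.

    Delegates to the C-grid selection; on success the returned record carries
    metrics for every role including validation, computed with the frozen
    classifier. ``split`` may be a normalized :class:`CohortSplit` or a
    prebuilt :class:`SearchContext`.
    """
    ctx = _as_context(split)
    missing = [p for p in probesets if p not in ctx.index]
    if missing:
        raise ValidationError(f"probesets outside the filtered universe: {missing}")
    if len(set(probesets)) != len(probesets):
        raise ValidationError("duplicate probeset in tuple")
    return _evaluate_rows(
        ctx, ctx.rows_for(probesets), thresholds, c_grid, decision_threshold
    )


def _eval_pair_block(ctx, pair_rows, thresholds, c_grid, decision_threshold):
    out = []
    for rows in pair_rows:
        st = _evaluate_rows(ctx, rows, thresholds, c_grid, decision_threshold)
        if st is not None:
            out.append(st)
    return out


def exhaustive_pair_search(
    universe,
    split,
    thresholds: ThresholdSet,
    c_grid=DEFAULT_C_GRID,
    decision_threshold: float = DEFAULT_DECISION_THRESHOLD,
    n_jobs: int = 1,
    progress: bool = False,
) -> list[ScoredTuple]:
    """Evaluate all C(n, 2) unordered probeset pairs and return the passing ones.

    Results are sorted by descending mean train∪filtration AUC with ties
    broken lexicographically by probeset tuple; output is identical for any
    ``n_jobs``.
    """
    ctx = _as_context(split)
    rows = [ctx.index[p] for p in universe]
    if len(rows) < 2:
        raise ValidationError("pair search needs a universe of at least 2 probesets")
    pairs = list(combinations(rows, 2))
    blocks = [pairs[i : i + _CHUNK] for i in range(0, len(pairs), _CHUNK)]
    if n_jobs == 1:
        results = []
        for bi, block in enumerate(blocks):
            results.append(
                _eval_pair_block(ctx, block, thresholds, c_grid, decision_threshold)
            )
            if progress:
                done = min((bi + 1) * _CHUNK, len(pairs))
                print(f"evaluated {done}/{len(pairs)} pairs", file=sys.stderr)
    else:
        results = Parallel(n_jobs=n_jobs)(
            delayed(_eval_pair_block)(ctx, block, thresholds, c_grid, decision_threshold)
            for block in blocks
        )
    hits = [st for block in results for st in block]
    hits.sort(key=_sort_key)
    return hits


def balanced_filter(tuples, thresholds: ThresholdSet) -> list[ScoredTuple]:
    """Keep tuples meeting the sensitivity/specificity floors everywhere.

    Applies ``sens_min``/``spec_min`` to the training and every filtration
    cohort at the fixed decision threshold (validation is reported, not
    filtered). Order of the survivors is preserved.
    """
    out = []
    for st in tuples:
        ok = True
        for role, m in st.per_dataset.items():
            if role == "validation":
                continue
            if m.sensitivity < thresholds.sens_min or m.specificity < thresholds.spec_min:
                ok = False
                break
        if ok:
            out.append(st)
    return out


def extend_tuples(
    seed_tuples,
    universe,
    split,
    thresholds: ThresholdSet,
    c_grid=DEFAULT_C_GRID,
    decision_threshold: float = DEFAULT_DECISION_THRESHOLD,
) -> list[ScoredTuple]:
    """Extend every size-k seed tuple by one probeset and keep passing (k+1)-tuples.

    Every universe probeset not already in the seed is tried; candidates are
    deduplicated by unordered probeset set (first seed in rank order wins).
    """
    ctx = _as_context(split)
    sizes = {st.size for st in seed_tuples}
    if len(sizes) > 1:
        raise ValidationError("seed tuples must all have the same size")
    seen: set[frozenset] = set()
    out = []
    for st in sorted(seed_tuples, key=_sort_key):
        base = ctx.rows_for(st.probesets)
        for p in universe:
            r = ctx.index[p]
            if r in base:
                continue
            key = frozenset(base + (r,))
            if key in seen:
                continue
            seen.add(key)
            cand = _evaluate_rows(
                ctx, base + (r,), thresholds, c_grid, decision_threshold
            )
            if cand is not None:
                out.append(cand)
    out.sort(key=_sort_key)
    return out


def greedy_optimize(
    scored: ScoredTuple,
    universe,
    split,
    thresholds: ThresholdSet,
    c_grid=DEFAULT_C_GRID,
    decision_threshold: float = DEFAULT_DECISION_THRESHOLD,
    trace: list | None = None,
) -> ScoredTuple:
    """Cyclic element-wise improvement of a tuple's mean train∪filtration AUC.

    Sweeps positions 1..k repeatedly; at each position every replacement from
    the universe (not already in the tuple) is evaluated and the best passing
    one is adopted only if it *strictly* increases the mean AUC (ties keep
    the incumbent; among tying replacements the earliest in universe order
    wins by first-encounter). Terminates when a full sweep changes nothing;
    the result passes all thresholds and never scores below the input.
    ``trace``, when given, records ``mean_auc_tf`` at the start and after
    every adopted replacement.
    """
    ctx = _as_context(split)
    current = scored
    if trace is not None:
        trace.append(current.mean_auc_tf)
    rows = list(ctx.rows_for(current.probesets))
    k = len(rows)
    improved = True
    while improved:
        improved = False
        for pos in range(k):
            best_st = None
            best_row = None
            occupied = set(rows)
            for p in universe:
                r = ctx.index[p]
                if r in occupied:
                    continue
                cand_rows = tuple(rows[:pos] + [r] + rows[pos + 1 :])
                cand = _evaluate_rows(
                    ctx, cand_rows, thresholds, c_grid, decision_threshold
                )
                if cand is None:
                    continue
                if cand.mean_auc_tf > current.mean_auc_tf and (
                    best_st is None or cand.mean_auc_tf > best_st.mean_auc_tf
                ):
                    best_st = cand
                    best_row = r
            if best_st is not None:
                current = best_st
                rows[pos] = best_row
                improved = True
                if trace is not None:
                    trace.append(current.mean_auc_tf)
    return current


def build_k_tuples(
    pairs,
    universe,
    split,
    thresholds_per_size: dict[int, ThresholdSet] | None = None,
    max_size: int = 5,
    c_grid=DEFAULT_C_GRID,
    decision_threshold: float = DEFAULT_DECISION_THRESHOLD,
) -> dict[int, list[ScoredTuple]]:
    """Grow pairs into triples .. ``max_size``-tuples by extend-then-optimize.

    For each size the previous size's tuples are extended by one probeset,
    each survivor is greedily optimized, and the results are deduplicated by
    unordered probeset set. Per-size thresholds default to the pair
    thresholds with the sensitivity/specificity floors enforced, mirroring
    the extension stage of the original procedure.
    """
    ctx = _as_context(split)
    if thresholds_per_size is None:
        thresholds_per_size = {}
    out: dict[int, list[ScoredTuple]] = {2: sorted(pairs, key=_sort_key)}
    default_thr = None
    for size in range(3, max_size + 1):
        thr = thresholds_per_size.get(size)
        if thr is None:
            if default_thr is None:
                base = thresholds_per_size.get(2)
                default_thr = (base or ThresholdSet()).with_balance(True)
            thr = default_thr
        seeds = out[size - 1]
        extended = extend_tuples(
            seeds, universe, ctx, thr, c_grid, decision_threshold
        )
        polished: dict[frozenset, ScoredTuple] = {}
        for st in extended:
            opt = greedy_optimize(st, universe, ctx, thr, c_grid, decision_threshold)
            key = frozenset(opt.probesets)
            prev = polished.get(key)
            if prev is None or _sort_key(opt) < _sort_key(prev):
                polished[key] = opt
        out[size] = sorted(polished.values(), key=_sort_key)
    return out


def unique_gene_view(tuples, annotation: dict[str, str]) -> list[ScoredTuple]:
    """Collapse probeset tuples mapping to the same unordered gene-symbol set.

    Reporting view only (probesets remain distinct features during search):
    for each gene set the representative with the highest mean
    train∪filtration AUC is kept. Unannotated probesets stand for themselves.
    """
    best: dict[frozenset, ScoredTuple] = {}
    for st in sorted(tuples, key=_sort_key):
        key = frozenset(annotation.get(p, p) for p in st.probesets)
        if key not in best:
            best[key] = st
    return sorted(best.values(), key=_sort_key)
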