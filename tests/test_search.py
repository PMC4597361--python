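"""Pair-search cascade, balanced filter, extension, and greedy optimization."""

import numpy as np
import pytest

import combosearch as cs
from combosearch import search as search_mod
from combosearch.errors import ValidationError


@pytest.fixture(scope="module")
def ctx(small_model):
    return small_model._context


@pytest.fixture(scope="module")
def planted_pair(small_split):
    _, _, ledger = small_split
    return tuple(ledger.planted_probesets[0])


class TestEvaluateTuple:
    def test_planted_pair_accepted_with_paper_thresholds(self, ctx, planted_pair):
        st = cs.evaluate_tuple(planted_pair, ctx, cs.ThresholdSet())
        assert st is not None
        assert st.per_dataset["training"].auc >= 0.75
        for role in ("filtration_1", "filtration_2"):
            assert st.per_dataset[role].auc >= 0.70
        assert "validation" in st.per_dataset
        tf_aucs = [
            st.per_dataset[r].auc
            for r in ("training", "filtration_1", "filtration_2")
        ]
        assert st.mean_auc_tf == pytest.approx(np.mean(tf_aucs))

    def test_noise_pair_rejected(self, ctx, small_split):
        _, _, ledger = small_split
        assert cs.evaluate_tuple(
            tuple(ledger.noise_probesets[:2]), ctx, cs.ThresholdSet()
        ) is None

    def test_auc_below_threshold_rejected(self, ctx, planted_pair):
        """Thresholds sit just above the best AUC any grid C can reach, so the
        pair must be rejected; the per-C sweep is the independent oracle."""
        rows = ctx.rows_for(planted_pair)
        datasets = ctx.tuple_datasets(rows)
        tf = [d for d in datasets if d[0] != "validation"]
        best_train, best_filt1 = 0.0, 0.0
        for C in (1.0, 16.0, 256.0):
            clf = cs.fit_linear_svm(tf[0][1], tf[0][2], C)
            best_train = max(best_train, cs.auc(cs.decision_values(clf, tf[0][1]), tf[0][2]))
            best_filt1 = max(best_filt1, cs.auc(cs.decision_values(clf, tf[1][1]), tf[1][2]))
        if best_train < 1.0:
            sharp = cs.ThresholdSet(auc_train_min=np.nextafter(best_train, 2.0))
        else:
            assert best_filt1 < 1.0
            sharp = cs.ThresholdSet(
                auc_filtration_min=np.nextafter(best_filt1, 2.0)
            )
        assert cs.evaluate_tuple(planted_pair, ctx, sharp) is None

    def test_unknown_probeset_rejected(self, ctx):
        with pytest.raises(ValidationError):
            cs.evaluate_tuple(("nope_at", "nada_at"), ctx, cs.ThresholdSet())


class TestExhaustivePairSearch:
    def test_evaluates_all_pairs_of_small_universe(self, ctx, monkeypatch):
        calls = []
        orig = search_mod._evaluate_rows

        def counting(ctx_, rows, *a, **k):
            calls.append(rows)
            return orig(ctx_, rows, *a, **k)

        monkeypatch.setattr(search_mod, "_evaluate_rows", counting)
        universe = ctx.universe[:3]
        cs.exhaustive_pair_search(universe, ctx, cs.ThresholdSet())
        assert len(calls) == 3  # C(3,2)
        assert len({frozenset(r) for r in calls}) == 3

    def test_planted_pair_found_and_ranked_first(self, small_results, planted_pair):
        hits = small_results.all_pairs
        assert planted_pair in [st.probesets for st in hits]
        assert hits[0].probesets == planted_pair

    def test_output_sorted_by_mean_auc(self, small_results):
        means = [st.mean_auc_tf for st in small_results.all_pairs]
        assert means == sorted(means, reverse=True)

    def test_worker_count_invariance(self, tmp_path, small_model):
        thr = cs.ThresholdSet()
        one = cs.exhaustive_pair_search(
            small_model.universe, small_model._context, thr, n_jobs=1
        )
        two = cs.exhaustive_pair_search(
            small_model.universe, small_model._context, thr, n_jobs=2
        )
        p1, p2 = tmp_path / "w1.tsv", tmp_path / "w2.tsv"
        cs.write_scored_tuples(one, p1, small_model.annotation)
        cs.write_scored_tuples(two, p2, small_model.annotation)
        assert p1.read_bytes() == p2.read_bytes()


class TestBalancedFilter:
    def test_below_floor_removed_above_kept(self, small_results):
        thr = cs.ThresholdSet()
        kept = cs.balanced_filter(small_results.all_pairs, thr)
        # brute-force re-check defines the expected set
        expected = []
        for st in small_results.all_pairs:
            ok = all(
                m.sensitivity >= 0.65 and m.specificity >= 0.65
                for role, m in st.per_dataset.items()
                if role != "validation"
            )
            if ok:
                expected.append(st.probesets)
        assert [st.probesets for st in kept] == expected

    def test_constructed_low_sensitivity_tuple_removed(self):
        lo = cs.ScoredTuple(
            probesets=("a", "b"),
            classifier=None,
            per_dataset={
                "training": cs.DatasetMetrics(0.9, 0.64, 0.9),
                "validation": cs.DatasetMetrics(0.6, 0.5, 0.5),
            },
            mean_auc_tf=0.9,
        )
        hi = cs.ScoredTuple(
            probesets=("c", "d"),
            classifier=None,
            per_dataset={"training": cs.DatasetMetrics(0.9, 0.66, 0.70)},
            mean_auc_tf=0.9,
        )
        out = cs.balanced_filter([lo, hi], cs.ThresholdSet())
        assert [st.probesets for st in out] == [("c", "d")]


class TestExtendTuples:
    def test_candidate_count_and_no_duplicates(self, ctx, small_results, monkeypatch):
        seed = small_results.all_pairs[:1]
        universe = ctx.universe[:10]
        calls = []
        orig = search_mod._evaluate_rows

        def counting(ctx_, rows, *a, **k):
            calls.append(rows)
            return orig(ctx_, rows, *a, **k)

        monkeypatch.setattr(search_mod, "_evaluate_rows", counting)
        out = cs.extend_tuples(seed, universe, ctx, cs.ThresholdSet())
        in_seed = sum(p in seed[0].probesets for p in universe)
        assert len(calls) == len(universe) - in_seed  # <= n - k, no repeats
        for st in out:
            assert len(set(st.probesets)) == 3

    def test_extension_passes_thresholds_on_recheck(self, ctx, small_results):
        thr = cs.ThresholdSet().with_balance(True)
        triples = cs.extend_tuples(
            small_results.all_pairs[:1], ctx.universe, ctx, thr
        )
        for st in triples[:5]:
            again = cs.evaluate_tuple(st.probesets, ctx, thr)
            assert again is not None
            assert again.mean_auc_tf == pytest.approx(st.mean_auc_tf, abs=1e-9)


class TestGreedyOptimize:
    def test_result_never_worse_and_threshold_clean(self, ctx, small_results):
        thr = cs.ThresholdSet()
        start = small_results.all_pairs[0]
        out = cs.greedy_optimize(start, ctx.universe, ctx, thr)
        assert out.mean_auc_tf >= start.mean_auc_tf
        again = cs.evaluate_tuple(out.probesets, ctx, thr)
        assert again is not None
        assert again.mean_auc_tf == pytest.approx(out.mean_auc_tf, abs=1e-9)

    def test_fixed_point_returned_unchanged(self, ctx, small_results):
        thr = cs.ThresholdSet()
        once = cs.greedy_optimize(
            small_results.all_pairs[0], ctx.universe, ctx, thr
        )
        twice = cs.greedy_optimize(once, ctx.universe, ctx, thr)
        assert twice.probesets == once.probesets
        assert twice.mean_auc_tf == pytest.approx(once.mean_auc_tf)

    def test_strictly_better_replacement_adopted(self, ctx, small_results, small_split):
        """Start from a deliberately weakened tuple: planted gene A paired with
        a noise probeset. The sweep must rediscover a strictly better partner."""
        _, _, ledger = small_split
        a, b = ledger.planted_probesets[0]
        noise = ledger.noise_probesets[0]
        weak_thr = cs.ThresholdSet(auc_train_min=0.5, auc_filtration_min=0.5)
        weak = cs.evaluate_tuple((a, noise), ctx, weak_thr)
        assert weak is not None
        out = cs.greedy_optimize(weak, ctx.universe, ctx, weak_thr)
        assert out.mean_auc_tf > weak.mean_auc_tf
        assert set(out.probesets) == {a, b}  # exhaustive one-position scan oracle


class TestBuildKTuples:
    def test_sizes_and_threshold_cleanliness(self, ctx, small_results):
        by_size = cs.build_k_tuples(
            small_results.all_pairs[:2], ctx.universe, ctx, max_size=3
        )
        assert set(by_size) == {2, 3}
        thr3 = cs.ThresholdSet().with_balance(True)
        keys = [frozenset(st.probesets) for st in by_size[3]]
        assert len(keys) == len(set(keys))  # deduplicated by unordered set
        for st in by_size[3][:5]:
            assert st.size == 3
            assert cs.evaluate_tuple(st.probesets, ctx, thr3) is not None


class TestGeneLevelView:
    def test_collapses_same_gene_sets(self):
        st1 = cs.ScoredTuple(
            ("ps1", "ps2"), None, {"training": cs.DatasetMetrics(0.9, 1, 1)}, 0.9
        )
        st2 = cs.ScoredTuple(
            ("ps1b", "ps2"), None, {"training": cs.DatasetMetrics(0.8, 1, 1)}, 0.8
        )
        ann = {"ps1": "GA", "ps1b": "GA", "ps2": "GB"}
        out = cs.unique_gene_view([st1, st2], ann)
        assert len(out) == 1
        assert out[0].probesets == ("ps1", "ps2")  # highest-ranked representative
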