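"""Ranking metrics vs hand values and brute-force double-loop oracles."""

import numpy as np
import pytest

import tcmrec as tr
from tcmrec.metrics import (RankedPrediction, ScoredSample, auc,
                            auc_from_predictions, build_report, corpus_hits_at_k,
                            hits_at_k, mean_rank, mrr, unit_hit_rate)


def pred(ranked, labels, sid="x"):
    return RankedPrediction(sample_id=sid, ranked_elements=list(ranked),
                            scores=list(np.linspace(1, 0, len(ranked))),
                            label_set=set(labels))


class TestAuc:
    def test_perfect_separation(self):
        s = [ScoredSample(0.9, True), ScoredSample(0.8, True),
             ScoredSample(0.7, False), ScoredSample(0.1, False)]
        assert auc(s) == 1.0

    def test_all_ties_half(self):
        s = [ScoredSample(0.5, p) for p in (True, True, False, False)]
        assert auc(s) == 0.5

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            auc([ScoredSample(0.5, True)])

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(5, 100))
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            flags = rng.random(n) < 0.4
            if flags.all() or not flags.any():
                continue
            samples = [ScoredSample(s, f) for s, f in zip(scores, flags)]
            total, pairs = 0.0, 0
            for sp, fp in zip(scores, flags):
                if not fp:
                    continue
                for sn, fn in zip(scores, flags):
                    if fn:
                        continue
                    pairs += 1
                    total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
            assert auc(samples) == pytest.approx(total / pairs, abs=1e-12)

    def test_matches_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(1)
        scores = rng.random(200)
        flags = rng.random(200) < 0.3
        ours = auc([ScoredSample(s, f) for s, f in zip(scores, flags)])
        ref = sklearn_metrics.roc_auc_score(flags, scores)
        assert ours == pytest.approx(ref, abs=1e-12)


class TestHitsAtK:
    def test_full_recall(self):
        assert hits_at_k(pred("abcdefghij", "ab"), 10) == 1.0

    def test_partial_recall(self):
        p = pred(list("abwxyzijkl") + list("cd"), "abcd")
        assert hits_at_k(p, 10) == 0.5

    def test_exhaustive_k(self):
        p = pred("abcd", "dc")
        assert hits_at_k(p, 4) == 1.0

    def test_non_decreasing_in_k(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            ranked = list(rng.permutation(20))
            labels = rng.choice(20, size=4, replace=False)
            p = pred(ranked, labels)
            vals = [hits_at_k(p, k) for k in range(1, 21)]
            assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_empty_labels_error(self):
        with pytest.raises(ValueError):
            hits_at_k(pred("abc", ""), 1)


class TestRankMetrics:
    def test_mean_rank_hand_case(self):
        preds = [pred("axy", "a"), pred("xby", "b"), pred("wxyc", "c")]
        # ranks 1, 2, 4
        assert mean_rank(preds) == pytest.approx(7 / 3, abs=1e-9)

    def test_mrr_hand_case(self):
        preds = [pred("axy", "a"), pred("xby", "b"), pred("wxyc", "c")]
        assert mrr(preds) == pytest.approx((1 + 0.5 + 0.25) / 3, abs=1e-9)
        assert mrr(preds) == pytest.approx(0.5833333333, abs=1e-9)

    def test_floor_and_symmetry(self):
        preds = [pred("ab", "a"), pred("cd", "c")]
        assert mean_rank(preds) == 1.0
        assert mrr(preds) == 1.0
        assert mean_rank(list(reversed(preds))) == mean_rank(preds)

    def test_multilabel_expands_units(self):
        p = pred("abcd", "ad")  # ranks 1 and 4
        assert mean_rank([p]) == 2.5
        assert mean_rank([p], unit="best") == 1.0

    def test_missing_label_gets_fallback_rank(self):
        p = pred("ab", ["a", "z"])
        assert mean_rank([p], vocab_size=5) == pytest.approx((1 + 6) / 2)

    def test_mrr_decreases_when_rank_worsens(self):
        better = [pred("ab?", "a")]
        worse = [pred("?ab", "a")]
        assert mrr(worse) < mrr(better)
        assert 0 < mrr(worse) <= 1


class TestUnitHitRate:
    def test_saturation_and_hand_case(self):
        preds = [pred("ab", "a"), pred("cd", "c")]
        rates, _ = unit_hit_rate(preds, k_max=2)
        assert rates[0] == 1.0
        two = [pred("ab", "a"), pred("cd", "x")]
        rates, _ = unit_hit_rate(two, k_max=2)
        assert rates[0] == 0.5

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(1, 30))
            preds = []
            for i in range(n):
                ranked = list(rng.permutation(12))
                labels = rng.choice(12, size=int(rng.integers(1, 5)), replace=False)
                preds.append(pred(ranked, labels, sid=str(i)))
            rates, hits_avg = unit_hit_rate(preds, k_max=10)
            for k in range(1, 11):
                count = sum(1 for p in preds
                            if p.ranked_elements[k - 1] in p.label_set)
                assert rates[k - 1] == pytest.approx(count / n, abs=1e-12)
            assert hits_avg == pytest.approx(float(np.mean(rates[:3])), abs=1e-12)

    def test_short_ranking_counts_misses(self):
        rates, _ = unit_hit_rate([pred("ab", "a")], k_max=5)
        assert list(rates) == [1.0, 0.0, 0.0, 0.0, 0.0]

    def test_uniform_random_ranking_expectation(self):
        """Single label, uniform ranking over V: each position hits 1/V."""
        rng = np.random.default_rng(4)
        V, trials = 8, 10000
        preds = [pred(rng.permutation(V), [int(rng.integers(V))], sid=str(i))
                 for i in range(trials)]
        rates, _ = unit_hit_rate(preds, k_max=V)
        assert np.allclose(rates, 1 / V, atol=3 * np.sqrt((1 / V) / trials) + 5e-3)


class TestReport:
    def test_duplicate_ranking_rejected(self):
        with pytest.raises(ValueError):
            RankedPrediction("x", ["a", "a"], [1.0, 0.5], {"a"})

    def test_report_consistency(self):
        rng = np.random.default_rng(5)
        preds = []
        for i in range(40):
            ranked = list(rng.permutation(15))
            labels = rng.choice(15, size=3, replace=False)
            preds.append(pred(ranked, labels, sid=str(i)))
        rep = build_report(preds, vocab_size=15)
        assert rep.hits_avg == pytest.approx(float(np.mean(rep.unit_hit_rate[:3])))
        assert rep.hits_at_10 == pytest.approx(corpus_hits_at_k(preds, 10))
        assert 0 <= rep.auc <= 1
        assert rep.mean_rank >= 1
        assert rep.n_samples == 40
        assert rep.auc == pytest.approx(auc_from_predictions(preds))

    def test_perfect_model_limit(self):
        preds = [pred("abcdefghij", "ab"), pred("bacdefghij", "ba")]
        rep = build_report(preds, vocab_size=10)
        assert rep.hits_at_10 == 1.0
        assert rep.mean_rank <= 2.0
        assert rep.unit_hit_rate[0] == 1.0

    def test_paired_bootstrap_detects_clear_gap(self):
        rng = np.random.default_rng(6)
        a = (rng.random(300) < 0.7).astype(float)
        b = (rng.random(300) < 0.4).astype(float)
        out = tr.metrics.paired_bootstrap(a.tolist(), b.tolist(), seed=1)
        assert out["mean_diff"] == pytest.approx(a.mean() - b.mean())
        assert out["ci_low"] > 0 and out["p_not_better"] < 0.01
        same = tr.metrics.paired_bootstrap(a.tolist(), a.tolist(), seed=1)
        assert same["mean_diff"] == 0.0 and same["p_not_better"] == 1.0
        with pytest.raises(ValueError):
            tr.metrics.paired_bootstrap([1.0], [])

    def test_position_table(self, tmp_path):
        preds = [pred("abcdefghij", "a")]
        tr.metrics.unit_hit_rate_table(preds, tmp_path / "pos.tsv")
        lines = (tmp_path / "pos.tsv").read_text().splitlines()
        assert lines[0] == "position\tunit_hit_rate"
        assert len(lines) == 12
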