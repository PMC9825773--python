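"""Confusion-matrix metrics, benchmark recovery, similarity analyses."""

import numpy as np
import pandas as pd
import pytest

import stcnet as sn
from conftest import pair_metrics_oracle


def build_world(n_drugs=100, targeting=10, adr_among_targeting=8,
                adr_among_rest=12):
    """Drug universe for the worked confusion example."""
    drugs = [f"d{i:03d}" for i in range(n_drugs)]
    tsets = {d: ({"P"} if i < targeting else set())
             for i, d in enumerate(drugs)}
    pairs = [(d, "A") for d in drugs[:adr_among_targeting]]
    pairs += [(d, "A") for d in drugs[targeting:targeting + adr_among_rest]]
    pairs += [(d, "other") for d in drugs]  # keep every drug labeled
    return tsets, sn.DrugADRLabels(pairs)


class TestConfusionCounts:
    def test_worked_example(self):
        tsets, labels = build_world()
        c = sn.confusion_counts("A", "P", tsets, labels)
        assert (c.tp, c.fp, c.fn, c.tn) == (8, 2, 12, 78)
        assert c.n == 100

    def test_untargeted_protein_has_empty_positive_margin(self):
        tsets, labels = build_world()
        c = sn.confusion_counts("A", "untargeted", tsets, labels)
        assert c.tp == 0 and c.fp == 0
        assert c.n == 100

    def test_unknown_adr_rejected(self):
        tsets, labels = build_world()
        with pytest.raises(KeyError):
            sn.confusion_counts("nope", "P", tsets, labels)


class TestPairMetrics:
    def test_worked_example(self):
        m = sn.pair_metrics(sn.ConfusionCounts(8, 2, 12, 78))
        assert m.ppv == pytest.approx(0.8)
        assert m.prevalence == pytest.approx(0.2)
        assert m.vappv == pytest.approx(0.6)
        assert m.lr == pytest.approx(16.0)
        assert not m.lr_corrected

    def test_zero_tp_with_positive_fp(self):
        m = sn.pair_metrics(sn.ConfusionCounts(0, 5, 20, 75))
        assert m.ppv == 0.0
        assert m.vappv == pytest.approx(-0.2)
        assert m.lr == 0.0

    def test_exact_independence_gives_zero_vappv(self):
        m = sn.pair_metrics(sn.ConfusionCounts(2, 8, 18, 72))
        assert m.vappv == pytest.approx(0.0)
        assert m.lr == pytest.approx(1.0)

    def test_zero_fp_triggers_continuity_correction(self):
        m = sn.pair_metrics(sn.ConfusionCounts(5, 0, 10, 85))
        assert m.lr_corrected
        assert np.isfinite(m.lr) and m.lr > 1

    def test_undefined_ppv_flagged_not_zeroed(self):
        m = sn.pair_metrics(sn.ConfusionCounts(0, 0, 30, 70))
        assert m.ppv is None and m.vappv is None
        assert m.lr_corrected

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            sn.pair_metrics(sn.ConfusionCounts(0, 0, 0, 0))

    def test_matches_rational_oracle_on_random_grid(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            tp, fp, fn, tn = (int(x) for x in rng.integers(0, 25, 4))
            if tp + fp + fn + tn == 0:
                tn = 1
            m = sn.pair_metrics(sn.ConfusionCounts(tp, fp, fn, tn))
            oppv, oprev, ovappv, olr = pair_metrics_oracle(tp, fp, fn, tn)
            assert m.prevalence == pytest.approx(float(oprev), abs=1e-12)
            if oppv is None:
                assert m.ppv is None
            else:
                assert m.ppv == pytest.approx(float(oppv), abs=1e-12)
                assert m.vappv == pytest.approx(float(ovappv), abs=1e-12)
            assert m.lr == pytest.approx(float(olr), abs=1e-12)


class TestVectorizedConfusion:
    def test_pairwise_confusion_matches_per_pair_counts(self, quick_world,
                                                        quick_labels):
        tsets = quick_world.drug_targets()
        prots, tp, fp, fn, tn = sn.pairwise_confusion(quick_labels, tsets)
        rng = np.random.default_rng(1)
        for _ in range(25):
            i = int(rng.integers(len(quick_labels.adrs)))
            j = int(rng.integers(len(prots)))
            c = sn.confusion_counts(quick_labels.adrs[i], prots[j], tsets,
                                    quick_labels)
            assert (tp[i, j], fp[i, j], fn[i, j], tn[i, j]) == \
                (c.tp, c.fp, c.fn, c.tn)

    def test_support_filtered_means_match_manual_average(self, quick_world,
                                                         quick_labels):
        tsets = quick_world.drug_targets()
        res = sn.support_filtered_pair_means(quick_labels, tsets,
                                             min_support=5)
        prots, tp, fp, fn, tn = sn.pairwise_confusion(quick_labels, tsets)
        manual_lr, manual_vappv = [], []
        adr_support = quick_labels.matrix.sum(axis=0)
        prot_support = (tp + fp)[0]
        for i, adr in enumerate(quick_labels.adrs):
            for j, prot in enumerate(prots):
                if adr_support[i] < 5 or prot_support[j] < 5:
                    continue
                m = sn.pair_metrics(sn.ConfusionCounts(
                    int(tp[i, j]), int(fp[i, j]), int(fn[i, j]),
                    int(tn[i, j])))
                manual_lr.append(m.lr)
                manual_vappv.append(m.vappv)
        assert res["n_pairs"] == len(manual_lr)
        assert res["mean_lr"] == pytest.approx(np.mean(manual_lr))
        assert res["mean_vappv"] == pytest.approx(np.mean(manual_vappv))


class TestEvaluateTopK:
    def test_below_support_adrs_reported_missing(self):
        tsets, labels = build_world(n_drugs=20, targeting=2,
                                    adr_among_targeting=2, adr_among_rest=2)
        scores = sn.ScoreMatrix(adr_ids=["A"], protein_ids=["P", "Q"],
                                scores=np.array([[0.9, 0.1]]))
        # protein P targeted by only 2 < 5 drugs, Q by none
        out = sn.evaluate_top_k(scores, tsets, labels, k=2, min_support=5)
        assert out["missing"] == ["A"]
        assert out["overall_mean_lr"] is None

    def test_single_surviving_pair_equals_its_metrics(self):
        tsets, labels = build_world()
        scores = sn.ScoreMatrix(adr_ids=["A"], protein_ids=["P", "Q"],
                                scores=np.array([[0.9, 0.1]]))
        out = sn.evaluate_top_k(scores, tsets, labels, k=1, min_support=5)
        expected = sn.pair_metrics(sn.confusion_counts("A", "P", tsets,
                                                       labels))
        assert out["overall_mean_vappv"] == pytest.approx(expected.vappv)
        assert out["overall_mean_lr"] == pytest.approx(expected.lr)
        assert out["n_pairs"] == 1


class TestBenchmarkRecovery:
    def test_argmax_pair_gets_top_percentile(self):
        scores = sn.ScoreMatrix(
            adr_ids=["a"], protein_ids=[f"p{i}" for i in range(10)],
            scores=np.linspace(0.9, 0.1, 10)[None, :])
        rec = sn.benchmark_recovery(scores, [("a", "p0")])
        assert rec["pairs"]["percentile"].iloc[0] <= 100 / 10

    def test_percentile_invariant_to_monotone_rescaling(self):
        rng = np.random.default_rng(3)
        raw = rng.random((2, 50))
        bench = [("a0", "p7"), ("a1", "p33")]
        ids = [f"p{i}" for i in range(50)]
        m1 = sn.ScoreMatrix(["a0", "a1"], ids, raw)
        m2 = sn.ScoreMatrix(["a0", "a1"], ids, 1 / (1 + np.exp(-5 * raw)))
        r1 = sn.benchmark_recovery(m1, bench)["pairs"]["percentile"]
        r2 = sn.benchmark_recovery(m2, bench)["pairs"]["percentile"]
        assert list(r1) == list(r2)

    def test_random_benchmark_null_fraction(self):
        rng = np.random.default_rng(4)
        ids = [f"p{i}" for i in range(100)]
        adrs = [f"a{j}" for j in range(20)]
        scores = sn.ScoreMatrix(adrs, ids, rng.random((20, 100)))
        bench = [(adrs[int(rng.integers(20))], ids[int(rng.integers(100))])
                 for _ in range(800)]
        rec = sn.benchmark_recovery(scores, sorted(set(bench)))
        assert 0.02 < rec["frac_top5"] < 0.08

    def test_unmapped_pairs_counted(self):
        scores = sn.ScoreMatrix(["a"], ["p1", "p2"],
                                np.array([[0.2, 0.8]]))
        rec = sn.benchmark_recovery(scores, [("a", "p1"), ("zz", "p1"),
                                             ("a", "zz")])
        assert rec["n_mapped"] == 1
        assert rec["n_unmapped"] == 2
        with pytest.raises(ValueError, match="mappable"):
            sn.benchmark_recovery(scores, [("zz", "zz")])


class TestBalancedBenchmarkEval:
    def test_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(5)
        ids = [f"p{i}" for i in range(15)]
        scores = sn.ScoreMatrix(["a", "b"], ids, rng.random((2, 15)))
        bench = [("a", "p1"), ("a", "p2"), ("b", "p3"), ("b", "p4"),
                 ("b", "p5")]
        r1 = sn.balanced_benchmark_eval(scores, bench, n_resamples=50, seed=9)
        r2 = sn.balanced_benchmark_eval(scores, bench, n_resamples=50, seed=9)
        assert np.array_equal(r1["auroc"], r2["auroc"])
        assert len(r1["ap"]) == 50

    def test_insufficient_negative_pool_rejected(self):
        scores = sn.ScoreMatrix(["a"], ["p1", "p2"],
                                np.array([[0.9, 0.8]]))
        bench = [("a", "p1"), ("a", "p2")]  # pool is empty
        with pytest.raises(ValueError, match="negative pool"):
            sn.balanced_benchmark_eval(scores, bench, n_resamples=5)


class TestSimilarities:
    def test_jaccard_and_cosine_worked_values(self):
        assert sn.jaccard({"a", "b"}, {"b", "c"}) == pytest.approx(1 / 3)
        assert sn.cosine([1.0, 2.0], [1.0, 2.0]) == pytest.approx(1.0)
        assert sn.cosine([1.0, 0.0], [0.0, 1.0]) == pytest.approx(0.0)

    def test_degenerate_inputs_flagged(self):
        with pytest.raises(ValueError):
            sn.jaccard(set(), set())
        with pytest.raises(ValueError):
            sn.cosine([0.0, 0.0], [1.0, 2.0])

    def test_duplicate_drugs_land_at_one_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 4))
        X[1] = X[0]  # identical embeddings
        drugs = [f"d{i}" for i in range(6)]
        pairs = [(d, a) for d in drugs for a in ("x", "y")
                 if rng.random() < 0.7] + [(d, "base") for d in drugs]
        labels = sn.DrugADRLabels(pairs)
        # force identical ADR sets for the duplicated pair
        labels.matrix[1] = labels.matrix[0]
        out = sn.drug_similarity_correlation(X, drugs, labels)
        top = out["pairs"][(out["pairs"]["jaccard"] == 1.0)
                           & (out["pairs"]["cosine"] > 0.999)]
        assert len(top) >= 1

    def test_randomized_labels_give_null_correlation(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 8))
        drugs = [f"d{i}" for i in range(60)]
        pairs = [(d, f"a{j}") for d in drugs for j in range(12)
                 if rng.random() < 0.4]
        labels = sn.DrugADRLabels(pairs)
        out = sn.drug_similarity_correlation(X, drugs, labels)
        assert abs(out["spearman"]) < 0.12


class TestSelectConfidenceThreshold:
    def test_noise_below_signal_threshold_selects_the_boundary(self):
        # two pharmacological groups with clean high-confidence targets;
        # sub-threshold noise records destroy the target-set alignment
        rng = np.random.default_rng(6)
        drugs = [f"d{i}" for i in range(12)]
        records, pairs = [], []
        for i, d in enumerate(drugs):
            group = i % 2
            tset = ["pa", "pb"] if group == 0 else ["pc", "pd"]
            adr = "adrX" if group == 0 else "adrY"
            pairs.append((d, adr))
            pairs.append((d, "common"))
            for p in tset:
                records.append(sn.InteractionRecord(d, p,
                                                    int(rng.integers(700, 1001))))
            for p in rng.choice(["pe", "pf", "pg", "ph"], 2, replace=False):
                records.append(sn.InteractionRecord(d, str(p),
                                                    int(rng.integers(100, 700))))
        labels = sn.DrugADRLabels(pairs)
        best, table = sn.select_confidence_threshold(records, labels,
                                                     [200, 450, 700])
        assert best == 700
        assert table.loc[table["threshold"] == 700, "pearson"].iloc[0] == \
            table["pearson"].max()

    def test_single_threshold_returned(self):
        labels = sn.DrugADRLabels([("d1", "a"), ("d2", "b")])
        best, _ = sn.select_confidence_threshold(
            [sn.InteractionRecord("d1", "p", 900)], labels, [700])
        assert best == 700


class TestGroupedScoreSimilarity:
    def test_identical_rows_give_unit_within_group_cosine(self):
        row = np.linspace(0.1, 0.9, 8)
        scores = sn.ScoreMatrix(["a1", "a2", "a3"],
                                [f"p{i}" for i in range(8)],
                                np.vstack([row, row, row * 0.5 + 0.2]))
        grouping = {"a1": {"g"}, "a2": {"g"}, "a3": set()}
        # need ≥2 pairs per label for the t-test: add one more member
        scores2 = sn.ScoreMatrix(["a1", "a2", "a3", "a4"],
                                 [f"p{i}" for i in range(8)],
                                 np.vstack([row, row, row * 0.5 + 0.2, row]))
        grouping = {"a1": {"g"}, "a2": {"g"}, "a4": {"g"}, "a3": set()}
        table = sn.grouped_score_similarity(scores2, grouping)
        assert table.loc[table["label"] == "g", "mean_cosine"].iloc[0] == \
            pytest.approx(1.0)

    def test_planted_module_grouping_beats_baseline(self, quick_world,
                                                    quick_fit):
        # group causal modules by parity so each label covers several ADR
        # pairs; same-module pairs inside a label pull its mean similarity
        # above the no-shared-label baseline
        grouping = {a: {f"parity{m % 2}"} for a, m in
                    quick_world.adr_module.items()}
        table = sn.grouped_score_similarity(quick_fit["scores"], grouping)
        assert (table["mean_cosine"] > table["baseline_mean"]).all()
        assert "p_bh" in table.columns

    def test_empty_baseline_pool_rejected(self):
        scores = sn.ScoreMatrix(["a1", "a2"], ["p1", "p2"],
                                np.array([[0.1, 0.9], [0.3, 0.7]]))
        with pytest.raises(ValueError, match="baseline"):
            sn.grouped_score_similarity(scores, {"a1": {"g"}, "a2": {"g"}})
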