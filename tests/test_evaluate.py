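"""Evaluation protocol: AUC, cross-validation, sweeps, FN candidates."""

import itertools

import numpy as np
import pandas as pd
import pytest

from binppi.evaluate import (
    auc,
    cross_validate,
    fit_fold,
    fn_candidates,
    mu_sweep,
    topk_similarity_curve,
)
from binppi.evidence import EvidenceTable
from binppi.labels import LabeledPairSet
from binppi.net_io import ProteinPair
from binppi.simulate import ChannelModel, sample_labeled_scores

from conftest import build_network


def pairwise_auc_oracle(scores, labels):
    """Exhaustive positive-negative comparison; ties count half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([4, 3, 2, 1], [1, 1, 0, 0]) == 1.0

    def test_constant_scores_give_half(self):
        assert auc([1, 1, 1, 1], [1, 0, 1, 0]) == 0.5

    def test_interleaved_hand_case(self):
        assert auc([3, 2, 1, 0], [1, 0, 1, 0]) == pytest.approx(
            pairwise_auc_oracle([3, 2, 1, 0], [1, 0, 1, 0])
        )
        assert auc([3, 2, 1, 0], [1, 0, 1, 0]) == 0.75

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auc([1, 2], [1, 1])

    def test_agrees_with_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            scores = rng.integers(0, 8, size=n).astype(float)  # heavy ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert auc(scores, labels) == pytest.approx(
                pairwise_auc_oracle(scores.tolist(), labels.tolist())
            )


def labeled_evidence(n=200, auc_like=True, seed=0):
    """Single-channel evidence with separable (or null) scores."""
    chan = (
        ChannelModel("ch", (8.0, 1.0), (1.0, 8.0))
        if auc_like
        else ChannelModel("ch", (2.0, 2.0), (2.0, 2.0))
    )
    pairs, scores, truth = sample_labeled_scores(n, chan, prior=0.5, seed=seed)
    table = EvidenceTable(pd.DataFrame({"ch": scores}, index=pairs))
    labels = LabeledPairSet(
        positives={p for p, t in zip(pairs, truth) if t},
        negatives={p for p, t in zip(pairs, truth) if not t},
    )
    return table, labels


class TestCrossValidate:
    def test_separable_data_high_auc_everywhere(self):
        table, labels = labeled_evidence(n=300, auc_like=True)
        reports = cross_validate(table, labels, k=5, mu_rel=0.05, seed=0)
        for report in reports:
            assert report.mean_auc > 0.9, report

    def test_null_scores_auc_near_half(self):
        table, labels = labeled_evidence(n=1000, auc_like=False)
        reports = cross_validate(
            table, labels, k=5, mu_rel=0.05,
            methods=[("ch", "raw"), ("ch", "bin_confidence")], seed=0,
        )
        for report in reports:
            assert 0.4 <= report.mean_auc <= 0.6

    def test_k_larger_than_class_errors(self):
        table, labels = labeled_evidence(n=12)
        with pytest.raises(ValueError):
            cross_validate(table, labels, k=50)

    def test_fold_count_as_configured(self):
        table, labels = labeled_evidence(n=100)
        reports = cross_validate(table, labels, k=4, methods=[("ch", "raw")])
        assert len(reports[0].fold_aucs) == 4

    def test_training_partitions_blind_to_test_labels(self):
        # the leakage guard: flip every test-fold label, partitions must
        # be bit-identical because they are built on the training fold only
        table, labels = labeled_evidence(n=120, seed=3)
        all_pairs = sorted(labels.positives) + sorted(labels.negatives)
        train_pairs = all_pairs[:80]
        test_pairs = all_pairs[80:]
        parts_before, feats_before = fit_fold(table, labels, train_pairs, mu_rel=0.1)
        flipped = LabeledPairSet(
            positives=(labels.positives - set(test_pairs)) | (labels.negatives & set(test_pairs)),
            negatives=(labels.negatives - set(test_pairs)) | (labels.positives & set(test_pairs)),
        )
        parts_after, feats_after = fit_fold(table, flipped, train_pairs, mu_rel=0.1)
        for channel in parts_before:
            pd.testing.assert_frame_equal(
                parts_before[channel].to_frame(), parts_after[channel].to_frame()
            )
            assert [b.member_pairs for b in parts_before[channel].bins] == [
                b.member_pairs for b in parts_after[channel].bins
            ]
        pd.testing.assert_frame_equal(feats_before, feats_after)


class TestMuSweep:
    def test_full_collapse_gives_half_auc(self):
        table, labels = labeled_evidence(n=200)
        df = mu_sweep(table, labels, [1.0], methods=[("ch", "bin_confidence")])
        # mu/n = 1 puts every training pair in a single bin: the feature
        # is constant and carries no ranking information
        assert df.mean_auc.iloc[0] == 0.5

    def test_grid_of_one_value_one_row_per_method(self):
        table, labels = labeled_evidence(n=100)
        df = mu_sweep(table, labels, [0.1], methods=[("ch", "raw"), ("ch", "bin_confidence")])
        assert len(df) == 2

    def test_empty_grid_errors(self):
        table, labels = labeled_evidence(n=100)
        with pytest.raises(ValueError):
            mu_sweep(table, labels, [])


class TestFnCandidates:
    def test_square_yields_diagonals(self, square_net):
        assert fn_candidates(square_net, 2) == [ProteinPair("A", "C"), ProteinPair("B", "D")]

    def test_triangle_yields_none(self):
        net = build_network([("A", "B"), ("B", "C"), ("C", "A")])
        assert fn_candidates(net, 1) == []

    def test_star_thresholds(self):
        net = build_network([("hub", "l1"), ("hub", "l2"), ("hub", "l3")])
        assert len(fn_candidates(net, 1)) == 3
        assert fn_candidates(net, 2) == []

    def test_never_returns_edges_or_self_pairs(self):
        rng = np.random.default_rng(7)
        edges = {(int(a), int(b)) for a, b in rng.integers(0, 30, size=(120, 2)) if a != b}
        net = build_network([(f"n{a}", f"n{b}") for a, b in edges])
        for pair in fn_candidates(net, 2):
            assert not net.has_edge(pair)
            assert pair.a != pair.b

    def test_min_common_validated(self, square_net):
        with pytest.raises(ValueError):
            fn_candidates(square_net, 0)


class TestTopkSimilarityCurve:
    def _ranked(self, n):
        pairs = [ProteinPair(f"a{i}", f"b{i}") for i in range(n)]
        return pd.DataFrame({"decision": np.linspace(1, 0, n)}, index=pairs)

    def test_constant_similarity_constant_curve(self):
        ranked = self._ranked(5)
        sims = {p: 0.4 for p in ranked.index}
        curve, skipped = topk_similarity_curve(ranked, sims, [2, 5])
        assert curve == [(2, pytest.approx(0.4)), (5, pytest.approx(0.4))]
        assert skipped == 0

    def test_rank_aligned_similarity_non_increasing(self):
        ranked = self._ranked(6)
        sims = {p: 1.0 - 0.1 * i for i, p in enumerate(ranked.index)}
        curve, _ = topk_similarity_curve(ranked, sims, [1, 3, 6])
        values = [v for _, v in curve]
        assert values == sorted(values, reverse=True)

    def test_hand_means_and_skip_count(self):
        ranked = self._ranked(5)
        pairs = list(ranked.index)
        sims = {pairs[0]: 0.8, pairs[1]: 0.6, pairs[3]: 0.4}  # 2 pairs missing
        curve, skipped = topk_similarity_curve(ranked, sims, [2, 5])
        assert skipped == 2
        assert curve[0] == (2, pytest.approx(0.7))
        with pytest.warns(UserWarning):
            topk_similarity_curve(ranked, sims, [10])
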