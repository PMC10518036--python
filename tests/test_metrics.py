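"""Metric formulas against enumeration oracles and analytic values."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sigensemble import (
    ActivityMatrix,
    ConfusionCounts,
    binary_confusion,
    confusion_rates,
    cosine_rvo,
    dominant_consensus,
    dominant_signature,
    jaccard,
    kendall_tau_b,
    rmse_vs_truth,
    samplewise_concordance,
    shannon_diversity,
    signaturewise_concordance,
)


def tau_b_enumeration(x, y) -> float:
    """O(n^2) pair-count oracle for tie-corrected Kendall correlation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    C = D = Tx = Ty = 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                Tx += 1
            elif dy == 0:
                Ty += 1
            elif dx * dy > 0:
                C += 1
            else:
                D += 1
    denom = math.sqrt((C + D + Tx) * (C + D + Ty))
    return (C - D) / denom if denom else float("nan")


def activity(props: dict, sigs: list[str]) -> ActivityMatrix:
    df = pd.DataFrame(props, index=sigs, dtype=float)
    return ActivityMatrix.from_proportions(df, np.full(df.shape[1], 1000.0))


class TestCosine:
    def test_identical_spectra(self):
        v = np.arange(96, dtype=float)
        assert cosine_rvo(v, v) == pytest.approx(1.0)

    def test_scale_invariance(self):
        v = np.random.default_rng(0).random(96)
        assert cosine_rvo(v, 3 * v) == pytest.approx(1.0)

    def test_disjoint_support(self):
        a = np.zeros(96)
        b = np.zeros(96)
        a[:48] = 1
        b[48:] = 1
        assert cosine_rvo(a, b) == 0.0

    def test_zero_vector_is_missing(self):
        assert np.isnan(cosine_rvo(np.zeros(96), np.ones(96)))


class TestJaccard:
    def test_equal_nonempty_sets(self):
        assert jaccard({"SBS1", "SBS2"}, {"SBS1", "SBS2"}) == 1.0

    def test_disjoint_sets(self):
        assert jaccard({"SBS1"}, {"SBS2"}) == 0.0

    def test_half_overlap(self):
        assert jaccard({"SBS1", "SBS2", "SBS3"}, {"SBS2", "SBS3", "SBS13"}) == 0.5

    def test_both_empty_is_missing(self):
        assert np.isnan(jaccard(set(), set()))

    @given(
        st.sets(st.integers(0, 9), max_size=6), st.sets(st.integers(0, 9), max_size=6)
    )
    def test_symmetric_and_bounded(self, a, b):
        if not (a | b):
            return
        assert jaccard(a, b) == jaccard(b, a)
        assert 0.0 <= jaccard(a, b) <= 1.0


class TestKendallTauB:
    def test_perfectly_concordant(self):
        assert kendall_tau_b([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)

    def test_perfectly_reversed(self):
        assert kendall_tau_b([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_tied_example_matches_enumeration(self):
        x, y = [1, 2, 2, 3], [1, 2, 3, 3]
        assert kendall_tau_b(x, y) == pytest.approx(tau_b_enumeration(x, y))

    def test_constant_input_is_missing(self):
        assert np.isnan(kendall_tau_b([1, 1, 1], [1, 2, 3]))

    @given(st.integers(0, 2**31 - 1), st.integers(2, 50))
    def test_matches_enumeration_oracle_with_ties(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, size=n).astype(float)
        y = rng.integers(0, 6, size=n).astype(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            return
        assert kendall_tau_b(x, y) == pytest.approx(tau_b_enumeration(x, y), abs=1e-12)


class TestShannonDiversity:
    def test_one_hot_is_zero(self):
        p = np.zeros(96)
        p[0] = 1.0
        assert shannon_diversity(p) == 0.0

    def test_uniform_is_ln_96(self):
        assert shannon_diversity(np.full(96, 1 / 96)) == pytest.approx(math.log(96))

    def test_two_equal_channels_is_ln_2(self):
        p = np.zeros(96)
        p[:2] = 0.5
        assert shannon_diversity(p) == pytest.approx(math.log(2))

    def test_uniform_is_the_maximum(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            assert shannon_diversity(rng.dirichlet(np.ones(96))) < math.log(96)


class TestRmse:
    def test_perfect_estimate_is_zero(self):
        t = activity({"S1": [0.6, 0.4], "S2": [0.5, 0.5]}, ["A", "B"])
        assert rmse_vs_truth(t, t) == 0.0

    def test_constant_offset_on_active_entries(self):
        t = activity({"S1": [0.6, 0.4]}, ["A", "B"])
        e = activity({"S1": [0.7, 0.3]}, ["A", "B"])
        assert rmse_vs_truth(e, t) == pytest.approx(0.1)

    def test_only_active_truth_entries_count(self):
        # one active entry off by 0.1, one exact; inactive entries ignored
        t = activity({"S1": [0.5, 0.5], "S2": [1.0, 0.0]}, ["A", "B"])
        e = activity({"S1": [0.6, 0.4], "S2": [1.0, 0.0]}, ["A", "B"])
        # active truth entries: (A,S1)=.5->.6, (B,S1)=.5->.4, (A,S2)=1->1
        assert rmse_vs_truth(e, t) == pytest.approx(math.sqrt(0.02 / 3))

    def test_invariant_to_row_and_column_order(self):
        rng = np.random.default_rng(2)
        t = activity({f"S{j}": list(rng.dirichlet([1, 1, 1])) for j in range(4)}, ["A", "B", "C"])
        e = activity({f"S{j}": list(rng.dirichlet([1, 1, 1])) for j in range(4)}, ["A", "B", "C"])
        shuffled = ActivityMatrix(
            proportions=e.proportions.iloc[::-1][["S3", "S1", "S0", "S2"]],
            counts=e.counts.iloc[::-1][["S3", "S1", "S0", "S2"]],
        )
        assert rmse_vs_truth(shuffled, t) == pytest.approx(rmse_vs_truth(e, t))


class TestConfusion:
    def test_ppv(self):
        assert confusion_rates(ConfusionCounts(9, 1, 0, 1))["ppv"] == pytest.approx(0.9)

    def test_npv_with_perfect_negatives(self):
        assert confusion_rates(ConfusionCounts(1, 0, 483, 0))["npv"] == 1.0

    def test_accuracy(self):
        rates = confusion_rates(ConfusionCounts(70, 10, 470, 10))
        assert rates["accuracy"] == pytest.approx(540 / 560)

    def test_zero_denominator_is_missing(self):
        assert np.isnan(confusion_rates(ConfusionCounts(0, 0, 5, 1))["ppv"])

    def test_binary_confusion_tally(self):
        pred = [True, True, False, False]
        truth = [True, False, True, False]
        c = binary_confusion(pred, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)


class TestDominant:
    def test_argmax_and_tie_flag(self):
        a = activity({"S1": [0.6, 0.4], "S2": [0.5, 0.5]}, ["B_SIG", "A_SIG"])
        dom = dominant_signature(a)
        assert dom.loc["S1", "dominant"] == "B_SIG"
        assert not dom.loc["S1", "tie"]
        assert dom.loc["S2", "dominant"] == "A_SIG"  # lexicographic tie-break
        assert dom.loc["S2", "tie"]

    def test_identical_members_have_full_consensus(self):
        a = activity({"S1": [0.6, 0.4], "S2": [0.2, 0.8]}, ["X", "Y"])
        cons = dominant_consensus([a] * 5)
        assert (cons["consensus"] == 5).all()


class TestConcordance:
    def make_members(self):
        m1 = activity(
            {"S1": [0.5, 0.5, 0.0], "S2": [0.4, 0.3, 0.3], "S3": [0.7, 0.2, 0.1]},
            ["A", "B", "C"],
        )
        m2 = activity(
            {"S1": [0.6, 0.4, 0.0], "S2": [0.3, 0.4, 0.3], "S3": [0.6, 0.3, 0.1]},
            ["A", "B", "C"],
        )
        return m1, m2

    def test_identical_members_are_perfectly_concordant(self):
        m1, _ = self.make_members()
        rep = samplewise_concordance([m1, m1])
        assert rep.pairwise_jaccard.iloc[0, 1] == 1.0
        assert rep.pairwise_tau.iloc[0, 1] == pytest.approx(1.0)

    def test_sample_with_one_signature_is_invalid_everywhere(self):
        m1 = activity({"S1": [1.0, 0.0], "S2": [0.5, 0.5]}, ["A", "B"])
        m2 = activity({"S1": [0.6, 0.4], "S2": [0.5, 0.5]}, ["A", "B"])
        rep = samplewise_concordance([m1, m2])
        assert rep.valid_sample_ids == ["S2"]

    def test_toy_means_match_hand_enumeration(self):
        m1, m2 = self.make_members()
        rep = samplewise_concordance([m1, m2])
        jacs, taus = [], []
        for s in ["S1", "S2", "S3"]:
            x = m1.assigned_proportions[s].to_numpy()
            y = m2.assigned_proportions[s].to_numpy()
            keep = (x > 0) | (y > 0)
            taus.append(tau_b_enumeration(x[keep], y[keep]))
            jacs.append(
                jaccard(set(np.flatnonzero(x > 0)), set(np.flatnonzero(y > 0)))
            )
        assert rep.pairwise_jaccard.iloc[0, 1] == pytest.approx(np.mean(jacs))
        assert rep.pairwise_tau.iloc[0, 1] == pytest.approx(np.nanmean(taus))

    def test_signature_identical_across_members_scores_one(self):
        rng = np.random.default_rng(3)
        vals = rng.dirichlet(np.ones(3), size=10).T
        df = pd.DataFrame(vals, index=["A", "B", "C"], columns=[f"S{i}" for i in range(10)])
        m = ActivityMatrix.from_proportions(df, np.full(10, 1000.0))
        rep = signaturewise_concordance([m, m, m])
        np.testing.assert_allclose(rep.per_signature_tau.to_numpy(), 1.0)

    def test_everywhere_inactive_signature_is_invalid(self):
        m1 = activity({"S1": [0.5, 0.5, 0.0], "S2": [0.6, 0.4, 0.0]}, ["A", "B", "C"])
        m2 = activity({"S1": [0.4, 0.6, 0.0], "S2": [0.7, 0.3, 0.0]}, ["A", "B", "C"])
        rep = signaturewise_concordance([m1, m2])
        assert "C" not in rep.valid_signature_ids
        assert set(rep.valid_signature_ids) == {"A", "B"}

    def test_pairwise_tau_matches_enumeration_for_two_members(self):
        m1, m2 = self.make_members()
        rep = signaturewise_concordance([m1, m2])
        for sig in rep.valid_signature_ids:
            x = m1.assigned_proportions.loc[sig].to_numpy()
            y = m2.assigned_proportions.loc[sig].to_numpy()
            keep = (x > 0) | (y > 0)
            assert rep.per_signature_tau[sig] == pytest.approx(
                tau_b_enumeration(x[keep], y[keep])
            )
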