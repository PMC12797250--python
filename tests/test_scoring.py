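from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xsar.bitmodel import categorize_bits, from_json, to_json
from xsar.dataio import DataError
from xsar.fingerprints import fingerprint
from xsar.scoring import (
    classify,
    compare_outcome_scores,
    landscape,
    pr_auc,
    score,
    tanimoto_baselines,
)

from conftest import make_bits, make_labelled


@pytest.fixture
def worked_model():
    # continues the five-bit categorisation example:
    # CBB={0,2}, CNB={3}, UCB={1}, USB={4}
    fps, ds = make_labelled(["10100", "11100"], ["01010", "10010"])
    return categorize_bits(fps, ds), fps, ds


class TestScore:
    def test_worked_example_compound(self, worked_model):
        model, _, _ = worked_model
        fps = make_bits(["10100"], ids=["q"])
        (rec,) = score(model, fps)
        assert rec.pbs_fraction == 1 and rec.nbs_fraction == 1

    def test_partial_compound(self, worked_model):
        model, _, _ = worked_model
        fps = make_bits(["10010"], ids=["q"])
        (rec,) = score(model, fps)
        assert rec.pbs_fraction == Fraction(1, 2)
        assert rec.nbs_fraction == 0

    def test_training_binders_score_one_exactly(self, worked_model):
        model, fps, ds = worked_model
        for rec in score(model, fps):
            if rec.id in ds.binder_ids:
                assert rec.pbs_fraction == 1 and rec.nbs_fraction == 1

    def test_empty_cnb_is_an_error(self):
        fps, ds = make_labelled(["11"], ["10"])
        model = categorize_bits(fps, ds)
        assert not model.cnb
        with pytest.raises(DataError, match="NBS"):
            score(model, fps)

    def test_param_mismatch_rejected(self, worked_model):
        model, _, _ = worked_model
        with pytest.raises(DataError):
            score(model, make_bits(["101000"]))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.integers(2, 10).flatmap(
            lambda m: st.tuples(
                st.lists(st.text("01", min_size=m, max_size=m), min_size=1, max_size=6),
                st.lists(st.text("01", min_size=m, max_size=m), min_size=1, max_size=6),
            )
        )
    )
    def test_bounds_and_binder_identity_property(self, rows):
        binders, nonbinders = rows
        fps, ds = make_labelled(binders, nonbinders)
        model = categorize_bits(fps, ds)
        if not model.cbb or not model.cnb:
            return
        for rec in score(model, fps):
            assert 0 <= rec.pbs_fraction <= 1
            assert 0 <= rec.nbs_fraction <= 1
            if rec.id in ds.binder_ids:
                assert rec.pbs_fraction == 1 and rec.nbs_fraction == 1

    def test_extra_bit_monotonicity(self, worked_model):
        model, _, _ = worked_model
        base = [0, 0, 0, 0, 0]
        for flip in range(5):
            row = list(base)
            row[flip] = 1
            before = score(model, make_bits(["00000"]))[0]
            after = score(model, make_bits(["".join(map(str, row))]))[0]
            assert after.pbs_fraction >= before.pbs_fraction
            assert after.nbs_fraction <= before.nbs_fraction

    def test_scores_survive_model_serialisation(self, worked_model, tmp_path):
        model, fps, _ = worked_model
        reloaded = from_json(to_json(model))
        direct = [(r.pbs_fraction, r.nbs_fraction) for r in score(model, fps)]
        loaded = [(r.pbs_fraction, r.nbs_fraction) for r in score(reloaded, fps)]
        assert direct == loaded


class TestClassify:
    def test_perfect_scores_predict_binder(self, worked_model):
        model, _, _ = worked_model
        (rec,) = score(model, make_bits(["10100"]))
        verdict = classify(rec)
        assert verdict.predicted_binder_by_pbs
        assert not verdict.predicted_nonbinder_by_nbs

    def test_pbs_rule_is_strict_equality(self, worked_model):
        model, _, _ = worked_model
        (rec,) = score(model, make_bits(["00100"]))  # pbs 1/2
        assert not classify(rec).predicted_binder_by_pbs

    def test_any_cnb_activation_predicts_nonbinder(self, worked_model):
        model, _, _ = worked_model
        (rec,) = score(model, make_bits(["10110"]))  # activates the CNB bit
        assert classify(rec).predicted_nonbinder_by_nbs


class TestTanimotoBaselines:
    def test_identical_to_one_of_three_binders(self):
        binders = make_bits(["1100", "0011", "0010"])
        query = make_bits(["1100"], ids=["q"])
        frame = tanimoto_baselines(query, binders)
        assert frame.loc["q", "max_sim"] == 1.0
        assert frame.loc["q", "mean_sim"] == pytest.approx(1 / 3)

    def test_single_identical_binder(self):
        binders = make_bits(["101"])
        frame = tanimoto_baselines(make_bits(["101"], ids=["q"]), binders)
        assert tuple(frame.loc["q"]) == (1.0, 1.0)

    def test_disjoint_query(self):
        binders = make_bits(["1100", "1000"])
        frame = tanimoto_baselines(make_bits(["0011"], ids=["q"]), binders)
        assert tuple(frame.loc["q"]) == (0.0, 0.0)

    def test_empty_binder_set_rejected(self):
        from xsar.fingerprints import FingerprintMatrix, FingerprintParams

        empty = FingerprintMatrix([], np.zeros((0, 2), np.uint8), FingerprintParams(2))
        with pytest.raises(DataError):
            tanimoto_baselines(make_bits(["11"]), empty)


def exact_mwu_oracle(scores, outcomes):
    """Independent exhaustive two-sided permutation p-value."""
    values = np.asarray(scores, float)
    n = len(values)
    n_pos = int(sum(outcomes))

    def u_of(mask):
        pos = values[list(mask)]
        neg = values[[i for i in range(n) if i not in mask]]
        return sum(
            1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
        )

    obs = u_of({i for i, o in enumerate(outcomes) if o})
    mu = n_pos * (n - n_pos) / 2
    hits = sum(
        abs(u_of(set(c)) - mu) >= abs(obs - mu) - 1e-12
        for c in combinations(range(n), n_pos)
    )
    from math import comb

    return hits / comb(n, n_pos)


class TestCompareOutcomeScores:
    def test_fully_separated_exact_p(self):
        res = compare_outcome_scores(
            [1.0, 1.0, 0.9, 0.2, 0.3, 0.1], [1, 1, 1, 0, 0, 0]
        )
        assert res.p_value == pytest.approx(0.1)
        assert res.u_statistic == 9.0
        assert res.delta == pytest.approx((1.0 + 1.0 + 0.9) / 3 - 0.2)

    def test_identical_groups_have_zero_delta(self):
        res = compare_outcome_scores([0.5, 0.7, 0.5, 0.7], [1, 1, 0, 0])
        assert res.delta == 0.0
        assert res.p_value == 1.0

    def test_single_pair(self):
        res = compare_outcome_scores([1.0, 0.0], [1, 0])
        assert res.delta == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(DataError):
            compare_outcome_scores([1.0, 0.5], [1, 1])

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        st.lists(st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]), min_size=2, max_size=8),
        st.data(),
    )
    def test_matches_exact_enumeration_oracle(self, values, data):
        n = len(values)
        n_pos = data.draw(st.integers(1, n - 1))
        outcomes = [i < n_pos for i in range(n)]
        res = compare_outcome_scores(values, outcomes)
        assert res.p_value == pytest.approx(exact_mwu_oracle(values, outcomes))


def pr_auc_oracle(scores, labels):
    """Brute-force threshold sweep, step-function convention."""
    order = np.argsort(-np.asarray(scores, float), kind="stable")
    s = np.asarray(scores, float)[order]
    y = np.asarray(labels, int)[order]
    ap, prev_recall = 0.0, 0.0
    n_pos = y.sum()
    for t in sorted(set(s), reverse=True):
        at_or_above = s >= t
        tp = int(y[at_or_above].sum())
        precision = tp / int(at_or_above.sum())
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestPrAuc:
    def test_perfect_separation(self):
        assert pr_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_constant_scores_give_prevalence(self):
        assert pr_auc([0.5] * 10, [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]) == pytest.approx(0.3)

    def test_matches_threshold_sweep_oracle(self):
        scores, labels = [0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]
        assert pr_auc(scores, labels) == pytest.approx(pr_auc_oracle(scores, labels))

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(st.tuples(st.sampled_from([0.1, 0.5, 0.9]), st.booleans()),
                    min_size=2, max_size=12))
    def test_oracle_property(self, pairs):
        scores = [p[0] for p in pairs]
        labels = [p[1] for p in pairs]
        if len(set(labels)) < 2:
            return
        assert pr_auc(scores, labels) == pytest.approx(pr_auc_oracle(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            pr_auc([0.1, 0.2], [1, 1])


class TestLandscape:
    def chemotypes(self, n_each=30, m=64, seed=0):
        rng = np.random.default_rng(seed)
        a = (rng.random((n_each, m // 2)) < 0.6).astype(np.uint8)
        b = (rng.random((n_each, m // 2)) < 0.6).astype(np.uint8)
        top = np.hstack([a, np.zeros_like(a)])
        bottom = np.hstack([np.zeros_like(b), b])
        return make_bits(["".join(map(str, r)) for r in np.vstack([top, bottom])])

    def test_shape_contract(self):
        fps = self.chemotypes()
        emb = landscape(fps, seed=0, perplexity=10)
        assert emb.shape == (60, 2)

    def test_deterministic_given_seed(self):
        fps = self.chemotypes()
        a = landscape(fps, seed=3, perplexity=10)
        b = landscape(fps, seed=3, perplexity=10)
        np.testing.assert_array_equal(a, b)

    def test_separates_planted_chemotypes(self):
        fps = self.chemotypes()
        emb = landscape(fps, seed=0, perplexity=10)
        first, second = emb[:30], emb[30:]
        intra = np.mean([
            np.linalg.norm(x - y)
            for grp in (first, second)
            for i, x in enumerate(grp)
            for y in grp[i + 1:]
        ])
        inter = np.mean([
            np.linalg.norm(x - y) for x in first for y in second
        ])
        assert inter > intra

    def test_too_few_samples_rejected(self):
        fps = make_bits(["10", "01"])
        with pytest.raises(DataError, match="perplexity"):
            landscape(fps, seed=0)
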