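import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xsar.bitmodel import (
    UndefinedModelError,
    categorize_bits,
    compare_categorizations,
    conservation_scores,
    feature_prevalence_in_bits,
    from_json,
    to_json,
)
from xsar.dataio import DataError

from conftest import make_labelled


def brute_force_categorize(binder_rows, nonbinder_rows):
    """Independent per-bit enumeration of the four categories."""
    M = len(binder_rows[0])
    out = {"cbb": set(), "cnb": set(), "ucb": set(), "usb": set()}
    for m in range(M):
        in_binders = [int(r[m]) for r in binder_rows]
        in_nonbinders = [int(r[m]) for r in nonbinder_rows]
        if all(in_binders):
            out["cbb"].add(m)
        elif any(in_binders):
            out["ucb"].add(m)
        elif any(in_nonbinders):
            out["cnb"].add(m)
        else:
            out["usb"].add(m)
    return out


bit_row = st.integers(1, 12).flatmap(
    lambda m: st.tuples(
        st.lists(st.text("01", min_size=m, max_size=m), min_size=1, max_size=8),
        st.lists(st.text("01", min_size=m, max_size=m), min_size=0, max_size=8),
    )
)


class TestConservationScores:
    def test_worked_example(self):
        fps, ds = make_labelled(["101", "110", "100"], [])
        np.testing.assert_allclose(
            conservation_scores(fps, ds), [1.0, 1 / 3, 1 / 3]
        )

    def test_single_binder_scores_are_binary(self):
        fps, ds = make_labelled(["1010"], ["0110"])
        s = conservation_scores(fps, ds)
        assert set(np.unique(s)) <= {0.0, 1.0}

    def test_no_binders_is_undefined(self):
        fps, ds = make_labelled([], ["101"])
        with pytest.raises(UndefinedModelError):
            conservation_scores(fps, ds)


class TestCategorizeBits:
    def test_worked_five_bit_example(self):
        fps, ds = make_labelled(["10100", "11100"], ["01010", "10010"])
        cat = categorize_bits(fps, ds)
        assert cat.cbb == {0, 2}
        assert cat.ucb == {1}
        assert cat.cnb == {3}
        assert cat.usb == {4}
        assert len(cat.cbb) + len(cat.cnb) + len(cat.ucb) + len(cat.usb) == 5

    def test_identical_binders_only(self):
        fps, ds = make_labelled(["1100", "1100"], [])
        cat = categorize_bits(fps, ds)
        assert cat.cbb == {0, 1} and cat.usb == {2, 3}
        assert not cat.cnb and not cat.ucb

    def test_disjoint_nonbinder_bits_all_cnb(self):
        fps, ds = make_labelled(["1100"], ["0011", "0010"])
        cat = categorize_bits(fps, ds)
        assert cat.cnb == {2, 3}

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(bit_row)
    def test_partition_matches_brute_force(self, rows):
        binders, nonbinders = rows
        fps, ds = make_labelled(binders, nonbinders)
        cat = categorize_bits(fps, ds)
        expected = brute_force_categorize(binders, nonbinders)
        assert cat.cbb == expected["cbb"]
        assert cat.cnb == expected["cnb"]
        assert cat.ucb == expected["ucb"]
        assert cat.usb == expected["usb"]

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(bit_row)
    def test_partition_complete_and_disjoint(self, rows):
        binders, nonbinders = rows
        fps, ds = make_labelled(binders, nonbinders)
        cat = categorize_bits(fps, ds)
        M = fps.length
        assert len(cat.cbb) + len(cat.cnb) + len(cat.ucb) + len(cat.usb) == M
        assert cat.cbb | cat.cnb | cat.ucb | cat.usb == set(range(M))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(bit_row, st.text("01", min_size=12, max_size=12))
    def test_appending_nonbinder_monotonicity(self, rows, extra):
        binders, nonbinders = rows
        extra = extra[: len(binders[0])]
        before = categorize_bits(*make_labelled(binders, nonbinders))
        after = categorize_bits(*make_labelled(binders, nonbinders + [extra]))
        assert after.cbb == before.cbb
        assert before.cnb <= after.cnb  # USB may move to CNB, never out

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(bit_row, st.text("01", min_size=12, max_size=12))
    def test_appending_binder_monotonicity(self, rows, extra):
        binders, nonbinders = rows
        extra = extra[: len(binders[0])]
        before = categorize_bits(*make_labelled(binders, nonbinders))
        after = categorize_bits(*make_labelled(binders + [extra], nonbinders))
        assert after.cbb <= before.cbb
        assert after.cnb <= before.cnb  # CNB may shrink towards UCB

    def test_permuting_compound_order_leaves_model_unchanged(self):
        binders, nonbinders = ["1010", "1110"], ["0101", "0001"]
        a = categorize_bits(*make_labelled(binders, nonbinders))
        b = categorize_bits(*make_labelled(binders[::-1], nonbinders[::-1]))
        assert (a.cbb, a.cnb, a.ucb, a.usb) == (b.cbb, b.cnb, b.ucb, b.usb)


class TestCompareCategorizations:
    def cat_with_cbb(self, bits, M=4):
        # one binder whose active bits are exactly the wanted CBB
        row = "".join("1" if i in bits else "0" for i in range(M))
        return categorize_bits(*make_labelled([row], []))

    def test_seven_region_partition(self):
        a = self.cat_with_cbb({0, 1})
        b = self.cat_with_cbb({1, 2})
        c = self.cat_with_cbb({1})
        venn = compare_categorizations(a, b, c)
        assert venn["abc"] == {1}
        assert venn["a_only"] == {0}
        assert venn["b_only"] == {2}
        assert venn["c_only"] == set()
        assert venn["ab"] == venn["ac"] == venn["bc"] == set()

    def test_identical_sets_all_triple(self):
        a = self.cat_with_cbb({0, 3})
        venn = compare_categorizations(a, a, a)
        assert venn["abc"] == {0, 3}
        assert all(not venn[k] for k in venn if k != "abc")

    def test_disjoint_sets_all_exclusive(self):
        venn = compare_categorizations(
            self.cat_with_cbb({0}), self.cat_with_cbb({1}), self.cat_with_cbb({2})
        )
        assert venn["a_only"] == {0} and venn["b_only"] == {1} and venn["c_only"] == {2}
        assert not venn["abc"]

    def test_mismatched_length_raises(self):
        with pytest.raises(DataError):
            compare_categorizations(
                self.cat_with_cbb({0}, M=4),
                self.cat_with_cbb({0}, M=8),
                self.cat_with_cbb({0}, M=4),
            )


class TestFeaturePrevalence:
    def build(self, exemplars):
        fps, ds = make_labelled(["1" * len(exemplars)], [])
        cat = categorize_bits(fps, ds)
        return cat, dict(enumerate(exemplars))

    def test_all_exemplars_match(self):
        cat, prov = self.build(["CCO", "CCCO"])
        assert feature_prevalence_in_bits(cat, prov, "[OX2H]") == 1.0

    def test_none_match(self):
        cat, prov = self.build(["CC", "CCC"])
        assert feature_prevalence_in_bits(cat, prov, "[OX2H]") == 0.0

    def test_nine_of_ten(self):
        cat, prov = self.build(["CCO"] * 9 + ["CC"])
        assert feature_prevalence_in_bits(cat, prov, "[OX2H]") == pytest.approx(0.9)

    def test_missing_provenance_listed(self):
        cat, prov = self.build(["CCO", "CCO"])
        del prov[1]
        with pytest.raises(DataError, match="1"):
            feature_prevalence_in_bits(cat, prov, "[OX2H]")


class TestSerialisation:
    def test_json_round_trip(self, tmp_path):
        fps, ds = make_labelled(["1010", "1011"], ["0101"])
        cat = categorize_bits(fps, ds)
        path = tmp_path / "model.json"
        to_json(cat, path)
        loaded = from_json(path)
        assert loaded.cbb == cat.cbb and loaded.cnb == cat.cnb
        assert loaded.ucb == cat.ucb and loaded.usb == cat.usb
        assert loaded.params == cat.params
        assert np.array_equal(loaded.binder_counts, cat.binder_counts)
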