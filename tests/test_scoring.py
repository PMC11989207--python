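"""Immunoscore and NAR score arithmetic, categories, and invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from larcscore.scoring import (categorize_nar, combined_stratum, immunoscore,
                               nar_pathologic, nar_radiologic,
                               percentile_ranks)

STAGE_DOMAIN = list(itertools.product(range(5), range(5), range(3)))


class TestPercentileRanks:
    def test_hazen_positions_without_ties(self):
        assert percentile_ranks([10, 20, 30, 40]) == [12.5, 37.5, 62.5, 87.5]

    def test_ties_take_mid_rank(self):
        assert percentile_ranks([5, 5]) == [50.0, 50.0]

    def test_single_value_is_its_own_median(self):
        assert percentile_ranks([7]) == [50.0]

    def test_output_order_matches_input_order(self):
        assert percentile_ranks([30, 10, 20]) == pytest.approx(
            [250 / 3, 50 / 3, 50.0])

    @pytest.mark.parametrize("bad", [[], [-1.0, 2.0], [float("nan")]])
    def test_rejects_empty_negative_or_nonfinite(self, bad):
        with pytest.raises(ValueError):
            percentile_ranks(bad)

    @given(st.lists(st.floats(0.01, 1e4), min_size=1, max_size=30),
           st.floats(0.1, 10.0), st.floats(0.0, 100.0))
    def test_invariant_under_positive_affine_transform(self, xs, a, b):
        base = percentile_ranks(xs)
        scaled = percentile_ranks([a * x + b for x in xs])
        assert scaled == pytest.approx(base)


class TestImmunoscore:
    @pytest.mark.parametrize("ps,mean,cls", [
        ((80, 70, 60, 62), 68.0, "high"),
        ((0, 0, 0, 0), 0.0, "low"),
        ((62, 62, 62, 62), 62.0, "high"),  # boundary is classed high
    ])
    def test_mean_and_class(self, ps, mean, cls):
        res = immunoscore(*ps)
        assert res.mean_percentile == pytest.approx(mean, abs=1e-9)
        assert res.is_class == cls

    def test_rejects_out_of_range_percentile(self):
        with pytest.raises(ValueError):
            immunoscore(101, 0, 0, 0)

    @given(ps=st.tuples(*[st.floats(0, 100)] * 4))
    def test_mean_invariant_under_permutation(self, ps):
        base = immunoscore(*ps).mean_percentile
        for perm in itertools.permutations(ps):
            assert immunoscore(*perm).mean_percentile == pytest.approx(base)

    @given(ps=st.tuples(*[st.floats(0, 99)] * 4), i=st.integers(0, 3),
           delta=st.floats(0.1, 1.0))
    def test_mean_monotone_in_each_argument(self, ps, i, delta):
        bumped = list(ps)
        bumped[i] = min(100.0, bumped[i] + delta)
        assert immunoscore(*bumped).mean_percentile >= \
            immunoscore(*ps).mean_percentile


class TestNarScore:
    @pytest.mark.parametrize("ct,ypt,ypn,value,cat", [
        (4, 0, 0, 0.0, "low"),
        (3, 0, 0, 9 / 9.61, "low"),
        (3, 3, 1, 289 / 9.61, "high"),
        (3, 2, 0, 81 / 9.61, "intermediate"),
    ])
    def test_pathologic_examples(self, ct, ypt, ypn, value, cat):
        res = nar_pathologic(ct, ypt, ypn)
        assert res.value == pytest.approx(value)
        assert res.category == cat
        assert res.variant == "pathologic"

    @pytest.mark.parametrize("ct_pre,ct_post,cn_post,value,cat", [
        (4, 0, 0, 0.0, "low"),
        (3, 0, 0, 9 / 9.61, "low"),
        (2, 2, 2, 484 / 9.61, "high"),
    ])
    def test_radiologic_examples(self, ct_pre, ct_post, cn_post, value, cat):
        res = nar_radiologic(ct_pre, ct_post, cn_post)
        assert res.value == pytest.approx(value)
        assert res.category == cat
        assert res.variant == "radiologic"

    @pytest.mark.parametrize("args", [(5, 0, 0), (3, -1, 0), (3, 0, 3)])
    def test_rejects_stage_out_of_encoded_range(self, args):
        with pytest.raises(ValueError):
            nar_pathologic(*args)

    def test_attainable_values_never_hit_category_boundaries(self):
        attainable = {round(k * k / 9.61, 9) for k in range(35)}
        for ct, ypt, ypn in STAGE_DOMAIN:
            v = nar_pathologic(ct, ypt, ypn).value
            assert round(v, 9) in attainable
            assert v != 8.0 and v != 16.0

    def test_pcr_patients_are_always_low_category(self):
        # ypT0/ypN0 with trial-eligible baseline cT gives NAR <= 36/9.61
        for ct in (2, 3, 4):
            res = nar_pathologic(ct, 0, 0)
            assert res.value <= 36 / 9.61 + 1e-9
            assert res.category == "low"

    def test_monotone_in_each_stage_over_the_domain(self):
        for ct, ypt, ypn in STAGE_DOMAIN:
            v = nar_pathologic(ct, ypt, ypn).value
            if ypn < 2:
                assert nar_pathologic(ct, ypt, ypn + 1).value >= v
            if ypt < 4:
                assert nar_pathologic(ct, ypt + 1, ypn).value >= v
            if ct < 4:
                assert nar_pathologic(ct + 1, ypt, ypn).value <= v


class TestCategorizeNar:
    @pytest.mark.parametrize("value,cat", [
        (0.937, "low"), (8.429, "intermediate"), (30.073, "high"),
        (7.999, "low"), (8.0, "intermediate"), (16.0, "intermediate"),
        (16.001, "high"),
    ])
    def test_thresholds(self, value, cat):
        assert categorize_nar(value) == cat

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            categorize_nar(-0.1)


class TestCombinedStratum:
    @pytest.mark.parametrize("cls,trg,expected", [
        ("high", 1, "is_high_and_trg1"),
        ("high", 2, "other"),
        ("low", 1, "other"),
        (None, 1, None),
        ("high", None, None),
    ])
    def test_stratum(self, cls, trg, expected):
        assert combined_stratum(cls, trg) == expected
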