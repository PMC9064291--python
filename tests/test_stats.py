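import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from centriomig.compartments import GroupCountRecord
from centriomig.stats import (
    fold_change,
    pair_records,
    paired_permutation_test,
    sem_from_sd,
    summarize,
    traversal_time,
)


class TestSummarize:
    @pytest.mark.parametrize(
        "sd,n,sem,digits",
        [
            (9.992, 20, 2.234, 3),
            (8.156, 24, 1.665, 3),
            (7.126, 24, 1.455, 3),
            (12.10, 24, 2.47, 2),
            (2.76, 12, 0.80, 2),
        ],
    )
    def test_sem_from_reported_sd(self, sd, n, sem, digits):
        assert round(sem_from_sd(sd, n), digits) == sem

    def test_constant_sample(self):
        s = summarize([5, 5, 5, 5])
        assert (s.mean, s.sd, s.sem) == (5.0, 0.0, 0.0)

    def test_single_value_flagged(self):
        s = summarize([3.2])
        assert not s.defined and math.isnan(s.sd) and math.isnan(s.sem)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])

    def test_sem_sd_relation(self, rng):
        v = rng.normal(size=17)
        s = summarize(v)
        assert s.sem * math.sqrt(s.n) == pytest.approx(s.sd, abs=1e-9)

    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=30),
        st.floats(-100, 100),
        st.floats(0.1, 10),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_location_scale_equivariance(self, values, shift, scale):
        base = summarize(values)
        moved = summarize([scale * v + shift for v in values])
        assert moved.mean == pytest.approx(scale * base.mean + shift, abs=1e-6 * scale + 1e-6)
        assert moved.sd == pytest.approx(scale * base.sd, rel=1e-9, abs=1e-6)


def brute_force_p(pairs, alternative="two-sided"):
    d = np.array([a - b for a, b in pairs])
    t_obs = d.mean()
    hits = total = 0
    for signs in itertools.product([-1, 1], repeat=len(d)):
        t = (d * signs).mean()
        total += 1
        if alternative == "two-sided":
            hits += abs(t) >= abs(t_obs) - 1e-12
        else:
            hits += t >= t_obs - 1e-12
    return hits / total


class TestPairedPermutation:
    def test_degenerate_null(self):
        res = paired_permutation_test([(2.0, 2.0)] * 5)
        assert res.observed_stat == 0.0 and res.p_value == 1.0

    def test_exact_mode_matches_brute_force(self, rng):
        for n in (2, 4, 7, 10):
            pairs = list(zip(rng.normal(1, 1, n), rng.normal(0, 1, n)))
            res = paired_permutation_test(pairs, n_resamples=10_000)
            assert res.exact == (2**n <= 10_000)
            if res.exact:
                assert res.p_value == pytest.approx(brute_force_p(pairs), abs=1e-12)

    def test_exact_p_values_are_multiples_of_tail_unit(self, rng):
        n = 6
        pairs = list(zip(rng.normal(1, 1, n), rng.normal(0, 1, n)))
        res = paired_permutation_test(pairs)
        assert (res.p_value * 2**n) == pytest.approx(round(res.p_value * 2**n), abs=1e-9)

    def test_invariant_under_global_sign_flip(self, rng):
        pairs = list(zip(rng.normal(1, 1, 6), rng.normal(0, 1, 6)))
        flipped = [(b, a) for a, b in pairs]
        p1 = paired_permutation_test(pairs).p_value
        p2 = paired_permutation_test(flipped).p_value
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_monte_carlo_converges_to_exact(self, rng):
        pairs = list(zip(rng.normal(0.8, 1, 10), rng.normal(0, 1, 10)))
        exact = paired_permutation_test(pairs, n_resamples=2**10).p_value
        for b in (1_000, 10_000, 100_000):
            mc = paired_permutation_test(pairs, n_resamples=b, seed=5, alternative="two-sided")
            if not mc.exact:
                assert abs(mc.p_value - exact) < 4 / math.sqrt(b) + 0.01
        # force Monte-Carlo with a tighter budget than 2^10
        mc = paired_permutation_test(pairs, n_resamples=1000, seed=5)
        assert not mc.exact
        assert mc.p_value >= 1 / 1001  # add-one correction: never zero

    def test_deterministic_under_seed(self, rng):
        pairs = list(zip(rng.normal(1, 1, 14), rng.normal(0, 1, 14)))
        p1 = paired_permutation_test(pairs, n_resamples=2000, seed=3).p_value
        p2 = paired_permutation_test(pairs, n_resamples=2000, seed=3).p_value
        assert p1 == p2

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            paired_permutation_test([(1.0, float("nan")), (2.0, 1.0)])

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            paired_permutation_test([(1.0, 2.0)])


class TestPairRecords:
    def make(self, animal, condition, compartment, count, length=1000.0, tp="1hr"):
        return GroupCountRecord(animal, condition, tp, compartment, count, length)

    def test_pivot(self):
        records = [
            self.make("A1", "control", "subapical", 20),
            self.make("A1", "drug", "subapical", 50),
            self.make("A1", "control", "middle_basal", 10),
            self.make("A1", "drug", "middle_basal", 12),
        ]
        pairs = pair_records(records)
        assert len(pairs) == 2
        diffs = sorted(d - c for d, c in pairs)
        assert diffs == pytest.approx([0.2, 3.0])

    def test_unpaired_category_rejected(self):
        records = [self.make("A1", "control", "subapical", 20)]
        with pytest.raises(ValueError):
            pair_records(records)


class TestFoldChange:
    def test_printed_ratio(self):
        drug = GroupCountRecord("A1", "drug", "6hr", "subapical", 516, 10000.0)
        ctrl = GroupCountRecord("A1", "control", "6hr", "subapical", 200, 10000.0)
        assert fold_change(drug, ctrl) == pytest.approx(2.58)

    def test_equal_densities(self):
        a = GroupCountRecord("A1", "drug", "6hr", "subapical", 10, 500.0)
        b = GroupCountRecord("A1", "control", "6hr", "subapical", 10, 500.0)
        assert fold_change(a, b) == 1.0

    def test_zero_control_undefined(self):
        a = GroupCountRecord("A1", "drug", "6hr", "subapical", 10, 500.0)
        b = GroupCountRecord("A1", "control", "6hr", "subapical", 0, 500.0)
        with pytest.raises(ZeroDivisionError):
            fold_change(a, b)

    def test_mismatched_categories(self):
        a = GroupCountRecord("A1", "drug", "6hr", "subapical", 10, 500.0)
        b = GroupCountRecord("A1", "control", "1hr", "subapical", 5, 500.0)
        with pytest.raises(ValueError):
            fold_change(a, b)


class TestTraversalTime:
    def test_reported_bound(self):
        assert traversal_time(100.0, 0.18) == 9.26

    def test_zero_distance(self):
        assert traversal_time(0.0, 0.18) == 0.0

    def test_nematode_rate(self):
        assert traversal_time(5.0, 0.076) == 1.10

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            traversal_time(10.0, 0.0)
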