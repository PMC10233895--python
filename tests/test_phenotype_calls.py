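"""LPI computation, BH FDR, and the dual-criterion phenotype caller."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from colonyscreen import (
    CallConfig,
    InvalidParameterError,
    LPIRecord,
    MissingDataError,
    bh_fdr,
    call_phenotypes,
    compute_lpi,
    exclude_slow_growers,
)


def bh_oracle(p):
    """Direct step-up definition: q_i = min over p_(j) >= p_i of p_(j)*m/rank(j)."""
    m = len(p)
    ps = sorted(p)
    q = []
    for pi in p:
        candidates = [ps[j] * m / (j + 1) for j in range(m) if ps[j] >= pi - 1e-15]
        q.append(min(1.0, min(candidates)))
    return q


class TestExcludeSlowGrowers:
    def test_infinite_cutoff_excludes_nobody(self):
        assert exclude_slow_growers({"a": 5.0, "b": 100.0}, math.inf) == set()

    def test_direct_threshold(self):
        assert exclude_slow_growers({"a": 0.1, "b": 2.0}, 1.5) == {"b"}

    def test_simulated_exclusion_fraction(self):
        """Strains planted above the cutoff are excluded at the planted rate."""
        rng = np.random.default_rng(8)
        means = {f"s{i}": float(rng.normal(0, 0.1)) for i in range(933)}
        slow = {f"slow{i}": float(rng.normal(2.5, 0.3)) for i in range(67)}
        excluded = exclude_slow_growers({**means, **slow}, 1.5)
        assert excluded == set(slow)
        assert len(excluded) / 1000 == pytest.approx(0.067, abs=0.001)


class TestComputeLPI:
    def test_arithmetic_of_means(self):
        reps, mean = compute_lpi([2.0, 2.2, 2.4], [0.1, 0.0, -0.1])
        assert mean == pytest.approx(2.2)
        assert reps == pytest.approx([2.0, 2.2, 2.4])

    def test_identical_inputs_give_zero(self):
        _, mean = compute_lpi([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert mean == 0.0

    def test_antisymmetry(self):
        a, b = [0.5, 0.7, 0.9], [0.1, 0.2, 0.3]
        _, m1 = compute_lpi(a, b)
        _, m2 = compute_lpi(b, a)
        assert m1 == pytest.approx(-m2)

    def test_insufficient_replicates(self):
        with pytest.raises(MissingDataError):
            compute_lpi([1.0], [0.0, 0.0])
        with pytest.raises(MissingDataError):
            compute_lpi([1.0, 2.0], [])

    def test_nan_replicates_dropped(self):
        reps, mean = compute_lpi([2.0, np.nan, 2.4], [0.0, np.nan])
        assert len(reps) == 2
        assert mean == pytest.approx(2.2)


class TestBHFDR:
    def test_single_p(self):
        q, rej = bh_fdr([0.005], alpha=0.01)
        assert q[0] == pytest.approx(0.005)
        assert rej[0]

    def test_worked_example(self):
        q, rej = bh_fdr([0.001, 0.008, 0.039, 0.041], alpha=0.05)
        assert q == pytest.approx([0.004, 0.016, 0.041, 0.041])
        assert rej.all()

    def test_all_ones_rejects_none(self):
        q, rej = bh_fdr([1.0, 1.0, 1.0], alpha=0.05)
        assert not rej.any()
        assert np.allclose(q, 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(InvalidParameterError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(InvalidParameterError):
            bh_fdr([-0.1])

    @given(
        p=st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=8
        )
    )
    def test_matches_direct_definition(self, p):
        q, _ = bh_fdr(p)
        assert q == pytest.approx(bh_oracle(p), abs=1e-12)

    def test_q_monotone_in_p_order(self, rng):
        p = rng.random(50)
        q, _ = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestCallPhenotypes:
    def test_zero_replicates_called_none(self):
        rec = LPIRecord("a", "metal", [0.0, 0.0, 0.0], 0.0)
        call_phenotypes([rec])
        assert rec.call == "none"
        assert rec.p_value == 1.0

    def test_strong_effect_called_sensitive(self):
        """t and p match the closed-form t CDF with 2 degrees of freedom."""
        rec = LPIRecord("a", "metal", [2.8, 3.0, 3.2], 3.0)
        call_phenotypes([rec], CallConfig(alpha=0.01, effect_threshold=2.5))
        t_expected = 3.0 / (0.2 / math.sqrt(3))
        # two-sided p for df=2: 1 - t/sqrt(t^2 + 2)
        p_expected = 1.0 - t_expected / math.sqrt(t_expected ** 2 + 2.0)
        assert rec.t_stat == pytest.approx(t_expected, rel=1e-9)
        assert rec.p_value == pytest.approx(p_expected, rel=1e-9)
        assert rec.p_value < 0.01
        assert rec.call == "sensitive"

    def test_effect_gate_blocks_small_significant_effects(self):
        rec = LPIRecord("a", "metal", [2.0, 2.0, 2.0], 2.0)
        call_phenotypes([rec])
        assert rec.p_value == 0.0  # zero-variance, nonzero mean convention
        assert rec.call == "none"  # mean 2.0 < 2.5 threshold

    def test_resistant_symmetric(self):
        rec = LPIRecord("a", "metal", [-2.8, -3.0, -3.2], -3.0)
        call_phenotypes([rec])
        assert rec.call == "resistant"

    def test_resistance_disabled(self):
        rec = LPIRecord("a", "metal", [-2.8, -3.0, -3.2], -3.0)
        call_phenotypes([rec], CallConfig(symmetric_resistance=False))
        assert rec.call == "none"

    def test_excluded_records_skipped(self):
        rec = LPIRecord("a", "metal", [], math.nan, call="excluded")
        call_phenotypes([rec])
        assert rec.call == "excluded"
        assert math.isnan(rec.q_value)

    def test_calls_invariant_under_strain_order(self, rng):
        def build():
            recs = []
            for i in range(40):
                vals = list(rng2.normal(0.0, 0.1, 3) + (3.0 if i < 5 else 0.0))
                recs.append(LPIRecord(f"s{i}", "metal", vals, float(np.mean(vals))))
            return recs

        rng2 = np.random.default_rng(4)
        recs = build()
        shuffled = list(recs)
        rng.shuffle(shuffled)
        call_phenotypes(shuffled)
        calls = {r.strain_id: r.call for r in recs}
        rng2 = np.random.default_rng(4)
        fresh = build()
        call_phenotypes(fresh)
        assert calls == {r.strain_id: r.call for r in fresh}

    def test_bh_applied_per_condition(self):
        """Identical p-values get identical q within, not across, conditions."""
        r1 = [LPIRecord(f"s{i}", "metalA", [3.0, 3.1, 2.9], 3.0) for i in range(3)]
        r2 = [LPIRecord("x", "metalB", [0.0, 0.05, -0.05], 0.0)]
        call_phenotypes(r1 + r2)
        assert all(r.call == "sensitive" for r in r1)
        assert r2[0].call == "none"
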