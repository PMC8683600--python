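"""Relative proportional mass, BCa bootstrap and the mass-to-individuals chain."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from scaletrace.mni_core import (
    ConversionFactor,
    MniEstimate,
    PrmEstimate,
    SackSample,
    aggregate_mni,
    bca_bootstrap,
    composition_shares,
    estimate_group_mass,
    estimate_mni,
    estimate_prm,
    mni_report,
    prm_matrix,
    relative_proportional_mass,
    smutsia_cf,
)
from scaletrace.synthetic_data import SackSimConfig, generate_sacks


def _sack(wb=0.0, bb=0.0, sm=0.0, unid=0.0, sack_id="S1"):
    total = wb + bb + sm + unid
    return SackSample(
        sack_id=sack_id,
        total_sampled_mass=total * 1.1 + 0.1,
        sorted_masses={
            "white_bellied": wb,
            "black_bellied": bb,
            "smutsia": sm,
            "unidentified": unid,
        },
    )


class TestRelativeProportionalMass:
    def test_single_species_sack(self):
        assert relative_proportional_mass(_sack(wb=10.0))["white_bellied"] == 1.0

    def test_hand_computed_ratio(self):
        prm = relative_proportional_mass(_sack(wb=3.0, bb=1.0))
        assert prm["white_bellied"] == pytest.approx(0.75)
        assert prm["black_bellied"] == pytest.approx(0.25)

    def test_unidentified_in_denominator(self):
        prm = relative_proportional_mass(_sack(wb=9.0, unid=1.0))
        assert prm["white_bellied"] == pytest.approx(0.9)
        assert prm["unidentified"] == pytest.approx(0.1)

    def test_all_zero_sack_rejected(self):
        with pytest.raises(ValueError, match="no sorted mass"):
            relative_proportional_mass(_sack())

    def test_rows_sum_to_one_on_generated_sacks(self):
        sacks = generate_sacks(SackSimConfig(), seed=5)
        matrix = prm_matrix(sacks)
        assert np.allclose(matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_sorted_mass_cannot_exceed_sampled(self):
        with pytest.raises(ValueError, match="exceed"):
            SackSample("S1", total_sampled_mass=1.0, sorted_masses={"white_bellied": 2.0})


def _bca_oracle(values, n_boot, seed, alpha=0.05):
    """Straight-line BCa written independently from the implementation.

    Shares the resampling stream (same generator construction) so that the
    z0/acceleration/percentile arithmetic can be compared to 1e-9.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = np.array([x[row].mean() for row in idx])
    theta = x.mean()
    prop = sum(1 for b in boot if b < theta) / n_boot
    prop = min(max(prop, 0.5 / n_boot), 1.0 - 0.5 / n_boot)
    z0 = norm.ppf(prop)
    jack = np.array([np.delete(x, i).mean() for i in range(n)])
    d = jack.mean() - jack
    a = np.sum(d**3) / (6.0 * np.sum(d**2) ** 1.5)
    lo_level = norm.cdf(z0 + (z0 + norm.ppf(alpha / 2)) / (1 - a * (z0 + norm.ppf(alpha / 2))))
    hi_level = norm.cdf(z0 + (z0 + norm.ppf(1 - alpha / 2)) / (1 - a * (z0 + norm.ppf(1 - alpha / 2))))
    return theta, float(np.quantile(boot, lo_level)), float(np.quantile(boot, hi_level))


class TestBcaBootstrap:
    def test_constant_sample_degenerates_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert bca_bootstrap([0.5] * 10, seed=0) == (0.5, 0.5, 0.5)

    @pytest.mark.parametrize("seed", [1, 7, 23])
    def test_matches_independent_straight_line_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.beta(2.0, 5.0, size=10)
        got = bca_bootstrap(values, n_boot=1000, seed=seed + 100)
        expected = _bca_oracle(values, n_boot=1000, seed=seed + 100)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_symmetric_data_close_to_percentile_interval(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0.5, 0.05, size=200)
        _, lo, hi = bca_bootstrap(values, n_boot=4000, seed=11)
        rng2 = np.random.default_rng(11)
        idx = rng2.integers(0, len(values), size=(4000, len(values)))
        boot = values[idx].mean(axis=1)
        plo, phi = np.quantile(boot, [0.025, 0.975])
        # symmetric data: z0 ~ 0, a ~ 0, so BCa ~ plain percentile interval
        assert lo == pytest.approx(plo, abs=2e-3)
        assert hi == pytest.approx(phi, abs=2e-3)

    def test_cross_check_against_scipy_bca(self):
        from scipy.stats import bootstrap as scipy_bootstrap

        rng = np.random.default_rng(17)
        values = rng.beta(2.0, 5.0, size=40)
        _, lo, hi = bca_bootstrap(values, n_boot=6000, seed=1)
        res = scipy_bootstrap(
            (values,),
            np.mean,
            method="BCa",
            n_resamples=6000,
            confidence_level=0.95,
            random_state=np.random.default_rng(2),
        )
        assert lo == pytest.approx(res.confidence_interval.low, abs=0.01)
        assert hi == pytest.approx(res.confidence_interval.high, abs=0.01)

    def test_deterministic_given_seed_and_stable_across_seeds(self):
        values = np.random.default_rng(0).beta(2.0, 5.0, size=67)
        first = bca_bootstrap(values, n_boot=10_000, seed=5)
        second = bca_bootstrap(values, n_boot=10_000, seed=5)
        other = bca_bootstrap(values, n_boot=10_000, seed=6)
        assert first == second
        assert abs(first[1] - other[1]) < 0.01
        assert abs(first[2] - other[2]) < 0.01

    def test_input_validation(self):
        with pytest.raises(ValueError):
            bca_bootstrap([0.5], seed=0)
        with pytest.raises(ValueError):
            bca_bootstrap([0.1, 0.2, 0.3], n_boot=50, seed=0)


class TestMassAndMniChain:
    def test_group_mass_scales_prm(self):
        prm = PrmEstimate("white_bellied", [0.5, 0.5, 0.4, 0.6], 0.5, 0.4, 0.6, 1000)
        assert estimate_group_mass(prm, 100.0) == pytest.approx((50.0, 40.0, 60.0))
        with pytest.raises(ValueError):
            estimate_group_mass(prm, 0.0)

    @given(
        k=st.floats(min_value=0.01, max_value=1e4),
        mean=st.floats(min_value=0.01, max_value=0.99),
    )
    @settings(max_examples=50, deadline=None)
    def test_mni_linear_in_mcs_and_inverse_in_cf(self, k, mean):
        prm = PrmEstimate("white_bellied", [mean], mean, mean * 0.9, min(mean * 1.1, 1.0), 1000)
        cf = ConversionFactor("white_bellied", 0.18)
        base = estimate_mni(estimate_group_mass(prm, 1000.0), cf)
        scaled = estimate_mni(estimate_group_mass(prm, 1000.0 * k), cf)
        assert scaled == pytest.approx(tuple(b * k for b in base), rel=1e-9)
        cf_k = ConversionFactor("white_bellied", 0.18 * k)
        divided = estimate_mni(estimate_group_mass(prm, 1000.0), cf_k)
        assert divided == pytest.approx(tuple(b / k for b in base), rel=1e-9)

    def test_simple_conversion(self):
        cf = ConversionFactor("white_bellied", 1.0)
        assert estimate_mni((5.0, 4.0, 6.0), cf) == pytest.approx((5.0, 4.0, 6.0))
        assert estimate_mni((0.0, 0.0, 0.0), cf) == (0.0, 0.0, 0.0)

    def test_smutsia_cf_is_arithmetic_mean(self):
        assert smutsia_cf(2.0, 4.0).cf == pytest.approx(3.0)
        assert smutsia_cf(1.7, 1.7).cf == pytest.approx(1.7)
        with pytest.raises(ValueError):
            smutsia_cf(-1.0, 2.0)

    def test_aggregate_single_group_is_total(self):
        est = MniEstimate("white_bellied", 100.0, (50.0, 40.0, 60.0), (5.0, 4.0, 6.0))
        totals, [annotated] = aggregate_mni([est])
        assert totals == pytest.approx((5.0, 4.0, 6.0))
        assert annotated.pct_of_total_mni == pytest.approx(100.0)

    def test_group_bounds_sum_to_totals(self):
        ests = [
            MniEstimate("white_bellied", 1.0, (1.0, 0.5, 2.0), (10.0, 5.0, 20.0)),
            MniEstimate("black_bellied", 1.0, (2.0, 1.0, 3.0), (4.0, 2.0, 6.0)),
        ]
        totals, _ = aggregate_mni(ests)
        assert totals == pytest.approx((14.0, 7.0, 26.0))


class TestMniReport:
    def test_total_row_sums_groups(self):
        sacks = generate_sacks(SackSimConfig(), seed=9)
        cfs = {
            "white_bellied": ConversionFactor("white_bellied", 0.18),
            "black_bellied": ConversionFactor("black_bellied", 0.20),
            "smutsia": smutsia_cf(2.6, 3.3),
        }
        report = mni_report(sacks, cfs, m_cs=190_404.0, n_boot=500, seed=2)
        groups = report[report["group"] != "total"]
        total = report[report["group"] == "total"].iloc[0]
        for col in ("est_mass_kg", "est_mass_low_kg", "est_mass_high_kg"):
            assert total[col] == pytest.approx(groups[col].sum())
        assert groups["pct_of_mni"].sum() == pytest.approx(100.0)

    def test_joint_resampling_mode_runs(self):
        sacks = generate_sacks(SackSimConfig(n_sacks=30), seed=4)
        cfs = {"white_bellied": ConversionFactor("white_bellied", 0.18)}
        report = mni_report(sacks, cfs, m_cs=1000.0, n_boot=400, seed=3, joint=True)
        row = report.iloc[0]
        assert row["est_mass_low_kg"] <= row["est_mass_kg"] <= row["est_mass_high_kg"]

    def test_deterministic_given_seed(self):
        sacks = generate_sacks(SackSimConfig(n_sacks=30), seed=4)
        cfs = {"white_bellied": ConversionFactor("white_bellied", 0.18)}
        a = mni_report(sacks, cfs, m_cs=1000.0, n_boot=400, seed=3)
        b = mni_report(sacks, cfs, m_cs=1000.0, n_boot=400, seed=3)
        assert a.equals(b)


class TestCompositionShares:
    def test_explicit_denominator(self):
        shares = composition_shares({"white_bellied": 50.0, "black_bellied": 30.0}, denominator=100.0)
        assert shares == pytest.approx({"white_bellied": 50.0, "black_bellied": 30.0})

    def test_default_denominator_sums_to_100(self):
        shares = composition_shares({"a_dummy": 0.0, "white_bellied": 3.0, "black_bellied": 1.0})
        assert sum(shares.values()) == pytest.approx(100.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            composition_shares({"white_bellied": 0.0})
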