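"""Rank tests and log10-mass model selection, checked against brute-force oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.stats import norm, rankdata

from scaletrace.seizure_io import PartialDate, SeizureRecord
from scaletrace.trade_statistics import (
    compare_models,
    dunn_posthoc,
    fit_mass_model,
    kruskal_wallis,
)


def _kw_oracle(groups):
    """Direct rank-sum formula with tie correction (independent of scipy)."""
    labels = list(groups)
    pooled = np.concatenate([np.asarray(groups[k], float) for k in labels])
    N = len(pooled)
    ranks = rankdata(pooled)
    start, H = 0, 0.0
    for k in labels:
        n_k = len(groups[k])
        r = ranks[start : start + n_k]
        H += r.sum() ** 2 / n_k
        start += n_k
    H = 12.0 / (N * (N + 1)) * H - 3.0 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (N**3 - N)
    return H / correction


def _dunn_oracle(groups, a, b):
    labels = list(groups)
    pooled = np.concatenate([np.asarray(groups[k], float) for k in labels])
    N = len(pooled)
    ranks = rankdata(pooled)
    means, start = {}, 0
    for k in labels:
        n_k = len(groups[k])
        means[k] = ranks[start : start + n_k].mean()
        start += n_k
    _, counts = np.unique(pooled, return_counts=True)
    ties = float(np.sum(counts**3 - counts))
    var = (N * (N + 1) / 12.0 - ties / (12.0 * (N - 1))) * (
        1.0 / len(groups[a]) + 1.0 / len(groups[b])
    )
    z = (means[a] - means[b]) / math.sqrt(var)
    return z, 2.0 * norm.sf(abs(z))


class TestKruskalWallis:
    def test_matches_rank_sum_oracle(self):
        groups = {"a": [1.0, 2.0], "b": [3.0, 4.0], "c": [5.0, 6.0]}
        res = kruskal_wallis(groups)
        assert res.H == pytest.approx(_kw_oracle(groups), abs=1e-12)
        assert res.df == 2 and res.n == 6

    def test_ties_handled_like_oracle(self):
        groups = {"a": [1.0, 2.0, 2.0], "b": [2.0, 3.0], "c": [3.0, 5.0, 5.0]}
        res = kruskal_wallis(groups)
        assert res.H == pytest.approx(_kw_oracle(groups), abs=1e-12)

    def test_all_equal_gives_zero(self):
        res = kruskal_wallis({"a": [2.0, 2.0], "b": [2.0, 2.0, 2.0]})
        assert res.H == 0.0 and res.p_value == 1.0

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis({"a": [1.0, 2.0], "b": []})

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        groups = {k: rng.lognormal(3, 1, size=9).tolist() for k in "abc"}
        base = kruskal_wallis(groups).H
        cubed = {k: [v**3 for v in vs] for k, vs in groups.items()}
        assert kruskal_wallis(cubed).H == pytest.approx(base, abs=1e-12)


class TestDunn:
    def test_identical_groups_give_zero(self):
        pairs = dunn_posthoc({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        (_, _, z, p) = pairs[0]
        assert z == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_matches_formula_oracle(self):
        groups = {"a": [1.0, 4.0, 7.0], "b": [2.0, 2.0, 9.0, 11.0], "c": [5.0, 6.0]}
        pairs = {(a, b): (z, p) for a, b, z, p in dunn_posthoc(groups)}
        for a, b in pairs:
            z_exp, p_exp = _dunn_oracle(groups, a, b)
            assert pairs[(a, b)][0] == pytest.approx(z_exp, abs=1e-12)
            assert pairs[(a, b)][1] == pytest.approx(p_exp, abs=1e-12)

    def test_adjustment_never_decreases_p(self):
        groups = {"a": [1.0, 2.0], "b": [5.0, 6.0], "c": [9.0, 10.0]}
        raw = {(a, b): p for a, b, _, p in dunn_posthoc(groups)}
        holm = {(a, b): p for a, b, _, p in dunn_posthoc(groups, adjust="holm")}
        assert all(holm[k] >= raw[k] - 1e-15 for k in raw)


def _records_from_frame(rows):
    out = []
    for i, (year, mode, mass) in enumerate(rows):
        out.append(
            SeizureRecord(
                record_id=f"M{i}",
                seizure_date=PartialDate(year, 6, 1),
                masses={"scales": mass},
                route=["NGA", "CHN"],
                seizure_country="NGA",
                mode=mode,
            )
        )
    return out


class TestMassModel:
    def test_exact_linear_trend_recovered(self):
        rows = [(y, "air", 10.0 ** (2.0 + 0.1 * (y - 2010))) for y in range(2010, 2021)]
        fit = fit_mass_model(_records_from_frame(rows), formula="log10_mass ~ year")
        est_intercept, _, _ = fit.coefficients["Intercept"]
        est_slope, _, _ = fit.coefficients["year"]
        assert est_slope == pytest.approx(0.1, abs=1e-10)
        assert est_intercept + 2010 * est_slope == pytest.approx(2.0, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_response_gives_zero_slopes(self):
        rows = [(y, m, 100.0) for y in range(2010, 2021) for m in ("air", "sea")]
        fit = fit_mass_model(_records_from_frame(rows), formula="log10_mass ~ year + C(mode)")
        assert fit.coefficients["year"][0] == pytest.approx(0.0, abs=1e-10)
        assert fit.r_squared == 0.0

    def test_ols_matches_normal_equations(self):
        rng = np.random.default_rng(9)
        rows = [
            (int(y), m, float(10.0 ** rng.normal(2.5, 0.3)))
            for y in rng.integers(2010, 2021, size=40)
            for m in ("air",)
        ]
        records = _records_from_frame(rows)
        fit = fit_mass_model(records, formula="log10_mass ~ year")
        years = np.array([r.year for r in records], float)
        X = np.column_stack([np.ones_like(years), years])
        y = np.log10([r.total_mass_kg for r in records])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.coefficients["Intercept"][0] == pytest.approx(beta[0], rel=1e-8)
        assert fit.coefficients["year"][0] == pytest.approx(beta[1], rel=1e-8)

    def test_rank_deficient_design_raises(self):
        rows = [(y, "air", float(100 + y)) for y in range(2010, 2021)]
        with pytest.raises(ValueError, match="collinear"):
            fit_mass_model(_records_from_frame(rows), formula="log10_mass ~ year + I(2*year)")

    def test_back_transform_returns_kg_scale(self):
        rows = [(y, "air", 10.0 ** (2.0 + 0.1 * (y - 2010))) for y in range(2010, 2021)]
        fit = fit_mass_model(_records_from_frame(rows), formula="log10_mass ~ year")
        import pandas as pd

        pred = fit.predict_mass_kg(pd.DataFrame({"year": [2010]}))
        assert pred[0] == pytest.approx(100.0, rel=1e-6)


class TestModelSelection:
    def test_interaction_model_selected_when_generating(self):
        rng = np.random.default_rng(2)
        rows = []
        for y in range(2010, 2021):
            for mode, trend in (("air", -0.08), ("sea", 0.20)):
                for _ in range(6):
                    mu = 2.5 + trend * (y - 2010)
                    rows.append((y, mode, float(10.0 ** rng.normal(mu, 0.2))))
        ranking = compare_models(_records_from_frame(rows))
        assert ranking[0][0] == "log10_mass ~ year * C(mode)"

    def test_equivalent_reparameterisations_tie(self):
        rng = np.random.default_rng(5)
        rows = [
            (int(y), "air", float(10.0 ** rng.normal(2.5, 0.3)))
            for y in rng.integers(2010, 2021, size=30)
        ]
        ranking = compare_models(
            _records_from_frame(rows),
            formulas=("log10_mass ~ year", "log10_mass ~ I(year - 2000)"),
        )
        assert ranking[0][1] == pytest.approx(ranking[1][1], abs=1e-8)
        assert ranking[0][2] == ranking[1][2]

    def test_useless_parameter_costs_about_two_aic_on_null_data(self):
        rng = np.random.default_rng(8)
        deltas = []
        for _ in range(120):
            rows = [
                (int(y), m, float(10.0 ** rng.normal(2.5, 0.3)))
                for y in rng.integers(2010, 2021, size=30)
                for m in ("air", "sea")
            ]
            ranked = dict(
                (f, v)
                for f, v, _ in compare_models(
                    _records_from_frame(rows),
                    formulas=("log10_mass ~ year", "log10_mass ~ year + C(mode)"),
                )
            )
            deltas.append(ranked["log10_mass ~ year + C(mode)"] - ranked["log10_mass ~ year"])
        # E[AIC penalty] = 2k - E[chi2_k] = 1 per useless parameter
        assert 0.2 < np.mean(deltas) < 1.8

    def test_aicc_penalises_more_than_aic(self):
        rng = np.random.default_rng(6)
        rows = [
            (int(y), m, float(10.0 ** rng.normal(2.5, 0.3)))
            for y in rng.integers(2010, 2021, size=15)
            for m in ("air", "sea")
        ]
        records = _records_from_frame(rows)
        aic = dict((f, v) for f, v, _ in compare_models(records))
        aicc = dict((f, v) for f, v, _ in compare_models(records, criterion="aicc"))
        assert all(aicc[f] > aic[f] for f in aic)
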