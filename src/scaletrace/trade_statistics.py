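"""Mass-trend statistics for curated seizure records.

Two analyses are provided:

* a Kruskal–Wallis rank test (with Dunn's tie-corrected post-hoc pairwise
  comparisons) of per-seizure mass across transport modes, and
* an ordinary-least-squares linear model of log10 seizure mass on shipment
  year, transport mode and (optionally) their interaction, with AIC-based
  selection among candidate formulas.

Masses span several orders of magnitude (tens of kg by air up to tens of
tonnes by sea), hence the rank test and the log10 response.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .seizure_io import SeizureRecord

__all__ = [
    "RankTestResult",
    "MassModelFit",
    "kruskal_wallis",
    "dunn_posthoc",
    "records_by_mode",
    "fit_mass_model",
    "compare_models",
]

MODEL_MODES = ("air", "land", "sea")


@dataclass
class RankTestResult:
    """Kruskal–Wallis H (chi-square distributed under H0) plus Dunn pairwise z tests."""

    H: float
    df: int
    n: int
    p_value: float
    pairwise: list[tuple[str, str, float, float]]


@dataclass
class MassModelFit:
    """OLS fit of log10 mass; ``coefficients`` maps term -> (estimate, se, p)."""

    formula: str
    coefficients: dict[str, tuple[float, float, float]]
    r_squared: float
    f_stat: tuple[float, float, float]
    aic: float
    nobs: int
    result: object  # underlying statsmodels result, for prediction/diagnostics

    def predict_mass_kg(self, frame: pd.DataFrame) -> np.ndarray:
        """Back-transform fitted log10 values to kg for visualisation."""
        return 10.0 ** np.asarray(self.result.predict(frame))


def _clean_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    cleaned = {k: np.asarray(v, dtype=float) for k, v in groups.items() if len(v) > 0}
    if len(cleaned) < 2:
        raise ValueError("need at least two non-empty groups")
    return cleaned


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> RankTestResult:
    """Kruskal–Wallis test on midranks with tie correction.

    ``groups`` maps a label (e.g. transport mode) to the observed masses.
    Returns the H statistic, its chi-square degrees of freedom (k-1), total n,
    the p-value, and Dunn post-hoc pairwise comparisons (unadjusted).
    """
    cleaned = _clean_groups(groups)
    samples = list(cleaned.values())
    n = int(sum(len(s) for s in samples))
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        H, p = 0.0, 1.0
    else:
        H, p = sps.kruskal(*samples)
    return RankTestResult(
        H=float(H),
        df=len(cleaned) - 1,
        n=n,
        p_value=float(p),
        pairwise=dunn_posthoc(cleaned),
    )


def dunn_posthoc(
    groups: Mapping[str, Sequence[float]], adjust: str | None = None
) -> list[tuple[str, str, float, float]]:
    """Dunn's pairwise z tests on pooled midranks with tie-corrected variance.

    For groups i, j with rank means R̄ and sizes n, the statistic is

        z = (R̄_i − R̄_j) / sqrt( [N(N+1)/12 − T/(12(N−1))] (1/n_i + 1/n_j) )

    where T = Σ(t³ − t) over tie groups of size t.  p-values are two-sided
    normal tail probabilities, unadjusted by default; ``adjust`` may be
    ``"bonferroni"`` or ``"holm"``.
    """
    cleaned = _clean_groups(groups)
    labels = list(cleaned)
    pooled = np.concatenate([cleaned[k] for k in labels])
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    rank_means: dict[str, float] = {}
    start = 0
    for k in labels:
        size = len(cleaned[k])
        rank_means[k] = float(ranks[start : start + size].mean())
        start += size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    variance_core = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))

    out: list[tuple[str, str, float, float]] = []
    pvals: list[float] = []
    for a_idx in range(len(labels)):
        for b_idx in range(a_idx + 1, len(labels)):
            a, b = labels[a_idx], labels[b_idx]
            na, nb = len(cleaned[a]), len(cleaned[b])
            denom = np.sqrt(variance_core * (1.0 / na + 1.0 / nb))
            z = 0.0 if denom == 0 else (rank_means[a] - rank_means[b]) / denom
            p = float(2.0 * sps.norm.sf(abs(z)))
            out.append((a, b, float(z), p))
            pvals.append(p)
    if adjust is not None:
        adjusted = multipletests(pvals, method=adjust)[1]
        out = [(a, b, z, float(p)) for (a, b, z, _), p in zip(out, adjusted)]
    return out


def records_by_mode(
    records: Iterable[SeizureRecord], modes: Sequence[str] = MODEL_MODES
) -> dict[str, list[float]]:
    """Group known per-seizure total masses (kg) by transport mode."""
    out: dict[str, list[float]] = {m: [] for m in modes}
    for r in records:
        if r.mass_known and r.mode in out:
            out[r.mode].append(r.total_mass_kg)
    return {m: v for m, v in out.items() if v}


def _model_frame(
    records: Iterable[SeizureRecord], years: tuple[int, int]
) -> pd.DataFrame:
    rows = [
        {"mass_kg": r.total_mass_kg, "year": r.year, "mode": r.mode}
        for r in records
        if r.mass_known
        and r.mode in MODEL_MODES
        and years[0] <= r.year <= years[1]
        and r.total_mass_kg > 0
    ]
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame["log10_mass"] = np.log10(frame["mass_kg"])
    return frame


def fit_mass_model(
    records: Iterable[SeizureRecord],
    formula: str = "log10_mass ~ year * C(mode)",
    years: tuple[int, int] = (2010, 2020),
) -> MassModelFit:
    """OLS of log10 seizure mass on year (continuous) and transport mode.

    Warehouse and unknown-mode records are excluded, as are records outside
    ``years`` (partial final years would bias the trend).  The categorical
    baseline is the alphabetically first mode (air).  Raises on rank-deficient
    designs, naming the collinear terms.
    """
    frame = _model_frame(records, years)
    if frame.empty:
        raise ValueError("no usable records for the mass model")
    model = smf.ols(formula, data=frame)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        # identify columns involved in the deficiency via QR pivoting
        _, r = np.linalg.qr(model.exog)
        bad = [
            model.exog_names[i]
            for i in range(model.exog.shape[1])
            if abs(r[i, i]) < 1e-10
        ]
        raise ValueError(f"rank-deficient design; collinear terms: {bad}")
    res = model.fit()
    coeffs = {
        name: (float(res.params[name]), float(res.bse[name]), float(res.pvalues[name]))
        for name in res.params.index
    }
    r_squared = float(res.rsquared)
    if not np.isfinite(r_squared):
        r_squared = 0.0  # constant response: no variance to explain
    return MassModelFit(
        formula=formula,
        coefficients=coeffs,
        r_squared=r_squared,
        f_stat=(float(res.fvalue), float(res.df_model), float(res.df_resid)),
        aic=float(res.aic),
        nobs=int(res.nobs),
        result=res,
    )


def compare_models(
    records: Iterable[SeizureRecord],
    formulas: Sequence[str] = (
        "log10_mass ~ year",
        "log10_mass ~ C(mode)",
        "log10_mass ~ year + C(mode)",
        "log10_mass ~ year * C(mode)",
    ),
    years: tuple[int, int] = (2010, 2020),
    criterion: str = "aic",
) -> list[tuple[str, float, int]]:
    """Rank candidate mass-model formulas by information criterion.

    Returns ``(formula, criterion_value, n_params)`` sorted best-first.  Ties
    (within 1e-9) are broken in favour of fewer parameters.  ``criterion`` is
    ``"aic"`` (default) or ``"aicc"`` (small-sample correction).
    """
    records = list(records)
    ranked: list[tuple[str, float, int]] = []
    for f in formulas:
        fit = fit_mass_model(records, formula=f, years=years)
        k = len(fit.coefficients) + 1  # +1 for the residual variance
        value = fit.aic
        if criterion == "aicc":
            n = fit.nobs
            if n - k - 1 <= 0:
                raise ValueError(f"too few observations for AICc with {k} parameters")
            value += 2.0 * k * (k + 1) / (n - k - 1)
        elif criterion != "aic":
            raise ValueError(f"unknown criterion {criterion!r}")
        ranked.append((f, float(value), k))
    ranked.sort(key=lambda t: (round(t[1], 9), t[2]))
    return ranked
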