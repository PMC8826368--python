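"""Group comparisons and trait correlations.

The analysis plan mirrors the experimental design: paired two-sided
t-tests for stimulus-vs-blank peak responses, one-way repeated-measures
ANOVA (generalized eta-squared effect size) across stimulation conditions,
Spearman rank correlation between response amplitudes and AQ scores with
Benjamini-Hochberg FDR correction over the declared test family, and OLS
linear fits with pointwise 95% confidence bands for plotting.

Hypothesis tests are delegated to pingouin / scipy / statsmodels; this
module defines the result container, the family bookkeeping and the
degenerate-input contracts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from hemovis.errors import DegenerateInputError, ParameterError, ValidationError

__all__ = ["StatResult", "paired_t", "rm_anova", "spearman_bh", "linear_fit_ci"]


@dataclass
class StatResult:
    """One hypothesis-test result with effect size and (optional) FDR p."""

    test: str
    statistic: float
    p_value: float
    effect_size: float | None = None
    effect_name: str | None = None
    ci_95: tuple[float, float] | None = None
    adjusted_p: float | None = None
    label: str = ""
    n: int | None = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValidationError("p-value must lie in [0, 1]")
        if self.adjusted_p is not None and not np.isnan(self.adjusted_p):
            if self.adjusted_p < self.p_value - 1e-12:
                raise ValidationError("adjusted p cannot be below the raw p")


def paired_t(stim_values, blank_values) -> StatResult:
    """Two-sided paired t-test (stimulus vs. blank peak responses).

    Zero variance of the paired differences is a documented degenerate
    case: identical pairs give t = 0, p = 1; a constant nonzero
    difference gives an infinite t with p = 0.
    """
    x = np.asarray(stim_values, dtype=float)
    y = np.asarray(blank_values, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("paired samples must have equal length")
    n = x.size
    if n < 2:
        raise ParameterError("paired t-test requires n >= 2")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            t, p = 0.0, 1.0
        else:
            t = math.inf if d.mean() > 0 else -math.inf
            p = 0.0
        return StatResult(test="paired_t", statistic=t, p_value=p,
                          effect_size=np.nan, effect_name="cohen_d", n=n)
    res = pg.ttest(x, y, paired=True, alternative="two-sided")
    row = res.iloc[0]
    ci = tuple(np.asarray(row["CI95"], dtype=float))
    return StatResult(test="paired_t", statistic=float(row["T"]),
                      p_value=float(row["p_val"]),
                      effect_size=float(row["cohen_d"]), effect_name="cohen_d",
                      ci_95=ci, n=n)


def rm_anova(data: pd.DataFrame, dv: str = "value", within: str = "condition",
             subject: str = "subject") -> StatResult:
    """One-way repeated-measures ANOVA with generalized eta-squared.

    Requires a complete design (every subject observed in every
    condition). Degrees of freedom are uncorrected (no sphericity
    correction), matching the quoted toolkit's default.
    """
    counts = data.groupby([subject, within]).size().unstack(fill_value=0)
    if (counts.values != 1).any():
        raise ValidationError("design must be complete: one value per cell")
    wide = data.pivot(index=subject, columns=within, values=dv)
    if np.allclose(wide.values.std(axis=0).sum(), 0.0) or \
            np.allclose((wide.values - wide.values.mean(axis=1, keepdims=True)).std(), 0.0):
        # all conditions identical within subjects: F = 0 by convention
        return StatResult(test="rm_anova", statistic=0.0, p_value=1.0,
                          effect_size=0.0, effect_name="ng2",
                          n=wide.shape[0])
    res = pg.rm_anova(data=data, dv=dv, within=within, subject=subject,
                      correction=False, effsize="ng2", detailed=False)
    row = res.iloc[0]
    return StatResult(test="rm_anova", statistic=float(row["F"]),
                      p_value=float(row["p_unc"]),
                      effect_size=float(row["ng2"]), effect_name="ng2",
                      n=wide.shape[0])


def spearman_bh(pairs: dict[str, tuple[np.ndarray, np.ndarray]],
                q: float = 0.05) -> list[StatResult]:
    """Spearman rank correlations with BH-FDR adjustment across a family.

    ``pairs`` maps a test label (e.g. ``"THb~AQ"``) to an ``(x, y)`` pair;
    the whole dict is one multiple-comparison family (chromophores x AQ
    scales x conditions). Missing values are dropped pairwise; a constant
    input vector makes the correlation undefined and raises. Ties are
    handled by average ranks (the default rank transform).
    """
    results: list[StatResult] = []
    for label, (x, y) in pairs.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        x, y = x[ok], y[ok]
        if x.size < 3:
            raise ParameterError(f"{label}: need at least 3 complete pairs")
        if np.all(x == x[0]) or np.all(y == y[0]):
            raise DegenerateInputError(f"{label}: constant vector, rho undefined")
        rho, p = sps.spearmanr(x, y)
        results.append(StatResult(test="spearman", statistic=float(rho),
                                  p_value=float(p), effect_size=float(rho),
                                  effect_name="rho", label=label, n=x.size))
    raw = [r.p_value for r in results]
    _, adj, _, _ = multipletests(raw, alpha=q, method="fdr_bh")
    for r, a in zip(results, adj):
        r.adjusted_p = float(a)
    return results


def linear_fit_ci(x, y, grid: np.ndarray | None = None):
    """OLS fit with a pointwise 95% confidence band for the mean response.

    Returns ``(slope, intercept, band)`` where ``band`` is a DataFrame
    with columns ``x``, ``fit``, ``lo``, ``hi``. Used to draw the
    regression line and shaded CI of amplitude-vs-AQ plots.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ParameterError("linear fit requires n >= 3")
    if np.all(x == x[0]):
        raise DegenerateInputError("constant x: singular fit")
    X = sm.add_constant(x)
    model = sm.OLS(y, X).fit()
    intercept, slope = model.params
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 50)
    pred = model.get_prediction(sm.add_constant(grid)).summary_frame(alpha=0.05)
    band = pd.DataFrame({
        "x": grid,
        "fit": pred["mean"].to_numpy(),
        "lo": pred["mean_ci_lower"].to_numpy(),
        "hi": pred["mean_ci_upper"].to_numpy(),
    })
    return float(slope), float(intercept), band
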