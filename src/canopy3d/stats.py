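"""Trait-to-yield regression utilities.

Simple (one trait) and multiple (19-percentile height profile) linear
regressions of plot fiber yield on extracted traits, reported with adjusted
R² and RMSE, plus the nested-model F-test comparing a small model (e.g. max
and mean height) against a larger one that contains its predictors (e.g. the
full cumulative height profile):

    F = ((RSS_small − RSS_big) / df1) / (RSS_big / df2)

with df1 the parameter-count difference and df2 the residual degrees of
freedom of the larger model.  Missing observations are dropped listwise per
regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


@dataclass
class RegressionResult:
    coefficients: np.ndarray          # intercept first
    adjusted_r2: float
    rmse: float
    p_value: float                    # overall model F-test p
    n: int
    rss: float
    df_resid: int
    predictors: tuple[str, ...] = ()
    obs_index: tuple[int, ...] = field(default=(), repr=False)


@dataclass
class FTestResult:
    f: float
    df1: int
    df2: int
    p_value: float


def significance_tier(p: float) -> str:
    """Report-style significance tier: '***' <0.001, '**' <0.01, '*' <0.05."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _prepare(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if len(x) != len(y):
        raise ValueError("predictor and response lengths differ")
    keep = np.isfinite(y) & np.all(np.isfinite(x), axis=1)
    return x[keep], y[keep], np.flatnonzero(keep)


def _fit_ols(x: np.ndarray, y: np.ndarray, idx: np.ndarray,
             names: tuple[str, ...]) -> RegressionResult:
    design = sm.add_constant(x, has_constant="add")
    p = x.shape[1]
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = _collinear_columns(design, names)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    model = sm.OLS(y, design).fit()
    resid = model.resid
    return RegressionResult(
        coefficients=np.asarray(model.params),
        adjusted_r2=float(model.rsquared_adj),
        rmse=float(np.sqrt(np.mean(resid**2))),
        p_value=float(model.f_pvalue),
        n=len(y),
        rss=float(resid @ resid),
        df_resid=int(model.df_resid),
        predictors=names,
        obs_index=tuple(int(i) for i in idx),
    )


def _collinear_columns(design: np.ndarray, names: tuple[str, ...]) -> list[str]:
    """Name the design columns that do not increase the rank."""
    bad = []
    rank = 0
    cols = [design[:, 0]]  # constant
    for k in range(1, design.shape[1]):
        trial = np.column_stack(cols + [design[:, k]])
        new_rank = np.linalg.matrix_rank(trial)
        if new_rank == len(cols):
            bad.append(names[k - 1] if k - 1 < len(names) else f"x{k}")
        else:
            cols.append(design[:, k])
        rank = new_rank
    return bad


def fit_univariate(x, y, name: str = "trait") -> RegressionResult:
    """OLS of yield on one trait: y = b0 + b1·x (listwise missing deletion)."""
    xm, ym, idx = _prepare(x, y)
    if len(ym) < 3:
        raise ValueError("need at least 3 complete observations")
    if np.ptp(xm) == 0:
        raise ValueError("constant predictor: regression undefined")
    return _fit_ols(xm, ym, idx, (name,))


def fit_multivariate(x, y, names: tuple[str, ...] | None = None) -> RegressionResult:
    """OLS of yield on a predictor matrix (e.g. the n×19 height profile)."""
    xm, ym, idx = _prepare(x, y)
    p = xm.shape[1]
    if len(ym) <= p + 1:
        raise ValueError(
            f"need more than {p + 1} observations for {p} predictors")
    if names is None:
        names = tuple(f"x{k + 1}" for k in range(p))
    return _fit_ols(xm, ym, idx, tuple(names))


def nested_f_test(small: RegressionResult, big: RegressionResult) -> FTestResult:
    """F-test of whether the larger model significantly reduces the RSS.

    Requires the small model's predictors to be a subset of the big model's
    and both fits to use the same observations.
    """
    if not set(small.predictors) <= set(big.predictors):
        raise ValueError("models are not nested (predictor sets)")
    if small.obs_index != big.obs_index:
        raise ValueError("models were fit on different observations")
    df1 = (len(big.predictors) - len(small.predictors))
    df2 = big.df_resid
    if df1 <= 0 or df2 <= 0:
        raise ValueError("degenerate degrees of freedom for the F-test")
    num = max(small.rss - big.rss, 0.0) / df1
    den = big.rss / df2
    f = num / den if den > 0 else 0.0
    p = float(sps.f.sf(f, df1, df2)) if f > 0 else 1.0
    return FTestResult(float(f), int(df1), int(df2), p)


def regress_traits_vs_yield(traits: pd.DataFrame, yields: pd.DataFrame,
                            profile_prefix: str = "height_p") -> pd.DataFrame:
    """Univariate regressions per trait column plus the profile model.

    ``traits``: one row per plot with trait columns; ``yields``: columns
    ``plot_id`` and ``fiber_yield``.  Returns a long-format table with
    adjusted R², RMSE, model p and significance tier; the profile row also
    carries the nested F-test p against the (max_height, mean_height) model.
    """
    merged = traits.merge(yields, on="plot_id", how="inner")
    y = merged["fiber_yield"].to_numpy(float)
    profile_cols = [c for c in merged.columns if c.startswith(profile_prefix)]
    scalar_cols = [c for c in merged.columns
                   if c not in ("plot_id", "dap", "genotype", "fiber_yield")
                   and c not in profile_cols]
    rows = []
    for col in scalar_cols:
        try:
            res = fit_univariate(merged[col].to_numpy(float), y, name=col)
        except ValueError:
            continue
        rows.append({"trait": col, "adj_R2": res.adjusted_r2, "RMSE": res.rmse,
                     "p": res.p_value, "tier": significance_tier(res.p_value),
                     "f_test_p": np.nan, "n": res.n})
    if profile_cols:
        prof = fit_multivariate(merged[profile_cols].to_numpy(float), y,
                                names=tuple(profile_cols))
        row = {"trait": "height_profile", "adj_R2": prof.adjusted_r2,
               "RMSE": prof.rmse, "p": prof.p_value,
               "tier": significance_tier(prof.p_value),
               "f_test_p": np.nan, "n": prof.n}
        try:
            heights = fit_multivariate(
                merged[["max_height", "mean_height"]].to_numpy(float), y,
                names=("max_height", "mean_height"))
            big = fit_multivariate(
                merged[["max_height", "mean_height"] + profile_cols].to_numpy(float),
                y, names=tuple(["max_height", "mean_height"] + profile_cols))
            row["f_test_p"] = nested_f_test(heights, big).p_value
        except (KeyError, ValueError):
            pass
        rows.append(row)
    return pd.DataFrame(rows)
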