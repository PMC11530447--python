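"""Nested regression comparison: narrative vs low-level predictors of heart rate.

The condition-level heart-rate series is the per-second mean of the
per-participant z-scored series.  Three nested OLS models predict one
condition's series: time alone (a linear trend in seconds), time plus the
other condition's series (the narrative proxy — the only signal the two
modality groups share), and additionally the low-level salience features.
Models are compared by R^2 and BIC; the BIC uses the Gaussian profile form

    BIC = n * ln(RSS / n) + k * ln(n)

with k counting the intercept, the slopes, and the error variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .preprocess import standardize
from .signal import SignalSeries

FEATURE_COLUMNS = ("rms_volume", "orientation", "colour", "flicker", "intensity", "motion")


@dataclass
class ModelFit:
    name: str
    predictors: list[str]
    k: int  # intercept + slopes + error variance
    r2: float
    bic: float
    coefficients: pd.Series
    residuals: np.ndarray


@dataclass
class RegressionSummary:
    r2: float
    f_stat: float
    df_num: int
    df_den: int
    p: float


def condition_mean_hr(series: list[SignalSeries]) -> pd.Series:
    """Average the condition's participants after per-participant z-scoring."""
    if len(series) < 2:
        raise ValueError("need at least two participants to average a condition")
    z = np.stack([standardize(s).values for s in series])
    t0 = int(series[0].t0_s)
    return pd.Series(
        z.mean(axis=0),
        index=pd.RangeIndex(t0, t0 + z.shape[1], name="t_s"),
        name="mean_hr",
    )


def _check_rank(X: pd.DataFrame) -> None:
    mat = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax() if len(X.columns) > 1 else (X.columns[0],) * 2
        raise ValueError(f"design is rank deficient; check columns {sorted(set(worst))}")


def _fit(name: str, y: np.ndarray, X: pd.DataFrame) -> ModelFit:
    _check_rank(X)
    design = sm.add_constant(X.to_numpy(dtype=float))
    res = sm.OLS(y, design).fit()
    n = len(y)
    rss = float(res.ssr)
    k = X.shape[1] + 2  # intercept + slopes + error variance
    bic = n * np.log(max(rss, 1e-300) / n) + k * np.log(n)
    coef = pd.Series(res.params, index=["intercept", *X.columns])
    return ModelFit(
        name=name,
        predictors=list(X.columns),
        k=k,
        r2=float(res.rsquared),
        bic=float(bic),
        coefficients=coef,
        residuals=np.asarray(res.resid),
    )


def fit_nested_models(
    target: pd.Series,
    other: pd.Series,
    features: pd.DataFrame,
    lag_s: int = 0,
    feature_columns: tuple[str, ...] = FEATURE_COLUMNS,
) -> list[ModelFit]:
    """Fit the three nested models for one prediction direction.

    ``target`` and ``other`` are condition-level HR series indexed by t_s;
    ``features`` is the per-second feature table.  ``lag_s`` shifts the
    predictors forward by that many seconds relative to the target, to
    explore physiological delay (default 0).  Returns fits for the trend
    model, the narrative model and the full low-level model, in that order.
    """
    feats = features.set_index("t_s") if "t_s" in features.columns else features
    cols = [c for c in feature_columns if c in feats.columns]
    df = pd.DataFrame({"target": target, "other_hr": other}).join(feats[cols], how="inner")
    if lag_s:
        for c in ["other_hr", *cols]:
            df[c] = df[c].shift(lag_s)
    df = df.dropna()
    df["seconds"] = df.index.to_numpy(dtype=float)
    n = len(df)
    if n <= len(cols) + 4:
        raise ValueError("not enough aligned seconds to fit the largest model")
    y = df["target"].to_numpy(dtype=float)
    fits = [
        _fit("trend", y, df[["seconds"]]),
        _fit("trend+narrative", y, df[["seconds", "other_hr"]]),
        _fit("trend+narrative+lowlevel", y, df[["seconds", "other_hr", *cols]]),
    ]
    return fits


def delta_r2(fits: list[ModelFit]) -> dict[str, float]:
    """Variance uniquely added by the narrative and low-level blocks."""
    r2 = {f.name: f.r2 for f in fits}
    return {
        "narrative": r2["trend+narrative"] - r2["trend"],
        "lowlevel": r2["trend+narrative+lowlevel"] - r2["trend+narrative"],
    }


def comparison_table(fits: list[ModelFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "model": [f.name for f in fits],
            "predictors": ["+".join(f.predictors) for f in fits],
            "df": [f.k for f in fits],
            "r2": [f.r2 for f in fits],
            "bic": [f.bic for f in fits],
        }
    )


def features_to_volume(
    features: pd.DataFrame,
    predictors: tuple[str, ...] = ("colour", "intensity", "motion", "flicker", "orientation"),
) -> RegressionSummary:
    """Regress RMS volume on the visual conspicuity channels.

    Quantifies audiovisual co-occurrence: how much loudness is predictable
    from visual salience alone.
    """
    cols = [c for c in predictors if c in features.columns]
    if len(cols) < 2:
        raise ValueError("need at least two predictor columns")
    df = features.dropna(subset=[*cols, "rms_volume"])
    if len(df) <= len(cols) + 1:
        raise ValueError("not enough rows for the regression")
    X = df[cols]
    _check_rank(X)
    res = sm.OLS(df["rms_volume"].to_numpy(), sm.add_constant(X.to_numpy())).fit()
    return RegressionSummary(
        r2=float(res.rsquared),
        f_stat=float(res.fvalue),
        df_num=int(res.df_model),
        df_den=int(res.df_resid),
        p=float(res.f_pvalue),
    )
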