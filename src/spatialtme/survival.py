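"""Association and survival statistics for spatial features.

Rank-based tests (Wilcoxon rank-sum for two groups, Kruskal-Wallis for more)
relate continuous spatial features (mixing scores, distances) to
clinicopathologic variables; Kaplan-Meier curves with log-rank tests and Cox
proportional-hazards models (Efron tie handling) relate dichotomized spatial
features to overall and recurrence-free survival.  P-values are two-sided and
unadjusted by default; a Benjamini-Hochberg switch is available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

logger = logging.getLogger("spatialtme")

ALPHA = 0.05


# ---------------------------------------------------------------------------
# Rank tests against clinical variables
# ---------------------------------------------------------------------------

def feature_vs_clinical_tests(features: pd.DataFrame,
                              clinical_variable: str,
                              feature_columns=None) -> pd.DataFrame:
    """Rank-sum (2 levels) or Kruskal-Wallis (>2 levels) test of each
    continuous spatial feature across the levels of a clinical variable.

    ``features`` holds one row per subject with the clinical variable and the
    feature columns.  Constant features are skipped with a warning.  Returns
    columns feature/test/statistic/p.
    """
    levels = features[clinical_variable].dropna().unique()
    if len(levels) < 2:
        raise ValueError(f"clinical variable {clinical_variable!r} needs >= 2 levels")
    if feature_columns is None:
        feature_columns = [c for c in features.select_dtypes("number").columns
                           if c != clinical_variable]
    rows = []
    for col in feature_columns:
        samples = [features.loc[features[clinical_variable] == lv, col].dropna()
                   for lv in levels]
        if any(len(s) < 2 for s in samples):
            logger.warning("feature %s: a level of %s has <2 observations; "
                           "test skipped", col, clinical_variable)
            continue
        pooled = pd.concat(samples)
        if pooled.nunique() <= 1:
            logger.warning("feature %s is constant; test skipped", col)
            continue
        if len(levels) == 2:
            stat, p = stats.mannwhitneyu(samples[0], samples[1],
                                         alternative="two-sided")
            test = "wilcoxon_rank_sum"
        else:
            stat, p = stats.kruskal(*samples)
            test = "kruskal_wallis"
        rows.append({"feature": col, "clinical_variable": clinical_variable,
                     "test": test, "statistic": float(stat), "p": float(p)})
    return pd.DataFrame(rows, columns=["feature", "clinical_variable", "test",
                                       "statistic", "p"])


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional; the default analysis is unadjusted)."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------

@dataclass
class KMResult:
    fits: dict  # level -> fitted KaplanMeierFitter
    logrank_statistic: float
    logrank_p: float
    n_per_level: dict


def km_logrank(time, event, feature, fit_curves: bool = True) -> KMResult:
    """Kaplan-Meier estimates per feature level with a two-sided log-rank test.

    ``feature`` is a per-subject categorical (e.g. close/long); every level
    must be nonempty.
    """
    df = pd.DataFrame({"time": np.asarray(time, float),
                       "event": np.asarray(event, int),
                       "level": np.asarray(feature)}).dropna()
    levels = pd.unique(df["level"])
    if len(levels) < 2:
        raise ValueError("log-rank test needs >= 2 nonempty feature levels")
    res = multivariate_logrank_test(df["time"], df["level"], df["event"])
    fits = {}
    if fit_curves:
        for lv in levels:
            sub = df[df["level"] == lv]
            kmf = KaplanMeierFitter(label=str(lv))
            kmf.fit(sub["time"], sub["event"])
            fits[lv] = kmf
    return KMResult(fits=fits, logrank_statistic=float(res.test_statistic),
                    logrank_p=float(res.p_value),
                    n_per_level=df["level"].value_counts().to_dict())


def logrank_pvalue(time, event, feature) -> float:
    """Log-rank p only (no curve fitting); convenience for simulations."""
    return km_logrank(time, event, feature, fit_curves=False).logrank_p


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class SurvivalFit:
    """Cox model fit: per-covariate B, SE, Wald, HR, 95% CI and p."""

    table: pd.DataFrame  # index = covariate
    log_likelihood: float
    n: int
    n_events: int
    flags: list

    def hr(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "HR"])


def _drop_constant_and_collinear(X: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    flags = []
    for c in list(X.columns):
        if X[c].nunique(dropna=True) <= 1:
            raise ValueError(f"covariate {c!r} is constant")
    cols = list(X.columns)
    keep = []
    for c in cols:
        collinear = None
        for k in keep:
            r = np.corrcoef(X[c], X[k])[0, 1]
            if abs(r) > 0.9999:
                collinear = k
                break
        if collinear is None:
            keep.append(c)
        else:
            msg = (f"covariate {c!r} dropped: collinear with {collinear!r}")
            flags.append(msg)
            warnings.warn(msg, stacklevel=3)
    return X[keep], flags


def cox_ph(data: pd.DataFrame, covariates, duration_col: str = "os_months",
           event_col: str = "os_event") -> SurvivalFit:
    """Cox proportional-hazards fit (Efron ties) of the given covariates.

    Emits a warning when events per covariate fall below 5, flags suspected
    complete separation (|B| or SE above 10), and reports the Wald statistic,
    hazard ratio and 95% CI per covariate.
    """
    covariates = list(covariates)
    df = data[covariates + [duration_col, event_col]].dropna()
    X, flags = _drop_constant_and_collinear(df[covariates].astype(float))
    df = pd.concat([X, df[[duration_col, event_col]]], axis=1)
    n_events = int(df[event_col].sum())
    if n_events == 0:
        raise ValueError("no events in the data")
    if n_events / max(len(X.columns), 1) < 5:
        warnings.warn(f"only {n_events} events for {len(X.columns)} covariates "
                      "(events/covariate < 5); estimates may be unstable",
                      stacklevel=2)
    cph = CoxPHFitter()
    cph.fit(df, duration_col=duration_col, event_col=event_col)
    s = cph.summary
    table = pd.DataFrame({
        "B": s["coef"], "SE": s["se(coef)"],
        "Wald": (s["coef"] / s["se(coef)"]) ** 2,
        "HR": s["exp(coef)"],
        "CI_lower": s["exp(coef) lower 95%"],
        "CI_upper": s["exp(coef) upper 95%"],
        "p": s["p"],
    })
    for cov in table.index:
        if abs(table.loc[cov, "B"]) > 10 or table.loc[cov, "SE"] > 10:
            msg = (f"covariate {cov!r}: suspected complete separation "
                   f"(B={table.loc[cov, 'B']:.3g}, SE={table.loc[cov, 'SE']:.3g})")
            flags.append(msg)
            warnings.warn(msg, stacklevel=2)
    return SurvivalFit(table=table, log_likelihood=float(cph.log_likelihood_),
                       n=len(df), n_events=n_events, flags=flags)


def multivariable_report(data: pd.DataFrame,
                         spatial_features,
                         clinical_adjusters=(),
                         duration_col: str = "os_months",
                         event_col: str = "os_event") -> SurvivalFit:
    """One joint Cox fit of dichotomized spatial feature blocks (density
    class, pattern, distance class) plus clinical adjusters, reported with
    columns B, SE, Wald, HR, CI and p in model order."""
    covariates = list(clinical_adjusters) + list(spatial_features)
    return cox_ph(data, covariates, duration_col=duration_col,
                  event_col=event_col)


def encode_binary(series: pd.Series, positive) -> pd.Series:
    """0/1 encoding of a two-level categorical (1 = ``positive`` level)."""
    out = pd.Series(np.nan, index=series.index)
    notna = series.notna()
    out[notna] = (series[notna] == positive).astype(float)
    return out
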