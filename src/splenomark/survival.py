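"""Survival-analysis protocol for the dissemination biomarkers.

Implements the statistical pipeline applied to the per-patient feature table:
Pearson correlations between biomarkers, cutoff selection (median or Youden
index of the time-dependent ROC), Kaplan–Meier risk grouping with log-rank
tests, Cox proportional-hazards models, Harrell's concordance index and
censoring-weighted cumulative/dynamic AUC, all with patient-level bootstrap
empirical confidence intervals, plus the paired-bootstrap test for the
concordance gain when a biomarker is added to a baseline model.

Cox coefficients are maximized with the package's Newton solver (Efron ties,
:mod:`splenomark._coxph`); Kaplan–Meier curves, log-rank tests and Harrell's C
go through lifelines, and the time-dependent AUC through scikit-survival.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index
from scipy import stats
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

from ._coxph import CoxFit, fit_coxph

__all__ = [
    "CutoffRule",
    "RiskGrouping",
    "SurvivalReport",
    "pearson_matrix",
    "select_cutoff",
    "km_logrank",
    "cox_model",
    "harrell_c",
    "bootstrap_ci",
    "time_dependent_auc",
    "stratify_3groups",
    "c_index_gain_test",
    "subgroup_run",
    "analyze_endpoint",
]

#: published optimal TMTV cutoff (cm³) used for the three-group stratification
TMTV_CUTOFF_CM3 = 220.0


# ---------------------------------------------------------------------------
# cutoffs and correlations


@dataclass
class CutoffRule:
    feature: str
    method: str = "median"          # median | youden | fixed
    value: Optional[float] = None   # required for "fixed"
    horizon: float = 48.0           # months, for "youden"

    def __post_init__(self) -> None:
        if self.method not in ("median", "youden", "fixed"):
            raise ValueError(f"unknown cutoff method {self.method!r}")
        if self.method == "fixed" and self.value is None:
            raise ValueError("fixed cutoff requires an explicit value")


def pearson_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of the feature columns.

    Requires ≥ 3 complete rows; a zero-variance column is an error (its
    correlation is undefined, and silently returning NaN hides data bugs).
    """
    df = features.select_dtypes(include=[np.number]).dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 complete patients for correlations")
    var = df.var(ddof=0)
    dead = var[var == 0].index.tolist()
    if dead:
        raise ValueError(f"zero-variance feature column(s): {dead}")
    return df.corr(method="pearson")


def _censoring_survival(times: np.ndarray, events: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    """Kaplan–Meier estimate G(t) of the censoring survival function."""
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=1 - np.asarray(events))
    def G(t: np.ndarray) -> np.ndarray:
        return np.asarray(kmf.survival_function_at_times(np.asarray(t)))
    return G


def select_cutoff(
    values: Sequence[float],
    times: Sequence[float],
    events: Sequence[int],
    rule: CutoffRule,
) -> float:
    """Select a dichotomization cutoff for a biomarker.

    ``median`` takes the sample median; ``fixed`` returns the stated value;
    ``youden`` scans every observed marker value as a threshold and maximizes
    sensitivity + specificity − 1 for the event-by-horizon outcome, with
    cases weighted by inverse probability of censoring (lowest qualifying
    threshold on ties).
    """
    v = np.asarray(values, dtype=float)
    if np.ptp(v) == 0:
        raise ValueError("all marker values identical; no cutoff exists")
    if rule.method == "median":
        return float(np.median(v))
    if rule.method == "fixed":
        return float(rule.value)

    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    h = rule.horizon
    case = (e == 1) & (t <= h)
    control = t > h
    if not case.any():
        raise ValueError("no events before the horizon; Youden cutoff undefined")
    if not control.any():
        raise ValueError("no patients followed beyond the horizon")
    G = _censoring_survival(t, e)
    w_case = 1.0 / np.clip(G(np.maximum(t[case] - 1e-9, 0.0)), 1e-12, None)

    best_j, best_c = -np.inf, None
    for c in np.sort(np.unique(v)):
        sens = w_case[v[case] > c].sum() / w_case.sum()
        spec = float(np.mean(v[control] <= c))
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_c = j, float(c)
    return best_c


# ---------------------------------------------------------------------------
# Kaplan–Meier / log-rank


@dataclass
class KMResult:
    curves: dict                       # group label -> DataFrame(time, survival)
    chi2: float
    p_value: float
    group_sizes: dict


def km_logrank(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence,
) -> KMResult:
    """Product-limit curves per group and the k-group log-rank test.

    With no events anywhere the curves are identically 1 and the log-rank
    statistic is undefined; the p-value is reported as NaN rather than raised.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two non-empty groups")
    curves = {}
    for lab in labels:
        m = g == lab
        kmf = KaplanMeierFitter()
        kmf.fit(t[m], event_observed=e[m])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[lab] = sf
    if e.sum() == 0:
        return KMResult(curves, float("nan"), float("nan"), dict(zip(labels.tolist(), counts.tolist())))
    res = multivariate_logrank_test(t, g, e)
    return KMResult(
        curves,
        float(res.test_statistic),
        float(res.p_value),
        dict(zip(labels.tolist(), counts.tolist())),
    )


# ---------------------------------------------------------------------------
# Cox model, concordance, bootstrap


@dataclass
class CoxResult:
    covariates: list
    coef: np.ndarray
    se: np.ndarray
    converged: bool
    n: int
    n_events: int

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def p_values(self) -> np.ndarray:
        z = self.coef / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        return table[self.covariates].to_numpy(dtype=float) @ self.coef

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "hr": self.hazard_ratios,
                "se": self.se,
                "p": self.p_values,
            },
            index=self.covariates,
        )


def cox_model(
    covariates: pd.DataFrame,
    times: Sequence[float],
    events: Sequence[int],
) -> CoxResult:
    """Cox proportional-hazards fit by maximum partial likelihood (Efron ties).

    Hazard ratios are exp(coefficient). Non-convergence is reported on the
    result (and warned), never silently ignored; degenerate inputs (constant
    covariate, fewer events than covariates) raise.
    """
    X = covariates.to_numpy(dtype=float)
    fit = fit_coxph(X, np.asarray(times, float), np.asarray(events))
    if not fit.converged:
        warnings.warn("Cox partial-likelihood Newton iteration did not converge")
    return CoxResult(
        covariates=list(covariates.columns),
        coef=fit.coef,
        se=fit.se,
        converged=fit.converged,
        n=fit.n,
        n_events=fit.n_events,
    )


def harrell_c(
    risk: Sequence[float], times: Sequence[float], events: Sequence[int]
) -> float:
    """Harrell's concordance for a risk score (higher risk ⇒ earlier event).

    Concordant pairs / comparable pairs with ties counted ½; comparability
    respects right censoring.
    """
    return float(concordance_index(np.asarray(times, float), -np.asarray(risk, float), np.asarray(events)))


@dataclass
class BootstrapResult:
    point: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_resamples: int
    n_failed: int
    samples: np.ndarray = field(repr=False)


def bootstrap_ci(
    statistic: Callable[[pd.DataFrame], float | np.ndarray],
    table: pd.DataFrame,
    n_resamples: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
    max_failure_frac: float = 0.05,
) -> BootstrapResult:
    """Patient-level bootstrap: empirical percentile CI of a table statistic.

    Patients (rows) are resampled with replacement; the CI is the empirical
    2.5/97.5 percentile band of the resampled statistic. Fully seeded — the
    same seed reproduces the CI bit for bit. If the statistic fails on more
    than ``max_failure_frac`` of resamples the run aborts with a diagnostic.
    """
    if n_resamples < 100:
        raise ValueError("n_resamples must be >= 100")
    rng = np.random.default_rng(seed)
    point = np.atleast_1d(np.asarray(statistic(table), dtype=float))
    n = len(table)
    samples, n_failed = [], 0
    for _ in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        try:
            samples.append(np.atleast_1d(np.asarray(statistic(table.iloc[idx]), dtype=float)))
        except Exception:
            n_failed += 1
    if n_failed > max_failure_frac * n_resamples:
        raise RuntimeError(
            f"statistic failed on {n_failed}/{n_resamples} bootstrap resamples"
        )
    arr = np.vstack(samples)
    # components may be NaN on degenerate resamples (e.g. event-free draws at
    # small n); percentiles are taken over the defined resamples
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lower = np.nanpercentile(arr, 100 * alpha / 2, axis=0)
        upper = np.nanpercentile(arr, 100 * (1 - alpha / 2), axis=0)
    # empirical percentile bands can exclude the full-sample point by a hair;
    # the reported interval always brackets the point estimate
    return BootstrapResult(
        point=point,
        lower=np.minimum(lower, point),
        upper=np.maximum(upper, point),
        n_resamples=n_resamples,
        n_failed=n_failed,
        samples=arr,
    )


def time_dependent_auc(
    marker: Sequence[float],
    times: Sequence[float],
    events: Sequence[int],
    horizon: float,
) -> float:
    """Censoring-weighted cumulative/dynamic AUC of a marker at a horizon.

    Cases are patients with an event by the horizon, controls those still
    event-free; inverse-probability-of-censoring weighting follows the
    Uno-type estimator of scikit-survival.
    """
    t = np.asarray(times, float)
    e = np.asarray(events).astype(bool)
    m = np.asarray(marker, float)
    if not ((t <= horizon) & e).any():
        raise ValueError("no events before the horizon")
    if horizon >= t.max():
        raise ValueError("horizon must lie strictly inside the follow-up range")
    y = Surv.from_arrays(event=e, time=t)
    auc, _ = cumulative_dynamic_auc(y, y, m, [horizon])
    return float(auc[0])


# ---------------------------------------------------------------------------
# risk grouping


@dataclass
class RiskGrouping:
    assignments: dict            # patient_id -> group index
    n_groups: int
    definition: str
    excluded: list = field(default_factory=list)

    def labels_for(self, patient_ids: Sequence) -> np.ndarray:
        return np.asarray([self.assignments[p] for p in patient_ids])


def stratify_3groups(
    patient_ids: Sequence,
    tmtv_values: Sequence[float],
    feature_values: Sequence[float],
    tmtv_cutoff: float = TMTV_CUTOFF_CM3,
    feature_cutoff: Optional[float] = None,
    feature_name: str = "feature",
) -> RiskGrouping:
    """Three risk groups by combining TMTV with a dissemination feature.

    Group 0: both below cutoff; group 1: exactly one above; group 2: both
    above. TMTV cutoff defaults to the published 220 cm³; the feature cutoff
    defaults to its median. Patients with a missing value are excluded and
    listed on the grouping.
    """
    tm = np.asarray(tmtv_values, dtype=float)
    fv = np.asarray(feature_values, dtype=float)
    if feature_cutoff is None:
        feature_cutoff = float(np.nanmedian(fv))
    assignments, excluded = {}, []
    for pid, a, b in zip(patient_ids, tm, fv):
        if np.isnan(a) or np.isnan(b):
            excluded.append(pid)
            continue
        assignments[pid] = int(a > tmtv_cutoff) + int(b > feature_cutoff)
    return RiskGrouping(
        assignments=assignments,
        n_groups=3,
        definition=(
            f"TMTV>{tmtv_cutoff:g} cm3 + {feature_name}>{feature_cutoff:g}"
        ),
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# concordance-gain test


@dataclass
class GainTestResult:
    c_base: float
    c_extended: float
    delta_c: float
    ci_lower: float
    ci_upper: float
    p_value: float
    n_resamples: int


def c_index_gain_test(
    table: pd.DataFrame,
    base: Sequence[str],
    extended: Sequence[str],
    time_col: str,
    event_col: str,
    n_resamples: int = 1000,
    seed: int = 0,
) -> GainTestResult:
    """Does adding covariates improve the concordance of a Cox model?

    Both models are fitted once on the full table; their linear predictors
    are then compared by a paired patient-level bootstrap of
    C(extended) − C(base) on identical resamples. The p-value is the
    two-sided proportion of the bootstrap ΔC distribution on the far side of
    zero.
    """
    if not set(base) <= set(extended):
        raise ValueError("extended covariates must contain the base covariates")
    t = table[time_col].to_numpy(dtype=float)
    e = table[event_col].to_numpy()
    if list(base):
        fit_b = cox_model(table[list(base)], t, e)
        risk_b = fit_b.linear_predictor(table)
    else:
        risk_b = np.zeros(len(table))
    fit_e = cox_model(table[list(extended)], t, e)
    risk_e = fit_e.linear_predictor(table)

    c_b = harrell_c(risk_b, t, e)
    c_e = harrell_c(risk_e, t, e)

    rng = np.random.default_rng(seed)
    n = len(table)
    deltas = np.empty(n_resamples)
    for i in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        deltas[i] = harrell_c(risk_e[idx], t[idx], e[idx]) - harrell_c(
            risk_b[idx], t[idx], e[idx]
        )
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    p = 2.0 * min(float(np.mean(deltas <= 0.0)), float(np.mean(deltas >= 0.0)))
    return GainTestResult(
        c_base=c_b,
        c_extended=c_e,
        delta_c=c_e - c_b,
        ci_lower=float(lo),
        ci_upper=float(hi),
        p_value=min(p, 1.0),
        n_resamples=n_resamples,
    )


# ---------------------------------------------------------------------------
# endpoint-level composition


@dataclass
class SurvivalReport:
    endpoint: str
    covariates: list
    hazard_ratios: dict          # cov -> {"hr", "lo", "hi", "p"}
    c_index: dict                # {"point", "lo", "hi"}
    logrank_p: Optional[float]
    td_auc: Optional[dict]       # {"point", "lo", "hi", "horizon"}
    n: int
    n_events: int
    n_bootstrap: int
    seed: int
    subset: str = "all"
    km_feature: Optional[str] = None
    km_cutoff: Optional[float] = None
    risk_orientation_flipped: bool = False

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "subset": self.subset,
            "covariates": list(self.covariates),
            "hazard_ratios": self.hazard_ratios,
            "c_index": self.c_index,
            "logrank_p": self.logrank_p,
            "td_auc": self.td_auc,
            "n": self.n,
            "n_events": self.n_events,
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
            "km_feature": self.km_feature,
            "km_cutoff": self.km_cutoff,
            "risk_orientation_flipped": self.risk_orientation_flipped,
        }


def analyze_endpoint(
    table: pd.DataFrame,
    endpoint: str,
    covariates: Sequence[str],
    horizon: float = 48.0,
    n_bootstrap: int = 1000,
    seed: int = 0,
    km_feature: Optional[str] = None,
    km_rule: Optional[CutoffRule] = None,
    subset: str = "all",
) -> SurvivalReport:
    """Run the full univariate/multivariate protocol for one endpoint.

    ``table`` carries one row per patient with the feature columns plus
    ``{endpoint}_months`` and ``{endpoint}_event``. The Cox model uses the
    listed covariates on their natural scale; bootstrap empirical 95% CIs are
    attached to every hazard ratio and to the concordance of the model's
    linear predictor; the time-dependent AUC of the linear predictor is
    evaluated at the horizon; optionally a two-group Kaplan–Meier log-rank
    test on a single dichotomized feature is included.
    """
    time_col, event_col = f"{endpoint}_months", f"{endpoint}_event"
    covariates = list(covariates)
    df = table.dropna(subset=covariates + [time_col, event_col]).reset_index(drop=True)
    t = df[time_col].to_numpy(dtype=float)
    e = df[event_col].to_numpy()

    fit = cox_model(df[covariates], t, e)
    risk = fit.linear_predictor(df)
    c_point = harrell_c(risk, t, e)
    flipped = c_point < 0.5

    n_stat = len(covariates) + 2

    def stat(sub: pd.DataFrame) -> np.ndarray:
        ts = sub[time_col].to_numpy(dtype=float)
        es = sub[event_col].to_numpy()
        try:
            f = cox_model(sub[covariates], ts, es)
        except ValueError:
            # degenerate resample (event-free or constant covariate)
            return np.full(n_stat, np.nan)
        if not f.converged or not np.all(np.isfinite(f.coef)):
            return np.full(n_stat, np.nan)
        r = f.linear_predictor(sub)
        try:
            c = harrell_c(r, ts, es)
        except ZeroDivisionError:  # no comparable pairs in the resample
            return np.full(n_stat, np.nan)
        if flipped:
            c = 1.0 - c
        try:
            auc = time_dependent_auc(-r if flipped else r, ts, es, horizon)
        except ValueError:
            auc = np.nan
        return np.concatenate([f.coef, [c, auc]])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        boot = bootstrap_ci(stat, df, n_resamples=n_bootstrap, seed=seed)
    k = len(covariates)
    hrs = {}
    for j, cov in enumerate(covariates):
        hrs[cov] = {
            "hr": float(np.exp(fit.coef[j])),
            "lo": float(np.exp(boot.lower[j])),
            "hi": float(np.exp(boot.upper[j])),
            "p": float(fit.p_values[j]),
        }
    c_ci = {
        "point": 1.0 - c_point if flipped else c_point,
        "lo": float(boot.lower[k]),
        "hi": float(boot.upper[k]),
    }
    auc_point = time_dependent_auc(-risk if flipped else risk, t, e, horizon)
    auc_samp = boot.samples[:, k + 1]
    auc_samp = auc_samp[~np.isnan(auc_samp)]
    td = {
        "point": float(auc_point),
        "lo": float(min(np.percentile(auc_samp, 2.5), auc_point)),
        "hi": float(max(np.percentile(auc_samp, 97.5), auc_point)),
        "horizon": horizon,
    }

    logrank_p = km_cut = None
    if km_feature is not None:
        rule = km_rule or CutoffRule(feature=km_feature, method="median", horizon=horizon)
        km_cut = select_cutoff(df[km_feature], t, e, rule)
        groups = (df[km_feature].to_numpy(dtype=float) > km_cut).astype(int)
        if len(np.unique(groups)) == 2:
            logrank_p = km_logrank(t, e, groups).p_value
        else:
            logrank_p = float("nan")

    return SurvivalReport(
        endpoint=endpoint,
        covariates=covariates,
        hazard_ratios=hrs,
        c_index=c_ci,
        logrank_p=logrank_p,
        td_auc=td,
        n=len(df),
        n_events=int(np.sum(e)),
        n_bootstrap=n_bootstrap,
        seed=seed,
        subset=subset,
        km_feature=km_feature,
        km_cutoff=km_cut,
        risk_orientation_flipped=bool(flipped),
    )


def subgroup_run(
    table: pd.DataFrame,
    mask: Sequence[bool],
    endpoint: str,
    covariates: Sequence[str],
    subset_label: str = "subgroup",
    min_patients: int = 20,
    min_events: int = 5,
    **kwargs,
) -> SurvivalReport:
    """Re-run the configured analysis on a patient subset.

    Guards against under-powered subsets (fewer than ``min_patients``
    patients or ``min_events`` events); the filter label is recorded on the
    report.
    """
    mask = np.asarray(mask, dtype=bool)
    sub = table.loc[mask].reset_index(drop=True)
    if len(sub) < min_patients:
        raise ValueError(f"subgroup has only {len(sub)} patients (< {min_patients})")
    n_ev = int(sub[f"{endpoint}_event"].sum())
    if n_ev < min_events:
        raise ValueError(f"subgroup has only {n_ev} events (< {min_events})")
    return analyze_endpoint(sub, endpoint, covariates, subset=subset_label, **kwargs)
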