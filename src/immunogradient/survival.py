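"""Recurrence-free-survival modeling pipeline.

Implements the statistical procedure around the gradient indicators:
administrative censoring, an event-stratified train/test split, univariable
Cox screening, exhaustive multivariable model enumeration with an
all-covariates-significant filter, 5-fold cross-validated ranking by
Harrell's C-index, Kaplan-Meier / log-rank stratification, tertile grouping
of continuous indicators, and the 3-point combined recurrence risk score.

Cox models are proportional-hazards fits by partial-likelihood maximisation
(Efron tie handling) via lifelines; a cohort is any pandas DataFrame with
``rfs_months`` (positive decimals) and ``event`` (0/1) columns plus
covariate columns.  Rows with missing covariate values are dropped per
model (complete-case analysis).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index

DURATION_COL = "rfs_months"
EVENT_COL = "event"
DEFAULT_HORIZON_MONTHS = 60.0
DEFAULT_ALPHA = 0.05


# ---------------------------------------------------------------------------
# cohort preparation
# ---------------------------------------------------------------------------

def censor_rfs(cohort: pd.DataFrame, horizon_months: float = DEFAULT_HORIZON_MONTHS) -> pd.DataFrame:
    """Administratively censor follow-up at ``horizon_months`` (default 5 years).

    Records with ``rfs_months`` beyond the horizon are truncated to the
    horizon with ``event = 0``; all others are unchanged.
    """
    if not horizon_months > 0:
        raise ValueError(f"horizon_months must be positive, got {horizon_months!r}")
    if (cohort[DURATION_COL] <= 0).any():
        raise ValueError("rfs_months must be positive")
    out = cohort.copy()
    over = out[DURATION_COL] > horizon_months
    out.loc[over, DURATION_COL] = horizon_months
    out.loc[over, EVENT_COL] = 0
    return out


def split_cohort(
    cohort: pd.DataFrame,
    n_train: int = 117,
    n_test: int = 40,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Event-stratified random split into training and hold-out test sets.

    Events and censored records are allocated proportionally (largest
    remainder to the training set), so the event proportions of the two sets
    differ by less than one event's worth.
    """
    n = len(cohort)
    if n_train + n_test != n:
        raise ValueError(f"n_train + n_test = {n_train + n_test} != cohort size {n}")
    rng = np.random.default_rng(seed)
    ev = cohort[EVENT_COL].to_numpy() != 0
    idx_e = np.flatnonzero(ev)
    idx_c = np.flatnonzero(~ev)
    rng.shuffle(idx_e)
    rng.shuffle(idx_c)
    ne_train = int(round(n_train * len(idx_e) / n))
    ne_train = min(max(ne_train, len(idx_e) - n_test), n_train, len(idx_e))
    nc_train = n_train - ne_train
    train_idx = np.concatenate([idx_e[:ne_train], idx_c[:nc_train]])
    test_idx = np.concatenate([idx_e[ne_train:], idx_c[nc_train:]])
    return cohort.iloc[np.sort(train_idx)], cohort.iloc[np.sort(test_idx)]


# ---------------------------------------------------------------------------
# Cox fitting
# ---------------------------------------------------------------------------

@dataclass
class CoxModelResult:
    """A fitted proportional-hazards model with its selection statistics."""

    covariates: tuple[str, ...]
    hr: dict[str, float]
    p: dict[str, float]
    coef: dict[str, float]
    se: dict[str, float]
    ci_lower: dict[str, float]  # 95% CI on the hazard ratio
    ci_upper: dict[str, float]
    log_likelihood: float
    aic: float
    n: int
    n_events: int
    converged: bool = True
    flag: str = ""
    tie_method: str = "Efron"
    train_c: float | None = None
    mean_validation_c: float | None = None
    test_c: float | None = None

    @property
    def all_significant(self) -> bool:
        return self.converged and all(self.p[c] < DEFAULT_ALPHA for c in self.covariates)

    def to_dict(self) -> dict:
        return {
            "covariates": list(self.covariates),
            "hr": self.hr,
            "p": self.p,
            "coef": self.coef,
            "se": self.se,
            "hr_ci95": {c: [self.ci_lower[c], self.ci_upper[c]] for c in self.covariates},
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "n": self.n,
            "n_events": self.n_events,
            "converged": self.converged,
            "flag": self.flag,
            "tie_method": self.tie_method,
            "train_c": self.train_c,
            "mean_validation_c": self.mean_validation_c,
            "test_c": self.test_c,
        }


def _fit_cox(cohort: pd.DataFrame, covariates: tuple[str, ...]) -> CoxModelResult:
    cols = [DURATION_COL, EVENT_COL, *covariates]
    data = cohort[cols].dropna()
    n, n_events = len(data), int(data[EVENT_COL].sum())
    if n_events < 1:
        raise ValueError("cohort has no events among complete cases")
    for c in covariates:
        if data[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant among complete cases")
    cph = CoxPHFitter()
    flag, converged = "", True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(data, duration_col=DURATION_COL, event_col=EVENT_COL)
        except ConvergenceError as err:
            return CoxModelResult(
                covariates=covariates,
                hr={c: float("nan") for c in covariates},
                p={c: float("nan") for c in covariates},
                coef={c: float("nan") for c in covariates},
                se={c: float("nan") for c in covariates},
                ci_lower={c: float("nan") for c in covariates},
                ci_upper={c: float("nan") for c in covariates},
                log_likelihood=float("nan"),
                aic=float("nan"),
                n=n,
                n_events=n_events,
                converged=False,
                flag=f"convergence failure: {err}",
            )
        for w in caught:
            if "convergence" in str(w.message).lower() or "collinear" in str(w.message).lower():
                flag = str(w.message).splitlines()[0]
    s = cph.summary
    k = len(covariates)
    return CoxModelResult(
        covariates=covariates,
        hr={c: float(s.loc[c, "exp(coef)"]) for c in covariates},
        p={c: float(s.loc[c, "p"]) for c in covariates},
        coef={c: float(s.loc[c, "coef"]) for c in covariates},
        se={c: float(s.loc[c, "se(coef)"]) for c in covariates},
        ci_lower={c: float(s.loc[c, "exp(coef) lower 95%"]) for c in covariates},
        ci_upper={c: float(s.loc[c, "exp(coef) upper 95%"]) for c in covariates},
        log_likelihood=float(cph.log_likelihood_),
        aic=float(2 * k - 2 * cph.log_likelihood_),
        n=n,
        n_events=n_events,
        converged=converged,
        flag=flag,
    )


def univariable_cox(cohort: pd.DataFrame, feature: str) -> CoxModelResult:
    """Single-covariate Cox fit: hazard ratio, Wald p, log-likelihood, AIC.

    Missing-covariate rows are dropped; non-convergence (e.g. complete
    separation) yields a flagged result rather than an exception.
    """
    return _fit_cox(cohort, (feature,))


def fit_multivariable(cohort: pd.DataFrame, covariates) -> CoxModelResult:
    """Multivariable Cox fit on an explicit covariate combination."""
    return _fit_cox(cohort, tuple(covariates))


def select_features(
    results: dict[str, CoxModelResult], alpha: float = DEFAULT_ALPHA
) -> list[str]:
    """Features whose univariable Wald p is strictly below ``alpha``."""
    return [
        f
        for f, r in results.items()
        if r.converged and np.isfinite(r.p[f]) and r.p[f] < alpha
    ]


def enumerate_models(features, min_size: int = 2) -> list[tuple[str, ...]]:
    """All covariate combinations of size >= ``min_size`` (deterministic order).

    Combinations that will prove redundant (e.g. containing both gradient
    indicators, or both history-flag variants) are enumerated too: they are
    expected to fail the all-significant filter, not to be pre-excluded.
    """
    feats = list(features)
    combos: list[tuple[str, ...]] = []
    for size in range(min_size, len(feats) + 1):
        combos.extend(itertools.combinations(feats, size))
    return combos


def fit_and_filter(
    train: pd.DataFrame, combos, alpha: float = DEFAULT_ALPHA
) -> list[CoxModelResult]:
    """Fit every combination on the training set; keep models in which every
    covariate's Wald p is strictly below ``alpha``.

    Non-converging fits (collinear duplicates, separation) are dropped.
    """
    kept = []
    for combo in combos:
        try:
            res = _fit_cox(train, tuple(combo))
        except ValueError:
            continue
        if res.converged and all(
            np.isfinite(res.p[c]) and res.p[c] < alpha for c in res.covariates
        ):
            kept.append(res)
    return kept


def profile_likelihood_ci(
    cohort: pd.DataFrame,
    covariates,
    target: str,
    level: float = 0.95,
) -> tuple[float, float]:
    """Profile-likelihood CI for one coefficient of a multivariable Cox model.

    The interval is the set of fixed values b of the target coefficient for
    which twice the profiled partial-log-likelihood drop from the maximum
    stays below the chi-square(1) quantile; the other coefficients are
    re-maximised at every b (fixed-offset refits).  Better calibrated than
    Wald intervals when the covariate distribution is skewed.  Returned on
    the log-hazard (coefficient) scale.
    """
    from scipy.optimize import brentq
    from scipy.stats import chi2
    from statsmodels.duration.hazard_regression import PHReg

    covariates = list(covariates)
    if target not in covariates:
        raise ValueError(f"target {target!r} not among covariates")
    data = cohort[[DURATION_COL, EVENT_COL, *covariates]].dropna()
    t = data[DURATION_COL].to_numpy()
    status = data[EVENT_COL].to_numpy()
    X = data[covariates].to_numpy(float)
    k = covariates.index(target)
    xk = X[:, k]
    others = [j for j in range(X.shape[1]) if j != k]
    Xo = X[:, others]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = PHReg(t, X, status=status, ties="efron").fit(disp=False)
        llmax = float(full.llf)
        bhat, se = float(full.params[k]), float(full.bse[k])
        crit = chi2.ppf(level, 1) / 2

        def drop(b: float) -> float:
            if others:
                m = PHReg(t, Xo, status=status, offset=b * xk, ties="efron").fit(
                    method="newton", start_params=full.params[others], disp=False
                )
                ll = float(m.llf)
            else:
                ll = float(PHReg(t, xk[:, None], status=status, ties="efron").loglike(
                    np.array([b])
                ))
            return (llmax - ll) - crit

        lo = brentq(drop, bhat - 8 * se, bhat, xtol=5e-3)
        hi = brentq(drop, bhat, bhat + 8 * se, xtol=5e-3)
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# concordance and cross-validation
# ---------------------------------------------------------------------------

def harrell_c(risks, times, events) -> float:
    """Harrell's concordance index for a risk score (higher risk = earlier event).

    Concordant comparable pairs over comparable pairs; pairs where the
    shorter time is censored are not comparable; ties in risk count 1/2.
    """
    risks = np.asarray(risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if not (len(risks) == len(times) == len(events)):
        raise ValueError("risks, times and events must have equal length")
    if len(times) < 2:
        raise ValueError("concordance needs at least two subjects")
    try:
        return float(concordance_index(times, -risks, events))
    except ZeroDivisionError as err:
        raise ValueError("no comparable pairs (all censored or single subject)") from err


def _stratified_folds(
    events: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold labels 0..k-1, event-stratified (round-robin after shuffling)."""
    fold = np.empty(len(events), dtype=int)
    for group in (np.flatnonzero(events), np.flatnonzero(~events)):
        g = group.copy()
        rng.shuffle(g)
        fold[g] = np.arange(len(g)) % k
    return fold


def cross_validate(
    train: pd.DataFrame,
    covariates,
    k: int = 5,
    seed: int | None = None,
) -> tuple[float, list[float]]:
    """K-fold cross-validated Harrell's C for one covariate combination.

    Folds are event-stratified and seeded.  Per fold the model is refitted
    on the other k-1 folds and scored on the held-out fold with the linear
    predictor as the risk score.  Returns (mean C, per-fold Cs).
    """
    covariates = tuple(covariates)
    if k < 2 or k > len(train):
        raise ValueError(f"k must be in [2, n], got {k}")
    if k == len(train):
        raise ValueError("leave-one-out folds carry no comparable pairs")
    data = train[[DURATION_COL, EVENT_COL, *covariates]].dropna().reset_index(drop=True)
    rng = np.random.default_rng(seed)
    fold = _stratified_folds(data[EVENT_COL].to_numpy() != 0, k, rng)
    cs = []
    for f in range(k):
        fit_part = data[fold != f]
        val_part = data[fold == f]
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(fit_part, duration_col=DURATION_COL, event_col=EVENT_COL)
        risk = cph.predict_log_partial_hazard(val_part[list(covariates)]).to_numpy()
        cs.append(
            harrell_c(risk, val_part[DURATION_COL].to_numpy(), val_part[EVENT_COL].to_numpy())
        )
    return float(np.mean(cs)), cs


def rank_models_by_cv(
    train: pd.DataFrame,
    models: list[CoxModelResult],
    k: int = 5,
    seed: int | None = None,
) -> list[CoxModelResult]:
    """Attach mean validation C to each model and sort best-first.

    Ties in mean validation C break toward lower AIC, then fewer covariates.
    """
    for m in models:
        m.mean_validation_c, _ = cross_validate(train, m.covariates, k=k, seed=seed)
    return sorted(
        models, key=lambda m: (-m.mean_validation_c, m.aic, len(m.covariates))
    )


def evaluate_on(cohort: pd.DataFrame, model: CoxModelResult, refit_on: pd.DataFrame) -> float:
    """Harrell's C of a model (fitted on ``refit_on``) applied to ``cohort``."""
    cph = CoxPHFitter()
    cols = [DURATION_COL, EVENT_COL, *model.covariates]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(refit_on[cols].dropna(), duration_col=DURATION_COL, event_col=EVENT_COL)
    data = cohort[cols].dropna()
    risk = cph.predict_log_partial_hazard(data[list(model.covariates)]).to_numpy()
    return harrell_c(risk, data[DURATION_COL].to_numpy(), data[EVENT_COL].to_numpy())


# ---------------------------------------------------------------------------
# non-parametric analysis and risk score
# ---------------------------------------------------------------------------

def km_logrank(
    cohort: pd.DataFrame, labels
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Kaplan-Meier curves per group plus pairwise two-sided log-rank p-values.

    ``labels`` is an array-like of group labels aligned with the cohort rows.
    Curves are returned as DataFrames (time, survival, at_risk); p-values are
    reported without multiplicity correction.
    """
    labels = np.asarray(labels)
    if len(labels) != len(cohort):
        raise ValueError("labels must align with cohort rows")
    groups = [g for g in pd.unique(labels)]
    curves: dict[str, pd.DataFrame] = {}
    for g in groups:
        sub = cohort[labels == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub[DURATION_COL], event_observed=sub[EVENT_COL])
        tbl = kmf.event_table
        curves[str(g)] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": tbl["at_risk"].reindex(kmf.survival_function_.index).to_numpy(),
            }
        )
    rows = []
    for a, b in itertools.combinations(groups, 2):
        sa, sb = cohort[labels == a], cohort[labels == b]
        res = logrank_test(
            sa[DURATION_COL], sb[DURATION_COL], sa[EVENT_COL], sb[EVENT_COL]
        )
        rows.append({"group_a": str(a), "group_b": str(b), "p": float(res.p_value)})
    return curves, pd.DataFrame(rows, columns=["group_a", "group_b", "p"])


def tertile_stratify(values) -> np.ndarray:
    """Split values into three equal-sized groups: low / medium / high.

    Group sizes differ by at most one; any remainder goes to the lower
    groups first (n = 10 -> 4/3/3).  Ties at tertile boundaries are broken
    by stable input order.  A constant input is flagged with a warning
    (stratification is then positional, not value-based).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 3:
        raise ValueError("need a 1-D array of at least 3 values")
    if np.nanmin(v) == np.nanmax(v):
        warnings.warn("degenerate stratification: all values identical", stacklevel=2)
    order = np.argsort(v, kind="stable")
    n = len(v)
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    labels = np.empty(n, dtype=object)
    start = 0
    for name, size in zip(("low", "medium", "high"), sizes):
        labels[order[start : start + size]] = name
        start += size
    return labels


@dataclass(frozen=True)
class RiskScore:
    """Combined recurrence risk score: 0-3 points mapped to three categories."""

    points: int
    category: str


_CATEGORY = {0: "low", 1: "low", 2: "intermediate", 3: "high"}


def risk_score(record) -> RiskScore:
    """Point-based recurrence risk score of one patient record.

    One point each for: G3 grade, positive reTUR or recurrent tumor, and a
    medium-or-high immunodrop tertile.  0-1 points -> low, 2 -> intermediate,
    3 -> high recurrence risk.

    ``record`` is any mapping (dict, Series) with fields ``grade`` (``"G3"``
    or truthy ``g3``), ``retur_or_recurrent`` and ``id_tertile``.
    """
    if "grade" in record:
        g3 = record["grade"] == "G3"
    else:
        g3 = bool(record["g3"])
    tertile = record["id_tertile"]
    if tertile not in ("low", "medium", "high"):
        raise ValueError(f"id_tertile must be low/medium/high, got {tertile!r}")
    points = int(g3) + int(bool(record["retur_or_recurrent"])) + int(tertile in ("medium", "high"))
    return RiskScore(points=points, category=_CATEGORY[points])


def score_cohort(cohort: pd.DataFrame, id_col: str = "id_value") -> pd.DataFrame:
    """Attach ID tertiles and the combined risk score to a cohort table."""
    out = cohort.copy()
    out["id_tertile"] = tertile_stratify(out[id_col].to_numpy())
    scores = [risk_score(row) for _, row in out.iterrows()]
    out["risk_points"] = [s.points for s in scores]
    out["risk_category"] = [s.category for s in scores]
    return out
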