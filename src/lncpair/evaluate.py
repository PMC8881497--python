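"""Risk-model evaluation under right censoring.

Time-dependent ROC/AUC at fixed horizons with inverse-probability-of-
censoring weights (cumulative cases / dynamic controls), optimal-cutpoint
selection, Kaplan-Meier / log-rank group comparison, and the
predictive-independence Cox tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

from lncpair.ingest import ClinicalTable
from lncpair.signature import Z_95, RiskProfile

logger = logging.getLogger(__name__)

#: Days per year used for horizon arithmetic.
YEAR_DAYS = 365.25

HIGH = "high"
LOW = "low"

#: Ordinal encodings for clinical covariates; unknown codes map to NaN and
#: are excluded from ordinal models.
_STAGE_MAP = {"i": 1, "ii": 2, "iii": 3, "iv": 4, "1": 1, "2": 2, "3": 3, "4": 4}
_GENDER_MAP = {"female": 0, "male": 1}
_GRADE_MAP = {"low": 0, "high": 1}


@dataclass
class TimeDependentROC:
    horizon: float
    thresholds: np.ndarray  # descending; leading +inf sentinel
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass
class CutoffResult:
    cutoff: float
    criterion: float  # TPR - FPR at the cutoff
    horizon: float


@dataclass
class SurvivalComparison:
    n_high: int
    n_low: int
    logrank_stat: float
    p: float
    km_curves: dict = field(default_factory=dict)


def _censoring_survival(time: np.ndarray, event: np.ndarray):
    """Kaplan-Meier estimate of the censoring distribution G(t) = P(C > t).

    Returns ``(unique_times, survival)``; evaluate with :func:`_g_eval`.
    """
    order = np.argsort(time, kind="mergesort")
    t = time[order]
    censored = 1 - event[order]
    uniq, first = np.unique(t, return_index=True)
    n = len(t)
    at_risk = n - first
    d = np.add.reduceat(censored, first)
    surv = np.cumprod(1.0 - d / at_risk)
    return uniq, surv


def _g_eval(uniq, surv, t, left=False):
    """Step-function evaluation of G; ``left=True`` gives the left limit G(t-)."""
    side = "left" if left else "right"
    idx = np.searchsorted(uniq, t, side=side) - 1
    out = np.where(idx >= 0, surv[np.clip(idx, 0, len(surv) - 1)], 1.0)
    return out


def _align_scores(profile: RiskProfile, clin: ClinicalTable):
    common = [s for s in profile.sample_ids if s in set(clin.sample_ids)]
    if not common:
        raise ValueError("no samples shared between risk profile and clinical table")
    sub = clin.subset(common)
    return (
        profile.rs[common].to_numpy(dtype=float),
        sub.time.to_numpy(dtype=float),
        sub.event.to_numpy(dtype=int),
        pd.Index(common),
    )


def td_roc(profile: RiskProfile, clin: ClinicalTable, horizon: float) -> TimeDependentROC:
    """IPCW cumulative-case / dynamic-control ROC at a fixed horizon.

    Cases are samples with an observed event by the horizon, weighted by
    1/G(T-); controls are samples still event-free past the horizon,
    weighted by 1/G(horizon). Samples censored before the horizon carry
    zero weight. With no censoring this reduces exactly to the classical
    binary ROC of event-by-horizon status against the score.
    """
    return _score_roc(*_align_scores(profile, clin)[:3], horizon=horizon)


def _score_roc(scores, time, event, horizon) -> TimeDependentROC:
    cases = (time <= horizon) & (event == 1)
    controls = time > horizon
    if not cases.any():
        raise ValueError(f"no cases at horizon {horizon}")
    if not controls.any():
        raise ValueError(f"no controls at horizon {horizon}")

    uniq, surv = _censoring_survival(time, event)
    g_tau = float(_g_eval(uniq, surv, np.array([horizon]), left=False)[0])
    if g_tau <= 0:
        raise ValueError("censoring survival reaches 0 before the horizon")
    w = np.zeros(len(scores))
    g_case = _g_eval(uniq, surv, time[cases], left=True)
    if (g_case <= 0).any():
        raise ValueError("zero censoring-survival weight for a case")
    w[cases] = 1.0 / g_case
    w[controls] = 1.0 / g_tau

    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    wc = np.where(cases, w, 0.0)[order]
    wk = np.where(controls, w, 0.0)[order]
    cum_case = np.cumsum(wc)
    cum_ctrl = np.cumsum(wk)
    # last position of each distinct score: classification rule is s >= c
    last = np.flatnonzero(np.r_[s[1:] != s[:-1], True])
    thresholds = np.r_[np.inf, s[last]]
    tpr = np.r_[0.0, cum_case[last] / cum_case[-1]]
    fpr = np.r_[0.0, cum_ctrl[last] / cum_ctrl[-1]]
    auc = float(np.trapezoid(tpr, fpr))
    return TimeDependentROC(
        horizon=float(horizon), thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc
    )


def optimal_cutoff(roc: TimeDependentROC) -> CutoffResult:
    """Grid point maximizing TPR - FPR; ties break toward the larger cutoff.

    The +inf sentinel is not a candidate. Degenerate score grids (all
    scores identical) are rejected.
    """
    finite = np.isfinite(roc.thresholds)
    if finite.sum() < 2:
        raise ValueError("all scores identical; no cutoff exists")
    j = roc.tpr - roc.fpr
    j[~finite] = -np.inf
    best = int(np.argmax(j))  # argmax returns the first (= largest) threshold
    return CutoffResult(
        cutoff=float(roc.thresholds[best]),
        criterion=float(j[best]),
        horizon=roc.horizon,
    )


def assign_groups(profile: RiskProfile, cutoff: float) -> RiskProfile:
    """rs > cutoff -> high risk; rs <= cutoff -> low risk."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    group = pd.Series(
        np.where(profile.rs.to_numpy(dtype=float) > cutoff, HIGH, LOW),
        index=profile.sample_ids,
        name="group",
    )
    return RiskProfile(rs=profile.rs, group=group)


def km_logrank(profile: RiskProfile, clin: ClinicalTable) -> SurvivalComparison:
    """Kaplan-Meier curves per risk group and the two-group log-rank test."""
    if profile.group is None:
        raise ValueError("risk profile has no group assignment")
    scores, time, event, ids = _align_scores(profile, clin)
    group = profile.group[ids].to_numpy()
    hi = group == HIGH
    lo = group == LOW
    if not hi.any() or not lo.any():
        raise ValueError("both risk groups must be non-empty")
    if event[hi].sum() == 0 and event[lo].sum() == 0:
        raise ValueError("no events in either risk group")

    res = logrank_test(time[hi], time[lo], event_observed_A=event[hi],
                       event_observed_B=event[lo])
    curves = {}
    for label, mask in ((HIGH, hi), (LOW, lo)):
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event_observed=event[mask], label=label)
        sf = kmf.survival_function_
        curves[label] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf[label].to_numpy()}
        )
    return SurvivalComparison(
        n_high=int(hi.sum()),
        n_low=int(lo.sum()),
        logrank_stat=float(res.test_statistic),
        p=float(res.p_value),
        km_curves=curves,
    )


def _norm_str(x) -> str | None:
    if pd.isna(x):
        return None
    return str(x).strip().lower()


def encode_clinical(clin: ClinicalTable) -> pd.DataFrame:
    """Ordinal encodings of clinical covariates for Cox/AUC models.

    stage I-IV -> 1-4; T1-4 -> 1-4; N0-3 -> 0-3; M0/M1 -> 0/1;
    grade low/high -> 0/1; gender female/male -> 0/1; age passes through
    numerically. Unknown codes (Tx/Nx/Mx, unparseable values) become NaN.
    """
    d = clin.data
    out = pd.DataFrame(index=d.index)

    def _map(col, fn):
        if col in d.columns:
            out[col] = [fn(_norm_str(v)) for v in d[col]]

    if "age" in d.columns:
        out["age"] = pd.to_numeric(d["age"], errors="coerce")
    _map("gender", lambda v: _GENDER_MAP.get(v, np.nan) if v else np.nan)
    _map("grade", lambda v: _GRADE_MAP.get(v, np.nan) if v else np.nan)
    _map(
        "stage",
        lambda v: _STAGE_MAP.get(v.replace("stage", "").strip(), np.nan) if v else np.nan,
    )

    def _tnm(prefix, lo, hi):
        def enc(v):
            if not v or not v.startswith(prefix):
                return np.nan
            code = v[len(prefix):][:1]
            if code.isdigit() and lo <= int(code) <= hi:
                return int(code)
            return np.nan  # x-codes and anything unassessable
        return enc

    _map("T", _tnm("t", 1, 4))
    _map("N", _tnm("n", 0, 3))
    _map("M", _tnm("m", 0, 1))
    known = {"age", "gender", "grade", "stage", "T", "N", "M", "time", "event"}
    for col in d.columns:  # extra numeric covariates pass through
        if col not in known and np.issubdtype(d[col].dtype, np.number):
            out[col] = d[col].astype(float)
    return out


def _fit_cox(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    X = df[covariates + ["time", "event"]].dropna()
    std = X[covariates].to_numpy(dtype=float)
    if len(covariates) > 1:
        sd = std.std(axis=0)
        sd[sd == 0] = 1.0
        cond = float(np.linalg.cond((std - std.mean(axis=0)) / sd))
        if not np.isfinite(cond) or cond > 1e8:
            warnings.warn(
                f"collinear covariates (condition number {cond:.3g})", stacklevel=3
            )
    cph = CoxPHFitter()
    try:
        cph.fit(X, duration_col="time", event_col="event")
    except ConvergenceError:
        warnings.warn("Cox fit unstable; retrying with a small ridge penalty",
                      stacklevel=3)
        cph = CoxPHFitter(penalizer=0.01)
        cph.fit(X, duration_col="time", event_col="event")
    betas = cph.params_
    ses = cph.standard_errors_
    return pd.DataFrame(
        {
            "coef": betas.to_numpy(),
            "hr": np.exp(betas.to_numpy()),
            "hr_low": np.exp(betas.to_numpy() - Z_95 * ses.to_numpy()),
            "hr_high": np.exp(betas.to_numpy() + Z_95 * ses.to_numpy()),
            "p": cph.summary["p"].to_numpy(),
            "n": len(X),
        },
        index=pd.Index(betas.index, name="covariate"),
    )


def independence_analysis(
    profile: RiskProfile, clin: ClinicalTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Uni- and multivariate Cox tables over clinical covariates plus RS.

    Univariate rows use all samples non-missing for that covariate; the
    multivariate fit uses complete cases across all covariates.
    """
    _, _, _, ids = _align_scores(profile, clin)
    sub = clin.subset(ids)
    enc = encode_clinical(sub)
    enc["risk_score"] = profile.rs[ids].to_numpy(dtype=float)
    enc["time"] = sub.time.to_numpy(dtype=float)
    enc["event"] = sub.event.to_numpy(dtype=int)
    covariates = [c for c in enc.columns if c not in ("time", "event")]

    uni_rows = []
    for cov in covariates:
        if enc[cov].dropna().nunique() < 2:
            warnings.warn(f"covariate {cov!r} is constant; skipped", stacklevel=2)
            continue
        uni_rows.append(_fit_cox(enc, [cov]))
    uni = pd.concat(uni_rows) if uni_rows else pd.DataFrame()
    usable = [c for c in covariates if enc[c].dropna().nunique() >= 2]
    multi = _fit_cox(enc, usable)
    return uni, multi


def compare_auc(
    profile: RiskProfile, clin: ClinicalTable, horizon: float = YEAR_DAYS
) -> pd.DataFrame:
    """Horizon AUC for the risk score and each ordinally-encoded covariate.

    Constant or unresolvable covariates are skipped with a warning and
    appear as missing rows.
    """
    _, time, event, ids = _align_scores(profile, clin)
    sub = clin.subset(ids)
    enc = encode_clinical(sub)
    enc.insert(0, "risk_score", profile.rs[ids].to_numpy(dtype=float))

    rows = []
    for cov in enc.columns:
        vals = enc[cov]
        ok = vals.notna().to_numpy()
        if vals.dropna().nunique() < 2:
            warnings.warn(f"predictor {cov!r} is constant or missing; skipped",
                          stacklevel=2)
            continue
        try:
            roc = _score_roc(vals.to_numpy(dtype=float)[ok], time[ok], event[ok], horizon)
        except ValueError as err:
            warnings.warn(f"predictor {cov!r}: {err}; skipped", stacklevel=2)
            continue
        rows.append({"predictor": cov, "auc": roc.auc, "n": int(ok.sum())})
    return pd.DataFrame(rows).set_index("predictor")
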