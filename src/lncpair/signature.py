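"""Prognostic signature fitting over pair indicators.

Three-stage selection: per-pair univariate Cox screen, repeated
cross-validated LASSO-Cox with selection-frequency accounting, and a final
joint Cox fit whose coefficients define the risk score
RS(sample) = sum_i beta_i * S_i(sample).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from lncpair.ingest import ClinicalTable
from lncpair.pairing import PairMatrix

logger = logging.getLogger(__name__)

Z_95 = 1.96


@dataclass
class UniCoxRow:
    pair: str
    beta: float
    hr: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class StabilityCount:
    pair: str
    frequency: int


@dataclass
class SignatureModel:
    """Selected pairs with Cox coefficients and Wald statistics.

    ``table`` is indexed by pair name with columns
    coef / hr / hr_low / hr_high / p; ``meta`` records fit provenance.
    """

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("duplicate pairs in signature model")

    @property
    def pairs(self) -> list[str]:
        return list(self.table.index)

    @property
    def betas(self) -> pd.Series:
        return self.table["coef"]

    @classmethod
    def from_coefficients(cls, coefficients: dict, meta: dict | None = None) -> "SignatureModel":
        """Build a model from bare coefficients (hr derived as exp(coef))."""
        idx = pd.Index(list(coefficients), name="pair")
        coefs = np.array([float(coefficients[k]) for k in idx])
        table = pd.DataFrame(
            {
                "coef": coefs,
                "hr": np.exp(coefs),
                "hr_low": np.nan,
                "hr_high": np.nan,
                "p": np.nan,
            },
            index=idx,
        )
        return cls(table, meta or {"source": "coefficients"})

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="pair")


@dataclass
class RiskProfile:
    """Per-sample risk score, optionally with a high/low group label."""

    rs: pd.Series
    group: pd.Series | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.rs.to_numpy(dtype=float)).all():
            raise ValueError("risk scores must be finite")

    @property
    def sample_ids(self) -> pd.Index:
        return self.rs.index


def _align(pairs: PairMatrix, clin: ClinicalTable):
    """Common samples (pair-matrix order) with time/event arrays."""
    common = [s for s in pairs.sample_ids if s in set(clin.sample_ids)]
    if not common:
        raise ValueError("no samples shared between pair matrix and clinical table")
    sub = clin.subset(common)
    return pairs.subset_samples(common), sub


def _wald_row(pair: str, beta: float, se: float, p: float) -> UniCoxRow:
    return UniCoxRow(
        pair=pair,
        beta=beta,
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z_95 * se)),
        ci_high=float(np.exp(beta + Z_95 * se)),
        p=p,
    )


def univariate_cox_screen(
    pairs: PairMatrix,
    clin: ClinicalTable,
    p_threshold: float = 0.05,
    return_all: bool = False,
) -> list[UniCoxRow]:
    """Single-covariate Cox fit (Efron ties) per pair; keep Wald p < threshold.

    Constant pairs and non-converging fits are skipped with a warning.
    """
    pairs, clin = _align(pairs, clin)
    if int(clin.event.sum()) == 0:
        raise ValueError("no events in cohort; cannot fit Cox models")
    base = pd.DataFrame(
        {"time": clin.time.to_numpy(dtype=float), "event": clin.event.to_numpy(dtype=int)},
        index=clin.sample_ids,
    )
    rows: list[UniCoxRow] = []
    n_constant = 0
    for name in pairs.pair_names:
        x = pairs.indicators.loc[name]
        if x.nunique() < 2:
            n_constant += 1
            continue
        df = base.copy()
        df["x"] = x.to_numpy(dtype=float)
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except ConvergenceError:
            warnings.warn(f"univariate Cox failed to converge for pair {name!r}; skipped",
                          stacklevel=2)
            continue
        beta = float(cph.params_["x"])
        se = float(cph.standard_errors_["x"])
        p = float(cph.summary.loc["x", "p"])
        rows.append(_wald_row(name, beta, se, p))
    if n_constant:
        warnings.warn(f"{n_constant} constant pair(s) skipped in univariate screen",
                      stacklevel=2)
    if return_all:
        return rows
    passing = [r for r in rows if r.p < p_threshold]
    logger.info("univariate Cox screen: %d/%d pairs pass p < %g",
                len(passing), pairs.n_pairs, p_threshold)
    return passing


def _breslow_pll(eta: np.ndarray, time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Breslow partial log-likelihood for each column of the linear
    predictor matrix ``eta`` (n_samples x n_models)."""
    order = np.argsort(time, kind="mergesort")
    time = time[order]
    event = event[order].astype(bool)
    eta = eta[order]
    shift = eta.max(axis=0, keepdims=True)
    ex = np.exp(eta - shift)
    # reverse cumulative sum = sum over risk set {j : time_j >= t_i}
    rcs = np.cumsum(ex[::-1], axis=0)[::-1]
    # map each position to the first index of its tie group so ties share
    # the full risk set
    first_idx = np.searchsorted(time, time, side="left")
    log_risk = np.log(rcs[first_idx])
    return (eta[event] - shift - log_risk[event]).sum(axis=0)


def _stratified_folds(event: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold labels balanced on event status."""
    fold = np.empty(len(event), dtype=int)
    for mask in (event == 1, event == 0):
        idx = np.flatnonzero(mask)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def lasso_stability_select(
    pairs: PairMatrix,
    clin: ClinicalTable,
    n_reps: int = 1000,
    n_folds: int = 10,
    freq_threshold: int = 100,
    seed: int | None = None,
    n_alphas: int = 50,
    alpha_min_ratio: float = 0.01,
) -> tuple[list[StabilityCount], list[str]]:
    """Repeated cross-validated LASSO-Cox with selection-frequency counting.

    Each cycle draws a fresh event-stratified fold assignment, scores the
    shared penalty path by the Verweij-van Houwelingen cross-validated
    partial-likelihood deviance, and counts the pairs with nonzero
    coefficients in the full-data fit at the deviance-minimizing penalty.
    Pairs appearing in strictly more than ``freq_threshold`` cycles are
    selected.
    """
    pairs, clin = _align(pairs, clin)
    time = clin.time.to_numpy(dtype=float)
    event = clin.event.to_numpy(dtype=int)
    if int(event.sum()) < n_folds:
        raise ValueError(
            f"need >= {n_folds} events for {n_folds}-fold CV, got {int(event.sum())}"
        )
    X = pairs.indicators.to_numpy(dtype=float).T  # samples x pairs
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    names = list(pairs.pair_names)

    full = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=alpha_min_ratio
    )
    full.fit(X, y)
    alphas = full.alphas_
    full_coefs = full.coef_  # p x n_alphas

    rng = np.random.default_rng(seed)
    counts = np.zeros(len(names), dtype=int)
    for _ in range(n_reps):
        fold = _stratified_folds(event, n_folds, rng)
        dev = np.zeros(len(alphas))
        for k in range(n_folds):
            train = fold != k
            model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X[train], y[train])
            B = model.coef_
            if B.shape[1] < len(alphas):  # path terminated early; pad
                B = np.hstack([B, np.repeat(B[:, -1:], len(alphas) - B.shape[1], axis=1)])
            pll_all = _breslow_pll(X @ B, time, event)
            pll_train = _breslow_pll(X[train] @ B, time[train], event[train])
            dev += -2.0 * (pll_all - pll_train)
        best = int(np.argmin(dev))
        counts[np.abs(full_coefs[:, best]) > 0] += 1

    if counts.sum() == 0:
        raise ValueError(
            "no pair was ever selected across all LASSO cycles; "
            "review penalty path and thresholds"
        )
    stability = [StabilityCount(pair=n, frequency=int(c)) for n, c in zip(names, counts)]
    selected = [n for n, c in zip(names, counts) if c > freq_threshold]
    logger.info(
        "stability selection: %d/%d pairs with frequency > %d over %d cycles",
        len(selected), len(names), freq_threshold, n_reps,
    )
    return stability, selected


def fit_multivariate_cox(pairs: PairMatrix, clin: ClinicalTable) -> SignatureModel:
    """Joint Cox fit over the selected pair indicators.

    Emits per-pair coefficient, HR = exp(coef) and Wald 95% limits.
    Warns when events are scarce relative to the number of pairs or when a
    coefficient is large enough to suggest separation.
    """
    if pairs.n_pairs == 0:
        raise ValueError("no pairs supplied to multivariate Cox fit")
    pairs, clin = _align(pairs, clin)
    n_events = int(clin.event.sum())
    if n_events <= pairs.n_pairs:
        warnings.warn(
            f"only {n_events} events for {pairs.n_pairs} pairs; estimates may be unstable",
            stacklevel=2,
        )
    df = pairs.indicators.T.astype(float)
    df["time"] = clin.time.to_numpy(dtype=float)
    df["event"] = clin.event.to_numpy(dtype=int)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as err:
        raise RuntimeError(
            f"multivariate Cox fit failed to converge for {pairs.n_pairs} pairs "
            f"on {len(df)} samples ({n_events} events): {err}"
        ) from err
    betas = cph.params_
    if (betas.abs() > 10).any():
        warnings.warn("very large coefficient(s); possible separation", stacklevel=2)
    ses = cph.standard_errors_
    table = pd.DataFrame(
        {
            "coef": betas.to_numpy(),
            "hr": np.exp(betas.to_numpy()),
            "hr_low": np.exp(betas.to_numpy() - Z_95 * ses.to_numpy()),
            "hr_high": np.exp(betas.to_numpy() + Z_95 * ses.to_numpy()),
            "p": cph.summary["p"].to_numpy(),
        },
        index=pd.Index(betas.index, name="pair"),
    )
    meta = {
        "n_samples": int(len(df)),
        "n_events": n_events,
        "ties": "efron",
        "converged": True,
    }
    return SignatureModel(table, meta)


def risk_score(model: SignatureModel, pairs: PairMatrix) -> RiskProfile:
    """RS(sample) = sum_i beta_i * S_i(sample) over the model's pairs."""
    missing = [p for p in model.pairs if p not in set(pairs.pair_names)]
    if missing:
        raise KeyError(f"pair(s) missing from pair matrix: {missing}")
    S = pairs.indicators.loc[model.pairs].to_numpy(dtype=float)
    rs = model.betas.to_numpy() @ S
    return RiskProfile(rs=pd.Series(rs, index=pairs.sample_ids, name="risk_score"))
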