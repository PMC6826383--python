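"""Prognostic evaluation statistics.

AUC (Mann-Whitney) with normal-approximation inference and Harrell-style
bootstrap optimism correction, X-tile-style optimal cutpoint by maximally
selected log-rank statistic, Cox proportional hazards (Breslow ties, via
statsmodels PHReg) with backward elimination, the reverse Kaplan-Meier
median follow-up, and the Hanley-McNeil ROC sample-size calculation.

Orientation convention: the AUC is reported as computed — values below 0.5
indicate association with *low* risk and are never flipped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AUCResult",
    "CoxResult",
    "auc_mann_whitney",
    "bootstrap_correct",
    "auc_with_optimism",
    "logrank_chi2",
    "optimal_cutpoint",
    "cox_fit",
    "backward_elimination",
    "reverse_km_median",
    "roc_sample_size",
]


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AUCResult:
    """Discrimination of a continuous feature for a binary endpoint."""

    auc: float
    ci95: tuple[float, float]
    p_value: float
    n_pos: int
    n_neg: int
    corrected_auc: float | None = None
    boot_ci95: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (self.ci95[0] <= self.auc <= self.ci95[1]):
            raise ValueError("CI must bracket the AUC")


def _auc_value(values: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with tie handling via midranks."""
    ranks = stats.rankdata(values)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    r_pos = ranks[labels == 1].sum()
    u = r_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def auc_mann_whitney(values, labels) -> AUCResult:
    """AUC of a continuous feature against an event indicator.

    ``auc = (#(pos > neg) + 0.5 #ties) / (n_pos * n_neg)``.  The p-value is
    the two-sided normal approximation of the Mann-Whitney statistic with
    tie correction; the CI uses the Hanley-McNeil variance at the observed
    AUC.  Orientation is never flipped.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels, int)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be equal-length 1-D arrays")
    if np.isnan(values).any():
        raise ValueError("values contain NaN")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")

    auc = _auc_value(values, labels)
    n = n_pos + n_neg
    u = auc * n_pos * n_neg

    # tie-corrected null variance of U
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n_pos * n_neg / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        p = 1.0
    else:
        zstat = (u - n_pos * n_neg / 2.0) / math.sqrt(var_u)
        p = 2.0 * stats.norm.sf(abs(zstat))

    se = _hanley_mcneil_se(auc, n_pos, n_neg)
    lo = max(0.0, auc - 1.959964 * se)
    hi = min(1.0, auc + 1.959964 * se)
    return AUCResult(auc=auc, ci95=(lo, hi), p_value=p, n_pos=n_pos, n_neg=n_neg)


def _hanley_mcneil_se(theta: float, n_pos: int, n_neg: int) -> float:
    q1 = theta / (2.0 - theta)
    q2 = 2.0 * theta**2 / (1.0 + theta)
    var = (
        theta * (1.0 - theta)
        + (n_pos - 1) * (q1 - theta**2)
        + (n_neg - 1) * (q2 - theta**2)
    ) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


# ---------------------------------------------------------------------------
# bootstrap optimism correction
# ---------------------------------------------------------------------------

def _stratified_indices(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Resample within each outcome class (keeps both classes populated)."""
    idx = np.arange(len(labels))
    out = []
    for cls in (0, 1):
        members = idx[labels == cls]
        out.append(rng.choice(members, size=len(members), replace=True))
    return np.concatenate(out)


def bootstrap_correct(
    statistic,
    data: pd.DataFrame,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
    stratify: str | None = "event",
    indices: np.ndarray | None = None,
):
    """Harrell-style optimism correction of a performance statistic.

    ``statistic(fit_df, eval_df) -> float`` derives its rule (cutpoints,
    orientation, ...) on ``fit_df`` and evaluates it on ``eval_df``.  The
    optimism is the mean over bootstrap resamples of
    ``statistic(resample, resample) - statistic(resample, original)`` and is
    subtracted from the apparent estimate.  Resamples are stratified by the
    ``stratify`` column (pass None to disable); degenerate single-class
    resamples are redrawn and counted.

    Returns
    -------
    dict with ``apparent``, ``corrected``, ``optimism``, ``percentile_ci``
    (2.5/97.5 percentiles of the resample statistics), ``n_redrawn``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    data = data.reset_index(drop=True)
    apparent = float(statistic(data, data))
    boot_stats = np.empty(B)
    optimism = np.empty(B)
    n_redrawn = 0
    labels = data[stratify].to_numpy() if stratify is not None else None
    for b in range(B):
        if indices is not None:
            take = indices[b]
        elif labels is not None:
            take = _stratified_indices(labels, rng)
        else:
            take = rng.integers(0, len(data), len(data))
            if stratify is None and "event" in data:
                # redraw degenerate resamples (single outcome class)
                while data["event"].to_numpy()[take].std() == 0:
                    n_redrawn += 1
                    take = rng.integers(0, len(data), len(data))
        res = data.iloc[take].reset_index(drop=True)
        s_res = float(statistic(res, res))
        s_orig = float(statistic(res, data))
        boot_stats[b] = s_res
        optimism[b] = s_res - s_orig
    corrected = apparent - optimism.mean()
    return dict(
        apparent=apparent,
        corrected=float(corrected),
        optimism=float(optimism.mean()),
        percentile_ci=(float(np.percentile(boot_stats, 2.5)),
                       float(np.percentile(boot_stats, 97.5))),
        n_redrawn=n_redrawn,
    )


def auc_with_optimism(
    values, labels, B: int = 1000, seed: int | np.random.Generator = 0
) -> AUCResult:
    """AUC with vectorized stratified-bootstrap optimism correction.

    For the AUC the resample-derived "rule" is the feature itself, so the
    statistic evaluated back on the original data is the apparent AUC and
    the optimism reduces to ``mean(AUC_b) - AUC_apparent``.  Vectorized over
    resamples (midranks per resample row) so the screening grid can afford
    B = 1000 per record.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = auc_mann_whitney(values, labels)
    values = np.asarray(values, float)
    labels = np.asarray(labels, int)
    idx = np.arange(len(labels))
    pos, neg = idx[labels == 1], idx[labels == 0]
    take_pos = rng.choice(pos, size=(B, len(pos)), replace=True)
    take_neg = rng.choice(neg, size=(B, len(neg)), replace=True)
    take = np.hstack([take_neg, take_pos])
    v = values[take]
    ranks = stats.rankdata(v, axis=1)
    r_pos = ranks[:, len(neg):].sum(axis=1)
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    boot = u / (len(pos) * len(neg))
    corrected = 2.0 * base.auc - float(boot.mean())
    return AUCResult(
        auc=base.auc,
        ci95=base.ci95,
        p_value=base.p_value,
        n_pos=base.n_pos,
        n_neg=base.n_neg,
        corrected_auc=float(np.clip(corrected, 0.0, 1.0)),
        boot_ci95=(float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5))),
    )


# ---------------------------------------------------------------------------
# log-rank and optimal cutpoint
# ---------------------------------------------------------------------------

def logrank_chi2(time, event, group) -> float:
    """Two-sample log-rank chi-square statistic (1 df).

    Hand-vectorized (the cutpoint search evaluates it thousands of times);
    cross-checked against lifelines in the test suite.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, int)
    event_times = np.unique(time[event == 1])
    # at-risk and event counts per distinct event time
    o1 = e1 = v = 0.0
    for t in event_times:
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if v <= 0:
        return 0.0
    return float((o1 - e1) ** 2 / v)


def _logrank_all_cutpoints(values, time, event, min_frac):
    """Log-rank chi-square for every admissible midpoint cutpoint, vectorized.

    Group 1 is ``value > cut``.  Returns (cutpoints, chi2s, balance) where
    balance is the absolute high/low group-size difference.
    """
    values = np.asarray(values, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    n = len(values)
    distinct = np.unique(values)
    if distinct.size < 2:
        return np.array([]), np.array([]), np.array([])
    cuts = (distinct[:-1] + distinct[1:]) / 2.0
    n_hi = (values[None, :] > cuts[:, None]).sum(axis=1)
    n_lo = n - n_hi
    min_n = min_frac * n
    ok = (n_hi >= min_n) & (n_lo >= min_n)
    cuts = cuts[ok]
    if cuts.size == 0:
        return np.array([]), np.array([]), np.array([])

    ev_times = np.unique(time[event == 1])
    at_risk = time[None, :] >= ev_times[:, None]          # (T, n)
    is_ev = (time[None, :] == ev_times[:, None]) & (event[None, :] == 1)
    n_t = at_risk.sum(axis=1).astype(float)               # (T,)
    d_t = is_ev.sum(axis=1).astype(float)

    grp = values[None, :] > cuts[:, None]                 # (C, n)
    n1 = at_risk.astype(float) @ grp.T.astype(float)      # (T, C)
    d1 = is_ev.astype(float) @ grp.T.astype(float)
    frac = n1 / n_t[:, None]
    o_minus_e = (d1 - d_t[:, None] * frac).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        vt = d_t[:, None] * frac * (1 - frac) * ((n_t[:, None] - d_t[:, None]) /
                                                 np.maximum(n_t[:, None] - 1, 1))
    v = vt.sum(axis=0)
    chi2 = np.where(v > 0, o_minus_e**2 / np.maximum(v, 1e-300), 0.0)
    balance = np.abs((values[None, :] > cuts[:, None]).sum(axis=1) * 2 - n)
    return cuts, chi2, balance


def optimal_cutpoint(values, time, event, min_group_fraction: float = 0.10) -> float:
    """X-tile-style optimal cutpoint: maximally selected log-rank statistic.

    Every midpoint between adjacent distinct values whose split leaves both
    groups with at least ``min_group_fraction`` of patients is evaluated;
    ties in the statistic break toward the more balanced split, then toward
    the smaller cutpoint.
    """
    values = np.asarray(values, float)
    if np.unique(values).size < 2:
        raise ValueError("optimal_cutpoint requires >= 2 distinct values")
    cuts, chi2, balance = _logrank_all_cutpoints(values, time, event, min_group_fraction)
    if cuts.size == 0:
        raise ValueError("no admissible split at the requested minimum group fraction")
    order = np.lexsort((cuts, balance, -chi2))  # chi2 desc, then balanced, then low cut
    return float(cuts[order[0]])


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoxResult:
    """A fitted proportional-hazards model."""

    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    hr_ci95: np.ndarray  # (k, 2)
    p_values: np.ndarray
    n: int
    n_events: int
    cutpoint: float | None = None
    ties: str = "breslow"

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                coef=self.coef,
                se=self.se,
                HR=self.hr,
                HR_lo=self.hr_ci95[:, 0],
                HR_hi=self.hr_ci95[:, 1],
                p=self.p_values,
            ),
            index=list(self.names),
        )


def cox_fit(covariates, time, event, ties: str = "breslow") -> CoxResult:
    """Cox proportional-hazards fit (partial likelihood, Breslow ties).

    ``covariates`` is a DataFrame (or 2-D array) of finite covariate values.
    Raises on datasets without events and on monotone-likelihood (perfect
    separation) failures, which surface as non-convergence or exploding
    coefficients.
    """
    from statsmodels.duration.hazard_regression import PHReg

    X = pd.DataFrame(covariates).copy()
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if event.sum() < 1:
        raise ValueError("Cox regression requires at least one event")
    if not np.isfinite(X.to_numpy(float)).all():
        raise ValueError("covariates must be finite")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = PHReg(time, X.to_numpy(float), status=event, ties=ties)
        fit = model.fit()
    coef = np.asarray(fit.params, float)
    se = np.asarray(fit.bse, float)
    if (
        not np.isfinite(coef).all()
        or not np.isfinite(se).all()
        or np.abs(coef).max() > 50
        or np.abs(se).max() > 100
    ):
        raise RuntimeError(
            "Cox fit did not converge (monotone likelihood / perfect separation?); "
            f"coefficients {coef}, se {se}"
        )
    z = 1.959964
    hr = np.exp(coef)
    ci = np.column_stack([np.exp(coef - z * se), np.exp(coef + z * se)])
    p = 2.0 * stats.norm.sf(np.abs(coef / se))
    return CoxResult(
        names=tuple(str(c) for c in X.columns),
        coef=coef,
        se=se,
        hr=hr,
        hr_ci95=ci,
        p_values=p,
        n=len(time),
        n_events=int(event.sum()),
        ties=ties,
    )


def backward_elimination(
    candidates: pd.DataFrame,
    time,
    event,
    p_enter: float = 0.2,
    p_stay: float = 0.05,
) -> tuple[list[str], CoxResult | None]:
    """Univariate entry screen then backward elimination.

    Candidates whose univariate Cox p exceeds ``p_enter`` never enter; the
    multivariate model then repeatedly drops the largest-p covariate with
    p >= ``p_stay`` (ties drop the later-listed) until all remaining
    covariates satisfy p < ``p_stay``.  Returns the retained names and the
    final fit (None when nothing survives).
    """
    candidates = pd.DataFrame(candidates)
    entered = []
    for col in candidates.columns:
        try:
            uni = cox_fit(candidates[[col]], time, event)
        except (ValueError, RuntimeError):
            continue
        if uni.p_values[0] <= p_enter:
            entered.append(col)
    current = list(entered)
    fit = None
    while current:
        fit = cox_fit(candidates[current], time, event)
        p = fit.p_values
        if (p < p_stay).all():
            return current, fit
        worst = max(range(len(current)), key=lambda i: (p[i], i))
        current.pop(worst)
        fit = None
    return [], None


# ---------------------------------------------------------------------------
# follow-up and sample size
# ---------------------------------------------------------------------------

def reverse_km_median(time, event) -> float:
    """Median follow-up by reverse Kaplan-Meier (censoring as the event).

    Returns the first time the censoring survivor function drops to <= 0.5.
    Raises if every observation is an event (no censoring to estimate).
    """
    from lifelines import KaplanMeierFitter

    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if (event == 1).all():
        raise ValueError("median follow-up undefined: no censored observations")
    km = KaplanMeierFitter()
    km.fit(time, event_observed=1 - event)
    med = km.median_survival_time_
    if not np.isfinite(med):
        raise ValueError("censoring survivor function never reaches 0.5")
    return float(med)


def roc_sample_size(
    alpha: float = 0.05,
    power: float = 0.80,
    auc_alt: float = 0.72,
    neg_per_pos: float = 4.0,
) -> tuple[int, int]:
    """Smallest positive-case count for a two-sided ROC test (Hanley-McNeil).

    Finds the smallest ``n_pos`` such that
    ``z_{alpha/2} * SE0 + z_beta * SE1 <= auc_alt - 0.5`` with Hanley-McNeil
    variances under the null (AUC 0.5) and the alternative, with
    ``neg_per_pos`` negatives per positive.  Returns
    ``(n_pos, n_total = n_pos * (1 + neg_per_pos))``.
    """
    if not 0.5 < auc_alt < 1.0:
        raise ValueError("auc_alt must lie strictly between 0.5 and 1")
    if neg_per_pos < 1:
        raise ValueError("neg_per_pos must be >= 1")
    z_a = stats.norm.isf(alpha / 2.0)
    z_b = stats.norm.isf(1.0 - power)
    delta = auc_alt - 0.5
    for n_pos in range(2, 100000):
        n_neg = int(round(neg_per_pos * n_pos))
        se0 = _hanley_mcneil_se(0.5, n_pos, n_neg)
        se1 = _hanley_mcneil_se(auc_alt, n_pos, n_neg)
        if z_a * se0 + z_b * se1 <= delta:
            return n_pos, n_pos + n_neg
    raise RuntimeError("sample-size search did not terminate")


def schoenfeld_ph_test(covariates, time, event) -> pd.DataFrame:
    """Optional proportional-hazards diagnostic (Schoenfeld residuals).

    Thin wrapper around lifelines' test; returns a table of per-covariate
    test statistics and p-values.  Diagnostic only — no gating.
    """
    from lifelines import CoxPHFitter
    from lifelines.statistics import proportional_hazard_test

    df = pd.DataFrame(covariates).copy()
    df["_time"] = np.asarray(time, float)
    df["_event"] = np.asarray(event, int)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="_time", event_col="_event")
    res = proportional_hazard_test(cph, df, time_transform="km")
    return res.summary
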