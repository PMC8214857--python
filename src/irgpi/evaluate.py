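"""Prognostic performance statistics for a risk score on censored survival data.

Covers the standard evaluation battery for a prognostic index: Kaplan-Meier
curves with the two-sample log-rank test, multivariate Cox adjustment for
clinical covariates, Harrell's concordance index (with an 80%-resampling
stability protocol), cumulative/dynamic time-dependent AUC with inverse
probability of censoring weights, and the restricted mean survival time
ratio between risk groups.

Kaplan-Meier estimation, the log-rank test, the multivariate Cox fit and
the concordance index are delegated to lifelines; the IPCW AUC and the
resampling protocol are implemented here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex
from lifelines.utils import restricted_mean_survival_time

from .errors import EmptyInputError, ParameterError, ValidationError
from .score import HRISK, LRISK

logger = logging.getLogger(__name__)


def _as_groups(groups: Sequence[str]) -> np.ndarray:
    g = np.asarray(list(groups))
    labels = set(g.tolist())
    if not labels.issubset({HRISK, LRISK}):
        raise ValidationError(f"group labels must be {{{HRISK}, {LRISK}}}, got {sorted(labels)}")
    return g


def _check_alignment(n: int, surv: pd.DataFrame) -> None:
    if n != surv.shape[0]:
        raise ValidationError("scores/groups and survival table have different lengths")


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank


@dataclass
class LogrankResult:
    chi2: float
    p: float
    km_curves: dict[str, pd.DataFrame]


def km_logrank(groups: Sequence[str], surv: pd.DataFrame) -> LogrankResult:
    """Per-group product-limit curves and the two-sample log-rank test."""
    g = _as_groups(groups)
    _check_alignment(g.size, surv)
    time = surv["time"].to_numpy()
    event = surv["event"].to_numpy()
    curves: dict[str, pd.DataFrame] = {}
    for label in (HRISK, LRISK):
        mask = g == label
        if not mask.any():
            raise EmptyInputError(f"group {label} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask], label=label)
        curves[label] = kmf.survival_function_.rename(columns={label: "survival"})
    hi = g == HRISK
    res = logrank_test(time[hi], time[~hi], event_observed_A=event[hi], event_observed_B=event[~hi])
    return LogrankResult(float(res.test_statistic), float(res.p_value), curves)


# ---------------------------------------------------------------------------
# multivariate Cox


def cox_multivariate(surv: pd.DataFrame, covariates: Sequence[str] | None = None) -> pd.DataFrame:
    """Multivariate Cox PH fit (Efron ties); HR with Wald 95% CI and p per covariate.

    ``covariates`` defaults to every column of ``surv`` other than
    time/event. Returns a DataFrame indexed by covariate with columns
    ``hr, ci_low, ci_high, p``.
    """
    covariates = list(covariates) if covariates is not None else [
        c for c in surv.columns if c not in ("time", "event")
    ]
    if not covariates:
        raise ValidationError("no covariates to fit")
    missing = [c for c in covariates if c not in surv.columns]
    if missing:
        raise ValidationError(f"covariate column(s) not in survival table: {missing}")
    for c in covariates:
        if surv[c].nunique() < 2:
            raise ValidationError(f"covariate {c!r} is constant; drop it from the model")
    n_events = int(surv["event"].sum())
    if n_events < len(covariates):
        raise ValidationError(
            f"{n_events} events cannot support {len(covariates)} covariates"
        )
    if n_events < 10 * len(covariates):
        logger.warning(
            "only %d events for %d covariates (<10 per covariate); estimates may be unstable",
            n_events,
            len(covariates),
        )
    df = surv[["time", "event", *covariates]].copy()
    fitter = CoxPHFitter()
    try:
        fitter.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError/Warning variants
        raise ValidationError(f"Cox fit failed (possible separation): {exc}") from exc
    summary = fitter.summary
    out = pd.DataFrame(
        {
            "hr": summary["exp(coef)"],
            "ci_low": summary["exp(coef) lower 95%"],
            "ci_high": summary["exp(coef) upper 95%"],
            "p": summary["p"],
        }
    )
    out.index.name = "covariate"
    return out


# ---------------------------------------------------------------------------
# concordance


def harrell_c(scores: Sequence[float], surv: pd.DataFrame) -> float:
    """Harrell's C: concordant / comparable subject pairs under censoring.

    Higher score is taken to mean higher risk (shorter survival). Ties in
    score count 1/2; pairs not comparable under censoring are excluded.
    """
    scores = np.asarray(list(scores), dtype=float)
    _check_alignment(scores.size, surv)
    try:
        return float(
            _lifelines_cindex(surv["time"].to_numpy(), -scores, surv["event"].to_numpy())
        )
    except ZeroDivisionError as exc:
        raise EmptyInputError("no comparable pairs (all times censored or tied)") from exc


def resample_c(
    scores: Sequence[float],
    surv: pd.DataFrame,
    fraction: float = 0.8,
    reps: int = 1000,
    p_threshold: float = 0.05,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Stability protocol: repeated scoring on random subcohorts.

    Each rep draws ``floor(fraction * n)`` samples without replacement,
    computes Harrell's C and the median-split log-rank p-value (the split
    recomputed within the resample). Returns (mean C, sd C, fraction of
    reps with p < p_threshold).
    """
    if not 0 < fraction <= 1:
        raise ParameterError(f"fraction must be in (0, 1], got {fraction}")
    if reps < 1:
        raise ParameterError("reps must be >= 1")
    if reps < 100:
        logger.warning("reps=%d < 100; the resampled sd will be noisy", reps)
    scores = np.asarray(list(scores), dtype=float)
    _check_alignment(scores.size, surv)
    time = surv["time"].to_numpy()
    event = surv["event"].to_numpy()
    n = scores.size
    m = int(np.floor(fraction * n))
    if m < 2:
        raise ParameterError("resample size below 2; raise fraction or n")
    rng = np.random.default_rng(seed)
    if m == n:  # degenerate: every resample is the whole cohort
        c = _lifelines_cindex(time, -scores, event)
        hi = scores > np.median(scores)
        res = logrank_test(time[hi], time[~hi],
                           event_observed_A=event[hi], event_observed_B=event[~hi])
        return float(c), 0.0, float(res.p_value < p_threshold)
    cs = np.empty(reps)
    sig = np.empty(reps, dtype=bool)
    for r in range(reps):
        idx = rng.choice(n, size=m, replace=False)
        s, t, e = scores[idx], time[idx], event[idx]
        cs[r] = _lifelines_cindex(t, -s, e)
        hi = s > np.median(s)
        if hi.any() and (~hi).any():
            res = logrank_test(t[hi], t[~hi], event_observed_A=e[hi], event_observed_B=e[~hi])
            sig[r] = res.p_value < p_threshold
        else:
            sig[r] = False
    return float(cs.mean()), float(cs.std(ddof=1)) if reps > 1 else 0.0, float(sig.mean())


# ---------------------------------------------------------------------------
# time-dependent ROC (cumulative/dynamic, IPCW)


def _censoring_survival(time: np.ndarray, event: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier estimate of the censoring distribution G(t).

    Computed by flipping the event indicator; returns step times and the
    right-continuous survival values at those times.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(time, 1 - event)
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def _step_left(step_t: np.ndarray, step_v: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Evaluate a right-continuous step function at t- (left limit)."""
    idx = np.searchsorted(step_t, t, side="left") - 1
    out = np.where(idx >= 0, step_v[np.clip(idx, 0, None)], 1.0)
    return out


def _step_right(step_t: np.ndarray, step_v: np.ndarray, t: float) -> float:
    idx = np.searchsorted(step_t, t, side="right") - 1
    return float(step_v[idx]) if idx >= 0 else 1.0


def time_dependent_auc(
    scores: Sequence[float], surv: pd.DataFrame, times: Sequence[float]
) -> dict[float, float]:
    """Cumulative/dynamic AUC(t) with inverse-censoring-probability weights.

    Cases at horizon t are subjects with an observed event at or before t,
    weighted by 1/G(T_i-) where G is the Kaplan-Meier estimate of the
    censoring distribution; controls are subjects still at risk beyond t.
    Ties in score count 1/2. Raises for a horizon with no prior events or
    beyond the observed follow-up.
    """
    scores = np.asarray(list(scores), dtype=float)
    _check_alignment(scores.size, surv)
    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy(dtype=int)
    gt, gv = _censoring_survival(time, event)
    out: dict[float, float] = {}
    for t0 in times:
        t0 = float(t0)
        if t0 >= time.max():
            raise ValidationError(f"horizon {t0} is not below the maximum follow-up {time.max()}")
        case = (event == 1) & (time <= t0)
        control = time > t0
        if not case.any():
            raise ValidationError(f"no events observed before horizon {t0}")
        w = 1.0 / _step_left(gt, gv, time[case])
        s_case = scores[case]
        s_ctrl = np.sort(scores[control])
        # for each case: #controls with smaller score + half the ties
        lo = np.searchsorted(s_ctrl, s_case, side="left")
        hi = np.searchsorted(s_ctrl, s_case, side="right")
        wins = lo + 0.5 * (hi - lo)
        out[t0] = float((w * wins).sum() / (w.sum() * s_ctrl.size))
    return out


# ---------------------------------------------------------------------------
# restricted mean survival time


def rms_ratio(groups: Sequence[str], surv: pd.DataFrame, tau: float | None = None) -> float:
    """Ratio of restricted mean survival times, HRisk over LRisk.

    Each group's RMS is the area under its Kaplan-Meier curve on [0, tau].
    ``tau`` defaults to the shorter of the two groups' largest observed
    times, the largest horizon where both curves are guaranteed defined;
    an explicit tau beyond a group's follow-up is accepted only if that
    group's curve has already dropped to zero (the remaining area is then
    exactly zero, not an extrapolation). A ratio below 1 means the
    high-risk group loses survival time.
    """
    g = _as_groups(groups)
    _check_alignment(g.size, surv)
    time = surv["time"].to_numpy()
    event = surv["event"].to_numpy()
    areas: dict[str, float] = {}
    max_obs = {}
    for label in (HRISK, LRISK):
        mask = g == label
        if not mask.any():
            raise EmptyInputError(f"group {label} is empty")
        max_obs[label] = float(time[mask].max())
    if tau is None:
        tau = min(max_obs.values())
    for label in (HRISK, LRISK):
        mask = g == label
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        curve_floor = float(kmf.survival_function_.iloc[-1, 0])
        if tau > max_obs[label] + 1e-12 and curve_floor > 0:
            raise ParameterError(
                f"tau={tau} exceeds max follow-up {max_obs[label]} in {label} "
                "and the survival curve is still positive there"
            )
        areas[label] = float(restricted_mean_survival_time(kmf, t=min(tau, max_obs[label])))
        # beyond the last observed time the curve is 0, adding no area
    return areas[HRISK] / areas[LRISK]


# ---------------------------------------------------------------------------
# report assembly


@dataclass
class EvalReport:
    """Bundle of every evaluation statistic for one scored cohort."""

    logrank_chi2: float
    logrank_p: float
    hr_with_ci: dict[str, dict[str, float]]
    c_index: float
    c_resample_mean: float
    c_resample_sd: float
    frac_p_below_threshold: float
    auc_at_times: dict[float, float]
    rms_ratio: float
    tau: float
    n_samples: int = 0
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "logrank_chi2": self.logrank_chi2,
            "logrank_p": self.logrank_p,
            "hr_with_ci": self.hr_with_ci,
            "c_index": self.c_index,
            "c_resample_mean": self.c_resample_mean,
            "c_resample_sd": self.c_resample_sd,
            "frac_p_below_threshold": self.frac_p_below_threshold,
            "auc_at_times": {str(k): v for k, v in self.auc_at_times.items()},
            "rms_ratio": self.rms_ratio,
            "tau": self.tau,
            "n_samples": self.n_samples,
            "seed": self.seed,
        }
        if self.extras:
            d["extras"] = self.extras
        return d

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


def evaluate(
    scores: Sequence[float],
    groups: Sequence[str],
    surv: pd.DataFrame,
    times: Sequence[float] = (),
    covariates: Sequence[str] | None = None,
    reps: int = 1000,
    fraction: float = 0.8,
    p_threshold: float = 0.05,
    tau: float | None = None,
    seed: int = 0,
) -> EvalReport:
    """Run the full evaluation battery on one scored cohort.

    ``times`` are AUC horizons in the survival table's own time unit. The
    multivariate Cox model always includes the score; any ``covariates``
    named from ``surv`` columns are added as adjustment terms.
    """
    scores = np.asarray(list(scores), dtype=float)
    lr = km_logrank(groups, surv)
    cox_df = surv[["time", "event", *(covariates or [])]].copy()
    cox_df["irgpi"] = scores
    hr = cox_multivariate(cox_df)
    c = harrell_c(scores, surv)
    c_mean, c_sd, frac_sig = resample_c(
        scores, surv, fraction=fraction, reps=reps, p_threshold=p_threshold, seed=seed
    )
    aucs = time_dependent_auc(scores, surv, times) if times else {}
    g = _as_groups(groups)
    time = surv["time"].to_numpy()
    tau_used = tau if tau is not None else min(
        float(time[g == HRISK].max()), float(time[g == LRISK].max())
    )
    ratio = rms_ratio(groups, surv, tau=tau_used)
    return EvalReport(
        logrank_chi2=lr.chi2,
        logrank_p=lr.p,
        hr_with_ci={k: dict(v) for k, v in hr.to_dict(orient="index").items()},
        c_index=c,
        c_resample_mean=c_mean,
        c_resample_sd=c_sd,
        frac_p_below_threshold=frac_sig,
        auc_at_times=aucs,
        rms_ratio=ratio,
        tau=tau_used,
        n_samples=int(surv.shape[0]),
        seed=seed,
    )
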