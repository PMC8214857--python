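"""Training: select prognostic gene pairs and coefficients from survival data.

Pipeline (``train_signature``):

1. variability prefilter of the gene set (raw MAD across samples),
2. order indicators for all within-set candidate pairs,
3. informative-pair frequency filter (order must flip in >= f_min of samples),
4. univariate Cox screen — score test of the partial likelihood with Efron
   tie handling, evaluated at beta = 0 and vectorised across pairs,
5. redundancy prune: pairs are ranked by their screen statistic and a pair
   is kept only if its indicator correlates weakly with every
   already-kept pair (pairs sharing a gene are nearly collinear and would
   otherwise enter the model many times over),
6. sparse selection by an L1-penalised Cox model — by default with
   stability selection (the lasso is refit on random subsamples and only
   pairs selected in a high fraction of subsamples are kept), or
   alternatively by a single lasso path with the penalty chosen by
   cross-validated partial likelihood,
7. block-swap refinement: each selected pair is tested against the
   correlated screened pairs its pruning block absorbed, by profile
   partial likelihood with the rest of the model held fixed, and the best
   block member takes its seat (the prune ranks pairs marginally, which
   can crown a correlated surrogate instead of the driver; the joint
   comparison corrects that),
8. final coefficients from an unpenalised multivariate Cox refit on the
   selected pairs (shrunken lasso coefficients would bias the score scale
   that the fixed cutoff presumes),
9. cutoff fixed at the median training score (or an externally supplied
   constant for cross-cohort use).

The product is a :class:`~irgpi.signature.GenePairSignature` that depends
only on within-sample expression orderings and therefore transfers across
platforms without renormalisation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import chi2 as chi2_dist
from sklearn.model_selection import StratifiedKFold

from .errors import (
    ConvergenceError,
    EmptyCandidateError,
    EmptySignatureError,
    IrgpiError,
    ParameterError,
    ValidationError,
)
from .io import GeneSet
from .pairs import (
    GenePair,
    PairIndicatorMatrix,
    all_candidate_pairs,
    build_indicator_matrix,
    filter_informative_pairs,
    prefilter_genes,
)
from .signature import GenePairSignature

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Knobs of the training pipeline.

    screen_p:
        Univariate score-test threshold; pairs with p below it enter the
        penalised fit. Controls the candidate count (pair spaces over an
        immune gene set reach 10^4-10^5).
    cv_folds:
        Folds for cross-validated penalty selection (>= 3), stratified by
        event status.
    lambda_rule:
        ``"min"`` takes the penalty maximising the cross-validated partial
        likelihood; ``"1se"`` takes the sparsest model within one standard
        error of that maximum. Applies to the ``"cv"`` selection rule.
    selection_rule:
        ``"stability"`` (default) keeps pairs the lasso selects in at
        least ``stability_pi`` of ``stability_reps`` half-subsample
        refits; ``"cv"`` uses one cross-validated lasso fit.
    max_corr:
        Redundancy prune threshold: a screened pair enters the candidate
        model only if the absolute correlation of its indicator with every
        stronger kept pair is at most this value.
    alpha:
        Optional fixed penalty weight; skips cross-validation. ``0`` fits
        an unpenalised Cox model (only sensible for few candidates).
    cutoff / cutoff_mode:
        ``"median"`` sets the risk cutoff to the median training score;
        ``"fixed"`` uses the supplied constant (e.g. a published
        cross-platform value such as 1.195).
    """

    screen_p: float = 0.05
    cv_folds: int = 5
    lambda_rule: Literal["min", "1se"] = "min"
    seed: int = 0
    f_min: float = 0.2
    mad_threshold: float = 0.5
    alpha: float | None = None
    n_alphas: int = 50
    alpha_min_ratio: float = 0.02
    selection_rule: Literal["stability", "cv"] = "stability"
    max_corr: float = 0.4
    stability_reps: int = 60
    stability_frac: float = 0.6
    stability_pi: float = 0.7
    refine_swaps: bool = True
    cutoff_mode: Literal["median", "fixed"] = "median"
    cutoff: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.screen_p <= 1:
            raise ParameterError(f"screen_p must be in (0, 1], got {self.screen_p}")
        if self.cv_folds < 3:
            raise ParameterError(f"cv_folds must be >= 3, got {self.cv_folds}")
        if self.lambda_rule not in ("min", "1se"):
            raise ParameterError(f"lambda_rule must be 'min' or '1se', got {self.lambda_rule!r}")
        if self.selection_rule not in ("stability", "cv"):
            raise ParameterError(f"selection_rule must be 'stability' or 'cv'")
        if not 0 < self.max_corr <= 1:
            raise ParameterError(f"max_corr must be in (0, 1], got {self.max_corr}")
        if not 0 < self.stability_frac <= 1 or not 0.5 <= self.stability_pi <= 1:
            raise ParameterError("stability_frac in (0,1] and stability_pi in [0.5,1] required")
        if self.cutoff_mode == "fixed" and self.cutoff is None:
            raise ParameterError("cutoff_mode='fixed' requires a cutoff value")

    @classmethod
    def from_file(cls, path: str | Path) -> "TrainConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ParameterError(f"unknown TrainConfig keys: {sorted(unknown)}")
        return cls(**doc)


# ---------------------------------------------------------------------------
# univariate screen


def efron_score_test(
    X: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Cox partial-likelihood score test at beta=0, Efron tie handling.

    ``X`` is covariates x samples; the score statistic U^2/I is computed
    for every row simultaneously (U = first, I = minus second derivative of
    the Efron log partial likelihood at 0). Returns ``(chi2, p)`` arrays;
    rows with zero information (constant covariate) get NaN.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if X.shape[1] != time.shape[0]:
        raise ValidationError("covariate matrix and survival table sample counts differ")
    if event.sum() < 2:
        raise ValidationError("need at least 2 events for the score test")

    order = np.argsort(-time, kind="stable")
    t, e, Xs = time[order], event[order], X[:, order]
    cum1 = np.cumsum(Xs, axis=1)
    cum2 = np.cumsum(Xs * Xs, axis=1)

    n = t.shape[0]
    U = np.zeros(X.shape[0])
    info = np.zeros(X.shape[0])
    i = 0
    while i < n:
        j = i + 1
        while j < n and t[j] == t[i]:
            j += 1
        ev = np.flatnonzero(e[i:j] == 1) + i
        d = ev.size
        if d:
            n_risk = j  # descending sort: risk set = first j samples
            s1r, s2r = cum1[:, j - 1], cum2[:, j - 1]
            s1d = Xs[:, ev].sum(axis=1)
            s2d = (Xs[:, ev] ** 2).sum(axis=1)
            frac = np.arange(d) / d
            phi = n_risk - frac * d  # size of the Efron-adjusted risk set
            a1 = (s1r[:, None] - frac[None, :] * s1d[:, None]) / phi[None, :]
            a2 = (s2r[:, None] - frac[None, :] * s2d[:, None]) / phi[None, :]
            U += s1d - a1.sum(axis=1)
            info += (a2 - a1 * a1).sum(axis=1)
        i = j

    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(info > 0, U * U / np.where(info > 0, info, 1.0), np.nan)
    p = np.where(np.isnan(chi2), np.nan, chi2_dist.sf(chi2, df=1))
    return chi2, p


def univariate_cox_screen(
    ind: PairIndicatorMatrix, surv: pd.DataFrame, screen_p: float = 0.05
) -> list[GenePair]:
    """Pairs whose univariate Cox score-test p-value is below ``screen_p``.

    Pairs with a constant indicator are inestimable and skipped with a
    warning. ``surv`` must be row-aligned with the indicator columns.
    """
    if not 0 < screen_p <= 1:
        raise ParameterError(f"screen_p must be in (0, 1], got {screen_p}")
    surv = surv.loc[ind.sample_ids]
    X = ind.data.to_numpy()
    if np.isnan(X).any():
        raise ValidationError("missing indicators: resolve missing-gene samples before screening")
    _, p = efron_score_test(X, surv["time"].to_numpy(), surv["event"].to_numpy())
    n_const = int(np.isnan(p).sum())
    if n_const:
        warnings.warn(f"{n_const} pair(s) had constant indicators and were skipped (inestimable)")
    keep = p < screen_p
    kept = [pair for pair, k in zip(ind.pairs, keep) if k]
    logger.info("univariate screen: %d/%d pairs at p<%g", len(kept), len(ind.pairs), screen_p)
    return kept


# ---------------------------------------------------------------------------
# redundancy prune


def decorrelate_pairs(
    ind: PairIndicatorMatrix,
    surv: pd.DataFrame,
    max_corr: float = 0.4,
) -> list[GenePair]:
    """Greedy redundancy prune of the candidate pair set.

    Pairs are visited in decreasing order of their univariate score
    statistic; a pair is kept only if the absolute Pearson correlation of
    its indicator with every already-kept indicator is at most
    ``max_corr``. Pairs sharing a gene are nearly collinear, so without
    this step the same prognostic contrast enters the penalised model many
    times and dilutes selection.
    """
    surv = surv.loc[ind.sample_ids]
    X = ind.data.to_numpy()
    chi2, _ = efron_score_test(X, surv["time"].to_numpy(), surv["event"].to_numpy())
    chi2 = np.where(np.isnan(chi2), -np.inf, chi2)
    order = np.argsort(-chi2, kind="stable")
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.sqrt((Xc * Xc).sum(axis=1))
    kept_idx: list[int] = []
    kept_rows = np.empty((0, X.shape[1]))
    for i in order:
        if norm[i] == 0 or not np.isfinite(chi2[i]):
            continue
        if kept_rows.shape[0]:
            r = kept_rows @ Xc[i] / (norm[kept_idx] * norm[i])
            if np.abs(r).max() > max_corr:
                continue
        kept_idx.append(i)
        kept_rows = np.vstack([kept_rows, Xc[i]])
    return [ind.pairs[i] for i in kept_idx]


# ---------------------------------------------------------------------------
# penalised fit


def breslow_partial_loglik(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow-approximation Cox partial log-likelihood of a linear predictor.

    Used only to score held-out folds during penalty selection; risk sets
    are formed within the supplied samples.
    """
    lp = np.asarray(lp, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(-time, kind="stable")
    t, e, z = time[order], event[order], lp[order]
    # subtract max for overflow safety; cancels between the two terms
    z = z - z.max()
    cumexp = np.cumsum(np.exp(z))
    ll = 0.0
    i, n = 0, t.shape[0]
    while i < n:
        j = i + 1
        while j < n and t[j] == t[i]:
            j += 1
        ev = np.flatnonzero(e[i:j] == 1) + i
        if ev.size:
            ll += z[ev].sum() - ev.size * np.log(cumexp[j - 1])
        i = j
    return float(ll)


def _surv_array(surv: pd.DataFrame):
    from sksurv.util import Surv

    return Surv.from_arrays(
        event=surv["event"].to_numpy().astype(bool), time=surv["time"].to_numpy()
    )


def fit_lasso_cox(
    ind: PairIndicatorMatrix, surv: pd.DataFrame, config: TrainConfig
) -> tuple[list[GenePair], list[float]]:
    """L1-penalised Cox fit over candidate pair indicators.

    The penalty path is computed once on the full data; each fold refits
    the path on its training portion and the held-out Breslow partial
    log-likelihood selects the penalty under ``config.lambda_rule``. Pairs
    with zero coefficient at the chosen penalty are dropped. Deterministic
    given ``config.seed``.
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis

    surv = surv.loc[ind.sample_ids]
    X = ind.data.to_numpy().T  # samples x pairs
    if np.isnan(X).any():
        raise ValidationError("missing indicators: resolve missing-gene samples before fitting")
    time = surv["time"].to_numpy()
    event = surv["event"].to_numpy().astype(int)
    n_events = int(event.sum())
    if n_events < 10:
        warnings.warn(f"only {n_events} events; penalised Cox selection will be unstable")
    y = _surv_array(surv)

    if config.alpha == 0:
        return _fit_unpenalized(ind, surv)

    def _coxnet(alphas=None):
        kwargs = dict(l1_ratio=1.0, max_iter=200_000, tol=1e-7, normalize=False)
        if alphas is not None:
            kwargs["alphas"] = alphas
        else:
            kwargs.update(n_alphas=config.n_alphas, alpha_min_ratio=config.alpha_min_ratio)
        return CoxnetSurvivalAnalysis(**kwargs)

    try:
        if config.alpha is not None:
            model = _coxnet(alphas=[config.alpha]).fit(X, y)
            coef = model.coef_[:, 0]
        else:
            path = _coxnet().fit(X, y)
            alphas = np.asarray(path.alphas_)
            folds = StratifiedKFold(
                n_splits=config.cv_folds, shuffle=True, random_state=config.seed % (2**31)
            )
            cv_ll = np.full((config.cv_folds, alphas.size), np.nan)
            for k, (tr, te) in enumerate(folds.split(X, event)):
                m = _coxnet(alphas=alphas).fit(X[tr], y[tr])
                # the fold's path may stop early; align on the alphas it kept
                fold_cols = {round(float(a), 12): c for c, a in enumerate(m.alphas_)}
                lp_te = X[te] @ m.coef_
                for a in range(alphas.size):
                    c = fold_cols.get(round(float(alphas[a]), 12))
                    if c is not None:
                        cv_ll[k, a] = breslow_partial_loglik(lp_te[:, c], time[te], event[te])
            valid = ~np.isnan(cv_ll).any(axis=0)
            if not valid.any():
                raise ConvergenceError("cross-validation failed at every penalty")
            mean_ll = np.where(valid, np.nanmean(cv_ll, axis=0), -np.inf)
            best = int(np.argmax(mean_ll))
            if config.lambda_rule == "1se":
                se = cv_ll[:, best].std(ddof=1) / np.sqrt(config.cv_folds)
                # alphas_ is decreasing: the first index within one SE is sparsest
                idx = int(np.flatnonzero(mean_ll >= mean_ll[best] - se)[0])
            else:
                idx = best
            coef = path.coef_[:, idx]
            logger.info(
                "coxnet CV: chose alpha=%.4g (%s rule), %d/%d nonzero",
                alphas[idx],
                config.lambda_rule,
                int(np.count_nonzero(coef)),
                coef.size,
            )
    except (ArithmeticError, ValueError) as exc:
        raise ConvergenceError(
            f"penalised Cox fit failed ({exc}); n={X.shape[0]}, p={X.shape[1]}, events={n_events}"
        ) from exc

    nz = np.flatnonzero(coef)
    if nz.size == 0:
        raise EmptySignatureError(
            "no pair retained a nonzero coefficient; the penalty removed every "
            "candidate (no prognostic signal at this sample size?)"
        )
    return [ind.pairs[i] for i in nz], [float(coef[i]) for i in nz]


def _fit_unpenalized(
    ind: PairIndicatorMatrix, surv: pd.DataFrame, penalizer: float = 0.0
) -> tuple[list[GenePair], list[float]]:
    from lifelines import CoxPHFitter

    df = ind.data.T.copy()
    df["time"] = surv["time"].to_numpy()
    df["event"] = surv["event"].to_numpy()
    fitter = CoxPHFitter(penalizer=penalizer)
    fitter.fit(df, duration_col="time", event_col="event")
    betas = fitter.params_
    return list(ind.pairs), [float(betas[p.label()]) for p in ind.pairs]


def stability_selection(
    ind: PairIndicatorMatrix, surv: pd.DataFrame, config: TrainConfig
) -> list[GenePair]:
    """Pairs the lasso selects consistently across random subsamples.

    A lasso path is fit once on the full data to locate penalties whose
    active set has a plausible signature size (5-30 pairs); the lasso is
    then refit at those penalties on ``stability_reps`` random subsamples
    of ``stability_frac`` of the cohort, and a pair is kept if it enters
    the active set in at least ``stability_pi`` of the refits. Consistent
    selection under subsampling separates genuinely prognostic pairs from
    pairs that ride one particular draw of the cohort.
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis

    surv = surv.loc[ind.sample_ids]
    X = ind.data.to_numpy().T
    if np.isnan(X).any():
        raise ValidationError("missing indicators: resolve missing-gene samples before fitting")
    time = surv["time"].to_numpy()
    event = surv["event"].to_numpy().astype(bool)
    y = _surv_array(surv)

    path = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=30, alpha_min_ratio=0.05, max_iter=200_000, tol=1e-7
    ).fit(X, y)
    alphas = np.asarray(path.alphas_)
    nnz = (path.coef_ != 0).sum(axis=0)
    window = np.flatnonzero((nnz >= 5) & (nnz <= 30))
    if window.size == 0:
        window = np.array([int(np.argmin(np.abs(nnz - 10)))])
    sub_alphas = alphas[window[:9]]

    rng = np.random.default_rng(config.seed)
    n = X.shape[0]
    m = max(2, int(config.stability_frac * n))
    counts = np.zeros(X.shape[1])
    n_ok = 0
    for _ in range(config.stability_reps):
        idx = rng.choice(n, size=m, replace=False)
        if event[idx].sum() < 2:
            continue
        model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=sub_alphas, max_iter=200_000)
        try:
            model.fit(X[idx], _surv_array(surv.iloc[idx]))
        except (ArithmeticError, ValueError):
            continue
        counts += (model.coef_ != 0).any(axis=1)
        n_ok += 1
    if n_ok == 0:
        raise ConvergenceError("every stability-selection refit failed; data too small?")
    freq = counts / n_ok
    kept = [p for p, f in zip(ind.pairs, freq) if f >= config.stability_pi]
    logger.info(
        "stability selection: %d/%d pairs at frequency >= %.2f over %d refits",
        len(kept), len(ind.pairs), config.stability_pi, n_ok,
    )
    if not kept:
        raise EmptySignatureError(
            f"no pair was selected in >= {config.stability_pi:.0%} of subsample refits; "
            "no stable prognostic signal at this sample size"
        )
    return kept


def refine_selected_pairs(
    ind_screened: PairIndicatorMatrix,
    surv: pd.DataFrame,
    selected: Sequence[GenePair],
    max_corr: float = 0.4,
) -> list[GenePair]:
    """Swap each selected pair for the best member of its correlated block.

    The redundancy prune keeps the *marginally* strongest pair of each
    correlated block, which under sampling noise can be a surrogate that
    shares a gene with the truly prognostic pair rather than the pair
    itself. For each selected pair this pass revisits every screened pair
    correlated with it (absolute indicator correlation above ``max_corr``)
    and keeps whichever maximises the Cox partial likelihood profiled over
    that pair's coefficient, with the remaining selected pairs held fixed
    as an offset. Deterministic; no randomness involved.
    """
    from scipy.optimize import minimize_scalar

    surv = surv.loc[ind_screened.sample_ids]
    X = ind_screened.data.to_numpy()
    time = surv["time"].to_numpy()
    event = surv["event"].to_numpy()
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.sqrt((Xc * Xc).sum(axis=1))
    norm[norm == 0] = np.inf
    idx_of = {p: i for i, p in enumerate(ind_screened.pairs)}
    current = list(selected)
    for k in range(len(current)):
        _, betas = _fit_unpenalized(ind_screened.subset(current), surv, penalizer=1e-6)
        i = idx_of[current[k]]
        r = (Xc @ Xc[i]) / (norm * norm[i])
        occupied = {idx_of[p] for p in current}
        block = [j for j in np.flatnonzero(np.abs(r) > max_corr)
                 if j == i or j not in occupied]
        if len(block) <= 1:
            continue
        offset = np.zeros(X.shape[1])
        for m, p in enumerate(current):
            if m != k:
                offset += betas[m] * X[idx_of[p]]
        best_j, best_ll = i, -np.inf
        for j in block:
            res = minimize_scalar(
                lambda b: -breslow_partial_loglik(offset + b * X[j], time, event),
                bounds=(-4.0, 4.0), method="bounded", options={"xatol": 1e-4},
            )
            if -res.fun > best_ll:
                best_ll, best_j = -res.fun, j
        current[k] = ind_screened.pairs[best_j]
    if len(set(current)) < len(current):  # two blocks converged on one pair
        current = list(dict.fromkeys(current))
    return current


# ---------------------------------------------------------------------------
# full pipeline


def _content_digest(config: TrainConfig, expr: pd.DataFrame, surv: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(json.dumps(asdict(config), sort_keys=True).encode())
    h.update("|".join(expr.index).encode())
    h.update("|".join(expr.columns).encode())
    h.update(np.ascontiguousarray(expr.to_numpy(dtype=float)).tobytes())
    h.update("|".join(surv.index).encode())
    h.update(np.ascontiguousarray(surv[["time", "event"]].to_numpy(dtype=float)).tobytes())
    return h.hexdigest()[:16]


def train_signature(
    expr: pd.DataFrame,
    gene_set: GeneSet | Sequence[str],
    surv: pd.DataFrame,
    config: TrainConfig | None = None,
) -> GenePairSignature:
    """Run the full training pipeline and return the portable signature."""
    from .io import align_samples

    config = config or TrainConfig()
    expr, surv = align_samples(expr, surv)
    if int(surv["event"].sum()) == 0:
        raise ValidationError("screen stage: survival table contains zero events")

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except IrgpiError as exc:
            raise type(exc)(f"{name} stage: {exc}") from exc

    genes = _stage("prefilter", prefilter_genes, expr, gene_set, config.mad_threshold)
    candidates = all_candidate_pairs(genes)
    ind = _stage("indicators", build_indicator_matrix, expr, candidates)
    informative = _stage("informative-filter", filter_informative_pairs, ind, config.f_min)
    if not informative:
        raise EmptyCandidateError("informative-filter stage: no pair within the frequency band")
    ind = ind.subset(informative)
    screened = _stage("screen", univariate_cox_screen, ind, surv, config.screen_p)
    if not screened:
        raise EmptyCandidateError(
            f"screen stage: no pair passed the univariate screen at p<{config.screen_p}"
        )
    ind_screened = ind.subset(screened)
    pruned = _stage("decorrelate", decorrelate_pairs, ind_screened, surv, config.max_corr)
    ind = ind_screened.subset(pruned)
    if config.selection_rule == "stability":
        pairs = _stage("stability-selection", stability_selection, ind, surv, config)
        if config.refine_swaps:
            pairs = _stage(
                "refine", refine_selected_pairs, ind_screened, surv, pairs, config.max_corr
            )
        _, betas = _stage(
            "refit", _fit_unpenalized,
            ind_screened.subset(pairs), surv.loc[ind_screened.sample_ids], 1e-6,
        )
    else:
        pairs, betas = _stage("lasso", fit_lasso_cox, ind, surv, config)

    scores = np.asarray(betas) @ ind_screened.subset(pairs).data.to_numpy()
    cutoff = float(config.cutoff) if config.cutoff_mode == "fixed" else float(np.median(scores))

    metadata = {
        "n_samples": int(expr.shape[1]),
        "n_events": int(surv["event"].sum()),
        "n_genes_prefiltered": len(genes),
        "n_candidate_pairs": len(candidates),
        "n_informative_pairs": len(informative),
        "n_screened_pairs": len(screened),
        "n_pruned_pairs": len(pruned),
        "selection_rule": config.selection_rule,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": _content_digest(config, expr, surv),
        "cutoff_mode": config.cutoff_mode,
    }
    return GenePairSignature(pairs, betas, cutoff, metadata)
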