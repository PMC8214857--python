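"""Synthetic multi-platform cohorts with a known pair-driven hazard.

The generator emulates the structure of a multi-cohort prognostic study
without any external download: a base expression matrix with log-normal
per-gene distributions, a small set of disjoint "true" gene pairs whose
order indicators drive the hazard through a proportional-hazards model,
right censoring tuned to a target rate, and several platform views of the
same samples produced by per-sample strictly monotone distortions (log,
power, rank, positive affine). Because the distortions are monotone within
each sample, every platform view carries exactly the same pair indicators
— which is the invariance the scoring method is built on.

True-pair genes are given matched location parameters so that their order
flips in a substantial fraction of samples; a pair whose order is
(near-)constant could drive no risk differences and would be discarded by
the informative-pair filter anyway.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ParameterError, ValidationError
from .pairs import GenePair, all_candidate_pairs, build_indicator_matrix
from .signature import GenePairSignature

DISTORTION_FAMILIES = ("log", "power", "rank", "affine")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Defaults describe the standard recovery scenario used throughout the
    test-bench: 600 patients, a 150-gene immune set, 8 true pairs with
    log-hazard effects of magnitude 0.5-1.0 (random sign), a baseline
    exponential hazard giving ~5-year median survival on the month scale,
    ~30% censoring, and two platform views.
    """

    n_samples: int = 600
    n_genes: int = 150
    n_true_pairs: int = 8
    beta_range: tuple[float, float] = (0.5, 1.0)
    baseline_hazard: float = np.log(2) / 60.0  # per month; median survival 60 months at eta=0
    censoring_rate_target: float = 0.3
    n_platforms: int = 2
    distortions: tuple[str, ...] | None = None
    weibull_shape: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_genes, self.n_true_pairs, self.n_platforms) < 1:
            raise ParameterError("all counts must be positive")
        if 2 * self.n_true_pairs > self.n_genes:
            raise ParameterError("need n_genes >= 2 * n_true_pairs (true pairs are disjoint)")
        if not 0 <= self.censoring_rate_target < 1:
            raise ParameterError("censoring_rate_target must lie in [0, 1)")
        if self.censoring_rate_target > 0.99:
            raise ParameterError("censoring target above 0.99 is infeasible")
        lo, hi = self.beta_range
        if not 0 < lo <= hi:
            raise ParameterError("beta_range must be a positive interval (low <= high)")
        if self.baseline_hazard <= 0 or self.weibull_shape <= 0:
            raise ParameterError("baseline_hazard and weibull_shape must be positive")
        if self.distortions is not None:
            self.distortions = tuple(self.distortions)
            unknown = set(self.distortions) - set(DISTORTION_FAMILIES)
            if unknown:
                raise ParameterError(f"unknown distortion families: {sorted(unknown)}")
            if len(self.distortions) != self.n_platforms:
                raise ParameterError("distortions must list one family per platform")


@dataclass
class SimulatedCohort:
    """Expression views, survival, and ground truth for one simulation."""

    base_expr: pd.DataFrame
    platforms: list[pd.DataFrame]
    surv: pd.DataFrame
    truth: GenePairSignature
    eta: pd.Series  # true linear predictor per sample
    config: SimulationConfig = field(repr=False)


def _apply_distortion(
    expr: pd.DataFrame, family: str, rng: np.random.Generator
) -> pd.DataFrame:
    """Apply a per-sample strictly increasing transform from one family."""
    x = expr.to_numpy(dtype=float)
    n = x.shape[1]
    if family == "log":
        shift = rng.uniform(0.5, 2.0, size=n)
        out = np.log2(x + shift[None, :])
    elif family == "power":
        gamma = rng.uniform(0.5, 2.0, size=n)
        out = np.power(x, gamma[None, :])
    elif family == "rank":
        out = rankdata(x, axis=0).astype(float)
    elif family == "affine":
        a = rng.uniform(0.5, 3.0, size=n)
        b = rng.uniform(-2.0, 5.0, size=n)
        out = a[None, :] * x + b[None, :]
    else:
        raise ParameterError(f"unknown distortion family {family!r}")
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def inject_gene_shift(
    expr: pd.DataFrame, seed: int = 0, scale: float = 50.0
) -> pd.DataFrame:
    """Adversarial per-gene (not per-sample) shift that breaks order invariance.

    Adds a random constant per gene row. This is monotone within each gene
    but not within each sample, so between-gene orderings — and hence pair
    indicators — are no longer preserved. Provided as a negative control.
    """
    rng = np.random.default_rng(seed)
    shift = rng.uniform(-scale, scale, size=expr.shape[0])
    return expr.add(shift, axis=0)


def _tune_censoring(t_event: np.ndarray, u: np.ndarray, target: float) -> np.ndarray:
    """Exponential censoring times whose realised censored fraction hits target.

    The censored fraction is monotone in the censoring rate for fixed
    uniform draws, so the rate is found by bisection on the realised
    fraction — deterministic given the draws.
    """
    if target == 0:
        return np.full_like(t_event, np.inf)

    def frac_censored(rate: float) -> float:
        c = -np.log(u) / rate
        return float((c < t_event).mean())

    lo, hi = 1e-9, 1e6
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac_censored(mid) < target:
            lo = mid
        else:
            hi = mid
    return -np.log(u) / np.sqrt(lo * hi)


def simulate_cohort(config: SimulationConfig | None = None, **overrides) -> SimulatedCohort:
    """Draw one cohort under ``config`` (seed-deterministic)."""
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = SimulationConfig(**{**asdict(config), **overrides})
    rng = np.random.default_rng(config.seed)

    genes = [f"IMM{i:04d}" for i in range(config.n_genes)]
    samples = [f"S{i:04d}" for i in range(config.n_samples)]

    # per-gene log2-scale location and spread
    loc = rng.normal(3.0, 1.0, size=config.n_genes)
    scale = rng.uniform(0.4, 1.2, size=config.n_genes)

    # disjoint true pairs with matched locations -> informative order frequency
    chosen = rng.choice(config.n_genes, size=2 * config.n_true_pairs, replace=False)
    true_pairs: list[GenePair] = []
    for k in range(config.n_true_pairs):
        ia, ib = int(chosen[2 * k]), int(chosen[2 * k + 1])
        loc[ib] = loc[ia] + rng.normal(0.0, 0.3)
        scale[ia] = rng.uniform(0.6, 1.0)
        scale[ib] = rng.uniform(0.6, 1.0)
        a, b = genes[ia], genes[ib]
        true_pairs.append(GenePair(a, b) if a < b else GenePair(b, a))

    log2_expr = rng.normal(
        loc[:, None], scale[:, None], size=(config.n_genes, config.n_samples)
    )
    base = pd.DataFrame(np.exp2(log2_expr), index=genes, columns=samples)

    lo_b, hi_b = config.beta_range
    betas = rng.uniform(lo_b, hi_b, size=config.n_true_pairs) * rng.choice(
        (-1.0, 1.0), size=config.n_true_pairs
    )

    ind = build_indicator_matrix(base, true_pairs).data.to_numpy()
    eta = betas @ ind
    hazard = config.baseline_hazard * np.exp(eta - eta.mean())

    e_draw = rng.exponential(1.0, size=config.n_samples)
    t_event = np.power(e_draw / hazard, 1.0 / config.weibull_shape)
    u = rng.uniform(size=config.n_samples)
    t_cens = _tune_censoring(t_event, u, config.censoring_rate_target)
    observed = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    # month-resolution follow-up (induces realistic ties); floor keeps time > 0
    observed = np.maximum(np.round(observed, 1), 0.1)

    surv = pd.DataFrame({"time": observed, "event": event}, index=pd.Index(samples, name="sample"))

    eta_series = pd.Series(eta, index=samples, name="eta")
    truth = GenePairSignature(
        true_pairs,
        [float(b) for b in betas],
        cutoff=float(np.median(betas @ ind)),
        metadata={"kind": "simulation-truth", "seed": config.seed, "config": asdict(config)},
    )

    families = config.distortions or tuple(
        DISTORTION_FAMILIES[k % len(DISTORTION_FAMILIES)] for k in range(config.n_platforms)
    )
    platforms = [_apply_distortion(base, fam, rng) for fam in families]

    return SimulatedCohort(base, platforms, surv, truth, eta_series, config)


def verify_platform_consistency(
    cohort: SimulatedCohort, pairs: Sequence[GenePair] | None = None
) -> bool:
    """True iff all platform views yield identical pair indicators.

    Checks every candidate pair by default; pass ``pairs`` to restrict.
    Requires at least two platform views.
    """
    if len(cohort.platforms) < 2:
        raise ValidationError("need at least 2 platform views to compare")
    pairs = list(pairs) if pairs is not None else all_candidate_pairs(cohort.base_expr.index)
    reference = build_indicator_matrix(cohort.platforms[0], pairs).data.to_numpy()
    for other in cohort.platforms[1:]:
        mat = build_indicator_matrix(other, pairs).data.to_numpy()
        if not np.array_equal(reference, mat, equal_nan=True):
            return False
    return True
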