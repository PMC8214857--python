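"""Single-sample risk scoring and risk-group stratification.

The index for a sample s is

    IRGPI(s) = sum_i beta_i * I(gene_a_i, gene_b_i; s)

with I the within-sample order indicator. Each sample is scored in
isolation: adding or removing other samples never changes a score, and any
strictly increasing within-sample transform of the expression values
leaves the score exactly unchanged. Higher scores mean poorer expected
survival; a sample is called high risk (HRisk) iff its score is strictly
above the cutoff (ties at the cutoff go to LRisk).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, MissingGeneError, ParameterError
from .pairs import pair_indicator
from .signature import GenePairSignature

logger = logging.getLogger(__name__)

HRISK = "HRisk"
LRISK = "LRisk"


@dataclass
class RiskResult:
    """Score and (optional) risk call for one sample."""

    sample_id: str
    irgpi: float
    group: str | None = None
    n_pairs_used: int = 0
    warnings: list[str] = field(default_factory=list)


def compute_irgpi(
    expr_sample: Mapping[str, float] | pd.Series,
    signature: GenePairSignature,
    missing_policy: Literal["strict", "drop"] = "strict",
) -> float:
    """Score one sample against a signature; returns the index value.

    See :func:`score_sample` for the variant that also reports how many
    pairs contributed.
    """
    return score_sample(expr_sample, signature, missing_policy=missing_policy).irgpi


def score_sample(
    expr_sample: Mapping[str, float] | pd.Series,
    signature: GenePairSignature,
    missing_policy: Literal["strict", "drop"] = "strict",
) -> RiskResult:
    """Score one sample against a signature.

    Under the default ``strict`` policy any signature gene absent from (or
    NaN in) the sample raises :class:`MissingGeneError`; under ``drop`` the
    affected pairs are skipped and counted in ``warnings`` — remaining
    coefficients are never rescaled, since rescaling would silently shift
    the score scale the fixed cutoff presumes.
    """
    if isinstance(expr_sample, pd.Series):
        name = str(expr_sample.name) if expr_sample.name is not None else "sample"
        values = expr_sample.to_dict()
    else:
        name = "sample"
        values = dict(expr_sample)

    total = 0.0
    used = 0
    notes: list[str] = []
    missing: list[str] = []
    for pair, beta in zip(signature.pairs, signature.betas):
        xa = values.get(pair.gene_a, float("nan"))
        xb = values.get(pair.gene_b, float("nan"))
        ind = pair_indicator(float(xa) if xa is not None else float("nan"),
                             float(xb) if xb is not None else float("nan"))
        if np.isnan(ind):
            missing.extend(g for g in pair if g not in values or pd.isna(values.get(g)))
            notes.append(f"pair {pair.label()} skipped (missing value)")
            continue
        total += beta * ind
        used += 1
    if missing and missing_policy == "strict":
        raise MissingGeneError(missing)
    if notes:
        logger.warning("%s: %d/%d pairs dropped", name, len(signature) - used, len(signature))
    return RiskResult(name, total, None, used, notes)


def score_cohort(
    expr: pd.DataFrame,
    signature: GenePairSignature,
    missing_policy: Literal["strict", "drop"] = "strict",
) -> list[RiskResult]:
    """Score every column of a genes x samples matrix independently."""
    results = []
    for sample in expr.columns:
        results.append(score_sample(expr[sample], signature, missing_policy=missing_policy))
    return results


def stratify(
    scores: Sequence[float],
    mode: Literal["median", "fixed"] = "median",
    cutoff: float | None = None,
) -> list[str]:
    """Assign HRisk/LRisk labels by thresholding scores.

    ``median`` uses the dataset-specific median of ``scores`` as the
    cutoff; ``fixed`` requires an explicit cutoff (e.g. a published
    cross-platform constant). HRisk iff score > cutoff.
    """
    scores = np.asarray(list(scores), dtype=float)
    if scores.size == 0:
        raise EmptyInputError("cannot stratify an empty score list")
    if mode == "median":
        cut = float(np.median(scores))
    elif mode == "fixed":
        if cutoff is None:
            raise ParameterError("mode='fixed' requires a cutoff")
        cut = float(cutoff)
    else:
        raise ParameterError(f"unknown stratification mode {mode!r}")
    return [HRISK if s > cut else LRISK for s in scores]


def score_table(
    expr: pd.DataFrame,
    signature: GenePairSignature,
    mode: Literal["median", "fixed"] = "median",
    cutoff: float | None = None,
    missing_policy: Literal["strict", "drop"] = "strict",
) -> pd.DataFrame:
    """Score a cohort and stratify; returns sample, irgpi, group, n_pairs_used."""
    results = score_cohort(expr, signature, missing_policy=missing_policy)
    groups = stratify([r.irgpi for r in results], mode=mode, cutoff=cutoff)
    return pd.DataFrame(
        {
            "irgpi": [r.irgpi for r in results],
            "group": groups,
            "n_pairs_used": [r.n_pairs_used for r in results],
        },
        index=pd.Index([str(c) for c in expr.columns], name="sample"),
    )
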