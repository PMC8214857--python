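"""Within-sample expression-order indicators for gene pairs.

The central primitive of the whole package: for a gene pair (a, b) and a
sample s, the indicator is

    I(a, b; s) = 1  if  expr[a, s] < expr[b, s]   else 0   (ties -> 0).

Because the indicator depends only on the *order* of two expression values
inside one sample, it is exactly invariant under any strictly increasing
transform applied per sample (log, rank, positive affine, quantile
normalisation, ...). This is what makes a pair-based risk score portable
across microarray and RNA-seq platforms without cross-sample normalisation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

from .errors import EmptyCandidateError, MissingGeneError, ParameterError, ValidationError


class GenePair(NamedTuple):
    """An ordered gene pair; orientation is meaningful (indicator is a < b)."""

    gene_a: str
    gene_b: str

    def label(self) -> str:
        return f"{self.gene_a}<{self.gene_b}"


@dataclass
class PairIndicatorMatrix:
    """Binary pairs x samples matrix of expression-order indicators.

    ``data`` holds float values in {0.0, 1.0, NaN}; NaN marks an indicator
    whose underlying expression value was missing. Rows are indexed by pair
    labels ``"A<B"`` in the same order as ``pairs``.
    """

    pairs: list[GenePair]
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.pairs) != self.data.shape[0]:
            raise ValidationError("pair list and indicator matrix row count differ")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValidationError("duplicate gene pairs in indicator matrix")
        vals = self.data.to_numpy()
        finite = vals[~np.isnan(vals)]
        if not np.isin(finite, (0.0, 1.0)).all():
            raise ValidationError("indicator entries must be 0, 1 or missing")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, pairs: Sequence[GenePair]) -> "PairIndicatorMatrix":
        labels = [p.label() for p in pairs]
        return PairIndicatorMatrix(list(pairs), self.data.loc[labels])


def pair_indicator(x_a: float, x_b: float) -> float:
    """Order indicator for a single pair in a single sample.

    Returns 1.0 if ``x_a < x_b``, 0.0 otherwise (ties count as 0), and NaN
    if either value is missing.
    """
    if np.isnan(x_a) or np.isnan(x_b):
        return float("nan")
    return 1.0 if x_a < x_b else 0.0


def prefilter_genes(
    expr: pd.DataFrame,
    gene_set: Iterable[str],
    mad_threshold: float = 0.5,
) -> list[str]:
    """Restrict to gene-set members that vary across samples.

    Keeps genes present in both ``expr`` (rows) and ``gene_set`` whose raw
    median absolute deviation across samples exceeds ``mad_threshold``
    (unscaled MAD, i.e. median |x - median x|). Genes with zero spread can
    never flip a pair indicator and only inflate the candidate space.
    """
    if mad_threshold < 0:
        raise ParameterError("mad_threshold must be >= 0")
    genes = [g for g in expr.index if g in set(gene_set)]
    if not genes:
        raise EmptyCandidateError(
            "no overlap between expression matrix genes and the gene set; "
            "check identifier conventions (symbols vs probes) on both sides"
        )
    sub = expr.loc[genes]
    mad = median_abs_deviation(sub.to_numpy(), axis=1, scale=1.0, nan_policy="omit")
    kept = [g for g, m in zip(genes, mad) if m > mad_threshold or mad_threshold == 0]
    if not kept:
        raise EmptyCandidateError(
            f"no gene passed the MAD threshold {mad_threshold}; lower the threshold "
            "or check that the matrix is not constant"
        )
    return kept


def all_candidate_pairs(genes: Sequence[str]) -> list[GenePair]:
    """All unordered pairs of ``genes``, one canonical orientation each.

    Orientation is lexicographic (gene_a < gene_b as strings) so that the
    candidate space has g(g-1)/2 members; the complementary orientation
    carries the same information (its indicator is 1 minus this one on
    tie-free data).
    """
    uniq = list(dict.fromkeys(genes))
    return [GenePair(a, b) for a, b in itertools.combinations(sorted(uniq), 2)]


def build_indicator_matrix(expr: pd.DataFrame, pairs: Sequence[GenePair]) -> PairIndicatorMatrix:
    """Evaluate the order indicator for every pair in every sample.

    Raises :class:`MissingGeneError` naming the absent genes if any pair
    member is not a row of ``expr``.
    """
    pairs = list(pairs)
    needed = {g for p in pairs for g in p}
    absent = needed.difference(expr.index)
    if absent:
        raise MissingGeneError(absent)

    values = expr.to_numpy(dtype=float)
    row_of = {g: i for i, g in enumerate(expr.index)}
    ia = np.fromiter((row_of[p.gene_a] for p in pairs), dtype=int, count=len(pairs))
    ib = np.fromiter((row_of[p.gene_b] for p in pairs), dtype=int, count=len(pairs))
    xa, xb = values[ia], values[ib]
    ind = (xa < xb).astype(float)
    ind[np.isnan(xa) | np.isnan(xb)] = np.nan
    data = pd.DataFrame(ind, index=[p.label() for p in pairs], columns=expr.columns)
    return PairIndicatorMatrix(pairs, data)


def filter_informative_pairs(ind: PairIndicatorMatrix, f_min: float = 0.2) -> list[GenePair]:
    """Keep pairs whose order flips in a non-trivial fraction of samples.

    A pair whose indicator mean across samples lies outside
    ``[f_min, 1 - f_min]`` has (nearly) constant order and carries no
    discriminative information. ``f_min`` must lie in (0, 0.5).
    """
    if not 0 < f_min < 0.5:
        raise ParameterError(f"f_min must be in (0, 0.5), got {f_min}")
    vals = ind.data.to_numpy()
    if np.isnan(vals).any():
        warnings.warn("missing indicators present; frequencies computed over observed samples")
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(vals, axis=1)
    keep = (freq >= f_min) & (freq <= 1 - f_min)
    return [p for p, k in zip(ind.pairs, keep) if k]
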