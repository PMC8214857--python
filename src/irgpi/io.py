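"""File input/output and identifier harmonization.

Conventions
-----------
Expression matrices are genes x samples tables: first column gene
identifiers, header row sample identifiers. TSV/CSV are read as-is; GCT
v1.2 additionally carries a two-line preamble and a ``Description`` column,
both of which are dropped. Only the within-sample ordering of values is
used downstream, so any within-sample monotone-comparable scale (FPKM,
TPM, log-intensity, rank) is acceptable; units must not be mixed inside a
column.

Gene identifiers are matched by exact string after whitespace trimming; no
alias databases are consulted (an explicit user-supplied alias table can be
applied with :func:`apply_alias_map`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, ValidationError
from .signature import GenePairSignature

logger = logging.getLogger(__name__)

MONTHS_PER_YEAR = 12.0


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers (e.g. an immune gene list)."""

    genes: tuple[str, ...]
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError("gene set is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("gene set contains duplicate identifiers")

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# expression matrices


def _validate_expression(df: pd.DataFrame) -> pd.DataFrame:
    if df.shape[1] == 0:
        raise EmptyInputError("expression matrix has zero samples")
    if df.shape[0] < 2:
        raise EmptyInputError("expression matrix needs at least 2 genes")
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample identifiers: {dupes}")
    return df


def read_expression(
    path: str | Path,
    format: Literal["tsv", "csv", "gct"] | None = None,
    collapse: Literal["mean", "max", "maxvar"] = "mean",
) -> pd.DataFrame:
    """Read a genes x samples expression matrix.

    ``format`` defaults to the file suffix. Duplicate gene rows are
    collapsed with :func:`collapse_duplicates` (a warning reports how many).
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "txt":
        fmt = "tsv"
    try:
        if fmt == "tsv":
            df = pd.read_csv(path, sep="\t", index_col=0)
        elif fmt == "csv":
            df = pd.read_csv(path, sep=",", index_col=0)
        elif fmt == "gct":
            with open(path) as fh:
                magic = fh.readline().strip()
            if not magic.startswith("#1.2"):
                raise FormatError(f"{path}: not a GCT v1.2 file (first line {magic!r})")
            df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0)
            desc_cols = [c for c in df.columns if c.lower() == "description"]
            df = df.drop(columns=desc_cols)
        else:
            raise FormatError(f"unknown expression format {fmt!r} for {path}")
    except FormatError:
        raise
    except (pd.errors.ParserError, UnicodeDecodeError, ValueError) as exc:
        raise FormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    df = df.apply(pd.to_numeric, errors="coerce")
    df = _validate_expression(df)
    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        warnings.warn(f"{path.name}: collapsed {n_dup} duplicate gene row(s) by {collapse}")
        df = collapse_duplicates(df, method=collapse)
    logger.info("read %s: %d genes x %d samples", path.name, *df.shape)
    return df


def write_expression(df: pd.DataFrame, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt in ("tsv", "txt"):
        df.to_csv(path, sep="\t", index_label="gene")
    elif fmt == "csv":
        df.to_csv(path, index_label="gene")
    elif fmt == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
            out = df.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="Name")
    else:
        raise FormatError(f"unknown expression format {fmt!r}")


def collapse_duplicates(
    df: pd.DataFrame, method: Literal["mean", "max", "maxvar"] = "mean"
) -> pd.DataFrame:
    """Collapse duplicate gene rows to one row per identifier.

    ``mean``/``max`` aggregate element-wise; ``maxvar`` keeps, per gene, the
    single row with the largest variance across samples. Row order of first
    appearance is preserved.
    """
    if not df.index.duplicated().any():
        return df
    order = df.index.drop_duplicates()
    if method in ("mean", "max"):
        out = df.groupby(level=0, sort=False).agg(method)
    elif method == "maxvar":
        keep_pos = []
        variances = df.var(axis=1).to_numpy()
        idx = np.asarray(df.index)
        for gene in order:
            positions = np.flatnonzero(idx == gene)
            keep_pos.append(positions[np.argmax(variances[positions])])
        out = df.iloc[sorted(keep_pos)]
    else:
        raise ValidationError(f"unknown collapse method {method!r}")
    return out.loc[order]


# ---------------------------------------------------------------------------
# gene sets


def read_gene_set(path: str | Path, source_label: str | None = None) -> GeneSet:
    """Read a two-column TSV (gene, category); category may be absent."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"could not parse gene set {path}: {exc}") from exc
    # tolerate a header line of the form "gene<tab>category"
    first = str(df.iloc[0, 0]).strip().lower()
    if first in ("gene", "symbol", "gene_id"):
        df = df.iloc[1:]
    genes = [str(g).strip() for g in df.iloc[:, 0] if str(g).strip()]
    genes = list(dict.fromkeys(genes))
    if not genes:
        raise EmptyInputError(f"gene set {path} is empty")
    return GeneSet(tuple(genes), source_label or path.stem)


def apply_alias_map(df: pd.DataFrame, alias_path: str | Path) -> pd.DataFrame:
    """Rename genes via a user-supplied two-column TSV (old_id, new_id)."""
    aliases = pd.read_csv(alias_path, sep="\t", header=None, dtype=str)
    mapping = {str(a).strip(): str(b).strip() for a, b in zip(aliases[0], aliases[1])}
    out = df.rename(index=mapping)
    if out.index.duplicated().any():
        out = collapse_duplicates(out, method="mean")
    return out


# ---------------------------------------------------------------------------
# survival tables


def read_survival(
    path: str | Path, time_unit: Literal["months", "years"] = "months"
) -> pd.DataFrame:
    """Read a survival TSV with columns sample, time, event [, covariates...].

    Returns a DataFrame indexed by sample with ``time`` in months (years are
    converted), binary ``event`` (1 = death/event, 0 = censored), and any
    additional covariate columns untouched.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"could not parse survival table {path}: {exc}") from exc
    cols = {c.lower(): c for c in df.columns}
    for needed in ("sample", "time", "event"):
        if needed not in cols:
            raise FormatError(f"{path}: survival table must have a {needed!r} column")
    df = df.rename(columns={cols["sample"]: "sample", cols["time"]: "time", cols["event"]: "event"})
    df["sample"] = df["sample"].astype(str).str.strip()
    if df["sample"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample identifiers in survival table")
    df = df.set_index("sample")
    df["time"] = pd.to_numeric(df["time"])
    df["event"] = pd.to_numeric(df["event"])
    return validate_survival(df, time_unit=time_unit)


def validate_survival(
    df: pd.DataFrame, time_unit: Literal["months", "years"] = "months"
) -> pd.DataFrame:
    """Check survival invariants and normalise the time unit to months."""
    if df.empty:
        raise EmptyInputError("survival table is empty")
    if (df["time"] <= 0).any():
        bad = df.index[df["time"] <= 0].tolist()
        raise ValidationError(f"non-positive follow-up times for samples {bad}")
    if not df["event"].isin((0, 1)).all():
        raise ValidationError("event column must be binary (1=event, 0=censored)")
    df = df.copy()
    if time_unit == "years":
        df["time"] = df["time"] * MONTHS_PER_YEAR
    elif time_unit != "months":
        raise ValidationError(f"unknown time unit {time_unit!r}")
    df["event"] = df["event"].astype(int)
    return df


def write_survival(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample")


def align_samples(expr: pd.DataFrame, surv: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict both tables to their common samples, preserving expression order.

    Logs how many samples were dropped from each side; raises if the
    intersection is empty.
    """
    common = [s for s in expr.columns if s in set(surv.index)]
    if not common:
        raise EmptyInputError("expression matrix and survival table share no samples")
    dropped_expr = expr.shape[1] - len(common)
    dropped_surv = surv.shape[0] - len(common)
    if dropped_expr or dropped_surv:
        logger.warning(
            "sample join dropped %d expression column(s) and %d survival row(s); %d kept",
            dropped_expr,
            dropped_surv,
            len(common),
        )
    return expr[common], surv.loc[common]


# ---------------------------------------------------------------------------
# signatures (delegated to the dataclass; kept here for a uniform io surface)


def read_signature(path: str | Path) -> GenePairSignature:
    return GenePairSignature.read(path)


def write_signature(sig: GenePairSignature, path: str | Path) -> None:
    sig.write(path)
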