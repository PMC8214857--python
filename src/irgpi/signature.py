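"""The portable trained artifact: gene pairs, Cox coefficients, risk cutoff.

A signature is everything needed to score a *single* sample on any
platform: an ordered list of gene pairs, one coefficient per pair, and a
fixed cutoff separating high- from low-risk. The published bladder-cancer
model of this kind has 29 pairs and a cross-platform cutoff of 1.195; this
package treats pair list and cutoff as data, so any signature trained here
(or transcribed from a publication) travels through the same JSON file.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

from .errors import ValidationError
from .pairs import GenePair

SIGNATURE_FORMAT_VERSION = "1"


@dataclass
class GenePairSignature:
    """Gene-pair risk signature with Cox coefficients and a fixed cutoff.

    Attributes
    ----------
    pairs:
        Ordered gene pairs; orientation matters (indicator is
        ``expr[gene_a] < expr[gene_b]``).
    betas:
        One real coefficient per pair (log-hazard contribution of the
        indicator being 1).
    cutoff:
        Risk score threshold; scores strictly above it are high risk.
    metadata:
        Free-form training provenance (sample size, seed, config hash, ...).
    """

    pairs: list[GenePair]
    betas: list[float]
    cutoff: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.betas):
            raise ValidationError("pairs and betas must have equal length")
        if len(self.pairs) < 1:
            raise ValidationError("a signature needs at least one pair")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValidationError("duplicate pairs in signature")
        for p in self.pairs:
            if p.gene_a == p.gene_b:
                raise ValidationError(f"self-pair {p.gene_a!r} is not allowed")
        if not math.isfinite(self.cutoff):
            raise ValidationError("cutoff must be finite")
        if any(not math.isfinite(b) for b in self.betas):
            raise ValidationError("all coefficients must be finite")
        if any(b == 0.0 for b in self.betas):
            warnings.warn("signature contains zero coefficients; those pairs never contribute")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pairs:
            seen.setdefault(p.gene_a)
            seen.setdefault(p.gene_b)
        return list(seen)

    def beta_of(self) -> Mapping[GenePair, float]:
        return dict(zip(self.pairs, self.betas))

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "version": SIGNATURE_FORMAT_VERSION,
            "pairs": [
                {"gene_a": p.gene_a, "gene_b": p.gene_b, "beta": b}
                for p, b in zip(self.pairs, self.betas)
            ],
            "cutoff": self.cutoff,
            "trained_on": self.metadata,
        }

    @classmethod
    def from_dict(cls, doc: Mapping[str, Any]) -> "GenePairSignature":
        for key in ("pairs", "cutoff"):
            if key not in doc:
                raise ValidationError(f"signature document missing required key {key!r}")
        pairs: list[GenePair] = []
        betas: list[float] = []
        for entry in doc["pairs"]:
            for key in ("gene_a", "gene_b", "beta"):
                if key not in entry:
                    raise ValidationError(f"pair entry missing required key {key!r}")
            pairs.append(GenePair(str(entry["gene_a"]).strip(), str(entry["gene_b"]).strip()))
            betas.append(float(entry["beta"]))
        return cls(pairs, betas, float(doc["cutoff"]), dict(doc.get("trained_on", {})))

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "GenePairSignature":
        try:
            doc = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ValidationError(f"signature file {path} is not valid JSON: {exc}") from exc
        return cls.from_dict(doc)


def make_signature(
    pairs: Sequence[tuple[str, str]] | Sequence[GenePair],
    betas: Sequence[float],
    cutoff: float,
    **metadata: Any,
) -> GenePairSignature:
    """Convenience constructor accepting plain (gene_a, gene_b) tuples."""
    gp = [p if isinstance(p, GenePair) else GenePair(*p) for p in pairs]
    return GenePairSignature(gp, [float(b) for b in betas], float(cutoff), dict(metadata))
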