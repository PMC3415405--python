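"""Gene-set enrichment: the (N, B, n, b) factor and hypergeometric tail tests.

N is the background universe size, B the background genes in the set, n the
target (DE) list size, and b the intersection; the enrichment factor is
(b/n)/(B/N) and the p-value is the hypergeometric upper tail P(X >= b).
Gene identity is by exact symbol, with an optional alias map applied before
counting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError

__all__ = [
    "EnrichmentRecord",
    "enrichment_factor",
    "hypergeom_tail",
    "geneset_enrichment",
    "heart_overlap",
]


@dataclass(frozen=True)
class EnrichmentRecord:
    name: str
    N: int
    B: int
    n: int
    b: int
    factor: float
    p_value: float
    q_value: float | None = None

    def summary(self) -> str:
        """Human-readable ``factor (N,B,n,b)`` rendering, factor to 2 decimals."""
        return f"{self.factor:.2f} ({self.N},{self.B},{self.n},{self.b})"

    def to_dict(self) -> dict:
        return {
            "name": self.name, "N": self.N, "B": self.B, "n": self.n,
            "b": self.b, "factor": self.factor, "p_value": self.p_value,
            "q_value": self.q_value,
        }


def _check_quadruple(N: int, B: int, n: int, b: int) -> None:
    if n <= 0 or B <= 0:
        raise DataError(f"n and B must be positive (got n={n}, B={B})")
    if N < max(n, B):
        raise DataError(f"N={N} smaller than n={n} or B={B}")
    if not 0 <= b <= min(B, n):
        raise DataError(f"b={b} outside [0, min(B={B}, n={n})]")


def enrichment_factor(N: int, B: int, n: int, b: int) -> float:
    """(b/n)/(B/N): fold over-representation of a set within the target list."""
    _check_quadruple(N, B, n, b)
    return (b * N) / (n * B)


def hypergeom_tail(N: int, B: int, n: int, b: int) -> float:
    """Upper-tail P(X >= b) for X ~ Hypergeometric(N, B, n)."""
    _check_quadruple(N, B, n, b)
    return float(stats.hypergeom.sf(b - 1, N, B, n))


def _apply_aliases(genes: Iterable[str], aliases: Mapping[str, str] | None) -> set[str]:
    if aliases is None:
        return set(genes)
    return {aliases.get(g, g) for g in genes}


def geneset_enrichment(
    de: Iterable[str],
    background: Iterable[str],
    catalog: Mapping[str, Sequence[str]],
    aliases: Mapping[str, str] | None = None,
) -> list[EnrichmentRecord]:
    """Enrichment record per catalog set, sorted by p-value.

    Sets are intersected with the background before counting, so B counts
    only expressed set members. Sets with no background member are skipped.
    A Benjamini-Hochberg q-value is attached for information only.
    """
    bg = _apply_aliases(background, aliases)
    if not bg:
        raise DataError("empty background")
    de_set = _apply_aliases(de, aliases)
    if not de_set <= bg:
        extra = sorted(de_set - bg)
        raise DataError(f"DE genes outside the background: {extra[:10]}")
    N, n = len(bg), len(de_set)
    records = []
    for name, members in catalog.items():
        in_bg = _apply_aliases(members, aliases) & bg
        B = len(in_bg)
        if B == 0 or n == 0:
            continue
        b = len(in_bg & de_set)
        records.append(
            EnrichmentRecord(
                name, N, B, n, b,
                factor=enrichment_factor(N, B, n, b),
                p_value=hypergeom_tail(N, B, n, b),
            )
        )
    if records:
        _, q, _, _ = multipletests([r.p_value for r in records], method="fdr_bh")
        records = [replace(r, q_value=float(qv)) for r, qv in zip(records, q)]
    return sorted(records, key=lambda r: (r.p_value, r.name))


def heart_overlap(
    de: Iterable[str],
    heart_list: Iterable[str],
    background: Iterable[str],
    aliases: Mapping[str, str] | None = None,
) -> tuple[float, EnrichmentRecord]:
    """Fraction of DE genes in the heart-expressed list plus its enrichment record."""
    de_set = _apply_aliases(de, aliases)
    if not de_set:
        raise DataError("empty DE list")
    bg = _apply_aliases(background, aliases)
    heart = _apply_aliases(heart_list, aliases) & bg
    b = len(de_set & heart)
    fraction = b / len(de_set)
    record = EnrichmentRecord(
        "heart_expressed", len(bg), len(heart), len(de_set), b,
        factor=enrichment_factor(len(bg), len(heart), len(de_set), b),
        p_value=hypergeom_tail(len(bg), len(heart), len(de_set), b),
    )
    return fraction, record


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    """TSV-ready frame with N, B, n, b, factor, p, q columns."""
    return pd.DataFrame([r.to_dict() for r in records]).set_index("name")
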