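"""Positional statistics: per-chromosome DE enrichment and the test for runs
of contiguous DE genes (doublets, triplets).

"Contiguous" means adjacent in the ordering of expressed genes on the
chromosome (the background set); the null model places the chromosome's DE
genes uniformly at random among its expressed-gene positions. The exact
probability of seeing at least one run of length >= k is computed by
inclusion-exclusion over run-free arrangements; a Monte-Carlo fallback kicks
in when C(N, d) exceeds ``exact_limit``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneAnnotation
from .errors import DataError

__all__ = [
    "chromosome_enrichment",
    "find_runs",
    "cluster_pvalue",
    "triplet_scan",
    "runs_table",
    "ClusterTestResult",
    "EXACT_LIMIT",
]

EXACT_LIMIT = 10**6  # exact method mandatory below this C(N, d)


def chromosome_enrichment(
    de: Iterable[str], background: Iterable[str], ann: GeneAnnotation
) -> pd.DataFrame:
    """Hypergeometric over-representation of DE genes per chromosome.

    For chromosome c with N_c background genes, d_c of them DE, the p-value
    is the upper tail of drawing >= d_c chromosome genes when |de| genes are
    drawn from the |background| universe; the factor is
    (d_c / |de|) / (N_c / |background|).
    """
    de_set, bg_set = set(de), set(background)
    if not de_set <= bg_set:
        extra = sorted(de_set - bg_set)
        raise DataError(f"DE genes outside the background: {extra[:10]}")
    gt = ann.gene_table()
    unknown = (de_set | bg_set) - set(gt.index)
    if unknown:
        raise DataError(f"unannotated genes: {sorted(unknown)[:10]}")
    n_bg, n_de = len(bg_set), len(de_set)
    rows = []
    chrom_of = gt["chromosome"]
    for chrom in dict.fromkeys(chrom_of.loc[sorted(bg_set)]):
        on_c = {g for g in bg_set if chrom_of[g] == chrom}
        n_c = len(on_c)
        d_c = len(on_c & de_set)
        factor = (d_c / n_de) / (n_c / n_bg) if n_de else 0.0
        p = float(stats.hypergeom.sf(d_c - 1, n_bg, n_c, n_de))
        rows.append((chrom, n_c, d_c, factor, p))
    return pd.DataFrame(
        rows, columns=["chromosome", "n_genes", "n_de", "factor", "p"]
    ).set_index("chromosome")


def find_runs(flags: Sequence[bool], k: int) -> list[tuple[int, int]]:
    """Maximal runs of consecutive True values with length >= k.

    Returns (start index, run length) pairs; a run longer than k is reported
    once with its full length (maximal-run convention).
    """
    if k < 1:
        raise DataError("k must be >= 1")
    arr = np.asarray(flags, dtype=bool)
    runs = []
    start = None
    for i, v in enumerate(arr):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start >= k:
                runs.append((start, i - start))
            start = None
    if start is not None and len(arr) - start >= k:
        runs.append((start, len(arr) - start))
    return runs


def _count_run_free(n: int, d: int, k: int) -> int:
    """Arrangements of d ones among n positions with every run of ones < k.

    Inclusion-exclusion over compositions of d into (n - d + 1) parts of
    size <= k - 1.
    """
    z = n - d
    total = 0
    for j in range(d // k + 1):
        term = math.comb(z + 1, j) * math.comb(d - j * k + z, z)
        total += term if j % 2 == 0 else -term
    return total


@dataclass(frozen=True)
class ClusterTestResult:
    chromosome: str | None
    n_genes: int
    n_de: int
    run_length: int
    observed_runs: int
    p_value: float
    method: str  # exact-enumeration | monte-carlo
    n_sims: int | None = None
    se: float | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "chromosome": self.chromosome,
            "n_genes": self.n_genes,
            "n_de": self.n_de,
            "run_length": self.run_length,
            "observed_runs": self.observed_runs,
            "p_value": self.p_value,
            "method": self.method,
            "n_sims": self.n_sims,
            "se": self.se,
        }


def _mc_run_probability(
    n: int, d: int, k: int, n_sims: int, seed: int | None
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = max(1, min(n_sims, 20_000_000 // max(n, 1)))
    remaining = n_sims
    while remaining > 0:
        c = min(chunk, remaining)
        vals = rng.random((c, n))
        idx = np.argpartition(vals, d - 1, axis=1)[:, :d]
        member = np.zeros((c, n), dtype=np.int8)
        np.put_along_axis(member, idx, 1, axis=1)
        csum = np.concatenate(
            [np.zeros((c, 1), dtype=np.int32), member.cumsum(axis=1, dtype=np.int32)],
            axis=1,
        )
        windows = csum[:, k:] - csum[:, :-k]
        hits += int((windows == k).any(axis=1).sum())
        remaining -= c
    p = hits / n_sims
    se = math.sqrt(max(p * (1 - p), 1e-300) / n_sims)
    return p, se


def cluster_pvalue(
    n_genes: int,
    n_de: int,
    k: int,
    n_sims: int = 100_000,
    seed: int | None = None,
    method: str | None = None,
    observed_runs: int | None = None,
    chromosome: str | None = None,
) -> ClusterTestResult:
    """P(>= 1 run of >= k contiguous DE genes) under the uniform-placement null.

    Chooses exact inclusion-exclusion when C(n_genes, n_de) <= 10^6 (or when
    forced via ``method="exact"``), Monte-Carlo with ``n_sims`` draws
    otherwise; the Monte-Carlo p comes with its binomial standard error.
    """
    if not 0 < k <= n_de:
        raise DataError(f"need 0 < k <= n_de (got k={k}, n_de={n_de})")
    if n_de > n_genes:
        raise DataError(f"n_de={n_de} exceeds n_genes={n_genes}")
    if method is None:
        method = "exact" if math.comb(n_genes, n_de) <= EXACT_LIMIT else "monte-carlo"
    if method == "exact":
        total = math.comb(n_genes, n_de)
        p = 1.0 - _count_run_free(n_genes, n_de, k) / total
        return ClusterTestResult(
            chromosome, n_genes, n_de, k, observed_runs or 0, p, "exact-enumeration"
        )
    if method != "monte-carlo":
        raise DataError(f"unknown method {method!r}")
    p, se = _mc_run_probability(n_genes, n_de, k, n_sims, seed)
    return ClusterTestResult(
        chromosome, n_genes, n_de, k, observed_runs or 0, p,
        "monte-carlo", n_sims=n_sims, se=se, seed=seed,
    )


def triplet_scan(
    de: Iterable[str],
    background: Iterable[str],
    ann: GeneAnnotation,
    k_values: Sequence[int] = (2, 3),
    n_sims: int = 100_000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> list[ClusterTestResult]:
    """Run detection + cluster p-value per chromosome for each run length k.

    The reported p-value is the null probability of at least one run of
    length >= k when at least one run was observed, and 1 otherwise. Results
    with p < alpha mark candidate positional clusters.
    """
    de_set, bg = set(de), set(background)
    if not de_set:
        return []
    if not de_set <= bg:
        raise DataError("DE genes must be a subset of the background")
    results = []
    for chrom in ann.chromosomes():
        order = [g for g in ann.genes_on(chrom) if g in bg]
        if not order:
            continue
        flags = [g in de_set for g in order]
        d_c = sum(flags)
        for k in k_values:
            runs = find_runs(flags, k)
            if d_c < k or not runs:
                results.append(
                    ClusterTestResult(chrom, len(order), d_c, k, len(runs), 1.0, "none")
                )
                continue
            res = cluster_pvalue(
                len(order), d_c, k, n_sims=n_sims, seed=seed,
                observed_runs=len(runs), chromosome=chrom,
            )
            results.append(res)
    return results


def runs_table(
    de: Iterable[str],
    background: Iterable[str],
    ann: GeneAnnotation,
    k: int,
) -> pd.DataFrame:
    """BED-style listing of detected runs: chrom, start, end, gene list, length.

    Coordinates are 0-based half-open spans from the first to the last gene
    of the run.
    """
    de_set, bg = set(de), set(background)
    gt = ann.gene_table()
    rows = []
    for chrom in ann.chromosomes():
        order = [g for g in ann.genes_on(chrom) if g in bg]
        flags = [g in de_set for g in order]
        for start, length in find_runs(flags, k):
            members = order[start:start + length]
            rows.append(
                (
                    chrom,
                    int(gt.loc[members, "start"].min()),
                    int(gt.loc[members, "end"].max()),
                    ",".join(members),
                    length,
                )
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "genes", "length"])
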