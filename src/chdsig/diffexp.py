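"""Differential expression: pairwise t-tests with a global common variance,
one-way ANOVA, the group-merge decision, PCA scores, and DE selection.

The "global common variance" is the per-transcript within-group variance
pooled across every group supplied in ``variance_groups`` (degrees of freedom
sum(n_g - 1)); passing only the two contrasted groups recovers the ordinary
two-sample pooled t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, SampleSheet
from .errors import DataError

__all__ = [
    "pooled_variance_ttest",
    "anova",
    "expected_null_count",
    "merge_decision",
    "MergeDecision",
    "pca_scores",
    "de_select",
    "pvalue_uniformity",
]


def _group_arrays(
    m: ExpressionMatrix, sheet: SampleSheet, groups: Sequence[str]
) -> dict[str, np.ndarray]:
    out = {}
    for g in groups:
        samples = sheet.samples(g)
        if len(samples) < 2:
            raise DataError(f"group {g!r} has fewer than 2 samples")
        out[g] = m.values[samples].to_numpy(dtype=float)
    return out


def pooled_variance_ttest(
    m: ExpressionMatrix,
    sheet: SampleSheet,
    group_a: str,
    group_b: str,
    variance_groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-transcript t-test of ``group_a`` vs ``group_b``.

    The variance is pooled over ``variance_groups`` (default: the two
    contrasted groups): s2 = sum (n_g - 1) s2_g / sum (n_g - 1), with
    t = (mean_a - mean_b) / sqrt(s2 (1/n_a + 1/n_b)) on df = sum (n_g - 1).

    Returns a frame indexed like the matrix with columns ``mean_a``,
    ``mean_b``, ``s2``, ``df``, ``t``, ``p``, ``ratio`` (geometric, linear
    scale) and ``zero_variance``.
    """
    if variance_groups is None:
        variance_groups = (group_a, group_b)
    if group_a not in variance_groups or group_b not in variance_groups:
        raise DataError("both contrasted groups must be in variance_groups")
    arrays = _group_arrays(m, sheet, variance_groups)
    a, b = arrays[group_a], arrays[group_b]
    n_a, n_b = a.shape[1], b.shape[1]

    df = sum(arr.shape[1] - 1 for arr in arrays.values())
    ss_within = sum(
        ((arr - arr.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        for arr in arrays.values()
    )
    s2 = ss_within / df
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    delta = mean_a - mean_b

    zero = s2 == 0
    if np.any(zero & (delta != 0)):
        bad = m.probe_ids[zero & (delta != 0)].tolist()
        raise DataError(
            f"zero pooled variance with unequal means for: {bad[:10]}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / np.sqrt(s2 * (1.0 / n_a + 1.0 / n_b))
    t = np.where(zero, 0.0, t)
    p = np.where(zero, 1.0, 2.0 * stats.t.sf(np.abs(t), df))
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "s2": s2,
            "df": df,
            "t": t,
            "p": p,
            "ratio": np.exp2(delta),
            "zero_variance": zero,
        },
        index=m.probe_ids,
    )


def anova(
    m: ExpressionMatrix, sheet: SampleSheet, groups: Sequence[str]
) -> pd.DataFrame:
    """Per-transcript one-way ANOVA across ``groups`` (columns F, p, dfs)."""
    if len(groups) < 2:
        raise DataError("ANOVA requires >= 2 groups")
    arrays = _group_arrays(m, sheet, groups)
    all_x = np.concatenate(list(arrays.values()), axis=1)
    n_total = all_x.shape[1]
    grand = all_x.mean(axis=1)
    ss_between = sum(
        arr.shape[1] * (arr.mean(axis=1) - grand) ** 2 for arr in arrays.values()
    )
    ss_within = sum(
        ((arr - arr.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        for arr in arrays.values()
    )
    df_between = len(groups) - 1
    df_within = n_total - len(groups)
    degenerate = ss_within == 0
    if np.any(degenerate & (ss_between > 0)):
        bad = m.probe_ids[degenerate & (ss_between > 0)].tolist()
        raise DataError(f"zero within-group variance with group separation for: {bad[:10]}")
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_between) / (ss_within / df_within)
    f = np.where(degenerate, 0.0, f)
    p = np.where(degenerate, 1.0, stats.f.sf(f, df_between, df_within))
    return pd.DataFrame(
        {
            "F": f,
            "p": p,
            "df_between": df_between,
            "df_within": df_within,
            "zero_variance": degenerate,
        },
        index=m.probe_ids,
    )


def expected_null_count(m: int, alpha: float) -> int:
    """Expected number of sub-``alpha`` p-values among ``m`` null tests."""
    if m < 0:
        raise DataError("m must be >= 0")
    if not 0.0 < alpha < 1.0:
        raise DataError("alpha must be in (0, 1)")
    return int(round(m * alpha))


@dataclass(frozen=True)
class MergeDecision:
    """Outcome of the p-value deficit check driving a group merge."""

    contrast: str
    m: int
    observed_count: int
    expected_count: int
    alpha: float
    merged: bool
    binomial_p: float
    ecdf_curve: pd.DataFrame  # columns p, ecdf

    def to_dict(self) -> dict:
        return {
            "contrast": self.contrast,
            "m": self.m,
            "observed_count": self.observed_count,
            "expected_count": self.expected_count,
            "alpha": self.alpha,
            "merged": self.merged,
            "binomial_p": self.binomial_p,
        }


def merge_decision(
    pvals: Sequence[float] | np.ndarray | pd.Series,
    alpha: float = 0.01,
    contrast: str = "",
) -> MergeDecision:
    """Decide whether a contrast shows fewer small p-values than the null expects.

    ``merged`` is True when the observed count of p < alpha falls strictly
    below round(m * alpha). The one-sided lower-tail binomial probability and
    the empirical CDF are attached as diagnostics, not gates.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise DataError("merge_decision requires a non-empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    observed = int((p < alpha).sum())
    expected = expected_null_count(m, alpha)
    sorted_p = np.sort(p)
    ecdf = pd.DataFrame(
        {"p": sorted_p, "ecdf": np.arange(1, m + 1) / m}
    )
    return MergeDecision(
        contrast=contrast,
        m=m,
        observed_count=observed,
        expected_count=expected,
        alpha=alpha,
        merged=observed < expected,
        binomial_p=float(stats.binom.cdf(observed, m, alpha)),
        ecdf_curve=ecdf,
    )


def pca_scores(
    m: ExpressionMatrix, n_components: int = 3
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Sample scores of a PCA on row-centered transcripts.

    Transcripts are centered per row before decomposition; the sign of each
    component is fixed by forcing its largest-magnitude transcript loading
    positive, so scores are fully deterministic.

    Returns (scores samples x PC, explained_variance, explained_ratio).
    """
    max_comp = min(m.n_samples, m.n_probes)
    if n_components > max_comp:
        raise DataError(
            f"n_components={n_components} exceeds min(samples, transcripts)={max_comp}"
        )
    x = m.values.to_numpy(dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    # samples as observations: SVD of the samples x transcripts matrix
    u, s, vt = np.linalg.svd(centered.T, full_matrices=False)
    for i in range(n_components):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    scores = u[:, :n_components] * s[:n_components]
    explained = s**2 / max(m.n_samples - 1, 1)
    ratio = explained / explained.sum() if explained.sum() > 0 else explained
    frame = pd.DataFrame(
        scores,
        index=m.sample_ids,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return frame, explained[:n_components], ratio[:n_components]


def de_select(pvals: pd.Series, alpha: float = 0.05) -> pd.Index:
    """Ids with p < alpha (the DE call used throughout the pipeline)."""
    p = pvals.astype(float)
    if np.any((p < 0) | (p > 1)):
        raise DataError("p-values must lie in [0, 1]")
    return p.index[p < alpha]


def pvalue_uniformity(pvals: Sequence[float] | np.ndarray) -> tuple[float, float]:
    """Kolmogorov-Smirnov statistic and p-value of the p-values against U(0,1)."""
    res = stats.kstest(np.asarray(pvals, dtype=float), "uniform")
    return float(res.statistic), float(res.pvalue)
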