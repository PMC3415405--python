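"""Entry-stage transforms: detection-based expression calls, quantile
normalization, and probe-to-gene collapsing."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneAnnotation, SampleSheet
from .errors import DataError

__all__ = ["expression_call", "quantile_normalize", "collapse_probes"]


def expression_call(
    m: ExpressionMatrix,
    sheet: SampleSheet,
    groups: Sequence[str],
    alpha: float = 0.01,
    min_arrays: int = 4,
) -> ExpressionMatrix:
    """Keep probes called expressed in every named group.

    A probe is retained when, in **each** group, at least ``min_arrays``
    samples have detection p-value below ``alpha``. Probe order and the
    sample set are unchanged.
    """
    if m.detection_p is None:
        raise DataError("expression_call requires detection p-values")
    if not groups:
        raise DataError("expression_call requires at least one group")
    keep = pd.Series(True, index=m.probe_ids)
    for group in groups:
        samples = sheet.samples(group)
        if len(samples) < min_arrays:
            raise DataError(
                f"group {group!r} has {len(samples)} samples, fewer than "
                f"min_arrays={min_arrays}"
            )
        detected = (m.detection_p[samples] < alpha).sum(axis=1)
        keep &= detected >= min_arrays
    return m.subset_probes(m.probe_ids[keep])


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the shared reference distribution.

    The reference is the across-sample mean of sorted values. After the
    transform every sample's sorted vector equals the reference; within-sample
    rank order is preserved; tied values within a sample receive the mean of
    the reference values over the tied span.
    """
    if m.n_samples < 2:
        raise DataError("quantile normalization requires >= 2 samples")
    x = m.values.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise DataError("quantile normalization does not accept missing values")
    n, _ = x.shape
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="stable")
        col = np.empty(n)
        col[order] = reference
        # ties: average the reference over each tied span
        vals = x[order, j]
        boundaries = np.flatnonzero(np.diff(vals) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n]))
        for s, e in zip(starts, ends):
            if e - s > 1:
                col[order[s:e]] = reference[s:e].mean()
        out[:, j] = col
    values = pd.DataFrame(out, index=m.probe_ids, columns=m.sample_ids)
    return ExpressionMatrix(values, m.detection_p)


def collapse_probes(
    m: ExpressionMatrix,
    ann: GeneAnnotation,
    rule: str = "max-mean",
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Collapse a probe-level matrix to one row per gene.

    With ``rule="max-mean"`` the probe with the highest mean intensity
    represents its gene; with ``rule="first"`` the first probe in matrix
    order does. Returns the gene-level matrix and the gene -> probe mapping
    actually used.
    """
    if rule not in ("max-mean", "first"):
        raise DataError(f"unknown collapse rule {rule!r}")
    missing = m.probe_ids.difference(ann.probe_ids)
    if len(missing):
        raise DataError(f"unannotated probes: {missing.tolist()[:10]}")
    gene_of = ann.table["gene"].reindex(m.probe_ids)
    if rule == "max-mean":
        means = m.values.mean(axis=1)
        # stable: ties broken by probe order
        ranked = pd.DataFrame({"gene": gene_of, "mean": means})
        ranked["order"] = np.arange(len(ranked))
        ranked = ranked.sort_values(["mean", "order"], ascending=[False, True], kind="stable")
        chosen = ranked.drop_duplicates("gene")
    else:
        chosen = pd.DataFrame({"gene": gene_of}).drop_duplicates("gene")
    # keep genes in first-appearance order of the probe matrix
    first_seen = pd.DataFrame({"gene": gene_of}).drop_duplicates("gene")["gene"]
    probe_for = pd.Series(chosen.index.to_numpy(), index=chosen["gene"].to_numpy())
    probes = probe_for.loc[first_seen].to_numpy()
    values = m.values.loc[probes].copy()
    values.index = pd.Index(first_seen.to_numpy(), name="gene")
    det = None
    if m.detection_p is not None:
        det = m.detection_p.loc[probes].copy()
        det.index = values.index
    mapping = pd.DataFrame(
        {"probe_id": probes}, index=values.index
    )
    return ExpressionMatrix(values, det), mapping
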