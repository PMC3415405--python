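"""Readers and writers for the plain-text interchange formats.

Expression matrices use the GenomeStudio-style layout: a ``probe_id`` column
followed by ``AVG_Signal.<sample>`` and ``Detection.Pval.<sample>`` column
pairs. Gene sets use the standard GMT layout (name, description, tab-separated
members). Everything is TSV so artifacts stay diffable.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import pandas as pd

from .datatypes import ExpressionMatrix, GeneAnnotation, SampleSheet
from .errors import DataError

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "read_sample_sheet_tsv",
    "write_sample_sheet_tsv",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
]

_SIGNAL = "AVG_Signal."
_DETECT = "Detection.Pval."


def write_expression_tsv(m: ExpressionMatrix, path: str | os.PathLike) -> None:
    cols: dict[str, pd.Series] = {}
    for s in m.sample_ids:
        cols[_SIGNAL + s] = m.values[s]
        if m.detection_p is not None:
            cols[_DETECT + s] = m.detection_p[s]
    out = pd.DataFrame(cols, index=m.probe_ids)
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


def read_expression_tsv(path: str | os.PathLike) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    sig = [c for c in df.columns if c.startswith(_SIGNAL)]
    det = [c for c in df.columns if c.startswith(_DETECT)]
    if not sig:
        raise DataError(f"{path}: no {_SIGNAL}* columns found")
    samples = [c[len(_SIGNAL):] for c in sig]
    values = df[sig].copy()
    values.columns = samples
    detection = None
    if det:
        det_samples = [c[len(_DETECT):] for c in det]
        if sorted(det_samples) != sorted(samples):
            raise DataError(f"{path}: signal and detection columns name different samples")
        detection = df[[_DETECT + s for s in samples]].copy()
        detection.columns = samples
    return ExpressionMatrix(values, detection)


def write_annotation_tsv(ann: GeneAnnotation, path: str | os.PathLike) -> None:
    out = ann.table.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def read_annotation_tsv(path: str | os.PathLike) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    return GeneAnnotation(df)


def write_sample_sheet_tsv(sheet: SampleSheet, path: str | os.PathLike) -> None:
    out = sheet.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_sample_sheet_tsv(path: str | os.PathLike) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return SampleSheet(df)


def write_gmt(
    catalog: Mapping[str, Sequence[str]],
    path: str | os.PathLike,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for name, members in catalog.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    catalog: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            if name in catalog:
                raise DataError(f"{path}:{lineno}: duplicate gene set {name!r}")
            catalog[name] = [g for g in fields[2:] if g]
    return catalog


def write_gene_list(genes: Sequence[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gene_list(path: str | os.PathLike) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
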