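"""Core data containers: expression matrix, gene annotation, sample sheet.

All three are thin, validated wrappers around :class:`pandas.DataFrame` so
that downstream stages can rely on a consistent shape without re-checking.
Coordinates are 0-based half-open; chromosome names are normalized to the
``chr*`` form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["ExpressionMatrix", "GeneAnnotation", "SampleSheet", "normalize_chrom"]


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name to the ``chr*`` convention."""
    name = str(name).strip()
    return name if name.lower().startswith("chr") else f"chr{name}"


@dataclass(frozen=True)
class ExpressionMatrix:
    """Probe (or gene) x sample log2 intensities with optional detection p-values.

    Parameters
    ----------
    values
        Log2 intensities, rows indexed by probe/gene id, columns by sample id.
    detection_p
        Per-cell detection p-values in [0, 1], same shape and labels as
        ``values``. May be ``None`` for gene-level matrices after collapsing.
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate probe ids: {dupes[:5]}")
        if v.columns.duplicated().any():
            dupes = v.columns[v.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample ids: {dupes[:5]}")
        d = self.detection_p
        if d is not None:
            if d.shape != v.shape:
                raise DataError(
                    f"values {v.shape} and detection_p {d.shape} differ in shape"
                )
            if not (d.index.equals(v.index) and d.columns.equals(v.columns)):
                raise DataError("values and detection_p labels differ")
            arr = d.to_numpy()
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise DataError("detection p-values outside [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_probes(self, ids) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``ids`` (order preserved as given)."""
        det = None if self.detection_p is None else self.detection_p.loc[ids]
        return ExpressionMatrix(self.values.loc[ids], det)

    def subset_samples(self, ids) -> "ExpressionMatrix":
        det = None if self.detection_p is None else self.detection_p[list(ids)]
        return ExpressionMatrix(self.values[list(ids)], det)


@dataclass(frozen=True)
class GeneAnnotation:
    """Probe -> (gene, chromosome, start, end) map with per-chromosome gene order.

    ``table`` is indexed by probe id with columns ``gene``, ``chromosome``,
    ``start``, ``end``. Genomic coordinates are 0-based half-open. The gene
    order on a chromosome is the order of gene start coordinates.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "chromosome", "start", "end"}
        missing = required - set(self.table.columns)
        if missing:
            raise DataError(f"annotation missing columns: {sorted(missing)}")
        if self.table.index.duplicated().any():
            raise DataError("annotation contains duplicate probe ids")
        # Each gene must live on a single chromosome at a single locus.
        spans = self.table.groupby("gene")["chromosome"].nunique()
        multi = spans[spans > 1]
        if len(multi):
            raise DataError(
                f"genes annotated on multiple chromosomes: {multi.index.tolist()[:5]}"
            )
        object.__setattr__(
            self, "table", self.table.assign(
                chromosome=self.table["chromosome"].map(normalize_chrom)
            )
        )

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def gene_of(self, probe_id: str) -> str:
        return self.table.at[probe_id, "gene"]

    def gene_table(self) -> pd.DataFrame:
        """One row per gene: chromosome, start, end (span over its probes)."""
        g = self.table.groupby("gene", sort=False)
        out = pd.DataFrame(
            {
                "chromosome": g["chromosome"].first(),
                "start": g["start"].min(),
                "end": g["end"].max(),
            }
        )
        return out

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chromosome"]))

    def genes_on(self, chromosome: str) -> list[str]:
        """Genes on ``chromosome`` ordered by start coordinate (then name)."""
        gt = self.gene_table()
        sub = gt[gt["chromosome"] == normalize_chrom(chromosome)]
        sub = sub.sort_values(["start", "end"], kind="stable")
        return sub.index.tolist()


@dataclass(frozen=True)
class SampleSheet:
    """Sample -> group assignment (optionally with covariate columns).

    ``table`` is indexed by sample id and carries at least a ``group`` column.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "group" not in self.table.columns:
            raise DataError("sample sheet must have a 'group' column")
        if self.table.index.duplicated().any():
            raise DataError("sample sheet contains duplicate sample ids")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.table["group"]))

    def samples(self, group: str) -> list[str]:
        sel = self.table.index[self.table["group"] == group]
        if len(sel) == 0:
            raise DataError(f"no samples in group {group!r}")
        return sel.tolist()

    def group_sizes(self) -> dict[str, int]:
        return self.table["group"].value_counts().to_dict()

    def merged(self, parts: tuple[str, ...] = ("ASD", "VSD"), name: str = "ASD+VSD") -> "SampleSheet":
        """Return a sheet with the given groups relabelled as one merged group."""
        for p in parts:
            if p not in set(self.table["group"]):
                raise DataError(f"cannot merge: group {p!r} absent from sample sheet")
        tab = self.table.copy()
        tab.loc[tab["group"].isin(parts), "group"] = name
        return SampleSheet(tab)
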