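"""Synthetic expression datasets with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: log2-scale intensities with per-gene noise, a ~1.5x dosage effect on
a subset of trisomy-chromosome genes in all trisomic samples, group-specific
differentially expressed genes, an optional planted run of contiguous DE
genes on one chromosome, genes planted to satisfy each of the four dosage
classes, and detection p-values that fail for low-intensity probes.

Everything is driven by one seed; sub-streams for structure, intensities,
and detection are derived with ``numpy.random.SeedSequence.spawn`` so the
same configuration always reproduces byte-identical artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneAnnotation, SampleSheet, normalize_chrom
from .errors import ConfigError

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "EnrichedSetSpec",
    "generate_dataset",
    "generate_genesets",
    "CLASS_LABELS",
]

CLASS_LABELS = ("IA", "IB", "IIA", "IIB")

#: default cohort sizes
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "2N": 12,
    "CHD-": 22,
    "AVSD": 7,
    "ASD": 8,
    "VSD": 6,
}

_DEFAULT_CHROM_WEIGHTS = {
    "chr1": 0.14, "chr2": 0.12, "chr7": 0.10, "chr11": 0.10, "chr16": 0.09,
    "chr17": 0.09, "chr19": 0.10, "chr20": 0.08, "chr21": 0.08, "chr22": 0.10,
}


def _default_chromosomes(n_genes: int) -> tuple[tuple[str, int], ...]:
    counts = {c: int(round(w * n_genes)) for c, w in _DEFAULT_CHROM_WEIGHTS.items()}
    # fix rounding drift on the largest chromosome
    drift = n_genes - sum(counts.values())
    counts["chr1"] += drift
    return tuple((c, n) for c, n in counts.items() if n > 0)


@dataclass
class SimConfig:
    """Parameters of one synthetic dataset.

    ``class_quota`` genes receive an effect pair (trisomy-vs-control effect
    ``e1`` applied to every trisomic sample, case-vs-rest effect ``e2``
    applied additionally to ``class_target`` samples) built to satisfy the
    four-class dosage rules on the true effects.
    """

    n_genes: int = 600
    chromosomes: tuple[tuple[str, int], ...] | None = None
    two_probe_fraction: float = 0.15
    group_sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    trisomy_chrom: str = "chr21"
    dosage_fraction: float = 0.30
    dosage_log2fc: float = math.log2(1.5)
    n_de_per_contrast: int = 40
    de_log2fc_range: tuple[float, float] = (0.4, 1.0)
    de_contrasts: tuple[str, ...] = ("AVSD", "ASD+VSD")
    planted_cluster: tuple[str, int, int, str] | None = None
    cluster_log2fc: float = 1.0
    class_quota: Mapping[str, int] = field(
        default_factory=lambda: {c: 0 for c in CLASS_LABELS}
    )
    class_target: str = "AVSD"
    class_base_effect: float = 0.6
    class_gap: float = 0.2
    class_equality_gap: float = 0.04
    noise_sd: tuple[float, float] = (0.2, 0.3)
    group_noise_scale: Mapping[str, float] = field(default_factory=dict)
    baseline_range: tuple[float, float] = (5.0, 11.0)
    detection_floor: float = 6.0
    seed: int = 0

    def resolved_chromosomes(self) -> tuple[tuple[str, int], ...]:
        if self.chromosomes is not None:
            return tuple((normalize_chrom(c), int(n)) for c, n in self.chromosomes)
        return _default_chromosomes(self.n_genes)

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        chroms = self.resolved_chromosomes()
        if any(n <= 0 for _, n in chroms):
            raise ConfigError("chromosome gene counts must be positive")
        if self.chromosomes is None and self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if not 0.0 <= self.dosage_fraction <= 1.0:
            raise ConfigError("dosage_fraction must be in [0, 1]")
        if not 0.0 <= self.two_probe_fraction <= 1.0:
            raise ConfigError("two_probe_fraction must be in [0, 1]")
        if self.n_de_per_contrast < 0:
            raise ConfigError("n_de_per_contrast must be >= 0")
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ConfigError(f"group {g!r} must have >= 2 samples (got {n})")
        by_name = dict(chroms)
        if normalize_chrom(self.trisomy_chrom) not in by_name:
            raise ConfigError(f"trisomy chromosome {self.trisomy_chrom!r} not simulated")
        if self.planted_cluster is not None:
            chrom, start, k, contrast = self.planted_cluster
            chrom = normalize_chrom(chrom)
            if chrom not in by_name:
                raise ConfigError(f"planted cluster chromosome {chrom!r} not simulated")
            if k < 1 or start < 0 or start + k > by_name[chrom]:
                raise ConfigError(
                    f"planted cluster [{start}, {start + k}) does not fit on "
                    f"{chrom} ({by_name[chrom]} genes)"
                )
            self._check_contrast_groups(contrast)
        for c in self.de_contrasts:
            self._check_contrast_groups(c)
        lo, hi = self.de_log2fc_range
        if lo > hi or lo < 0:
            raise ConfigError("de_log2fc_range must be 0 <= lo <= hi")
        lo, hi = self.noise_sd
        if lo > hi or lo <= 0:
            raise ConfigError("noise_sd must be 0 < lo <= hi")
        for g, s in self.group_noise_scale.items():
            if g not in self.group_sizes:
                raise ConfigError(f"group_noise_scale names unknown group {g!r}")
            if s <= 0:
                raise ConfigError("group noise scales must be positive")
        self._validate_class_quota()

    def _check_contrast_groups(self, contrast: str) -> None:
        for g in contrast.split("+"):
            if g not in self.group_sizes:
                raise ConfigError(f"contrast {contrast!r} names unknown group {g!r}")

    def _validate_class_quota(self) -> None:
        quota = {c: int(self.class_quota.get(c, 0)) for c in CLASS_LABELS}
        unknown = set(self.class_quota) - set(CLASS_LABELS)
        if unknown:
            raise ConfigError(f"unknown class labels in quota: {sorted(unknown)}")
        if any(v < 0 for v in quota.values()):
            raise ConfigError("class quota counts must be >= 0")
        if sum(quota.values()) == 0:
            return
        self._check_contrast_groups(self.class_target)
        base, gap, eq = self.class_base_effect, self.class_gap, self.class_equality_gap
        band_hi = math.log2(1.05)
        if quota["IA"] and (base <= 0 or gap <= 0):
            raise ConfigError("class IA infeasible: needs class_base_effect > 0 and class_gap > 0")
        if quota["IB"] and base <= 0:
            raise ConfigError("class IB infeasible: needs class_base_effect > 0")
        if quota["IIA"] and (base - gap <= 0 or 2 * gap <= band_hi):
            raise ConfigError(
                "class IIA infeasible: needs class_gap < class_base_effect and "
                "2*class_gap outside the equality band"
            )
        if quota["IIB"] and not (0 < eq <= band_hi and base - eq > 0):
            raise ConfigError(
                "class IIB infeasible: class_equality_gap must lie in "
                f"(0, {band_hi:.4f}] and below class_base_effect"
            )


@dataclass
class SyntheticTruth:
    """Ground truth attached to one simulated dataset (gene-level)."""

    de_flags: pd.DataFrame          # genes x contrasts, bool
    effect_log2fc: pd.DataFrame     # genes x contrasts, float
    trisomy_log2fc: pd.Series       # gene -> trisomy-vs-2N planted effect
    class_label: pd.Series          # gene -> {IA, IB, IIA, IIB, none}
    cluster_members: list[str]
    dosage_genes: list[str]

    def contrasts(self) -> list[str]:
        return list(self.de_flags.columns)


# ---------------------------------------------------------------------------


def _class_effect_pair(label: str, sign: int, cfg: SimConfig) -> tuple[float, float]:
    """True (e1, e2) for a planted class gene; e1 = trisomy-vs-2N, e2 = case-vs-rest."""
    base, gap, eq = cfg.class_base_effect, cfg.class_gap, cfg.class_equality_gap
    if label == "IA":
        return sign * base, sign * (base + gap)
    if label == "IB":
        return 0.0, sign * base
    if label == "IIA":
        return sign * (base + gap), -sign * (base - gap)
    if label == "IIB":
        return sign * base, -sign * (base - eq)
    raise ConfigError(f"unknown class label {label!r}")


def generate_dataset(
    config: SimConfig,
) -> tuple[ExpressionMatrix, GeneAnnotation, SampleSheet, SyntheticTruth]:
    """Simulate a probe-level expression matrix plus annotation, sheet, and truth.

    Intensities are additive on log2 scale: per-probe baseline + gene-level
    group effects + Normal(0, sigma_gene) noise. Trisomic samples (every
    group except ``2N``) receive ``dosage_log2fc`` on the dosage genes.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_intensity, rng_detect = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    # -- annotation ------------------------------------------------------
    chroms = config.resolved_chromosomes()
    genes: list[str] = []
    gene_chrom: list[str] = []
    gene_start: list[int] = []
    gi = 0
    for chrom, n in chroms:
        for j in range(n):
            genes.append(f"G{gi:05d}")
            gene_chrom.append(chrom)
            gene_start.append(1000 * (j + 1))
            gi += 1
    n_genes = len(genes)
    gene_idx = pd.Index(genes, name="gene")

    n_probes_per_gene = 1 + (rng_struct.random(n_genes) < config.two_probe_fraction)
    probe_rows: list[tuple[str, str, str, int, int]] = []
    pi = 0
    for g, chrom, start, np_g in zip(genes, gene_chrom, gene_start, n_probes_per_gene):
        for _ in range(int(np_g)):
            probe_rows.append((f"P{pi:05d}", g, chrom, start, start + 500))
            pi += 1
    ann_table = pd.DataFrame(
        probe_rows, columns=["probe_id", "gene", "chromosome", "start", "end"]
    ).set_index("probe_id")
    annotation = GeneAnnotation(ann_table)

    # -- sample sheet ----------------------------------------------------
    sample_ids: list[str] = []
    sample_group: list[str] = []
    for group, n in config.group_sizes.items():
        for j in range(int(n)):
            sample_ids.append(f"{group}_{j + 1:02d}")
            sample_group.append(group)
    sheet = SampleSheet(pd.DataFrame({"group": sample_group}, index=pd.Index(sample_ids, name="sample_id")))
    n_samples = len(sample_ids)
    group_arr = np.asarray(sample_group)

    # -- special gene selection (structure stream) -----------------------
    trisomy = normalize_chrom(config.trisomy_chrom)
    tri_genes = [g for g, c in zip(genes, gene_chrom) if c == trisomy]
    n_dosage = int(round(config.dosage_fraction * len(tri_genes)))
    dosage_genes = sorted(
        rng_struct.choice(tri_genes, size=n_dosage, replace=False).tolist()
    ) if n_dosage else []

    cluster_members: list[str] = []
    cluster_contrast = None
    if config.planted_cluster is not None:
        chrom, start, k, cluster_contrast = config.planted_cluster
        on_chrom = annotation.genes_on(chrom)
        cluster_members = on_chrom[start:start + k]

    contrasts = list(
        dict.fromkeys(
            [*config.de_contrasts]
            + ([cluster_contrast] if cluster_contrast else [])
            + ([config.class_target] if sum(config.class_quota.values()) else [])
        )
    )
    effect = pd.DataFrame(0.0, index=gene_idx, columns=contrasts, dtype=float)

    reserved = set(cluster_members) | set(tri_genes)
    pool = [g for g in genes if g not in reserved]

    # class-quota genes (kept off the trisomy chromosome so the planted
    # e1/e2 pair is not confounded by the dosage effect)
    class_label = pd.Series("none", index=gene_idx, name="class_label")
    e1 = pd.Series(0.0, index=gene_idx)  # trisomy-vs-2N effect
    quota = {c: int(config.class_quota.get(c, 0)) for c in CLASS_LABELS}
    n_class = sum(quota.values())
    if n_class:
        if n_class > len(pool):
            raise ConfigError("class quota exceeds available genes")
        chosen = rng_struct.choice(pool, size=n_class, replace=False).tolist()
        pool = [g for g in pool if g not in set(chosen)]
        pos = 0
        for label in CLASS_LABELS:
            for _ in range(quota[label]):
                g = chosen[pos]
                pos += 1
                sign = 1 if rng_struct.random() < 0.5 else -1
                ge1, ge2 = _class_effect_pair(label, sign, config)
                class_label[g] = label
                e1[g] = ge1
                effect.loc[g, config.class_target] = ge2

    # generic per-contrast DE genes
    lo, hi = config.de_log2fc_range
    for contrast in config.de_contrasts:
        n_de = min(config.n_de_per_contrast, len(pool))
        if n_de == 0:
            continue
        chosen = rng_struct.choice(pool, size=n_de, replace=False).tolist()
        pool = [g for g in pool if g not in set(chosen)]
        mags = rng_struct.uniform(lo, hi, size=n_de)
        signs = np.where(rng_struct.random(n_de) < 0.5, 1.0, -1.0)
        effect.loc[chosen, contrast] = mags * signs

    if cluster_members:
        effect.loc[cluster_members, cluster_contrast] = config.cluster_log2fc

    de_flags = effect != 0.0

    # -- intensities (intensity stream) ----------------------------------
    blo, bhi = config.baseline_range
    probe_baseline = rng_intensity.uniform(blo, bhi, size=len(ann_table))
    sigma_gene = rng_intensity.uniform(*config.noise_sd, size=n_genes)
    sigma = pd.Series(sigma_gene, index=gene_idx)

    # genes carrying planted structure must pass the detection filter
    special = (
        set(dosage_genes)
        | set(cluster_members)
        | set(class_label.index[class_label != "none"])
        | set(de_flags.index[de_flags.any(axis=1)])
    )
    probe_gene = ann_table["gene"].to_numpy()
    is_special = np.isin(probe_gene, list(special))
    probe_baseline = np.where(
        is_special, np.maximum(probe_baseline, config.detection_floor + 0.5), probe_baseline
    )

    # per-sample gene-level offsets
    offsets = np.zeros((n_genes, n_samples))
    trisomic_cols = group_arr != "2N"
    if dosage_genes:
        rows = gene_idx.get_indexer(dosage_genes)
        offsets[np.ix_(rows, np.flatnonzero(trisomic_cols))] += config.dosage_log2fc
    nonzero_e1 = e1[e1 != 0.0]
    if len(nonzero_e1):
        rows = gene_idx.get_indexer(nonzero_e1.index)
        offsets[np.ix_(rows, np.flatnonzero(trisomic_cols))] += nonzero_e1.to_numpy()[:, None]
    for contrast in contrasts:
        members = set(contrast.split("+"))
        cols = np.flatnonzero(np.isin(group_arr, list(members)))
        eff = effect[contrast]
        nz = eff[eff != 0.0]
        if len(nz):
            rows = gene_idx.get_indexer(nz.index)
            offsets[np.ix_(rows, cols)] += nz.to_numpy()[:, None]

    gene_row = gene_idx.get_indexer(probe_gene)
    noise = rng_intensity.standard_normal((len(ann_table), n_samples))
    sample_scale = np.array(
        [config.group_noise_scale.get(g, 1.0) for g in group_arr]
    )
    values = (
        probe_baseline[:, None]
        + offsets[gene_row, :]
        + noise * sigma.to_numpy()[gene_row, None] * sample_scale[None, :]
    )

    # -- detection p-values (detection stream) ---------------------------
    expressed_probe = probe_baseline >= config.detection_floor
    detect = np.where(
        expressed_probe[:, None],
        rng_detect.uniform(0.0, 0.005, size=(len(ann_table), n_samples)),
        rng_detect.uniform(0.2, 1.0, size=(len(ann_table), n_samples)),
    )

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=ann_table.index, columns=sample_ids),
        pd.DataFrame(detect, index=ann_table.index, columns=sample_ids),
    )
    truth = SyntheticTruth(
        de_flags=de_flags,
        effect_log2fc=effect,
        trisomy_log2fc=e1.rename("trisomy_log2fc"),
        class_label=class_label,
        cluster_members=list(cluster_members),
        dosage_genes=list(dosage_genes),
    )
    return matrix, annotation, sheet, truth


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnrichedSetSpec:
    """One gene set built to overlap a target list by a known fraction."""

    name: str
    targets: tuple[str, ...]
    overlap_fraction: float
    size: int | None = None  # defaults to len(targets)


def generate_genesets(
    annotation: GeneAnnotation,
    n_sets: int = 50,
    set_size_range: tuple[int, int] = (5, 100),
    enriched_set: EnrichedSetSpec | None = None,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Random gene-set catalog over the annotated genes, GMT-writable.

    The optional ``enriched_set`` contains ``round(overlap_fraction * size)``
    of its members forced in from ``targets``; the remainder is drawn
    uniformly from the genes not yet chosen, so ``overlap_fraction=0`` yields
    a plain uniform random set (expected enrichment factor 1) and
    ``overlap_fraction=1`` with ``size == len(targets)`` yields exactly the
    target list.
    """
    rng = np.random.default_rng(seed)
    genes = list(dict.fromkeys(annotation.table["gene"]))
    lo, hi = set_size_range
    if lo < 1 or hi < lo:
        raise ConfigError("set_size_range must be 1 <= lo <= hi")
    if hi > len(genes):
        raise ConfigError(
            f"set sizes up to {hi} exceed the {len(genes)} annotated genes"
        )
    catalog: dict[str, list[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False).tolist()
        catalog[f"SET{i:03d}"] = sorted(members)
    if enriched_set is not None:
        frac = enriched_set.overlap_fraction
        if not 0.0 <= frac <= 1.0:
            raise ConfigError("overlap_fraction must be in [0, 1]")
        targets = [g for g in enriched_set.targets if g in set(genes)]
        size = enriched_set.size if enriched_set.size is not None else len(targets)
        if size > len(genes):
            raise ConfigError("enriched set size exceeds annotated genes")
        n_in = int(round(frac * size))
        if n_in > len(targets):
            raise ConfigError(
                f"enriched set needs {n_in} target genes but only {len(targets)} exist"
            )
        members = rng.choice(targets, size=n_in, replace=False).tolist()
        remaining = [g for g in genes if g not in set(members)]
        if size - n_in > len(remaining):
            raise ConfigError("enriched set size exceeds available genes")
        members += rng.choice(remaining, size=size - n_in, replace=False).tolist()
        catalog[enriched_set.name] = sorted(members)
    return catalog
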