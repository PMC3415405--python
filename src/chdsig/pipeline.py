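"""End-to-end orchestration: simulate/load -> expression calls -> quantile
normalization -> probe collapse -> merge decision -> ANOVA + pairwise tests ->
DE selection -> dosage classification -> positional scan -> enrichment.

The run report records counts at every stage together with all parameters
and seeds; identical configuration and seed reproduce a byte-identical
report (timings are logged, never written into the report).
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import ClassificationRules, classify_table
from .datatypes import ExpressionMatrix, GeneAnnotation, SampleSheet
from .diffexp import (
    anova,
    de_select,
    merge_decision,
    pca_scores,
    pooled_variance_ttest,
)
from .enrichment import geneset_enrichment, heart_overlap, records_to_frame
from .errors import ConfigError, DataError
from . import io as cio
from .positional import runs_table, triplet_scan
from .preprocess import collapse_probes, expression_call, quantile_normalize
from .simulate import EnrichedSetSpec, SimConfig, generate_dataset, generate_genesets

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]

logger = logging.getLogger("chdsig")

CONTROL = "2N"
BASELINE = "CHD-"
MERGE_PARTS = ("ASD", "VSD")
MERGED_NAME = "ASD+VSD"


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run.

    Defaults equal the published analysis settings where one exists:
    detection and merge thresholds 0.01, DE threshold 0.05, at least 4
    arrays per group, run lengths k in {2, 3}.
    """

    sim: SimConfig | None = None
    expression_path: str | None = None
    annotation_path: str | None = None
    samples_path: str | None = None
    detection_alpha: float = 0.01
    min_arrays: int = 4
    merge_alpha: float = 0.01
    de_alpha: float = 0.05
    collapse_rule: str = "max-mean"
    equality_mode: str = "pvalue"
    equality_band: tuple[float, float] = (0.95, 1.05)
    k_values: tuple[int, ...] = (2, 3)
    n_sims: int = 100_000
    n_genesets: int = 30
    geneset_size_range: tuple[int, int] = (5, 50)
    heart_list_fraction: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if self.sim is None and not (
            self.expression_path and self.annotation_path and self.samples_path
        ):
            raise ConfigError(
                "either a simulation config or expression/annotation/samples paths required"
            )
        for name, a in (
            ("detection_alpha", self.detection_alpha),
            ("merge_alpha", self.merge_alpha),
            ("de_alpha", self.de_alpha),
        ):
            if not 0 < a < 1:
                raise ConfigError(f"{name} must be in (0, 1)")
        if self.min_arrays < 1:
            raise ConfigError("min_arrays must be >= 1")
        if any(k < 1 for k in self.k_values):
            raise ConfigError("k values must be >= 1")


def load_run_config(path: str | os.PathLike) -> RunConfig:
    """Build a RunConfig from a YAML file; the ``simulate`` block maps to SimConfig."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = None
    if "simulate" in raw:
        sim_raw = dict(raw.pop("simulate") or {})
        for key in ("chromosomes", "planted_cluster", "de_contrasts",
                    "de_log2fc_range", "noise_sd", "baseline_range"):
            if key in sim_raw and sim_raw[key] is not None:
                val = sim_raw[key]
                sim_raw[key] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in val
                )
        sim = SimConfig(**sim_raw)
    for key in ("equality_band", "k_values", "geneset_size_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    try:
        cfg = RunConfig(sim=sim, **raw)
    except TypeError as exc:
        raise ConfigError(f"bad run config: {exc}") from exc
    return cfg


def _seed_for(master: int, label: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    offsets = {"simulate": 0, "genesets": 1, "heart": 2, "positional": 3}
    return int(np.random.SeedSequence([master, offsets[label]]).generate_state(1)[0])


def run_pipeline(cfg: RunConfig, outdir: str | os.PathLike) -> dict:
    """Execute every stage, write all intermediates under ``outdir``, return the report."""
    cfg.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "detection_alpha": cfg.detection_alpha,
            "min_arrays": cfg.min_arrays,
            "merge_alpha": cfg.merge_alpha,
            "de_alpha": cfg.de_alpha,
            "collapse_rule": cfg.collapse_rule,
            "equality_mode": cfg.equality_mode,
            "equality_band": list(cfg.equality_band),
            "k_values": list(cfg.k_values),
            "n_sims": cfg.n_sims,
        },
        "stages": {},
    }

    # -- input -----------------------------------------------------------
    t0 = time.perf_counter()
    if cfg.sim is not None:
        sim = SimConfig(**{**asdict(cfg.sim), "seed": _seed_for(cfg.seed, "simulate")})
        matrix, annotation, sheet, truth = generate_dataset(sim)
        cio.write_expression_tsv(matrix, out / "expression.tsv")
        cio.write_annotation_tsv(annotation, out / "annotation.tsv")
        cio.write_sample_sheet_tsv(sheet, out / "samples.tsv")
        truth.de_flags.to_csv(out / "truth_de_flags.tsv", sep="\t")
        truth.effect_log2fc.to_csv(out / "truth_effects.tsv", sep="\t")
        truth.class_label.to_frame().to_csv(out / "truth_classes.tsv", sep="\t")
    else:
        matrix = cio.read_expression_tsv(cfg.expression_path)
        annotation = cio.read_annotation_tsv(cfg.annotation_path)
        sheet = cio.read_sample_sheet_tsv(cfg.samples_path)
    report["stages"]["input"] = {
        "probes": matrix.n_probes,
        "samples": matrix.n_samples,
        "groups": sheet.group_sizes(),
    }
    logger.info("input: %d probes, %d samples (%.2fs)",
                matrix.n_probes, matrix.n_samples, time.perf_counter() - t0)

    # -- preprocessing ---------------------------------------------------
    t0 = time.perf_counter()
    call_groups = [g for g in sheet.groups() if g != CONTROL]
    called = expression_call(
        matrix, sheet, call_groups, alpha=cfg.detection_alpha, min_arrays=cfg.min_arrays
    )
    normalized = quantile_normalize(called)
    genes, mapping = collapse_probes(normalized, annotation, rule=cfg.collapse_rule)
    cio.write_expression_tsv(genes, out / "genes_normalized.tsv")
    mapping.to_csv(out / "gene_probe_map.tsv", sep="\t")
    report["stages"]["preprocess"] = {
        "probes_called": called.n_probes,
        "genes": genes.n_probes,
    }
    logger.info("preprocess: %d probes called, %d genes (%.2fs)",
                called.n_probes, genes.n_probes, time.perf_counter() - t0)

    # -- merge decision on the two smallest case groups ------------------
    groups = set(sheet.groups())
    merged = False
    if set(MERGE_PARTS) <= groups:
        case_groups = [g for g in ("AVSD", *MERGE_PARTS) if g in groups]
        tt = pooled_variance_ttest(
            genes, sheet, *MERGE_PARTS, variance_groups=case_groups
        )
        decision = merge_decision(tt["p"], alpha=cfg.merge_alpha,
                                  contrast=f"{MERGE_PARTS[0]}/{MERGE_PARTS[1]}")
        decision.ecdf_curve.to_csv(out / "merge_ecdf.tsv", sep="\t", index=False)
        (out / "merge_decision.json").write_text(
            json.dumps(decision.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        merged = decision.merged
        report["stages"]["merge"] = decision.to_dict()
        if merged:
            sheet = sheet.merged(MERGE_PARTS, MERGED_NAME)
    case_groups = [g for g in sheet.groups() if g not in (CONTROL, BASELINE)]

    # -- differential expression -----------------------------------------
    t0 = time.perf_counter()
    design_groups = [BASELINE, *case_groups]
    av = anova(genes, sheet, design_groups)
    av.to_csv(out / "anova.tsv", sep="\t")
    scores, explained, ratio = pca_scores(
        genes.subset_samples(
            [s for g in design_groups for s in sheet.samples(g)]
        ),
        n_components=min(3, len(design_groups) + 1),
    )
    scores.to_csv(out / "pca_scores.tsv", sep="\t")

    de_sets: dict[str, set[str]] = {}
    de_counts: dict[str, dict] = {}
    tables: dict[str, pd.DataFrame] = {}
    for case in case_groups:
        tab = pooled_variance_ttest(
            genes, sheet, case, BASELINE, variance_groups=design_groups
        )
        tables[case] = tab
        tab.to_csv(out / f"detable_{case.replace('+', '_')}.tsv", sep="\t")
        de = de_select(tab["p"], alpha=cfg.de_alpha)
        de_sets[case] = set(de)
        # probe-level count for the same contrast, mirrored on the
        # uncollapsed matrix
        probe_tab = pooled_variance_ttest(
            normalized, sheet, case, BASELINE, variance_groups=design_groups
        )
        de_counts[case] = {
            "genes": int(len(de)),
            "probes": int((probe_tab["p"] < cfg.de_alpha).sum()),
        }
    overlap = (
        len(set.intersection(*de_sets.values())) if len(de_sets) > 1 else None
    )
    report["stages"]["diffexp"] = {
        "design_groups": design_groups,
        "m": genes.n_probes,
        "de_counts": de_counts,
        "overlap": overlap,
        "pca_explained_ratio": [round(float(r), 6) for r in ratio],
    }
    logger.info("diffexp on %s (%.2fs)", design_groups, time.perf_counter() - t0)

    # -- classification ---------------------------------------------------
    class_counts: dict[str, dict] = {}
    if CONTROL in groups:
        rules = ClassificationRules(
            equality_band=cfg.equality_band,
            equality_mode=cfg.equality_mode,
            alpha=cfg.de_alpha,
        )
        base_tab = pooled_variance_ttest(genes, sheet, BASELINE, CONTROL)
        for case in case_groups:
            case_2n = pooled_variance_ttest(genes, sheet, case, CONTROL)
            inputs = pd.DataFrame(
                {
                    "ratio_chd_2n": base_tab["ratio"],
                    "p_chd_2n": base_tab["p"],
                    "ratio_case_chd": tables[case]["ratio"],
                    "p_case_chd": tables[case]["p"],
                    "ratio_case_2n": case_2n["ratio"],
                    "p_case_2n": case_2n["p"],
                }
            )
            classified, counts = classify_table(inputs, rules)
            classified.to_csv(
                out / f"classification_{case.replace('+', '_')}.tsv", sep="\t"
            )
            class_counts[case] = counts
    report["stages"]["classify"] = class_counts

    # -- positional -------------------------------------------------------
    t0 = time.perf_counter()
    background = set(genes.probe_ids)
    positional_report: dict[str, list] = {}
    for case in case_groups:
        results = triplet_scan(
            de_sets[case], background, annotation,
            k_values=cfg.k_values, n_sims=cfg.n_sims,
            seed=_seed_for(cfg.seed, "positional"),
        )
        frame = pd.DataFrame([r.to_dict() for r in results])
        frame.to_csv(
            out / f"positional_{case.replace('+', '_')}.tsv", sep="\t", index=False
        )
        for k in cfg.k_values:
            bed = runs_table(de_sets[case], background, annotation, k)
            bed.to_csv(
                out / f"runs_{case.replace('+', '_')}_k{k}.bed",
                sep="\t", index=False, header=False,
            )
        positional_report[case] = [
            {"chromosome": r.chromosome, "k": r.run_length,
             "p": round(r.p_value, 6), "observed_runs": r.observed_runs}
            for r in results if r.p_value < 0.05
        ]
    report["stages"]["positional"] = {"flagged": positional_report}
    logger.info("positional scan (%.2fs)", time.perf_counter() - t0)

    # -- enrichment -------------------------------------------------------
    t0 = time.perf_counter()
    rng_heart = np.random.default_rng(_seed_for(cfg.seed, "heart"))
    bg_sorted = sorted(background)
    heart_list = set(
        rng_heart.choice(
            bg_sorted,
            size=int(round(cfg.heart_list_fraction * len(bg_sorted))),
            replace=False,
        ).tolist()
    )
    cio.write_gene_list(sorted(heart_list), out / "heart_list.txt")
    catalog = generate_genesets(
        annotation,
        n_sets=cfg.n_genesets,
        set_size_range=cfg.geneset_size_range,
        enriched_set=None,
        seed=_seed_for(cfg.seed, "genesets"),
    )
    cio.write_gmt(catalog, out / "genesets.gmt")
    enrich_report: dict[str, dict] = {}
    for case in case_groups:
        if not de_sets[case]:
            continue
        records = geneset_enrichment(de_sets[case], background, catalog)
        records_to_frame(records).to_csv(
            out / f"enrichment_{case.replace('+', '_')}.tsv", sep="\t"
        )
        fraction, record = heart_overlap(de_sets[case], heart_list, background)
        enrich_report[case] = {
            "top_sets": [
                {"name": r.name, "factor": round(r.factor, 2),
                 "p": float(f"{r.p_value:.3g}")}
                for r in records[:5]
            ],
            "heart_fraction": round(fraction, 4),
            "heart_p": float(f"{record.p_value:.3g}"),
        }
    report["stages"]["enrichment"] = enrich_report
    logger.info("enrichment (%.2fs)", time.perf_counter() - t0)

    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report
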