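import math

import numpy as np
import pandas as pd
import pytest

from chdsig.datatypes import normalize_chrom
from chdsig.errors import ConfigError
from chdsig.enrichment import enrichment_factor
from chdsig.simulate import (
    CLASS_LABELS,
    EnrichedSetSpec,
    SimConfig,
    generate_dataset,
    generate_genesets,
)


def null_config(seed=0, **kw):
    return SimConfig(
        n_genes=150,
        de_log2fc_range=(0.0, 0.0),
        dosage_fraction=0.0,
        class_quota={c: 0 for c in CLASS_LABELS},
        planted_cluster=None,
        seed=seed,
        **kw,
    )


class TestGenerateDataset:
    def test_null_configuration_has_no_truth_structure(self):
        m, ann, sheet, truth = generate_dataset(null_config())
        assert not truth.de_flags.to_numpy().any()
        assert truth.dosage_genes == []
        assert truth.cluster_members == []
        assert (truth.class_label == "none").all()

    def test_planted_cluster_members_are_consecutive(self):
        cfg = SimConfig(n_genes=300, planted_cluster=("chr21", 10, 3, "AVSD"), seed=2)
        m, ann, sheet, truth = generate_dataset(cfg)
        on_chrom = ann.genes_on("chr21")
        assert truth.cluster_members == on_chrom[10:13]
        assert truth.de_flags.loc[truth.cluster_members, "AVSD"].all()

    def test_seeded_runs_are_identical(self):
        a = generate_dataset(SimConfig(n_genes=100, seed=7,
                                       class_quota={"IA": 2, "IB": 2, "IIA": 2, "IIB": 2}))
        b = generate_dataset(SimConfig(n_genes=100, seed=7,
                                       class_quota={"IA": 2, "IB": 2, "IIA": 2, "IIB": 2}))
        pd.testing.assert_frame_equal(a[0].values, b[0].values)
        pd.testing.assert_frame_equal(a[0].detection_p, b[0].detection_p)
        pd.testing.assert_frame_equal(a[3].effect_log2fc, b[3].effect_log2fc)
        assert a[3].cluster_members == b[3].cluster_members

    def test_different_seeds_differ(self):
        a, _, _, _ = generate_dataset(null_config(seed=1, two_probe_fraction=0.0))
        b, _, _, _ = generate_dataset(null_config(seed=2, two_probe_fraction=0.0))
        assert not np.allclose(a.values.to_numpy(), b.values.to_numpy())

    def test_group_sizes_respected(self):
        m, ann, sheet, truth = generate_dataset(null_config())
        assert sheet.group_sizes() == {"2N": 12, "CHD-": 22, "AVSD": 7, "ASD": 8, "VSD": 6}

    def test_class_truth_consistent_with_rules(self):
        cfg = SimConfig(
            n_genes=200, seed=3,
            class_quota={"IA": 5, "IB": 5, "IIA": 5, "IIB": 5},
        )
        m, ann, sheet, truth = generate_dataset(cfg)
        band = math.log2(1.05)
        labelled = truth.class_label[truth.class_label != "none"]
        assert len(labelled) == 20
        for gene, label in labelled.items():
            e1 = truth.trisomy_log2fc[gene]
            e2 = truth.effect_log2fc.loc[gene, cfg.class_target]
            assert truth.de_flags.loc[gene, cfg.class_target]
            if label in ("IA", "IB"):
                assert abs(e2) > abs(e1)
            else:
                assert abs(e2) < abs(e1)
            if label == "IA":
                assert abs(e1) > band          # baseline clearly shifted
            elif label == "IB":
                assert e1 == 0.0               # baseline exactly unshifted
            elif label == "IIA":
                assert abs(e1 + e2) > band     # case stays away from control
            else:
                assert 0 < abs(e1 + e2) <= band  # case reverts to control
        counts = truth.class_label.value_counts()
        for c in CLASS_LABELS:
            assert counts[c] == 5

    def test_dosage_ratio_in_expectation(self):
        # large balanced groups so group means are tight
        cfg = SimConfig(
            n_genes=200,
            group_sizes={"2N": 40, "CHD-": 40, "AVSD": 4, "ASD": 4, "VSD": 4},
            dosage_fraction=0.5,
            n_de_per_contrast=0,
            seed=11,
        )
        m, ann, sheet, truth = generate_dataset(cfg)
        assert truth.dosage_genes
        gene_means = m.values.groupby(ann.table["gene"]).mean()
        chd = gene_means[sheet.samples("CHD-")].mean(axis=1)
        ctrl = gene_means[sheet.samples("2N")].mean(axis=1)
        ratios = np.exp2(chd - ctrl).loc[truth.dosage_genes]
        assert 1.4 <= ratios.mean() <= 1.6

    def test_effect_recovery_bias(self):
        # realized log2 fold changes of flagged genes recover the truth
        cfg = SimConfig(
            n_genes=220,
            group_sizes={"2N": 4, "CHD-": 20, "AVSD": 20, "ASD": 4, "VSD": 4},
            n_de_per_contrast=200,
            de_contrasts=("AVSD",),
            de_log2fc_range=(0.3, 1.2),
            dosage_fraction=0.0,
            planted_cluster=None,
            seed=5,
        )
        m, ann, sheet, truth = generate_dataset(cfg)
        flagged = truth.de_flags.index[truth.de_flags["AVSD"]]
        assert len(flagged) >= 200
        gene_means = m.values.groupby(ann.table["gene"]).mean()
        est = (
            gene_means[sheet.samples("AVSD")].mean(axis=1)
            - gene_means[sheet.samples("CHD-")].mean(axis=1)
        ).loc[flagged]
        bias = (est - truth.effect_log2fc.loc[flagged, "AVSD"]).mean()
        assert abs(bias) < 0.05

    def test_detection_fails_below_floor(self):
        m, ann, sheet, truth = generate_dataset(null_config(seed=4))
        mean_intensity = m.values.mean(axis=1)
        det = m.detection_p
        low = mean_intensity < 5.0   # clearly below the floor of 6
        high = mean_intensity > 7.0
        assert (det.loc[low] >= 0.2).all().all()
        assert (det.loc[high] < 0.01).all().all()

    def test_infeasible_class_quota_names_class(self):
        cfg = SimConfig(class_quota={"IIB": 3}, class_equality_gap=0.5)
        with pytest.raises(ConfigError, match="IIB"):
            cfg.validate()

    def test_cluster_must_fit_on_chromosome(self):
        cfg = SimConfig(n_genes=100, planted_cluster=("chr21", 1000, 3, "AVSD"))
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_group_size_minimum(self):
        cfg = SimConfig(group_sizes={"2N": 1, "CHD-": 4})
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_two_probe_fraction_creates_extra_probes(self):
        cfg = null_config(seed=9)
        cfg.two_probe_fraction = 0.5
        m, ann, sheet, truth = generate_dataset(cfg)
        assert m.n_probes > 150
        assert ann.table["gene"].nunique() == 150


class TestGenerateGenesets:
    @pytest.fixture
    def annotation(self):
        cfg = null_config()
        _, ann, _, _ = generate_dataset(cfg)
        return ann

    def test_contract_sizes_and_membership(self, annotation):
        catalog = generate_genesets(annotation, n_sets=50, set_size_range=(5, 100), seed=1)
        genes = set(annotation.table["gene"])
        assert len(catalog) == 50
        for members in catalog.values():
            assert 5 <= len(members) <= 100
            assert set(members) <= genes

    def test_full_overlap_equals_targets(self, annotation):
        targets = tuple(sorted(set(annotation.table["gene"])))[:20]
        spec = EnrichedSetSpec("planted", targets, overlap_fraction=1.0, size=20)
        catalog = generate_genesets(annotation, n_sets=0, enriched_set=spec, seed=3)
        assert sorted(catalog["planted"]) == sorted(targets)

    def test_overlap_above_one_rejected(self, annotation):
        spec = EnrichedSetSpec("bad", ("g",), overlap_fraction=1.5)
        with pytest.raises(ConfigError):
            generate_genesets(annotation, n_sets=0, enriched_set=spec)

    def test_zero_overlap_factor_near_one_over_seeds(self, annotation):
        # Monte-Carlo over 1000 seeds: with overlap fraction 0 the enriched
        # set is a uniform random draw, so the expected factor is 1
        genes = sorted(set(annotation.table["gene"]))
        targets = tuple(genes[:30])
        factors = []
        for seed in range(1000):
            spec = EnrichedSetSpec("rand", targets, overlap_fraction=0.0, size=30)
            catalog = generate_genesets(annotation, n_sets=0, enriched_set=spec, seed=seed)
            members = set(catalog["rand"])
            b = len(members & set(targets))
            factors.append(enrichment_factor(len(genes), len(members), len(targets), b))
        mean = np.mean(factors)
        se = np.std(factors, ddof=1) / math.sqrt(len(factors))
        assert abs(mean - 1.0) <= 3 * se
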