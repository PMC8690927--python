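"""Cluster-first synthetic cohort generator and its closed-form oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from iccclust.cluster_rules import SEVEN_GENES, assign_all
from iccclust.errors import ValidationError
from iccclust.synthetic_cohort import (
    CLUSTER_OF,
    REQUIRED_SETS,
    SUBCLUSTERS,
    SyntheticConfig,
    analytic_marginal,
    analytic_pair_or,
    genotype_distribution,
    simulate,
)


def _enumeration_or(config, gene_a, gene_b):
    """Independent oracle: walk every (sub-cluster, genotype pattern) outcome."""
    ia, ib = SEVEN_GENES.index(gene_a), SEVEN_GENES.index(gene_b)
    cells = {"11": 0.0, "10": 0.0, "01": 0.0, "00": 0.0}
    for sub in SUBCLUSTERS:
        probs = [config.gene_probs[sub][g] for g in SEVEN_GENES]
        weight_all_wt_of_required = 0.0
        total = 0.0
        raw = {}
        for pattern in itertools.product((0, 1), repeat=len(SEVEN_GENES)):
            w = 1.0
            for p, x in zip(probs, pattern):
                w *= p if x else 1.0 - p
            required = REQUIRED_SETS[sub]
            if required and not any(pattern[SEVEN_GENES.index(g)] for g in required):
                weight_all_wt_of_required += w
                continue
            raw[pattern] = w
            total += w
        for pattern, w in raw.items():
            key = f"{pattern[ia]}{pattern[ib]}"
            cells[key] += config.mixing[sub] * w / total
    return (cells["11"] * cells["00"]) / (cells["10"] * cells["01"])


class TestConfig:
    def test_bad_mixing_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticConfig(mixing={s: 1.0 for s in SUBCLUSTERS})

    def test_bad_probability_rejected(self):
        cfg = SyntheticConfig()
        probs = {s: dict(cfg.gene_probs[s]) for s in SUBCLUSTERS}
        probs["1A"]["KRAS"] = 1.5
        with pytest.raises(ValidationError):
            SyntheticConfig(gene_probs=probs)

    def test_defining_set_must_be_realisable(self):
        cfg = SyntheticConfig()
        probs = {s: dict(cfg.gene_probs[s]) for s in SUBCLUSTERS}
        probs["2B"]["FGFR2_fusion"] = 0.0
        with pytest.raises(ValidationError):
            SyntheticConfig(gene_probs=probs)


class TestGenotypeDistribution:
    def test_defining_constraint_has_probability_zero_of_failing(self):
        cfg = SyntheticConfig()
        for sub in SUBCLUSTERS:
            patterns, w = genotype_distribution(cfg, sub)
            required = REQUIRED_SETS[sub]
            if not required:
                continue
            idx = [SEVEN_GENES.index(g) for g in required]
            bad = patterns[:, idx].sum(axis=1) == 0
            assert w[bad].sum() == 0.0
            assert w.sum() == pytest.approx(1.0)


class TestAnalyticOracle:
    def test_single_cluster_independent_genes_or_one(self):
        cfg = SyntheticConfig(
            mixing={"1A": 1.0, "1B": 0.0, "2A": 0.0, "2B": 0.0, "2C": 0.0, "3": 0.0}
        )
        # TP53 and SMAD4 are conditionally independent within 1A
        assert analytic_pair_or(cfg, "TP53", "SMAD4") == pytest.approx(1.0)

    def test_disjoint_clusters_give_zero_or(self):
        probs = {s: {g: 0.0 for g in SEVEN_GENES} for s in SUBCLUSTERS}
        probs["1A"]["KRAS"] = 0.8
        probs["1A"]["TP53"] = 1e-9  # keep the marginal non-degenerate
        probs["2C"]["BAP1"] = 0.8
        probs["1B"].update({"TP53": 1.0})
        probs["2A"].update({"IDH1": 1.0})
        probs["2B"].update({"FGFR2_fusion": 1.0})
        cfg = SyntheticConfig(
            mixing={"1A": 0.5, "1B": 0.0, "2A": 0.0, "2B": 0.0, "2C": 0.5, "3": 0.0},
            gene_probs=probs,
        )
        assert analytic_pair_or(cfg, "KRAS", "BAP1") == 0.0

    def test_degenerate_marginal_rejected(self):
        cfg = SyntheticConfig()
        with pytest.raises(ValidationError):
            analytic_pair_or(cfg, "KRAS", "UNKNOWN_GENE")

    @pytest.mark.parametrize("pair", [("KRAS", "IDH1"), ("TP53", "SMAD4"), ("IDH1", "BAP1")])
    def test_matches_exhaustive_enumeration(self, pair):
        cfg = SyntheticConfig(comutant_leak=0.05)
        assert analytic_pair_or(cfg, *pair) == pytest.approx(_enumeration_or(cfg, *pair))

    def test_passenger_genes_independent_of_clusters(self):
        cfg = SyntheticConfig()
        assert analytic_pair_or(cfg, "KRAS", "ARID1A") == pytest.approx(1.0)
        assert analytic_marginal(cfg, "ARID1A") == cfg.passenger_probs["ARID1A"]


class TestSimulate:
    def test_pure_cluster3_all_wildtype(self):
        cfg = SyntheticConfig(
            n_samples=50,
            mixing={"1A": 0.0, "1B": 0.0, "2A": 0.0, "2B": 0.0, "2C": 0.0, "3": 1.0},
        )
        cohort = simulate(cfg)
        seven = cohort.mutations.status[list(SEVEN_GENES)]
        assert (cohort.labels == "3").all()
        assert seven.eq(1).fillna(False).to_numpy().sum() == 0

    def test_identical_seed_bit_identical(self):
        a = simulate(SyntheticConfig(n_samples=120, seed=21))
        b = simulate(SyntheticConfig(n_samples=120, seed=21))
        pd.testing.assert_frame_equal(a.mutations.status, b.mutations.status)
        pd.testing.assert_frame_equal(a.clinical, b.clinical)
        pd.testing.assert_frame_equal(a.expression, b.expression)
        pd.testing.assert_frame_equal(a.beta, b.beta)

    def test_different_seed_differs(self):
        a = simulate(SyntheticConfig(n_samples=120, seed=21))
        b = simulate(SyntheticConfig(n_samples=120, seed=22))
        assert not a.mutations.status.equals(b.mutations.status)

    def test_marginal_frequencies_near_analytic(self):
        cfg = SyntheticConfig(n_samples=10_000, seed=30)
        cohort = simulate(cfg)
        freq = cohort.mutations.mutation_frequency()
        for gene in list(SEVEN_GENES) + list(cfg.passenger_probs):
            assert freq[gene] == pytest.approx(analytic_marginal(cfg, gene), abs=0.02)

    def test_zero_leak_label_recovery_is_exact(self):
        cfg = SyntheticConfig(n_samples=2000, seed=31, comutant_leak=0.0)
        cohort = simulate(cfg)
        fully_assayed = cohort.mutations.status.notna().all(axis=1)
        assigned = assign_all(cohort.mutations)
        expected_cluster = cohort.clusters
        expected_sub = cohort.labels.where(cohort.labels != "3", "none")
        assert (assigned.loc[fully_assayed, "cluster"] == expected_cluster[fully_assayed]).all()
        assert (assigned.loc[fully_assayed, "subcluster"] == expected_sub[fully_assayed]).all()
        assert not assigned["co_mutant"].any()

    def test_comutants_enriched_in_high_stage(self, default_cohort):
        cfg = SyntheticConfig(n_samples=4000, seed=32, comutant_leak=0.05)
        cohort = simulate(cfg)
        assigned = assign_all(cohort.mutations)
        stage34 = cohort.clinical["stage"].isin(["III", "IV"])
        co = assigned["co_mutant"]
        assert stage34[co].mean() > stage34[~co].mean()

    def test_exclusivity_edge_between_cluster_sets(self, default_cohort):
        # with default effect sizes the C1/C2 exclusivity must surface as a
        # significant negative KRAS-IDH1-style edge at cohort scale
        from iccclust.comut_stats import all_pairs

        network = all_pairs(default_cohort.mutations.subset(genes=list(SEVEN_GENES)))
        negative = [
            e for e in network.edges if e.direction == "exclusivity"
        ]
        assert negative, "expected at least one exclusivity edge on the default cohort"

    def test_cluster_labels_match_mixing(self):
        cfg = SyntheticConfig(n_samples=20_000, seed=33)
        cohort = simulate(cfg)
        observed = cohort.labels.value_counts(normalize=True)
        for sub in SUBCLUSTERS:
            assert observed.get(sub, 0.0) == pytest.approx(cfg.mixing[sub], abs=0.01)

    def test_modalities_share_sample_universe(self, default_cohort):
        samples = default_cohort.mutations.samples
        assert list(default_cohort.clinical.index) == samples
        assert list(default_cohort.expression.columns) == samples
        assert list(default_cohort.beta.columns) == samples
        assert list(default_cohort.labels.index) == samples
        assert set(CLUSTER_OF[s] for s in default_cohort.labels) <= {"C1", "C2", "C3"}
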