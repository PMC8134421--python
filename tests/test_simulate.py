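"""Synthetic-data generators: determinism, planted signal, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, hypergeom

from asepred import (CohortSimConfig, FeatureSimConfig, enrich_profile,
                     simulate_cohort, simulate_feature_matrix,
                     simulate_gene_annotation)
from asepred.simulate import ConfigError


class TestCohortSim:
    def test_same_seed_identical_tables(self):
        cfg = CohortSimConfig(n_loci=50, seed=9)
        a, b = simulate_cohort(cfg), simulate_cohort(CohortSimConfig(n_loci=50, seed=9))
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_different_seeds_differ(self):
        a = simulate_cohort(CohortSimConfig(n_loci=50, seed=1))
        b = simulate_cohort(CohortSimConfig(n_loci=50, seed=2))
        assert not a.counts.equals(b.counts)

    def test_null_cohort_symmetry(self):
        cfg = CohortSimConfig(n_loci=300, n_individuals_per_locus=20,
                              ase_fraction=0.0, rho=0.02, seed=5)
        cohort = simulate_cohort(cfg)
        assert not cohort.truth["is_ase"].any()
        k = cohort.counts["alt_count"].to_numpy()
        n = k + cohort.counts["ref_count"].to_numpy()
        frac = k.sum() / n.sum()
        # pooled fraction within 3 SEs of 0.5 (conservative binomial SE)
        se = 0.5 / np.sqrt(n.sum())
        assert abs(frac - 0.5) < 3 * se * (1 + (n.mean() - 1) * cfg.rho) ** 0.5

    def test_depths_at_least_one_and_truth_consistent(self):
        cfg = CohortSimConfig(n_loci=100, n_individuals_per_locus=(5, 40), seed=2)
        cohort = simulate_cohort(cfg)
        totals = cohort.counts["ref_count"] + cohort.counts["alt_count"]
        assert (totals >= 1).all()
        assert set(cohort.truth["locus_id"]) == set(cohort.counts["locus_id"])
        ase = cohort.truth["is_ase"]
        pi = cohort.truth["true_pi"]
        assert (pi[~ase] == cfg.pi_null).all()
        assert (abs(pi[ase] - 0.5) >= 0.1 - 1e-12).all()

    @pytest.mark.parametrize("field,kwargs", [
        ("ase_fraction", {"ase_fraction": 1.5}),
        ("rho", {"rho": 0.0}),
        ("depth_distribution", {"depth_distribution": {"kind": "bogus"}}),
        ("pi_ase_distribution",
         {"pi_ase_distribution": {"kind": "mirrored_uniform", "low": 0.4, "high": 0.9}}),
        ("n_individuals_per_locus", {"n_individuals_per_locus": 0}),
    ])
    def test_invalid_config_names_field(self, field, kwargs):
        with pytest.raises(ConfigError, match=field.split("_")[0]):
            CohortSimConfig(**kwargs)


class TestFeatureSim:
    @staticmethod
    def _truth(n=2000, frac=0.4, seed=0):
        rng = np.random.default_rng(seed)
        return pd.Series(rng.random(n) < frac,
                         index=[f"L{i:05d}" for i in range(n)])

    def test_planted_numeric_shift(self):
        truth = self._truth()
        cfg = FeatureSimConfig(n_features_numeric=3, n_features_categorical=0,
                               effect_vector=(1.5, 0.0, 0.0), seed=1)
        m = simulate_feature_matrix(truth, cfg)
        x = m.values["num_00"]
        diff = x[truth.values].mean() - x[~truth.values].mean()
        se = np.sqrt(1 / truth.sum() + 1 / (~truth).sum())
        assert abs(diff - 1.5) < 2 * se
        # untouched feature shows no shift beyond noise
        x0 = m.values["num_01"]
        assert abs(x0[truth.values].mean() - x0[~truth.values].mean()) < 4 * se

    def test_missingness_within_binomial_interval(self):
        truth = self._truth(n=3000)
        cfg = FeatureSimConfig(n_features_numeric=1, n_features_categorical=0,
                               effect_vector=(0.0,), missing_rate=0.5, seed=3)
        m = simulate_feature_matrix(truth, cfg)
        observed = int(m.missing_mask["num_00"].sum())
        lo, hi = binom.ppf([0.005, 0.995], 3000, 0.5)
        assert lo <= observed <= hi

    def test_categorical_tilt_follows_label(self):
        truth = self._truth(n=4000)
        cfg = FeatureSimConfig(n_features_numeric=0, n_features_categorical=1,
                               effect_vector=(2.0,), seed=4)
        m = simulate_feature_matrix(truth, cfg)
        col = m.values["cat_00"]
        top_frac_pos = (col[truth.values] == "C").mean()
        top_frac_neg = (col[~truth.values] == "C").mean()
        assert top_frac_pos > top_frac_neg + 0.1

    def test_effect_vector_length_mismatch(self):
        with pytest.raises(ConfigError, match="effect_vector"):
            FeatureSimConfig(n_features_numeric=2, n_features_categorical=0,
                             effect_vector=(1.0,))

    def test_empty_truth_rejected(self):
        with pytest.raises(ConfigError):
            simulate_feature_matrix(pd.Series(dtype=bool), FeatureSimConfig())

    def test_determinism(self):
        truth = self._truth(n=100)
        cfg = FeatureSimConfig(seed=5, missing_rate=0.1)
        a = simulate_feature_matrix(truth, cfg)
        b = simulate_feature_matrix(truth, cfg)
        pd.testing.assert_frame_equal(a.values, b.values)


class TestGeneAnnotation:
    def test_empty_collection(self):
        sim = simulate_gene_annotation(n_genes=50, n_terms=0)
        assert sim.gene_sets == {}

    def test_determinism(self):
        a = simulate_gene_annotation(100, 10, seed=6)
        b = simulate_gene_annotation(100, 10, seed=6)
        assert a.gene_sets == b.gene_sets

    def test_planted_term_attains_rank_one(self):
        sim = simulate_gene_annotation(n_genes=300, n_terms=20,
                                       genes_per_term=(10, 20), seed=7,
                                       enriched_subset_size=25)
        profile = enrich_profile(sim.enriched_subset, sim.gene_sets, sim.universe)
        assert profile.rank_of(sim.enriched_term) == 1
        # sanity: hypergeometric tail for the planted overlap is tiny
        row = profile.table.set_index("term").loc[sim.enriched_term]
        x, K = int(row["overlap"]), int(row["term_size"])
        p = float(hypergeom.sf(x - 1, 300, K, len(sim.enriched_subset)))
        assert p == pytest.approx(row["p_value"], rel=1e-12)
        assert p < 1e-6

    def test_impossible_sizes_rejected(self):
        with pytest.raises(ConfigError, match="n_genes"):
            simulate_gene_annotation(n_genes=5, n_terms=3, genes_per_term=(2, 10))
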