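"""Synthetic-data generators: determinism, planted structure, LD model."""

import numpy as np
import pandas as pd
import pytest

from myoqtl.datatypes import ENHANCER_STATES
from myoqtl.sim import (
    SIM_COVERAGE_BAND,
    SimConfig,
    simulate_allele_counts,
    simulate_expression,
    simulate_genes,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_tissue_panel,
    simulate_study,
)
from myoqtl.specificity import entropy, relative_expression


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestGenotypes:
    def test_same_seed_identical(self):
        cfg = SimConfig(n_samples=50, n_genes=10, n_variants=200)
        a = simulate_genotypes(cfg, _rng(5))
        b = simulate_genotypes(cfg, _rng(5))
        np.testing.assert_array_equal(a.dosages, b.dosages)
        pd.testing.assert_frame_equal(a.variants, b.variants)

    def test_independent_variants_uncorrelated(self):
        cfg = SimConfig(n_samples=10_000, n_genes=10, n_variants=2, ld_decay=0.0,
                        ld_block_size=2)
        gm = simulate_genotypes(cfg, _rng(1))
        r = np.corrcoef(gm.dosages[0], gm.dosages[1])[0, 1]
        assert r * r < 0.01

    def test_high_copy_prob_gives_strong_adjacent_ld(self):
        cfg = SimConfig(n_samples=10_000, n_genes=10, n_variants=2, ld_decay=0.95,
                        ld_block_size=2)
        gm = simulate_genotypes(cfg, _rng(2))
        r = np.corrcoef(gm.dosages[0], gm.dosages[1])[0, 1]
        assert r * r > 0.5

    def test_cross_block_independence(self):
        cfg = SimConfig(n_samples=5_000, n_genes=10, n_variants=20, ld_decay=0.95,
                        ld_block_size=10)
        gm = simulate_genotypes(cfg, _rng(3))
        r = np.corrcoef(gm.dosages[9], gm.dosages[10])[0, 1]  # block boundary
        assert r * r < 0.01

    def test_maf_within_configured_range(self):
        cfg = SimConfig(n_samples=2_000, n_genes=10, n_variants=500,
                        maf_range=(0.1, 0.4))
        gm = simulate_genotypes(cfg, _rng(4))
        # 4 sigma sampling slack on a binomial proportion at 2n=4000 draws
        slack = 4 * np.sqrt(0.25 / (2 * cfg.n_samples))
        assert gm.maf.min() > 0.1 - slack
        assert gm.maf.max() < 0.4 + slack

    def test_dosages_are_hard_calls(self, small_study):
        assert set(np.unique(small_study.genotypes.dosages)) <= {0.0, 1.0, 2.0}

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_samples=1, n_genes=10, n_variants=10)


class TestTissuePanel:
    def test_planted_gene_target_share_above_09(self):
        cfg = SimConfig(n_samples=10, n_genes=200, n_variants=100,
                        frac_specific_genes=0.1)
        panel, truth = simulate_tissue_panel(cfg, _rng(0))
        p = relative_expression(panel)
        assert (p.loc[truth["gene_id"], "skeletal_muscle"] > 0.9).all()

    def test_no_specific_genes_when_fraction_zero(self):
        cfg = SimConfig(n_samples=10, n_genes=200, n_variants=100,
                        frac_specific_genes=0.0)
        panel, truth = simulate_tissue_panel(cfg, _rng(0))
        p = relative_expression(panel)
        assert truth.empty
        assert (p["skeletal_muscle"] < 0.9).all()

    def test_background_entropy_near_four_bits(self):
        cfg = SimConfig(n_samples=10, n_genes=300, n_variants=100,
                        frac_specific_genes=0.0)
        panel, _ = simulate_tissue_panel(cfg, _rng(1))
        p = relative_expression(panel)
        hs = [entropy(row) for row in p.to_numpy()]
        assert np.mean(hs) > 3.9  # near log2(16) = 4

    def test_all_values_nonnegative(self, small_study):
        assert (small_study.panel.x.to_numpy() >= 0).all()


class TestExpression:
    def test_noiseless_beta_recovered_exactly(self):
        cfg = SimConfig(n_samples=100, n_genes=50, n_variants=500,
                        eqtl_effect_sizes=(1.0,), frac_eqtl_genes=1.0,
                        n_latent_factors=0, batch_levels=1)
        gm = simulate_genotypes(cfg, _rng(0))
        genes = simulate_genes(gm, cfg, _rng(1))
        expr, cov, truth = simulate_expression(gm, genes, cfg, _rng(1), noise_sd=0.0)
        # on the log scale, after removing covariates, the planted per-allele
        # slope is exact
        from myoqtl.stats import residualize

        row = truth.iloc[0]
        y = np.log(expr.loc[row.gene_id].to_numpy())
        g = gm.dosages[gm.index_of([row.variant_id])[0]]
        resid_y = residualize(y, cov)
        resid_g = residualize(g, cov)
        slope = np.dot(resid_g, resid_y) / np.dot(resid_g, resid_g)
        # truth beta is on the final standardized scale: sd 1 here (noise 0)
        assert slope * g.std() == pytest.approx(1.0, abs=1e-8)

    def test_truth_references_existing_ids(self, small_study):
        truth = small_study.truth.eqtl_truth
        assert truth["gene_id"].isin(small_study.expression.index).all()
        assert truth["variant_id"].isin(small_study.genotypes.variants["id"]).all()

    def test_batch_structure_removed_by_latent_adjustment(self):
        from myoqtl.eqtl import latent_factor_adjust

        cfg = SimConfig(n_samples=150, n_genes=120, n_variants=500,
                        batch_levels=3, n_latent_factors=2)
        gm = simulate_genotypes(cfg, _rng(0))
        genes = simulate_genes(gm, cfg, _rng(1))
        expr, cov, _ = simulate_expression(gm, genes, cfg, _rng(1))
        adj = latent_factor_adjust(expr, cov, k=10, rng=_rng(2))
        batch = pd.get_dummies(cov["batch"], drop_first=True).to_numpy(float)
        # R^2 of batch on adjusted expression, averaged over genes
        q, _ = np.linalg.qr(np.column_stack([np.ones(len(cov)), batch]))
        Y = adj.to_numpy().T
        fitted = q @ (q.T @ Y)
        r2 = 1 - ((Y - fitted) ** 2).sum(0) / (Y**2).sum(0)
        assert r2.mean() < 0.01


@pytest.fixture(scope="module")
def counts():
    cfg = SimConfig(n_samples=150, n_genes=50, n_variants=2000,
                    frac_ase_sites=0.1, coverage_mean=100.0)
    gm = simulate_genotypes(cfg, _rng(0))
    return cfg, gm, simulate_allele_counts(gm, cfg, _rng(1))


class TestAlleleCounts:

    def test_only_heterozygous_cells_counted(self, counts):
        cfg, gm, (table, mask, ase_truth, bias) = counts
        idx = {v: i for i, v in enumerate(gm.variants["id"])}
        sidx = {s: i for i, s in enumerate(gm.sample_ids)}
        merged = table.groupby(["sample_id", "variant_id"]).size().reset_index()
        dos = gm.dosages
        for row in merged.sample(n=min(200, len(merged)), random_state=0).itertuples():
            assert dos[idx[row.variant_id], sidx[row.sample_id]] == 1.0

    def test_null_sites_near_half_fracref(self, counts):
        cfg, gm, (table, mask, ase_truth, bias) = counts
        special = set(ase_truth["variant_id"]) | set(bias["variant_id"])
        null = table[~table["variant_id"].isin(special)]
        agg = null.groupby("variant_id")[["ref_count", "alt_count"]].sum()
        frac = agg["ref_count"] / (agg["ref_count"] + agg["alt_count"])
        # pair baselines are within 0.47..0.53
        assert frac.mean() == pytest.approx(0.5, abs=0.02)

    def test_planted_site_shows_imbalance(self, counts):
        cfg, gm, (table, mask, ase_truth, bias) = counts
        m = table.merge(ase_truth, on="variant_id")
        agg = m.groupby(["variant_id", "true_fracref"])[
            ["ref_count", "alt_count"]
        ].sum().reset_index()
        frac = agg["ref_count"] / (agg["ref_count"] + agg["alt_count"])
        assert np.abs(frac - agg["true_fracref"]).mean() < 0.05

    def test_bias_snps_get_out_of_band_coverage(self, counts):
        cfg, gm, (table, mask, ase_truth, bias) = counts
        lo, hi = SIM_COVERAGE_BAND
        m = mask.set_index("variant_id")
        sim = m.loc[bias["variant_id"], "simulated_coverage"]
        assert ((sim < lo) | (sim > hi)).all()
        clean = m.drop(bias["variant_id"])
        assert clean["simulated_coverage"].between(lo, hi).all()

    def test_invalid_coverage_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_samples=10, n_genes=10, n_variants=10, coverage_mean=0)


class TestChromatin:
    def test_planted_stretch_runs_at_least_3kb_and_binned(self, small_study):
        truth = small_study.truth.enhancer_truth
        stretch = truth[truth["class"] == "stretch"]
        lengths = stretch["end"] - stretch["start"]
        assert (lengths >= 3000).all()
        assert (lengths % 200 == 0).all()

    def test_segmentations_nonoverlapping(self, small_study):
        for seg in small_study.segmentations:
            iv = seg.intervals
            for _, grp in iv.groupby("chrom"):
                starts = grp["start"].to_numpy()
                ends = grp["end"].to_numpy()
                assert (starts[1:] >= ends[:-1]).all()

    def test_emits_target_plus_other_tissues(self, small_study):
        ids = [s.tissue_id for s in small_study.segmentations]
        assert ids[0] == "target_tissue"
        assert len(ids) >= 3

    def test_typical_runs_at_most_800bp(self, small_study):
        truth = small_study.truth.enhancer_truth
        typical = truth[truth["class"] == "typical"]
        assert ((typical["end"] - typical["start"]) <= 800).all()

    def test_planted_runs_only_in_target_tissue(self, small_study):
        truth = small_study.truth.enhancer_truth
        assert set(truth.loc[truth["over_eqtl"], "tissue_id"]) <= {"target_tissue"}


class TestPhenotypes:
    def test_no_planted_effects_gives_null_de(self):
        from myoqtl import trait_assoc as ta

        cfg = SimConfig(n_samples=200, n_genes=400, n_variants=500,
                        frac_de_genes=0.0, length_confound=0.0)
        study = simulate_study(cfg)
        y = ta.transform_expression(study.expression, rng=_rng(0), double=False)
        res = ta.t2d_association(y, study.phenotypes["t2d"].to_numpy(),
                                 study.covariates)
        # expected number of discoveries under the null is ~0.05; allow the
        # occasional single chance rejection
        assert (res["q"] <= 0.05).sum() <= 2

    def test_go_truth_terms_exist_in_memberships(self, small_study):
        terms = set(small_study.go_memberships["term_id"])
        assert set(small_study.truth.go_truth["term_id"]) <= terms

    def test_sample_mismatch_rejected(self, small_study):
        with pytest.raises(ValueError):
            simulate_phenotypes(
                small_study.expression.iloc[:, :-1],
                small_study.covariates,
                small_study.config,
                _rng(0),
            )


class TestDeterminism:
    def test_full_study_reproducible(self):
        cfg = SimConfig(n_samples=60, n_genes=60, n_variants=500, seed=7)
        a = simulate_study(cfg)
        b = simulate_study(cfg)
        np.testing.assert_array_equal(a.genotypes.dosages, b.genotypes.dosages)
        pd.testing.assert_frame_equal(a.expression, b.expression)
        pd.testing.assert_frame_equal(a.allele_counts, b.allele_counts)
        pd.testing.assert_frame_equal(a.truth.eqtl_truth, b.truth.eqtl_truth)
        pd.testing.assert_frame_equal(
            a.segmentations[0].intervals, b.segmentations[0].intervals
        )
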