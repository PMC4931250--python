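"""cis-eQTL mapping, LD pruning and conditional analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from myoqtl import eqtl
from myoqtl.datatypes import GeneAnnotation, GenotypeMatrix
from myoqtl.sim import SimConfig, simulate_genotypes
from myoqtl.sim.scenarios import (
    conditional_independent_scenario,
    conditional_shadow_scenario,
)


def _gm(dosages, positions=None, chrom="chr1"):
    dosages = np.atleast_2d(np.asarray(dosages, dtype=float))
    m, n = dosages.shape
    positions = positions if positions is not None else 1000 * (np.arange(m) + 1)
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "id": [f"v{i}" for i in range(m)],
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(
        variants=variants, dosages=dosages, sample_ids=[f"s{i}" for i in range(n)]
    )


def _genes(rows):
    return GeneAnnotation(
        genes=pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss_list"])
    )


class TestLatentFactorAdjust:
    def test_k0_equals_plain_residualization(self, rng):
        from myoqtl.stats import inverse_normal, residualize

        expr = pd.DataFrame(
            rng.lognormal(size=(10, 60)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(60)],
        )
        cov = pd.DataFrame({"age": rng.normal(size=60)}, index=expr.columns)
        out = eqtl.latent_factor_adjust(expr, cov, k=0, rng=np.random.default_rng(9))
        gen = np.random.default_rng(9)
        for i in range(10):
            y = inverse_normal(expr.iloc[i].to_numpy(), rng=gen)
            manual = inverse_normal(residualize(y, cov), rng=gen)
            np.testing.assert_allclose(out.iloc[i].to_numpy(), manual, atol=1e-10)

    def test_planted_factors_removed(self, rng):
        n, g, kf = 150, 200, 3
        factors = rng.normal(size=(kf, n))
        loadings = rng.normal(0, 1.0, size=(g, kf))
        Y = loadings @ factors + rng.normal(size=(g, n))
        expr = pd.DataFrame(
            np.exp(Y), index=[f"g{i}" for i in range(g)],
            columns=[f"s{i}" for i in range(n)],
        )
        adj = eqtl.latent_factor_adjust(expr, None, k=3, rng=np.random.default_rng(0))
        cors = [
            abs(np.corrcoef(adj.to_numpy().mean(axis=0) * 0 + adj.iloc[i], factors[j])[0, 1])
            for i in range(0, g, 40)
            for j in range(kf)
        ]
        # mean absolute factor correlation collapses after adjustment
        assert np.mean(cors) < 0.05

    def test_k_too_large_rejected(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 20)))
        with pytest.raises(ValueError):
            eqtl.latent_factor_adjust(expr, None, k=20)


class TestCisPairs:
    def test_window_boundaries_inclusive(self):
        gm = _gm(
            np.random.default_rng(0).integers(0, 3, size=(3, 10)),
            positions=[5_000, 1_005_000, 1_005_001],
        )
        genes = _genes([("G1", "chr1", "+", (5_000,))])
        pairs = eqtl.cis_pairs(genes, gm)
        ids = set(pairs["variant_id"])
        assert "v0" in ids  # at the anchor
        assert "v1" in ids  # exactly 1 Mb away
        assert "v2" not in ids  # 1 Mb + 1

    def test_negative_strand_anchor_is_largest_tss(self):
        gm = _gm(np.random.default_rng(0).integers(0, 3, size=(1, 10)),
                 positions=[2_100_000])
        genes = _genes([("G1", "chr1", "-", (1_000_000, 1_500_000))])
        pairs = eqtl.cis_pairs(genes, gm)
        # anchor = 1.5 Mb (largest position on - strand); v0 within 1 Mb of it
        assert len(pairs) == 1

    def test_different_chromosome_excluded(self):
        gm = _gm(np.random.default_rng(0).integers(0, 3, size=(1, 10)), chrom="chr2")
        genes = _genes([("G1", "chr1", "+", (1_000,))])
        assert eqtl.cis_pairs(genes, gm).empty


class TestMapCisEqtl:
    def test_standardized_relationship_beta_one(self):
        gen = np.random.default_rng(0)
        g = gen.integers(0, 3, size=200).astype(float)
        gm = _gm([g])
        y = (g - g.mean()) / g.std()
        Y = pd.DataFrame([y], index=["G1"], columns=gm.sample_ids)
        pairs = pd.DataFrame({"gene_id": ["G1"], "variant_id": ["v0"]})
        rec = eqtl.map_cis_eqtl(Y, gm, pairs)
        assert rec["beta"].iloc[0] * g.std() == pytest.approx(1.0, abs=1e-10)
        assert rec["p"].iloc[0] < 1e-100

    def test_matches_normal_equations_oracle(self, rng):
        n = 50
        g = rng.integers(0, 3, size=n).astype(float)
        y = rng.normal(size=n)
        gm = _gm([g])
        Y = pd.DataFrame([y], index=["G1"], columns=gm.sample_ids)
        rec = eqtl.map_cis_eqtl(
            Y, gm, pd.DataFrame({"gene_id": ["G1"], "variant_id": ["v0"]})
        )
        X = np.column_stack([np.ones(n), g])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        se = np.sqrt(resid @ resid / (n - 2) * np.linalg.inv(X.T @ X)[1, 1])
        p = 2 * sps.t.sf(abs(beta[1] / se), n - 2)
        assert rec["beta"].iloc[0] == pytest.approx(beta[1], abs=1e-10)
        assert rec["se"].iloc[0] == pytest.approx(se, abs=1e-10)
        assert rec["p"].iloc[0] == pytest.approx(p, abs=1e-12)

    def test_power_at_common_planted_effect(self):
        # beta_std = 0.5 at maf 0.3, n = 267: detection is essentially certain
        gen = np.random.default_rng(1)
        n, m = 267, 2000
        hits = 0
        dos = gen.binomial(2, 0.3, size=(m, n)).astype(float)
        gm = _gm(dos)
        ys = []
        n_signal = 100
        for i in range(n_signal):
            g = dos[i]
            gs = (g - g.mean()) / g.std()
            ys.append(0.5 * gs + np.sqrt(1 - 0.25) * gen.normal(size=n))
        for i in range(n_signal, m):
            ys.append(gen.normal(size=n))
        Y = pd.DataFrame(ys, index=[f"G{i}" for i in range(m)], columns=gm.sample_ids)
        pairs = pd.DataFrame(
            {"gene_id": [f"G{i}" for i in range(m)], "variant_id": [f"v{i}" for i in range(m)]}
        )
        rec = eqtl.map_cis_eqtl(Y, gm, pairs).set_index("gene_id")
        signal = rec.loc[[f"G{i}" for i in range(n_signal)]]
        assert (signal["q"] <= 0.05).mean() > 0.9

    def test_monotone_power_in_beta_and_maf(self):
        gen = np.random.default_rng(2)
        n, reps = 200, 150
        power = {}
        for maf in (0.1, 0.4):
            for b in (0.15, 0.35):
                hits = 0
                for _ in range(reps):
                    g = gen.binomial(2, maf, size=n).astype(float)
                    if g.std() == 0:
                        continue
                    gs = (g - g.mean()) / g.std()
                    y = b * gs + gen.normal(size=n)
                    gm = _gm([g])
                    Y = pd.DataFrame([y], index=["G1"], columns=gm.sample_ids)
                    rec = eqtl.map_cis_eqtl(
                        Y, gm, pd.DataFrame({"gene_id": ["G1"], "variant_id": ["v0"]})
                    )
                    hits += rec["p"].iloc[0] < 0.01
                power[(maf, b)] = hits / reps
        assert power[(0.1, 0.35)] >= power[(0.1, 0.15)]
        assert power[(0.4, 0.35)] >= power[(0.4, 0.15)]
        assert power[(0.4, 0.35)] >= power[(0.1, 0.35)] - 0.05

    def test_low_mac_pairs_skipped(self):
        g = np.zeros(100)
        g[0] = 1  # MAC 1
        gm = _gm([g])
        Y = pd.DataFrame([np.random.default_rng(0).normal(size=100)],
                         index=["G1"], columns=gm.sample_ids)
        rec = eqtl.map_cis_eqtl(
            Y, gm, pd.DataFrame({"gene_id": ["G1"], "variant_id": ["v0"]})
        )
        assert rec.empty


class TestLd:
    def test_identical_vectors(self, rng):
        g = rng.integers(0, 3, 100).astype(float)
        assert eqtl.ld_r2(g, g) == pytest.approx(1.0)

    def test_allele_flip_invariance(self, rng):
        g = rng.integers(0, 3, 100).astype(float)
        assert eqtl.ld_r2(g, 2 - g) == pytest.approx(1.0)

    def test_independent_variants_near_zero(self):
        gen = np.random.default_rng(3)
        g1 = gen.binomial(2, 0.3, 10_000).astype(float)
        g2 = gen.binomial(2, 0.3, 10_000).astype(float)
        assert eqtl.ld_r2(g1, g2) < 0.01

    def test_zero_variance_sentinel(self):
        assert np.isnan(eqtl.ld_r2(np.zeros(10), np.arange(10.0)))


class TestLdPrune:
    def _records(self, ps):
        return pd.DataFrame(
            {
                "gene_id": "G1",
                "variant_id": [f"v{i}" for i in range(len(ps))],
                "p": ps,
            }
        )

    def test_perfect_proxies_keep_lower_p(self, rng):
        g = rng.integers(0, 3, 200).astype(float)
        gm = _gm([g, g])
        pruned = eqtl.ld_prune_per_gene(self._records([0.01, 0.001]), gm)
        assert list(pruned["variant_id"]) == ["v1"]

    def test_independent_all_kept(self):
        gen = np.random.default_rng(4)
        dos = gen.binomial(2, 0.3, size=(3, 5000)).astype(float)
        gm = _gm(dos)
        pruned = eqtl.ld_prune_per_gene(self._records([0.01, 0.02, 0.03]), gm)
        assert len(pruned) == 3

    def test_greedy_chain_keeps_a_and_c(self):
        # continuous (imputation-style) dosages with r2(a,b)~0.5,
        # r2(b,c)~0.5, r2(a,c)~0.1; p(a) < p(b) < p(c): greedy keeps {a, c}
        gen = np.random.default_rng(5)
        n = 20_000
        cov = np.array(
            [[1.0, 0.707, 0.316], [0.707, 1.0, 0.707], [0.316, 0.707, 1.0]]
        )
        L = np.linalg.cholesky(cov)
        z = L @ gen.normal(size=(3, n))
        dos = np.clip(1.0 + 0.25 * z, 0, 2)
        gm = _gm(dos)
        r_ab = eqtl.ld_r2(dos[0], dos[1])
        r_bc = eqtl.ld_r2(dos[1], dos[2])
        r_ac = eqtl.ld_r2(dos[0], dos[2])
        assert 0.3 < r_ab < 0.7 and 0.3 < r_bc < 0.7 and r_ac < 0.2
        pruned = eqtl.ld_prune_per_gene(self._records([0.001, 0.01, 0.1]), gm)
        assert list(pruned["variant_id"]) == ["v0", "v2"]

    def test_no_kept_pair_above_threshold(self, small_study):
        gm = small_study.genotypes
        gen = np.random.default_rng(6)
        vids = gm.variants["id"].iloc[:40]
        rec = pd.DataFrame(
            {"gene_id": "G1", "variant_id": vids, "p": gen.uniform(size=40)}
        )
        pruned = eqtl.ld_prune_per_gene(rec, gm, threshold=0.2)
        idx = gm.index_of(pruned["variant_id"].to_numpy())
        for i in range(len(idx)):
            for j in range(i + 1, len(idx)):
                r2 = eqtl.ld_r2(gm.dosages[idx[i]], gm.dosages[idx[j]])
                assert not (np.isfinite(r2) and r2 >= 0.2)


class TestBestPerGene:
    def test_single_record(self):
        gm = _gm([np.random.default_rng(0).integers(0, 3, 10)])
        rec = pd.DataFrame({"gene_id": ["G1"], "variant_id": ["v0"], "p": [0.5]})
        out = eqtl.best_per_gene(rec, gm)
        assert len(out) == 1

    def test_min_p_wins(self, rng):
        gm = _gm(rng.integers(0, 3, size=(2, 10)))
        rec = pd.DataFrame(
            {"gene_id": "G1", "variant_id": ["v0", "v1"], "p": [0.02, 0.01]}
        )
        assert eqtl.best_per_gene(rec, gm)["variant_id"].iloc[0] == "v1"

    def test_exact_tie_lower_position_wins(self, rng):
        gm = _gm(rng.integers(0, 3, size=(2, 10)), positions=[100, 500])
        rec = pd.DataFrame(
            {"gene_id": "G1", "variant_id": ["v1", "v0"], "p": [0.01, 0.01]}
        )
        assert eqtl.best_per_gene(rec, gm)["variant_id"].iloc[0] == "v0"


class TestConditional:
    def test_empty_selection_returns_marginal(self, rng):
        dos = rng.integers(0, 3, size=(5, 100)).astype(float)
        gm = _gm(dos)
        y = rng.normal(size=100)  # pure noise: nothing passes stop_p
        Y = pd.DataFrame([y], index=["GENE"], columns=gm.sample_ids)
        res = eqtl.conditional_gwas_eqtl("v0", "GENE", Y, gm, gm.variants["id"])
        assert res.selected_covariate_variants == []
        assert res.conditional_p == pytest.approx(res.marginal_p, abs=1e-12)

    def test_shadow_snp_conditional_p_null(self):
        ps = []
        for rep in range(40):
            Y, gm, genes, gwas = conditional_shadow_scenario(n=200, seed=rep)
            res = eqtl.conditional_gwas_eqtl(
                gwas, "GENE", Y, gm, gm.variants["id"].to_numpy()
            )
            ps.append(res.conditional_p)
        assert np.median(ps) > 0.1

    def test_independent_effect_survives_conditioning(self):
        hits = 0
        for rep in range(40):
            Y, gm, genes, gwas = conditional_independent_scenario(n=267, seed=rep)
            res = eqtl.conditional_gwas_eqtl(
                gwas, "GENE", Y, gm, gm.variants["id"].to_numpy()
            )
            hits += res.conditional_p < 0.05
        assert hits / 40 >= 0.9

    def test_collinear_selected_variant_flagged(self, rng):
        g = rng.integers(0, 3, size=100).astype(float)
        causal = g.copy()
        dos = np.vstack([g, causal, rng.integers(0, 3, size=(3, 100))]).astype(float)
        gm = _gm(dos)
        y = 2.0 * (g - g.mean()) + rng.normal(0, 0.5, 100)
        Y = pd.DataFrame([y], index=["GENE"], columns=gm.sample_ids)
        res = eqtl.conditional_gwas_eqtl("v0", "GENE", Y, gm, gm.variants["id"])
        # the perfect duplicate is never addable (rank deficient), so it
        # cannot be selected; no crash and a valid stopping reason
        assert res.stopped_reason in (
            "no candidate below stop_p",
            "no addable candidate",
        )


class TestEndToEndRecovery:
    def test_estimated_betas_track_planted_betas(self, small_study):
        study = small_study
        y = eqtl.latent_factor_adjust(
            study.expression, study.covariates, k=8, rng=np.random.default_rng(0)
        )
        pairs = eqtl.cis_pairs(study.genes, study.genotypes)
        rec = eqtl.map_cis_eqtl(y, study.genotypes, pairs)
        m = rec.merge(
            study.truth.eqtl_truth, on=["gene_id", "variant_id"],
            suffixes=("_est", "_true"),
        )
        gm = study.genotypes
        sd = gm.dosages[gm.index_of(m["variant_id"].to_numpy())].std(axis=1)
        est_std = m["beta_est"] * sd
        true_std = m["beta_std"] / np.sqrt(1 + m["beta_std"] ** 2)
        slope = sps.linregress(true_std, est_std).slope
        # the small fixture (120 samples, 150 genes) attenuates more than the
        # study-scale run checked in the acceptance suite
        assert 0.8 <= slope <= 1.2
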