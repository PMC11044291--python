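import numpy as np
import pytest
from scipy import stats

from xwaspipe.config import LayerConfig, TraitConfig
from xwaspipe.simulate import (
    scan_cis_qtl,
    scan_gwas,
    simulate_genotypes,
    simulate_molecular_layers,
    simulate_trait,
)
from xwaspipe.types import ConfigurationError


class TestGenotypes:
    def test_zero_within_block_r_gives_independent_variants(self):
        geno = simulate_genotypes(2000, 100, 20, 0.0, (0.1, 0.5), seed=1)
        R = np.corrcoef(geno.dosage.astype(float), rowvar=False)
        off = np.abs(R[np.triu_indices(100, k=1)])
        assert off.mean() < 3 / np.sqrt(2000)

    def test_block_size_one_is_blockwise_singleton(self):
        geno = simulate_genotypes(50, 10, 1, 0.9, (0.1, 0.5), seed=1)
        assert all(len(b) == 1 for b in geno.ld_blocks)

    def test_same_seed_same_matrix(self):
        a = simulate_genotypes(100, 30, 10, 0.5, (0.1, 0.5), seed=42)
        b = simulate_genotypes(100, 30, 10, 0.5, (0.1, 0.5), seed=42)
        np.testing.assert_array_equal(a.dosage, b.dosage)
        assert [v.variant_id for v in a.variants] == [v.variant_id for v in b.variants]

    def test_degenerate_maf_range_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_genotypes(10, 10, 5, 0.5, (0.0, 0.0), seed=1)

    def test_maf_within_range_up_to_sampling_error(self):
        geno = simulate_genotypes(3000, 60, 20, 0.5, (0.1, 0.4), seed=2)
        freq = geno.dosage.mean(axis=0) / 2
        maf = np.minimum(freq, 1 - freq)
        assert (maf > 0.05).all() and (maf < 0.45).all()

    def test_within_block_neighbours_correlated(self):
        geno = simulate_genotypes(2000, 40, 20, 0.8, (0.2, 0.5), seed=3)
        R = np.corrcoef(geno.dosage.astype(float), rowvar=False)
        lag1 = [R[i, i + 1] for i in range(39) if (i % 20) != 19]
        assert np.mean(lag1) > 0.4


class TestLayers:
    def test_zero_effect_sd_gives_uniform_qtl_p(self):
        geno = simulate_genotypes(400, 400, 20, 0.5, (0.1, 0.5), seed=5)
        layers, _ = simulate_molecular_layers(
            geno, {"eQTL": LayerConfig(n_features=300, effect_sd=0.0)},
            cis_window_bp=100_000, seed=5,
        )
        qtls = scan_cis_qtl(geno, layers[0])
        # one p per feature (its first cis SNP) -> independent-ish sample
        pvals = [q.records["P"].iloc[0] for q in qtls]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_full_sharing_reuses_eqtl_symbols(self):
        geno = simulate_genotypes(100, 60, 20, 0.5, (0.1, 0.5), seed=6)
        layers, truth = simulate_molecular_layers(
            geno,
            {
                "eQTL": LayerConfig(n_features=5),
                "sQTL": LayerConfig(n_features=6, sharing_fraction=1.0),
            },
            cis_window_bp=100_000,
            seed=6,
        )
        eqtl_symbols = {f.gene_symbol for f in layers[0].features}
        assert all(f.gene_symbol in eqtl_symbols for f in layers[1].features)
        assert len(truth.shares_with) == 6

    def test_noise_free_single_causal_equals_dosage(self):
        geno = simulate_genotypes(80, 30, 10, 0.5, (0.1, 0.5), seed=7)
        layers, _ = simulate_molecular_layers(
            geno,
            {"eQTL": LayerConfig(n_features=1, n_causal=1, residual_sd=0.0)},
            cis_window_bp=1_000_000,
            seed=7,
        )
        feat = layers[0].features[0]
        expected = feat.causal_effects[0] * geno.dosage[:, feat.causal_indices[0]]
        np.testing.assert_allclose(feat.phenotype, expected)

    def test_causal_indices_subset_of_cis(self, small_layers):
        layers, _ = small_layers
        for layer in layers:
            for f in layer.features:
                assert set(f.causal_indices) <= set(f.cis_indices)


class TestTrait:
    def test_null_trait_independent_of_genotype(self, small_geno, small_layers):
        layers, _ = small_layers
        cfg = TraitConfig(mediated_fraction=0.0, n_direct=0, residual_sd=1.0)
        y, truth = simulate_trait(small_geno, layers, cfg, seed=8)
        assert truth.bxy_true == {} and truth.direct_effects == {}
        gwas = scan_gwas(small_geno, y, "NULL")
        assert gwas.records["P"].min() > 1e-5  # no real signal at n=500

    def test_single_mediated_effect_recovered_by_ols(self):
        # independent OLS oracle: regress trait on the feature phenotype
        geno = simulate_genotypes(5000, 30, 10, 0.5, (0.1, 0.5), seed=9)
        layers, _ = simulate_molecular_layers(
            geno, {"eQTL": LayerConfig(n_features=1, effect_sd=0.8)},
            cis_window_bp=1_000_000, seed=9,
        )
        feat = layers[0].features[0]
        rng = np.random.default_rng(9)
        y = 0.3 * feat.phenotype + rng.normal(0, 1, 5000)
        slope = stats.linregress(feat.phenotype, y).slope
        assert slope == pytest.approx(0.3, abs=0.05)

    def test_all_components_zero_rejected(self, small_geno, small_layers):
        layers, _ = small_layers
        cfg = TraitConfig(bxy_sd=0.0, direct_sd=0.0, residual_sd=1.0)
        y, _ = simulate_trait(small_geno, layers, cfg, seed=1)
        assert np.std(y) > 0
        bad = TraitConfig.model_construct(
            mediated_fraction=0.1, bxy_sd=0.0, n_direct=1, direct_sd=0.0,
            residual_sd=0.0,
        )
        with pytest.raises(ConfigurationError):
            simulate_trait(small_geno, layers, bad, seed=1)

    def test_fixed_seed_identical_trait(self, small_geno, small_layers):
        layers, _ = small_layers
        cfg = TraitConfig()
        y1, _ = simulate_trait(small_geno, layers, cfg, seed=3)
        y2, _ = simulate_trait(small_geno, layers, cfg, seed=3)
        np.testing.assert_array_equal(y1, y2)


class TestScans:
    def test_exact_linear_relation_recovered(self, small_geno):
        j = 5
        y = 2.0 * small_geno.dosage[:, j].astype(float)
        gwas = scan_gwas(small_geno, y, "T")
        row = gwas.records.set_index("SNP").loc[small_geno.variants[j].variant_id]
        assert row["BETA"] == pytest.approx(2.0)
        assert row["P"] < 1e-100

    def test_z_equals_beta_over_se(self, small_geno):
        rng = np.random.default_rng(0)
        gwas = scan_gwas(small_geno, rng.normal(size=500), "T")
        np.testing.assert_allclose(
            gwas.records["Z"], gwas.records["BETA"] / gwas.records["SE"], rtol=1e-6
        )

    def test_permuted_trait_p_uniform(self):
        geno = simulate_genotypes(300, 2000, 1, 0.0, (0.1, 0.5), seed=10)
        rng = np.random.default_rng(10)
        gwas = scan_gwas(geno, rng.permutation(rng.normal(size=300)), "T")
        assert stats.kstest(gwas.records["P"], "uniform").pvalue > 0.01

    def test_causal_variant_attains_min_p(self):
        geno = simulate_genotypes(800, 500, 10, 0.4, (0.1, 0.5), seed=11)
        layers, _ = simulate_molecular_layers(
            geno,
            {"eQTL": LayerConfig(n_features=50, effect_sd=1.5, residual_sd=0.2)},
            cis_window_bp=100_000,
            seed=11,
        )
        qtls = scan_cis_qtl(geno, layers[0])
        by_id = {f.feature_id: f for f in layers[0].features}
        hits = 0
        for q in qtls:
            top = q.records.loc[q.records["P"].idxmin(), "SNP"]
            causal_ids = {
                geno.variants[j].variant_id for j in by_id[q.feature_id].causal_indices
            }
            hits += top in causal_ids
        assert hits >= 45

    def test_non_cis_variant_absent(self, small_geno, small_layers):
        layers, _ = small_layers
        qtls = scan_cis_qtl(small_geno, layers[0])
        positions = {v.variant_id: v.position for v in small_geno.variants}
        by_id = {f.feature_id: f for f in layers[0].features}
        for q in qtls:
            anchor = by_id[q.feature_id].anchor_bp
            assert all(
                abs(positions[s] - anchor) <= 200_000 for s in q.records["SNP"]
            )

    def test_mediation_links_gwas_and_qtl_z(self):
        # With pure mediation, z_gwas ~ b_xy * scaled z_eqtl at the causal SNP.
        geno = simulate_genotypes(5000, 20, 20, 0.5, (0.2, 0.5), seed=12)
        layers, _ = simulate_molecular_layers(
            geno, {"eQTL": LayerConfig(n_features=1, effect_sd=1.0, residual_sd=0.5)},
            cis_window_bp=1_000_000, seed=12,
        )
        feat = layers[0].features[0]
        rng = np.random.default_rng(12)
        b_xy = 0.3
        y = b_xy * feat.phenotype + rng.normal(0, 1, 5000)
        gwas = scan_gwas(geno, y, "T").records.set_index("SNP")
        qtl = scan_cis_qtl(geno, layers[0])[0].records.set_index("SNP")
        snp = geno.variants[feat.causal_indices[0]].variant_id
        ratio = gwas.loc[snp, "BETA"] / qtl.loc[snp, "BETA"]
        assert ratio == pytest.approx(b_xy, abs=0.05)


class TestLayerExchangeability:
    def test_layer_label_changes_labels_not_distributions(self):
        # same spec, same seed, different non-expression layer label:
        # numeric content identical, only the type tag differs
        geno = simulate_genotypes(200, 60, 20, 0.5, (0.1, 0.5), seed=13)
        spec = {"n": LayerConfig(n_features=6, tissue_label="blood")}
        a, _ = simulate_molecular_layers(
            geno, {"pQTL": spec["n"]}, cis_window_bp=100_000, seed=13
        )
        b, _ = simulate_molecular_layers(
            geno, {"m6AQTL": spec["n"]}, cis_window_bp=100_000, seed=13
        )
        for fa, fb in zip(a[0].features, b[0].features):
            assert fa.layer_type.value == "pQTL" and fb.layer_type.value == "m6AQTL"
            np.testing.assert_array_equal(fa.phenotype, fb.phenotype)
            np.testing.assert_array_equal(fa.causal_indices, fb.causal_indices)
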