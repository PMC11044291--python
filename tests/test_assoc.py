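import numpy as np
import pytest

from conftest import make_gwas, make_qtl
from xwaspipe.assoc import (
    HeidiParams,
    bonferroni_filter,
    heidi_test,
    smr_test,
    tissue_group_of,
    train_weights,
    twas_association,
)
from xwaspipe.config import LayerConfig
from xwaspipe.simulate import (
    ld_reference,
    scan_cis_qtl,
    scan_gwas,
    simulate_genotypes,
    simulate_molecular_layers,
)
from xwaspipe.types import (
    LdReference,
    QtlType,
    TissueGroup,
    Tool,
    VariantRecord,
    WeightModel,
    XwasResult,
)


def _weight_model(weights, tissue="brain_cortex"):
    return WeightModel(
        feature_id="F1",
        gene_symbol="GENE1",
        qtl_type=QtlType.EQTL,
        tissue_label=tissue,
        weights=weights,
        model_tag="top1",
        cv_r2=0.5,
    )


def _ld(ids, R):
    variants = [
        VariantRecord(i, "1", 1000 + k, "A", "G") for k, i in enumerate(ids)
    ]
    return LdReference(variants=variants, correlation=np.asarray(R, float))


class TestTissueGroup:
    @pytest.mark.parametrize(
        "label,expected",
        [
            ("brain_cortex", TissueGroup.BRAIN),
            ("Cerebellum", TissueGroup.BRAIN),
            ("whole_blood", TissueGroup.NON_BRAIN),
            ("Lung", TissueGroup.NON_BRAIN),
        ],
    )
    def test_keyword_grouping(self, label, expected):
        assert tissue_group_of(label) is expected


class TestTrainWeights:
    def test_single_cis_variant_top1_forced(self, small_geno, small_layers):
        layers, _ = small_layers
        feat = layers[0].features[0]
        single = type(feat)(**{**feat.__dict__})
        single.cis_indices = feat.causal_indices[:1]
        model = train_weights(small_geno, single, model="top1")
        assert len(model.weights) == 1
        (w,) = model.weights.values()
        assert w == 1.0

    def test_noise_free_feature_high_cv_r2(self):
        geno = simulate_genotypes(1000, 30, 10, 0.4, (0.1, 0.5), seed=21)
        layers, _ = simulate_molecular_layers(
            geno,
            {"eQTL": LayerConfig(n_features=1, effect_sd=1.0, residual_sd=1e-6)},
            cis_window_bp=1_000_000,
            seed=21,
        )
        model = train_weights(
            geno, layers[0].features[0], model="ridge", ridge_penalty=0.01, seed=0
        )
        assert model.cv_r2 > 0.95

    def test_pure_noise_cv_r2_near_zero(self):
        geno = simulate_genotypes(500, 200, 10, 0.4, (0.1, 0.5), seed=22)
        layers, _ = simulate_molecular_layers(
            geno, {"eQTL": LayerConfig(n_features=50, effect_sd=0.0)},
            cis_window_bp=50_000, seed=22,
        )
        r2 = [
            train_weights(geno, f, model="ridge", cv_folds=3, seed=0).cv_r2
            for f in layers[0].features
        ]
        assert np.mean(r2) < 0.05


class TestTwas:
    def test_single_variant_identity(self):
        model = _weight_model({"rs1": 1.0})
        gwas = make_gwas([{"SNP": "rs1", "Z": 2.5, "P": 0.0124}])
        res = twas_association(model, gwas, _ld(["rs1"], [[1.0]]))
        assert res.z_stat == pytest.approx(2.5)
        assert res.tool is Tool.FUSION

    def test_two_independent_variants_quadratic_form(self):
        # hand evaluation: (1+1)/sqrt(2) = sqrt(2)
        model = _weight_model({"rs1": 1.0, "rs2": 1.0})
        gwas = make_gwas(
            [{"SNP": "rs1", "Z": 1.0, "P": 0.317}, {"SNP": "rs2", "Z": 1.0, "P": 0.317}]
        )
        res = twas_association(model, gwas, _ld(["rs1", "rs2"], np.eye(2)))
        assert res.z_stat == pytest.approx(np.sqrt(2.0))

    def test_weight_negation_flips_sign_only(self):
        gwas = make_gwas(
            [{"SNP": "rs1", "Z": 1.4, "P": 0.162}, {"SNP": "rs2", "Z": -0.3, "P": 0.764}]
        )
        ld = _ld(["rs1", "rs2"], [[1.0, 0.3], [0.3, 1.0]])
        plus = twas_association(_weight_model({"rs1": 0.7, "rs2": 0.2}), gwas, ld)
        minus = twas_association(_weight_model({"rs1": -0.7, "rs2": -0.2}), gwas, ld)
        assert minus.z_stat == pytest.approx(-plus.z_stat)
        assert minus.p_value == pytest.approx(plus.p_value)

    @pytest.mark.parametrize("scale", [0.1, 3.0, 250.0])
    def test_positive_rescaling_invariance(self, scale):
        gwas = make_gwas(
            [{"SNP": "rs1", "Z": 1.4, "P": 0.162}, {"SNP": "rs2", "Z": -0.3, "P": 0.764}]
        )
        ld = _ld(["rs1", "rs2"], [[1.0, 0.5], [0.5, 1.0]])
        base = twas_association(_weight_model({"rs1": 0.7, "rs2": 0.2}), gwas, ld)
        scaled = twas_association(
            _weight_model({"rs1": 0.7 * scale, "rs2": 0.2 * scale}), gwas, ld
        )
        assert scaled.z_stat == pytest.approx(base.z_stat)


class TestSmr:
    def test_equal_z_halves_chi2(self):
        # z_zy = z_zx = z  ->  z_smr^2 = z^2 / 2
        z = 6.0
        qtl = make_qtl([{"SNP": "rs1", "BETA": 0.6, "SE": 0.1, "P": 1e-9}])
        gwas = make_gwas(
            [{"SNP": "rs1", "Z": z, "BETA": 0.6, "SE": 0.1, "P": 2e-9}]
        )
        res = smr_test(qtl, gwas)
        assert res.z_stat**2 == pytest.approx(z**2 / 2)

    def test_hand_evaluated_chi2(self):
        # z_zy=4, z_zx=8 -> 16*64/80 = 12.8
        qtl = make_qtl([{"SNP": "rs1", "BETA": 0.8, "SE": 0.1, "P": 1e-14}])
        gwas = make_gwas(
            [{"SNP": "rs1", "Z": 4.0, "BETA": 0.4, "SE": 0.1, "P": 6.3e-5}]
        )
        res = smr_test(qtl, gwas)
        assert res.z_stat**2 == pytest.approx(12.8)
        assert res.b_xy_hat == pytest.approx(0.5)

    def test_no_instrument_returns_none(self):
        qtl = make_qtl([{"SNP": "rs1", "P": 1e-4}])
        gwas = make_gwas([{"SNP": "rs1", "Z": 2.0, "P": 0.0455}])
        assert smr_test(qtl, gwas, instrument_p_threshold=5e-8) is None

    def test_p_depends_only_on_z(self):
        # metamorphic: rescale beta and se together (z fixed) -> p unchanged
        qtl1 = make_qtl([{"SNP": "rs1", "BETA": 0.6, "SE": 0.1, "P": 1e-9}])
        qtl2 = make_qtl([{"SNP": "rs1", "BETA": 6.0, "SE": 1.0, "P": 1e-9}])
        gwas = make_gwas([{"SNP": "rs1", "Z": 4.0, "BETA": 0.4, "SE": 0.1, "P": 6.3e-5}])
        assert smr_test(qtl1, gwas).p_value == pytest.approx(
            smr_test(qtl2, gwas).p_value
        )

    def test_allele_flip_preserves_b_xy(self):
        qtl = make_qtl([{"SNP": "rs1", "A1": "A", "A2": "G", "BETA": 0.8,
                         "SE": 0.1, "P": 1e-14}])
        gwas_flipped = make_gwas(
            [{"SNP": "rs1", "A1": "G", "A2": "A", "Z": -4.0, "BETA": -0.4,
              "SE": 0.1, "P": 6.3e-5}]
        )
        res = smr_test(qtl, gwas_flipped)
        assert res.b_xy_hat == pytest.approx(0.5)


def _mediated_setup(seed, n=3000, two_causal=False):
    """Region + feature + trait; optionally a linkage (distinct causal) trait."""
    rng = np.random.default_rng(seed)
    geno = simulate_genotypes(n, 40, 40, 0.75, (0.1, 0.5), seed=rng)
    causal = 20
    phen = 0.9 * geno.dosage[:, causal].astype(float) + rng.normal(0, 1, n)
    if two_causal:
        # trait driven by a *different* variant in LD with the QTL causal one
        y = 0.35 * geno.dosage[:, causal + 2].astype(float) + rng.normal(0, 1, n)
    else:
        y = 0.3 * phen + rng.normal(0, 1, n)
    from xwaspipe.simulate import FeatureSim, MolecularLayer

    feat = FeatureSim(
        feature_id="F0", gene_symbol="G0", layer_type=QtlType.EQTL,
        tissue_label="brain", dataset_tag="SIM", chromosome="1",
        anchor_bp=geno.variants[causal].position,
        gene_start=1, gene_end=2,
        cis_indices=np.arange(40), causal_indices=np.array([causal]),
        causal_effects=np.array([0.9]), phenotype=phen,
    )
    layer = MolecularLayer(layer_type=QtlType.EQTL, features=[feat])
    qtl = scan_cis_qtl(geno, layer)[0]
    gwas = scan_gwas(geno, y, "SIM_2022")
    return geno, qtl, gwas


class TestHeidi:
    def test_too_few_eligible_snps_flagged(self):
        qtl = make_qtl(
            [
                {"SNP": "rs1", "P": 1e-12},
                {"SNP": "rs2", "P": 0.5},
                {"SNP": "rs3", "P": 0.5},
            ]
        )
        gwas = make_gwas(
            [{"SNP": f"rs{i}", "Z": 1.0, "P": 0.317} for i in (1, 2, 3)]
        )
        p, n = heidi_test(qtl, gwas, _ld(["rs1", "rs2", "rs3"], np.eye(3)))
        assert p is None and n == 0

    def test_single_shared_causal_variant_retained(self):
        geno, qtl, gwas = _mediated_setup(31)
        p, n = heidi_test(qtl, gwas, ld_reference(geno), seed=1)
        assert p is not None and n >= 3
        assert p > 0.05

    def test_linkage_scenario_detected(self):
        ps = []
        for seed in range(5):
            geno, qtl, gwas = _mediated_setup(100 + seed, n=6000, two_causal=True)
            p, _ = heidi_test(qtl, gwas, ld_reference(geno), seed=seed)
            if p is not None:
                ps.append(p)
        assert np.median(ps) < 0.05


def _result(p, tool=Tool.FUSION, p_heidi=None, dataset="SCZ_2022", panel="P1"):
    return XwasResult(
        gene_symbol="G", feature_id="F", qtl_type=QtlType.EQTL,
        tissue_label="brain", tissue_group=TissueGroup.BRAIN, tool=tool,
        gwas_dataset=dataset, qtl_dataset=panel, z_stat=1.0, p_value=p,
        b_xy_hat=0.2 if tool is Tool.SMR else None, p_heidi=p_heidi,
    )


class TestBonferroni:
    def test_family_of_20_threshold_arithmetic(self):
        results = [_result(0.002)] + [_result(0.003)] + [_result(0.5)] * 18
        out = bonferroni_filter(results, alpha=0.05)
        assert out[0].passes_correction is True  # 0.002 < 0.05/20
        assert out[1].passes_correction is False  # 0.003 > 0.0025

    def test_smr_heidi_retention_gate(self):
        results = [
            _result(1e-10, tool=Tool.SMR, p_heidi=0.01),
            _result(1e-10, tool=Tool.SMR, p_heidi=0.5),
            _result(1e-10, tool=Tool.SMR, p_heidi=None),
        ]
        out = bonferroni_filter(results, alpha=0.05)
        assert [r.passes_correction for r in out] == [False, True, True]

    def test_families_are_independent(self):
        results = [_result(0.004, dataset="SCZ_2022")] + [
            _result(0.5, dataset="BP_2021", panel="P2") for _ in range(50)
        ]
        out = bonferroni_filter(results, alpha=0.05)
        assert out[0].passes_correction is True  # family of 1
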