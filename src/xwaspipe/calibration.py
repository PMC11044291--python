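"""Calibration and recovery experiments for the summary-based statistics.

These are the package's standing statistical checks, runnable from a single
seed: type-I error of the FUSION-style and SMR tests under a null trait,
HEIDI retention under a single shared causal variant, Wald-ratio parameter
recovery and power monotonicity, and the set-algebra oracles for the novelty
window and replication-ratio computations. Each experiment simulates
independent cis regions so empirical rates carry binomial, not LD-clustered,
Monte-Carlo error.

Problem sizes default to the package's standard study conditions: cohorts of
2,000 individuals (5,000 for parameter recovery), cis regions of ~50 variants
at 10 kb spacing with AR(1) latent LD (r = 0.6), one causal cis variant per
feature with effect s.d. 0.6 on a unit-noise molecular phenotype, and a
mediated trait effect b_xy = 0.3 where stated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assoc import (
    HeidiParams,
    heidi_test,
    smr_test,
    train_weights,
    twas_association,
)
from .config import substream
from .novelty import min_p_in_window
from .metrics import replication_matrix
from .simulate import (
    FeatureSim,
    ld_reference,
    scan_cis_qtl,
    scan_gwas,
    simulate_genotypes,
    MolecularLayer,
)
from .types import GeneAnnotation, GwasSumstats, QtlType
import pandas as pd


def _region(
    rng: np.random.Generator,
    n: int,
    n_variants: int = 50,
    block_size: int = 25,
    r: float = 0.6,
):
    return simulate_genotypes(
        n_individuals=n,
        n_variants=n_variants,
        block_size=block_size,
        within_block_r=r,
        maf_range=(0.05, 0.5),
        seed=rng,
    )


def _make_feature(
    rng: np.random.Generator,
    geno,
    effect_sd: float = 0.6,
    noise_sd: float = 1.0,
    fixed_effect: float | None = None,
) -> FeatureSim:
    causal = int(rng.integers(0, geno.n_variants))
    if fixed_effect is not None:
        # fixed magnitude, random sign: guarantees a usable instrument
        effect = float(fixed_effect * rng.choice([-1.0, 1.0]))
    else:
        effect = rng.normal(0.0, effect_sd) if effect_sd > 0 else 0.0
    phen = effect * geno.dosage[:, causal].astype(float) + rng.normal(
        0.0, noise_sd, geno.n_individuals
    )
    return FeatureSim(
        feature_id="F0",
        gene_symbol="G0",
        layer_type=QtlType.EQTL,
        tissue_label="brain_cortex",
        dataset_tag="SIM",
        chromosome="1",
        anchor_bp=geno.variants[causal].position,
        gene_start=max(1, geno.variants[causal].position - 10_000),
        gene_end=geno.variants[causal].position + 10_000,
        cis_indices=np.arange(geno.n_variants),
        causal_indices=np.array([causal]),
        causal_effects=np.array([effect]),
        phenotype=phen,
    )


@dataclass
class NullCalibration:
    smr_type1: float
    twas_type1: float
    n_smr_tested: int
    n_twas_tested: int


def null_calibration(
    n_features: int = 2000,
    n_individuals: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> NullCalibration:
    """Empirical type-I error of SMR and the FUSION-style test on a null trait.

    Each feature lives on its own independent cis region; the trait is pure
    noise, so any rejection at nominal level ``alpha`` is a false positive.
    SMR is evaluated over the features whose top cis-QTL reaches the
    instrument threshold.
    """
    rng = substream(seed, "null-calibration")
    smr_rej = smr_n = twas_rej = twas_n = 0
    for _ in range(n_features):
        geno = _region(rng, n_individuals)
        feat = _make_feature(rng, geno)
        y = rng.normal(0.0, 1.0, n_individuals)
        gwas = scan_gwas(geno, y, "NULL_2022")
        layer = MolecularLayer(layer_type=QtlType.EQTL, features=[feat])
        qtl = scan_cis_qtl(geno, layer)[0]
        ld = ld_reference(geno)
        res = smr_test(qtl, gwas)
        if res is not None:
            smr_n += 1
            smr_rej += res.p_value < alpha
        model = train_weights(
            geno, feat, model="ridge", cv_folds=3, seed=int(rng.integers(2**31 - 1))
        )
        tw = twas_association(model, gwas, ld)
        twas_n += 1
        twas_rej += tw.p_value < alpha
    return NullCalibration(
        smr_type1=smr_rej / max(smr_n, 1),
        twas_type1=twas_rej / max(twas_n, 1),
        n_smr_tested=smr_n,
        n_twas_tested=twas_n,
    )


def heidi_retention_single_causal(
    n_features: int = 200,
    n_individuals: int = 2000,
    b_xy: float = 0.3,
    retain_threshold: float = 0.05,
    seed: int = 0,
) -> tuple[float, int]:
    """Fraction of single-shared-causal-variant features retained by HEIDI.

    Under a single causal variant driving both the molecular phenotype and
    (through it) the trait, HEIDI's null holds and P_HEIDI should be roughly
    uniform, so retention at P > 0.05 should approach 0.95.
    Returns (retention fraction, number of features with an evaluable HEIDI p).
    """
    rng = substream(seed, "heidi-retention")
    retained = evaluated = attempts = 0
    # Denser LD (r=0.75) so most features carry >= 3 eligible HEIDI SNPs;
    # simulate until n_features evaluable features have been scored.
    while evaluated < n_features and attempts < 10 * n_features:
        attempts += 1
        geno = _region(rng, n_individuals, r=0.75)
        feat = _make_feature(rng, geno, fixed_effect=0.9)
        y = b_xy * feat.phenotype + rng.normal(0.0, 1.0, n_individuals)
        gwas = scan_gwas(geno, y, "MED_2022")
        layer = MolecularLayer(layer_type=QtlType.EQTL, features=[feat])
        qtl = scan_cis_qtl(geno, layer)[0]
        if smr_test(qtl, gwas) is None:
            continue
        ld = ld_reference(geno)
        p_h, _ = heidi_test(
            qtl, gwas, ld, HeidiParams(), seed=int(rng.integers(2**31 - 1))
        )
        if p_h is None:
            continue
        evaluated += 1
        retained += p_h > retain_threshold
    return retained / max(evaluated, 1), evaluated


@dataclass
class RecoveryResult:
    mean_bxy_hat: float
    n_replicates: int
    smr_chi2_medians: list[float]
    twas_z2_medians: list[float]
    bxy_grid: list[float]


def smr_parameter_recovery(
    b_xy: float = 0.3,
    n_individuals: int = 5000,
    n_replicates: int = 200,
    monotonic_grid: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3),
    n_monotonic: int = 100,
    seed: int = 0,
) -> RecoveryResult:
    """Wald-ratio recovery of a known mediated effect, plus power monotonicity.

    Part 1: ``n_replicates`` independent regions with trait
    ``y = b_xy * phenotype + noise``; reports the mean SMR b_xy estimate.
    Part 2: on ``n_monotonic`` shared genotype/feature draws, the trait is
    regenerated at each grid effect size (matched noise), and the per-level
    medians of the SMR χ² and squared FUSION z are reported.
    """
    rng = substream(seed, "smr-recovery")
    estimates = []
    while len(estimates) < n_replicates:
        geno = _region(rng, n_individuals)
        feat = _make_feature(rng, geno, fixed_effect=0.8)
        y = b_xy * feat.phenotype + rng.normal(0.0, 1.0, n_individuals)
        gwas = scan_gwas(geno, y, "MED_2022")
        layer = MolecularLayer(layer_type=QtlType.EQTL, features=[feat])
        qtl = scan_cis_qtl(geno, layer)[0]
        res = smr_test(qtl, gwas)
        if res is not None:
            estimates.append(res.b_xy_hat)

    chi2 = {b: [] for b in monotonic_grid}
    z2 = {b: [] for b in monotonic_grid}
    for _ in range(n_monotonic):
        geno = _region(rng, n_individuals)
        feat = _make_feature(rng, geno, fixed_effect=0.8)
        noise = rng.normal(0.0, 1.0, n_individuals)
        model = train_weights(
            geno, feat, model="top1", cv_folds=3, seed=int(rng.integers(2**31 - 1))
        )
        ld = ld_reference(geno)
        layer = MolecularLayer(layer_type=QtlType.EQTL, features=[feat])
        qtl = scan_cis_qtl(geno, layer)[0]
        for b in monotonic_grid:
            y = b * feat.phenotype + noise
            gwas = scan_gwas(geno, y, "MED_2022")
            res = smr_test(qtl, gwas)
            if res is not None:
                chi2[b].append(res.z_stat**2)
            tw = twas_association(model, gwas, ld)
            z2[b].append(tw.z_stat**2)
    return RecoveryResult(
        mean_bxy_hat=float(np.mean(estimates)),
        n_replicates=len(estimates),
        smr_chi2_medians=[float(np.median(chi2[b])) for b in monotonic_grid],
        twas_z2_medians=[float(np.median(z2[b])) for b in monotonic_grid],
        bxy_grid=list(monotonic_grid),
    )


def novelty_window_oracle_agreement(
    n_genes: int = 1000, n_variants: int = 1500, seed: int = 0
) -> tuple[int, int]:
    """Compare the windowed min-p implementation with a brute-force scan.

    Random genes and random variant panels across three chromosomes; the
    oracle loops over every variant and applies the window predicate directly.
    Returns (n_agreeing, n_genes).
    """
    rng = substream(seed, "novelty-oracle")
    chroms = np.array(["1", "2", "6"])[rng.integers(0, 3, n_variants)]
    bps = rng.integers(1, 50_000_000, n_variants)
    p = rng.uniform(1e-12, 1.0, n_variants) ** 3  # heavy low-p tail
    records = pd.DataFrame(
        {
            "SNP": [f"rs{i}" for i in range(n_variants)],
            "CHR": chroms,
            "BP": bps,
            "A1": "A",
            "A2": "G",
            "Z": 0.0,
            "BETA": np.nan,
            "SE": np.nan,
            "P": np.clip(p, 1e-300, 1.0),
            "N": 10_000,
        }
    )
    gwas = GwasSumstats(trait_id="ORACLE", records=records)
    rows = list(zip(chroms, bps, np.clip(p, 1e-300, 1.0)))
    window_bp = 1_000_000
    agree = 0
    for i in range(n_genes):
        chrom = str(np.array(["1", "2", "6"])[rng.integers(0, 3)])
        start = int(rng.integers(1, 48_000_000))
        end = start + int(rng.integers(1, 200_000))
        gene = GeneAnnotation(
            canonical_symbol=f"G{i}",
            aliases=frozenset(),
            chromosome=chrom,
            start=start,
            end=end,
        )
        call = min_p_in_window(gene, gwas, window_bp)
        lo, hi = max(1, start - window_bp), end + window_bp
        inside = [pp for (c, b, pp) in rows if c == chrom and lo <= b <= hi]
        oracle = min(inside) if inside else None
        if oracle is None:
            agree += call.min_p is None
        else:
            agree += call.min_p is not None and np.isclose(call.min_p, oracle)
    return agree, n_genes


def replication_ratio_oracle_agreement(
    n_trials: int = 100, seed: int = 0
) -> tuple[int, int]:
    """Check directed replication ratios against hand set algebra.

    Random small gene sets (<= 20 genes per label); the oracle computes
    |A∩B|/|A| by explicit membership loops. Returns (n_agreeing, n_trials).
    """
    rng = substream(seed, "ratio-oracle")
    universe = [f"G{i}" for i in range(40)]
    agree = 0
    for _ in range(n_trials):
        labels = ["A", "B", "C"]
        sets = {
            lab: set(
                rng.choice(universe, size=int(rng.integers(0, 21)), replace=False)
            )
            for lab in labels
        }
        rm = replication_matrix(sets)
        ok = True
        for a in labels:
            for b in labels:
                overlap = sum(1 for g in sets[a] if g in sets[b])
                expected = overlap / len(sets[a]) if sets[a] else None
                got = rm.ratios.loc[a, b]
                if expected is None:
                    ok &= bool(np.isnan(got))
                else:
                    ok &= bool(np.isclose(got, expected))
                ok &= int(rm.counts.loc[a, b]) == overlap
        agree += ok
    return agree, n_trials


def _scaled_layers(scale: float) -> dict:
    from .config import LayerConfig

    base = {
        "eQTL": ("brain_cortex", 120),
        "sQTL": ("brain_dlpfc", 60),
        "pQTL": ("brain_rosmap", 40),
        "mQTL": ("blood", 60),
        "m6AQTL": ("brain_m6a", 30),
    }
    return {
        name: LayerConfig(
            n_features=max(2, int(n * scale)),
            sharing_fraction=0.0 if name == "eQTL" else 0.4,
            tissue_label=tissue,
        )
        for name, (tissue, n) in base.items()
    }


def mmrp_experiment(seed: int, outdir=None) -> dict:
    """Full-pipeline MMRP check: partition property and sharing enrichment.

    Runs the end-to-end pipeline on a cohort with 310 molecular features
    (40% cross-layer causal sharing outside the expression layer), verifies
    that per-disorder pattern gene counts sum to the number of multi-QTL
    genes, and estimates the odds ratio (Haldane-corrected) for genes
    simulated with cross-layer sharing to land in an MMRP set, relative to
    single-layer genes, over all genes with any retained evidence.
    """
    import tempfile
    from pathlib import Path

    from .config import AnalysisConfig
    from .evidence import disorder_of
    from .metrics import gene_qtl_profiles
    from .pipeline import run_pipeline

    cfg = AnalysisConfig(seed=seed)
    cfg = cfg.model_copy(
        update={
            "simulation": cfg.simulation.model_copy(
                update={"layers": _scaled_layers(1.0)}
            )
        }
    )
    state: dict = {}
    with tempfile.TemporaryDirectory() as tmp:
        run_dir = Path(outdir) if outdir is not None else Path(tmp)
        run_pipeline(cfg, run_dir, state=state)
    layers = state["cohort"]["layers"]
    lines = state["lines"]

    layer_count: dict[str, set] = {}
    for layer in layers:
        for feat in layer.features:
            layer_count.setdefault(feat.gene_symbol, set()).add(layer.layer_type)
    shared_genes = {g for g, ls in layer_count.items() if len(ls) >= 2}

    partition_ok = True
    mmrp_genes: set[str] = set()
    for disorder in sorted({disorder_of(l.gwas_dataset) for l in lines}):
        profiles = gene_qtl_profiles(lines, disorder)
        multi = {g for g, q in profiles.items() if len(q) >= 2}
        from .metrics import enumerate_mmrp

        patterns = enumerate_mmrp(profiles, disorder)
        partition_ok &= sum(len(p.genes) for p in patterns) == len(multi)
        partition_ok &= set().union(*[set(p.genes) for p in patterns], set()) == multi
        mmrp_genes |= multi

    universe = {l.gene_symbol for l in lines}
    a = len(universe & shared_genes & mmrp_genes)
    b = len((universe & shared_genes) - mmrp_genes)
    c = len((universe - shared_genes) & mmrp_genes)
    d = len((universe - shared_genes) - mmrp_genes)
    odds_ratio = ((a + 0.5) / (b + 0.5)) / ((c + 0.5) / (d + 0.5))
    return {
        "partition_consistent": bool(partition_ok),
        "odds_ratio": float(odds_ratio),
        "n_universe": len(universe),
        "n_shared_detected": len(universe & shared_genes),
        "n_mmrp_genes": len(mmrp_genes),
        "table": (a, b, c, d),
        "state": state,
    }


def determinism_check(seed: int, scale: float = 0.5) -> bool:
    """Two full pipeline runs with one seed: reliable-gene, novelty and MMRP
    tables must be byte-identical."""
    import tempfile
    from pathlib import Path

    from .config import AnalysisConfig
    from .pipeline import run_pipeline

    cfg = AnalysisConfig(seed=seed)
    cfg = cfg.model_copy(
        update={
            "simulation": cfg.simulation.model_copy(
                update={
                    "n_individuals": 800,
                    "n_variants": 400,
                    "layers": _scaled_layers(scale),
                }
            )
        }
    )
    tables = ("reliable_genes.tsv", "novelty.tsv", "mmrp.tsv")
    payloads = []
    with tempfile.TemporaryDirectory() as tmp:
        for run in ("a", "b"):
            out = Path(tmp) / run
            run_pipeline(cfg, out)
            payloads.append({t: (out / t).read_bytes() for t in tables})
    return payloads[0] == payloads[1]
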