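"""Synthetic cohorts with the causal structure the integration pipeline assumes.

The generator produces, from one seed: LD-blocked diploid genotypes, five
molecular layers (expression, splicing, protein, DNA methylation, m6A) whose
features receive cis-acting variant effects with partial cross-layer sharing,
a quantitative trait receiving mediated plus direct genetic effects, and the
marginal summary statistics (GWAS scan, nominal-pass cis-QTL scan) that every
downstream stage consumes. Case-control GWAS are emulated on the quantitative
(liability) scale since all downstream statistics consume z/beta/se only.

Cross-layer sharing reuses an expression feature's causal variants *and* gene
symbol in the other layers — the minimal structure that makes cross-QTL
replication and multi-QTL patterns non-degenerate downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import LayerConfig, SimulationConfig, TraitConfig
from .types import (
    ConfigurationError,
    GeneAnnotation,
    GwasSumstats,
    LdReference,
    QtlSumstats,
    QtlType,
    VariantRecord,
)

logger = logging.getLogger(__name__)

# Non-strand-ambiguous allele pairs only, so harmonization keeps all variants.
_ALLELE_PAIRS = [
    ("A", "G"),
    ("A", "C"),
    ("G", "A"),
    ("C", "A"),
    ("T", "G"),
    ("T", "C"),
    ("G", "T"),
    ("C", "T"),
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class GenotypeMatrix:
    """Diploid dosages (0/1/2) with contiguous LD blocks."""

    dosage: np.ndarray  # n_individuals x n_variants
    variants: list[VariantRecord]
    ld_blocks: list[np.ndarray]

    def __post_init__(self) -> None:
        if self.dosage.shape[1] != len(self.variants):
            raise ConfigurationError("dosage column count != variant count")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.position for v in self.variants])


@dataclass
class FeatureSim:
    """One simulated molecular feature (ground truth plus phenotype vector)."""

    feature_id: str
    gene_symbol: str
    layer_type: QtlType
    tissue_label: str
    dataset_tag: str
    chromosome: str
    anchor_bp: int
    gene_start: int
    gene_end: int
    cis_indices: np.ndarray
    causal_indices: np.ndarray
    causal_effects: np.ndarray
    phenotype: np.ndarray


@dataclass
class MolecularLayer:
    layer_type: QtlType
    features: list[FeatureSim]


@dataclass
class SimTruth:
    """Ground truth for parameter-recovery and enrichment tests."""

    bxy_true: dict[str, float] = field(default_factory=dict)  # feature_id -> effect
    direct_effects: dict[str, float] = field(default_factory=dict)  # variant_id
    shares_with: dict[str, str] = field(default_factory=dict)  # feature -> eQTL feature
    gene_of_feature: dict[str, str] = field(default_factory=dict)


def simulate_genotypes(
    n_individuals: int,
    n_variants: int,
    block_size: int,
    within_block_r: float,
    maf_range: tuple[float, float],
    seed,
    chromosome: str = "1",
    spacing_bp: int = 10_000,
    start_bp: int = 1_000_000,
) -> GenotypeMatrix:
    """Draw LD-blocked diploid genotypes.

    Each haplotype is a thresholded AR(1) latent Gaussian chain restarting at
    block boundaries, so within-block correlation decays with distance
    (latent correlation ``within_block_r ** |i-j|``) and across-block
    correlation is zero in expectation; thresholds are set per-variant so
    allele frequencies land in ``maf_range`` under Hardy-Weinberg.
    """
    lo, hi = maf_range
    if lo <= 0 or hi <= 0:
        raise ConfigurationError("degenerate maf_range: bounds must be > 0")
    if not (lo <= hi <= 0.5):
        raise ConfigurationError("maf_range must satisfy low <= high <= 0.5")
    if n_variants < block_size:
        raise ConfigurationError("n_variants must be >= block_size")
    rng = _rng(seed)
    maf = rng.uniform(lo, hi, n_variants)
    thresh = stats.norm.ppf(maf)

    r = within_block_r
    carry = np.sqrt(1.0 - r * r)
    dosage = np.zeros((n_individuals, n_variants), dtype=np.int8)
    for _hap in range(2):
        latent = np.empty((n_individuals, n_variants))
        eps = rng.standard_normal((n_individuals, n_variants))
        for j in range(n_variants):
            if j % block_size == 0:
                latent[:, j] = eps[:, j]
            else:
                latent[:, j] = r * latent[:, j - 1] + carry * eps[:, j]
        dosage += (latent < thresh).astype(np.int8)

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), n_variants)
    variants = [
        VariantRecord(
            variant_id=f"rs{j + 1:06d}",
            chromosome=chromosome,
            position=start_bp + j * spacing_bp,
            effect_allele=_ALLELE_PAIRS[pair_idx[j]][0],
            other_allele=_ALLELE_PAIRS[pair_idx[j]][1],
            effect_allele_frequency=float(maf[j]),
        )
        for j in range(n_variants)
    ]
    blocks = [
        np.arange(s, min(s + block_size, n_variants))
        for s in range(0, n_variants, block_size)
    ]
    return GenotypeMatrix(dosage=dosage, variants=variants, ld_blocks=blocks)


def simulate_molecular_layers(
    geno: GenotypeMatrix,
    layer_specs: dict[str, LayerConfig],
    cis_window_bp: int,
    seed,
) -> tuple[list[MolecularLayer], SimTruth]:
    """Generate molecular features per layer; each phenotype is a sparse linear
    function of its cis causal dosages plus Gaussian noise.

    A ``sharing_fraction`` of features in non-expression layers reuses the
    causal variants and gene symbol of a randomly drawn expression feature.
    m6A features are assigned a host gene symbol directly (no peak-to-gene
    mapping layer).
    """
    rng = _rng(seed)
    positions = geno.positions
    chrom = geno.variants[0].chromosome
    truth = SimTruth()
    gene_counter = 0
    layers: list[MolecularLayer] = []

    ordered = sorted(layer_specs.items(), key=lambda kv: kv[0] != QtlType.EQTL.value)
    eqtl_pool: list[FeatureSim] = []
    for layer_name, spec in ordered:
        layer_type = QtlType(layer_name)
        if not 0.0 <= spec.sharing_fraction <= 1.0:
            raise ConfigurationError("sharing_fraction outside [0,1]")
        features = []
        for i in range(spec.n_features):
            fid = f"{layer_type.value}_{i:04d}"
            share_source = None
            if (
                layer_type is not QtlType.EQTL
                and eqtl_pool
                and rng.uniform() < spec.sharing_fraction
            ):
                share_source = eqtl_pool[rng.integers(0, len(eqtl_pool))]
            if share_source is not None:
                anchor = share_source.anchor_bp
                cis = share_source.cis_indices
                causal = share_source.causal_indices
                symbol = share_source.gene_symbol
                truth.shares_with[fid] = share_source.feature_id
            else:
                anchor = int(positions[rng.integers(0, len(positions))])
                cis = np.flatnonzero(np.abs(positions - anchor) <= cis_window_bp)
                n_causal = min(spec.n_causal, len(cis))
                causal = rng.choice(cis, size=n_causal, replace=False)
                gene_counter += 1
                symbol = f"GENE{gene_counter:04d}"
            effects = rng.normal(0.0, spec.effect_sd, len(causal))
            noise = rng.normal(0.0, spec.residual_sd, geno.n_individuals)
            phen = geno.dosage[:, causal].astype(float) @ effects + noise
            feat = FeatureSim(
                feature_id=fid,
                gene_symbol=symbol,
                layer_type=layer_type,
                tissue_label=spec.tissue_label,
                dataset_tag=spec.dataset_tag,
                chromosome=chrom,
                anchor_bp=anchor,
                gene_start=max(1, anchor - 10_000),
                gene_end=anchor + 10_000,
                cis_indices=np.asarray(cis),
                causal_indices=np.asarray(causal),
                causal_effects=effects,
                phenotype=phen,
            )
            truth.gene_of_feature[fid] = symbol
            features.append(feat)
        if layer_type is QtlType.EQTL:
            eqtl_pool = features
        layers.append(MolecularLayer(layer_type=layer_type, features=features))
    return layers, truth


def simulate_trait(
    geno: GenotypeMatrix,
    layers: list[MolecularLayer],
    trait_cfg: TraitConfig,
    seed,
    truth: SimTruth | None = None,
) -> tuple[np.ndarray, SimTruth]:
    """Trait = mediated molecular effects + direct variant effects + noise."""
    if not layers:
        raise ConfigurationError("simulate_trait needs at least one layer")
    rng = _rng(seed)
    truth = truth or SimTruth()
    all_features = [f for layer in layers for f in layer.features]
    if (
        trait_cfg.bxy_sd == 0
        and trait_cfg.direct_sd == 0
        and trait_cfg.residual_sd == 0
    ):
        raise ConfigurationError("all trait variance components are zero")
    n_mediated = int(round(trait_cfg.mediated_fraction * len(all_features)))
    y = np.zeros(geno.n_individuals)
    if n_mediated > 0 and trait_cfg.bxy_sd > 0:
        chosen = rng.choice(len(all_features), size=n_mediated, replace=False)
        for idx in chosen:
            feat = all_features[idx]
            bxy = rng.normal(0.0, trait_cfg.bxy_sd)
            truth.bxy_true[feat.feature_id] = float(bxy)
            y = y + bxy * feat.phenotype
    if trait_cfg.n_direct > 0 and trait_cfg.direct_sd > 0:
        direct_idx = rng.choice(geno.n_variants, size=trait_cfg.n_direct, replace=False)
        effects = rng.normal(0.0, trait_cfg.direct_sd, len(direct_idx))
        y = y + geno.dosage[:, direct_idx].astype(float) @ effects
        for j, e in zip(direct_idx, effects):
            truth.direct_effects[geno.variants[j].variant_id] = float(e)
    y = y + rng.normal(0.0, trait_cfg.residual_sd, geno.n_individuals)
    return y, truth


def _marginal_regression(X: np.ndarray, y: np.ndarray):
    """Vectorised per-column simple linear regression of y on each column of X.

    Returns (beta, se, z, p, keep_mask); zero-variance columns are masked out.
    p is the two-sided Gaussian tail of z.
    """
    n = len(y)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", Xc, Xc)
    keep = sxx > 0
    sxx_safe = np.where(keep, sxx, 1.0)
    sxy = Xc.T @ yc
    beta = sxy / sxx_safe
    syy = float(yc @ yc)
    sse = np.maximum(syy - beta * sxy, 0.0)
    dof = max(n - 2, 1)
    se = np.sqrt(np.maximum(sse / dof, 1e-300) / sxx_safe)
    z = beta / se
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    return beta, se, z, p, keep


def scan_gwas(geno: GenotypeMatrix, trait: np.ndarray, trait_id: str) -> GwasSumstats:
    """Per-variant marginal GWAS of the trait (beta, se, z, two-sided Gaussian p)."""
    if len(trait) != geno.n_individuals:
        raise ConfigurationError("trait length != number of individuals")
    beta, se, z, p, keep = _marginal_regression(geno.dosage.astype(float), trait)
    if not keep.all():
        logger.warning(
            "scan_gwas %s: skipped %d zero-variance variants",
            trait_id,
            int((~keep).sum()),
        )
    rows = {
        "SNP": [v.variant_id for v in geno.variants],
        "CHR": [v.chromosome for v in geno.variants],
        "BP": [v.position for v in geno.variants],
        "A1": [v.effect_allele for v in geno.variants],
        "A2": [v.other_allele for v in geno.variants],
        "Z": z,
        "BETA": beta,
        "SE": se,
        "P": p,
        "N": geno.n_individuals,
    }
    df = pd.DataFrame(rows).loc[keep].reset_index(drop=True)
    return GwasSumstats(trait_id=trait_id, records=df)


def scan_cis_qtl(
    geno: GenotypeMatrix,
    layer: MolecularLayer,
    cis_window_bp: int | None = None,
) -> list[QtlSumstats]:
    """Nominal-pass cis-QTL scan: marginal beta/se/p per cis variant per feature."""
    positions = geno.positions
    out = []
    for feat in layer.features:
        if cis_window_bp is not None:
            cis = np.flatnonzero(np.abs(positions - feat.anchor_bp) <= cis_window_bp)
        else:
            cis = feat.cis_indices
        if len(cis) == 0:
            logger.warning("scan_cis_qtl: feature %s has no cis variants", feat.feature_id)
            continue
        X = geno.dosage[:, cis].astype(float)
        beta, se, z, p, keep = _marginal_regression(X, feat.phenotype)
        cis = cis[keep]
        df = pd.DataFrame(
            {
                "SNP": [geno.variants[j].variant_id for j in cis],
                "CHR": [geno.variants[j].chromosome for j in cis],
                "BP": [geno.variants[j].position for j in cis],
                "A1": [geno.variants[j].effect_allele for j in cis],
                "A2": [geno.variants[j].other_allele for j in cis],
                "BETA": beta[keep],
                "SE": se[keep],
                "P": p[keep],
            }
        )
        out.append(
            QtlSumstats(
                feature_id=feat.feature_id,
                gene_symbol=feat.gene_symbol,
                qtl_type=feat.layer_type,
                tissue_label=feat.tissue_label,
                dataset_tag=feat.dataset_tag,
                records=df,
            )
        )
    return out


def ld_reference(geno: GenotypeMatrix, indices: np.ndarray | None = None) -> LdReference:
    """Empirical genotype correlation matrix over (a subset of) the panel."""
    idx = np.arange(geno.n_variants) if indices is None else np.asarray(indices)
    X = geno.dosage[:, idx].astype(float)
    sd = X.std(axis=0)
    ok = sd > 0
    R = np.eye(len(idx))
    if ok.any():
        sub = np.corrcoef(X[:, ok], rowvar=False)
        sub = np.atleast_2d(sub)
        R[np.ix_(ok, ok)] = sub
    np.fill_diagonal(R, 1.0)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    return LdReference(variants=[geno.variants[j] for j in idx], correlation=R)


def gene_annotations(layers: list[MolecularLayer]) -> list[GeneAnnotation]:
    """One annotation per distinct gene symbol (gene body = anchor +/- 10 kb)."""
    seen: dict[str, GeneAnnotation] = {}
    for layer in layers:
        for feat in layer.features:
            if feat.gene_symbol not in seen:
                seen[feat.gene_symbol] = GeneAnnotation(
                    canonical_symbol=feat.gene_symbol,
                    aliases=frozenset(),
                    chromosome=feat.chromosome,
                    start=feat.gene_start,
                    end=feat.gene_end,
                )
    return sorted(seen.values(), key=lambda g: (g.chromosome, g.start, g.canonical_symbol))


def simulate_cohort(cfg: SimulationConfig, seed) -> dict:
    """Convenience wrapper: genotypes, layers, per-disorder traits and GWAS scans.

    Each disorder gets a current GWAS (full cohort, tag ``<DIS>_2022``) and an
    earlier, down-sampled GWAS (tag ``<DIS>_old``) used to emulate published
    (curated) analyses.
    """
    rng = _rng(seed)
    geno = simulate_genotypes(
        cfg.n_individuals,
        cfg.n_variants,
        cfg.block_size,
        cfg.within_block_r,
        cfg.maf_range,
        rng,
        spacing_bp=cfg.variant_spacing_bp,
    )
    layers, truth = simulate_molecular_layers(geno, cfg.layers, cfg.cis_window_bp, rng)
    traits = {}
    for disorder in cfg.disorders:
        # Per-disorder trait truth; the layer-level sharing/gene maps stay shared.
        dis_truth = SimTruth(
            shares_with=truth.shares_with, gene_of_feature=truth.gene_of_feature
        )
        y, dis_truth = simulate_trait(geno, layers, cfg.trait, rng, truth=dis_truth)
        n_old = int(round(cfg.old_gwas_fraction * geno.n_individuals))
        sub = rng.choice(geno.n_individuals, size=n_old, replace=False)
        geno_old = GenotypeMatrix(
            dosage=geno.dosage[sub], variants=geno.variants, ld_blocks=geno.ld_blocks
        )
        traits[disorder] = {
            "trait": y,
            "truth": dis_truth,
            "gwas": scan_gwas(geno, y, f"{disorder}_2022"),
            "gwas_old": scan_gwas(geno_old, y[sub], f"{disorder}_old"),
            "old_subset": sub,
        }
    return {"geno": geno, "layers": layers, "truth": truth, "traits": traits}
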