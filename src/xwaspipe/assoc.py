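"""Summary-based molecular association statistics.

Two tools are implemented, mirroring the two families of summary-level xWAS
methods:

* FUSION-style imputation: per-feature variant weights ``w`` (top1 or ridge,
  cross-validated) combined with GWAS z-scores and an LD reference ``R``
  through the quadratic form ``z = wᵀz_gwas / sqrt(wᵀ R_reg w)``.
* SMR: a Wald-ratio Mendelian-randomisation test using the feature's top
  cis-QTL as instrument, ``b_xy = b_zy / b_zx`` and
  ``z_smr² = z_zy² z_zx² / (z_zy² + z_zx²)`` referred to χ²(1), followed by
  the HEIDI heterogeneity test which distinguishes a single shared causal
  variant from linkage of distinct causal variants. HEIDI's null is evaluated
  by seeded Monte-Carlo sampling of the multivariate-normal difference vector
  rather than the original analytic approximation (asymptotically equivalent;
  see the methods note).

Multiple testing uses Bonferroni within a family (default: one GWAS dataset x
one QTL dataset x one tool); SMR rows are additionally retained only when
P_HEIDI exceeds the retention threshold.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

from .config import DEFAULT_BRAIN_KEYWORDS
from .simulate import FeatureSim, GenotypeMatrix, _marginal_regression
from .types import (
    ConfigurationError,
    DataError,
    GwasSumstats,
    LdReference,
    QtlSumstats,
    TissueGroup,
    Tool,
    WeightModel,
    XwasResult,
)

logger = logging.getLogger(__name__)


def tissue_group_of(
    tissue_label: str, brain_keywords: list[str] | None = None
) -> TissueGroup:
    """Collapse a free-text tissue label to the brain / non-brain dichotomy."""
    keywords = brain_keywords if brain_keywords is not None else DEFAULT_BRAIN_KEYWORDS
    label = tissue_label.lower()
    if any(k.lower() in label for k in keywords):
        return TissueGroup.BRAIN
    return TissueGroup.NON_BRAIN


class NonPositiveVarianceError(DataError):
    """wᵀRw remained non-positive after LD regularization."""


class UntrainableFeatureError(DataError):
    """Every cis variant of the feature has zero variance."""


# ---------------------------------------------------------------------------
# Weight training (FUSION-style reference weights)
# ---------------------------------------------------------------------------


def _fit_weights(X: np.ndarray, y: np.ndarray, model: str, ridge_penalty: float):
    """Weights on standardized dosage columns for one training split."""
    if model == "top1":
        _, _, _, p, keep = _marginal_regression(X, y)
        p = np.where(keep, p, np.inf)
        w = np.zeros(X.shape[1])
        w[int(np.argmin(p))] = 1.0
        return w
    if model == "ridge":
        reg = Ridge(alpha=ridge_penalty, fit_intercept=True)
        reg.fit(X, y)
        return reg.coef_
    raise ConfigurationError(f"unknown weight model {model!r}")


def _cv_r2(
    X: np.ndarray,
    y: np.ndarray,
    model: str,
    cv_folds: int,
    ridge_penalty: float,
    seed: int,
) -> float:
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    pred = np.zeros_like(y, dtype=float)
    for train, test in kf.split(X):
        w = _fit_weights(X[train], y[train], model, ridge_penalty)
        pred[test] = X[test] @ w
    if pred.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(pred, y)[0, 1] ** 2)


def train_weights(
    geno: GenotypeMatrix,
    feature: FeatureSim,
    model: str = "ridge",
    cv_folds: int = 5,
    ridge_penalty: float = 1.0,
    seed: int = 0,
) -> WeightModel:
    """Train per-feature variant weights on the reference panel.

    ``model`` is "top1" (unit weight on the cis variant with minimum marginal
    p), "ridge" (penalized multivariate regression on standardized dosages),
    or "best" (both trained, higher cross-validated R² wins). ``cv_r2`` is the
    cross-validated squared correlation between predicted and observed
    molecular phenotype.
    """
    if cv_folds < 2:
        raise ConfigurationError("cv_folds must be >= 2")
    cis = np.asarray(feature.cis_indices)
    if len(cis) == 0:
        raise UntrainableFeatureError(f"{feature.feature_id}: no cis variants")
    X = geno.dosage[:, cis].astype(float)
    sd = X.std(axis=0)
    ok = sd > 0
    if not ok.any():
        raise UntrainableFeatureError(
            f"{feature.feature_id}: all cis variants have zero variance"
        )
    cis = cis[ok]
    X = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
    y = feature.phenotype

    candidates = ["top1", "ridge"] if model == "best" else [model]
    scored = [
        (m, _cv_r2(X, y, m, cv_folds, ridge_penalty, seed)) for m in candidates
    ]
    tag, r2 = max(scored, key=lambda t: t[1])
    w = _fit_weights(X, y, tag, ridge_penalty)
    if not np.any(w != 0):  # ridge can zero out under extreme penalty
        w = _fit_weights(X, y, "top1", ridge_penalty)
        tag = "top1"
    weights = {
        geno.variants[j].variant_id: float(w[k])
        for k, j in enumerate(cis)
        if w[k] != 0.0
    }
    return WeightModel(
        feature_id=feature.feature_id,
        gene_symbol=feature.gene_symbol,
        qtl_type=feature.layer_type,
        tissue_label=feature.tissue_label,
        weights=weights,
        model_tag=tag,
        cv_r2=r2,
    )


# ---------------------------------------------------------------------------
# FUSION-style association
# ---------------------------------------------------------------------------


def _regularize(R: np.ndarray, lam: float = 0.1) -> np.ndarray:
    """Blend toward the identity when R is not PSD: R_reg = (1-λ)R + λI."""
    eigmin = float(np.linalg.eigvalsh(R).min())
    if eigmin < -1e-8:
        return (1.0 - lam) * R + lam * np.eye(len(R))
    return R


def twas_association(
    model: WeightModel,
    gwas: GwasSumstats,
    ld: LdReference,
    gwas_dataset: str | None = None,
    qtl_dataset: str = "",
    brain_keywords: list[str] | None = None,
) -> XwasResult:
    """Impute the feature-trait association from weights, GWAS z and LD.

    ``z = wᵀz / sqrt(wᵀ R_reg w)``, two-sided p from the standard normal. The
    statistic is invariant to rescaling all weights by a positive constant and
    antisymmetric under ``w -> -w``.
    """
    ids = list(model.weights.keys())
    gwas_z = gwas.records.set_index("SNP")["Z"]
    missing = [i for i in ids if i not in gwas_z.index]
    if missing:
        raise DataError(
            f"{model.feature_id}: weighted variants absent from GWAS: {missing[:3]}"
        )
    ld_ids = set(ld.variant_ids)
    missing_ld = [i for i in ids if i not in ld_ids]
    if missing_ld:
        raise DataError(
            f"{model.feature_id}: weighted variants absent from LD: {missing_ld[:3]}"
        )
    w = np.array([model.weights[i] for i in ids])
    z = gwas_z.loc[ids].to_numpy(float)
    R = _regularize(ld.submatrix(ids))
    qform = float(w @ R @ w)
    if qform <= 0:
        qform = float(w @ _regularize(R, 1.0) @ w)  # pure identity fallback
        if qform <= 0:
            raise NonPositiveVarianceError(
                f"{model.feature_id}: non-positive imputation variance"
            )
    z_stat = float(w @ z) / np.sqrt(qform)
    p = float(np.clip(2.0 * stats.norm.sf(abs(z_stat)), np.finfo(float).tiny, 1.0))
    return XwasResult(
        gene_symbol=model.gene_symbol,
        feature_id=model.feature_id,
        qtl_type=model.qtl_type,
        tissue_label=model.tissue_label,
        tissue_group=tissue_group_of(model.tissue_label, brain_keywords),
        tool=Tool.FUSION,
        gwas_dataset=gwas_dataset or gwas.trait_id,
        qtl_dataset=qtl_dataset,
        z_stat=z_stat,
        p_value=p,
    )


# ---------------------------------------------------------------------------
# SMR / HEIDI
# ---------------------------------------------------------------------------


def _merge_qtl_gwas(feature_qtl: QtlSumstats, gwas: GwasSumstats) -> pd.DataFrame:
    """Inner-join cis-QTL and GWAS rows on SNP, flipping GWAS effects when the
    effect/other alleles are swapped relative to the QTL orientation."""
    q = feature_qtl.records.rename(
        columns={"BETA": "b_zx", "SE": "se_zx", "P": "p_zx"}
    )[["SNP", "CHR", "BP", "A1", "A2", "b_zx", "se_zx", "p_zx"]]
    g = gwas.records.rename(
        columns={"A1": "GA1", "A2": "GA2", "BETA": "b_zy", "SE": "se_zy", "Z": "z_zy"}
    )[["SNP", "GA1", "GA2", "b_zy", "se_zy", "z_zy"]]
    m = q.merge(g, on="SNP", how="inner")
    if m.empty:
        return m
    swapped = (m["GA1"] == m["A2"]) & (m["GA2"] == m["A1"])
    matched = swapped | ((m["GA1"] == m["A1"]) & (m["GA2"] == m["A2"]))
    m = m[matched].copy()
    flip = swapped[matched]
    m.loc[flip, "z_zy"] = -m.loc[flip, "z_zy"]
    m.loc[flip, "b_zy"] = -m.loc[flip, "b_zy"]
    # GWAS published z only: fall back to the standardized scale (beta=z, se=1).
    no_bse = m["b_zy"].isna() | m["se_zy"].isna()
    m.loc[no_bse, "b_zy"] = m.loc[no_bse, "z_zy"]
    m.loc[no_bse, "se_zy"] = 1.0
    return m.drop(columns=["GA1", "GA2"])


def smr_test(
    feature_qtl: QtlSumstats,
    gwas: GwasSumstats,
    instrument_p_threshold: float = 5e-8,
    gwas_dataset: str | None = None,
    brain_keywords: list[str] | None = None,
) -> XwasResult | None:
    """Wald-ratio SMR test with the top cis-QTL as instrument.

    Returns None (feature skipped) when no cis variant reaches the instrument
    threshold; raises on a zero QTL effect at the instrument.
    """
    m = _merge_qtl_gwas(feature_qtl, gwas)
    if m.empty or float(m["p_zx"].min()) >= instrument_p_threshold:
        logger.info("smr %s: no instrument", feature_qtl.feature_id)
        return None
    top = m.loc[m["p_zx"].idxmin()]
    b_zx, se_zx = float(top["b_zx"]), float(top["se_zx"])
    b_zy, se_zy = float(top["b_zy"]), float(top["se_zy"])
    if b_zx == 0:
        raise DataError(f"{feature_qtl.feature_id}: zero QTL effect at instrument")
    z_zx = b_zx / se_zx
    z_zy = b_zy / se_zy
    b_xy = b_zy / b_zx
    z2 = (z_zy**2 * z_zx**2) / (z_zy**2 + z_zx**2)
    p = float(np.clip(stats.chi2.sf(z2, df=1), np.finfo(float).tiny, 1.0))
    z_stat = float(np.sign(b_xy) * np.sqrt(z2))
    return XwasResult(
        gene_symbol=feature_qtl.gene_symbol,
        feature_id=feature_qtl.feature_id,
        qtl_type=feature_qtl.qtl_type,
        tissue_label=feature_qtl.tissue_label,
        tissue_group=tissue_group_of(feature_qtl.tissue_label, brain_keywords),
        tool=Tool.SMR,
        gwas_dataset=gwas_dataset or gwas.trait_id,
        qtl_dataset=feature_qtl.dataset_tag,
        z_stat=z_stat,
        p_value=p,
        b_xy_hat=float(b_xy),
    )


@dataclass
class HeidiParams:
    min_snps: int = 3
    max_snps: int = 20
    r2_prune_high: float = 0.9
    r2_min: float = 0.05
    snp_p_zx_threshold: float = 1.57e-3  # chi2(1) > 10
    n_draws: int = 10_000


def heidi_test(
    feature_qtl: QtlSumstats,
    gwas: GwasSumstats,
    ld: LdReference,
    params: HeidiParams | None = None,
    seed: int = 0,
) -> tuple[float | None, int]:
    """HEIDI heterogeneity test around the SMR instrument.

    For each eligible non-instrument cis SNP i, ``d_i = b_xy(i) - b_xy(top)``;
    the joint null of the d-vector is multivariate normal with covariance from
    LD and the per-SNP standard errors (delta method on both Wald ratios).
    The p-value is the Monte-Carlo exceedance probability of
    ``Σ (d_i / se(d_i))²`` under that null. Returns (p_heidi, n_snps_used);
    p_heidi is None when fewer than ``min_snps`` SNPs are eligible.
    """
    params = params or HeidiParams()
    rng = np.random.default_rng(seed)
    m = _merge_qtl_gwas(feature_qtl, gwas)
    ld_ids = set(ld.variant_ids)
    m = m[m["SNP"].isin(ld_ids)].reset_index(drop=True)
    if m.empty:
        return None, 0
    top_i = int(m["p_zx"].idxmin())
    ids = m["SNP"].tolist()
    R = ld.submatrix(ids)
    r_top = R[:, top_i]
    eligible = (
        (m["p_zx"].to_numpy() < params.snp_p_zx_threshold)
        & (r_top**2 >= params.r2_min)
        & (r_top**2 <= params.r2_prune_high)
    )
    eligible[top_i] = False
    cand = np.flatnonzero(eligible)
    cand = cand[np.argsort(m["p_zx"].to_numpy()[cand], kind="stable")]
    # prune mutually near-collinear SNPs, keeping the smaller p_zx
    selected: list[int] = []
    for i in cand:
        if all(R[i, j] ** 2 <= params.r2_prune_high for j in selected):
            selected.append(int(i))
        if len(selected) >= params.max_snps:
            break
    if len(selected) < params.min_snps:
        return None, len(selected)

    order = selected + [top_i]
    b_zx = m["b_zx"].to_numpy(float)[order]
    se_zx = m["se_zx"].to_numpy(float)[order]
    b_zy = m["b_zy"].to_numpy(float)[order]
    se_zy = m["se_zy"].to_numpy(float)[order]
    Rs = R[np.ix_(order, order)]
    b_xy = b_zy / b_zx
    # Delta-method covariance of the Wald ratios; GWAS and QTL samples are
    # independent, each contributing an LD-structured term.
    cov_zy = Rs * np.outer(se_zy, se_zy)
    cov_zx = Rs * np.outer(se_zx, se_zx)
    inv_bzx = 1.0 / b_zx
    C = cov_zy * np.outer(inv_bzx, inv_bzx) + cov_zx * np.outer(
        b_zy * inv_bzx**2, b_zy * inv_bzx**2
    )
    k = len(selected)
    V = C[:k, :k] - C[:k, [k]] - C[[k], :k] + C[k, k]
    se_d = np.sqrt(np.maximum(np.diag(V), 1e-300))
    d = b_xy[:k] - b_xy[k]
    obs = float(np.sum((d / se_d) ** 2))

    jitter = 1e-10 * float(np.mean(np.diag(V)))
    for _ in range(6):
        try:
            L = np.linalg.cholesky(V + jitter * np.eye(k))
            break
        except np.linalg.LinAlgError:
            jitter *= 100.0
    else:  # pragma: no cover - pathological covariance
        return None, k
    draws = rng.standard_normal((params.n_draws, k)) @ L.T
    sims = np.sum((draws / se_d) ** 2, axis=1)
    p = (1.0 + float(np.sum(sims >= obs))) / (params.n_draws + 1.0)
    return float(p), k


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------


def bonferroni_filter(
    results: list[XwasResult],
    alpha: float = 0.05,
    family_key=None,
    heidi_retain_threshold: float = 0.05,
) -> list[XwasResult]:
    """Set ``passes_correction`` by Bonferroni within each test family.

    The default family is one GWAS dataset x one QTL dataset x one tool; SMR
    rows with an evaluated HEIDI p are retained only when it exceeds
    ``heidi_retain_threshold``.
    """
    if not results:
        raise ConfigurationError("bonferroni_filter: empty result list")
    if not (0.0 < alpha < 1.0):
        raise ConfigurationError("alpha must lie in (0,1)")
    key = family_key or (lambda r: (r.gwas_dataset, r.qtl_dataset, r.tool))
    families: dict[tuple, list[XwasResult]] = defaultdict(list)
    for r in results:
        families[key(r)].append(r)
    for fam in families.values():
        cutoff = alpha / len(fam)
        for r in fam:
            ok = r.p_value < cutoff
            if r.tool is Tool.SMR and r.p_heidi is not None:
                ok = ok and (r.p_heidi > heidi_retain_threshold)
            r.passes_correction = bool(ok)
    logger.info(
        "bonferroni: %d results in %d families, %d pass",
        len(results),
        len(families),
        sum(r.passes_correction for r in results),
    )
    return results


def results_to_frame(results: list[XwasResult]) -> pd.DataFrame:
    rows = [
        {
            "GENE": r.gene_symbol,
            "FEATURE": r.feature_id,
            "QTL_TYPE": r.qtl_type.value,
            "TISSUE": r.tissue_label,
            "TISSUE_GROUP": r.tissue_group.value,
            "TOOL": r.tool.value,
            "GWAS_DATASET": r.gwas_dataset,
            "QTL_DATASET": r.qtl_dataset,
            "Z": r.z_stat,
            "P": r.p_value,
            "B_XY": r.b_xy_hat if r.b_xy_hat is not None else np.nan,
            "P_HEIDI": r.p_heidi if r.p_heidi is not None else np.nan,
            "N_SNPS_HEIDI": r.n_snps_heidi if r.n_snps_heidi is not None else -1,
            "PASS": r.passes_correction,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
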