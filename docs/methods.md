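# Methods

## Scope and model

`xwaspipe` integrates five molecular QTL layers (eQTL, sQTL, pQTL, mQTL,
m6AQTL) with complex-trait GWAS summary statistics. The causal model assumed
throughout is the standard instrumental/mediation picture: cis variants
perturb a molecular phenotype *x* (effect b_zx), *x* may affect the trait *y*
(effect b_xy), and variants may additionally affect *y* directly. All
statistics consume only summary-level quantities (z, beta, se, p) plus an LD
reference.

### FUSION-style association

Per-feature weights are trained on a reference panel with individual-level
genotypes and molecular phenotypes:

* `top1` — unit weight on the cis variant with minimum marginal p;
* `ridge` — penalized regression on standardized dosages (scikit-learn
  Ridge, default penalty 1.0);
* `best` — both, keeping the model with higher K-fold cross-validated R²
  (squared correlation of out-of-fold prediction with the phenotype).

The trait association is the quadratic-form z-score
`z = wᵀz_gwas / sqrt(wᵀ R_reg w)` with two-sided Gaussian p. When the
empirical LD matrix is not positive semi-definite (eigenvalue < −1e−8) or
the variance form is non-positive, it is blended toward the identity,
`R_reg = 0.9 R + 0.1 I`; the statistic is invariant to positive rescaling of
*w* and antisymmetric in its sign.

### SMR and HEIDI

SMR uses the minimum-p cis variant with p_zx < 5e−8 as instrument and
reports the Wald ratio `b̂_xy = b_zy/b_zx` with
`z²_SMR = z²_zy z²_zx / (z²_zy + z²_zx)` referred to χ²(1). When a GWAS
publishes only z, the standardized scale (beta = z, se = 1) is used; the
ratio and χ² are scale-free in that case.

HEIDI selects non-instrument cis SNPs with p_zx < 1.57e−3 (χ²₁ > 10) whose
r² with the instrument lies in [0.05, 0.9], greedily prunes mutual r² > 0.9
keeping smaller p_zx, and uses between 3 and 20 SNPs (fewer → the feature is
flagged "HEIDI not evaluable" rather than given a p). For each selected SNP,
`d_i = b̂_xy(i) − b̂_xy(top)`; the covariance of the d-vector follows the
delta method applied to both Wald ratios, with the GWAS and QTL samples
independent and each contributing an LD-structured term
(`cov(b_i, b_j) = r_ij se_i se_j`). The p-value of Σ(d_i/se(d_i))² is the
exceedance fraction over 10,000 seeded Monte-Carlo draws from MVN(0, V)
(with escalating diagonal jitter if V is numerically non-PSD). This replaces
the original analytic Satterthwaite-style approximation with an
asymptotically equivalent sampling evaluation — simpler to audit and to
seed. The `+1` numerator/denominator correction keeps p in (0, 1].

### Multiple testing and filters

Bonferroni is applied within a family — by default one GWAS dataset × one
QTL panel × one tool (the family is configurable; a global or per-chromosome
family would also be defensible). SMR rows with an evaluated HEIDI p are
retained only when P_HEIDI > 0.05. The extended MHC interval
(chr6:28477797–33448354, 1-based closed, configurable) is removed from GWAS
and QTL records before association.

### Evidence dictionary, reliable and novel genes

Evidence lines are the five-field key `GWAS dataset — QTL type — tissue
group — tool — gene`. Tissue labels collapse to brain/non-brain via a
configurable keyword list *before* keying, and the QTL panel name is
deliberately **not** part of the key: two panels with the same tissue group
and tool contribute one line. This is consequential and easy to misread —
support counts are counts of distinct keys, not of analyses. Gene symbols
are normalized through an alias table (exact, then case- and
hyphen/underscore-insensitive lookup; unmapped symbols pass through and are
reported). The shipped table (`data/synthetic_hgnc_aliases.tsv`) is a small
synthetic fixture in HGNC style, not a copy of the live nomenclature
service.

A gene is *reliable* at ≥ 2 distinct lines. Source groups: CG (curated,
published-style) and SG (supplementary, re-analysed). The "Total" reliable
set pools CG+SG lines, deduplicates on the five-field key, then thresholds;
the union of per-source reliable sets is reported alongside for
reconciliation, since pooling can promote genes that neither source reaches
alone.

*Novelty*: window = gene body ± 1 Mb (strand-free, closed at both edges,
clamped at 1); a gene is novel iff the minimum GWAS p in the window is
strictly greater than 5e−8. Genes with empty windows or missing coordinates
are reported unclassifiable, never dropped.

### Replication metrics and MMRP

Directed replication ratio (A, B) = |A∩B| / |A| (the size of A is the
denominator); counts are symmetric, ratios are not; empty A gives a missing
ratio. Novel vs non-novel support counts are compared by a two-sided
Mann-Whitney rank-sum test (normal approximation, tie-corrected) — the
choice of test is this package's own; single-member groups are flagged
degenerate. An MMRP is the exact set of ≥ 2 QTL types in a gene's evidence
profile for one disorder; each gene belongs to exactly one pattern (its full
profile), so pattern gene counts partition the multi-QTL genes.

## Synthetic cohorts

The generator emulates the statistical structure the integration assumes:

* **Genotypes** — diploid 0/1/2 dosages from two thresholded AR(1) latent
  Gaussian haplotype chains restarting at block boundaries (default blocks
  of 20 variants, latent r = 0.6, MAF ~ U(0.05, 0.5), 10 kb spacing).
  Within-block LD decays with distance; blocks are independent.
* **Molecular layers** — each feature gets an anchor variant, a ±500 kb cis
  window, 1 causal cis variant with effect ~ N(0, 0.6²) and unit residual
  noise. A fraction (default 0.4) of features in non-expression layers
  reuses the causal variants *and* gene symbol of a random expression
  feature — the minimal structure making cross-QTL replication and MMRP
  non-degenerate. m6A features are assigned a host gene directly.
* **Traits** — quantitative only (case-control GWAS are emulated on the
  liability scale since every downstream statistic consumes z/beta/se):
  y = Σ b_xy·x + Σ direct dosage effects + noise, with 20% of features
  mediated (b_xy ~ N(0, 0.3²)), 10 direct variants (N(0, 0.15²)) and unit
  residual. Two synthetic disorders (labelled SCZ, BP) are generated per
  run; each also gets an "earlier" GWAS on a 60% subsample whose retained
  hits are tagged CG, emulating published studies on older releases.
* **Scans** — GWAS and nominal-pass cis-QTL scans are vectorized marginal
  regressions with Gaussian two-sided p; zero-variance variants are skipped
  with a warning.

Deliberately absent: population structure, relatedness, imputation noise,
sex chromosomes, realistic effect-size spectra, allele-frequency-dependent
architectures. Passing tests therefore demonstrate correctness of the
statistics and the integration logic under idealized LD and Gaussian noise,
not robustness to the confounding of real cohorts.

## Calibration experiments (problem sizes)

`xwaspipe.calibration` fixes the study conditions used by the tests and the
acceptance script:

* null calibration — 2,000 features on independent 50-variant regions,
  n = 2,000 individuals, null trait; type-I error of SMR (over features with
  an instrument) and the FUSION-style test at α = 0.05;
* HEIDI retention — single shared causal variant (|effect| = 0.9, b_xy =
  0.3, latent r = 0.75 so ≥ 3 eligible SNPs usually exist), simulated until
  200 evaluable features;
* recovery — b_xy = 0.3, n = 5,000, 200 replicates (mean Wald ratio), and
  100 matched-noise replicates across b_xy ∈ {0, 0.1, 0.2, 0.3} for
  monotonicity of median χ²;
* MMRP experiment — full pipeline on 310 features with 40% sharing;
  partition property plus the Haldane-corrected odds ratio for
  shared-construction genes to appear in MMRP sets;
* determinism — two full runs at reduced scale compared byte-for-byte on
  the reliable-gene, novelty and MMRP tables.

Each experiment draws from a named substream of the master seed
(`crc32(name) XOR seed`), so stages and experiments are independently
reproducible and adding one never perturbs another.

## Numerical choices and degenerate inputs

* Two-sided p-values come from the Gaussian tail of beta/se (no t
  correction; cohort sizes here make the difference negligible) and are
  clipped away from exact 0/1.
* Marginal-regression SSE is floored at 0 and σ² at 1e−300 to keep the
  noise-free identity cases finite.
* Harmonization matches variants by id, flips z/beta when effect/other
  alleles are swapped, drops strand-ambiguous (A/T, C/G) variants — no
  frequency-based resolution is attempted — and errors on empty overlap.
  |z| is never altered.
* Coordinates are 1-based closed everywhere; the only 0-based field is the
  BED-style START column on disk, converted on read. Genome build is
  opaque; the MHC constant is configurable.
* Ties: top1 weight and the SMR instrument take the first minimum-p variant
  in panel order; HEIDI pruning is stable-sorted by p_zx.

## Known limitations

* The Bonferroni family convention (per GWAS × panel × tool) changes what
  "significant" means; alternatives are one config switch away but results
  are not invariant to the choice.
* HEIDI's Monte-Carlo p has resolution 1/10,001 per evaluation; far tails
  are not distinguished.
* The CG/SG distinction in synthetic runs comes from one down-sampled GWAS
  re-analysis, a thinner notion of "published literature" than real curation.
* Default cohort sizes favour fast, deterministic runs; power at n = 2,000
  with 1,200 variants yields small gene sets, which is intended for
  auditability rather than realism.
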