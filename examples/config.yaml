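# Fully commented example configuration for `xwaspipe run --config ...`.
# Every key is optional; omitted keys take the defaults shown here.

# Master seed. Each pipeline stage derives a named substream from it, so
# stages are independently reproducible.
seed: 1

# Extended MHC interval excluded before association (chromosome, start, end;
# 1-based closed). The long-range LD of this region produces spurious hits.
mhc_region: ["6", 28477797, 33448354]

# Bonferroni level applied within each GWAS-dataset x QTL-panel x tool family.
bonferroni_alpha: 0.05

# SMR hits are kept only when P_HEIDI exceeds this (heterogeneity filter).
heidi_retain_threshold: 0.05

# A reliable gene is novel when the minimum GWAS p in its window is strictly
# greater than this genome-wide threshold.
novelty_threshold: 5.0e-8

# Minimum number of distinct evidence lines for a gene to be "reliable".
reliable_min_count: 2

# Novelty window: bp added upstream and downstream of the gene body.
window_bp: 1000000

# Minimum cis-QTL p for a variant to serve as the SMR instrument.
instrument_p_threshold: 5.0e-8

# Substrings (case-insensitive) marking a tissue label as brain.
brain_keywords: [brain, cortex, dlpfc, cerebellum, hippocampus, frontal,
                 psychencode, cmc]

simulation:
  n_individuals: 2000        # cohort size for genotypes, layers and traits
  n_variants: 1200           # variant panel size
  block_size: 20             # variants per LD block
  within_block_r: 0.6        # latent AR(1) correlation inside a block
  maf_range: [0.05, 0.5]     # minor-allele frequencies drawn uniformly
  variant_spacing_bp: 10000  # physical spacing between adjacent variants
  cis_window_bp: 500000      # cis window around each feature's anchor

  # One entry per molecular layer. sharing_fraction is the probability that
  # a non-expression feature reuses an expression feature's causal variants
  # and gene symbol (what makes cross-QTL replication non-trivial).
  layers:
    eQTL:   {n_features: 60, tissue_label: brain_cortex}
    sQTL:   {n_features: 30, sharing_fraction: 0.4, tissue_label: brain_dlpfc}
    pQTL:   {n_features: 20, sharing_fraction: 0.4, tissue_label: brain_rosmap}
    mQTL:   {n_features: 30, sharing_fraction: 0.4, tissue_label: blood}
    m6AQTL: {n_features: 15, sharing_fraction: 0.4, tissue_label: brain_m6a}

  trait:
    mediated_fraction: 0.2   # fraction of features with a trait effect
    bxy_sd: 0.3              # s.d. of mediated effects b_xy
    n_direct: 10             # variants with direct (non-mediated) effects
    direct_sd: 0.15          # s.d. of direct effects
    residual_sd: 1.0         # trait residual noise

  # Synthetic disorder labels; each gets a current GWAS (<NAME>_2022) and an
  # earlier down-sampled GWAS (<NAME>_old) whose hits are tagged CG.
  disorders: [SCZ, BP]
  old_gwas_fraction: 0.6     # fraction of the cohort in the earlier GWAS
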