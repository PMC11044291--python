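import numpy as np
import pandas as pd
import pytest

from xwaspipe.simulate import simulate_genotypes, simulate_molecular_layers
from xwaspipe.config import LayerConfig
from xwaspipe.types import GwasSumstats, QtlSumstats, VariantRecord


def gwas_frame(rows: list[dict]) -> pd.DataFrame:
    """Build a canonical GWAS records frame from terse row dicts."""
    base = {
        "SNP": "rs1",
        "CHR": "1",
        "BP": 1000,
        "A1": "A",
        "A2": "G",
        "Z": 0.0,
        "BETA": np.nan,
        "SE": np.nan,
        "P": 0.5,
        "N": 1000,
    }
    return pd.DataFrame([{**base, **r} for r in rows])


def qtl_frame(rows: list[dict]) -> pd.DataFrame:
    base = {
        "SNP": "rs1",
        "CHR": "1",
        "BP": 1000,
        "A1": "A",
        "A2": "G",
        "BETA": 0.1,
        "SE": 0.05,
        "P": 0.05,
    }
    return pd.DataFrame([{**base, **r} for r in rows])


def make_qtl(rows, feature_id="F1", gene="GENE1", qtl_type="eQTL",
             tissue="brain_cortex", dataset="PANEL") -> QtlSumstats:
    return QtlSumstats(
        feature_id=feature_id,
        gene_symbol=gene,
        qtl_type=qtl_type,
        tissue_label=tissue,
        dataset_tag=dataset,
        records=qtl_frame(rows),
    )


def make_gwas(rows, trait_id="SCZ_2022") -> GwasSumstats:
    return GwasSumstats(trait_id=trait_id, records=gwas_frame(rows))


def variant(vid="rs1", chrom="1", bp=1000, a1="A", a2="G") -> VariantRecord:
    return VariantRecord(
        variant_id=vid, chromosome=chrom, position=bp,
        effect_allele=a1, other_allele=a2,
    )


@pytest.fixture(scope="session")
def small_geno():
    return simulate_genotypes(
        n_individuals=500,
        n_variants=60,
        block_size=20,
        within_block_r=0.6,
        maf_range=(0.1, 0.5),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_layers(small_geno):
    specs = {
        "eQTL": LayerConfig(n_features=8, tissue_label="brain_cortex"),
        "sQTL": LayerConfig(n_features=5, sharing_fraction=0.5, tissue_label="brain_dlpfc"),
    }
    return simulate_molecular_layers(small_geno, specs, cis_window_bp=200_000, seed=11)
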