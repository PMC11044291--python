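"""Core domain types shared by every pipeline stage.

Tabular payloads (per-variant and per-record data) live in pandas DataFrames
with canonical column names; the dataclasses here carry identity, metadata and
validated invariants. Coordinates are 1-based, fully closed intervals
throughout; the only 0-based field is the START column of BED-like annotation
files, converted on read.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """A parameter or required column is missing or out of range."""


class DataError(ValueError):
    """Input rows violate an invariant (duplicates, bad alleles, ...)."""


class QtlType(str, enum.Enum):
    """The five molecular layers integrated by the pipeline."""

    EQTL = "eQTL"
    SQTL = "sQTL"
    PQTL = "pQTL"
    MQTL = "mQTL"
    M6AQTL = "m6AQTL"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Tool(str, enum.Enum):
    FUSION = "FUSION"
    SMR = "SMR"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class TissueGroup(str, enum.Enum):
    BRAIN = "brain"
    NON_BRAIN = "non-brain"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class SourceGroup(str, enum.Enum):
    """Curated (published) vs supplementary (re-analysed) evidence."""

    CG = "CG"
    SG = "SG"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_NUCLEOTIDES = frozenset("ACGT")
STRAND_AMBIGUOUS_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})


@dataclass(frozen=True)
class VariantRecord:
    """One bi-allelic variant; `effect_allele` is the allele the z/beta refers to."""

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    effect_allele_frequency: float | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise DataError(f"{self.variant_id}: position must be >= 1")
        for allele in (self.effect_allele, self.other_allele):
            if allele not in _NUCLEOTIDES:
                raise DataError(f"{self.variant_id}: invalid allele {allele!r}")
        if self.effect_allele == self.other_allele:
            raise DataError(f"{self.variant_id}: effect and other allele identical")
        if self.effect_allele_frequency is not None and not (
            0.0 < self.effect_allele_frequency < 1.0
        ):
            raise DataError(f"{self.variant_id}: EAF outside (0,1)")

    @property
    def is_strand_ambiguous(self) -> bool:
        return (self.effect_allele, self.other_allele) in STRAND_AMBIGUOUS_PAIRS


# Canonical column sets for the tabular containers.
GWAS_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "Z", "BETA", "SE", "P", "N"]
QTL_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P"]


def _check_variant_table(df: pd.DataFrame, label: str) -> None:
    if df["SNP"].duplicated().any():
        dup = df.loc[df["SNP"].duplicated(), "SNP"].iloc[0]
        raise DataError(f"{label}: duplicate variant_id {dup!r}")
    if (df["BP"] < 1).any():
        bad = df.loc[df["BP"] < 1, "SNP"].iloc[0]
        raise DataError(f"{label}: position < 1 for {bad!r}")
    same = df["A1"].astype(str) == df["A2"].astype(str)
    if same.any():
        bad = df.loc[same, "SNP"].iloc[0]
        raise DataError(f"{label}: identical alleles for {bad!r}")


@dataclass
class GwasSumstats:
    """Per-variant marginal trait associations (one GWAS summary dataset).

    `records` columns: SNP, CHR, BP, A1, A2, Z, BETA, SE, P, N. BETA/SE may be
    NaN when only Z was published; when both are present Z must equal BETA/SE.
    """

    trait_id: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in GWAS_COLUMNS if c not in self.records.columns]
        if missing:
            raise ConfigurationError(f"GWAS table missing columns {missing}")
        df = self.records.reset_index(drop=True)
        _check_variant_table(df, f"GWAS {self.trait_id}")
        p = df["P"].to_numpy(float)
        if ((p <= 0) | (p > 1)).any():
            raise DataError(f"GWAS {self.trait_id}: p outside (0,1]")
        has_bse = df["BETA"].notna() & df["SE"].notna()
        if has_bse.any():
            z = df.loc[has_bse, "Z"].to_numpy(float)
            ratio = df.loc[has_bse, "BETA"].to_numpy(float) / df.loc[
                has_bse, "SE"
            ].to_numpy(float)
            tol = 1e-6 * np.maximum(1.0, np.abs(z))
            if (np.abs(z - ratio) > tol).any():
                bad = df.loc[has_bse].loc[np.abs(z - ratio) > tol, "SNP"].iloc[0]
                raise DataError(f"GWAS {self.trait_id}: Z != BETA/SE for {bad!r}")
        self.records = df

    @property
    def n_variants(self) -> int:
        return len(self.records)


@dataclass
class QtlSumstats:
    """Cis associations of one molecular feature (b_zx, se_zx, p_zx per variant)."""

    feature_id: str
    gene_symbol: str
    qtl_type: QtlType
    tissue_label: str
    dataset_tag: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        self.qtl_type = QtlType(self.qtl_type)
        missing = [c for c in QTL_COLUMNS if c not in self.records.columns]
        if missing:
            raise ConfigurationError(f"QTL table missing columns {missing}")
        df = self.records.reset_index(drop=True)
        _check_variant_table(df, f"QTL {self.feature_id}")
        if (df["SE"].to_numpy(float) <= 0).any():
            raise DataError(f"QTL {self.feature_id}: non-positive SE")
        self.records = df


@dataclass
class GeneAnnotation:
    """Gene body coordinates plus symbol aliases (1-based closed interval)."""

    canonical_symbol: str
    aliases: frozenset[str]
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.canonical_symbol:
            raise DataError("empty canonical symbol")
        if self.start < 1 or self.end < self.start:
            raise DataError(f"{self.canonical_symbol}: bad interval")
        self.aliases = frozenset(self.aliases)


@dataclass
class LdReference:
    """Pairwise genotype correlations over an ordered variant panel."""

    variants: list[VariantRecord]
    correlation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.correlation, float)
        m = len(self.variants)
        if R.shape != (m, m):
            raise DataError("LD matrix dimension does not match variant count")
        if not np.allclose(R, R.T, atol=1e-8):
            raise DataError("LD matrix not symmetric")
        if np.abs(R).max() > 1 + 1e-8 or not np.allclose(np.diag(R), 1.0, atol=1e-6):
            raise DataError("LD entries outside [-1,1] or non-unit diagonal")
        self.correlation = R

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def submatrix(self, ids: list[str]) -> np.ndarray:
        index = {v: i for i, v in enumerate(self.variant_ids)}
        idx = [index[i] for i in ids]
        return self.correlation[np.ix_(idx, idx)]


@dataclass
class WeightModel:
    """Per-feature variant weights for summary-based imputation."""

    feature_id: str
    gene_symbol: str
    qtl_type: QtlType
    tissue_label: str
    weights: dict[str, float]
    model_tag: str  # "top1" or "ridge"
    cv_r2: float

    def __post_init__(self) -> None:
        self.qtl_type = QtlType(self.qtl_type)
        if not any(w != 0.0 for w in self.weights.values()):
            raise DataError(f"{self.feature_id}: all weights zero")


@dataclass
class XwasResult:
    """One feature x tool association against one GWAS dataset."""

    gene_symbol: str
    feature_id: str
    qtl_type: QtlType
    tissue_label: str
    tissue_group: TissueGroup
    tool: Tool
    gwas_dataset: str
    qtl_dataset: str
    z_stat: float
    p_value: float
    b_xy_hat: float | None = None
    p_heidi: float | None = None
    n_snps_heidi: int | None = None
    passes_correction: bool = False

    def __post_init__(self) -> None:
        self.qtl_type = QtlType(self.qtl_type)
        self.tool = Tool(self.tool)
        self.tissue_group = TissueGroup(self.tissue_group)
        if (self.b_xy_hat is not None) != (self.tool is Tool.SMR):
            raise DataError("b_xy_hat present iff tool is SMR")


@dataclass(frozen=True)
class EvidenceLine:
    """One record of the dictionary 'GWAS dataset—xQTL type—tissue—tool—gene'."""

    gwas_dataset: str
    qtl_type: QtlType
    tissue_group: TissueGroup
    tool: Tool
    gene_symbol: str
    source_group: SourceGroup

    def __post_init__(self) -> None:
        object.__setattr__(self, "qtl_type", QtlType(self.qtl_type))
        object.__setattr__(self, "tissue_group", TissueGroup(self.tissue_group))
        object.__setattr__(self, "tool", Tool(self.tool))
        object.__setattr__(self, "source_group", SourceGroup(self.source_group))
        for f in ("gwas_dataset", "gene_symbol"):
            if not getattr(self, f):
                raise DataError(f"evidence line with empty {f}")

    @property
    def key(self) -> tuple:
        """The five-field dictionary key (source group deliberately excluded)."""
        return (
            self.gwas_dataset,
            self.qtl_type,
            self.tissue_group,
            self.tool,
            self.gene_symbol,
        )


@dataclass
class SupportCount:
    gene_symbol: str
    disorder: str
    count: int
    lines: frozenset[EvidenceLine] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.lines = frozenset(self.lines)
        if self.count != len(self.lines):
            raise DataError(
                f"{self.gene_symbol}: count {self.count} != {len(self.lines)} lines"
            )


@dataclass
class NoveltyCall:
    """Minimum GWAS p in the gene's +/- window and the resulting novelty flag."""

    gene_symbol: str
    disorder: str
    window: tuple[str, int, int]
    min_p: float | None
    n_snps_in_window: int
    is_novel: bool | None = None
    reason: str | None = None


@dataclass
class ReplicationMatrix:
    """Pairwise overlap counts and directed ratios |A∩B|/|A| over gene sets."""

    labels: list[str]
    counts: pd.DataFrame
    ratios: pd.DataFrame


@dataclass
class MmrpPattern:
    """A multi-QTL regulation pattern: the exact set of >=2 layers mapping genes."""

    disorder: str
    qtl_set: frozenset[QtlType]
    contains_eqtl: bool
    genes: list[str]

    def __post_init__(self) -> None:
        self.qtl_set = frozenset(QtlType(q) for q in self.qtl_set)
        if len(self.qtl_set) < 2:
            raise DataError("MMRP pattern needs at least two QTL types")
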