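"""Readers/writers for the tabular formats, allele harmonization, region filters.

All files are plain tab-separated text with a header. Canonical GWAS columns
are SNP, CHR, BP, A1 (effect allele), A2, Z, BETA, SE, P, N; dialects are
accommodated through a ``column_map``. The gene-annotation format is BED-like:
its START column is the single 0-based field in the package and is converted
to 1-based on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    ConfigurationError,
    DataError,
    GeneAnnotation,
    GwasSumstats,
    QtlSumstats,
    VariantRecord,
    GWAS_COLUMNS,
)

logger = logging.getLogger(__name__)

_REQUIRED_GWAS = ["SNP", "CHR", "BP", "A1", "A2", "P", "N"]


def _norm_chrom(label: object) -> str:
    s = str(label)
    return s[3:] if s.lower().startswith("chr") else s


def read_gwas_sumstats(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    trait_id: str | None = None,
) -> GwasSumstats:
    """Read GWAS summary statistics; Z is computed from BETA/SE when absent.

    ``column_map`` maps canonical names to the file's column names, e.g.
    ``{"SNP": "rsid", "P": "pval"}``.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"GWAS file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        df = df.rename(columns=rename)
    for col in _REQUIRED_GWAS:
        if col not in df.columns:
            raise ConfigurationError(f"{path}: missing required column {col}")
    has_z = "Z" in df.columns
    has_bse = "BETA" in df.columns and "SE" in df.columns
    if not has_z and not has_bse:
        raise ConfigurationError(f"{path}: need either Z or BETA+SE")
    if not has_z:
        df["Z"] = df["BETA"].astype(float) / df["SE"].astype(float)
    for col in ("BETA", "SE"):
        if col not in df.columns:
            df[col] = np.nan
    df["CHR"] = df["CHR"].map(_norm_chrom)
    df = df[GWAS_COLUMNS]
    return GwasSumstats(trait_id=trait_id or path.stem, records=df)


def write_gwas_sumstats(gwas: GwasSumstats, path: str | Path) -> None:
    gwas.records.to_csv(path, sep="\t", index=False, na_rep="NA")


_QTL_META = ["FEATURE", "GENE", "QTL_TYPE", "TISSUE", "DATASET"]
_QTL_REC = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P"]


def read_qtl_sumstats(path: str | Path) -> list[QtlSumstats]:
    """Read a cis-QTL table (one file, many features) into per-feature objects."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"QTL file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    missing = [c for c in _QTL_META + _QTL_REC if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing columns {missing}")
    df["CHR"] = df["CHR"].map(_norm_chrom)
    out = []
    for feature_id, grp in df.groupby("FEATURE", sort=True):
        meta = grp.iloc[0]
        out.append(
            QtlSumstats(
                feature_id=str(feature_id),
                gene_symbol=str(meta["GENE"]),
                qtl_type=str(meta["QTL_TYPE"]),
                tissue_label=str(meta["TISSUE"]),
                dataset_tag=str(meta["DATASET"]),
                records=grp[_QTL_REC].reset_index(drop=True),
            )
        )
    return out


def write_qtl_sumstats(features: list[QtlSumstats], path: str | Path) -> None:
    frames = []
    for f in features:
        df = f.records.copy()
        df.insert(0, "FEATURE", f.feature_id)
        df.insert(1, "GENE", f.gene_symbol)
        df.insert(2, "QTL_TYPE", f.qtl_type.value)
        df.insert(3, "TISSUE", f.tissue_label)
        df.insert(4, "DATASET", f.dataset_tag)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_gene_annotations(path: str | Path) -> list[GeneAnnotation]:
    """BED-like annotation: CHR, START (0-based), END, SYMBOL, ALIASES (;-joined)."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"annotation file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    for col in ("CHR", "START", "END", "SYMBOL"):
        if col not in df.columns:
            raise ConfigurationError(f"{path}: missing column {col}")
    genes = []
    for _, row in df.iterrows():
        aliases = (
            frozenset(str(row["ALIASES"]).split(";"))
            if "ALIASES" in df.columns and pd.notna(row.get("ALIASES"))
            and str(row.get("ALIASES"))
            else frozenset()
        )
        genes.append(
            GeneAnnotation(
                canonical_symbol=str(row["SYMBOL"]),
                aliases=aliases,
                chromosome=_norm_chrom(row["CHR"]),
                start=int(row["START"]) + 1,  # BED 0-based half-open -> 1-based closed
                end=int(row["END"]),
            )
        )
    return genes


def write_gene_annotations(genes: list[GeneAnnotation], path: str | Path) -> None:
    rows = [
        {
            "CHR": g.chromosome,
            "START": g.start - 1,
            "END": g.end,
            "SYMBOL": g.canonical_symbol,
            "ALIASES": ";".join(sorted(g.aliases)),
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=["CHR", "START", "END", "SYMBOL", "ALIASES"]).to_csv(
        path, sep="\t", index=False
    )


EVIDENCE_COLUMNS = ["GWAS_DATASET", "QTL_TYPE", "TISSUE", "TOOL", "GENE", "SOURCE"]


def read_evidence_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"evidence file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing columns {missing}")
    return df[EVIDENCE_COLUMNS]


def read_alias_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV ALIAS<TAB>CANONICAL mapping aliases to canonical symbols."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"alias table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    if not {"ALIAS", "CANONICAL"} <= set(df.columns):
        raise ConfigurationError(f"{path}: need ALIAS and CANONICAL columns")
    return dict(zip(df["ALIAS"].astype(str), df["CANONICAL"].astype(str)))


@dataclass
class HarmonizationReport:
    n_input: int
    n_matched: int
    n_flipped: int
    n_ambiguous_dropped: int
    n_unmatched_dropped: int
    n_allele_mismatch_dropped: int

    def as_dict(self) -> dict[str, int]:
        return asdict(self)


def harmonize_to_reference(
    gwas: GwasSumstats, reference: list[VariantRecord]
) -> tuple[GwasSumstats, HarmonizationReport]:
    """Align GWAS effect alleles to a reference variant panel.

    Variants are matched by id; z (and beta) signs flip when the effect/other
    alleles are swapped relative to the reference; strand-ambiguous variants
    (A/T, C/G) and variants absent from the reference are dropped. |z| is never
    changed, only its sign or the variant's presence.
    """
    ref = {v.variant_id: v for v in reference}
    df = gwas.records
    keep_rows = []
    n_flipped = n_amb = n_unmatched = n_mismatch = 0
    for row in df.itertuples(index=False):
        rv = ref.get(row.SNP)
        if rv is None:
            n_unmatched += 1
            continue
        a1, a2 = str(row.A1), str(row.A2)
        if (a1, a2) in {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}:
            n_amb += 1
            continue
        rec = row._asdict()
        if (a1, a2) == (rv.effect_allele, rv.other_allele):
            pass
        elif (a1, a2) == (rv.other_allele, rv.effect_allele):
            rec["Z"] = -rec["Z"]
            if not pd.isna(rec["BETA"]):
                rec["BETA"] = -rec["BETA"]
            rec["A1"], rec["A2"] = rv.effect_allele, rv.other_allele
            n_flipped += 1
        else:
            n_mismatch += 1
            continue
        keep_rows.append(rec)
    if not keep_rows:
        raise DataError(
            f"GWAS {gwas.trait_id}: no variants survive harmonization (empty overlap)"
        )
    out = pd.DataFrame(keep_rows, columns=list(df.columns))
    report = HarmonizationReport(
        n_input=len(df),
        n_matched=len(keep_rows),
        n_flipped=n_flipped,
        n_ambiguous_dropped=n_amb,
        n_unmatched_dropped=n_unmatched,
        n_allele_mismatch_dropped=n_mismatch,
    )
    logger.info(
        "harmonize %s: %d in, %d matched, %d flipped, %d ambiguous, %d unmatched",
        gwas.trait_id,
        report.n_input,
        report.n_matched,
        report.n_flipped,
        report.n_ambiguous_dropped,
        report.n_unmatched_dropped,
    )
    return GwasSumstats(trait_id=gwas.trait_id, records=out), report


def exclude_region(collection, region: tuple[str, int, int]):
    """Remove variants falling inside a 1-based closed genomic interval.

    Accepts a GwasSumstats, a QtlSumstats, a list of VariantRecord, or a bare
    DataFrame with CHR/BP columns, and returns the same type. Idempotent.
    """
    chrom, start, end = region
    if start > end:
        raise ConfigurationError(f"region start > end: {region}")
    chrom = _norm_chrom(chrom)

    def _mask(df: pd.DataFrame) -> pd.Series:
        inside = (
            (df["CHR"].map(_norm_chrom) == chrom)
            & (df["BP"] >= start)
            & (df["BP"] <= end)
        )
        return ~inside

    if isinstance(collection, GwasSumstats):
        kept = collection.records[_mask(collection.records)].reset_index(drop=True)
        return GwasSumstats(trait_id=collection.trait_id, records=kept)
    if isinstance(collection, QtlSumstats):
        kept = collection.records[_mask(collection.records)].reset_index(drop=True)
        return QtlSumstats(
            feature_id=collection.feature_id,
            gene_symbol=collection.gene_symbol,
            qtl_type=collection.qtl_type,
            tissue_label=collection.tissue_label,
            dataset_tag=collection.dataset_tag,
            records=kept,
        )
    if isinstance(collection, pd.DataFrame):
        return collection[_mask(collection)].reset_index(drop=True)
    if isinstance(collection, list):
        return [
            v
            for v in collection
            if not (
                _norm_chrom(v.chromosome) == chrom and start <= v.position <= end
            )
        ]
    raise TypeError(f"unsupported collection type {type(collection)!r}")
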