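"""GWAS novelty calls for reliable genes.

A gene is *novel* when the minimum GWAS p over all SNPs within ``window_bp``
(default 1 Mb) upstream and downstream of the gene body is strictly greater
than the genome-wide threshold (default 5e-8). The window is anchored to the
gene body boundaries (strand-free), closed at both edges, and clamped at
position 1. Genes whose window holds no SNP, or whose chromosome is absent
from the GWAS, are reported as unclassifiable rather than silently dropped.
"""

from __future__ import annotations

import logging

import pandas as pd

from .types import GeneAnnotation, GwasSumstats, NoveltyCall

logger = logging.getLogger(__name__)


def min_p_in_window(
    gene: GeneAnnotation,
    gwas: GwasSumstats,
    window_bp: int = 1_000_000,
    disorder: str = "",
) -> NoveltyCall:
    """Minimum GWAS p over [gene.start - window_bp, gene.end + window_bp]."""
    start = max(1, gene.start - window_bp)
    end = gene.end + window_bp
    df = gwas.records
    on_chrom = df["CHR"].astype(str) == str(gene.chromosome)
    if not on_chrom.any():
        return NoveltyCall(
            gene_symbol=gene.canonical_symbol,
            disorder=disorder,
            window=(gene.chromosome, start, end),
            min_p=None,
            n_snps_in_window=0,
            reason="chromosome absent from GWAS",
        )
    inside = on_chrom & (df["BP"] >= start) & (df["BP"] <= end)
    n = int(inside.sum())
    if n == 0:
        return NoveltyCall(
            gene_symbol=gene.canonical_symbol,
            disorder=disorder,
            window=(gene.chromosome, start, end),
            min_p=None,
            n_snps_in_window=0,
            reason="no SNPs in window",
        )
    return NoveltyCall(
        gene_symbol=gene.canonical_symbol,
        disorder=disorder,
        window=(gene.chromosome, start, end),
        min_p=float(df.loc[inside, "P"].min()),
        n_snps_in_window=n,
    )


def classify_novel(call: NoveltyCall, threshold: float = 5e-8) -> NoveltyCall:
    """Set ``is_novel = (min_p > threshold)``; strict inequality at the bound."""
    if call.min_p is None:
        call.is_novel = None
        return call
    call.is_novel = bool(call.min_p > threshold)
    return call


def novelty_calls(
    genes: list[GeneAnnotation],
    gwas: GwasSumstats,
    window_bp: int = 1_000_000,
    threshold: float = 5e-8,
    disorder: str = "",
) -> list[NoveltyCall]:
    calls = [
        classify_novel(min_p_in_window(g, gwas, window_bp, disorder), threshold)
        for g in genes
    ]
    unclassifiable = sum(c.is_novel is None for c in calls)
    if unclassifiable:
        logger.warning("novelty: %d unclassifiable genes", unclassifiable)
    return calls


def novelty_frame(calls: list[NoveltyCall]) -> pd.DataFrame:
    rows = [
        {
            "DISORDER": c.disorder,
            "GENE": c.gene_symbol,
            "CHR": c.window[0],
            "WINDOW_START": c.window[1],
            "WINDOW_END": c.window[2],
            "MIN_P": c.min_p if c.min_p is not None else "NA",
            "N_SNPS": c.n_snps_in_window,
            "IS_NOVEL": (
                "NA" if c.is_novel is None else ("novel" if c.is_novel else "non-novel")
            ),
            "REASON": c.reason or "",
        }
        for c in calls
    ]
    columns = [
        "DISORDER", "GENE", "CHR", "WINDOW_START", "WINDOW_END",
        "MIN_P", "N_SNPS", "IS_NOVEL", "REASON",
    ]
    return pd.DataFrame(rows, columns=columns).sort_values(
        ["DISORDER", "GENE"], ignore_index=True
    )
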