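"""Evidence curation: symbol normalization, dictionary lines, reliable genes.

The unit of evidence is the five-field key 'GWAS dataset—xQTL type—tissue
(brain/non-brain)—tool—gene'. A gene's support count is the number of
distinct keys carrying it; genes replicated at least twice (default) are
"reliable". Note the key deliberately excludes the QTL *panel* name: two
different expression panels analysed with the same tool in the same tissue
group contribute a single line.

Sources are grouped as CG (curated, from published studies) and SG
(supplementary, re-analysed here). Counting modes:

* ``"CG"`` / ``"SG"`` — lines of one source group only;
* ``"pooled"`` (the default "Total") — CG and SG lines pooled first, then
  deduplicated on the five-field key, then thresholded;
* the union of the per-source reliable sets is also reported for
  reconciliation (a gene can reach the threshold only when pooled).
"""

from __future__ import annotations

import logging
import re

import pandas as pd

from .assoc import tissue_group_of
from .types import (
    DataError,
    EvidenceLine,
    QtlType,
    SourceGroup,
    SupportCount,
    TissueGroup,
    Tool,
    XwasResult,
)

logger = logging.getLogger(__name__)

_SEP = re.compile(r"[-_]")


def _fold(symbol: str) -> str:
    """Case-insensitive, hyphen/underscore-insensitive folding for lookups."""
    return _SEP.sub("", symbol.strip().upper())


def normalize_symbols(
    raw: list[str], alias_table: dict[str, str]
) -> tuple[list[str], list[str]]:
    """Map raw gene symbols to canonical symbols via an alias table.

    Exact lookup first, then case/hyphen-insensitive; unmapped symbols pass
    through verbatim and are returned in the unmapped report.
    """
    folded = {_fold(a): c for a, c in alias_table.items()}
    canonical_folds = {_fold(c) for c in alias_table.values()}
    out, unmapped = [], []
    for sym in raw:
        s = sym.strip()
        if s in alias_table:
            out.append(alias_table[s])
        elif _fold(s) in folded:
            out.append(folded[_fold(s)])
        else:
            out.append(s)
            if _fold(s) not in canonical_folds:
                unmapped.append(s)
    if unmapped:
        logger.info("normalize_symbols: %d unmapped symbols", len(unmapped))
    return out, unmapped


def build_lines(
    rows,
    source_group: SourceGroup | str,
    alias_table: dict[str, str] | None = None,
    brain_keywords: list[str] | None = None,
) -> set[EvidenceLine]:
    """Construct deduplicated evidence lines from result rows.

    ``rows`` is either a list of :class:`XwasResult` (only rows passing
    correction contribute) or a DataFrame with columns GWAS_DATASET, QTL_TYPE,
    TISSUE, TOOL, GENE. Raw tissue labels are collapsed to brain/non-brain
    before keying, so rows differing only in tissue label collapse.
    """
    source_group = SourceGroup(source_group)
    lines: set[EvidenceLine] = set()
    if isinstance(rows, pd.DataFrame):
        for i, row in enumerate(rows.itertuples(index=False)):
            record = row._asdict()
            for field in ("GWAS_DATASET", "QTL_TYPE", "TISSUE", "TOOL", "GENE"):
                value = record.get(field)
                if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
                    raise DataError(f"evidence row {i}: missing {field}")
            gene = str(record["GENE"])
            if alias_table:
                gene = normalize_symbols([gene], alias_table)[0][0]
            tissue = str(record["TISSUE"])
            group = (
                TissueGroup(tissue)
                if tissue in (t.value for t in TissueGroup)
                else tissue_group_of(tissue, brain_keywords)
            )
            lines.add(
                EvidenceLine(
                    gwas_dataset=str(record["GWAS_DATASET"]),
                    qtl_type=QtlType(str(record["QTL_TYPE"])),
                    tissue_group=group,
                    tool=Tool(str(record["TOOL"])),
                    gene_symbol=gene,
                    source_group=source_group,
                )
            )
    else:
        for r in rows:
            assert isinstance(r, XwasResult)
            if not r.passes_correction:
                continue
            gene = r.gene_symbol
            if alias_table:
                gene = normalize_symbols([gene], alias_table)[0][0]
            lines.add(
                EvidenceLine(
                    gwas_dataset=r.gwas_dataset,
                    qtl_type=r.qtl_type,
                    tissue_group=r.tissue_group,
                    tool=r.tool,
                    gene_symbol=gene,
                    source_group=source_group,
                )
            )
    return lines


def disorder_of(gwas_dataset: str) -> str:
    """Disorder label = dataset tag prefix before the first underscore."""
    return gwas_dataset.split("_", 1)[0]


def count_support(
    lines: set[EvidenceLine],
    disorder: str,
    mode: str = "pooled",
) -> list[SupportCount]:
    """Per-gene distinct-line counts for one disorder.

    ``mode``: "CG" or "SG" restricts to that source group; "pooled" pools both
    groups and deduplicates on the five-field key (cross-source duplicates of
    an identical key collapse to one line).
    """
    sel = [l for l in lines if disorder_of(l.gwas_dataset) == disorder]
    if mode in ("CG", "SG"):
        sel = [l for l in sel if l.source_group is SourceGroup(mode)]
    elif mode != "pooled":
        raise DataError(f"unknown counting mode {mode!r}")
    by_gene: dict[str, set] = {}
    line_of_key: dict[tuple, EvidenceLine] = {}
    for l in sel:
        by_gene.setdefault(l.gene_symbol, set()).add(l.key)
        line_of_key.setdefault(l.key, l)
    out = [
        SupportCount(
            gene_symbol=g,
            disorder=disorder,
            count=len(keys),
            lines=frozenset(line_of_key[k] for k in keys),
        )
        for g, keys in sorted(by_gene.items())
    ]
    return out


def reliable_genes(counts: list[SupportCount], min_count: int = 2) -> set[str]:
    """Genes replicated at least ``min_count`` times (default twice)."""
    if min_count < 1:
        raise DataError("min_count must be >= 1")
    return {c.gene_symbol for c in counts if c.count >= min_count}


def reliable_by_mode(
    lines: set[EvidenceLine], disorder: str, min_count: int = 2
) -> dict[str, set[str]]:
    """Reliable sets per counting mode, plus the reconciling union.

    Returns keys "CG", "SG", "Total" (pooled-then-thresholded, the default
    Total semantics) and "Union" (union of CG- and SG-reliable with the
    pooled-only genes, always a superset check of "Total").
    """
    cg = reliable_genes(count_support(lines, disorder, "CG"), min_count)
    sg = reliable_genes(count_support(lines, disorder, "SG"), min_count)
    pooled = reliable_genes(count_support(lines, disorder, "pooled"), min_count)
    return {"CG": cg, "SG": sg, "Total": pooled, "Union": cg | sg | pooled}


def support_counts_frame(counts: list[SupportCount]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"DISORDER": c.disorder, "GENE": c.gene_symbol, "COUNT": c.count}
            for c in counts
        ],
        columns=["DISORDER", "GENE", "COUNT"],
    ).sort_values(["DISORDER", "GENE"], ignore_index=True)
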