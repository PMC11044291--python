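"""Cross-QTL / cross-disorder replication metrics and multi-QTL patterns.

Replication ratios are directed: entry (A, B) = |A ∩ B| / |A| — the size of
set A is the denominator and the overlap the numerator, so the matrix is
generally asymmetric while the overlap counts are symmetric.

An MMRP (multiple molecular regulation pattern) is the exact set of >= 2 QTL
types mapping a gene for one disorder; each gene belongs to exactly one
pattern, the one equal to its full QTL-type profile, so pattern gene counts
partition the multi-QTL genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    EvidenceLine,
    MmrpPattern,
    NoveltyCall,
    QtlType,
    ReplicationMatrix,
    SupportCount,
)
from .evidence import disorder_of


def replication_matrix(sets: dict[str, set[str]]) -> ReplicationMatrix:
    """Pairwise overlap counts and directed ratios over labelled gene sets."""
    if len(sets) < 2:
        raise ValueError("replication_matrix needs at least two labelled sets")
    labels = list(sets.keys())
    n = len(labels)
    counts = np.zeros((n, n), dtype=int)
    ratios = np.full((n, n), np.nan)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            overlap = len(sets[a] & sets[b])
            counts[i, j] = overlap
            if len(sets[a]) > 0:
                ratios[i, j] = overlap / len(sets[a])
    return ReplicationMatrix(
        labels=labels,
        counts=pd.DataFrame(counts, index=labels, columns=labels),
        ratios=pd.DataFrame(ratios, index=labels, columns=labels),
    )


@dataclass
class ReplicationComparison:
    median_novel: float | None
    median_non_novel: float | None
    test_p: float | None
    degenerate: bool = False


def compare_replication_times(
    counts: list[SupportCount], novelty: list[NoveltyCall]
) -> ReplicationComparison:
    """Compare support-count distributions of novel vs non-novel genes.

    Uses a two-sided Mann-Whitney rank-sum test with normal approximation and
    tie correction. Unclassifiable genes are excluded; when either group is
    empty the medians are still reported and the test p is missing; when
    either group has a single member the test is flagged degenerate.
    """
    count_of = {(c.disorder, c.gene_symbol): c.count for c in counts}
    novel, non_novel = [], []
    for call in novelty:
        c = count_of.get((call.disorder, call.gene_symbol))
        if c is None or call.is_novel is None:
            continue
        (novel if call.is_novel else non_novel).append(c)
    med = lambda xs: float(np.median(xs)) if xs else None
    if not novel or not non_novel:
        return ReplicationComparison(med(novel), med(non_novel), None)
    degenerate = min(len(novel), len(non_novel)) < 2
    p = float(
        stats.mannwhitneyu(
            novel, non_novel, alternative="two-sided", method="asymptotic"
        ).pvalue
    )
    return ReplicationComparison(med(novel), med(non_novel), p, degenerate)


def gene_qtl_profiles(
    lines: set[EvidenceLine], disorder: str
) -> dict[str, set[QtlType]]:
    """Per gene, the set of distinct QTL types across its evidence lines."""
    profiles: dict[str, set[QtlType]] = {}
    for l in lines:
        if disorder_of(l.gwas_dataset) != disorder:
            continue
        profiles.setdefault(l.gene_symbol, set()).add(l.qtl_type)
    return profiles


def enumerate_mmrp(
    profiles: dict[str, set[QtlType]],
    disorder: str = "",
    restrict_to: set[str] | None = None,
) -> list[MmrpPattern]:
    """Partition multi-QTL genes into patterns by their exact QTL-type profile.

    Patterns are sorted by (profile size, gene count descending); the
    ``contains_eqtl`` flag distinguishes expression-anchored patterns.
    """
    if restrict_to is not None:
        profiles = {g: q for g, q in profiles.items() if g in restrict_to}
    groups: dict[frozenset, list[str]] = {}
    for gene, qset in profiles.items():
        if len(qset) >= 2:
            groups.setdefault(frozenset(qset), []).append(gene)
    patterns = [
        MmrpPattern(
            disorder=disorder,
            qtl_set=qset,
            contains_eqtl=QtlType.EQTL in qset,
            genes=sorted(genes),
        )
        for qset, genes in groups.items()
    ]
    patterns.sort(key=lambda p: (len(p.qtl_set), -len(p.genes), sorted(q.value for q in p.qtl_set)))
    return patterns


def mmrp_frame(patterns: list[MmrpPattern]) -> pd.DataFrame:
    rows = [
        {
            "DISORDER": p.disorder,
            "QTL_SET": "+".join(sorted(q.value for q in p.qtl_set)),
            "CONTAINS_EQTL": p.contains_eqtl,
            "N_GENES": len(p.genes),
            "GENES": ";".join(p.genes),
        }
        for p in patterns
    ]
    return pd.DataFrame(
        rows, columns=["DISORDER", "QTL_SET", "CONTAINS_EQTL", "N_GENES", "GENES"]
    )
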