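"""Co-occupancy groups (G1-G5), expression association and enrichment.

Co-bound sites are classified by how many of the assayed transcription
factors bind there: with five TFs, G1 means all five co-bind and G5 means
a single factor.  Group target genes are then compared on expression
(two-sided Wilcoxon rank-sum tests between groups) and tested for overlap
with a deregulated-gene list using the hypergeometric upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import TargetAssignment
from .intervals import CoboundSite

__all__ = [
    "GROUPS",
    "EnrichmentResult",
    "label_groups",
    "group_label",
    "gene_group_assignment",
    "group_expression",
    "rank_sum_test",
    "hypergeom_enrichment",
    "write_enrichment",
]

GROUPS = ("G1", "G2", "G3", "G4", "G5")


def group_label(n_factors: int, n_total_factors: int = 5) -> str:
    """Map a co-bound factor count to its group label (G1 = all factors)."""
    if not 1 <= n_factors <= n_total_factors:
        raise ValueError(f"n_factors must be in [1, {n_total_factors}], got {n_factors}")
    return f"G{n_total_factors + 1 - n_factors}"


def label_groups(
    sites: Sequence[CoboundSite], n_total_factors: int = 5
) -> dict[int, str]:
    """Label every site by index: G1 = bound by all factors ... G5 = one factor."""
    return {i: group_label(s.n_factors, n_total_factors) for i, s in enumerate(sites)}


def gene_group_assignment(
    sites: Sequence[CoboundSite],
    site_targets: Mapping[int, Iterable[str]],
    n_total_factors: int = 5,
) -> dict[str, str]:
    """Per-gene group: a gene keeps the *maximum* co-bound count over its sites.

    ``site_targets`` maps site index -> target gene symbols of that site.
    """
    best_count: dict[str, int] = {}
    for i, s in enumerate(sites):
        for gene in site_targets.get(i, ()):
            if s.n_factors > best_count.get(gene, 0):
                best_count[gene] = s.n_factors
    return {g: group_label(k, n_total_factors) for g, k in best_count.items()}


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when both samples have <=25 observations and the
    pooled data are tie-free; otherwise the tie-corrected normal
    approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (len(x) <= 25 and len(y) <= 25 and not ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def group_expression(
    gene_groups: Mapping[str, str],
    expr: pd.DataFrame,
    samples: Sequence[str] | None = None,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Per-group expression distributions and pairwise rank-sum p-values.

    ``expr`` is a genes x samples table (TPM).  Each gene contributes its
    mean over the selected samples.  Groups without any expressed gene are
    excluded.  Returns ``(distributions, p_matrix)`` where ``p_matrix`` is
    a symmetric DataFrame over the retained groups.
    """
    sub = expr if samples is None else expr[list(samples)]
    means = sub.mean(axis=1)
    dists: dict[str, np.ndarray] = {}
    for grp in GROUPS:
        genes = [g for g, lab in gene_groups.items() if lab == grp and g in means.index]
        if genes:
            dists[grp] = means.loc[genes].to_numpy()
    labels = list(dists)
    pmat = pd.DataFrame(np.ones((len(labels), len(labels))), index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            p = rank_sum_test(dists[a], dists[b])
            pmat.loc[a, b] = pmat.loc[b, a] = p
    return dists, pmat


@dataclass(frozen=True)
class EnrichmentResult:
    group: str
    overlap_count: int
    group_size: int
    overlap_pct: float
    p_value: float


def hypergeom_enrichment(
    group_genes: set[str],
    dereg_genes: set[str],
    universe: set[str],
    group: str = "",
) -> EnrichmentResult:
    """Hypergeometric upper-tail overlap test of a group against a gene list.

    With ``N = |universe|``, ``K = |dereg|``, ``n = |group|`` and
    ``k = |group & dereg|``, the p-value is ``P(X >= k)`` for
    ``X ~ Hypergeometric(N, K, n)``; the overlap percentage is
    ``100 * k / n``.
    """
    if not group_genes:
        raise ValueError("undefined percentage: empty group")
    if not group_genes <= universe or not dereg_genes <= universe:
        raise ValueError("group and deregulated genes must be subsets of the universe")
    N, K, n = len(universe), len(dereg_genes), len(group_genes)
    k = len(group_genes & dereg_genes)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(
        group=group,
        overlap_count=k,
        group_size=n,
        overlap_pct=100.0 * k / n,
        p_value=min(1.0, p),
    )


def write_enrichment(results: Iterable[EnrichmentResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("group\toverlap_count\tgroup_size\toverlap_pct\tp_value\n")
        for r in results:
            fh.write(
                f"{r.group}\t{r.overlap_count}\t{r.group_size}\t"
                f"{r.overlap_pct:.4f}\t{r.p_value:.6g}\n"
            )
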