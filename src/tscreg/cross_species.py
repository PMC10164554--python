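"""Cross-species comparison of TF targets through a 1:1 ortholog map.

Genes are compared between two species (A and B, e.g. human and mouse) on
three axes:

* how many of the assayed factors bind each gene in each species
  (:func:`bound_counts`), and the derived common / HMFB / MMFB class —
  HMFB ("human multiple factors bound") genes are bound by all factors in
  species A but by at most ``low_max`` (2) factors in species B, MMFB the
  mirror image, and common genes by all factors in both;
* which species expresses the gene at least ``fold`` (2x) higher
  (:func:`species_enriched`), with a pseudocount guarding zero TPM;
* pairwise similarity of (factor, species) target sets over the
  ortholog-mapped universe: Pearson correlation of binary membership
  vectors plus Jaccard overlap (:func:`target_similarity`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OrthologMap",
    "SpeciesGeneRecord",
    "read_ortholog_map",
    "bound_counts",
    "classify_species_group",
    "species_enriched",
    "classify_genes",
    "target_similarity",
    "write_species_records",
]

DEFAULT_FACTORS = ("FOS", "GATA2", "MAFK", "TEAD4", "TFAP2C", "EP300")


class OrthologMap:
    """One-to-one gene symbol pairs between two species."""

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        self.a_to_b: dict[str, str] = {}
        self.b_to_a: dict[str, str] = {}
        for a, b in pairs:
            if a in self.a_to_b or b in self.b_to_a:
                raise ValueError(f"ortholog map is not one-to-one at ({a}, {b})")
            self.a_to_b[a] = b
            self.b_to_a[b] = a

    def __len__(self) -> int:
        return len(self.a_to_b)

    def pairs(self) -> list[tuple[str, str]]:
        return sorted(self.a_to_b.items())


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Two-column TSV (symbol_a, symbol_b); a header line is tolerated."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            if lineno == 1 and fields[0].lower() in ("symbol_a", "gene_a", "human"):
                continue
            pairs.append((fields[0], fields[1]))
    return OrthologMap(pairs)


def bound_counts(gene: str, per_factor_targets: Mapping[str, set[str]]) -> int:
    """Number of factors whose target set contains the gene."""
    return sum(1 for targets in per_factor_targets.values() if gene in targets)


def classify_species_group(
    count_a: int, count_b: int, n_factors: int = 6, low_max: int = 2
) -> str:
    """common / HMFB / MMFB / other classification from per-species counts."""
    for c in (count_a, count_b):
        if not 0 <= c <= n_factors:
            raise ValueError(f"bound count {c} outside [0, {n_factors}]")
    if count_a == n_factors and count_b == n_factors:
        return "common"
    if count_a == n_factors and count_b <= low_max:
        return "HMFB"
    if count_b == n_factors and count_a <= low_max:
        return "MMFB"
    return "other"


def species_enriched(
    expr_a: float, expr_b: float, fold: float = 2.0, pseudocount: float = 1.0
) -> str:
    """Which species expresses the gene >= ``fold`` higher (pseudocounted)."""
    if expr_a < 0 or expr_b < 0:
        raise ValueError("expression must be non-negative")
    ra = (expr_a + pseudocount) / (expr_b + pseudocount)
    if ra >= fold:
        return "A-enriched"
    if 1.0 / ra >= fold:
        return "B-enriched"
    return "neither"


@dataclass(frozen=True)
class SpeciesGeneRecord:
    gene_a: str
    gene_b: str
    bound_count_a: int
    bound_count_b: int
    expr_a: float
    expr_b: float
    species_class: str
    enrichment_class: str


def classify_genes(
    orthologs: OrthologMap,
    targets_a: Mapping[str, set[str]],
    targets_b: Mapping[str, set[str]],
    expr_a: Mapping[str, float],
    expr_b: Mapping[str, float],
    n_factors: int = 6,
    low_max: int = 2,
    fold: float = 2.0,
    pseudocount: float = 1.0,
) -> list[SpeciesGeneRecord]:
    """Full per-gene record over the ortholog-mapped universe.

    Genes missing from an expression table contribute 0 TPM there.
    """
    records = []
    for ga, gb in orthologs.pairs():
        ca = bound_counts(ga, targets_a)
        cb = bound_counts(gb, targets_b)
        ea = float(expr_a.get(ga, 0.0))
        eb = float(expr_b.get(gb, 0.0))
        records.append(
            SpeciesGeneRecord(
                gene_a=ga,
                gene_b=gb,
                bound_count_a=ca,
                bound_count_b=cb,
                expr_a=ea,
                expr_b=eb,
                species_class=classify_species_group(ca, cb, n_factors, low_max),
                enrichment_class=species_enriched(ea, eb, fold, pseudocount),
            )
        )
    return records


def target_similarity(
    targets: Mapping[tuple[str, str], set[str]],
    universe: Sequence[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson and Jaccard similarity of target sets.

    ``targets`` maps (factor, species) -> target gene set; membership is
    evaluated over ``universe`` (an ortholog-mapped gene list).  Pearson
    correlation of a pair involving a constant membership vector (all in
    or all out) is undefined and reported as NaN.
    """
    if len(targets) < 2:
        raise ValueError("need at least two target sets")
    if not universe:
        raise ValueError("empty universe")
    keys = sorted(targets)
    labels = [f"{f}_{s}" for f, s in keys]
    mat = np.array(
        [[1.0 if g in targets[k] else 0.0 for g in universe] for k in keys]
    )
    n = len(keys)
    pearson = np.eye(n)
    jacc = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            xi, xj = mat[i], mat[j]
            if xi.std() == 0 or xj.std() == 0:
                r = math.nan
            else:
                r = float(np.corrcoef(xi, xj)[0, 1])
            union = float(np.maximum(xi, xj).sum())
            inter = float((xi * xj).sum())
            jac = inter / union if union > 0 else math.nan
            pearson[i, j] = pearson[j, i] = r
            jacc[i, j] = jacc[j, i] = jac
    return (
        pd.DataFrame(pearson, index=labels, columns=labels),
        pd.DataFrame(jacc, index=labels, columns=labels),
    )


def write_species_records(records: Iterable[SpeciesGeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene_a\tgene_b\tbound_count_a\tbound_count_b\texpr_a\texpr_b\t"
            "species_class\tenrichment_class\n"
        )
        for r in records:
            fh.write(
                f"{r.gene_a}\t{r.gene_b}\t{r.bound_count_a}\t{r.bound_count_b}\t"
                f"{r.expr_a:.4f}\t{r.expr_b:.4f}\t{r.species_class}\t{r.enrichment_class}\n"
            )
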