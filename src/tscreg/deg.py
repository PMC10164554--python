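"""Integration of knockdown DEG tables with TF target sets.

DEG tables arrive pre-filtered (adjusted p < 0.01, |fold change| > 1 in
the upstream caller).  Two summaries are computed per TF:

* the direct / indirect split of up- and down-regulated DEGs, where a DEG
  is *direct* iff the TF has a binding-site target assignment to it;
* the repressed:activated ratio — within a stratum of genes (e.g. bound
  by all five TFs vs by at most one), the ratio of genes going down after
  knockdown (genes the TF activates) to genes going up (genes it
  represses).  Both counts are always reported so either orientation of
  the ratio is recoverable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "DegRecord",
    "DirectnessSummary",
    "StratumRatio",
    "read_deg_table",
    "split_direct",
    "repression_activation_ratio",
]


@dataclass(frozen=True)
class DegRecord:
    gene: str
    log2fc: float
    padj: float

    @property
    def direction(self) -> str:
        return "up" if self.log2fc > 0 else "down"


def read_deg_table(path: str | Path) -> list[DegRecord]:
    """TSV with columns gene, log2fc, padj (header required)."""
    df = pd.read_csv(path, sep="\t")
    return [
        DegRecord(str(r.gene), float(r.log2fc), float(r.padj))
        for r in df.itertuples(index=False)
    ]


@dataclass(frozen=True)
class DirectnessSummary:
    n_direct_up: int
    n_indirect_up: int
    n_direct_down: int
    n_indirect_down: int

    @property
    def pct_direct_up(self) -> float:
        n = self.n_direct_up + self.n_indirect_up
        return 100.0 * self.n_direct_up / n if n else math.nan

    @property
    def pct_direct_down(self) -> float:
        n = self.n_direct_down + self.n_indirect_down
        return 100.0 * self.n_direct_down / n if n else math.nan

    @property
    def pct_direct_overall(self) -> float:
        n = (
            self.n_direct_up
            + self.n_indirect_up
            + self.n_direct_down
            + self.n_indirect_down
        )
        return 100.0 * (self.n_direct_up + self.n_direct_down) / n if n else math.nan


def split_direct(degs: Sequence[DegRecord], tf_targets: set[str]) -> DirectnessSummary:
    """Split DEGs into direct (TF-bound) and indirect, per direction."""
    if not degs:
        raise ValueError("empty DEG list")
    du = iu = dd = idn = 0
    for d in degs:
        direct = d.gene in tf_targets
        if d.direction == "up":
            du += direct
            iu += not direct
        else:
            dd += direct
            idn += not direct
    return DirectnessSummary(du, iu, dd, idn)


@dataclass(frozen=True)
class StratumRatio:
    stratum: str
    n_down: int  # activated by the TF (down after knockdown)
    n_up: int  # repressed by the TF (up after knockdown)

    @property
    def ratio(self) -> float:
        """Down:up ratio; infinite when nothing went up after knockdown."""
        return self.n_down / self.n_up if self.n_up else math.inf

    @property
    def infinite(self) -> bool:
        return self.n_up == 0


def repression_activation_ratio(
    degs: Sequence[DegRecord],
    fully_bound: set[str],
    sparsely_bound: set[str],
) -> tuple[StratumRatio, StratumRatio]:
    """Down:up DEG ratios within the fully- and sparsely-bound strata."""
    if fully_bound & sparsely_bound:
        raise ValueError("strata must be disjoint")
    out = []
    for name, stratum in (("fully_bound", fully_bound), ("sparsely_bound", sparsely_bound)):
        n_down = sum(1 for d in degs if d.gene in stratum and d.direction == "down")
        n_up = sum(1 for d in degs if d.gene in stratum and d.direction == "up")
        out.append(StratumRatio(name, n_down, n_up))
    return out[0], out[1]
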