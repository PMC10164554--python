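"""Seeded generator of a miniature two-species regulatory-genomics study.

The generator emits every input the analysis pipeline consumes — gene
annotations, per-factor peak BEDs for two species, treatment/control tag
tracks, expression tables, a deregulated-gene list, an ortholog map and
per-TF knockdown DEG tables — together with a machine-readable ground-truth
manifest, so every pipeline stage can be validated against planted truth
without any external download.

Planted structure
-----------------
* Genes sit on a regular grid (one per ~50 kb cell) on each chromosome;
  the first five cells of chromosome 1 host the five assayed TF genes.
* Co-bound sites: each site belongs to one gene, sits 4-12 kb from its
  TSS, and carries peaks of 1-5 TFs (its *tier*) plus an EP300 peak.  The
  tier composition follows configured proportions exactly (largest-
  remainder rounding).  All peaks of a site share its center up to a
  small Gaussian jitter, so the 500 bp co-occupancy clustering recovers
  the tier.
* Super-enhancers: clusters of 5-15 high-weight EP300 peaks spanning
  <= 20 kb, placed at intergenic cell boundaries, >= 2.5 kb from every
  TSS and >= 25 kb apart, with per-peak tag weight ``signal_ratio`` times
  a background site peak.
* Cross-species classes: common genes carry all six factors (5 TFs +
  EP300) in both species, HMFB genes all six in species A but <= 2 in
  species B, MMFB the mirror image; remaining genes get conserved-ish
  low counts.  The ortholog map is identity-with-renaming
  (``geneNNNN_h <-> geneNNNN_m``).
* Expression: log2 TPM ~ Normal(mu + delta * tier, sigma) in stem-like
  (TSC) samples, Normal(mu, sigma) in differentiated (ST/EVT) samples;
  species B uses its own tier so HMFB/MMFB genes are boosted only where
  they are multiply bound.
* The deregulated list samples an exact, monotonically tier-graded
  fraction of each tier's genes (5x base rate at tier 5).
* Knockdown DEG tables: four TFs are planted as activators of fully
  co-bound genes (down after KD) and one (TFAP2C) as a repressor,
  mirroring the asymmetry such studies report.

The EP300 peaks of planted SE clusters can fall within 20 kb of a
neighboring gene's TSS; manifest ``count_a`` records the site-derived
counts, which is why species-class recovery is asserted on the class
labels (no class requires exactly one EP300 contact).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotation import GeneAnnotation, GeneModel, assign_targets, write_refflat
from .cross_species import species_enriched
from .intervals import Peak, PeakSet, write_bed

__all__ = ["TF_FACTORS", "SimConfig", "TruthManifest", "simulate", "simulate_tiered_expression"]

TF_FACTORS = ("FOS", "GATA2", "MAFK", "TEAD4", "TFAP2C")
ALL_FACTORS = TF_FACTORS + ("EP300",)
SAMPLES = ("TSC_1", "TSC_2", "ST_1", "ST_2", "EVT_1", "EVT_2")
STEM_SAMPLES = ("TSC_1", "TSC_2")

# offsets (bp from the TSS) at which a gene's co-bound sites may sit;
# all outside the +/-2.5 kb promoter exclusion zone and far enough from
# neighboring genes that the +/-20 kb target rule stays unambiguous
SITE_SLOTS = (-12_000, -8_000, -4_000, 4_000, 8_000, 12_000)


@dataclass
class SimConfig:
    """Study conditions of the simulated experiment."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 10_000_000
    n_genes: int = 400
    n_sites: int = 600
    tier_proportions: tuple[float, ...] = (0.25, 0.20, 0.18, 0.17, 0.20)
    n_planted_se: int = 12
    se_cluster_size: tuple[int, int] = (5, 15)
    se_cluster_span: int = 20_000
    se_separation: int = 25_000
    signal_ratio: float = 10.0
    tag_depth: int = 200_000
    background_frac: float = 0.2
    tag_spread: float = 75.0
    expr_mu: float = 3.0
    expr_sigma: float = 1.0
    tier_effect: float = 1.0
    n_common: int = 70
    n_hmfb: int = 50
    n_mmfb: int = 30
    jitter_sd: float = 50.0
    dereg_base_rate: float = 0.08
    dereg_g1_factor: float = 5.0

    def validate(self) -> None:
        if abs(sum(self.tier_proportions) - 1.0) > 1e-9 or len(self.tier_proportions) != 5:
            raise ValueError("tier_proportions must be 5 values summing to 1")
        if any(p < 0 for p in self.tier_proportions):
            raise ValueError("tier_proportions must be non-negative")
        for name in ("n_chroms", "chrom_length", "n_genes", "n_sites", "tag_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_planted_se < 0 or min(self.n_common, self.n_hmfb, self.n_mmfb) < 0:
            raise ValueError("counts must be non-negative")
        if self.se_cluster_size[0] < 1 or self.se_cluster_size[0] > self.se_cluster_size[1]:
            raise ValueError("invalid se_cluster_size range")
        comp = tier_composition(self.n_sites, self.tier_proportions)
        if comp[4] < self.n_common + self.n_hmfb:
            raise ValueError(
                f"tier-5 sites ({comp[4]}) cannot cover n_common+n_hmfb "
                f"({self.n_common + self.n_hmfb}); adjust tier_proportions or class counts"
            )
        if comp[0] < self.n_mmfb:
            raise ValueError(f"tier-1 sites ({comp[0]}) cannot cover n_mmfb ({self.n_mmfb})")


def tier_composition(n_sites: int, proportions: Sequence[float]) -> list[int]:
    """Deterministic per-tier site counts (largest-remainder rounding)."""
    raw = [n_sites * p for p in proportions]
    counts = [int(x) for x in raw]
    short = n_sites - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:short]:
        counts[i] += 1
    return counts


class TruthManifest(dict):
    """Ground-truth record of everything the generator planted."""

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self, indent=1, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "TruthManifest":
        return cls(json.loads(Path(path).read_text()))


@dataclass
class _Gene:
    idx: int
    symbol: str  # species-A symbol (TF genes keep their factor name)
    chrom: str
    cell_index: int
    tss: int
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    is_tf: bool = False
    species_class: str = "other"
    sites: list = field(default_factory=list)
    factor_set: tuple[str, ...] = ()
    count_b: int = 0

    @property
    def tier_a(self) -> int:
        return max((s["tier"] for s in self.sites), default=0)

    @property
    def count_a(self) -> int:
        return len(self.factor_set) + 1 if self.sites else 0

    @property
    def tier_b(self) -> int:
        return max(0, self.count_b - 1)


def _make_genes(cfg: SimConfig, rng: np.random.Generator) -> list[_Gene]:
    genes: list[_Gene] = []
    per_chrom = cfg.n_genes // cfg.n_chroms
    extra = cfg.n_genes - per_chrom * cfg.n_chroms
    idx = 0
    for c in range(cfg.n_chroms):
        n_here = per_chrom + (1 if c < extra else 0)
        cell = cfg.chrom_length // n_here
        jit_max = min(5000, cell // 10)
        for i in range(n_here):
            tss = cell * i + cell // 2 + int(rng.integers(-jit_max, jit_max + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            tx_len = int(rng.integers(5000, 20001))
            if strand == "+":
                tx_start, tx_end = tss, tss + tx_len
            else:
                tx_start, tx_end = tss + 1 - tx_len, tss + 1
            n_ex = int(rng.integers(2, 5))
            chunk = tx_len // (2 * n_ex - 1)
            exons = tuple(
                (tx_start + 2 * j * chunk, tx_start + (2 * j + 1) * chunk)
                for j in range(n_ex)
            )
            is_tf = c == 0 and i < len(TF_FACTORS)
            symbol = TF_FACTORS[i] if is_tf else f"gene{idx:04d}"
            genes.append(
                _Gene(
                    idx=idx,
                    symbol=symbol,
                    chrom=f"chr{c + 1}",
                    cell_index=i,
                    tss=tss,
                    strand=strand,
                    tx_start=tx_start,
                    tx_end=tx_end,
                    exons=exons,
                    is_tf=is_tf,
                )
            )
            idx += 1
    return genes


def _assign_classes_and_sites(
    cfg: SimConfig, genes: list[_Gene], rng: np.random.Generator
) -> list[dict]:
    regular = [g for g in genes if not g.is_tf]
    comp = tier_composition(cfg.n_sites, cfg.tier_proportions)
    order = rng.permutation(len(regular))
    shuffled = [regular[i] for i in order]
    pos = 0

    def take(n: int) -> list[_Gene]:
        nonlocal pos
        out = shuffled[pos : pos + n]
        pos += n
        return out

    common = take(cfg.n_common)
    hmfb = take(cfg.n_hmfb)
    mmfb = take(cfg.n_mmfb)
    pool: list[int] = []
    for tier, count in enumerate(comp, start=1):
        pool.extend([tier] * count)
    # class genes consume their tier-5 / tier-1 sites from the pool
    for tier, n in ((5, cfg.n_common + cfg.n_hmfb), (1, cfg.n_mmfb)):
        for _ in range(n):
            pool.remove(tier)
    # surplus tier-5 sites promote additional genes to the common class
    surplus5 = pool.count(5)
    extra_common = take(surplus5)
    for _ in range(surplus5):
        pool.remove(5)
    other = shuffled[pos:]
    if len(pool) > 2 * len(other):
        raise ValueError("not enough genes for the requested site count (max 2 sites/gene)")

    for g in common + extra_common:
        g.species_class = "common"
    for g in hmfb:
        g.species_class = "HMFB"
    for g in mmfb:
        g.species_class = "MMFB"

    sites: list[dict] = []

    def add_site(gene: _Gene, tier: int) -> None:
        used = [st["slot"] for st in gene.sites]
        slot_pool = [s for s in SITE_SLOTS if s not in used]
        if used:
            # a gene's sites straddle its TSS, as enhancers typically do;
            # the promoter exclusion zone then separates them when stitching
            opposite = [s for s in slot_pool if s * used[0] < 0]
            slot_pool = opposite or slot_pool
        slot = int(rng.choice(slot_pool))
        center = gene.tss + slot
        site = {
            "chrom": gene.chrom,
            "center": center,
            "slot": slot,
            "tier": tier,
            "gene": gene.symbol,
        }
        gene.sites.append(site)
        sites.append(site)

    for g in common + hmfb + extra_common:
        add_site(g, 5)
    for g in mmfb:
        add_site(g, 1)
    tiers = [int(t) for t in rng.permutation(pool)]
    # round-robin over the remaining genes, at most two sites per gene
    targets = other + other
    for gene, tier in zip(targets, tiers):
        add_site(gene, tier)

    # per-gene factor sets: every site uses a subset of the gene's set so
    # the union of factors over sites equals the gene's maximum tier
    for g in regular:
        if not g.sites:
            continue
        tier_max = g.tier_a
        chosen = rng.choice(len(TF_FACTORS), size=tier_max, replace=False)
        g.factor_set = tuple(TF_FACTORS[i] for i in sorted(chosen))
        for s in g.sites:
            sub = rng.choice(len(g.factor_set), size=s["tier"], replace=False)
            s["factors"] = sorted(g.factor_set[i] for i in sorted(sub))

    # species-B bound counts
    for g in regular:
        if g.species_class == "common":
            g.count_b = 6
        elif g.species_class == "HMFB":
            g.count_b = int(rng.integers(0, 3))
        elif g.species_class == "MMFB":
            g.count_b = 6
        else:
            g.count_b = int(np.clip(g.count_a + rng.integers(-1, 2), 0, 5))
    return sites


def _place_se_clusters(
    cfg: SimConfig, genes: list[_Gene], rng: np.random.Generator
) -> list[dict]:
    """Plant SE clusters at intergenic cell boundaries.

    Boundaries are >= one grid cell apart, so distinct boundaries keep
    clusters separated by >= ``se_separation`` even when adjacent; the
    half-cell distance to the flanking TSSs keeps every cluster peak
    >= 2.5 kb away from any TSS.
    """
    per_chrom: dict[str, tuple[int, int]] = {}
    for g in genes:
        lo, hi = per_chrom.get(g.chrom, (10**12, -1))
        per_chrom[g.chrom] = (min(lo, g.cell_index), max(hi, g.cell_index))
    candidates: list[tuple[str, int]] = []
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        n_here = max(g.cell_index for g in genes if g.chrom == chrom) + 1
        cell = cfg.chrom_length // n_here
        first_ok = len(TF_FACTORS) + 1 if c == 0 else 1  # keep clear of TF genes
        for b in range(first_ok, n_here):
            candidates.append((chrom, b * cell))
    if cfg.n_planted_se > len(candidates):
        raise ValueError("not enough intergenic room for the requested SE count")
    chosen = rng.choice(len(candidates), size=cfg.n_planted_se, replace=False)
    clusters = []
    half = cfg.se_cluster_span // 2
    for i in sorted(int(j) for j in chosen):
        chrom, center = candidates[i]
        n_peaks = int(rng.integers(cfg.se_cluster_size[0], cfg.se_cluster_size[1] + 1))
        # evenly spaced constituents with bounded jitter: consecutive gaps
        # stay far below the 12.5 kb stitch distance, so every planted
        # cluster stitches into a single region
        spacing = cfg.se_cluster_span / max(1, n_peaks - 1)
        base = center - half + spacing * np.arange(n_peaks)
        wobble = rng.uniform(-spacing / 3, spacing / 3, size=n_peaks)
        centers = np.sort(np.round(base + wobble).astype(int))
        clusters.append({"chrom": chrom, "center": center, "peak_centers": [int(x) for x in centers]})
    return clusters


def _jitter(rng: np.random.Generator, sd: float) -> int:
    return int(round(rng.normal(0.0, sd))) if sd > 0 else 0


def simulate_tiered_expression(
    rng: np.random.Generator,
    n_per_tier: int = 100,
    delta: float = 1.0,
    mu: float = 3.0,
    sigma: float = 1.0,
    n_samples: int = 2,
):
    """Stem-cell expression table with a planted per-tier boost.

    Returns ``(expr DataFrame in TPM, gene->group mapping)`` for tiers
    1..5 with ``n_per_tier`` genes each; tier-k genes get a log2 boost of
    ``delta * k``.  Used both by the full generator and directly when only
    the expression gradient is under study.
    """
    import pandas as pd

    rows = {}
    groups = {}
    for tier in range(1, 6):
        for i in range(n_per_tier):
            gene = f"t{tier}_g{i:03d}"
            log2 = rng.normal(mu + delta * tier, sigma, size=n_samples)
            rows[gene] = np.round(2.0**log2, 3)
            groups[gene] = f"G{6 - tier}"
    expr = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"TSC_{i + 1}" for i in range(n_samples)]
    )
    return expr, groups


def simulate(config: SimConfig, outdir: str | Path) -> TruthManifest:
    """Generate the full miniature study under ``outdir``.

    Deterministic given ``config.seed``: running twice with the same seed
    produces byte-identical files.  Returns the ground-truth manifest
    (also written as ``manifest.json``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    (outdir / "tags").mkdir(exist_ok=True)
    (outdir / "deg").mkdir(exist_ok=True)

    genes = _make_genes(config, rng)
    sites = _assign_classes_and_sites(config, genes, rng)
    clusters = _place_se_clusters(config, genes, rng)
    regular = [g for g in genes if not g.is_tf]

    # ------------------------------------------------------------- peaks
    def peak_at(chrom: str, center: int, factor: str, width: int, score: float) -> Peak:
        half = width // 2
        start = max(0, center - half)
        return Peak(chrom, start, start + width, score=round(score, 3), factor=factor)

    peaks_a: dict[str, list[Peak]] = {f: [] for f in ALL_FACTORS}
    ep300_weights: list[tuple[Peak, float]] = []
    for s in sites:
        for f in s["factors"]:
            c = s["center"] + _jitter(rng, config.jitter_sd)
            peaks_a[f].append(peak_at(s["chrom"], c, f, 300, 100.0))
        # modest tier-proportional EP300 occupancy: enough to order the
        # G1..G5 metaprofiles while keeping every background peak well
        # below the signal_ratio of planted SE constituents
        w = (1.0 + 0.08 * (s["tier"] - 1)) * float(np.exp(rng.normal(0.0, 0.1)))
        c = s["center"] + _jitter(rng, config.jitter_sd)
        p = peak_at(s["chrom"], c, "EP300", 300, 10.0 * w)
        peaks_a["EP300"].append(p)
        ep300_weights.append((p, w))

    # TF core: every TF binds every TF gene (its own included) at a
    # factor-specific offset, planting the fully interconnected circuitry
    tf_genes = [g for g in genes if g.is_tf]
    for fi, f in enumerate(TF_FACTORS):
        offset = 3000 + 1500 * fi
        for g in tf_genes:
            c = g.tss + offset + _jitter(rng, config.jitter_sd)
            peaks_a[f].append(peak_at(g.chrom, c, f, 300, 100.0))

    se_truth = []
    for cl in clusters:
        placed = []
        for c in cl["peak_centers"]:
            w = config.signal_ratio * float(np.exp(rng.normal(0.0, 0.25)))
            p = peak_at(cl["chrom"], c + _jitter(rng, config.jitter_sd), "EP300", 400, 10.0 * w)
            peaks_a["EP300"].append(p)
            ep300_weights.append((p, w))
            placed.append(p)
        se_truth.append(
            {
                "chrom": cl["chrom"],
                "start": min(p.start for p in placed),
                "end": max(p.end for p in placed),
            }
        )

    # H3K27ac-like peaks: EP300 peaks re-jittered/widened with 5% dropout
    h3k27ac = []
    for p, _w in ep300_weights:
        if rng.random() < 0.05:
            continue
        c = p.center + int(rng.integers(-200, 201))
        h3k27ac.append(peak_at(p.chrom, c, "H3K27ac", p.length * 2, p.score))
    peaks_a["H3K27ac"] = h3k27ac

    for f, plist in peaks_a.items():
        write_bed(sorted(plist, key=lambda p: (p.chrom, p.start)), outdir / "peaks" / f"{f}_human.bed")

    # species B: per-gene count-driven placement
    peaks_b: dict[str, list[Peak]] = {f: [] for f in ALL_FACTORS}
    for g in regular:
        cb = g.count_b
        if cb == 0:
            continue
        if cb == 6:
            chosen = list(ALL_FACTORS)
        else:
            extra = rng.choice(len(TF_FACTORS), size=cb - 1, replace=False) if cb > 1 else []
            chosen = ["EP300"] + [TF_FACTORS[i] for i in sorted(extra)]
        slots = rng.choice(len(SITE_SLOTS), size=min(len(chosen), len(SITE_SLOTS)), replace=False)
        for f, si in zip(chosen, list(slots) * 2):
            c = g.tss + SITE_SLOTS[int(si)] + _jitter(rng, config.jitter_sd)
            peaks_b[f].append(peak_at(g.chrom, c, f, 300, 100.0))
    for f, plist in peaks_b.items():
        write_bed(sorted(plist, key=lambda p: (p.chrom, p.start)), outdir / "peaks" / f"{f}_mouse.bed")

    # ------------------------------------------------------- annotations
    def gene_model(g: _Gene, suffix: str) -> GeneModel:
        if g.is_tf:
            sym = g.symbol if suffix == "_h" else g.symbol.capitalize()
        else:
            sym = g.symbol + suffix
        return GeneModel(
            name=sym,
            transcript_id=f"tx{g.idx:04d}{suffix}",
            chrom=g.chrom,
            strand=g.strand,
            tx_start=g.tx_start,
            tx_end=g.tx_end,
            exons=g.exons,
        )

    models_a = [gene_model(g, "_h") for g in genes]
    models_b = [gene_model(g, "_m") for g in genes]
    write_refflat(models_a, outdir / "refflat_human.txt")
    write_refflat(models_b, outdir / "refflat_mouse.txt")

    with open(outdir / "orthologs.tsv", "w") as fh:
        fh.write("symbol_a\tsymbol_b\n")
        for g in regular:
            fh.write(f"{g.symbol}_h\t{g.symbol}_m\n")

    # -------------------------------------------------------- tag tracks
    chrom_names = sorted({g.chrom for g in genes})
    n_bg = int(round(config.tag_depth * config.background_frac))
    n_peak_tags = config.tag_depth - n_bg

    def uniform_tags(n: int) -> list[tuple[str, int]]:
        chroms = rng.choice(len(chrom_names), size=n)
        pos = rng.integers(200, config.chrom_length - 200, size=n)
        return [(chrom_names[int(c)], int(p)) for c, p in zip(chroms, pos)]

    weights = np.array([w for _, w in ep300_weights])
    alloc = rng.multinomial(n_peak_tags, weights / weights.sum())
    treat: list[tuple[str, int]] = uniform_tags(n_bg)
    for (p, _w), n in zip(ep300_weights, alloc):
        if n == 0:
            continue
        pos = np.clip(
            np.round(rng.normal(p.center, config.tag_spread, size=n)),
            p.start,
            p.end - 1,
        ).astype(int)
        treat.extend((p.chrom, int(x)) for x in pos)
    control = uniform_tags(config.tag_depth)

    def write_tags(tags: list[tuple[str, int]], path: Path) -> None:
        with open(path, "w") as fh:
            for chrom, mid in sorted(tags):
                fh.write(f"{chrom}\t{mid - 100}\t{mid + 100}\n")

    write_tags(treat, outdir / "tags" / "ep300_treatment.bed")
    write_tags(control, outdir / "tags" / "input_control.bed")

    # orthogonal H3K27ac track, same depth and tag model as EP300
    h3_weights = np.array([p.score for p in h3k27ac])
    h3_alloc = rng.multinomial(n_peak_tags, h3_weights / h3_weights.sum())
    h3_treat: list[tuple[str, int]] = uniform_tags(n_bg)
    for p, n in zip(h3k27ac, h3_alloc):
        if n == 0:
            continue
        pos = np.clip(
            np.round(rng.normal(p.center, config.tag_spread, size=n)),
            p.start,
            p.end - 1,
        ).astype(int)
        h3_treat.extend((p.chrom, int(x)) for x in pos)
    write_tags(h3_treat, outdir / "tags" / "h3k27ac_treatment.bed")

    # SE target genes, assigned with the package's own rule on the truth regions
    ann_a = GeneAnnotation(models_a)
    for rec in se_truth:
        pseudo = Peak(rec["chrom"], rec["start"], rec["end"], factor="SE")
        rec["genes"] = sorted({a.gene for a in assign_targets([pseudo], ann_a)})

    # -------------------------------------------------------- expression
    def expr_table(models: list[GeneModel], tiers: dict[str, int], path: Path) -> dict[str, float]:
        stem_mean: dict[str, float] = {}
        with open(path, "w") as fh:
            fh.write("gene\t" + "\t".join(SAMPLES) + "\n")
            for m in models:
                k = tiers.get(m.name, 0)
                vals = []
                for s in SAMPLES:
                    boost = config.tier_effect * k if s in STEM_SAMPLES else 0.0
                    vals.append(round(2.0 ** rng.normal(config.expr_mu + boost, config.expr_sigma), 3))
                stem_mean[m.name] = float(np.mean(vals[: len(STEM_SAMPLES)]))
                fh.write(m.name + "\t" + "\t".join(f"{v}" for v in vals) + "\n")
        return stem_mean

    tiers_a = {g.symbol + "_h": g.tier_a for g in regular}
    tiers_a.update({g.symbol: 5 for g in tf_genes})
    tiers_b = {g.symbol + "_m": g.tier_b for g in regular}
    tiers_b.update({g.symbol.capitalize(): 5 for g in tf_genes})
    expr_table(models_a, tiers_a, outdir / "expression_human.tsv")
    expr_table(models_b, tiers_b, outdir / "expression_mouse.tsv")

    # --------------------------------------------- deregulated gene list
    by_tier: dict[int, list[_Gene]] = {}
    for g in regular:
        by_tier.setdefault(g.tier_a, []).append(g)
    dereg: list[str] = []
    for tier, members in sorted(by_tier.items()):
        if tier == 0:
            rate = config.dereg_base_rate
        else:
            rate = config.dereg_base_rate * (
                1.0 + (config.dereg_g1_factor - 1.0) * (tier - 1) / 4.0
            )
        n_pick = int(round(rate * len(members)))
        picked = rng.choice(len(members), size=n_pick, replace=False)
        dereg.extend(members[int(i)].symbol + "_h" for i in sorted(picked))
    dereg.sort()
    (outdir / "deregulated_genes.txt").write_text("\n".join(dereg) + "\n")

    # --------------------------------------------------- knockdown DEGs
    tf_modes = {f: ("repressor" if f == "TFAP2C" else "activator") for f in TF_FACTORS}

    def lfc(down: bool) -> float:
        mag = 0.8 + float(rng.exponential(0.7))
        return round(-mag if down else mag, 3)

    for f in TF_FACTORS:
        activator = tf_modes[f] == "activator"
        rows = []
        for g in regular:
            sym = g.symbol + "_h"
            tier = g.tier_a
            r = rng.random()
            flip = rng.random() < 0.15  # a minority of targets responds contrarily
            if tier == 5 and r < 0.7:
                rows.append((sym, lfc(down=activator != flip)))
            elif tier <= 1 and r < 0.25:
                rows.append((sym, lfc(down=(not activator) != flip)))
            elif 2 <= tier <= 4 and r < 0.15:
                rows.append((sym, lfc(down=rng.random() < 0.5)))
        with open(outdir / "deg" / f"{f}_kd_deg.tsv", "w") as fh:
            fh.write("gene\tlog2fc\tpadj\n")
            for sym, fc in rows:
                padj = 10.0 ** (-rng.uniform(3, 8))
                fh.write(f"{sym}\t{fc}\t{padj:.3e}\n")

    # ----------------------------------------------------------- manifest
    manifest = TruthManifest(
        {
            "config": dataclasses.asdict(config),
            "factors": list(ALL_FACTORS),
            "tf_modes": tf_modes,
            "sites": [
                {
                    "chrom": s["chrom"],
                    "center": s["center"],
                    "tier": s["tier"],
                    "factors": s["factors"],
                    "gene": s["gene"] + "_h",
                }
                for s in sites
            ],
            "se_regions": se_truth,
            "genes": {
                g.symbol
                + "_h": {
                    "ortholog": g.symbol + "_m",
                    "tier_a": g.tier_a,
                    "tier_b": g.tier_b,
                    "count_a": g.count_a,
                    "count_b": g.count_b,
                    "species_class": g.species_class,
                    "enrichment_class": species_enriched(
                        2.0 ** (config.expr_mu + config.tier_effect * g.tier_a),
                        2.0 ** (config.expr_mu + config.tier_effect * g.tier_b),
                    ),
                }
                for g in regular
            },
            "dereg_genes": dereg,
        }
    )
    manifest.save(outdir / "manifest.json")
    return manifest
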