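"""End-to-end orchestration over a study directory.

``run_all`` executes the stages in dependency order — super-enhancer
calling, peak annotation, co-occupancy grouping with expression and
enrichment, regulatory-network motifs, cross-species comparison and DEG
integration — on a directory laid out like the synthetic generator's
output (which is also the documented input contract for user data).
Every stage writes its TSV outputs and a JSON summary; the run is fully
deterministic given its inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import annotation as ann_mod
from . import cooccupancy as co_mod
from . import cross_species as cs_mod
from . import deg as deg_mod
from . import network as net_mod
from . import superenhancer as se_mod
from .intervals import cluster_cobound, read_bed, write_regions_bed, Peak
from .synthetic import ALL_FACTORS, TF_FACTORS

__all__ = ["RunConfig", "run_all"]

logger = logging.getLogger(__name__)

# defaults match the published analysis settings
DEFAULTS = {
    "window": 500,
    "stitch_gap": 12_500,
    "tss_exclusion": 2_500,
    "flank": 20_000,
    "promoter_halfwidth": 2_000,
    "fold": 2.0,
    "low_max": 2,
}


@dataclass
class RunConfig:
    indir: str
    outdir: str
    window: int = DEFAULTS["window"]
    stitch_gap: int = DEFAULTS["stitch_gap"]
    tss_exclusion: int = DEFAULTS["tss_exclusion"]
    flank: int = DEFAULTS["flank"]
    promoter_halfwidth: int = DEFAULTS["promoter_halfwidth"]
    fold: float = DEFAULTS["fold"]
    low_max: int = DEFAULTS["low_max"]
    seed: int = 0

    def validate(self) -> None:
        for name in ("window", "stitch_gap", "tss_exclusion", "flank", "promoter_halfwidth"):
            v = getattr(self, name)
            if name == "window" and v <= 0:
                raise ValueError("window must be > 0")
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.fold <= 1:
            raise ValueError("fold must be > 1")


def _required_paths(indir: Path) -> list[Path]:
    paths = [
        indir / "refflat_human.txt",
        indir / "refflat_mouse.txt",
        indir / "orthologs.tsv",
        indir / "expression_human.tsv",
        indir / "expression_mouse.tsv",
        indir / "deregulated_genes.txt",
        indir / "tags" / "ep300_treatment.bed",
        indir / "tags" / "input_control.bed",
    ]
    paths += [indir / "peaks" / f"{f}_human.bed" for f in ALL_FACTORS]
    paths += [indir / "peaks" / f"{f}_mouse.bed" for f in ALL_FACTORS]
    paths += [indir / "deg" / f"{f}_kd_deg.tsv" for f in TF_FACTORS]
    return paths


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the combined summary (also written as JSON)."""
    config.validate()
    indir, outdir = Path(config.indir), Path(config.outdir)
    missing = [str(p) for p in _required_paths(indir) if not p.exists()]
    if missing:
        raise FileNotFoundError("missing input files:\n" + "\n".join(missing))
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    logging.getLogger().addHandler(fh)
    logger.info("run_all parameters: %s", dataclasses.asdict(config))

    summary: dict = {"parameters": dataclasses.asdict(config)}
    ann = ann_mod.read_refflat(indir / "refflat_human.txt")
    tf_peaks = {
        f: read_bed(indir / "peaks" / f"{f}_human.bed", factor=f) for f in TF_FACTORS
    }
    ep300 = read_bed(indir / "peaks" / "EP300_human.bed", factor="EP300")
    treatment = se_mod.read_tag_bed(indir / "tags" / "ep300_treatment.bed")
    control = se_mod.read_tag_bed(indir / "tags" / "input_control.bed")

    # stage 1: super-enhancers -------------------------------------------
    se_result = se_mod.call_superenhancers(
        ep300,
        treatment,
        control,
        ann,
        stitch_gap=config.stitch_gap,
        tss_exclusion=config.tss_exclusion,
    )
    se_mod.write_ranked_regions(se_result, outdir / "se_ranked_regions.tsv")
    write_regions_bed(se_result.se_regions(), outdir / "se_calls.bed")
    (outdir / "se_genes.txt").write_text("\n".join(se_result.se_genes) + "\n")
    summary["se_calls"] = {
        "n_regions": len(se_result.regions),
        "n_se": se_result.n_se,
        "cutoff_score": se_result.cutoff_score,
        "n_se_genes": len(se_result.se_genes),
    }
    logger.info("stage se_calls done: %s", summary["se_calls"])

    # stage 2: feature annotation ----------------------------------------
    counts = {c: 0 for c in ann_mod.FEATURE_CLASSES}
    with open(outdir / "ep300_features.tsv", "w") as out:
        out.write("chrom\tstart\tend\tfeature\n")
        for p in ep300:
            feat = ann_mod.classify_feature(p, ann, config.promoter_halfwidth)
            counts[feat] += 1
            out.write(f"{p.chrom}\t{p.start}\t{p.end}\t{feat}\n")
    summary["feature_counts"] = counts
    logger.info("stage annotate done: %s", counts)

    # stage 3: co-occupancy ----------------------------------------------
    sites = cluster_cobound(list(tf_peaks.values()), window=config.window)
    site_targets = {}
    for i, s in enumerate(sites):
        pseudo = Peak(s.chrom, max(0, s.span_start - 1), s.span_end + 1, factor="site")
        site_targets[i] = {
            a.gene for a in ann_mod.assign_targets([pseudo], ann, flank=config.flank)
        }
    gene_groups = co_mod.gene_group_assignment(sites, site_targets)
    expr = pd.read_csv(indir / "expression_human.tsv", sep="\t", index_col=0)
    dists, pmat = co_mod.group_expression(gene_groups, expr, samples=["TSC_1", "TSC_2"])
    dereg = {
        line.strip()
        for line in (indir / "deregulated_genes.txt").read_text().splitlines()
        if line.strip()
    }
    universe = ann.symbols()
    enrich = []
    for grp in co_mod.GROUPS:
        members = {g for g, lab in gene_groups.items() if lab == grp}
        if members:
            enrich.append(co_mod.hypergeom_enrichment(members, dereg & universe, universe, group=grp))
    co_mod.write_enrichment(enrich, outdir / "group_enrichment.tsv")
    pmat.to_csv(outdir / "group_expression_pvalues.tsv", sep="\t")
    with open(outdir / "gene_groups.tsv", "w") as out:
        out.write("gene\tgroup\n")
        for g in sorted(gene_groups):
            out.write(f"{g}\t{gene_groups[g]}\n")
    summary["cooccupancy"] = {
        "n_sites": len(sites),
        "group_sizes": {
            grp: sum(1 for v in gene_groups.values() if v == grp) for grp in co_mod.GROUPS
        },
        "g1_vs_g5_p": float(pmat.loc["G1", "G5"]) if {"G1", "G5"} <= set(pmat.index) else None,
        "enrichment": [dataclasses.asdict(e) for e in enrich],
    }
    logger.info("stage cooccupancy done")

    # stage 4: regulatory network ----------------------------------------
    assignments = {
        f: ann_mod.assign_targets(ps, ann, flank=config.flank) for f, ps in tf_peaks.items()
    }
    assignments["EP300"] = ann_mod.assign_targets(ep300, ann, flank=config.flank)
    net = net_mod.build_network(assignments, motif_tfs=TF_FACTORS)
    motifs = net_mod.count_motifs(net)
    net_mod.write_network(net, outdir / "network_edges.tsv", outdir / "network.sif")
    net_mod.write_motifs(motifs, outdir / "motif_counts.json")
    summary["network"] = dataclasses.asdict(motifs)
    logger.info("stage network done: %s", summary["network"])

    # stage 5: cross-species ---------------------------------------------
    ann_b = ann_mod.read_refflat(indir / "refflat_mouse.txt")
    orthologs = cs_mod.read_ortholog_map(indir / "orthologs.tsv")
    targets_a = {
        f: {a.gene for a in assignments[f]} for f in ALL_FACTORS
    }
    targets_b = {}
    for f in ALL_FACTORS:
        ps = read_bed(indir / "peaks" / f"{f}_mouse.bed", factor=f)
        targets_b[f] = {a.gene for a in ann_mod.assign_targets(ps, ann_b, flank=config.flank)}
    expr_b = pd.read_csv(indir / "expression_mouse.tsv", sep="\t", index_col=0)
    expr_a_stem = expr[["TSC_1", "TSC_2"]].mean(axis=1).to_dict()
    expr_b_stem = expr_b[["TSC_1", "TSC_2"]].mean(axis=1).to_dict()
    records = cs_mod.classify_genes(
        orthologs,
        targets_a,
        targets_b,
        expr_a_stem,
        expr_b_stem,
        low_max=config.low_max,
        fold=config.fold,
    )
    cs_mod.write_species_records(records, outdir / "species_classes.tsv")
    universe_pairs = [r.gene_a for r in records]
    sim_targets = {(f, "human"): targets_a[f] for f in ALL_FACTORS}
    sim_targets.update(
        {(f, "mouse"): {orthologs.b_to_a[g] for g in targets_b[f] if g in orthologs.b_to_a} for f in ALL_FACTORS}
    )
    pearson, jaccard = cs_mod.target_similarity(sim_targets, universe_pairs)
    pearson.to_csv(outdir / "target_pearson.tsv", sep="\t")
    jaccard.to_csv(outdir / "target_jaccard.tsv", sep="\t")
    summary["cross_species"] = {
        "species_class_counts": {
            cls: sum(1 for r in records if r.species_class == cls)
            for cls in ("common", "HMFB", "MMFB", "other")
        },
        "n_orthologs": len(orthologs),
    }
    logger.info("stage cross_species done: %s", summary["cross_species"])

    # stage 6: DEG integration -------------------------------------------
    fully = {g for g, lab in gene_groups.items() if lab == "G1"}
    sparse = {g for g, lab in gene_groups.items() if lab == "G5"}
    sparse |= ann.symbols() - set(gene_groups) - fully
    deg_summary = {}
    with open(outdir / "deg_summary.tsv", "w") as out:
        out.write(
            "tf\tn_deg\tpct_direct\tfully_down\tfully_up\tfully_ratio\t"
            "sparse_down\tsparse_up\tsparse_ratio\n"
        )
        for f in TF_FACTORS:
            degs = deg_mod.read_deg_table(indir / "deg" / f"{f}_kd_deg.tsv")
            split = deg_mod.split_direct(degs, targets_a[f])
            full_r, sparse_r = deg_mod.repression_activation_ratio(degs, fully, sparse)
            deg_summary[f] = {
                "n_deg": len(degs),
                "pct_direct": split.pct_direct_overall,
                "fully_bound_ratio": None if full_r.infinite else full_r.ratio,
                "sparsely_bound_ratio": None if sparse_r.infinite else sparse_r.ratio,
            }
            out.write(
                f"{f}\t{len(degs)}\t{split.pct_direct_overall:.2f}\t"
                f"{full_r.n_down}\t{full_r.n_up}\t"
                f"{'inf' if full_r.infinite else f'{full_r.ratio:.3f}'}\t"
                f"{sparse_r.n_down}\t{sparse_r.n_up}\t"
                f"{'inf' if sparse_r.infinite else f'{sparse_r.ratio:.3f}'}\n"
            )
    summary["deg"] = deg_summary
    logger.info("stage deg done")

    with open(outdir / "summary.json", "w") as out:
        json.dump(summary, out, indent=1, sort_keys=True)
        out.write("\n")
    logging.getLogger().removeHandler(fh)
    fh.close()
    return summary
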