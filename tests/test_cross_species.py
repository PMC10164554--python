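import math

import numpy as np
import pytest

from _oracles import pearson_binary
from tscreg.cross_species import (
    OrthologMap,
    bound_counts,
    classify_genes,
    classify_species_group,
    species_enriched,
    target_similarity,
)


class TestBoundCounts:
    def test_all_and_none(self):
        targets = {f: {"g"} for f in "ABCDEF"}
        assert bound_counts("g", targets) == 6
        assert bound_counts("x", targets) == 0

    def test_matches_membership_oracle(self, rng):
        genes = [f"g{i}" for i in range(50)]
        targets = {
            f"F{j}": {g for g in genes if rng.random() < 0.4} for j in range(6)
        }
        for g in genes:
            expected = sum(1 for s in targets.values() if g in s)
            assert bound_counts(g, targets) == expected


class TestSpeciesClass:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (6, 6, "common"),
            (6, 2, "HMFB"),
            (6, 0, "HMFB"),
            (1, 6, "MMFB"),
            (2, 6, "MMFB"),
            (6, 3, "other"),
            (3, 6, "other"),
            (5, 5, "other"),
            (0, 0, "other"),
        ],
    )
    def test_classification_rule(self, a, b, expected):
        assert classify_species_group(a, b) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_species_group(7, 0)

    def test_classes_partition_ortholog_list(self, rng):
        orth = OrthologMap([(f"g{i}_h", f"g{i}_m") for i in range(100)])
        counts_a = {f"g{i}_h": int(rng.integers(0, 7)) for i in range(100)}
        counts_b = {f"g{i}_m": int(rng.integers(0, 7)) for i in range(100)}
        targets_a = {f"F{j}": {g for g, c in counts_a.items() if c > j} for j in range(6)}
        targets_b = {f"F{j}": {g for g, c in counts_b.items() if c > j} for j in range(6)}
        records = classify_genes(orth, targets_a, targets_b, {}, {})
        assert len(records) == 100
        assert all(
            r.species_class in {"common", "HMFB", "MMFB", "other"} for r in records
        )


class TestSpeciesEnriched:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(10, 1, "A-enriched"), (1, 10, "B-enriched"), (3, 3, "neither"), (0, 0, "neither")],
    )
    def test_fold_rule_with_pseudocount(self, a, b, expected):
        assert species_enriched(a, b) == expected

    def test_negative_expression_rejected(self):
        with pytest.raises(ValueError):
            species_enriched(-1, 0)


class TestOrthologMap:
    def test_one_to_one_enforced(self):
        with pytest.raises(ValueError):
            OrthologMap([("a", "x"), ("a", "y")])
        with pytest.raises(ValueError):
            OrthologMap([("a", "x"), ("b", "x")])


class TestTargetSimilarity:
    def test_identical_sets_unit_similarity(self):
        universe = [f"g{i}" for i in range(10)]
        sets = {("F1", "h"): {"g0", "g1"}, ("F1", "m"): {"g0", "g1"}}
        pearson, jaccard = target_similarity(sets, universe)
        assert pearson.iloc[0, 1] == pytest.approx(1.0)
        assert jaccard.iloc[0, 1] == pytest.approx(1.0)

    def test_complementary_half_sets_anticorrelated(self):
        universe = [f"g{i}" for i in range(10)]
        sets = {("A", "h"): set(universe[:5]), ("B", "h"): set(universe[5:])}
        pearson, _ = target_similarity(sets, universe)
        assert pearson.iloc[0, 1] == pytest.approx(-1.0)

    def test_constant_vector_reported_missing(self):
        universe = ["g0", "g1"]
        sets = {("A", "h"): set(universe), ("B", "h"): {"g0"}}
        pearson, _ = target_similarity(sets, universe)
        assert math.isnan(pearson.iloc[0, 1])

    def test_matches_formula_oracle_on_random_sets(self, rng):
        universe = [f"g{i}" for i in range(40)]
        for _ in range(50):
            sa = {g for g in universe if rng.random() < 0.5}
            sb = {g for g in universe if rng.random() < 0.5}
            pearson, jaccard = target_similarity({("A", "h"): sa, ("B", "h"): sb}, universe)
            expected = pearson_binary(sa, sb, universe)
            if expected is None:
                assert math.isnan(pearson.iloc[0, 1])
            else:
                assert pearson.iloc[0, 1] == pytest.approx(expected, abs=1e-12)
            if sa or sb:
                assert jaccard.iloc[0, 1] == pytest.approx(
                    len(sa & sb) / len(sa | sb)
                )


class TestPlantedRecovery:
    def test_species_classes_match_manifest(self, noisefree_sim):
        import pandas as pd

        manifest = noisefree_sim["manifest"]
        rec = pd.read_csv(
            noisefree_sim["outdir"] / "species_classes.tsv", sep="\t", index_col=0
        )
        mismatches = [
            g
            for g, info in manifest["genes"].items()
            if rec.loc[g, "species_class"] != info["species_class"]
        ]
        assert mismatches == []

    def test_bound_counts_separate_enriched_groups(self, default_sim):
        """Genes expressed higher in one species carry more factors there."""
        import pandas as pd
        from scipy import stats

        rec = pd.read_csv(
            default_sim["outdir"] / "species_classes.tsv", sep="\t", index_col=0
        )
        a_enriched = rec[rec.enrichment_class == "A-enriched"].bound_count_a
        b_enriched = rec[rec.enrichment_class == "B-enriched"].bound_count_a
        assert a_enriched.median() > b_enriched.median()
        p = stats.mannwhitneyu(a_enriched, b_enriched, alternative="greater").pvalue
        assert p < 0.01

    def test_expression_difference_monotone_in_count_difference(self, default_sim):
        import pandas as pd

        rec = pd.read_csv(
            default_sim["outdir"] / "species_classes.tsv", sep="\t", index_col=0
        )
        rec["count_diff"] = rec.bound_count_a - rec.bound_count_b
        rec["expr_diff"] = np.log2(rec.expr_a + 1) - np.log2(rec.expr_b + 1)
        buckets = {
            "low": rec[rec.count_diff <= -3].expr_diff.mean(),
            "mid": rec[rec.count_diff.abs() < 3].expr_diff.mean(),
            "high": rec[rec.count_diff >= 3].expr_diff.mean(),
        }
        assert buckets["low"] < buckets["mid"] < buckets["high"]
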