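"""Comparison of pipeline output against a ground-truth manifest."""

from __future__ import annotations

from typing import Mapping, Sequence

__all__ = ["se_precision_recall", "species_class_accuracy"]


def se_precision_recall(
    called: Sequence[tuple[str, int, int]],
    truth: Sequence[tuple[str, int, int]],
) -> tuple[float, float]:
    """Precision/recall of called SE regions against planted clusters.

    A planted cluster is recovered when a called region fully contains it
    (stitched calls always cover their constituents); a called region is a
    true positive when it contains at least one planted cluster.
    """

    def contains(region, cluster):
        return (
            region[0] == cluster[0]
            and region[1] <= cluster[1]
            and cluster[2] <= region[2]
        )

    tp_called = sum(1 for r in called if any(contains(r, t) for t in truth))
    recovered = sum(1 for t in truth if any(contains(r, t) for r in called))
    precision = tp_called / len(called) if called else 0.0
    recall = recovered / len(truth) if truth else 1.0
    return precision, recall


def species_class_accuracy(
    recovered: Mapping[str, str], truth: Mapping[str, str]
) -> float:
    """Fraction of manifest genes whose recovered class matches the truth."""
    if not truth:
        raise ValueError("empty truth mapping")
    hits = sum(1 for g, cls in truth.items() if recovered.get(g) == cls)
    return hits / len(truth)
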