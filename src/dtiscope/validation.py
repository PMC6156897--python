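"""Cross-reference evaluation: overlap of ranked predictions with known edges.

Given a D-score-ranked list of predicted interactions and an independent
reference edge list (in the real setting: STITCH, DGIdb or CTD; in tests:
held-out planted truth), the sliding-window overlap curve counts how many
pairs in each window of ``bin_width`` consecutive ranks appear in the
reference. A predictor whose top-ranked pairs are enriched for reference
edges produces a curve that decays from left to right.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Set, Tuple

from dtiscope.scoring import RankedPrediction

__all__ = ["ReferenceSet", "OverlapCurve", "overlap_count", "sliding_overlap"]


@dataclass
class ReferenceSet:
    """A named set of reference (drug, gene) edges; de-duplicated, trimmed."""

    name: str
    edges: Set[Tuple[str, str]]

    def __post_init__(self) -> None:
        self.edges = {(d.strip(), g.strip()) for d, g in self.edges}


@dataclass
class OverlapCurve:
    bin_width: int
    bin_start_ranks: List[int]
    overlap_counts: List[int]

    def __post_init__(self) -> None:
        if len(self.bin_start_ranks) != len(self.overlap_counts):
            raise ValueError("curve lists misaligned")
        if any(c < 0 or c > self.bin_width for c in self.overlap_counts):
            raise ValueError("overlap counts must lie in [0, bin_width]")


def overlap_count(ranked: List[RankedPrediction], ref: ReferenceSet) -> int:
    """Number of ranked pairs present in the reference set (exact key match)."""
    if not ranked:
        raise ValueError("ranked list is empty")
    if not ref.edges:
        raise ValueError(f"reference set {ref.name!r} is empty")
    return sum(
        1 for r in ranked if (r.drug_id.strip(), r.gene_id.strip()) in ref.edges
    )


def sliding_overlap(
    ranked: List[RankedPrediction],
    ref: ReferenceSet,
    bin_width: int = 500,
    step: int = 1,
) -> OverlapCurve:
    """Overlap counts over sliding windows of consecutive ranked pairs.

    Window starts run s = 0, step, 2*step, ... while s + bin_width fits;
    step = bin_width gives disjoint bins.
    """
    if bin_width < 1 or step < 1:
        raise ValueError("bin_width and step must be positive")
    if bin_width > len(ranked):
        raise ValueError(
            f"bin_width {bin_width} exceeds ranked list length {len(ranked)}"
        )
    member = [
        1 if (r.drug_id.strip(), r.gene_id.strip()) in ref.edges else 0 for r in ranked
    ]
    if not ref.edges:
        raise ValueError(f"reference set {ref.name!r} is empty")
    starts, counts = [], []
    window = sum(member[:bin_width])
    s = 0
    while s + bin_width <= len(ranked):
        starts.append(s)
        counts.append(window)
        # advance by `step`: subtract leavers, add entrants
        if s + step + bin_width <= len(ranked):
            window -= sum(member[s : s + step])
            window += sum(member[s + bin_width : s + bin_width + step])
        s += step
    return OverlapCurve(bin_width=bin_width, bin_start_ranks=starts, overlap_counts=counts)
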