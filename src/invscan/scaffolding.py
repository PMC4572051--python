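"""Reference-guided scaffold placement, gap estimation and superscaffolding.

Draft scaffolds are anchored to the reference region with unique k-mers,
their order and orientation taken from the dominant anchor chain, inter-
scaffold gaps estimated by projecting scaffold ends onto reference
coordinates, and the ordered, oriented scaffolds concatenated with N runs
into a superscaffold described by AGP v2.0 rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import SequenceRecord
from .synteny import (
    DEFAULT_K,
    DEFAULT_MAX_DIAG_DRIFT,
    DEFAULT_MAX_GAP,
    DEFAULT_MAX_OCCURRENCES,
    SyntenyBlock,
    chain_anchors,
    find_anchors,
)


@dataclass
class ScaffoldPlacement:
    """Placement of one scaffold on the reference."""

    scaffold_id: str
    t_start: int
    t_end: int
    orientation: str
    anchor_support: int
    est_gap_to_next: int | None = None
    overlaps_next: bool = False
    minority_coverage_bp: int = 0  # anchor coverage chained in the other orientation

    @property
    def t_interval(self) -> tuple[int, int]:
        return (self.t_start, self.t_end)


@dataclass
class Superscaffold:
    """An ordered, oriented concatenation of scaffolds with gap N-runs."""

    record: SequenceRecord
    components: list[ScaffoldPlacement]
    agp: pd.DataFrame


def _project_extent(blocks: list[SyntenyBlock], scaffold_len: int) -> tuple[int, int]:
    """Project the scaffold extent onto the target through its chains.

    Each scaffold edge is projected through the same-orientation block nearest
    to that edge in query space, so a scaffold whose interior rearranges (e.g.
    spans an inversion) still gets accurate end coordinates from its flanking
    chains.
    """
    strand = blocks[0].strand
    if strand == "+":
        lead = min(blocks, key=lambda b: b.q_span[0])  # closest to query start
        trail = min(blocks, key=lambda b: scaffold_len - b.q_span[1])
        start = lead.t_span[0] - lead.q_span[0]
        end = trail.t_span[1] + (scaffold_len - trail.q_span[1])
    else:  # query start maps to the target end
        lead = min(blocks, key=lambda b: b.q_span[0])
        trail = min(blocks, key=lambda b: scaffold_len - b.q_span[1])
        end = lead.t_span[1] + lead.q_span[0]
        start = trail.t_span[0] - (scaffold_len - trail.q_span[1])
    return max(0, start), end


def place_scaffolds(
    scaffolds: list[SequenceRecord],
    target: SequenceRecord,
    k: int = DEFAULT_K,
    max_occurrences: int = DEFAULT_MAX_OCCURRENCES,
    max_gap: int = DEFAULT_MAX_GAP,
    max_diag_drift: int = DEFAULT_MAX_DIAG_DRIFT,
    min_block_anchors: int = 1,
) -> tuple[list[ScaffoldPlacement], list[str]]:
    """Place each scaffold on the target by its dominant anchor chain.

    Orientation is decided by majority anchor coverage across all chains of
    the scaffold (a scaffold spanning an inversion breakpoint chains in both
    orientations; the dominant-coverage rule decides and the minority coverage
    is recorded). Scaffolds with no unique anchors are returned separately as
    unplaced. Placements are sorted by target interval.
    """
    placements: list[ScaffoldPlacement] = []
    unplaced: list[str] = []
    for scf in scaffolds:
        anchors = find_anchors(scf, target, k=k, max_occurrences=max_occurrences)
        blocks = chain_anchors(
            anchors, max_gap=max_gap, max_diag_drift=max_diag_drift, min_block_anchors=min_block_anchors
        )
        if not blocks:
            unplaced.append(scf.id)
            continue
        cov = {"+": 0, "-": 0}
        for b in blocks:
            cov[b.strand] += b.coverage_bp
        orientation = "+" if cov["+"] >= cov["-"] else "-"
        same = [b for b in blocks if b.strand == orientation]
        biggest = max(b.coverage_bp for b in same)
        # drop stray micro-blocks so they cannot hijack the edge projection
        same = [b for b in same if b.coverage_bp >= 0.1 * biggest]
        t0, t1 = _project_extent(same, len(scf))
        placements.append(
            ScaffoldPlacement(
                scaffold_id=scf.id,
                t_start=t0,
                t_end=t1,
                orientation=orientation,
                anchor_support=sum(b.n_anchors for b in same),
                minority_coverage_bp=cov["-" if orientation == "+" else "+"],
            )
        )
    placements.sort(key=lambda p: (p.t_start, p.t_end))
    return placements, unplaced


def estimate_gaps(placements: list[ScaffoldPlacement]) -> list[ScaffoldPlacement]:
    """Fill in estimated gaps between consecutive placements.

    The gap is the reference-projected distance between scaffold ends; a
    negative projected distance (overlap) is reported as 0 with the overlap
    annotated.
    """
    ordered = sorted(placements, key=lambda p: (p.t_start, p.t_end))
    for cur, nxt in zip(ordered, ordered[1:]):
        raw = nxt.t_start - cur.t_end
        cur.est_gap_to_next = max(0, raw)
        cur.overlaps_next = raw < 0
    if ordered:
        ordered[-1].est_gap_to_next = None
        ordered[-1].overlaps_next = False
    return ordered


def placements_to_frame(placements: list[ScaffoldPlacement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scaffold_id": p.scaffold_id,
                "t_start": p.t_start,
                "t_end": p.t_end,
                "orientation": p.orientation,
                "anchor_support": p.anchor_support,
                "est_gap_to_next": p.est_gap_to_next,
                "overlaps_next": p.overlaps_next,
                "minority_coverage_bp": p.minority_coverage_bp,
            }
            for p in placements
        ]
    )


_AGP_COLUMNS = [
    "object",
    "object_beg",
    "object_end",
    "part_number",
    "component_type",
    "component_id",
    "component_beg",
    "component_end",
    "orientation",
]


def build_superscaffold(
    placements: list[ScaffoldPlacement],
    scaffolds: list[SequenceRecord],
    gap_fill: str = "N",
    object_id: str = "superscaffold",
) -> Superscaffold:
    """Concatenate placed scaffolds (oriented) with N-runs at estimated gaps.

    Unknown or zero-length gaps get a single N (AGP requires a positive gap
    between components). Emits AGP v2.0-style rows: W lines for scaffold
    components, N lines for gaps.
    """
    by_id = {s.id: s for s in scaffolds}
    ordered = sorted(placements, key=lambda p: (p.t_start, p.t_end))
    for p in ordered:
        if p.scaffold_id not in by_id:
            raise ValueError(f"placement references unknown scaffold {p.scaffold_id!r}")

    parts: list[str] = []
    rows: list[dict] = []
    pos = 0
    part_no = 0
    for i, p in enumerate(ordered):
        scf = by_id[p.scaffold_id]
        seq = scf.seq if p.orientation == "+" else scf.reverse_complement().seq
        part_no += 1
        rows.append(
            {
                "object": object_id,
                "object_beg": pos + 1,
                "object_end": pos + len(seq),
                "part_number": part_no,
                "component_type": "W",
                "component_id": p.scaffold_id,
                "component_beg": 1,
                "component_end": len(seq),
                "orientation": p.orientation,
            }
        )
        parts.append(seq)
        pos += len(seq)
        if i < len(ordered) - 1:
            gap = p.est_gap_to_next if p.est_gap_to_next else 0
            gap = max(1, gap)
            part_no += 1
            rows.append(
                {
                    "object": object_id,
                    "object_beg": pos + 1,
                    "object_end": pos + gap,
                    "part_number": part_no,
                    "component_type": "N",
                    "component_id": gap,  # gap length in the component_id slot, per AGP
                    "component_beg": "scaffold",
                    "component_end": "yes",
                    "orientation": "align_genus",
                }
            )
            parts.append(gap_fill * gap)
            pos += gap
    record = SequenceRecord(id=object_id, seq="".join(parts), build_tag="superscaffold")
    agp = pd.DataFrame(rows, columns=_AGP_COLUMNS)
    return Superscaffold(record=record, components=ordered, agp=agp)


def write_agp(superscaffold: Superscaffold, path) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version 2.0\n")
        superscaffold.agp.to_csv(fh, sep="\t", header=False, index=False)


def read_agp(path) -> pd.DataFrame:
    """Read AGP rows back (round-trip safe with :func:`write_agp`)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=_AGP_COLUMNS)
    return df
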