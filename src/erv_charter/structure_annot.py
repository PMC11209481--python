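"""Per-element structural annotation against the reference provirus.

Each locus sequence is aligned semi-globally to the full consensus
(end gaps free, affine gap penalties); the alignment yields per-region
completeness percentages and a list of insertions/deletions in
consensus coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from Bio import Align

from .reference_model import REGION_LABELS, ReferenceProvirus

GAP = "-"


@dataclass(frozen=True)
class PairwiseAlignment:
    """Gapped reference/element string pair with its score."""

    aligned_ref: str
    aligned_elem: str
    score: float
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.aligned_ref) != len(self.aligned_elem):
            raise ValueError("aligned rows must have equal length")
        for a, b in zip(self.aligned_ref, self.aligned_elem):
            if a == GAP and b == GAP:
                raise ValueError("column with gaps in both rows")

    @property
    def ref_seq(self) -> str:
        return self.aligned_ref.replace(GAP, "")

    @property
    def elem_seq(self) -> str:
        return self.aligned_elem.replace(GAP, "")


@dataclass(frozen=True)
class RegionCompleteness:
    """Percent of each reference region covered by aligned element bases."""

    percent: Mapping[str, float]

    def rounded(self) -> dict[str, float]:
        return {label: round(value, 2) for label, value in self.percent.items()}


@dataclass(frozen=True)
class IndelAnnotation:
    """(kind, 1-based consensus position, length) events.

    Deletions give the first deleted consensus base; insertions give the
    consensus position they follow (0 for an insertion before base 1).
    """

    events: tuple[tuple[str, int, int], ...]

    def deletions(self) -> list[tuple[int, int]]:
        return [(pos, ln) for kind, pos, ln in self.events if kind == "deletion"]

    def insertions(self) -> list[tuple[int, int]]:
        return [(pos, ln) for kind, pos, ln in self.events if kind == "insertion"]


def align_global(
    element: str,
    reference: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
    free_end_gaps: bool = True,
) -> PairwiseAlignment:
    """Optimal semi-global alignment of an element to the consensus.

    With ``free_end_gaps`` (the default) terminal gaps are unpenalized,
    so a truncated element pays nothing for the consensus it never had.
    The first optimal path reported by the aligner is used, which gives
    a deterministic trace.
    """
    if not element or not reference:
        raise ValueError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    if free_end_gaps:
        try:
            aligner.open_end_insertion_score = 0.0
            aligner.extend_end_insertion_score = 0.0
            aligner.open_end_deletion_score = 0.0
            aligner.extend_end_deletion_score = 0.0
        except AttributeError:  # older Biopython
            aligner.target_end_open_gap_score = 0.0
            aligner.target_end_extend_gap_score = 0.0
            aligner.query_end_open_gap_score = 0.0
            aligner.query_end_extend_gap_score = 0.0
    alignments = aligner.align(reference.upper(), element.upper())
    best = alignments[0]
    return PairwiseAlignment(
        aligned_ref=str(best[0]),
        aligned_elem=str(best[1]),
        score=best.score,
        params={
            "match": match,
            "mismatch": mismatch,
            "gap_open": gap_open,
            "gap_extend": gap_extend,
        },
    )


def region_completeness(
    alignment: PairwiseAlignment, reference: ReferenceProvirus
) -> RegionCompleteness:
    """Fraction of each region's consensus positions aligned to a base.

    Overlapping regions are scored independently: a covered base in the
    gag/pro overlap counts toward both. Values are percentages in
    [0, 100].
    """
    if alignment.ref_seq != reference.sequence:
        raise ValueError("alignment reference row does not match the consensus")
    covered = [False] * (reference.total_length + 1)  # 1-based
    ref_pos = 0
    for r, e in zip(alignment.aligned_ref, alignment.aligned_elem):
        if r != GAP:
            ref_pos += 1
            if e != GAP:
                covered[ref_pos] = True
    percent = {}
    for label in REGION_LABELS:
        start, end = reference.regions[label]
        n_cov = sum(covered[start : end + 1])
        percent[label] = 100.0 * n_cov / (end - start + 1)
    return RegionCompleteness(percent=percent)


def annotate_indels(
    alignment: PairwiseAlignment, min_len: int = 1
) -> IndelAnnotation:
    """Maximal gap runs of the alignment, in consensus coordinates."""
    events: list[tuple[str, int, int]] = []
    ref_pos = 0  # last consumed 1-based consensus position
    open_kind: str | None = None
    open_pos = 0
    open_len = 0

    def _close() -> None:
        nonlocal open_kind, open_len
        if open_kind is not None and open_len >= min_len:
            events.append((open_kind, open_pos, open_len))
        open_kind = None
        open_len = 0

    for r, e in zip(alignment.aligned_ref, alignment.aligned_elem):
        if r != GAP and e != GAP:
            _close()
            ref_pos += 1
        elif e == GAP:  # deletion relative to the consensus
            if open_kind != "deletion":
                _close()
                open_kind = "deletion"
                open_pos = ref_pos + 1
            open_len += 1
            ref_pos += 1
        else:  # insertion relative to the consensus
            if open_kind != "insertion":
                _close()
                open_kind = "insertion"
                open_pos = ref_pos
            open_len += 1
    _close()
    return IndelAnnotation(events=tuple(events))


def write_alignment_fasta(
    alignments: Mapping[str, PairwiseAlignment], path: str | Path
) -> None:
    """Export gapped element rows (plus the consensus) as aligned FASTA.

    Hand-off format for external phylogenetics; rows are written as
    pairwise projections onto the consensus, one record per element.
    """
    with open(path, "w") as fh:
        for name, alignment in alignments.items():
            # project the element onto ungapped consensus coordinates
            row = []
            for r, e in zip(alignment.aligned_ref, alignment.aligned_elem):
                if r != GAP:
                    row.append(e)
            fh.write(f">{name}\n{''.join(row)}\n")
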