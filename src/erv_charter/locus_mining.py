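"""Turn similarity hits into classified, named ERV loci.

A locus is either a *provirus* (its match to the consensus covers
internal coding bases) or a *solo LTR* (the match lies entirely inside
an LTR region and covers at least 90% of the LTR model). Completeness
is the aligned fraction of the full reference provirus, binned into
deciles for reporting.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .genome_io import AlignmentHit, GenomicInterval, reverse_complement
from .reference_model import ReferenceProvirus


class ClassificationError(ValueError):
    """A candidate matches neither the LTR nor the internal region."""


@dataclass(frozen=True)
class ErvLocus:
    name: str
    interval: GenomicInterval
    element_class: str  # 'provirus' | 'solo_ltr'
    completeness: float  # aligned / reference length, fraction in [0, 1]
    completeness_bin: str
    q_gap_ratio: float = 0.0
    context: str | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.element_class not in ("provirus", "solo_ltr"):
            raise ValueError(f"unknown element class {self.element_class!r}")
        if not (0 <= self.completeness <= 1):
            raise ValueError("completeness must be a fraction in [0, 1]")

    @property
    def element_length(self) -> int:
        return self.interval.length

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass(frozen=True)
class CandidateElement:
    """Chained hits from one query forming one putative locus."""

    target: GenomicInterval
    q_start: int
    q_end: int
    matches: int
    mismatches: int
    q_gap_bases: int
    n_hits: int = 1

    @property
    def aligned(self) -> int:
        return self.matches + self.mismatches

    @property
    def q_gap_ratio(self) -> float:
        denom = self.aligned + self.q_gap_bases
        return self.q_gap_bases / denom if denom else 0.0


# ---------------------------------------------------------------------------
# Built-in seed-and-extend search (naive BLAT stand-in for toy genomes)
# ---------------------------------------------------------------------------

def seed_extend_search(
    genome: Mapping[str, str],
    query: str,
    k: int = 12,
    min_identity: float = 0.75,
    min_hit_len: int = 30,
    window: int = 16,
) -> list[AlignmentHit]:
    """Exact k-mer seeds chained along diagonals with ungapped extension.

    Both strands are searched; minus-strand hits are reported with query
    coordinates normalized to plus-strand query space. Extension from
    each seed run proceeds base by base until the identity of the last
    ``window`` compared bases drops below ``min_identity``; terminal
    mismatches are trimmed. Output is deterministic (sorted by target
    interval, then strand).
    """
    query = query.upper()
    if k < 8:
        raise ValueError("k must be >= 8")
    if k > len(query):
        raise ValueError("k larger than query")
    if not genome:
        raise ValueError("empty genome")

    hits: list[AlignmentHit] = []
    for strand, q in (("+", query), ("-", reverse_complement(query))):
        seed_index: dict[str, list[int]] = defaultdict(list)
        for i in range(len(q) - k + 1):
            kmer = q[i : i + k]
            if "N" not in kmer:
                seed_index[kmer].append(i)
        for chrom, seq in genome.items():
            seq = seq.upper()
            diagonals: dict[int, list[int]] = defaultdict(list)  # diag -> q pos
            for g in range(len(seq) - k + 1):
                for qpos in seed_index.get(seq[g : g + k], ()):
                    diagonals[g - qpos].append(qpos)
            for diag, qposs in diagonals.items():
                spans = []
                for q0, q1 in _merge_seed_runs(sorted(qposs), k, max_skip=3 * k):
                    span = _extend_ungapped(
                        seq, q, diag, q0, q1, min_identity, window
                    )
                    if span is not None:
                        spans.append(span[:2])
                # a local mismatch cluster can stop extension mid-element;
                # same-diagonal spans separated by a short gap are one hit
                for qs, qe in _merge_spans(spans, max_join=3 * window):
                    if qe - qs < min_hit_len:
                        continue
                    matches = sum(
                        q[i] == seq[i + diag] and q[i] != "N"
                        for i in range(qs, qe)
                    )
                    mismatches = (qe - qs) - matches
                    t0, t1 = qs + diag, qe + diag
                    if strand == "-":
                        qs, qe = len(q) - qe, len(q) - qs
                    hits.append(
                        AlignmentHit(
                            query="query",
                            target=GenomicInterval(chrom, t0, t1, strand),
                            q_start=qs,
                            q_end=qe,
                            matches=matches,
                            mismatches=mismatches,
                            q_gap_bases=0,
                            strand=strand,
                        )
                    )
    hits = _drop_shadow_hits(hits)
    hits.sort(key=lambda h: (h.target.chrom, h.target.start, h.target.end, h.strand))
    return hits


def _merge_seed_runs(
    qposs: list[int], k: int, max_skip: int
) -> list[tuple[int, int]]:
    """Merge sorted seed start positions on one diagonal into runs."""
    runs: list[tuple[int, int]] = []
    start = prev = qposs[0]
    for qpos in qposs[1:]:
        if qpos - prev <= max_skip:
            prev = qpos
        else:
            runs.append((start, prev + k))
            start = prev = qpos
    runs.append((start, prev + k))
    return runs


def _merge_spans(
    spans: list[tuple[int, int]], max_join: int
) -> list[tuple[int, int]]:
    """Union overlapping or nearly adjacent (start, end) spans."""
    if not spans:
        return []
    spans = sorted(spans)
    merged = [spans[0]]
    for qs, qe in spans[1:]:
        ps, pe = merged[-1]
        if qs - pe <= max_join:
            merged[-1] = (ps, max(pe, qe))
        else:
            merged.append((qs, qe))
    return merged


def _extend_ungapped(
    seq: str,
    q: str,
    diag: int,
    q0: int,
    q1: int,
    min_identity: float,
    window: int,
) -> tuple[int, int, int, int] | None:
    """Extend [q0, q1) along ``diag`` in both directions.

    Extension stops when the identity over the last ``window`` compared
    bases falls below ``min_identity``; the reported end is then rolled
    back to the best-scoring endpoint (match +1, mismatch -2), so a hit
    never overruns into unrelated flanking sequence.
    """

    def compare(qpos: int) -> bool:
        a, b = q[qpos], seq[qpos + diag]
        return a == b and a != "N"

    # right extension
    right = best_right = q1
    score = best_score = 0
    recent: list[bool] = []
    while right < len(q) and right + diag < len(seq):
        ok = compare(right)
        recent.append(ok)
        if len(recent) > window:
            recent.pop(0)
        if len(recent) == window and sum(recent) / window < min_identity:
            break
        score += 1 if ok else -2
        right += 1
        if score > best_score:
            best_score, best_right = score, right
    right = best_right
    # left extension
    left = best_left = q0
    score = best_score = 0
    recent = []
    while left > 0 and left + diag > 0:
        ok = compare(left - 1)
        recent.append(ok)
        if len(recent) > window:
            recent.pop(0)
        if len(recent) == window and sum(recent) / window < min_identity:
            break
        score += 1 if ok else -2
        left -= 1
        if score > best_score:
            best_score, best_left = score, left
    left = best_left
    # trim terminal mismatches
    while left < right and not compare(left):
        left += 1
    while right > left and not compare(right - 1):
        right -= 1
    if right <= left:
        return None
    matches = sum(compare(i) for i in range(left, right))
    return left, right, matches, right - left - matches


def _drop_shadow_hits(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Drop hits whose target interval is mostly inside a stronger hit.

    The two identical LTR copies of the reference each match every
    genomic LTR, producing duplicate hits at the same locus; only the
    best-supported one is kept.
    """
    kept: list[AlignmentHit] = []
    for hit in sorted(hits, key=lambda h: (-h.aligned, h.target)):
        iv = hit.target
        shadowed = False
        for other in kept:
            if other.target.chrom != iv.chrom or other.strand != hit.strand:
                continue
            overlap = min(other.target.end, iv.end) - max(other.target.start, iv.start)
            if overlap > 0.5 * iv.length:
                shadowed = True
                break
        if not shadowed:
            kept.append(hit)
    return kept


# ---------------------------------------------------------------------------
# Chaining
# ---------------------------------------------------------------------------

def chain_hits(
    hits: Iterable[AlignmentHit],
    max_gap: int = 5000,
    colinear_slop: int = 30,
) -> list[CandidateElement]:
    """Merge colinear same-chromosome, same-strand hits into candidates.

    Hits chain when the target gap is at most ``max_gap`` and the query
    spans advance colinearly (consensus order on '+', reversed on '-').
    Unaligned query bases between chained hits are accumulated as query
    gap bases — internal deletions of an element show up there.
    """
    groups: dict[tuple[str, str], list[AlignmentHit]] = defaultdict(list)
    for hit in hits:
        groups[(hit.target.chrom, hit.strand)].append(hit)

    candidates: list[CandidateElement] = []
    for (chrom, strand), group in sorted(groups.items()):
        group.sort(key=lambda h: (h.target.start, h.target.end))
        open_chain: list[AlignmentHit] = []
        for hit in group:
            if open_chain and _chainable(open_chain[-1], hit, max_gap, colinear_slop):
                open_chain.append(hit)
            else:
                if open_chain:
                    candidates.append(_aggregate(open_chain))
                open_chain = [hit]
        if open_chain:
            candidates.append(_aggregate(open_chain))
    candidates.sort(key=lambda c: (c.target.chrom, c.target.start, c.target.end))
    return candidates


def _chainable(
    prev: AlignmentHit, nxt: AlignmentHit, max_gap: int, slop: int
) -> bool:
    t_gap = nxt.target.start - prev.target.end
    if t_gap > max_gap or t_gap < -slop:
        return False
    if prev.strand == "+":
        return nxt.q_start >= prev.q_end - slop
    return nxt.q_end <= prev.q_start + slop


def _aggregate(chain: list[AlignmentHit]) -> CandidateElement:
    strand = chain[0].strand
    t_start = min(h.target.start for h in chain)
    t_end = max(h.target.end for h in chain)
    q_start = min(h.q_start for h in chain)
    q_end = max(h.q_end for h in chain)
    q_gap = sum(h.q_gap_bases for h in chain)
    # unaligned query bases between consecutive chained hits
    ordered = chain if strand == "+" else list(reversed(chain))
    for a, b in zip(ordered, ordered[1:]):
        q_gap += max(0, b.q_start - a.q_end)
    return CandidateElement(
        target=GenomicInterval(chain[0].target.chrom, t_start, t_end, strand),
        q_start=q_start,
        q_end=q_end,
        matches=sum(h.matches for h in chain),
        mismatches=sum(h.mismatches for h in chain),
        q_gap_bases=q_gap,
        n_hits=len(chain),
    )


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

COMPLETENESS_DECILES = [
    "(0-10%)", "(10-20%)", "(20-30%)", "(30-40%)", "(40-50%)",
    "(50-60%)", "(60-70%)", "(70-80%)", "(80-90%)", "(90-100%)",
]


def decile_bin(ratio: float) -> str:
    return COMPLETENESS_DECILES[min(int(ratio * 10), 9)]


def classify_element(
    candidate: CandidateElement,
    reference: ReferenceProvirus,
    solo_ltr_min_frac: float = 0.9,
    deletion_threshold: float = 0.10,
    insertion_threshold: int = 100,
    boundary_slop: int = 10,
) -> ErvLocus:
    """Classify a chained candidate as provirus or solo LTR.

    A candidate whose matched consensus span stays inside an LTR region
    and covers at least ``solo_ltr_min_frac`` of the LTR model is a solo
    LTR; any candidate reaching internal coding bases is a provirus.
    Candidates covering neither are rejected.
    """
    f0, f1 = reference.region_slice("five_ltr")
    t0, t1 = reference.region_slice("three_ltr")
    qs, qe = candidate.q_start, candidate.q_end

    internal_overlap = min(qe, t0) - max(qs, f1)
    in_five = qs >= f0 - boundary_slop and qe <= f1 + boundary_slop
    in_three = qs >= t0 - boundary_slop and qe <= t1 + boundary_slop

    if in_five or in_three:
        if candidate.aligned < solo_ltr_min_frac * reference.ltr_length:
            raise ClassificationError(
                f"LTR-only candidate at {candidate.target.chrom}:"
                f"{candidate.target.start}-{candidate.target.end} covers only "
                f"{candidate.aligned}/{reference.ltr_length} LTR bases "
                f"(< {solo_ltr_min_frac:.0%})"
            )
        element_class = "solo_ltr"
    elif internal_overlap > boundary_slop:
        element_class = "provirus"
    else:
        raise ClassificationError(
            "candidate span covers neither LTR nor internal consensus bases"
        )

    completeness = min(candidate.aligned / reference.total_length, 1.0)
    flags = []
    if candidate.q_gap_ratio > deletion_threshold:
        flags.append("deletion")
    if candidate.target.length - (qe - qs) > insertion_threshold:
        flags.append("insertion")
    return ErvLocus(
        name="",
        interval=candidate.target,
        element_class=element_class,
        completeness=completeness,
        completeness_bin=decile_bin(completeness),
        q_gap_ratio=candidate.q_gap_ratio,
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# Completeness banding
# ---------------------------------------------------------------------------

COMPLETENESS_BANDS = (">70%", "40-70%", "<40%")


def bin_completeness(ratios: Iterable[float]) -> dict:
    """Count completeness ratios per band and per decile.

    Bands partition [0, 1] as (0.70, 1] / [0.40, 0.70] / [0, 0.40): a
    ratio of exactly 0.70 falls in the middle band, matching the common
    reading of 'longer than 70%'.
    """
    bands = {band: 0 for band in COMPLETENESS_BANDS}
    deciles: Counter[str] = Counter()
    n = 0
    for ratio in ratios:
        if hasattr(ratio, "completeness"):  # accept loci too
            ratio = ratio.completeness
        n += 1
        if ratio > 0.70:
            bands[">70%"] += 1
        elif ratio >= 0.40:
            bands["40-70%"] += 1
        else:
            bands["<40%"] += 1
        deciles[decile_bin(ratio)] += 1
    assert sum(bands.values()) == n
    return {"bands": bands, "deciles": dict(deciles), "n": n}


# ---------------------------------------------------------------------------
# Naming
# ---------------------------------------------------------------------------

def name_locus(
    interval: GenomicInterval,
    assembly: str,
    cytobands: Sequence[tuple[str, int, int, str]] | None = None,
) -> str:
    """Name one locus by cytogenetic band, or assembly/position fallback.

    ``cytobands`` rows are (chrom, start0, end0, band), e.g.
    ('chr16', 0, 10400000, 'p13.3'). Without a band table the name is
    '<assembly>_<chrom>_<1-based start>'.
    """
    if cytobands:
        mid = int(interval.midpoint)
        for chrom, start, end, band in cytobands:
            if chrom == interval.chrom and start <= mid < end:
                return interval.chrom.removeprefix("chr") + band
    return f"{assembly}_{interval.chrom}_{interval.start1}"


def name_loci(
    loci: Sequence[ErvLocus],
    assembly: str,
    cytobands: Sequence[tuple[str, int, int, str]] | None = None,
) -> list[ErvLocus]:
    """Assign unique names; collisions get deterministic a, b, ... suffixes."""
    ordered = sorted(loci, key=lambda l: (l.interval.chrom, l.interval.start))
    base_names = [name_locus(l.interval, assembly, cytobands) for l in ordered]
    counts = Counter(base_names)
    seen: Counter[str] = Counter()
    named = []
    for locus, base in zip(ordered, base_names):
        if counts[base] > 1:
            suffix = chr(ord("a") + seen[base])
            seen[base] += 1
            name = base + suffix
        else:
            name = base
        named.append(replace(locus, name=name))
    return named


def mine_loci(
    hits: Iterable[AlignmentHit],
    reference: ReferenceProvirus,
    assembly: str = "asm",
    max_gap: int = 5000,
    solo_ltr_min_frac: float = 0.9,
    cytobands: Sequence[tuple[str, int, int, str]] | None = None,
) -> list[ErvLocus]:
    """Full mining pipeline: chain hits, classify, and name the loci.

    Candidates failing classification (too little of the consensus
    matched) are dropped with a log-free rejection — they are the
    sub-threshold BLAT noise a curator would discard.
    """
    loci = []
    for candidate in chain_hits(hits, max_gap=max_gap):
        try:
            loci.append(
                classify_element(
                    candidate, reference, solo_ltr_min_frac=solo_ltr_min_frac
                )
            )
        except ClassificationError:
            continue
    return name_loci(loci, assembly, cytobands)


# ---------------------------------------------------------------------------
# Homolog bookkeeping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HomologyLedger:
    """Locus sets of two genomes plus a user-supplied pairing by name."""

    loci_a: tuple[ErvLocus, ...]
    loci_b: tuple[ErvLocus, ...]
    pairing: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        names_a = {l.name for l in self.loci_a}
        names_b = {l.name for l in self.loci_b}
        seen_a: set[str] = set()
        seen_b: set[str] = set()
        for a, b in self.pairing:
            if a not in names_a:
                raise ValueError(f"pair references unknown A locus {a!r}")
            if b not in names_b:
                raise ValueError(f"pair references unknown B locus {b!r}")
            if a in seen_a or b in seen_b:
                raise ValueError(f"locus appears in more than one pair: {a!r}/{b!r}")
            seen_a.add(a)
            seen_b.add(b)


def compare_homologs(ledger: HomologyLedger) -> dict[str, int]:
    """Partition both locus sets into shared and species-specific counts."""
    class_of_a = {l.name: l.element_class for l in ledger.loci_a}
    paired_a = {a for a, _ in ledger.pairing}
    paired_b = {b for _, b in ledger.pairing}
    shared_proviruses = sum(
        1 for a, _ in ledger.pairing if class_of_a[a] == "provirus"
    )
    return {
        "shared": len(ledger.pairing),
        "shared_proviruses": shared_proviruses,
        "shared_solo_ltrs": len(ledger.pairing) - shared_proviruses,
        "a_specific": len(ledger.loci_a) - len(paired_a),
        "b_specific": len(ledger.loci_b) - len(paired_b),
    }
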