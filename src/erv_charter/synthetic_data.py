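"""Synthetic genomes with planted ERV structure and known ground truth.

The generator emulates the observable footprint of germline ERV
fixation: a provirus is an LTR-internal-LTR copy of the reference
inserted with a target-site duplication, whose every site then
substitutes independently with probability r*tau (linear clock, rate r
per nucleotide per My, age tau My; the two LTRs diverge independently).
Solo LTRs arise by removing the internal span plus one LTR, truncations
by deleting explicit consensus intervals. Background sequence is
i.i.d. uniform, so the built-in search sees no repeat structure it did
not plant itself.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .genome_io import GeneModel, GenomicInterval, reverse_complement
from .reference_model import DEFAULT_LAYOUT, REGION_LABELS, ReferenceProvirus

BASES = np.array(list("ACGT"))

REFERENCE_SPAN = 8608  # canonical provirus length the layout is scaled from


@dataclass(frozen=True)
class SyntheticTruth:
    """Ledger row for one planted element."""

    name: str
    interval: GenomicInterval
    element_class: str  # 'provirus' | 'solo_ltr'
    age_my: float
    rate: float
    deleted: tuple[tuple[int, int], ...] = ()  # 1-based consensus intervals
    tsd_len: int = 5
    pbs_present: bool = True

    def __post_init__(self) -> None:
        if self.age_my < 0:
            raise ValueError("age must be >= 0")


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def scaled_layout(total_length: int) -> dict[str, tuple[int, int]]:
    """The canonical region proportions scaled to ``total_length``.

    The two LTRs are forced to equal length and pinned to the sequence
    ends; interior boundaries scale linearly.
    """
    scale = total_length / REFERENCE_SPAN
    regions = {
        label: (
            max(1, round((start - 1) * scale) + 1),
            min(total_length, round(end * scale)),
        )
        for label, (start, end) in DEFAULT_LAYOUT.items()
    }
    ltr_len = regions["five_ltr"][1]
    regions["five_ltr"] = (1, ltr_len)
    regions["three_ltr"] = (total_length - ltr_len + 1, total_length)
    return regions


def make_reference(
    seed: int, total_length: int = REFERENCE_SPAN, name: str = "synthetic_consensus"
) -> ReferenceProvirus:
    """Random consensus with two identical LTRs at scaled proportions."""
    rng = np.random.default_rng(seed)
    layout = (
        dict(DEFAULT_LAYOUT) if total_length == REFERENCE_SPAN
        else scaled_layout(total_length)
    )
    seq = list(random_sequence(rng, total_length))
    f0, f1 = layout["five_ltr"][0] - 1, layout["five_ltr"][1]
    t0, t1 = layout["three_ltr"][0] - 1, layout["three_ltr"][1]
    seq[t0:t1] = seq[f0:f1]  # identical LTR copies at age 0
    return ReferenceProvirus(name=name, sequence="".join(seq), regions=layout)


def reference_pbs(reference: ReferenceProvirus, offset: int = 3, length: int = 18) -> str:
    """The reference's own PBS window (just downstream of the 5' LTR)."""
    ltr_end = reference.regions["five_ltr"][1]
    return reference.sequence[ltr_end + offset : ltr_end + offset + length]


def mutate_sequence(
    seq: str, age_my: float, rate: float, rng: np.random.Generator
) -> str:
    """Per-site Bernoulli substitution with probability min(rate*age, 0.75)."""
    p = min(rate * age_my, 0.75)
    if p <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < p
    if hit.any():
        # uniform over the three alternative bases
        shifts = rng.integers(1, 4, size=int(hit.sum()))
        idx = np.searchsorted(BASES, arr[hit])
        arr[hit] = BASES[(idx + shifts) % 4]
    return "".join(arr)


def implant_provirus(
    seq: str,
    reference: ReferenceProvirus,
    position: int,
    age_my: float,
    rate: float = 0.002,
    tsd_len: int = 5,
    rng: np.random.Generator | int | None = None,
    strand: str = "+",
    name: str = "provirus",
    chrom: str = "chr1",
    existing: Sequence[SyntheticTruth] = (),
) -> tuple[str, SyntheticTruth]:
    """Insert a mutated reference copy with a target-site duplication.

    The host bases at [position, position+tsd_len) are duplicated to
    flank the insert. All sites of the copy (both LTRs included)
    substitute independently, so the expected LTR-LTR divergence is the
    2-LTR clock's input. Raises if the position falls inside a
    previously planted element.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if not (0 <= position <= len(seq) - tsd_len):
        raise ValueError("position outside genome")
    for prior in existing:
        if prior.interval.chrom == chrom and prior.interval.start <= position < prior.interval.end:
            raise ValueError(
                f"position {position} overlaps planted element {prior.name!r}"
            )
    copy = mutate_sequence(reference.sequence, age_my, rate, rng)
    if strand == "-":
        copy = reverse_complement(copy)
    start = position + tsd_len
    new_seq = seq[: position + tsd_len] + copy + seq[position:]
    truth = SyntheticTruth(
        name=name,
        interval=GenomicInterval(chrom, start, start + len(copy), strand),
        element_class="provirus",
        age_my=age_my,
        rate=rate,
        tsd_len=tsd_len,
    )
    return new_seq, truth


def make_solo_ltr(
    seq: str, truth: SyntheticTruth, reference: ReferenceProvirus
) -> tuple[str, SyntheticTruth]:
    """Recombine a planted provirus down to a single LTR.

    LTR-LTR homologous recombination excises the internal span together
    with one LTR, leaving one LTR between the original target-site
    duplications.
    """
    if truth.element_class != "provirus":
        raise ValueError("can only recombine a provirus")
    ltr_len = reference.ltr_length
    if truth.interval.length < 2 * ltr_len:
        raise ValueError("provirus lacks two LTRs")
    start, end = truth.interval.start, truth.interval.end
    new_seq = seq[: start + ltr_len] + seq[end:]
    ltr_end = reference.regions["five_ltr"][1]
    new_truth = replace(
        truth,
        interval=GenomicInterval(
            truth.interval.chrom, start, start + ltr_len, truth.interval.strand
        ),
        element_class="solo_ltr",
        deleted=truth.deleted + ((ltr_end + 1, reference.total_length),),
        pbs_present=False,
    )
    return new_seq, new_truth


def apply_truncation(
    seq: str,
    truth: SyntheticTruth,
    reference: ReferenceProvirus,
    consensus_interval: tuple[int, int],
) -> tuple[str, SyntheticTruth]:
    """Delete the element bases matching a 1-based consensus interval."""
    c0, c1 = consensus_interval
    L = reference.total_length
    if not (1 <= c0 <= c1 <= L):
        raise ValueError("interval outside consensus coordinates")
    if truth.interval.strand == "+":
        off0, off1 = c0 - 1, c1
    else:
        off0, off1 = L - c1, L - c0 + 1
    cut0 = truth.interval.start + off0
    cut1 = truth.interval.start + off1
    new_seq = seq[:cut0] + seq[cut1:]
    removed = cut1 - cut0
    new_truth = replace(
        truth,
        interval=GenomicInterval(
            truth.interval.chrom,
            truth.interval.start,
            truth.interval.end - removed,
            truth.interval.strand,
        ),
        deleted=truth.deleted + ((c0, c1),),
    )
    return new_seq, new_truth


def analytic_region_completeness(
    truth: SyntheticTruth, reference: ReferenceProvirus
) -> dict[str, float]:
    """Exact per-region completeness from the truth's deleted intervals."""
    percent = {}
    for label in REGION_LABELS:
        start, end = reference.regions[label]
        length = end - start + 1
        removed = 0
        for pos in range(start, end + 1):
            if any(c0 <= pos <= c1 for c0, c1 in truth.deleted):
                removed += 1
        percent[label] = 100.0 * (length - removed) / length
    return percent


# ---------------------------------------------------------------------------
# Whole-genome simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Simulation:
    genome: dict[str, str]
    reference: ReferenceProvirus
    truths: tuple[SyntheticTruth, ...]
    trnas: dict[str, str]


def simulate_genome(
    seed: int,
    chrom_length: int = 60_000,
    ref_length: int = 2_000,
    ages: Sequence[float] = (5.0, 10.0, 20.0, 30.0),
    n_solo: int = 3,
    rate: float = 0.002,
    tsd_len: int = 5,
    chrom: str = "chr1",
) -> Simulation:
    """Background chromosome with one provirus per age plus solo LTRs.

    Elements are planted left to right at evenly spaced background
    positions with seeded jitter; every coordinate in the returned truth
    ledger refers to the final genome. Bit-reproducible per seed.
    """
    rng = np.random.default_rng(seed)
    reference = make_reference(seed + 1, ref_length)
    background = random_sequence(rng, chrom_length)

    n_elements = len(ages) + n_solo
    slot = chrom_length // (n_elements + 1)
    if slot < 5500 + ref_length:
        raise ValueError(
            "chromosome too short for the requested element count: elements "
            "closer than the default chaining gap would merge into one locus"
        )
    plans: list[tuple[int, float, str, bool]] = []  # (bg position, age, strand, solo?)
    for i in range(n_elements):
        pos = (i + 1) * slot + int(rng.integers(-slot // 8, slot // 8))
        age = ages[i] if i < len(ages) else float(ages[int(rng.integers(0, len(ages)))])
        strand = "+" if rng.random() < 0.5 else "-"
        plans.append((pos, age, strand, i >= len(ages)))
    plans.sort(key=lambda p: p[0])

    seq = background
    offset = 0  # accumulated length added left of the next plan
    truths: list[SyntheticTruth] = []
    for i, (pos, age, strand, solo) in enumerate(plans):
        kind = "solo" if solo else "provirus"
        prev_len = len(seq)
        seq, truth = implant_provirus(
            seq,
            reference,
            pos + offset,
            age,
            rate=rate,
            tsd_len=tsd_len,
            rng=rng,
            strand=strand,
            name=f"{kind}_{i + 1}",
            chrom=chrom,
            existing=truths,
        )
        if solo:
            seq, truth = make_solo_ltr(seq, truth, reference)
        truths.append(truth)
        offset += len(seq) - prev_len

    trnas = make_trnas(seed + 2, reference)
    return Simulation(
        genome={chrom: seq},
        reference=reference,
        truths=tuple(truths),
        trnas=trnas,
    )


def make_trnas(
    seed: int, reference: ReferenceProvirus, n_decoys: int = 19
) -> dict[str, str]:
    """A tRNA set whose lysine member primes the reference PBS.

    tRNA-Lys's 3'-terminal 18 nt are the reverse complement of the
    reference's own PBS window; decoy tRNAs are random 76-mers ending
    in CCA.
    """
    rng = np.random.default_rng(seed)
    pbs = reference_pbs(reference)
    trnas = {"tRNA-Lys": random_sequence(rng, 76 - 18) + reverse_complement(pbs)}
    for i in range(n_decoys):
        trnas[f"tRNA-decoy{i + 1:02d}"] = random_sequence(rng, 73) + "CCA"
    return trnas


# ---------------------------------------------------------------------------
# Toy gene annotation and gene sets
# ---------------------------------------------------------------------------

def make_gene_annotation(
    seed: int,
    n_genes: int,
    chrom_length: int,
    chrom: str = "chr1",
    loci: Sequence[GenomicInterval] | None = None,
    n_background_sets: int = 8,
) -> tuple[list[GeneModel], dict[str, set[str]]]:
    """Non-overlapping genes with exons, plus gene sets with one planted
    enrichment.

    When loci are supplied, the set ``PLANTED`` collects the genes whose
    basal-plus-extension regulatory domains the loci overlap, so an ORA
    of the locus-associated gene list must rank it first.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    slot = chrom_length // (n_genes + 1)
    genes: list[GeneModel] = []
    for i in range(n_genes):
        length = int(rng.integers(2_000, min(8_000, max(2_001, slot - 200))))
        start = (i + 1) * slot - length // 2 + int(rng.integers(-slot // 8, slot // 8))
        start = max(0, min(start, chrom_length - length - 1))
        strand = "+" if rng.random() < 0.5 else "-"
        body = GenomicInterval(chrom, start, start + length, strand)
        n_exons = int(rng.integers(2, 5))
        bounds = sorted(
            int(x) for x in rng.integers(0, length - 100, size=2 * n_exons)
        )
        exons = []
        for j in range(n_exons):
            e0, e1 = bounds[2 * j], bounds[2 * j + 1] + 100
            exons.append(GenomicInterval(chrom, start + e0, start + e1, strand))
        genes.append(GeneModel(f"GENE{i + 1:04d}", body, tuple(exons)))

    all_ids = [g.gene_id for g in genes]
    gene_sets: dict[str, set[str]] = {}
    for s in range(n_background_sets):
        size = int(rng.integers(5, max(6, min(30, n_genes))))
        members = rng.choice(all_ids, size=min(size, n_genes), replace=False)
        gene_sets[f"SET{s + 1:02d}"] = set(members)
    if loci:
        from .regulation import associate_loci, regulatory_domains

        domains = regulatory_domains(genes, chrom_lengths={chrom: chrom_length})
        hits = {a.gene_id for a in associate_loci(list(loci), domains)}
        if hits:
            gene_sets["PLANTED"] = hits
    return genes, gene_sets


def genes_to_gff3(genes: Sequence[GeneModel]) -> str:
    """Deterministic GFF3 text for a gene collection."""
    lines = ["##gff-version 3"]
    for gene in genes:
        b = gene.body
        lines.append(
            f"{b.chrom}\t.\tgene\t{b.start1}\t{b.end1}\t.\t{b.strand}\t.\t"
            f"ID={gene.gene_id}"
        )
        mrna_id = f"{gene.gene_id}.t1"
        lines.append(
            f"{b.chrom}\t.\tmRNA\t{b.start1}\t{b.end1}\t.\t{b.strand}\t.\t"
            f"ID={mrna_id};Parent={gene.gene_id}"
        )
        for j, exon in enumerate(gene.exons, start=1):
            lines.append(
                f"{exon.chrom}\t.\texon\t{exon.start1}\t{exon.end1}\t.\t"
                f"{exon.strand}\t.\tID={mrna_id}.e{j};Parent={mrna_id}"
            )
    return "\n".join(lines) + "\n"
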