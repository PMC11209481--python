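"""Regulatory gene association (basal-plus-extension) and ORA.

Each gene gets a basal regulatory domain of 5 kb upstream and 1 kb
downstream of its TSS (strand-aware); the domain is then extended
outward up to 1 Mb, stopping at the nearest neighboring basal domain
and at chromosome ends. A locus is associated with every gene whose
extended domain it overlaps. Candidate gene lists are tested against
gene-set categories with the hypergeometric upper tail and
Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_io import GeneModel, GenomicInterval

BASAL_UPSTREAM = 5000
BASAL_DOWNSTREAM = 1000
MAX_EXTENSION = 1_000_000

DISTANCE_BINS = ("<5kb", "5-50kb", "50-500kb", ">500kb")


@dataclass(frozen=True)
class RegulatoryDomain:
    gene_id: str
    tss: int  # 0-based
    strand: str
    basal: GenomicInterval
    extended: GenomicInterval

    def __post_init__(self) -> None:
        if not self.extended.contains(self.basal):
            raise ValueError("basal domain must lie within the extended domain")


def regulatory_domains(
    genes: Sequence[GeneModel],
    basal_up: int = BASAL_UPSTREAM,
    basal_down: int = BASAL_DOWNSTREAM,
    max_ext: int = MAX_EXTENSION,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[RegulatoryDomain]:
    """Basal-plus-extension domains for a set of genes.

    Extension on each side runs to the nearest of: ``max_ext`` past the
    basal edge, the closest neighboring basal domain boundary, and the
    chromosome end (when lengths are supplied).
    """
    basals: dict[str, GenomicInterval] = {}
    for gene in genes:
        tss = gene.tss
        if gene.strand == "+":
            start, end = tss - basal_up, tss + basal_down + 1
        else:
            start, end = tss - basal_down, tss + basal_up + 1
        start = max(start, 0)
        if chrom_lengths and gene.body.chrom in chrom_lengths:
            end = min(end, chrom_lengths[gene.body.chrom])
        basals[gene.gene_id] = GenomicInterval(
            gene.body.chrom, start, end, gene.strand
        )

    by_chrom: dict[str, list[GeneModel]] = {}
    for gene in genes:
        by_chrom.setdefault(gene.body.chrom, []).append(gene)

    domains = []
    for chrom, chrom_genes in by_chrom.items():
        chrom_len = (chrom_lengths or {}).get(chrom)
        for gene in chrom_genes:
            basal = basals[gene.gene_id]
            left_bound, right_bound = 0, chrom_len
            for other in chrom_genes:
                if other.gene_id == gene.gene_id:
                    continue
                ob = basals[other.gene_id]
                if ob.end <= basal.start:
                    left_bound = max(left_bound, ob.end)
                elif ob.start >= basal.end:
                    right_bound = (
                        ob.start if right_bound is None
                        else min(right_bound, ob.start)
                    )
                else:
                    # overlapping basal: no extension through it
                    if ob.start < basal.start:
                        left_bound = max(left_bound, basal.start)
                    if ob.end > basal.end:
                        right_bound = (
                            basal.end if right_bound is None
                            else min(right_bound, basal.end)
                        )
            ext_start = max(basal.start - max_ext, left_bound)
            ext_end = basal.end + max_ext
            if right_bound is not None:
                ext_end = min(ext_end, max(right_bound, basal.end))
            domains.append(
                RegulatoryDomain(
                    gene_id=gene.gene_id,
                    tss=gene.tss,
                    strand=gene.strand,
                    basal=basal,
                    extended=GenomicInterval(chrom, ext_start, ext_end, gene.strand),
                )
            )
    domains.sort(key=lambda d: (d.basal.chrom, d.basal.start, d.gene_id))
    return domains


@dataclass(frozen=True)
class Association:
    locus_name: str
    gene_id: str
    distance: float  # signed midpoint-to-TSS distance, gene-strand polarity
    bin: str


def distance_bin(abs_distance: float) -> str:
    if abs_distance < 5_000:
        return "<5kb"
    if abs_distance < 50_000:
        return "5-50kb"
    if abs_distance < 500_000:
        return "50-500kb"
    return ">500kb"


def _locus_key(locus) -> str:
    interval = locus.interval if hasattr(locus, "interval") else locus
    return getattr(locus, "name", "") or f"{interval.chrom}:{interval.start}"


def associate_loci(
    loci: Sequence, domains: Sequence[RegulatoryDomain]
) -> list[Association]:
    """Associate every locus with genes whose extended domain it overlaps.

    The distance is (locus midpoint - TSS), sign flipped on minus-strand
    genes so that positive means downstream of the gene.
    """
    associations = []
    for locus in loci:
        interval = locus.interval if hasattr(locus, "interval") else locus
        name = _locus_key(locus)
        for domain in domains:
            if not interval.overlaps(domain.extended):
                continue
            raw = interval.midpoint - (domain.tss + 0.5)
            signed = raw if domain.strand == "+" else -raw
            associations.append(
                Association(
                    locus_name=name,
                    gene_id=domain.gene_id,
                    distance=signed,
                    bin=distance_bin(abs(signed)),
                )
            )
    return associations


def summarize_associations(
    loci: Sequence, associations: Sequence[Association]
) -> dict:
    """Genes-per-locus histogram and distance-bin counts."""
    per_locus: dict[str, int] = {_locus_key(l): 0 for l in loci}
    for assoc in associations:
        per_locus[assoc.locus_name] += 1
    gene_count_hist: dict[int, int] = {}
    for count in per_locus.values():
        gene_count_hist[count] = gene_count_hist.get(count, 0) + 1
    bins = {b: 0 for b in DISTANCE_BINS}
    for assoc in associations:
        bins[assoc.bin] += 1
    return {
        "genes_per_locus": gene_count_hist,
        "distance_bins": bins,
        "genes": sorted({a.gene_id for a in associations}),
    }


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    category_size: int  # K within the universe, after size filtering
    list_size: int  # n
    overlap: int  # k
    universe_size: int  # N
    p: float
    fdr: float
    rank: int


def ora_enrich(
    gene_list: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    min_size: int = 5,
    max_size: int = 2000,
    top: int = 10,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation with BH FDR control.

    Categories are intersected with the universe and kept when their
    size lands in [min_size, max_size]; p = P[X >= k] under the
    hypergeometric(N, K, n) null; BH adjustment runs across all tested
    categories and the top ``top`` by (FDR, p, name) are returned.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    genes = set(gene_list) & universe_set
    if not genes:
        raise ValueError("empty gene list (after intersecting with the universe)")
    n = len(genes)
    N = len(universe_set)

    tested: list[tuple[str, int, int, float]] = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe_set
        K = len(members)
        if not (min_size <= K <= max_size):
            continue
        k = len(members & genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        tested.append((name, K, k, min(p, 1.0)))
    if not tested:
        return []

    pvals = [t[3] for t in tested]
    _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(
            category=name,
            category_size=K,
            list_size=n,
            overlap=k,
            universe_size=N,
            p=p,
            fdr=float(fdr),
            rank=0,
        )
        for (name, K, k, p), fdr in zip(tested, fdrs)
    ]
    results.sort(key=lambda r: (r.fdr, r.p, r.category))
    ranked = [
        EnrichmentResult(**{**r.__dict__, "rank": i + 1})
        for i, r in enumerate(results[:top])
    ]
    return ranked


def benjamini_hochberg(pvals: Sequence[float]) -> list[float]:
    """Step-up BH adjusted p-values (convenience wrapper)."""
    _, fdrs, _, _ = multipletests(list(pvals), method="fdr_bh")
    return [float(f) for f in fdrs]
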