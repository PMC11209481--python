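"""Expected-vs-observed chromosomal distribution and genomic context.

Under random integration the expected number of insertions on a
chromosome is e = Cl * n / Tl, where Cl is the (gap-excluded) length of
the chromosome, n the total number of loci, and Tl the summed length of
all chromosomes. Departures are tested with chi-square statistics, both
genome-wide (df = k - 1) and per chromosome (two-cell, df = 1, with an
exact binomial backup when the expectation is small).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GenomicInterval, GeneModel

CONTEXT_LABELS = (
    "intergenic", "intron", "exonic&intronic", "genic&intergenic", "exon"
)


def expected_counts(
    chrom_lengths: Mapping[str, int], n: int
) -> dict[str, float]:
    """Expected insertions per chromosome: e = Cl * n / Tl."""
    if not chrom_lengths:
        raise ValueError("empty chromosome length table")
    if n < 0:
        raise ValueError("n must be >= 0")
    if any(l <= 0 for l in chrom_lengths.values()):
        raise ValueError("chromosome lengths must be positive")
    total = sum(chrom_lengths.values())
    return {chrom: length * n / total for chrom, length in chrom_lengths.items()}


def chisq_overall(
    observed: Sequence[float], expected: Sequence[float]
) -> tuple[float, int, float]:
    """Genome-wide goodness-of-fit: sum (O-E)^2/E over chromosomes."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected must have matching categories")
    if np.all(exp == 0):
        raise ValueError("all expected counts are zero")
    if not np.isclose(obs.sum(), exp.sum(), rtol=1e-6):
        raise ValueError("observed and expected totals differ")
    mask = exp > 0
    statistic = float(((obs[mask] - exp[mask]) ** 2 / exp[mask]).sum())
    df = int(mask.sum()) - 1
    p = float(stats.chi2.sf(statistic, df)) if df > 0 else 1.0
    return statistic, df, min(p, 1.0)


def chisq_per_chromosome(
    observed_c: int, e_c: float, n: int
) -> dict[str, float]:
    """Two-cell (on-chromosome vs elsewhere) test for one chromosome.

    Returns the 1-df chi-square p-value and, whenever the expectation is
    below 5 (where the chi-square approximation is unreliable), an exact
    two-sided binomial p-value as well.
    """
    if e_c <= 0:
        raise ValueError("expected count must be positive")
    if not (0 <= observed_c <= n):
        raise ValueError("observed count outside [0, n]")
    cells_obs = np.array([observed_c, n - observed_c], dtype=float)
    cells_exp = np.array([e_c, n - e_c], dtype=float)
    mask = cells_exp > 0  # a zero off-chromosome expectation is degenerate
    statistic = float(
        ((cells_obs[mask] - cells_exp[mask]) ** 2 / cells_exp[mask]).sum()
    )
    p_chi2 = float(stats.chi2.sf(statistic, 1))
    out = {"statistic": statistic, "df": 1, "p": p_chi2}
    if e_c < 5:
        out["p_binomial"] = float(
            stats.binomtest(observed_c, n, e_c / n).pvalue
        )
    return out


@dataclass(frozen=True)
class DistributionReport:
    """Per-chromosome expected/observed table with test results."""

    table: pd.DataFrame  # chrom, length, observed, expected, p_per_chrom
    n: int
    total_length: int
    statistic: float
    df: int
    p: float


def distribution_report(
    loci_chroms: Iterable[str], chrom_lengths: Mapping[str, int]
) -> DistributionReport:
    """Build the full expected-vs-observed report for a locus set."""
    observed = Counter(loci_chroms)
    unknown = set(observed) - set(chrom_lengths)
    if unknown:
        raise ValueError(f"loci on chromosomes without lengths: {sorted(unknown)}")
    n = sum(observed.values())
    expected = expected_counts(chrom_lengths, n)
    chroms = list(chrom_lengths)
    rows = []
    for chrom in chroms:
        o, e = observed.get(chrom, 0), expected[chrom]
        per = chisq_per_chromosome(o, e, n) if n else {"p": 1.0}
        rows.append(
            {
                "chrom": chrom,
                "length": chrom_lengths[chrom],
                "observed": o,
                "expected": e,
                "p_per_chrom": per["p"],
                "p_binomial": per.get("p_binomial", float("nan")),
            }
        )
    statistic, df, p = chisq_overall(
        [observed.get(c, 0) for c in chroms], [expected[c] for c in chroms]
    )
    return DistributionReport(
        table=pd.DataFrame(rows),
        n=n,
        total_length=sum(chrom_lengths.values()),
        statistic=statistic,
        df=df,
        p=p,
    )


# ---------------------------------------------------------------------------
# Genomic context
# ---------------------------------------------------------------------------

def genomic_context(
    interval: GenomicInterval, genes: Sequence[GeneModel]
) -> str:
    """Label a locus by its relation to gene bodies and exons.

    intergenic: overlaps no gene body; genic&intergenic: partially
    overlaps a gene body; exon / intron: fully inside an exon / inside a
    gene but touching no exon; exonic&intronic: inside a gene touching
    both exon and non-exon sequence.
    """
    overlapping = [g for g in genes if interval.overlaps(g.body)]
    if not overlapping:
        return "intergenic"
    if not any(g.body.contains(interval) for g in overlapping):
        return "genic&intergenic"
    containing = [g for g in overlapping if g.body.contains(interval)]
    for gene in containing:
        exon_hits = [e for e in gene.exons if interval.overlaps(e)]
        if not exon_hits:
            continue
        if any(e.contains(interval) for e in exon_hits):
            return "exon"
        return "exonic&intronic"
    return "intron"


@dataclass(frozen=True)
class ContextSummary:
    counts: Mapping[str, int]
    percents: Mapping[str, float]
    n: int


def summarize_contexts(labels: Iterable[str]) -> ContextSummary:
    """Count context labels and express them as percentages."""
    counts = Counter(labels)
    unknown = set(counts) - set(CONTEXT_LABELS)
    if unknown:
        raise ValueError(f"unknown context labels: {sorted(unknown)}")
    n = sum(counts.values())
    percents = {
        label: round(100 * counts.get(label, 0) / n, 2) if n else 0.0
        for label in CONTEXT_LABELS
    }
    return ContextSummary(
        counts={label: counts.get(label, 0) for label in CONTEXT_LABELS},
        percents=percents,
        n=n,
    )
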