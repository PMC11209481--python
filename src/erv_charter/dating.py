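"""Molecular-clock dating of provirus insertions.

The two LTRs of a provirus are identical at integration and then
diverge independently, so with a neutral substitution rate of
0.2%/nucleotide/million years the insertion age is

    T_2LTR = D / 0.2 / 2        (D in percent divergence between LTRs)

Elements lacking an LTR pair are dated from their internal coding
regions against a consensus:

    T_int = D / 0.2             (D in percent divergence vs consensus)

Divergences are uncorrected p-distances; D is stored as a fraction and
converted to percent exactly once, inside the two clock formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

#: Neutral substitution rate in percent per nucleotide per million years.
DEFAULT_RATE_PCT_PER_MY = 0.2

SKIP_CHARS = frozenset("-N")


def p_distance(seq_a: str, seq_b: str) -> float:
    """Fraction of differing columns between two equal-length rows.

    Columns containing a gap or an N in either row are excluded from
    both numerator and denominator.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    compared = 0
    diff = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a in SKIP_CHARS or b in SKIP_CHARS:
            continue
        compared += 1
        if a != b:
            diff += 1
    if compared == 0:
        raise ValueError("no comparable columns after gap/N removal")
    return diff / compared


def build_consensus(
    aligned: Sequence[str], reference: str
) -> str:
    """Majority-rule consensus of aligned rows, reference-tie-broken.

    ``reference`` must be aligned to the same columns. Per column the
    most frequent base among {A, C, G, T} wins; ties go to the reference
    base when it is among the tied bases (otherwise alphabetical).
    Columns that are gap in every row are removed.
    """
    if len(aligned) < 2:
        raise ValueError("need at least two sequences")
    length = len(aligned[0])
    if any(len(s) != length for s in aligned) or len(reference) != length:
        raise ValueError("all rows (and reference) must share one aligned length")
    out = []
    for col in range(length):
        counts: dict[str, int] = {}
        for row in aligned:
            base = row[col].upper()
            if base not in SKIP_CHARS:
                counts[base] = counts.get(base, 0) + 1
        if not counts:
            continue  # all-gap column
        best = max(counts.values())
        tied = sorted(b for b, c in counts.items() if c == best)
        ref_base = reference[col].upper()
        out.append(ref_base if ref_base in tied else tied[0])
    return "".join(out)


def age_2ltr(
    d_ltr: float, rate: float = DEFAULT_RATE_PCT_PER_MY
) -> float:
    """Insertion age (My) from the LTR-LTR divergence fraction.

    T = (100 * D) / rate / 2 — the factor 2 because both LTRs diverge.
    """
    if d_ltr < 0:
        raise ValueError("divergence must be non-negative")
    if d_ltr > 1:
        raise ValueError("divergence is a fraction in [0, 1]")
    return (100.0 * d_ltr) / rate / 2.0


def age_internal(
    region_divergences: Mapping[str, float] | Sequence[float],
    rate: float = DEFAULT_RATE_PCT_PER_MY,
) -> tuple[float, float]:
    """(mean divergence, age in My) from internal regions vs consensus.

    The mean is taken over the regions actually present; T = 100*D/rate.
    """
    values = (
        [v for v in region_divergences.values() if v is not None and not math.isnan(v)]
        if isinstance(region_divergences, Mapping)
        else [v for v in region_divergences if v is not None and not math.isnan(v)]
    )
    if not values:
        raise ValueError("no region divergences present")
    if any(v < 0 or v > 1 for v in values):
        raise ValueError("divergences are fractions in [0, 1]")
    mean_d = sum(values) / len(values)
    return mean_d, (100.0 * mean_d) / rate


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (22.75 -> 23, 25.39 -> 25, -0.5 -> -1)."""
    factor = 10**ndigits
    scaled = x * factor
    rounded = math.floor(scaled + 0.5) if scaled >= 0 else math.ceil(scaled - 0.5)
    return rounded / factor if ndigits else float(rounded)


@dataclass(frozen=True)
class DivergenceRecord:
    """Per-element divergences and derived ages (Table-6-shaped row)."""

    locus: str
    species: str = ""
    region_divergences: Mapping[str, float] | None = None
    mean_divergence: float | None = None
    age_internal_my: float | None = None
    d_ltr: float | None = None
    age_ltr_my: float | None = None

    @classmethod
    def from_divergences(
        cls,
        locus: str,
        region_divergences: Mapping[str, float] | None = None,
        d_ltr: float | None = None,
        species: str = "",
        rate: float = DEFAULT_RATE_PCT_PER_MY,
    ) -> "DivergenceRecord":
        mean_d = t_int = t_ltr = None
        present = {
            k: v for k, v in (region_divergences or {}).items() if v is not None
        }
        if present:
            mean_d, t_int = age_internal(present, rate)
        if d_ltr is not None:
            t_ltr = age_2ltr(d_ltr, rate)
        return cls(
            locus=locus,
            species=species,
            region_divergences=present or None,
            mean_divergence=mean_d,
            age_internal_my=t_int,
            d_ltr=d_ltr,
            age_ltr_my=t_ltr,
        )


@dataclass(frozen=True)
class AgeSummary:
    group: str
    count: int
    min_my: float
    max_my: float
    mean_my: float

    @property
    def rounded(self) -> tuple[int, int, int]:
        """(min, max, mean) rounded to integers, half away from zero."""
        return (
            int(round_half_away(self.min_my)),
            int(round_half_away(self.max_my)),
            int(round_half_away(self.mean_my)),
        )


def summarize_ages(ages: Iterable[float], group: str = "") -> AgeSummary:
    values = [float(a) for a in ages]
    if not values:
        raise ValueError("empty age collection")
    return AgeSummary(
        group=group,
        count=len(values),
        min_my=min(values),
        max_my=max(values),
        mean_my=sum(values) / len(values),
    )


def compare_groups(
    ages_a: Sequence[float], ages_b: Sequence[float]
) -> tuple[float, int, float]:
    """Pooled-variance unpaired Student's t-test, two-sided.

    Degenerate inputs (zero pooled variance) give p = 1 for equal means
    and an error otherwise.
    """
    a = np.asarray(ages_a, dtype=float)
    b = np.asarray(ages_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    df = len(a) + len(b) - 2
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, df, 1.0
        raise ValueError("degenerate: zero variance with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), df, float(p)
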