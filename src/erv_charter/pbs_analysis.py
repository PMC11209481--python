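"""Primer binding site extraction, tRNA typing, and conservation logos.

The PBS of an HML-9 provirus sits three residues downstream of the
5' LTR, is 18 nt long, and is complementary to the 3' end of the host
tRNA that primes reverse transcription — for the ERV-K family
typically a lysine tRNA, hence the family letter K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genome_io import reverse_complement

PBS_LENGTH = 18
PBS_OFFSET = 3

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class PbsRecord:
    locus: str
    present: bool
    sequence: str | None = None
    offset: int = PBS_OFFSET
    trna: str | None = None
    identity: float | None = None

    def __post_init__(self) -> None:
        if self.present and (self.sequence is None or len(self.sequence) != PBS_LENGTH):
            raise ValueError(f"present PBS must be {PBS_LENGTH} nt")
        if self.identity is not None and not (0 <= self.identity <= 1):
            raise ValueError("identity must be in [0, 1]")


def extract_pbs(
    element: str,
    five_ltr_end: int | None,
    locus: str = "",
    offset: int = PBS_OFFSET,
    length: int = PBS_LENGTH,
) -> PbsRecord:
    """Cut the PBS window out of a plus-strand-oriented element.

    ``five_ltr_end`` is the 0-based exclusive end of the element's
    5' LTR (None when the element has no 5' LTR). Absence of the LTR or
    a window running off the element yields ``present=False``.
    """
    if five_ltr_end is None:
        return PbsRecord(locus=locus, present=False)
    start = five_ltr_end + offset
    end = start + length
    if start < 0 or end > len(element):
        return PbsRecord(locus=locus, present=False)
    return PbsRecord(
        locus=locus, present=True, sequence=element[start:end].upper(), offset=offset
    )


def match_trna(
    pbs: str,
    trnas: Mapping[str, str],
    min_identity_bases: int = 14,
) -> tuple[str | None, float]:
    """Type a PBS by complementarity to tRNA 3' ends.

    The PBS is compared against the reverse complement of the
    3'-terminal 18 nt of every tRNA (CCA tails, when present in the
    input, are part of that window). The best match is returned — ties
    broken by lexicographic tRNA name — and the assignment is kept only
    when at least ``min_identity_bases`` of 18 positions match.
    """
    if not trnas:
        raise ValueError("empty tRNA set")
    pbs = pbs.upper()
    if len(pbs) != PBS_LENGTH:
        raise ValueError(f"PBS must be {PBS_LENGTH} nt")
    best_name: str | None = None
    best_matches = -1
    for name in sorted(trnas):
        tail = trnas[name].upper().replace("U", "T")[-PBS_LENGTH:]
        if len(tail) < PBS_LENGTH:
            continue
        template = reverse_complement(tail)
        matches = sum(
            a == b and a != "N" for a, b in zip(pbs, template)
        )
        if matches > best_matches:
            best_matches = matches
            best_name = name
    if best_matches < 0:
        raise ValueError("no tRNA of sufficient length")
    identity = best_matches / PBS_LENGTH
    if best_matches < min_identity_bases:
        return None, identity
    return best_name, identity


@dataclass(frozen=True)
class LogoMatrix:
    """Per-column base frequencies and information content in bits."""

    frequencies: np.ndarray  # shape (L, 4), columns ordered A C G T
    information: np.ndarray  # shape (L,), in [0, 2] bits

    @property
    def length(self) -> int:
        return self.frequencies.shape[0]

    def consensus(self, first_n: int | None = None) -> str:
        """Most frequent base per column (ties to alphabetical order)."""
        idx = self.frequencies.argmax(axis=1)
        s = "".join(BASES[i] for i in idx)
        return s[:first_n] if first_n else s


def logo_matrix(sequences: Sequence[str]) -> LogoMatrix:
    """Column frequencies and information (2 - Shannon entropy, bits).

    Gaps and Ns are ignored by renormalizing each column over the
    observed A/C/G/T counts; an all-ambiguous column is uniform with
    zero information.
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("sequences must have equal length")
    freqs = np.zeros((length, 4))
    info = np.zeros(length)
    for col in range(length):
        counts = np.zeros(4)
        for seq in sequences:
            base = seq[col].upper()
            if base in BASES:
                counts[BASES.index(base)] += 1
        total = counts.sum()
        if total == 0:
            freqs[col] = 0.25
            info[col] = 0.0
            continue
        p = counts / total
        freqs[col] = p
        entropy = -sum(pi * math.log2(pi) for pi in p if pi > 0)
        info[col] = 2.0 - entropy
    return LogoMatrix(frequencies=freqs, information=info)


def write_logo_tsv(logo: LogoMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tA\tC\tG\tT\tinformation_bits\n")
        for i in range(logo.length):
            row = "\t".join(f"{v:.4f}" for v in logo.frequencies[i])
            fh.write(f"{i + 1}\t{row}\t{logo.information[i]:.4f}\n")
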