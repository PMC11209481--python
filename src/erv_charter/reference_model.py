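"""Reference provirus model: consensus sequence plus named region layout.

The canonical HML-9 provirus (the Dfam LTR14C-HERVK14C-LTR14C assembly)
is an 8,608-nt consensus laid out as 5'LTR - gag - pro - pol - env -
3'LTR, with short overlaps between adjacent coding frames. Region
intervals are stored 1-based inclusive, mirroring how such annotations
are published, and converted to the internal 0-based convention on use.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .genome_io import read_fasta, read_config

REGION_LABELS = ("five_ltr", "gag", "pro", "pol", "env", "three_ltr")

#: Canonical HML-9 (HERV-K14C) region coordinates, 1-based inclusive.
DEFAULT_LAYOUT: dict[str, tuple[int, int]] = {
    "five_ltr": (1, 587),
    "gag": (758, 2548),
    "pro": (2548, 3435),
    "pol": (3411, 6060),
    "env": (5975, 8020),
    "three_ltr": (8022, 8608),
}

INTERNAL_REGIONS = ("gag", "pro", "pol", "env")
LTR_REGIONS = ("five_ltr", "three_ltr")


@dataclass(frozen=True)
class ReferenceProvirus:
    """Consensus sequence with its 1-based inclusive region intervals."""

    name: str
    sequence: str
    regions: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        n = len(self.sequence)
        starts = []
        for label in REGION_LABELS:
            if label not in self.regions:
                raise ValueError(f"missing region {label!r}")
            start, end = self.regions[label]
            if not (1 <= start <= end <= n):
                raise ValueError(
                    f"region {label!r} [{start}, {end}] out of bounds for "
                    f"sequence of length {n}"
                )
            starts.append(start)
        if starts != sorted(starts):
            raise ValueError("region starts must be nondecreasing in canonical order")
        if self.regions["five_ltr"][1] >= self.regions["three_ltr"][0]:
            raise ValueError("5'LTR must precede 3'LTR")

    @property
    def total_length(self) -> int:
        return len(self.sequence)

    def region_length(self, label: str) -> int:
        start, end = self.regions[label]
        return end - start + 1

    def region_slice(self, label: str) -> tuple[int, int]:
        """Region as 0-based half-open (start, end) on the consensus."""
        start, end = self.regions[label]
        return start - 1, end

    def region_sequence(self, label: str) -> str:
        start, end = self.region_slice(label)
        return self.sequence[start:end]

    @property
    def ltr_length(self) -> int:
        """Length of the LTR model (the 5' copy)."""
        return self.region_length("five_ltr")


def load_reference(
    fasta_path: str | Path,
    layout: Mapping[str, tuple[int, int]] | str | Path | None = None,
    name: str | None = None,
) -> ReferenceProvirus:
    """Load the consensus FASTA and its region layout.

    ``layout`` may be a mapping, a key=value config file with
    ``region.<label>.start`` / ``region.<label>.end`` entries, or None
    to use the canonical HML-9 coordinates (which require a sequence of
    at least 8,608 nt).
    """
    seqs = read_fasta(fasta_path)
    if name is None:
        name, sequence = next(iter(seqs.items()))
    else:
        sequence = seqs[name]

    if layout is None:
        if len(sequence) < 8608:
            raise ValueError(
                "default HML-9 layout requires a consensus of >= 8608 nt; "
                f"got {len(sequence)}"
            )
        regions = dict(DEFAULT_LAYOUT)
    elif isinstance(layout, (str, Path)):
        regions = layout_from_config(read_config(layout))
    else:
        regions = dict(layout)
    return ReferenceProvirus(name=name, sequence=sequence, regions=regions)


def layout_from_config(cfg: Mapping[str, str]) -> dict[str, tuple[int, int]]:
    regions = {}
    for label in REGION_LABELS:
        try:
            regions[label] = (
                int(cfg[f"region.{label}.start"]),
                int(cfg[f"region.{label}.end"]),
            )
        except KeyError as exc:
            raise ValueError(f"layout config missing {exc.args[0]}") from None
    return regions


def regions_at(reference: ReferenceProvirus, position: int) -> set[str]:
    """All region labels containing a 1-based consensus position.

    Positions in overlap zones (e.g. the gag/pro junction) return both
    labels; leader/spacer positions return an empty set.
    """
    if not (1 <= position <= reference.total_length):
        raise ValueError(
            f"position {position} outside [1, {reference.total_length}]"
        )
    return {
        label
        for label in REGION_LABELS
        if reference.regions[label][0] <= position <= reference.regions[label][1]
    }
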