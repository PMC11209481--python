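"""Curated HML-9 locus catalogs shipped with the package.

These TSVs record the published survey of the HML-9 (HERV-K14C) group
in the chimpanzee (panTro6) and human (hg38) reference assemblies: the
26 chimpanzee proviruses and 38 solo LTRs with their coordinates,
completeness and genomic context; the cross-species homolog pairings;
per-region structural integrity; per-element divergences and clock
ages; and approximate gap-excluded chromosome lengths for both
assemblies. They let every piece of desk-scale arithmetic in the
pipeline run offline.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .genome_io import GenomicInterval
from .locus_mining import ErvLocus, HomologyLedger

_PKG = "erv_charter.data"


def _read(name: str) -> pd.DataFrame:
    with resources.files(_PKG).joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", na_values=["NA"])


def load_proviruses() -> pd.DataFrame:
    """The 26 chimpanzee HML-9 proviruses (1-based inclusive positions)."""
    return _read("chimp_proviruses.tsv")


def load_solo_ltrs() -> pd.DataFrame:
    """The 38 chimpanzee HML-9 solo LTRs."""
    return _read("chimp_solo_ltrs.tsv")


def load_integration_times() -> pd.DataFrame:
    """Per-element divergences and clock ages for both species.

    Divergences are fractions; ``age_ltr`` / ``age_internal`` are the
    printed per-element ages in My (treated as the authoritative values
    for aggregation, since a few printed 3-decimal divergences are
    rounded past the point of reproducing their own age column).
    """
    return _read("integration_times.tsv")


def load_region_completeness() -> pd.DataFrame:
    """Per-region structural integrity (%) of the 26 proviruses."""
    return _read("region_completeness.tsv")


def load_chrom_lengths(assembly: str) -> dict[str, int]:
    """Approximate gap-excluded chromosome lengths for panTro6 or hg38."""
    df = _read("chrom_lengths.tsv")
    sub = df[df["assembly"] == assembly]
    if sub.empty:
        raise ValueError(f"unknown assembly {assembly!r}")
    return dict(zip(sub["chrom"], sub["length"]))


def _catalog_loci(df: pd.DataFrame, element_class: str, prefix: str) -> list[ErvLocus]:
    loci = []
    for _, row in df.iterrows():
        indel = row.get("indel")
        flags = () if pd.isna(indel) else tuple(str(indel).split(";"))
        loci.append(
            ErvLocus(
                name=f"{prefix}{int(row['number'])}",
                interval=GenomicInterval.from_1based(
                    row["chrom"], int(row["start"]), int(row["end"]), row["strand"]
                ),
                element_class=element_class,
                completeness=min(float(row["completeness_pct"]) / 100, 1.0),
                completeness_bin=row["range"],
                q_gap_ratio=float(row["qgap_pct"]) / 100,
                context=row["context"],
                flags=flags,
            )
        )
    return loci


def catalog_provirus_loci() -> list[ErvLocus]:
    return _catalog_loci(load_proviruses(), "provirus", "PV")


def catalog_solo_ltr_loci() -> list[ErvLocus]:
    return _catalog_loci(load_solo_ltrs(), "solo_ltr", "SL")


def homolog_ledger() -> HomologyLedger:
    """Cross-species pairing over both catalogs (chimp = A, human = B).

    Element class is taken from membership in the provirus vs solo-LTR
    comparison table.
    """
    loci_a: list[ErvLocus] = []
    loci_b: list[ErvLocus] = []
    pairs: dict[str, list[str]] = {}
    for table, element_class in (
        ("homolog_proviruses.tsv", "provirus"),
        ("homolog_solo_ltrs.tsv", "solo_ltr"),
    ):
        df = _read(table)
        for _, row in df.iterrows():
            name = f"{row['species']}_{row['chrom']}_{int(row['start'])}"
            locus = ErvLocus(
                name=name,
                interval=GenomicInterval.from_1based(
                    row["chrom"], int(row["start"]), int(row["end"]), row["strand"]
                ),
                element_class=element_class,
                completeness=0.0,
                completeness_bin="(0-10%)",
            )
            (loci_a if row["species"] == "chimp" else loci_b).append(locus)
            if not pd.isna(row["pair"]):
                pairs.setdefault(str(row["pair"]), []).append(name)
    pairing = tuple(
        (a, b) for a, b in (sorted(v, key=lambda n: n.startswith("human"))
                            for v in pairs.values())
    )
    return HomologyLedger(
        loci_a=tuple(loci_a), loci_b=tuple(loci_b), pairing=pairing
    )
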