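"""Receptor–HD allele association survey and mating-system classification.

Given a table of natural isolates carrying labelled pheromone-receptor and
HD1/HD2 alleles, summarizes how HD alleles distribute over receptor classes
and classifies the architecture: a bipolar species shows exactly two HD
alleles, each locked to one receptor; a tetrapolar species shows HD alleles
segregating independently of the receptor (shared between receptor
classes); a pseudo-bipolar species shows the diagnostic one-to-many pattern
— many HD alleles, each associated with exactly one receptor.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import pandas as pd

__all__ = ["Behaviour", "SystemClass", "association_summary", "classify_system"]


class Behaviour(str, Enum):
    A1 = "A1"
    A2 = "A2"
    SELF_FERTILE = "SELF_FERTILE"
    ASEXUAL = "ASEXUAL"
    UNKNOWN = "UNKNOWN"


class SystemClass(str, Enum):
    BIPOLAR = "BIPOLAR"
    TETRAPOLAR = "TETRAPOLAR"
    PSEUDO_BIPOLAR = "PSEUDO_BIPOLAR"
    UNDETERMINED = "UNDETERMINED"


_REQUIRED = ("strain", "species", "receptor", "hd", "behaviour")


def _is_haploid(row: pd.Series) -> bool:
    # self-fertile strains carry both receptors (recorded "A1/A2"); they and
    # other multi-receptor records are not haploid evidence
    return row["behaviour"] != Behaviour.SELF_FERTILE.value and "/" not in str(row["receptor"])


def association_summary(table: pd.DataFrame) -> dict:
    """Summarize receptor <-> HD allele association over haploid strains.

    Returns allele counts, the HD alleles observed with each receptor, HD
    alleles shared between receptors, and recombinant receptor–HD pairs
    (minority associations of an HD allele otherwise locked to the other
    receptor).  Self-fertile/diploid records are excluded from haploid
    counts and reported separately.
    """
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"strain table missing columns: {missing}")
    if table.empty:
        raise ValueError("strain table is empty")
    if table["strain"].duplicated().any():
        dups = table.loc[table["strain"].duplicated(), "strain"].tolist()
        raise ValueError(f"duplicate strain ids: {dups}")

    haploid_mask = table.apply(_is_haploid, axis=1)
    haploid = table[haploid_mask]
    excluded = table[~haploid_mask]

    pair_counts = Counter(zip(haploid["receptor"], haploid["hd"]))
    hd_per_receptor: dict[str, set[str]] = {}
    for receptor, hd in pair_counts:
        hd_per_receptor.setdefault(receptor, set()).add(hd)

    receptors_per_hd: dict[str, set[str]] = {}
    for receptor, hd in pair_counts:
        receptors_per_hd.setdefault(hd, set()).add(receptor)
    shared = {hd for hd, rs in receptors_per_hd.items() if len(rs) > 1}

    recombinant_pairs: set[tuple[str, str]] = set()
    for hd in shared:
        by_receptor = {r: pair_counts[(r, hd)] for r in receptors_per_hd[hd]}
        top = max(by_receptor.values())
        minority = {r for r, n in by_receptor.items() if n < top}
        if minority:
            recombinant_pairs.update((r, hd) for r in minority)
        else:  # tie: association cannot be oriented, report all
            recombinant_pairs.update((r, hd) for r in by_receptor)

    return {
        "n_haploid_strains": int(len(haploid)),
        "n_pr_alleles": int(haploid["receptor"].nunique()),
        "n_hd_alleles": int(haploid["hd"].nunique()),
        "hd_alleles_per_receptor": {r: sorted(s) for r, s in sorted(hd_per_receptor.items())},
        "shared_hd_alleles": sorted(shared),
        "recombinant_pairs": sorted(recombinant_pairs),
        "excluded_records": excluded["strain"].tolist(),
    }


def classify_system(summary: dict, min_haploid: int = 4) -> SystemClass:
    """Pattern-based mating-system classification from an association summary."""
    if summary["n_haploid_strains"] < min_haploid:
        return SystemClass.UNDETERMINED
    per_receptor = summary["hd_alleles_per_receptor"]
    if summary["shared_hd_alleles"]:
        return SystemClass.TETRAPOLAR
    if summary["n_hd_alleles"] == 2 and all(len(s) == 1 for s in per_receptor.values()):
        return SystemClass.BIPOLAR
    if summary["n_hd_alleles"] > 2:
        return SystemClass.PSEUDO_BIPOLAR
    return SystemClass.UNDETERMINED
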