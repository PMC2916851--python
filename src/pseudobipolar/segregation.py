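"""Marker-segregation analysis of meiotic progeny.

Reproduces the analysis applied to colonies recovered from individually
germinated teliospores: parental-origin assignment of raw allele calls,
diploid (failed-meiosis) detection, parsimony-based crossover vs
gene-conversion event calling along scaffolds, two-point recombination
fractions and physical/genetic map densities (kb/cM), a MAT-cohesion
summary over teliospores, and minimal-event inference of the relative
orientation of two scaffolds sharing a junction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .meiosis import HET, MISSING, P1, P2, MarkerMap

__all__ = [
    "EventKind",
    "EventCall",
    "LinkageClass",
    "LinkageResult",
    "assign_origin",
    "detect_diploid",
    "call_events",
    "recombination_fraction",
    "collapse_products",
    "mat_cohesion_summary",
    "infer_scaffold_orientation",
    "OrientationResult",
]

_CALLS = {P1, P2, HET, MISSING}


class EventKind(str, Enum):
    CROSSOVER = "CROSSOVER"
    CONVERSION = "CONVERSION"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class EventCall:
    """One inferred recombination event on one meiotic product.

    CROSSOVER events span the inter-marker interval in which the origin
    switches; CONVERSION (and AMBIGUOUS) events span the run of markers
    carrying the intruding origin.
    """

    kind: EventKind
    scaffold: str
    start_kb: float
    end_kb: float
    markers: tuple[str, ...]
    product: str = ""


class LinkageClass(str, Enum):
    LINKED = "LINKED"
    PARTIAL = "PARTIAL"
    UNLINKED = "UNLINKED"


@dataclass(frozen=True)
class LinkageResult:
    marker_a: str
    marker_b: str
    n_informative: int
    n_recombinant: int
    rf: float
    map_distance_cM: float
    distance_kb: Optional[float]
    kb_per_cM: Optional[float]  # None when RF = 0 (no recombination observed)
    linkage: LinkageClass
    p_value: float  # exact binomial, H0: RF = 0.5 against RF < 0.5


def assign_origin(
    raw: pd.DataFrame, parental: Mapping[str, tuple[str, str]]
) -> pd.DataFrame:
    """Translate raw allele calls into parental-origin calls.

    ``raw`` has ``teliospore``/``colony`` columns plus one column per marker
    holding allele strings; a call listing both parental alleles separated
    by ``/`` (either order) is scored HET, empty/``NA`` is MISSING.
    ``parental`` maps marker -> (P1 allele, P2 allele).  Markers where the
    parents carry identical alleles are uninformative and dropped with a
    warning.
    """
    meta = [c for c in ("teliospore", "colony") if c in raw.columns]
    markers = [c for c in raw.columns if c not in meta]
    unknown = [m for m in markers if m not in parental]
    if unknown:
        raise KeyError(f"markers absent from parental genotypes: {unknown}")

    out = raw[meta].copy()
    for marker in markers:
        a1, a2 = parental[marker]
        if a1 == a2:
            warnings.warn(
                f"marker {marker!r}: parents share allele {a1!r}; dropped as uninformative",
                stacklevel=2,
            )
            continue

        def score(value: object) -> str:
            if value is None or (isinstance(value, float) and math.isnan(value)):
                return MISSING
            text = str(value).strip()
            if text in ("", MISSING):
                return MISSING
            alleles = set(text.split("/"))
            if alleles == {a1, a2}:
                return HET
            if alleles == {a1}:
                return P1
            if alleles == {a2}:
                return P2
            raise ValueError(f"marker {marker!r}: allele call {text!r} matches neither parent")

        out[marker] = raw[marker].map(score)
    return out


def detect_diploid(origins: Mapping[str, str], min_het_fraction: float = 1.0) -> bool:
    """True iff HET calls reach ``min_het_fraction`` of informative markers.

    The default (1.0) flags a product as diploid only when it carries both
    parental alleles at every non-missing marker.
    """
    if not 0.0 < min_het_fraction <= 1.0:
        raise ValueError("min_het_fraction must be in (0, 1]")
    calls = [v for v in origins.values() if v != MISSING]
    if not calls:
        return False
    het = sum(1 for v in calls if v == HET)
    return het / len(calls) >= min_het_fraction


def call_events(
    origins: Mapping[str, str],
    marker_map: MarkerMap,
    max_conversion_markers: int = 1,
    max_conversion_kb: float = math.inf,
    terminal_ambiguous: bool = False,
    product: str = "",
) -> list[EventCall]:
    """Minimal-event parsimony calling of crossovers and conversions.

    Per scaffold, maximal runs of constant origin over the informative
    (non-missing) markers are delimited.  An internal run of at most
    ``max_conversion_markers`` markers spanning at most ``max_conversion_kb``
    — necessarily flanked on both sides by the opposite origin — is called
    one CONVERSION (one event instead of two crossovers); every remaining
    switch between adjacent runs is a CROSSOVER placed in the inter-marker
    interval, which widens naturally across MISSING markers.  Runs touching
    a scaffold end cannot be conversions (one flank is unobserved); with
    ``terminal_ambiguous`` short terminal runs are reported AMBIGUOUS
    instead of being delimited by a crossover.  Invariant under relabeling
    P1 <-> P2.
    """
    if any(v == HET for v in origins.values()):
        raise ValueError("HET calls present: run detect_diploid first and exclude diploids")

    events: list[EventCall] = []
    for scaffold in marker_map.scaffolds():
        sub = marker_map.scaffold_markers(scaffold)
        informative = [
            (m, p)
            for m, p in zip(sub["marker"], sub["position_kb"])
            if origins.get(m, MISSING) in (P1, P2)
        ]
        if len(informative) < 2:
            continue
        # run-length encode origins along the scaffold
        runs: list[list[tuple[str, float]]] = []
        for m, p in informative:
            if runs and origins[runs[-1][-1][0]] == origins[m]:
                runs[-1].append((m, p))
            else:
                runs.append([(m, p)])

        def run_span(run: list[tuple[str, float]]) -> float:
            return run[-1][1] - run[0][1]

        # left-to-right greedy: a short internal run flanked by the opposite
        # origin is a conversion unless its left neighbour was already
        # absorbed as one (alternating short runs -> alternate conversions,
        # not a conversion at every run)
        is_conversion = [False] * len(runs)
        is_ambiguous = [False] * len(runs)
        for i, run in enumerate(runs):
            short = len(run) <= max_conversion_markers and run_span(run) <= max_conversion_kb
            if not short:
                continue
            if 0 < i < len(runs) - 1 and not is_conversion[i - 1]:
                is_conversion[i] = True
            elif (i == 0 or i == len(runs) - 1) and terminal_ambiguous and len(runs) > 1:
                is_ambiguous[i] = True

        for i, run in enumerate(runs):
            if is_conversion[i]:
                events.append(
                    EventCall(
                        kind=EventKind.CONVERSION,
                        scaffold=scaffold,
                        start_kb=run[0][1],
                        end_kb=run[-1][1],
                        markers=tuple(m for m, _ in run),
                        product=product,
                    )
                )
            elif is_ambiguous[i]:
                events.append(
                    EventCall(
                        kind=EventKind.AMBIGUOUS,
                        scaffold=scaffold,
                        start_kb=run[0][1],
                        end_kb=run[-1][1],
                        markers=tuple(m for m, _ in run),
                        product=product,
                    )
                )
        # crossovers between consecutive runs not absorbed by a conversion
        # or an ambiguous terminal run
        for i in range(len(runs) - 1):
            if is_conversion[i] or is_conversion[i + 1]:
                continue
            if is_ambiguous[i] or is_ambiguous[i + 1]:
                continue
            left_marker, left_pos = runs[i][-1]
            right_marker, right_pos = runs[i + 1][0]
            events.append(
                EventCall(
                    kind=EventKind.CROSSOVER,
                    scaffold=scaffold,
                    start_kb=left_pos,
                    end_kb=right_pos,
                    markers=(left_marker, right_marker),
                    product=product,
                )
            )
    return events


def collapse_products(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse clonal colonies to distinct products per teliospore.

    Colonies of one teliospore sharing an identical genotype are mitotic
    clones and count once.  Returns one row per distinct genotype class,
    with a ``product`` identifier.
    """
    markers = [c for c in table.columns if c not in ("teliospore", "colony")]
    rows = []
    for telio, sub in table.groupby("teliospore", sort=False):
        distinct = sub[markers].drop_duplicates()
        for k, (_, geno) in enumerate(distinct.iterrows(), start=1):
            row = {"teliospore": telio, "product": f"{telio}.g{k}"}
            row.update(geno.to_dict())
            rows.append(row)
    return pd.DataFrame(rows, columns=["teliospore", "product", *markers])


def recombination_fraction(
    table: pd.DataFrame,
    marker_a: str,
    marker_b: str,
    marker_map: Optional[MarkerMap] = None,
    distance_kb: Optional[float] = None,
    alpha: float = 0.05,
    linked_rf: float = 0.15,
    per_product: bool = True,
) -> LinkageResult:
    """Two-point recombination fraction between two markers.

    Colonies are collapsed to distinct products per teliospore; diploid
    (HET) and missing calls are uninformative.  RF = recombinant/informative
    products; map distance is taken as 100·RF centimorgans directly (the
    small-sample convention under which 3 recombinants among 7 products
    across 27 kb give 0.63 kb/cM) and kb/cM = distance / (100·RF), undefined
    at RF = 0.  Linkage is UNLINKED unless an exact one-sided binomial test
    rejects RF = 0.5 at ``alpha``, then LINKED/PARTIAL by an RF cut.
    ``per_product=False`` keeps only the first product of each teliospore.
    """
    for m in (marker_a, marker_b):
        if m not in table.columns:
            raise KeyError(f"marker {m!r} not in progeny table")
    products = collapse_products(table)
    if not per_product:
        products = products.groupby("teliospore", sort=False).head(1)
    calls = products[[marker_a, marker_b]]
    informative = calls.isin([P1, P2]).all(axis=1)
    n_informative = int(informative.sum())
    if n_informative == 0:
        raise ValueError(f"no informative products for {marker_a!r} x {marker_b!r}")
    sub = calls[informative]
    n_recombinant = int((sub[marker_a] != sub[marker_b]).sum())
    rf = n_recombinant / n_informative

    if distance_kb is None and marker_map is not None:
        if marker_map.scaffold_of(marker_a) == marker_map.scaffold_of(marker_b):
            distance_kb = abs(marker_map.position(marker_a) - marker_map.position(marker_b))
    map_cm = 100.0 * rf
    kb_per_cM = None
    if distance_kb is not None and rf > 0:
        kb_per_cM = distance_kb / map_cm

    p_value = stats.binomtest(n_recombinant, n_informative, p=0.5, alternative="less").pvalue
    if p_value >= alpha:
        linkage = LinkageClass.UNLINKED
    elif rf <= linked_rf:
        linkage = LinkageClass.LINKED
    else:
        linkage = LinkageClass.PARTIAL
    return LinkageResult(
        marker_a=marker_a,
        marker_b=marker_b,
        n_informative=n_informative,
        n_recombinant=n_recombinant,
        rf=rf,
        map_distance_cM=map_cm,
        distance_kb=distance_kb,
        kb_per_cM=kb_per_cM,
        linkage=linkage,
        p_value=float(p_value),
    )


def mat_cohesion_summary(
    table: pd.DataFrame,
    pr_marker: str,
    hd_marker: str,
    phase: Mapping[str, tuple[str, str]],
) -> dict:
    """Classify each teliospore by the fate of the PR–HD linkage.

    ``phase`` names the parental receptor/HD allele combinations, e.g.
    ``{"P1": ("A1", "A1-3"), "P2": ("A2", "A2-15")}``; with origin-coded
    calls a product is parental at PR–HD iff its two origins agree.
    Classes DIPLOID / RECOMBINANT / PARENTAL partition the teliospores;
    ``both_types_recovered`` additionally counts teliospores whose colonies
    yielded both parental mating types (distinct all-parental genotype
    classes).
    """
    if set(phase) != {P1, P2}:
        raise ValueError("phase must name the P1 and P2 receptor/HD combinations")
    for m in (pr_marker, hd_marker):
        if m not in table.columns:
            raise KeyError(f"marker {m!r} not in progeny table")

    per_teliospore: dict[str, str] = {}
    both_types: list[str] = []
    markers = [c for c in table.columns if c not in ("teliospore", "colony")]
    for telio, sub in table.groupby("teliospore", sort=False):
        pairs = sub[[pr_marker, hd_marker]].drop_duplicates()
        if ((sub[pr_marker] == HET) | (sub[hd_marker] == HET)).any():
            per_teliospore[telio] = "DIPLOID"
            continue
        recombinant = (
            pairs.isin([P1, P2]).all(axis=1) & (pairs[pr_marker] != pairs[hd_marker])
        ).any()
        if recombinant:
            per_teliospore[telio] = "RECOMBINANT"
            continue
        per_teliospore[telio] = "PARENTAL"
        mating_types = set(
            sub.loc[sub[pr_marker].isin([P1, P2]), pr_marker]
        )
        if len(sub[markers].drop_duplicates()) >= 2 and len(mating_types) == 2:
            both_types.append(telio)

    counts = {
        "parental": sum(1 for v in per_teliospore.values() if v == "PARENTAL"),
        "recombinant": sum(1 for v in per_teliospore.values() if v == "RECOMBINANT"),
        "diploid": sum(1 for v in per_teliospore.values() if v == "DIPLOID"),
        "both_types_recovered": len(both_types),
    }
    return {
        "counts": counts,
        "classes": per_teliospore,
        "both_types_teliospores": both_types,
        "phase": {k: tuple(v) for k, v in phase.items()},
    }


@dataclass(frozen=True)
class OrientationResult:
    best: tuple[tuple[str, str], ...]  # e.g. (("+", "+"),) — (scaffold_a, scaffold_b) strands
    event_counts: Mapping[tuple[str, str], int]
    resolved: bool


def infer_scaffold_orientation(
    table: pd.DataFrame,
    marker_map: MarkerMap,
    scaffold_a: str,
    scaffold_b: str,
) -> OrientationResult:
    """Infer the relative orientation of two scaffolds joined end to end.

    Evaluates the four junction orientations (each scaffold forward ``+``
    or reversed ``-``, A preceding B) and counts the total origin switches
    each implies across the haploid products; switches internal to a
    scaffold are orientation-invariant, so the orientations differ only in
    which scaffold ends abut.  Returns the minimal-event orientation(s);
    ties (e.g. all-parental products) are reported as unresolved.
    """
    products = collapse_products(table)
    haploid = products[
        ~products[[c for c in products.columns if c not in ("teliospore", "product")]]
        .eq(HET)
        .any(axis=1)
    ]
    if len(haploid) < 2:
        return OrientationResult(best=(), event_counts={}, resolved=False)

    ordered: dict[str, list[str]] = {}
    for scaffold in (scaffold_a, scaffold_b):
        ordered[scaffold] = marker_map.scaffold_markers(scaffold)["marker"].tolist()

    def switches(seq_calls: Sequence[str]) -> int:
        informative = [c for c in seq_calls if c in (P1, P2)]
        return sum(1 for x, y in zip(informative, informative[1:]) if x != y)

    counts: dict[tuple[str, str], int] = {}
    for oa in ("+", "-"):
        for ob in ("+", "-"):
            order_a = ordered[scaffold_a] if oa == "+" else ordered[scaffold_a][::-1]
            order_b = ordered[scaffold_b] if ob == "+" else ordered[scaffold_b][::-1]
            merged = order_a + order_b
            total = 0
            for _, row in haploid.iterrows():
                total += switches([row.get(m, MISSING) for m in merged])
            counts[(oa, ob)] = total

    minimum = min(counts.values())
    best = tuple(sorted(k for k, v in counts.items() if v == minimum))
    return OrientationResult(best=best, event_counts=counts, resolved=len(best) == 1)
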