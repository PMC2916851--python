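"""Meiosis and teliospore-packaging simulator for a two-parent yeast cross.

Emulates the genetics of a red-yeast cross followed by teliospore
micromanipulation: crossovers placed as a Poisson process along physical
(kb) coordinates with piecewise-constant genetic rate (baseline plus
hotspots, no chiasma interference), four-strand chromatid bookkeeping,
gene-conversion tracts, independent assortment of scaffolds, packaging of
the four meiotic nuclei into two binucleate basidiospores with asynchronous
germination (usually only one meiotic product is recovered per meiosis),
and rare failed-meiosis diploid products.  Every stochastic event is
written to a truth log so the segregation classifier can be validated
against known ground truth.

Conventions: positions are 1-based kb midpoints, intervals half-open
(pos_i, pos_{i+1}]; the centromere of each scaffold sits at its left end,
so sister chromatids keep their identity through crossing-over.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMap",
    "Hotspot",
    "SimConfig",
    "HaploidGenotype",
    "simulate_meiosis",
    "package_teliospore",
    "simulate_cross_experiment",
    "haldane_rf",
]

P1, P2, HET, MISSING = "P1", "P2", "HET", "NA"


class MarkerMap:
    """Physical marker positions (kb) on named scaffolds.

    Wraps a DataFrame with columns ``scaffold``, ``marker``, ``position_kb``;
    marker names must be unique and positions strictly increasing within a
    scaffold.
    """

    COLUMNS = ("scaffold", "marker", "position_kb")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"marker map missing columns: {missing}")
        table = table.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        table["position_kb"] = table["position_kb"].astype(float)
        if table["marker"].duplicated().any():
            dups = table.loc[table["marker"].duplicated(), "marker"].tolist()
            raise ValueError(f"duplicate marker names: {dups}")
        if (table["position_kb"] < 0).any():
            raise ValueError("marker positions must be >= 0 kb")
        for scaffold, sub in table.groupby("scaffold", sort=False):
            pos = sub["position_kb"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on scaffold {scaffold!r}")
        self.table = table

    def __len__(self) -> int:
        return len(self.table)

    @property
    def markers(self) -> list[str]:
        return self.table["marker"].tolist()

    def scaffolds(self) -> list[str]:
        return list(dict.fromkeys(self.table["scaffold"]))

    def scaffold_markers(self, scaffold: str) -> pd.DataFrame:
        sub = self.table[self.table["scaffold"] == scaffold]
        if sub.empty:
            raise KeyError(f"unknown scaffold {scaffold!r}")
        return sub

    def position(self, marker: str) -> float:
        row = self.table[self.table["marker"] == marker]
        if row.empty:
            raise KeyError(f"unknown marker {marker!r}")
        return float(row["position_kb"].iloc[0])

    def scaffold_of(self, marker: str) -> str:
        row = self.table[self.table["marker"] == marker]
        if row.empty:
            raise KeyError(f"unknown marker {marker!r}")
        return str(row["scaffold"].iloc[0])

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, float]]) -> "MarkerMap":
        return cls(pd.DataFrame(records, columns=list(cls.COLUMNS)))


@dataclass(frozen=True)
class Hotspot:
    scaffold: str
    start_kb: float
    end_kb: float
    kb_per_cM: float

    def __post_init__(self) -> None:
        if self.end_kb <= self.start_kb:
            raise ValueError("hotspot end must exceed start")
        if self.kb_per_cM <= 0:
            raise ValueError("kb_per_cM must be positive")


@dataclass
class SimConfig:
    """Simulation parameters for one cross.

    Defaults mirror the genetics of the studied cross: ~32 kb/cM autosomal
    recombination, recovery of both basidiospores' products in ~1/8 of
    teliospores (asynchronous germination), and a ~1/8 rate of
    failed-meiosis diploid products (one of eight teliospores examined).
    """

    kb_per_cM_baseline: float = 32.0
    hotspots: tuple[Hotspot, ...] = ()
    conversion_rate_per_marker: float = 0.01
    conversion_tract_mean_kb: float = 5.0
    p_recover_both_spores: float = 1 / 8
    p_diploid: float = 1 / 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kb_per_cM_baseline <= 0:
            raise ValueError("kb_per_cM_baseline must be positive")
        for p_name in ("conversion_rate_per_marker", "p_recover_both_spores", "p_diploid"):
            p = getattr(self, p_name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{p_name}={p} outside [0, 1]")
        if self.conversion_tract_mean_kb <= 0:
            raise ValueError("conversion_tract_mean_kb must be positive")
        by_scaffold: dict[str, list[Hotspot]] = {}
        for h in self.hotspots:
            by_scaffold.setdefault(h.scaffold, []).append(h)
        for scaffold, spots in by_scaffold.items():
            spots = sorted(spots, key=lambda h: h.start_kb)
            for a, b in zip(spots, spots[1:]):
                if b.start_kb < a.end_kb:
                    raise ValueError(f"overlapping hotspots on scaffold {scaffold!r}")

    def kb_per_cM_at(self, scaffold: str, pos_kb: float) -> float:
        for h in self.hotspots:
            if h.scaffold == scaffold and h.start_kb <= pos_kb < h.end_kb:
                return h.kb_per_cM
        return self.kb_per_cM_baseline


@dataclass
class HaploidGenotype:
    """Per-marker parental-origin calls for one recovered product."""

    origins: dict[str, str]  # marker -> P1 | P2 | HET
    meiosis: int = 0
    product: int = 0

    def is_diploid(self) -> bool:
        return any(v == HET for v in self.origins.values())


def _rate_segments(
    positions: np.ndarray, scaffold: str, config: SimConfig
) -> list[tuple[float, float, float]]:
    """Piecewise-constant genetic rate over [0, last marker]: (start, end, kb_per_cM)."""
    right = float(positions[-1])
    cuts = {0.0, right}
    for h in config.hotspots:
        if h.scaffold == scaffold:
            cuts.add(min(max(h.start_kb, 0.0), right))
            cuts.add(min(max(h.end_kb, 0.0), right))
    edges = sorted(cuts)
    segments = []
    for a, b in zip(edges, edges[1:]):
        if b > a:
            segments.append((a, b, config.kb_per_cM_at(scaffold, (a + b) / 2)))
    return segments


def haldane_rf(distance_kb: float, kb_per_cM: float) -> float:
    """Expected recombinant fraction between two markers under this model.

    The chromatid-level crossover rate is 1/(100·kb_per_cM) per kb (Morgans
    per kb), so with no interference RF = (1 − e^(−2m))/2 at map distance m
    Morgans.
    """
    m = distance_kb / (100.0 * kb_per_cM)
    return (1.0 - np.exp(-2.0 * m)) / 2.0


def simulate_meiosis(
    marker_map: MarkerMap, config: SimConfig, rng: np.random.Generator
) -> tuple[list[HaploidGenotype], dict]:
    """Simulate one meiosis; return the four products and a truth-log entry.

    Crossovers are sampled per scaffold as a Poisson process on the kb axis
    at bundle intensity 2/(100·kb_per_cM_local) per kb (so each chromatid
    accumulates exchanges at the Morgan rate).  Each crossover involves one
    randomly chosen chromatid of each homolog and swaps their distal
    segments.  Scaffolds assort independently (meiosis I orientation and
    meiosis II sister separation are randomized per scaffold).  Conversion
    tracts then overwrite covered markers on single chromatids with the
    homolog's allele, breaking the 2:2 ratio to 3:1 at covered markers.
    """
    if len(marker_map) == 0:
        raise ValueError("marker map is empty")

    origins_by_marker: dict[str, np.ndarray] = {}
    crossovers: list[dict] = []
    conversions: list[dict] = []
    founders: dict[str, list[str]] = {}

    # nucleus layout: [pole A product 0, pole A product 1, pole B 0, pole B 1]
    for scaffold in marker_map.scaffolds():
        sub = marker_map.scaffold_markers(scaffold)
        markers = sub["marker"].tolist()
        pos = sub["position_kb"].to_numpy()

        # chromatids 0,1 = P1 sisters; 2,3 = P2 sisters (origin coded 0/1)
        chrom = np.array([[0] * len(pos), [0] * len(pos), [1] * len(pos), [1] * len(pos)])

        segments = _rate_segments(pos, scaffold, config)
        xs: list[float] = []
        for a, b, kbcm in segments:
            if not np.isfinite(kbcm):
                continue
            lam = 2.0 * (b - a) / (100.0 * kbcm)  # bundle-level expected crossovers
            n = rng.poisson(lam)
            xs.extend(rng.uniform(a, b, size=n))
        for x in sorted(xs):
            i = rng.integers(0, 2)
            j = rng.integers(2, 4)
            distal = pos > x
            chrom[[i, j]] = chrom[[j, i]] * distal + chrom[[i, j]] * ~distal
            crossovers.append(
                {"scaffold": scaffold, "pos_kb": float(x), "chromatids": [int(i), int(j)]}
            )

        # gene conversion: per chromatid per marker, tract anchored at the marker
        if config.conversion_rate_per_marker > 0:
            for c in range(4):
                hits = rng.random(len(pos)) < config.conversion_rate_per_marker
                for k in np.flatnonzero(hits):
                    tract_len = rng.exponential(config.conversion_tract_mean_kb)
                    start, end = pos[k], pos[k] + tract_len
                    covered = (pos >= start) & (pos < end)
                    chrom[c, covered] = 1 - chrom[c, covered]
                    conversions.append(
                        {
                            "scaffold": scaffold,
                            "start_kb": float(start),
                            "end_kb": float(end),
                            "recipient_chromatid": int(c),
                            "markers": [markers[m] for m in np.flatnonzero(covered)],
                            "donor": P2 if chrom[c, k] == 1 else P1,
                        }
                    )

        # independent assortment: MI pole orientation + MII sister order
        if rng.random() < 0.5:
            pole_a, pole_b = [0, 1], [2, 3]
        else:
            pole_a, pole_b = [2, 3], [0, 1]
        rng.shuffle(pole_a)
        rng.shuffle(pole_b)
        nucleus_order = pole_a + pole_b
        for m_idx, marker in enumerate(markers):
            origins_by_marker[marker] = chrom[nucleus_order, m_idx]

        # remap logged chromatid ids to nucleus ids so truth refers to products;
        # founders give each product's origin at the scaffold's left end
        founders[scaffold] = [P1 if chromatid < 2 else P2 for chromatid in nucleus_order]
        to_nucleus = {chromatid: n for n, chromatid in enumerate(nucleus_order)}
        for ev in crossovers:
            if ev["scaffold"] == scaffold and "products" not in ev:
                ev["products"] = sorted(to_nucleus[c] for c in ev["chromatids"])
        for ev in conversions:
            if ev["scaffold"] == scaffold and "product" not in ev:
                ev["product"] = to_nucleus[ev.pop("recipient_chromatid")]

    products = []
    for n in range(4):
        origins = {
            marker: (P1 if origins_by_marker[marker][n] == 0 else P2)
            for marker in marker_map.markers
        }
        products.append(HaploidGenotype(origins=origins, product=n))

    truth = {
        "crossovers": crossovers,
        "conversions": conversions,
        "founders": founders,
        "outcome": None,
    }
    return products, truth


def package_teliospore(
    products: Sequence[HaploidGenotype], config: SimConfig, rng: np.random.Generator
) -> tuple[list[HaploidGenotype], str]:
    """Package four meiotic nuclei into basidiospores and recover products.

    With probability ``p_diploid`` the teliospore yields a single diploid
    (HET at every marker), modelling failed meiosis.  Otherwise the four
    nuclei are partitioned at random into two binucleate basidiospores;
    asynchronous germination means the recovered colony descends from one
    clonal product of one spore, and only with probability
    ``p_recover_both_spores`` is a product of the second spore recovered
    too.  Returns recovered genotypes and an outcome class.
    """
    if len(products) != 4:
        raise ValueError("a meiosis yields exactly four products")
    if rng.random() < config.p_diploid:
        markers = products[0].origins.keys()
        diploid = HaploidGenotype(origins={m: HET for m in markers}, product=-1)
        return [diploid], "DIPLOID"
    order = rng.permutation(4)
    spore_a, spore_b = order[:2], order[2:]
    first = products[int(rng.choice(spore_a))]
    recovered = [first]
    outcome = "HAPLOID_ONE_SPORE"
    if rng.random() < config.p_recover_both_spores:
        recovered.append(products[int(rng.choice(spore_b))])
        outcome = "HAPLOID_BOTH_SPORES"
    return recovered, outcome


def simulate_cross_experiment(
    marker_map: MarkerMap,
    config: SimConfig,
    n_teliospores: int,
    colonies_per_teliospore: int = 3,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Simulate a micromanipulation experiment over ``n_teliospores`` meioses.

    Returns a progeny table (one row per colony; colonies of one teliospore
    are mitotic clones of the recovered product(s)) and the truth log.  When
    both basidiospores' products are recovered, each contributes at least
    one colony.
    """
    if n_teliospores < 1:
        raise ValueError("n_teliospores must be >= 1")
    if colonies_per_teliospore < 1:
        raise ValueError("colonies_per_teliospore must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    rows = []
    truth_log = []
    for t in range(1, n_teliospores + 1):
        products, truth = simulate_meiosis(marker_map, config, rng)
        recovered, outcome = package_teliospore(products, config, rng)
        truth["meiosis"] = t
        truth["outcome"] = outcome
        truth["recovered_products"] = [g.product for g in recovered]
        truth_log.append(truth)
        # assign colonies to recovered clonal products; every product seen >= once
        assignment = list(range(len(recovered)))
        if colonies_per_teliospore > len(recovered):
            assignment += list(
                rng.integers(0, len(recovered), size=colonies_per_teliospore - len(recovered))
            )
        for c, which in enumerate(assignment[:colonies_per_teliospore], start=1):
            genotype = recovered[which]
            row = {"teliospore": f"T{t}", "colony": f"T{t}.{c}"}
            row.update(genotype.origins)
            rows.append(row)
    table = pd.DataFrame(rows, columns=["teliospore", "colony", *marker_map.markers])
    return table, truth_log
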