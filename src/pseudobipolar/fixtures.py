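"""Worked-example fixtures built programmatically.

Three small datasets mirror the published worked examples of the studied
cross (CBS 6832, MAT A2, HD allele A2-15 × ML 2241, MAT A1, HD allele
A1-3; origin convention P1 = ML 2241, P2 = CBS 6832):

* the eight-teliospore cohesion table (six parental meioses, T1 yielding
  both parental mating types, T7 the receptor–HD recombinant, T8 an
  all-heterozygous diploid);
* the cross-outcome panel for the novel recombinant mating type T7.1;
* the 27-kb recombination-hotspot example (3 recombinants among 7 haploid
  products, i.e. 0.63 kb/cM).

A synthetic natural-isolate survey table emulates the one-to-many
receptor/HD association (six A1-linked and seven A2-linked HD alleles).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .mating import Compatibility, MatingType
from .meiosis import HET, P1, P2, Hotspot, MarkerMap, SimConfig

__all__ = [
    "PHASE",
    "cohesion_fixture",
    "mating_panel_fixture",
    "hotspot_fixture",
    "cross_marker_map",
    "cross_sim_config",
    "natural_isolate_table",
    "make_fixtures",
]

# parental phase of the cross: which receptor travels with which HD allele
PHASE = {P1: ("A1", "A1-3"), P2: ("A2", "A2-15")}


def cohesion_fixture() -> tuple[pd.DataFrame, dict]:
    """Eight-teliospore progeny table at the STE3 and HD1/HD2 markers."""
    rows = []

    def add(telio: str, genotypes: list[tuple[str, str]]) -> None:
        for i, (ste3, hd) in enumerate(genotypes, start=1):
            rows.append(
                {"teliospore": telio, "colony": f"{telio}.{i}", "STE3": ste3, "HD": hd}
            )

    add("T1", [(P1, P1), (P2, P2), (P2, P2)])  # both parental mating types recovered
    add("T2", [(P2, P2)] * 3)
    add("T3", [(P1, P1)] * 3)
    add("T4", [(P1, P1)] * 3)
    add("T5", [(P2, P2)] * 3)
    add("T6", [(P1, P1)] * 3)
    add("T7", [(P1, P2)] * 3)  # novel mating type: A1 receptor with the A2-15 HD allele
    add("T8", [(HET, HET)] * 3)  # failed meiosis, diploid
    return pd.DataFrame(rows), dict(PHASE)


def mating_panel_fixture() -> tuple[dict[str, MatingType], list[tuple[str, str, Compatibility]]]:
    """Cross panel for the recombinant strain T7.1 and its expected outcomes."""
    strains = {
        "T7.1": MatingType("A1", "A2-15"),
        "ML 2241": MatingType("A1", "A1-3"),
        "CBS 6832": MatingType("A2", "A2-15"),
        "tester_A2": MatingType("A2", "A2-7"),  # differs at both regions from T7.1
    }
    expected = [
        ("T7.1", "ML 2241", Compatibility.NONE),  # shared receptor: no filamentation
        ("T7.1", "CBS 6832", Compatibility.PHEROMONE_ONLY),  # shared HD allele
        ("T7.1", "tester_A2", Compatibility.COMPLETE),
        ("ML 2241", "CBS 6832", Compatibility.COMPLETE),  # the parental cross itself
    ]
    return strains, expected


def hotspot_fixture() -> tuple[pd.DataFrame, MarkerMap]:
    """Seven haploid products over the 27-kb hotspot flanking the HD1/HD2 pair.

    Three of seven products are recombinant between the flanking markers:
    RF = 3/7, map distance 42.9 cM, 27/42.9 = 0.63 kb/cM.
    """
    marker_map = MarkerMap.from_records(
        [("scaffold_7", "RecQ", 1200.0), ("scaffold_7", "HD", 1227.0)]
    )
    calls = [
        (P1, P1),
        (P2, P2),
        (P1, P1),
        (P2, P2),
        (P2, P1),  # recombinant (T5)
        (P1, P2),  # recombinant (T6)
        (P1, P2),  # recombinant (T7)
    ]
    rows = [
        {"teliospore": f"T{i}", "colony": f"T{i}.1", "RecQ": a, "HD": b}
        for i, (a, b) in enumerate(calls, start=1)
    ]
    return pd.DataFrame(rows), marker_map


def cross_marker_map() -> MarkerMap:
    """Marker map emulating the two MAT-bearing scaffolds of the cross.

    scaffold_7 carries the HD1/HD2 gene pair with the adjacent 27-kb
    recombination hotspot; scaffold_9 carries the STE3 receptor gene.
    Positions (1-based kb) are plausible stand-ins for the published gene
    arrangement, not real coordinates.
    """
    return MarkerMap.from_records(
        [
            ("scaffold_7", "MIP", 10.0),
            ("scaffold_7", "CYC1", 230.0),
            ("scaffold_7", "GLN1", 980.0),
            ("scaffold_7", "RecQ", 1200.0),
            ("scaffold_7", "HD", 1227.0),
            ("scaffold_9", "PAN6", 40.0),
            ("scaffold_9", "IsocL", 210.0),
            ("scaffold_9", "LSm7", 560.0),
            ("scaffold_9", "STE3", 590.0),
            ("scaffold_9", "RPL11", 900.0),
        ]
    )


def cross_sim_config(seed: int = 0) -> SimConfig:
    """Simulation parameters emulating the studied cross.

    ~32 kb/cM baseline, a 0.63 kb/cM hotspot over the 27 kb adjacent to the
    HD pair, sparse single-marker gene-conversion tracts, 1/8 chance of
    recovering both basidiospores' products and 1/8 chance of a diploid
    (failed-meiosis) teliospore.
    """
    return SimConfig(
        kb_per_cM_baseline=32.0,
        hotspots=(Hotspot("scaffold_7", 1200.0, 1227.0, 0.63),),
        conversion_rate_per_marker=0.01,
        conversion_tract_mean_kb=5.0,
        p_recover_both_spores=1 / 8,
        p_diploid=1 / 8,
        seed=seed,
    )


def natural_isolate_table(n_strains: int = 36) -> pd.DataFrame:
    """Synthetic natural-isolate strain table (one-to-many association).

    Thirteen HD alleles, six locked to the Ste3.A1 receptor and seven to
    Ste3.A2, distributed over ``n_strains`` haploid isolates plus one
    self-fertile record; emulates the structure of a worldwide isolate
    survey, not real strain identities.
    """
    a1_alleles = [f"A1-{i}" for i in range(1, 7)]
    a2_alleles = [f"A2-{i}" for i in range(11, 18)]
    rows = []
    k = 0
    while len(rows) < n_strains:
        if k % 2 == 0:
            receptor, hd = "A1", a1_alleles[(k // 2) % len(a1_alleles)]
            behaviour = "A1"
        else:
            receptor, hd = "A2", a2_alleles[(k // 2) % len(a2_alleles)]
            behaviour = "A2"
        rows.append(
            {
                "strain": f"SYN {1000 + k}",
                "species": "S. salmonicolor",
                "receptor": receptor,
                "hd": hd,
                "behaviour": behaviour,
            }
        )
        k += 1
    rows.append(
        {
            "strain": "SYN 2000",
            "species": "S. johnsonii",
            "receptor": "A1/A2",
            "hd": "A1-1/A2-11",
            "behaviour": "SELF_FERTILE",
        }
    )
    return pd.DataFrame(rows)


def make_fixtures(out_dir) -> dict[str, Path]:
    """Write all packaged fixtures as TSV files; returns the paths."""
    from .io import write_marker_map, write_progeny_table, write_tsv_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    cohesion, phase = cohesion_fixture()
    paths["cohesion_progeny"] = out / "cohesion_progeny.tsv"
    write_progeny_table(paths["cohesion_progeny"], cohesion)
    phase_rows = pd.DataFrame(
        [{"parent": p, "receptor": r, "hd": h} for p, (r, h) in phase.items()]
    )
    paths["phase"] = out / "phase.tsv"
    write_tsv_table(paths["phase"], phase_rows)

    strains, expected = mating_panel_fixture()
    panel = pd.DataFrame(
        [
            {"strain": name, "receptor": mt.receptor_allele, "hd": mt.hd_allele}
            for name, mt in strains.items()
        ]
    )
    paths["mating_panel"] = out / "mating_panel.tsv"
    write_tsv_table(paths["mating_panel"], panel)
    crosses = pd.DataFrame(
        [{"strain_a": a, "strain_b": b, "expected": o.value} for a, b, o in expected]
    )
    paths["mating_crosses"] = out / "mating_crosses.tsv"
    write_tsv_table(paths["mating_crosses"], crosses)

    hotspot_table, hotspot_map = hotspot_fixture()
    paths["hotspot_progeny"] = out / "hotspot_progeny.tsv"
    write_progeny_table(paths["hotspot_progeny"], hotspot_table)
    paths["hotspot_map"] = out / "hotspot_map.tsv"
    write_marker_map(paths["hotspot_map"], hotspot_map)

    paths["strains"] = out / "strains.tsv"
    write_tsv_table(paths["strains"], natural_isolate_table())
    return paths
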