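"""Independent oracles used by the test suite.

Deliberately written against Biopython's translation machinery and plain
Python enumeration, independent of the package's own implementations.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Seq import Seq

BASES = "ACGT"


def translate(codon: str) -> str:
    """Amino acid, with '*' for stop (Biopython translation)."""
    return str(Seq(codon).translate())


def syn_sites_bruteforce(codon: str) -> float:
    """Fractional synonymous sites by enumerating all 9 single-base changes."""
    aa = translate(codon)
    syn = 0
    for pos, b in itertools.product(range(3), BASES):
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        if translate(alt) == aa:
            syn += 1
    return syn / 3.0


def pathway_diffs_bruteforce(c1: str, c2: str) -> tuple[float, float]:
    """(syn, nonsyn) differences by recursive DFS over mutational pathways.

    Explores every order of fixing the differing positions one at a time;
    pathways visiting a stop codon are collected separately and used only
    if no stop-free pathway exists.
    """
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []

    def walk(current: str, remaining: list[int], syn: int, nonsyn: int, hit_stop: bool) -> None:
        if not remaining:
            (blocked if hit_stop else valid).append((syn, nonsyn))
            return
        for pos in remaining:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            step_stop = translate(nxt) == "*"
            step_syn = (not step_stop) and translate(nxt) == translate(current)
            walk(
                nxt,
                [p for p in remaining if p != pos],
                syn + int(step_syn),
                nonsyn + int((not step_stop) and not step_syn),
                hit_stop or step_stop,
            )

    walk(c1, [i for i in range(3) if c1[i] != c2[i]], 0, 0, False)
    paths = valid or blocked
    if not paths:
        return 0.0, 0.0
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


SENSE_CODONS_BRUTE = [
    "".join(c) for c in itertools.product(BASES, repeat=3) if translate("".join(c)) != "*"
]


def sib_odds_enumeration(r: float) -> float:
    """Sib-compatibility odds by enumerating the 16 ordered genotype pairs."""
    genotypes = [((0, 0), (1 - r) / 2), ((1, 1), (1 - r) / 2), ((0, 1), r / 2), ((1, 0), r / 2)]
    total = 0.0
    for (g1, f1), (g2, f2) in itertools.product(genotypes, repeat=2):
        if g1[0] != g2[0] and g1[1] != g2[1]:
            total += f1 * f2
    return total


def replay_truth_origins(truth: dict, marker_map) -> list[dict[str, str]]:
    """Reconstruct the four products' marker origins from a truth-log entry."""
    origins: list[dict[str, str]] = [{} for _ in range(4)]
    for scaffold in marker_map.scaffolds():
        sub = marker_map.scaffold_markers(scaffold)
        markers = sub["marker"].tolist()
        pos = sub["position_kb"].to_numpy()
        rows = np.array(
            [[0 if f == "P1" else 1] * len(pos) for f in truth["founders"][scaffold]]
        )
        events = [e for e in truth["crossovers"] if e["scaffold"] == scaffold]
        for ev in sorted(events, key=lambda e: e["pos_kb"]):
            i, j = ev["products"]
            distal = pos > ev["pos_kb"]
            tmp = rows[i, distal].copy()
            rows[i, distal] = rows[j, distal]
            rows[j, distal] = tmp
        for conv in truth["conversions"]:
            if conv["scaffold"] != scaffold:
                continue
            for m in conv["markers"]:
                k = markers.index(m)
                rows[conv["product"], k] = 1 - rows[conv["product"], k]
        for n in range(4):
            for k, m in enumerate(markers):
                origins[n][m] = "P1" if rows[n, k] == 0 else "P2"
    return origins
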