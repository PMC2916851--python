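"""Pairwise Nei–Gojobori (1986) dN/dS with sliding-window and domain averages.

Implements the classic counting method on codon alignments: fractional
synonymous/nonsynonymous site counts per codon, substitution pathways
averaged over all orderings of single-step mutations (pathways through stop
codons excluded), proportions converted to distances with the Jukes–Cantor
correction d = −(3/4)·ln(1 − 4p/3).  Window and domain statistics average
dN and dS over all unordered allele pairs and report the ratio of the means
(robust when single pairs have dS = 0).

Universal genetic code only; gap/ambiguity handling is pairwise deletion
per codon column.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "CodonAlignment",
    "NG86Result",
    "ng86_pair",
    "pairwise_matrix",
    "sliding_window",
    "domain_averages",
    "jukes_cantor",
    "SENSE_CODONS",
    "translate_codon",
]

_TABLE = CodonTable.standard_dna_table
_FORWARD = dict(_TABLE.forward_table)
_STOPS = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_FORWARD))
_BASES = "ACGT"


def translate_codon(codon: str) -> Optional[str]:
    """Amino acid for a sense codon, None for a stop codon."""
    return _FORWARD.get(codon)


def _is_sense(codon: str) -> bool:
    return codon in _FORWARD


@lru_cache(maxsize=None)
def _syn_sites(codon: str) -> float:
    """Fractional synonymous sites of one codon (NG86).

    Each position contributes (synonymous single-base changes)/3; changes to
    stop codons count as nonsynonymous, so sites per codon always sum to 3.
    """
    aa = _FORWARD[codon]
    syn = 0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if _FORWARD.get(alt) == aa:
                syn += 1
    return syn / 3.0


@lru_cache(maxsize=None)
def _pair_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons.

    Codons differing at k positions are resolved by averaging over the k!
    orderings of single-step pathways; pathways passing through a stop codon
    are excluded (if every pathway is blocked, all are used as a fallback).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in itertools.permutations(diff_pos):
        current = c1
        syn = nonsyn = 0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if nxt in _STOPS:
                through_stop = True
            elif _FORWARD.get(nxt) == _FORWARD.get(current):
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        (blocked if through_stop else valid).append((syn, nonsyn))
    paths = valid or blocked
    s = sum(p[0] for p in paths) / len(paths)
    n = sum(p[1] for p in paths) / len(paths)
    return s, n


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor multiple-hit correction; NaN for p >= 3/4 (saturation)."""
    if not np.isfinite(p) or p >= 0.75:
        return math.nan
    if p < 0:
        raise ValueError("proportion must be >= 0")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _to_codons(seq) -> list[str]:
    s = str(seq).upper().replace("U", "T")
    if len(s) % 3 != 0:
        raise ValueError(f"sequence length {len(s)} not divisible by 3")
    return [s[i : i + 3] for i in range(0, len(s), 3)]


@dataclass(frozen=True)
class NG86Result:
    n_sites: float
    s_sites: float
    n_diffs: float
    s_diffs: float

    @property
    def pn(self) -> float:
        return self.n_diffs / self.n_sites if self.n_sites > 0 else math.nan

    @property
    def ps(self) -> float:
        return self.s_diffs / self.s_sites if self.s_sites > 0 else math.nan

    @property
    def dn(self) -> float:
        return jukes_cantor(self.pn) if np.isfinite(self.pn) else math.nan

    @property
    def ds(self) -> float:
        return jukes_cantor(self.ps) if np.isfinite(self.ps) else math.nan


def _pair_arrays(codons_a: Sequence[str], codons_b: Sequence[str]) -> np.ndarray:
    """Per-codon-column (s_sites, n_sites, s_diffs, n_diffs, comparable) arrays.

    Columns where either codon is not an unambiguous sense codon (gaps,
    ambiguity codes, stops) are excluded pairwise (all-zero, flag 0).
    """
    if len(codons_a) != len(codons_b):
        raise ValueError("sequences differ in codon length")
    out = np.zeros((len(codons_a), 5))
    for i, (ca, cb) in enumerate(zip(codons_a, codons_b)):
        if not (_is_sense(ca) and _is_sense(cb)):
            continue
        s_sites = (_syn_sites(ca) + _syn_sites(cb)) / 2.0
        sd, nd = _pair_diffs(ca, cb)
        out[i] = (s_sites, 3.0 - s_sites, sd, nd, 1.0)
    return out


def ng86_pair(seq_a, seq_b) -> NG86Result:
    """NG86 site and difference counts for one pair of coding sequences.

    Accepts nucleotide strings (or Seq objects) of equal length divisible
    by 3, or pre-split codon lists.
    """
    codons_a = list(seq_a) if _looks_like_codons(seq_a) else _to_codons(seq_a)
    codons_b = list(seq_b) if _looks_like_codons(seq_b) else _to_codons(seq_b)
    arr = _pair_arrays(codons_a, codons_b)
    if arr[:, 4].sum() == 0:
        raise ValueError("no comparable codon columns after pairwise exclusion")
    s_sites, n_sites, s_diffs, n_diffs, _ = arr.sum(axis=0)
    return NG86Result(n_sites=n_sites, s_sites=s_sites, n_diffs=n_diffs, s_diffs=s_diffs)


def _looks_like_codons(seq) -> bool:
    return isinstance(seq, (list, tuple)) and all(isinstance(c, str) and len(c) == 3 for c in seq)


class CodonAlignment:
    """An in-frame multiple alignment of coding sequences.

    Sequences must share one length divisible by 3 and contain no internal
    stop codons; the optional domain partition is a list of
    (name, start_codon, end_codon) in 1-based inclusive codon coordinates
    covering the alignment without overlap.
    """

    def __init__(
        self,
        sequences: dict[str, str],
        domains: Optional[Sequence[tuple[str, int, int]]] = None,
    ):
        if not sequences:
            raise ValueError("alignment has no sequences")
        lengths = {len(str(s)) for s in sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError(f"alignment length {length} not divisible by 3")
        self.codons = {name: _to_codons(seq) for name, seq in sequences.items()}
        self.n_codons = length // 3
        for name, codons in self.codons.items():
            for i, c in enumerate(codons[:-1]):
                if c in _STOPS:
                    raise ValueError(f"internal stop codon in {name!r} at codon {i + 1}")
        self.domains = list(domains) if domains else None
        if self.domains:
            self._validate_domains()

    def _validate_domains(self) -> None:
        covered = 0
        prev_end = 0
        for name, start, end in self.domains:
            if start != prev_end + 1 or end < start:
                raise ValueError(f"domain {name!r} [{start}, {end}] breaks the partition")
            covered += end - start + 1
            prev_end = end
        if covered != self.n_codons:
            raise ValueError("domain partition does not cover the alignment")

    @property
    def names(self) -> list[str]:
        return list(self.codons)

    def pairs(self) -> list[tuple[str, str]]:
        return list(itertools.combinations(self.names, 2))

    @classmethod
    def from_fasta(cls, path, domains=None) -> "CodonAlignment":
        from Bio import SeqIO

        sequences = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(sequences, domains=domains)


def pairwise_matrix(alignment: CodonAlignment) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric dN and dS matrices over all allele pairs (NaN where undefined)."""
    names = alignment.names
    if len(names) < 2:
        raise ValueError("pairwise matrix needs >= 2 alleles")
    dn = pd.DataFrame(0.0, index=names, columns=names)
    ds = pd.DataFrame(0.0, index=names, columns=names)
    for a, b in alignment.pairs():
        res = ng86_pair(alignment.codons[a], alignment.codons[b])
        dn.loc[a, b] = dn.loc[b, a] = res.dn
        ds.loc[a, b] = ds.loc[b, a] = res.ds
    return dn, ds


def _window_stats(cum: np.ndarray, start: int, stop: int) -> tuple[float, float]:
    """(dn, ds) of one pair over codon slice [start, stop) from cumulative sums."""
    s_sites, n_sites, s_diffs, n_diffs, n_cmp = cum[stop] - cum[start]
    if n_cmp == 0 or s_sites == 0 or n_sites == 0:
        return math.nan, math.nan
    return jukes_cantor(n_diffs / n_sites), jukes_cantor(s_diffs / s_sites)


def _pair_cumulative(alignment: CodonAlignment) -> dict[tuple[str, str], np.ndarray]:
    cums = {}
    for a, b in alignment.pairs():
        arr = _pair_arrays(alignment.codons[a], alignment.codons[b])
        cums[(a, b)] = np.vstack([np.zeros(5), np.cumsum(arr, axis=0)])
    return cums


def _aggregate(pair_vals: Iterable[tuple[float, float]]) -> tuple[float, float, float]:
    """Mean dN, mean dS over pairs with both defined, and their ratio."""
    vals = [(dn, ds) for dn, ds in pair_vals if np.isfinite(dn) and np.isfinite(ds)]
    if not vals:
        return math.nan, math.nan, math.nan
    mean_dn = float(np.mean([v[0] for v in vals]))
    mean_ds = float(np.mean([v[1] for v in vals]))
    ratio = mean_dn / mean_ds if mean_ds > 0 else math.nan
    return mean_dn, mean_ds, ratio


def sliding_window(alignment: CodonAlignment, size: int = 20, step: int = 1) -> pd.DataFrame:
    """Sliding-window dN, dS and dN/dS averaged over all allele pairs.

    Windows of ``size`` codons start at codons 1 … L−size+1 (1-based, step
    in codons).  The ratio is mean-dN over mean-dS; windows where mean dS
    is zero or no pair is defined report NaN.
    """
    if size < 1 or step < 1:
        raise ValueError("size and step must be >= 1")
    if alignment.n_codons < size:
        raise ValueError(f"alignment ({alignment.n_codons} codons) shorter than window ({size})")
    if len(alignment.names) < 2:
        raise ValueError("sliding window needs >= 2 alleles")
    cums = _pair_cumulative(alignment)
    rows = []
    for start in range(0, alignment.n_codons - size + 1, step):
        mean_dn, mean_ds, ratio = _aggregate(
            _window_stats(cum, start, start + size) for cum in cums.values()
        )
        rows.append(
            {"window_start_codon": start + 1, "dn": mean_dn, "ds": mean_ds, "dn_ds": ratio}
        )
    return pd.DataFrame(rows)


def domain_averages(alignment: CodonAlignment) -> pd.DataFrame:
    """Per-domain mean dN, dS and dN/dS over all allele pairs."""
    if not alignment.domains:
        raise ValueError("alignment has no domain partition")
    if len(alignment.names) < 2:
        raise ValueError("domain averages need >= 2 alleles")
    cums = _pair_cumulative(alignment)
    rows = []
    for name, start, end in alignment.domains:
        mean_dn, mean_ds, ratio = _aggregate(
            _window_stats(cum, start - 1, end) for cum in cums.values()
        )
        rows.append(
            {
                "domain": name,
                "start_codon": start,
                "end_codon": end,
                "dn": mean_dn,
                "ds": mean_ds,
                "dn_ds": ratio,
            }
        )
    return pd.DataFrame(rows)
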