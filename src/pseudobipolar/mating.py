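"""Two-checkpoint mating-compatibility model and sib-mating (inbreeding) odds.

In bipolar and tetrapolar basidiomycetes two molecular recognition systems
gate sexual reproduction: a pheromone/receptor (PR) checkpoint controlling
cell-cell recognition and filamentation, and a homeodomain (HD1/HD2)
checkpoint whose heterodimer licenses progression through the sexual cycle.
A cross succeeds only when the two haploids carry different alleles at BOTH
regions.  The functions here encode that truth table and compute the
probability that two sibling spores of a single meiosis can mate, as a
function of the recombination fraction ``r`` between the two MAT regions:
``r = 0`` is a fully linked bipolar locus, ``r = 0.5`` two unlinked
(tetrapolar) regions, and ``0 < r < 0.5`` the intermediate pseudo-bipolar
configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "MatingType",
    "Compatibility",
    "CrossOutcome",
    "SystemKind",
    "MatingSystemSpec",
    "cross_outcome",
    "sib_compatibility_probability",
    "simulate_sib_matings",
    "SibMatingEstimate",
]


@dataclass(frozen=True)
class MatingType:
    """A haploid strain's mating identity: (receptor allele, HD allele).

    The two fields are independent: recombinant combinations that do not
    occur among natural isolates (e.g. a Ste3.A1 receptor with an A2-linked
    HD allele) are representable.
    """

    receptor_allele: str
    hd_allele: str

    def __post_init__(self) -> None:
        if not self.receptor_allele or not self.hd_allele:
            raise ValueError("mating type requires non-empty receptor and HD allele ids")


class Compatibility(str, Enum):
    COMPLETE = "COMPLETE"          # dikaryotic mycelium with clamps + teliospores
    PHEROMONE_ONLY = "PHEROMONE_ONLY"  # pseudohyphal growth from pheromone signalling
    NONE = "NONE"                  # no switch to filamentous growth


@dataclass(frozen=True)
class CrossOutcome:
    category: Compatibility
    mycelium_with_clamps: bool
    teliospores: bool


class SystemKind(str, Enum):
    BIPOLAR = "BIPOLAR"
    TETRAPOLAR = "TETRAPOLAR"
    PSEUDO_BIPOLAR = "PSEUDO_BIPOLAR"


@dataclass(frozen=True)
class MatingSystemSpec:
    """MAT architecture: kind plus the PR–HD recombination fraction ``r``.

    ``n_pr_alleles``/``n_hd_alleles`` describe population-level allele
    richness; a single meiosis segregates at most two alleles per region,
    so sib-mating odds depend on ``r`` only.
    """

    kind: SystemKind
    r: float = field(default=0.0)
    n_pr_alleles: int = 2
    n_hd_alleles: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 0.5:
            raise ValueError(f"recombination fraction r={self.r!r} outside [0, 0.5]")
        if self.n_pr_alleles < 2 or self.n_hd_alleles < 2:
            raise ValueError("a mating system needs >= 2 alleles per region")
        kind = SystemKind(self.kind)
        if kind is SystemKind.BIPOLAR and self.r != 0.0:
            raise ValueError("bipolar implies r = 0")
        if kind is SystemKind.TETRAPOLAR and self.r != 0.5:
            raise ValueError("tetrapolar implies r = 0.5")
        if kind is SystemKind.PSEUDO_BIPOLAR and not 0.0 < self.r < 0.5:
            raise ValueError("pseudo-bipolar implies 0 < r < 0.5")

    @classmethod
    def bipolar(cls) -> "MatingSystemSpec":
        return cls(SystemKind.BIPOLAR, r=0.0)

    @classmethod
    def tetrapolar(cls) -> "MatingSystemSpec":
        return cls(SystemKind.TETRAPOLAR, r=0.5)

    @classmethod
    def pseudo_bipolar(cls, r: float) -> "MatingSystemSpec":
        return cls(SystemKind.PSEUDO_BIPOLAR, r=r)

    @classmethod
    def from_r(cls, r: float) -> "MatingSystemSpec":
        if r == 0.0:
            return cls.bipolar()
        if r == 0.5:
            return cls.tetrapolar()
        return cls.pseudo_bipolar(r)


def cross_outcome(a: MatingType, b: MatingType) -> CrossOutcome:
    """Outcome of a cross between two haploids under the two-checkpoint model.

    Heterozygosity at both regions is a prerequisite for completing the
    sexual cycle.  Sharing the pheromone receptor allele aborts the switch
    to filamentous growth altogether; different receptors with a shared HD
    allele permit pheromone-driven pseudohyphal growth but no dikaryotic
    mycelium or teliospores.  Symmetric in its arguments.
    """
    if not isinstance(a, MatingType) or not isinstance(b, MatingType):
        raise TypeError("cross_outcome expects two MatingType values")
    if a.receptor_allele == b.receptor_allele:
        return CrossOutcome(Compatibility.NONE, mycelium_with_clamps=False, teliospores=False)
    if a.hd_allele == b.hd_allele:
        return CrossOutcome(Compatibility.PHEROMONE_ONLY, mycelium_with_clamps=False, teliospores=False)
    return CrossOutcome(Compatibility.COMPLETE, mycelium_with_clamps=True, teliospores=True)


def _spore_frequencies(r: float) -> np.ndarray:
    """Genotype frequencies of meiotic products of a doubly heterozygous cross.

    Order: (PR1,HD1), (PR2,HD2) parental at (1-r)/2 each; (PR1,HD2), (PR2,HD1)
    recombinant at r/2 each.
    """
    return np.array([(1 - r) / 2, (1 - r) / 2, r / 2, r / 2])


# Genotypes as (pr allele index, hd allele index); same order as _spore_frequencies.
_SPORE_GENOTYPES = np.array([(0, 0), (1, 1), (0, 1), (1, 0)])


def sib_compatibility_probability(spec: MatingSystemSpec) -> float:
    """Probability that two sibling spores can complete the sexual cycle.

    Two spores are drawn independently (with replacement) from the genotype
    frequency distribution of one meiosis' products; they are compatible iff
    they differ at both the receptor and the HD region.  Closed form
    ``((1-r)^2 + r^2) / 2``: 0.50 for bipolar (r=0), 0.25 for tetrapolar
    (r=0.5), strictly in between for pseudo-bipolar systems.
    """
    r = spec.r
    return ((1 - r) ** 2 + r**2) / 2


@dataclass(frozen=True)
class SibMatingEstimate:
    p_hat: float
    se: float
    n_pairs: int


def simulate_sib_matings(spec: MatingSystemSpec, n_pairs: int, seed: int) -> SibMatingEstimate:
    """Monte-Carlo check of :func:`sib_compatibility_probability`.

    Draws ``n_pairs`` independent spore pairs from the meiotic genotype
    distribution and scores full (two-checkpoint) compatibility.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    freqs = _spore_frequencies(spec.r)
    first = rng.choice(4, size=n_pairs, p=freqs)
    second = rng.choice(4, size=n_pairs, p=freqs)
    g1 = _SPORE_GENOTYPES[first]
    g2 = _SPORE_GENOTYPES[second]
    compatible = (g1[:, 0] != g2[:, 0]) & (g1[:, 1] != g2[:, 1])
    p_hat = float(compatible.mean())
    se = math.sqrt(max(p_hat * (1 - p_hat), 1e-12) / n_pairs)
    return SibMatingEstimate(p_hat=p_hat, se=se, n_pairs=n_pairs)
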