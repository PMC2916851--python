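"""Synthetic codon-alignment generator with domain-structured selection.

Emulates a multi-allelic transcription-factor gene of the kind found at
fungal MAT loci: a hypervariable N-terminal (specificity) domain under
diversifying selection (target dN/dS > 1), a strongly conserved
homeodomain, and a moderately conserved C-terminal domain.  Alleles evolve
independently from a common random ancestor by single-nucleotide codon
substitutions; nonsynonymous changes are accepted with a domain-specific
probability tuned so the realized pairwise dN/dS approximates the target.
No indels; no stop codons are ever introduced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dnds import SENSE_CODONS, translate_codon

__all__ = ["DomainSpec", "SyntheticAlignment", "synthesize_coding_alignment"]

_BASES = "ACGT"


@dataclass(frozen=True)
class DomainSpec:
    """One gene domain: length (codons), target dN/dS, substitution intensity.

    ``subs_per_codon`` scales divergence: the expected number of attempted
    substitutions per codon per allele lineage.
    """

    name: str
    n_codons: int
    omega: float
    subs_per_codon: float = 0.5

    def __post_init__(self) -> None:
        if self.n_codons < 1:
            raise ValueError("domain length must be >= 1 codon")
        if self.omega < 0:
            raise ValueError("target omega must be >= 0")
        if self.subs_per_codon < 0:
            raise ValueError("subs_per_codon must be >= 0")


@dataclass
class SyntheticAlignment:
    sequences: dict[str, str]  # allele name -> nucleotide sequence
    domains: list[tuple[str, int, int]]  # (name, start_codon, end_codon), 1-based inclusive

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n{seq}\n")


def _evolve_domain(codons: list[str], spec: DomainSpec, rng: np.random.Generator) -> None:
    """Apply accepted substitutions to ``codons`` in place.

    Proposal: random codon, random position, random alternative base.
    Proposals creating stop codons are rejected outright.  Acceptance
    probability min(1, omega) for nonsynonymous and min(1, 1/omega) for
    synonymous proposals, so the realized nonsyn/syn rate ratio tracks the
    target omega on both sides of 1.
    """
    n_attempts = rng.poisson(spec.n_codons * spec.subs_per_codon)
    p_nonsyn = min(1.0, spec.omega)
    p_syn = 1.0 if spec.omega == 0 else min(1.0, 1.0 / spec.omega)
    for _ in range(n_attempts):
        k = int(rng.integers(spec.n_codons))
        pos = int(rng.integers(3))
        old = codons[k]
        alternatives = [b for b in _BASES if b != old[pos]]
        new = old[:pos] + alternatives[int(rng.integers(3))] + old[pos + 1 :]
        if translate_codon(new) is None:  # stop codon: rejected
            continue
        synonymous = translate_codon(new) == translate_codon(old)
        p_accept = p_syn if synonymous else p_nonsyn
        if rng.random() < p_accept:
            codons[k] = new


def synthesize_coding_alignment(
    n_alleles: int, domain_specs: Sequence[DomainSpec], seed: int
) -> SyntheticAlignment:
    """Evolve ``n_alleles`` independent alleles from one random ancestor."""
    if n_alleles < 1:
        raise ValueError("n_alleles must be >= 1")
    if not domain_specs:
        raise ValueError("at least one domain is required")
    rng = np.random.default_rng(seed)
    total = sum(d.n_codons for d in domain_specs)
    ancestor = list(rng.choice(SENSE_CODONS, size=total))

    sequences: dict[str, str] = {}
    for a in range(1, n_alleles + 1):
        codons = list(ancestor)
        offset = 0
        for spec in domain_specs:
            segment = codons[offset : offset + spec.n_codons]
            _evolve_domain(segment, spec, rng)
            codons[offset : offset + spec.n_codons] = segment
            offset += spec.n_codons
        sequences[f"allele_{a}"] = "".join(codons)

    domains = []
    start = 1
    for spec in domain_specs:
        domains.append((spec.name, start, start + spec.n_codons - 1))
        start += spec.n_codons
    return SyntheticAlignment(sequences=sequences, domains=domains)
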