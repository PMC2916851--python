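# Methods

## Compatibility model and sib-mating odds

A haploid's mating identity is the pair (receptor allele, HD allele). The
cross-outcome rule is categorical: identical receptor alleles → no switch
to filamentous growth (`NONE`); different receptors but identical HD
alleles → pheromone signalling and pseudohyphal growth only
(`PHEROMONE_ONLY`); different alleles at both regions → dikaryotic
mycelium with clamp connections and teliospores (`COMPLETE`). Signalling
intensity is not modelled.

Sib-mating odds condition on a parental cross heterozygous at both
regions. One meiosis segregates at most two alleles per region, so the
multi-allelic population case reduces to the biallelic one. Meiotic
products have genotype frequencies (1−r)/2 for each parental and r/2 for
each recombinant combination, where r ∈ [0, 0.5] is the recombination
fraction between the regions. Two spores are drawn independently **with
replacement** from this distribution (drawing two distinct tetrad members
without replacement would give 1/3 rather than the standard 25% tetrapolar
figure, and is deliberately not used). Compatibility requires differing at
both regions, giving

    P(r) = ((1−r)² + r²) / 2,

which is continuous, strictly decreasing on [0, 0.5], and maps exactly
onto [0.25, 0.50]: 50% bipolar, 25% tetrapolar, intermediate values for
pseudo-bipolar. The closed form is this package's formalization of the
qualitative claim that pseudo-bipolar inbreeding odds lie between the
bipolar and tetrapolar figures; no published numeric value exists for the
intermediate case. `simulate_sib_matings` re-estimates P(r) by direct
sampling and agrees within 4 standard errors at 10⁵ pairs.

## Meiosis simulator

The simulator is the package's synthetic-data generator; its defaults are
the study conditions of the emulated cross.

* **Crossovers.** Per scaffold, a Poisson process along the physical kb
  axis with piecewise-constant intensity: baseline 32 kb/cM with optional
  hotspot intervals (the packaged cross configuration includes a 27-kb
  interval at 0.63 kb/cM adjacent to the HD1/HD2 pair). The chromatid-level
  rate is 1/(100·kb_per_cM) per kb (Morgans per kb); events are sampled at
  the four-chromatid bundle level at twice that rate and each involves one
  randomly chosen chromatid per homolog, so a given chromatid is hit with
  probability 1/2 and the recombinant fraction follows Haldane's
  RF = (1−e^(−2m))/2 with no chiasma interference. Realized map densities
  therefore match the configured kb/cM up to the small Haldane shrinkage
  over multi-cM intervals.
* **Independent assortment.** Centromeres sit at the left end of each
  scaffold; sister pairs are (chromatids 0,1) and (2,3). Meiosis I pole
  orientation and meiosis II sister order are randomized per scaffold, so
  unlinked scaffolds assort independently and a tetrapolar two-scaffold
  configuration yields all four mating types across meioses.
* **Gene conversion.** Per chromatid per marker with probability
  `conversion_rate_per_marker` (default 0.01), a tract anchored at the
  marker with exponential length (mean 5 kb, well below the inter-marker
  spacing, so tracts usually cover a single marker) overwrites covered
  markers with the homolog's allele, breaking the 2:2 tetrad ratio to 3:1
  at covered markers only. The tract model is intentionally minimal: the
  observable signal is an isolated marker switch.
* **Packaging and recovery.** With probability `p_diploid` (default 1/8,
  one diploid among the eight examined teliospores) the teliospore yields a
  single product heterozygous at every marker. Otherwise the four nuclei
  are partitioned randomly into two binucleate basidiospores; asynchronous
  germination is collapsed to a single recovery probability — one clonal
  product is always recovered, and a product of the second spore with
  probability `p_recover_both_spores` (default 1/8, matching one teliospore
  in eight yielding both parental mating types). Colonies are mitotic
  clones of the recovered product(s).
* **Truth log.** Every crossover (position, products involved), conversion
  tract, founder origin and outcome class is logged once, in product
  coordinates, so the segregation classifier can be validated by replay.

What the generator does **not** emulate: marker-level DNA sequence (origin
calls only), genotyping error, segregation distortion, chiasma
interference, teliospore dormancy/germination kinetics, or aneuploidy
beyond the haploid/diploid dichotomy. Tests passing on this generator
demonstrate internal consistency of the analysis chain and statistical
calibration of the crossover model — not robustness to real-data noise.

## Segregation analysis

* **Origin assignment** maps raw allele calls to {P1, P2, HET, NA} given
  the parental genotypes; markers where the parents share an allele are
  dropped with a warning. Diploids are flagged when HET reaches a
  configurable fraction of informative markers (default: all of them).
* **Event calling** is minimal-event parsimony per scaffold over the
  informative markers. Maximal constant-origin runs are delimited; an
  internal run of ≤ `max_conversion_markers` (default 1) markers spanning
  ≤ `max_conversion_kb` is one CONVERSION (one event instead of two
  crossovers); remaining switches are CROSSOVERs placed in the inter-marker
  interval, which widens across missing markers. Ties among equal-count
  labelings are broken left-to-right (alternating short runs become
  alternating conversions, never conversions at every run). Terminal short
  runs cannot be conversions — one flank is unobserved; by default they are
  delimited by a crossover, and with `terminal_ambiguous=True` they are
  reported AMBIGUOUS instead. Calling is invariant under relabeling
  P1 ↔ P2. A conversion tract and a double crossover flanking a single
  marker are observationally identical; the classifier prefers the
  single-event reading, and the simulator's truth log exists precisely so
  this confusion can be quantified rather than resolved.
* **Linkage.** Clonal colonies collapse to distinct products per
  teliospore before counting; RF = recombinants/informative products. Map
  distance is cM = 100·RF **directly** — no Haldane/Kosambi correction —
  because that is the only defensible arithmetic at seven products, and it
  is the convention that turns 3/7 recombinants over 27 kb into 0.63 kb/cM.
  kb/cM is undefined at RF = 0. Linkage is classed UNLINKED unless an exact
  one-sided binomial test rejects RF = 0.5 (α = 0.05), then LINKED/PARTIAL
  by an RF cut (default 0.15). Large-sample RF estimates consequently
  overestimate kb/cM by the Haldane shrinkage (≈3% at 5 cM intervals).
* **Cohesion summary.** Teliospores partition into DIPLOID (any HET at the
  receptor or HD marker), RECOMBINANT (any product with a non-parental
  receptor–HD combination) and PARENTAL; `both_types_recovered`
  additionally counts parental teliospores whose colonies contained both
  parental mating types.
* **Scaffold orientation** evaluates the four junction orientations of two
  scaffolds joined end to end and returns the orientation(s) minimizing
  total origin switches across haploid products; ties are reported as
  unresolved rather than broken arbitrarily. At seven products the test
  has power only when crossovers cluster near the junction.

## NG86 dN/dS

Sites are counted by the standard fractional method (per codon position,
the fraction of the three single-base changes that are synonymous,
averaged over the two sequences); changes to stop codons count as
nonsynonymous so sites per codon always sum to 3. Codons differing at
k positions are resolved by averaging over all k! single-step pathway
orderings, excluding pathways through stop codons (with an all-pathways
fallback in the degenerate case where every ordering is blocked).
Proportions are corrected with Jukes–Cantor, d = −(3/4)·ln(1−4p/3),
undefined at p ≥ 3/4. Universal genetic code only; gaps and ambiguity
codes are handled by pairwise deletion per codon column.

Windows are 20 codons, step 1 (codon units). Window and domain statistics
average dN and dS separately over all unordered allele pairs and report
the **ratio of means** — robust when individual pairs have dS = 0 in a
short window; pairs where either distance is undefined (saturation,
no comparable sites) are dropped from both means for that window. The
alignment container enforces equal lengths, frame, absence of internal
stop codons, and a non-overlapping covering domain partition (1-based
codon coordinates). Domain boundaries for real alignments must be supplied
by the user.

## Synthetic codon alignments

Alleles evolve independently from one random ancestor of sense codons.
Proposed substitutions (random codon, position, base) that would create a
stop are rejected; otherwise acceptance is min(1, ω) for nonsynonymous and
min(1, 1/ω) for synonymous proposals, so the realized pairwise dN/dS
tracks the target on both sides of 1. The packaged three-domain
configuration (30 codons at ω = 1.5, 60 at 0.1, 60 at 0.3, about one
attempted substitution per codon per lineage — substantial divergence, as
observed among natural HD1 alleles) recovers the domain ordering and
confines window ratios above 1 to windows overlapping the high-ω domain
in at least 9 of 10 seeds. There are no indels, no transition/transversion
bias and no codon-usage bias.

## Problem sizes and numerics

The test suite and drivers use sizes chosen to make stochastic checks
decisive at modest cost: 10⁵ spore pairs for Monte-Carlo odds (4-SE
agreement), ~10⁴ meiotic products for RF calibration (|ΔRF| < 0.01;
kb/cM within 10%), 10³ meioses for the tetrapolar mating-type census and
hotspot density contrast, 300 meioses for exact truth-log equivalence of
crossover calls (at marker resolution: two crossovers inside one
inter-marker interval cancel and are invisible to any marker-based
caller), 200 dense-map meioses for conversion recovery (≥ 90% of internal
single-marker tracts), and 10 seeds for dN/dS parameter recovery. All
randomness flows through a single `numpy` Generator per run, seeded
explicitly; fixtures are generated programmatically.

## Known limitations

* The pseudo-bipolar inbreeding formula assumes exactly one meiosis per
  teliospore and random spore pairing; population-level allele frequencies
  and negative frequency-dependent selection are out of scope.
* RF-based map densities inherit both small-sample noise (7 products in
  the worked examples) and the no-correction convention above.
* The mating-system classifier is pattern-based, not statistical: a single
  sampled recombinant lineage flips a pseudo-bipolar call to tetrapolar if
  it makes an HD allele appear with both receptors; a minimum of four
  haploid strains guards against over-claiming, nothing more.
* NG86 is a counting method; no maximum-likelihood ω estimation and no
  site-level selection inference is provided.
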