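# pirnakit

Classification and upstream-motif analysis of *Caenorhabditis elegans*
piRNAs (21U RNAs) from multi-library small-RNA sequencing counts.

## The problem

*C. elegans* piRNAs are 21-nucleotide, 5′-uridine small RNAs bound by the
Piwi Argonaute PRG-1. Each is transcribed as a tiny autonomous unit: an
8-nt upstream core motif (consensus `CTGTTTCA`) drives expression from a
genomic thymidine an optimal ~39 nt downstream, across an A/T-rich spacer
of ~35–42 nt. A majority of 21U RNA species are selectively expressed in
either the male or the female germline, and the motif's 5′ nucleotide
(cytidine for male-enriched species) carries part of that information.

`pirnakit` implements the computational side of this analysis as a tested,
reusable pipeline for anyone working with multi-library small-RNA count
data: researchers who want to classify small-RNA species by sex/stage
enrichment, relate that classification to upstream promoter elements, and
quantify downstream targeting — together with a synthetic-data generator so
every stage can be validated against planted truth without downloading
anything.

## What it computes

**Enrichment Score.** For a species with per-library abundance, and every
within-protocol pair of one male library *m* and one female library *f*,

    score -= 1  if  a_m > φ · a_f        (φ = 5 by default)
    score += 1  if  a_f > φ · a_m

summed over all pairs (23 in the default 17-library germline design).
Species with score ≤ −3 are male germline-enriched, ≥ +3 female, the rest
non-enriched; species with no germline reads or with higher abundance in a
piwi-mutant library are excluded, and classified species whose geometric
mean fold abundance does not favor their class are demoted.

**Poisson-null FDR.** Counts for each species are re-drawn from a Poisson
distribution with rate equal to its count in a reference library, assigned
to 17 control libraries whose sex/protocol labels are randomly permuted,
and re-classified; the mean classified fraction over 1,000 repetitions
estimates the false discovery rate of the thresholds (≈1.7% under a
realistic low-count rate spectrum).

Around this core the package provides the 3′-linker removal cascade, an
internal exact best-stratum short-read mapper, upstream `GTTTC` motif
scanning with spacer measurement (spacer = nucleotides strictly between the
8-mer's 3′ end and the locus 5′-T), background-corrected motif matrices,
minicluster grouping with the random-assortment pair test
(expected matching fraction *p²* + *q²* for member fractions *p*, *q*),
mismatch-tolerant (≤3) antisense target search with 40-nt 22G RNA
attribution and randomization tests, and strand-aware signal metaprofiles.

## Worked example

```python
import numpy as np
from pirnakit import simulate, enrichment
from pirnakit.simulate import CassetteSpec

design = simulate.default_design()          # 17 germline + embryo/reference libraries
rng = np.random.default_rng(0)
specs = [
    CassetteSpec(
        five_prime_class="C" if i % 3 == 0 else "A",
        spacer_length=int(simulate.spacer_distribution(rng, 1)[0]),
        truth_class=("male", "female", "non_enriched")[i % 3],
    )
    for i in range(120)
]
genome = simulate.generate_genome(1, [300_000], seed=0)
genome, loci = simulate.plant_cassettes(genome, specs, seed=1)
counts, truth = simulate.simulate_counts(loci, design, seed=2)

model = enrichment.GermlineEnrichment(counts, design,
                                      mutant_lib="prg1_ya", reference_lib="n2_ya")
results = model.fit()
print(results.summary())

lam = simulate.reference_lambda_mixture(1000, seed=3)
fdr = enrichment.fdr_simulation(lam, design, n_reps=1000, seed=4)
print(f"Poisson-null FDR at |score| >= 3: {fdr.mean_percent:.2f}%")
```

prints

```
Germline enrichment classification
==================================================
species total            145
excluded (no reads)      0
excluded (mutant filter) 0
analyzed                 145
comparisons per species  23
fold / score thresholds  5 / 3
--------------------------------------------------
male                         47  ( 32.4%)
female                       38  ( 26.2%)
non_enriched                 60  ( 41.4%)
reclassified by avg fold 0

Poisson-null FDR at |score| >= 3: 1.75%
```

145 species arise from 120 cassettes because a cassette whose primary
spacer falls outside the optimal 35–42 nt window also receives one
guaranteed expressible window thymidine. All 47 male-truth species are
recovered as male and 38 of 47 female-truth species as female (the weaker
4× female enrichment leaves nine below the score threshold, mirroring the
asymmetry seen in real germline data); no non-enriched species is
misclassified. The null FDR says that with random counts only ~1.7% of
species would reach |score| ≥ 3.

The `pirnakit` command exposes the same stages as subcommands
(`simulate`, `trim`, `map`, `classify`, `fdr`, `motif`, `minicluster`,
`targets`, `profile`); `pirnakit classify --help` shows the options.

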