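# Methods

This note records the models, conventions, and design choices behind
`pirnakit`, in the order the pipeline runs.

## Coordinates and conventions

All genomic coordinates are 0-based half-open (BED-native). A piRNA locus
is the 21-nt interval whose first base on the locus strand is the genomic
thymidine encoding the 5′ uridine. The **spacer** is the number of
nucleotides strictly between the core motif 8-mer's 3′ end and that
thymidine; the canonical range 35–42 nt, the abundance optimum 39 nt, and
the no-motif fallback anchor (−44 to the G of `GTTTC`) are all stated under
this convention. Conventions shift these constants by ±1, so any comparison
with other tools should check the endpoint definition first.

## Linker removal

The 3′-linker cascade applies eight rules in strict order: full-linker
perfect match anywhere in the read (leftmost occurrence wins), full linker
with exactly one mismatch, then anchored comparisons of the last k read
bases against the first k linker bases for k = 5, 4, 3, each with 0 then 1
mismatch. Reads matching no rule are discarded. Two interpretation points
are configurable because the procedure's description leaves them open: ties
among full-linker occurrences resolve to the leftmost (earliest linker
start), and the 1-mismatch variant is applied at every suffix length
including k = 3 (`allow_1mm_k3=False` disables the near-vacuous last rule).
N bases never match anything. The cascade is verified against an
independent brute-force enumerator on 10,000 random reads per test run.

## Mapping and annotation

The internal mapper reports ungapped alignments with ≤2 mismatches on both
strands, using pigeonhole seeding (three 7-mers, one of which must be
exact) with full Hamming verification — exact by construction, and checked
against an all-position scan on 100-kb genomes. Only the best stratum (the
minimum mismatch count achieved) is reported, capped at 50 loci. Known 21U
sequences become genomic coordinates only through perfect full-length
alignments. A read counts toward a 21U species iff its alignment lies
entirely within the locus interval on the same strand; sub-21-nt reads
therefore count by default (`exact_length_only` restricts to 21-mers).
Abundance is RPM — reads per million mapped reads — with each read first
weighted by the reciprocal of its number of mapped loci; raw per-species
counts stay unweighted.

## Enrichment classification

Scores accumulate ±1 over every within-protocol male×female library pair
(23 pairs in the default design: 5×1 monophosphate-dependent plus 9×2
-independent) whenever one side is more than 5-fold the other. Thresholds:
|score| ≥ 3. Zero handling is the one genuinely open point. The
classification path uses the strict multiplicative rule — any positive
abundance beats a zero, zero against zero contributes nothing — because it
needs no extra constant. The raw-count Poisson null instead floors the fold
denominator at one read (`min_unit=1`): at rates of a few counts per
library, one read against zero is sampling noise, and under the strict rule
the null would classify ~30% of low-count species, which is irreconcilable
with the sub-1% false discovery rates such thresholds achieve in practice.
Both behaviors are exposed via `min_unit`.

Average-fold validation uses the geometric mean over pairs of
(m + 0.25)/(f + 0.25) RPM; the 0.25 pseudocount keeps ratios defined at
zero and the geometric mean makes male and female averages exact
reciprocals. Classified species whose average fold does not favor their
class are demoted to non-enriched. Exclusion filters (no germline reads at
all; higher normalized abundance in a piwi-mutant than in a wild-type
reference library) take precedence over any score. The engine is generic
over the manifest, so a 26G RNA analysis is the same fit under a reduced
13-library design (16 comparisons).

The FDR null draws one Poisson count per species per control library with
rate equal to the species' count in a reference library, randomly permutes
the design's sex/protocol labels over the 17 control libraries each
repetition, reclassifies, and averages the classified fraction over 1,000
repetitions. The packaged rate spectrum (`reference_lambda_mixture`) is
Zipf-distributed with exponent 2 truncated at 1,000 — about 89% of species
at 1–5 reads with a long tail, the shape of a real library's species-count
distribution. Under it the null classifies ≈1.7% of species.

## Synthetic data

The generator is the package's test surface; its defaults are the study
conditions and are not per-test knobs.

- **Genome/cassettes.** Random genomes at 36% GC. Each cassette is an
  A/T-only upstream flank, the 8-mer motif, a controlled downstream region,
  and a random tail. Every position of the optimal 35–42 window that is not
  a designated thymidine is set to A, and the region between motif and the
  farthest designated T is G-free, so plant-then-scan recovery and window
  T-richness are exact, not approximate. Spacers are drawn from a discrete
  distribution peaked at 39 nt with support 30–50. A cassette with
  `n_window_Ts > 1` yields overlapping loci sharing one motif — a
  minicluster by construction.
- **Counts.** Species baselines are log-normal (log-mean 3.5, log-sd 0.8,
  i.e. median ≈33 counts per library at 10⁶ depth); the favored sex's
  germline libraries see 8× (male) or 4× (female) the baseline — the
  deliberate asymmetry mirrors the weaker female enrichment seen in real
  germline data. Counts are negative binomial with dispersion 0.08
  (variance μ + 0.08 μ²), a typical value for deep small-RNA libraries;
  the analysis-side FDR null stays Poisson because that is the stated null
  of the procedure, not a model of real libraries. Embryo libraries carry
  the same-sex germline level, multiplied by `embryo_carryover` (default 4)
  for female species, so the embryo-vs-germline fold ratio between classes
  recovers the carryover parameter directly. The piwi-mutant-like library
  draws no piRNA counts. Under these defaults, measured over 1,000+
  species: 100% of male-truth species classify male, ~90% of female-truth
  species classify female, and with all folds at 1 only ~1.3–1.8% of
  species classify at all.
- **Reads.** Each read is the 21-mer plus the full linker, a 3–5-nt linker
  prefix (the range the cascade's suffix rules cover), or a
  guaranteed-non-linker tail that the cascade must discard. Quality strings
  are constant; there are no indels or PCR duplicates, so trimming and
  mapping tests measure rule correctness, not robustness to noisy base
  calls — results on real data depend additionally on error handling that
  these tests do not exercise.
- **Targets/22G.** Planted target sites carry exactly the planned Hamming
  distance (0–3) to their 21U; 22-nt 5′-G reads are placed antisense at
  planned footprint gaps; background 22G species are counted only in the
  piwi-mutant-like library.
- **Signal tracks.** Baseline + per-anchor bump + optional Gaussian noise.

## Motif scanning and miniclusters

The scanner takes all `GTTTC` occurrences in the 60-nt upstream window
(locus strand) whose full 8-mer context fits, and selects the occurrence
whose implied spacer is closest to 39 nt, ties to the shorter spacer. The
selection rule is a package choice — the best-conserved-occurrence notion
is not otherwise operationalized — and `leftmost`/`rightmost` alternatives
are available. Multi-mapping loci are excluded from motif analysis because
their upstream sequence is ambiguous. Motif matrices align windows on the
central T of the motif's TTT (fallback anchor for no-motif loci) and report
per-position relative entropy in bits against the genome's base
composition. `GTTTC` density over regions counts overlapping occurrences on
both strands per kilobase.

Miniclusters are groups of ≥2 uniquely-mapping loci sharing a motif
instance (chromosome, strand, motif start). The pair-composition test uses
only two-member miniclusters whose members are both germline-enriched:
random assortment of the observed members predicts matching fractions
p² + q², and both the analytic expectation and a seeded permutation
(shuffle members, re-pair) are reported; the χ² compares matching vs mixed
counts, Pearson, no continuity correction.

## Targets and 22G attribution

Target sites are ungapped antisense windows with Hamming distance ≤3 (U≡T,
no G:U wobble, all 21 positions equal weight). 22G attribution measures the
footprint-to-footprint gap on the transcript (overlap = 0) and attributes
within 40 nt; species near sites of both sexes are ambiguous, and species
with any read in the piwi-mutant library are excluded first. The
randomization test redraws disjoint male/female 21U sets of the observed
sizes 1,000 times and compares the observed both-attributed count (or
shared-target-gene count) to the random distribution.

## Metaprofiles

Signal windows are extracted per anchor, oriented 5′→3′ on the anchor
strand, and averaged per offset; anchors that would cross a chromosome edge
are skipped (not zero-padded, which would fake dips) and anchors failing an
abundance/expression filter are dropped before averaging. Half-width
defaults to 500 nt. Intergenic background anchors are non-overlapping
1,000-nt windows placed at seeded random offsets within unannotated gaps.
Quartile profiles rank anchors by abundance with stable-order tie-breaks.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
genomes of 0.1–3 Mb, 24–1,200 cassettes, 23-library designs at 10⁶ mapped
reads, 1,000-repetition nulls and randomizations. These sizes keep every
oracle comparison exhaustive (all-position scans, full enumerations) while
the whole suite completes in well under a minute of compute.

## Known limitations

- The mapper is built for synthetic-scale genomes (k-mer dictionary index);
  it is exact but not engineered for a 100-Mb genome.
- No quality-aware trimming, indel handling, or duplicate collapsing.
- Transcript expression (FPKM) is accepted as an input attribute, never
  computed.
- The spacer–abundance profile uses arithmetic bin means; with log-normal
  abundance spread, adjacent-bin comparisons need hundreds of loci per bin
  to be stable.
- The pair-composition analytic expectation treats member draws as
  independent (p², q², 2pq); the permutation mode quantifies the small
  finite-n difference.
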