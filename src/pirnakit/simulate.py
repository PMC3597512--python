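"""Synthetic-data generators with known truth for every pipeline stage.

The generators emulate the statistical structure of a multi-library
C. elegans small-RNA-seq meta-analysis: a random genome carrying planted
piRNA cassettes (8-nt core motif, A/T-rich spacer peaked at 39 nt, one or
more expressible thymidines in the optimal 35-42 nt window), per-library
negative-binomial counts with configurable male/female fold enrichment,
linkered raw reads, transcripts with planted antisense target sites plus
nearby 22G reads, and per-nucleotide signal tracks. Truth labels are
recorded for every planted feature and are consumed only by tests and
acceptance checks, never by the analysis stages.

Counts for the simulated "real" libraries are negative binomial (real
small-RNA libraries are overdispersed); the false-discovery-rate null in the
enrichment module deliberately stays Poisson, which is the stated null of
the classification procedure.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from pirnakit.io import CountTable, Interval, LibraryDesign, LibraryMeta
from pirnakit.mapping import PiRNALocus
from pirnakit.sequence import random_seq, revcomp
from pirnakit.targets import TargetSite, TranscriptHit
from pirnakit.trim import trim_read

CONSENSUS_MOTIF = "CTGTTTCA"
SPACER_SUPPORT = (30, 50)
WINDOW_RANGE = (35, 42)
_FLANK = 25  # A/T-only run upstream of the motif; keeps the scan window clean


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def generate_genome(
    n_chrom: int,
    lengths: Sequence[int],
    gc_fraction: float = 0.36,
    seed: int | None = None,
) -> dict[str, str]:
    """Random genome; chromosome names chrS1..chrSn. Deterministic given seed."""
    if len(lengths) != n_chrom:
        raise ValueError("lengths must have one entry per chromosome")
    if any(l <= 0 for l in lengths):
        raise ValueError("chromosome lengths must be positive")
    rng = np.random.default_rng(seed)
    return {
        f"chrS{i + 1}": random_seq(rng, int(length), gc_fraction)
        for i, length in enumerate(lengths)
    }


# ---------------------------------------------------------------------------
# cassettes
# ---------------------------------------------------------------------------

def spacer_distribution(rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Spacer lengths peaked at 39 nt with support 30-50."""
    support = np.arange(SPACER_SUPPORT[0], SPACER_SUPPORT[1] + 1)
    weights = np.exp(-0.5 * ((support - 39) / 2.5) ** 2)
    weights /= weights.sum()
    return rng.choice(support, size=size, p=weights)


@dataclasses.dataclass
class CassetteSpec:
    """One planted piRNA transcriptional cassette."""

    motif_8mer: str = CONSENSUS_MOTIF
    five_prime_class: str | None = None  # overrides motif_8mer[0] when set
    spacer_length: int = 39
    n_window_Ts: int = 1
    strand: str = "+"
    truth_class: str = "non_enriched"

    def __post_init__(self):
        if self.five_prime_class is not None:
            self.motif_8mer = self.five_prime_class + self.motif_8mer[1:]
        if len(self.motif_8mer) != 8:
            raise ValueError("core motif must be 8 nt")
        if self.motif_8mer[2:7] != "GTTTC":
            raise ValueError("canonical core motif must carry GTTTC at positions 3-7")
        if self.spacer_length < 0:
            raise ValueError("spacer length must be >= 0")
        if not 1 <= self.n_window_Ts <= 8:
            raise ValueError("n_window_Ts must be in 1..8")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if self.truth_class not in ("male", "female", "non_enriched"):
            raise ValueError(f"bad truth_class {self.truth_class!r}")

    @property
    def five_prime_nt(self) -> str:
        return self.motif_8mer[0]


@dataclasses.dataclass(frozen=True)
class PlantedLocus:
    """Truth record for one planted 21U locus."""

    species_id: str
    chrom: str
    strand: str
    start: int  # forward-genome interval of the 21-mer
    end: int
    sequence: str  # 5'->3' on the locus strand, starts with T
    truth_class: str
    spacer_length: int
    motif_start: int  # genomic position of the 8-mer 5' end on the locus strand
    five_prime_nt: str
    cassette_index: int

    def to_pirna_locus(self) -> PiRNALocus:
        return PiRNALocus(
            species_id=self.species_id,
            chrom=self.chrom,
            strand=self.strand,
            start=self.start,
            end=self.end,
            sequence=self.sequence,
            n_mapped_loci=1,
        )


def _at_only(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(np.array(["A", "T"]), size=length))


def _build_cassette(
    spec: CassetteSpec, rng: np.random.Generator, gc_fraction: float
) -> tuple[str, list[int]]:
    """Cassette string on the locus strand plus T positions as spacer distances.

    Layout: [A/T flank][8-mer motif][controlled downstream region][random
    tail]. Every position in the optimal window that is not a designated T is
    set to A, so window thymidine counts are exact; everything between motif
    and the farthest designated T is G-free, so the upstream scan of every
    planted locus sees exactly one GTTTC.
    """
    spacers = {spec.spacer_length}
    lo, hi = WINDOW_RANGE
    window_positions = [s for s in range(lo, hi + 1) if s != spec.spacer_length]
    needed = spec.n_window_Ts - (1 if lo <= spec.spacer_length <= hi else 0)
    if needed > len(window_positions) + (1 if lo <= spec.spacer_length <= hi else 0):
        raise ValueError("n_window_Ts exceeds the window capacity")
    if needed > 0:
        extra = rng.choice(window_positions, size=needed, replace=False)
        spacers.update(int(s) for s in extra)
    max_s = max(max(spacers), hi)  # control the full optimal window

    region = []
    for s in range(max_s + 1):
        if s in spacers:
            region.append("T")
        elif lo <= s <= hi:
            region.append("A")  # keep the optimal-window T count exact
        else:
            base = rng.choice(np.array(["A", "T"]), p=[0.55, 0.45])
            region.append(str(base))
    tail = random_seq(rng, 21 + 10, gc_fraction)
    cassette = _at_only(rng, _FLANK) + spec.motif_8mer + "".join(region) + tail

    scan_span = cassette[: _FLANK + 8 + max_s]
    if scan_span.count("GTTTC") != 1:
        raise AssertionError("cassette construction produced a stray GTTTC")
    return cassette, sorted(spacers)


def plant_cassettes(
    genome: Mapping[str, str],
    specs: Sequence[CassetteSpec],
    min_separation: int = 150,
    gc_fraction: float = 0.36,
    seed: int | None = None,
) -> tuple[dict[str, str], list[PlantedLocus]]:
    """Write cassettes into the genome; returns (edited genome, truth loci).

    Cassettes are placed left to right on each chromosome in turn with at
    least `min_separation` nt between them; raises naming the failing spec
    if the genome runs out of space.
    """
    rng = np.random.default_rng(seed)
    chroms = {c: list(s.upper()) for c, s in genome.items()}
    chrom_names = sorted(chroms)
    loci: list[PlantedLocus] = []
    cursor = {c: min_separation for c in chrom_names}
    chrom_cycle = 0

    for idx, spec in enumerate(specs):
        cassette, spacers = _build_cassette(spec, rng, gc_fraction)
        placed = False
        for _ in range(len(chrom_names)):
            chrom = chrom_names[chrom_cycle % len(chrom_names)]
            pos = cursor[chrom] + int(rng.integers(0, min_separation))
            if pos + len(cassette) + min_separation <= len(chroms[chrom]):
                placed = True
                break
            chrom_cycle += 1
        if not placed:
            raise ValueError(f"insufficient genome space for cassette spec #{idx}")
        insert = cassette if spec.strand == "+" else revcomp(cassette)
        chroms[chrom][pos : pos + len(cassette)] = list(insert)
        cursor[chrom] = pos + len(cassette) + min_separation
        chrom_cycle += 1

        clen = len(cassette)
        for k, s in enumerate(spacers):
            c_t = _FLANK + 8 + s  # cassette-strand index of the 5'-T
            if spec.strand == "+":
                t_pos = pos + c_t
                start, end = t_pos, t_pos + 21
                motif_start = pos + _FLANK
            else:
                t_pos = pos + clen - 1 - c_t
                start, end = t_pos - 20, t_pos + 1
                motif_start = pos + clen - 1 - _FLANK
            loci.append(
                PlantedLocus(
                    species_id=f"21U-syn{idx:04d}{chr(ord('a') + k)}",
                    chrom=chrom,
                    strand=spec.strand,
                    start=start,
                    end=end,
                    sequence="",  # filled below once the genome is final
                    truth_class=spec.truth_class,
                    spacer_length=s,
                    motif_start=motif_start,
                    five_prime_nt=spec.five_prime_nt,
                    cassette_index=idx,
                )
            )

    edited = {c: "".join(chars) for c, chars in chroms.items()}
    final = []
    for locus in loci:
        sub = edited[locus.chrom][locus.start : locus.end]
        seq = sub if locus.strand == "+" else revcomp(sub)
        if not seq.startswith("T"):
            raise AssertionError("planted locus does not start with T")
        final.append(dataclasses.replace(locus, sequence=seq))
    return edited, final


def truth_to_bed(loci: Iterable[PlantedLocus]) -> list[Interval]:
    """Truth loci as BED intervals; the name field encodes species and class."""
    return [
        Interval(l.chrom, l.start, l.end, f"{l.species_id}|{l.truth_class}", 0.0, l.strand)
        for l in loci
    ]


# ---------------------------------------------------------------------------
# library design and counts
# ---------------------------------------------------------------------------

def default_design(depth: int = 1_000_000) -> LibraryDesign:
    """The default 23-library manifest.

    17 germline libraries in the 5/1 monophosphate-dependent and 9/2
    -independent male/female structure (23 male x female comparisons), plus
    4 mixed-stage embryo libraries, one wild-type young-adult reference and
    one piwi-mutant-like young-adult library.
    """
    libs: list[LibraryMeta] = []
    for i in range(5):
        libs.append(LibraryMeta(f"male_dep_{i + 1}", "male", "monoP_dependent", "N2", "adult", depth))
    libs.append(LibraryMeta("female_dep_1", "female", "monoP_dependent", "fem", "adult", depth))
    for i in range(9):
        libs.append(LibraryMeta(f"male_indep_{i + 1}", "male", "monoP_independent", "N2", "adult", depth))
    for i in range(2):
        libs.append(LibraryMeta(f"female_indep_{i + 1}", "female", "monoP_independent", "fem", "adult", depth))
    for i in range(4):
        libs.append(LibraryMeta(f"embryo_{i + 1}", "embryo", "monoP_independent", "N2", "embryo", depth))
    libs.append(LibraryMeta("n2_ya", "mixed", "monoP_independent", "N2", "young_adult", depth))
    libs.append(LibraryMeta("prg1_ya", "mixed", "monoP_independent", "prg-1", "young_adult", depth))
    return LibraryDesign(libs)


def gaussian_spacer_effect(peak: int = 39, width: float = 1.2, depth: float = 0.95) -> Callable[[int], float]:
    """Abundance multiplier peaked at `peak`; falls to (1 - depth) far away."""

    def effect(spacer: int) -> float:
        return (1.0 - depth) + depth * float(np.exp(-0.5 * ((spacer - peak) / width) ** 2))

    return effect


@dataclasses.dataclass
class ExpressionModel:
    """Statistical model for per-library species abundance.

    Mean counts are log-normal across species; the favored sex's germline
    libraries see `sex_fold_*` times the baseline (male default 8x, female
    4x, mirroring the qualitative male/female asymmetry of real data);
    embryo libraries carry over the female germline level times
    `embryo_carryover` while male species keep their male germline level;
    counts are negative-binomial with mean mu and variance mu + dispersion *
    mu^2. The piwi-mutant-like library draws no piRNA counts.
    """

    baseline_log_mean: float = 3.5
    baseline_log_sd: float = 0.8
    sex_fold_male: float = 8.0
    sex_fold_female: float = 4.0
    dispersion: float = 0.08
    embryo_carryover: float = 4.0
    spacer_effect: Callable[[int], float] | None = None

    def __post_init__(self):
        if self.sex_fold_male < 1 or self.sex_fold_female < 1:
            raise ValueError("sex folds must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 1e-9:
        return rng.poisson(mu)
    n = 1.0 / dispersion
    p = n / (n + mu)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    out[pos] = rng.negative_binomial(n, p[pos])
    return out


def simulate_counts(
    loci: Sequence[PlantedLocus],
    design: LibraryDesign,
    model: ExpressionModel | None = None,
    seed: int | None = None,
) -> tuple[CountTable, pd.Series]:
    """Draw per-library raw counts for every truth locus.

    Returns (CountTable with RPM normalization by manifest depths, truth
    classes indexed by species id). Deterministic given seed.
    """
    model = model or ExpressionModel()
    rng = np.random.default_rng(seed)
    species = [l.species_id for l in loci]
    base = np.exp(rng.normal(model.baseline_log_mean, model.baseline_log_sd, size=len(loci)))
    if model.spacer_effect is not None:
        base = base * np.array([model.spacer_effect(l.spacer_length) for l in loci])
    truth = pd.Series([l.truth_class for l in loci], index=species, name="truth_class")

    is_male = truth.to_numpy() == "male"
    is_female = truth.to_numpy() == "female"

    raw = {}
    for lib in design:
        mu = base.copy()
        if lib.sex == "male":
            mu[is_male] *= model.sex_fold_male
        elif lib.sex == "female":
            mu[is_female] *= model.sex_fold_female
        elif lib.sex == "embryo":
            mu[is_male] *= model.sex_fold_male
            mu[is_female] *= model.sex_fold_female * model.embryo_carryover
        if lib.genotype.startswith("prg-1"):
            mu = np.zeros_like(mu)
        raw[lib.id] = _nb_draw(rng, mu, model.dispersion)
    raw_df = pd.DataFrame(raw, index=species)
    totals = {lib.id: lib.total_mapped_reads for lib in design}
    table = CountTable.from_raw(raw_df, total_mapped=totals)
    return table, truth


def reference_lambda_mixture(
    n_species: int,
    seed: int | None = None,
    exponent: float = 2.0,
    max_count: int = 1000,
) -> np.ndarray:
    """Low-count Poisson rates emulating a reference library's count spectrum.

    Species counts in a deep small-RNA library are close to power-law
    distributed; a Zipf(2) draw puts roughly 85-90% of species at 1-5 reads
    with a long high-count tail. Used as the rate vector for the
    false-discovery-rate null.
    """
    rng = np.random.default_rng(seed)
    k = np.arange(1, max_count + 1)
    p = 1.0 / k.astype(float) ** exponent
    p /= p.sum()
    return rng.choice(k, size=n_species, p=p).astype(float)


# ---------------------------------------------------------------------------
# raw reads with linkers
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ReadTruth:
    read_id: str
    library: str
    species_id: str
    trim_point: int
    mode: str  # full / truncated / absent


def emit_raw_reads(
    loci: Sequence[PlantedLocus],
    raw_counts: pd.DataFrame,
    linker_3p: str,
    truncated_frac: float = 0.15,
    absent_frac: float = 0.05,
    error_rate: float = 0.0,
    seed: int | None = None,
) -> tuple[dict[str, list[tuple[str, str, str]]], list[ReadTruth]]:
    """Emit per-library FASTQ-style reads: insert + 3'-linker (or not).

    Each read is the 21-nt locus sequence followed by the full linker, a
    truncated linker prefix of >= 3 nt, or (with probability `absent_frac`)
    a non-linker tail that the trim cascade is guaranteed to discard.
    Substitution errors at `error_rate` are applied to linkered reads only.
    Returns ({library: [(id, seq, qual), ...]}, truth trim points).
    """
    linker = linker_3p.upper()
    if len(linker) < 5:
        raise ValueError("linker must be >= 5 nt")
    rng = np.random.default_rng(seed)
    seq_of = {l.species_id: l.sequence for l in loci}
    reads: dict[str, list[tuple[str, str, str]]] = {lib: [] for lib in raw_counts.columns}
    truths: list[ReadTruth] = []
    bases = np.array(list("ACGT"))

    for lib in raw_counts.columns:
        counter = 0
        for species, count in raw_counts[lib].items():
            insert = seq_of.get(species)
            if insert is None:
                continue
            for _ in range(int(count)):
                counter += 1
                rid = f"{lib}:{counter}"
                u = rng.random()
                if u < absent_frac:
                    mode = "absent"
                    for _ in range(200):
                        tail = random_seq(rng, len(linker))
                        seq = insert + tail
                        if trim_read(seq, linker).discarded:
                            break
                    else:
                        raise RuntimeError("could not draw a non-linker tail")
                elif u < absent_frac + truncated_frac:
                    mode = "truncated"
                    # 3-5 nt of residual linker: the range the suffix rules cover
                    k = int(rng.integers(3, 6))
                    seq = insert + linker[:k]
                else:
                    mode = "full"
                    seq = insert + linker
                if error_rate > 0 and mode != "absent":
                    chars = np.array(list(seq))
                    hits = rng.random(chars.size) < error_rate
                    for i in np.flatnonzero(hits):
                        chars[i] = rng.choice(bases[bases != chars[i]])
                    seq = "".join(chars)
                reads[lib].append((rid, seq, "I" * len(seq)))
                truths.append(ReadTruth(rid, lib, species, len(insert), mode))
    return reads, truths


# ---------------------------------------------------------------------------
# transcriptome, target sites, 22G reads
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TargetPlanItem:
    species_21u: str
    n_mismatches: int = 0
    offsets_22g: tuple[int, ...] = (0,)  # footprint gaps of planted 22G reads


@dataclasses.dataclass
class TargetSimulation:
    transcripts: dict[str, str]
    sites: list[TargetSite]  # planted truth sites
    hits_22g: dict[str, list[TranscriptHit]]
    counts_wt: pd.Series  # 22G raw counts in the wild-type-like library
    counts_prg1: pd.Series  # 22G raw counts in the piwi-mutant-like library


def simulate_transcriptome_and_22g(
    loci: Sequence[PlantedLocus],
    target_plan: Sequence[TargetPlanItem],
    n_transcripts: int = 20,
    transcript_length: int = 1000,
    n_prg1_background: int = 0,
    gc_fraction: float = 0.42,
    seed: int | None = None,
) -> TargetSimulation:
    """Plant antisense target sites and proximal 22G reads on transcripts.

    Each plan item embeds the reverse complement of its 21U with exactly the
    planned number of mismatches at a random position of a dedicated
    transcript region, then places 22-nt 5'-G antisense reads downstream of
    the site at the planned footprint gaps. Background 22G species (counted
    in the piwi-mutant-like library) are planted on otherwise untargeted
    transcripts.
    """
    rng = np.random.default_rng(seed)
    seq_of = {l.species_id: l.sequence for l in loci}
    transcripts = {
        f"tx{i + 1:03d}": list(random_seq(rng, transcript_length, gc_fraction))
        for i in range(n_transcripts)
    }
    tx_names = sorted(transcripts)
    sites: list[TargetSite] = []
    hits_22g: dict[str, list[TranscriptHit]] = {}
    counts_wt: dict[str, int] = {}
    counts_prg1: dict[str, int] = {}
    g_counter = 0

    def plant_22g(tid: str, fp_start: int, prg1: bool) -> None:
        nonlocal g_counter
        g_counter += 1
        tseq = transcripts[tid]
        # a 22G read antisense to [fp_start, fp_start+22) starts at the
        # complement of the window's last base; force it to G
        tseq[fp_start + 21] = "C"
        gid = f"22G-syn{g_counter:04d}"
        hits_22g[gid] = [TranscriptHit(tid, fp_start, fp_start + 22)]
        counts_wt[gid] = 0 if prg1 else 10
        counts_prg1[gid] = 10 if prg1 else 0

    for j, item in enumerate(target_plan):
        if item.species_21u not in seq_of:
            raise KeyError(f"unknown 21U species {item.species_21u!r}")
        tid = tx_names[j % n_transcripts]
        tseq = transcripts[tid]
        max_offset = max(item.offsets_22g, default=0)
        lo, hi = 40, transcript_length - 21 - max_offset - 30
        if hi <= lo:
            raise ValueError("transcript too short for the planned site and offsets")
        start = int(rng.integers(lo, hi))
        window = list(revcomp(seq_of[item.species_21u]))
        if item.n_mismatches:
            mm_pos = rng.choice(21, size=item.n_mismatches, replace=False)
            for p in mm_pos:
                window[p] = str(rng.choice(np.array([b for b in "ACGT" if b != window[p]])))
        tseq[start : start + 21] = window
        sites.append(TargetSite(tid, start, start + 21, item.species_21u, item.n_mismatches))
        for gap in item.offsets_22g:
            plant_22g(tid, start + 21 + gap, prg1=False)

    bg_tx = tx_names[len(target_plan) % n_transcripts :] or tx_names
    for b in range(n_prg1_background):
        tid = bg_tx[b % len(bg_tx)]
        fp_start = 5 + 30 * b % (transcript_length - 60)
        plant_22g(tid, fp_start, prg1=True)

    return TargetSimulation(
        transcripts={t: "".join(s) for t, s in transcripts.items()},
        sites=sites,
        hits_22g=hits_22g,
        counts_wt=pd.Series(counts_wt, dtype=int),
        counts_prg1=pd.Series(counts_prg1, dtype=int),
    )


# ---------------------------------------------------------------------------
# signal tracks
# ---------------------------------------------------------------------------

def simulate_signal_track(
    chrom_lengths: Mapping[str, int],
    anchors: Sequence[tuple[str, int]] = (),
    bump_shape: np.ndarray | None = None,
    baseline: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Per-nucleotide signal: baseline + bump at each anchor + Gaussian noise.

    `bump_shape` is centred on the anchor position (odd length recommended).
    Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    tracks = {c: np.full(n, float(baseline)) for c, n in chrom_lengths.items()}
    if bump_shape is not None and len(anchors):
        bump = np.asarray(bump_shape, dtype=float)
        half = len(bump) // 2
        for chrom, pos in anchors:
            arr = tracks[chrom]
            lo = pos - half
            hi = lo + len(bump)
            b_lo = max(0, -lo)
            b_hi = len(bump) - max(0, hi - arr.size)
            arr[max(lo, 0) : min(hi, arr.size)] += bump[b_lo:b_hi]
    if noise_sd > 0:
        for chrom in tracks:
            tracks[chrom] = tracks[chrom] + rng.normal(0.0, noise_sd, tracks[chrom].size)
    return tracks
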