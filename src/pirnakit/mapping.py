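"""Internal short-read mapper, 21U locus building, and read annotation.

The mapper reports ungapped alignments of short inserts against a genome with
up to `max_mismatches` substitutions, keeping only the best stratum (the
minimum mismatch count actually achieved for that insert) and capping the
number of reported loci. It is exact by construction: a seed-and-extend
search with pigeonhole seeding (max_mismatches + 1 non-overlapping seeds, at
least one of which must be exact) followed by full Hamming verification.

Abundance normalization follows the RPM convention: each read is weighted by
the reciprocal of its number of mapped genomic loci, then scaled to reads
per million mapped reads in its library.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from pirnakit.io import CountTable
from pirnakit.sequence import encode, revcomp, sliding_mismatches


@dataclasses.dataclass(frozen=True)
class Alignment:
    """An ungapped alignment on the forward-strand coordinate system."""

    chrom: str
    start: int
    end: int
    strand: str
    n_mismatches: int


@dataclasses.dataclass
class MapResult:
    alignments: list[Alignment]
    flagged: bool = False  # more best-stratum loci than max_loci

    @property
    def n_loci(self) -> int:
        return len(self.alignments)


@dataclasses.dataclass(frozen=True)
class PiRNALocus:
    """A genomic 21-nt piRNA locus.

    `start`/`end` delimit the forward-strand interval; the genomic thymidine
    encoding the 5' uridine sits at `start` on '+' loci and `end - 1` on '-'
    loci. `sequence` reads 5'->3' on the locus strand and begins with T.
    """

    species_id: str
    chrom: str
    strand: str
    start: int
    end: int
    sequence: str
    n_mapped_loci: int = 1

    def __post_init__(self):
        if self.end - self.start != len(self.sequence):
            raise ValueError("locus interval length must match sequence length")
        if len(self.sequence) != 21:
            raise ValueError("piRNA locus must be 21 nt")

    @property
    def five_prime_t(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def unique(self) -> bool:
        return self.n_mapped_loci == 1


class GenomeIndex:
    """Exact k-mer seed index over the forward strand of each chromosome."""

    def __init__(self, genome: Mapping[str, str], seed_len: int = 7):
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.seed_len = seed_len
        self._index: dict[str, dict[str, list[int]]] = {}
        for chrom, seq in self.genome.items():
            idx: dict[str, list[int]] = defaultdict(list)
            for i in range(len(seq) - seed_len + 1):
                idx[seq[i : i + seed_len]].append(i)
            self._index[chrom] = dict(idx)

    def _candidates(self, pattern: str, max_mismatches: int) -> Iterable[tuple[str, int]]:
        """Candidate (chrom, start) pairs from pigeonhole seeding."""
        n = len(pattern)
        n_seeds = max_mismatches + 1
        k = self.seed_len
        if n < n_seeds * k:
            # pattern too short for pigeonhole seeds: fall back to full scan
            for chrom, seq in self.genome.items():
                for start in range(len(seq) - n + 1):
                    yield chrom, start
            return
        offsets = [round(j * (n - k) / (n_seeds - 1)) if n_seeds > 1 else 0 for j in range(n_seeds)]
        seen: set[tuple[str, int]] = set()
        for off in offsets:
            seed = pattern[off : off + k]
            for chrom, idx in self._index.items():
                for hit in idx.get(seed, ()):
                    start = hit - off
                    if start < 0 or start + n > len(self.genome[chrom]):
                        continue
                    key = (chrom, start)
                    if key not in seen:
                        seen.add(key)
                        yield key

    def align(self, insert: str, max_mismatches: int = 2) -> list[Alignment]:
        """All ungapped alignments of `insert` with <= max_mismatches, both strands."""
        insert = insert.upper()
        hits = []
        for strand, pattern in (("+", insert), ("-", revcomp(insert))):
            for chrom, start in self._candidates(pattern, max_mismatches):
                window = self.genome[chrom][start : start + len(pattern)]
                mm = sum(a != b or a == "N" or b == "N" for a, b in zip(pattern, window))
                if mm <= max_mismatches:
                    hits.append(Alignment(chrom, start, start + len(pattern), strand, mm))
        hits.sort(key=lambda a: (a.chrom, a.start, a.strand))
        return hits


def map_reads(
    inserts: Iterable[str],
    genome: Mapping[str, str] | GenomeIndex,
    max_mismatches: int = 2,
    max_loci: int = 50,
) -> dict[str, MapResult]:
    """Map distinct insert sequences; keep only the best mismatch stratum.

    Returns {insert sequence: MapResult}; inserts with no alignment get an
    empty result. Inserts whose best stratum exceeds `max_loci` alignments
    are truncated to `max_loci` and flagged.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    out: dict[str, MapResult] = {}
    for insert in inserts:
        insert = insert.upper()
        if insert in out:
            continue
        hits = index.align(insert, max_mismatches)
        if not hits:
            out[insert] = MapResult([])
            continue
        best = min(h.n_mismatches for h in hits)
        stratum = [h for h in hits if h.n_mismatches == best]
        flagged = len(stratum) > max_loci
        out[insert] = MapResult(stratum[:max_loci], flagged)
    return out


def brute_force_align(
    insert: str, genome: Mapping[str, str], max_mismatches: int = 2
) -> list[Alignment]:
    """All-position Hamming scan over both strands (vectorised reference path)."""
    insert = insert.upper()
    hits = []
    for strand, pattern in (("+", insert), ("-", revcomp(insert))):
        for chrom, seq in genome.items():
            mism = sliding_mismatches(pattern, seq.upper())
            for start in np.flatnonzero(mism <= max_mismatches):
                hits.append(
                    Alignment(chrom, int(start), int(start) + len(pattern), strand, int(mism[start]))
                )
    hits.sort(key=lambda a: (a.chrom, a.start, a.strand))
    return hits


def build_21u_coordinates(
    known_21u: Mapping[str, str], genome: Mapping[str, str] | GenomeIndex
) -> tuple[list[PiRNALocus], list[str]]:
    """Turn known 21U sequences into genomic coordinates.

    Only perfect, full-length 21-nt alignments become coordinates; a sequence
    mapping to k loci yields k PiRNALocus records sharing n_mapped_loci = k.
    Returns (loci, ids of sequences with no perfect hit).
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    loci: list[PiRNALocus] = []
    dropped: list[str] = []
    for species_id, seq in known_21u.items():
        seq = seq.upper().replace("U", "T")
        if len(seq) != 21:
            raise ValueError(f"{species_id}: 21U sequence must be 21 nt, got {len(seq)}")
        hits = [h for h in index.align(seq, max_mismatches=0) if h.n_mismatches == 0]
        if not hits:
            dropped.append(species_id)
            continue
        for hit in hits:
            loci.append(
                PiRNALocus(
                    species_id=species_id,
                    chrom=hit.chrom,
                    strand=hit.strand,
                    start=hit.start,
                    end=hit.end,
                    sequence=seq,
                    n_mapped_loci=len(hits),
                )
            )
    return loci, dropped


def _contained(aln: Alignment, locus: PiRNALocus) -> bool:
    return (
        aln.chrom == locus.chrom
        and aln.strand == locus.strand
        and aln.start >= locus.start
        and aln.end <= locus.end
    )


def annotate_reads(
    read_counts: pd.DataFrame,
    map_results: Mapping[str, MapResult],
    loci: Iterable[PiRNALocus],
    total_mapped: Mapping[str, float] | None = None,
    exact_length_only: bool = False,
) -> CountTable:
    """Assign mapped reads to 21U species and build a normalized count table.

    `read_counts` is a DataFrame of raw read counts indexed by insert
    sequence with one column per library. A read counts toward a 21U species
    iff one of its best-stratum alignments lies entirely within the locus
    interval on the same strand (`exact_length_only` restricts this to 21-nt
    reads). Multi-locus reads are weighted 1/n_mapped_loci before RPM
    normalization; raw per-species counts stay unweighted.
    """
    loci = list(loci)
    by_chrom: dict[tuple[str, str], list[PiRNALocus]] = defaultdict(list)
    for locus in loci:
        by_chrom[(locus.chrom, locus.strand)].append(locus)

    species_ids = sorted({l.species_id for l in loci})
    libraries = list(read_counts.columns)
    raw = pd.DataFrame(0.0, index=species_ids, columns=libraries)
    weighted = pd.DataFrame(0.0, index=species_ids, columns=libraries)

    mapped_read_totals = pd.Series(0.0, index=libraries)
    for insert, result in map_results.items():
        if insert not in read_counts.index or not result.alignments:
            continue
        counts = read_counts.loc[insert]
        mapped_read_totals += counts
        if exact_length_only and len(insert) != 21:
            continue
        n_loci = result.n_loci
        hit_species: set[str] = set()
        for aln in result.alignments:
            for locus in by_chrom.get((aln.chrom, aln.strand), ()):
                if _contained(aln, locus):
                    hit_species.add(locus.species_id)
        for sp in hit_species:
            raw.loc[sp] += counts
            weighted.loc[sp] += counts / n_loci

    if total_mapped is None:
        totals = mapped_read_totals.replace(0.0, np.nan)
    else:
        totals = pd.Series(dict(total_mapped)).reindex(libraries)
    norm = weighted.mul(1e6 / totals, axis=1).fillna(0.0)
    return CountTable(raw, norm)


def classify_read_length(insert: str) -> str | None:
    """Small-RNA class by length and 5' nucleotide: 22G and 26G RNAs."""
    if len(insert) == 22 and insert.startswith("G"):
        return "22G"
    if len(insert) == 26 and insert.startswith("G"):
        return "26G"
    if len(insert) == 21 and insert.startswith("T"):
        return "21U"
    return None
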