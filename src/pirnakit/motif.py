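"""Upstream core-motif scanning, spacer measurement, and motif matrices.

Each C. elegans piRNA locus carries an 8-nt core motif (consensus CTGTTTCA)
upstream of the genomic thymidine encoding its 5' uridine. The scanner looks
for the best-conserved central GTTTC within the 60 nt upstream of the locus
on the locus strand; among multiple occurrences it selects the one whose
implied spacer is closest to the abundance-optimal 39 nt (ties -> shorter
spacer). The spacer convention used for every constant in this module is the
number of nucleotides strictly between the 8-mer's 3' end and the locus 5'-T;
the canonical range is 35-42 nt. Loci with no GTTTC are "NM" (no motif) and
receive a fallback anchor that aligns position -44 to the G of the core
motif.
"""

from __future__ import annotations

import dataclasses
import itertools
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from pirnakit.io import Interval
from pirnakit.mapping import PiRNALocus
from pirnakit.sequence import revcomp

CANONICAL_SPACER = (35, 42)
OPTIMAL_SPACER = 39
FALLBACK_G_OFFSET = 44  # position -44 aligned to the G of GTTTC for NM loci


@dataclasses.dataclass(frozen=True)
class MotifCall:
    locus_id: str
    chrom: str
    strand: str
    has_gtttc: bool
    motif_start: int  # genomic position of the 8-mer 5' end on the locus strand
    core_8mer: str
    five_prime_nt: str  # C/A/G/T or NM
    spacer_length: int | None
    in_canonical_range: bool
    truncated_window: bool = False
    at_edge: bool = False

    @property
    def motif_key(self) -> tuple[str, str, int]:
        """Identity of the motif instance; loci sharing it form miniclusters."""
        return (self.chrom, self.strand, self.motif_start)


def upstream_window(locus: PiRNALocus, genome: Mapping[str, str], window: int = 60) -> str:
    """The `window` nt upstream of the locus 5'-T, 5'->3' on the locus strand.

    The returned string's last character is adjacent to the 5'-T. Truncated
    at chromosome edges.
    """
    seq = genome[locus.chrom]
    t = locus.five_prime_t
    if locus.strand == "+":
        lo = max(0, t - window)
        return seq[lo:t].upper()
    hi = min(len(seq), t + 1 + window)
    return revcomp(seq[t + 1 : hi]).upper()


def _window_index_to_genomic(locus: PiRNALocus, wlen: int, idx: int) -> int:
    """Map an upstream-window index (0 = 5'-most) to a forward-genome position."""
    t = locus.five_prime_t
    if locus.strand == "+":
        return t - wlen + idx
    return t + wlen - idx


def scan_upstream(
    locus: PiRNALocus,
    genome: Mapping[str, str],
    window: int = 60,
    select: str = "nearest39",
) -> MotifCall:
    """Scan the upstream window of a locus for the core-motif GTTTC.

    Occurrences are considered only where the full 8-mer context (2 nt
    upstream of GTTTC and 1 nt downstream) fits inside the window. `select`
    chooses among multiple occurrences: 'nearest39' (spacer closest to 39,
    ties to the shorter spacer), 'leftmost' (5'-most in the window, i.e.
    longest spacer) or 'rightmost'.
    """
    w = upstream_window(locus, genome, window)
    wlen = len(w)
    truncated = wlen < window

    occurrences = []  # (i, spacer) for GTTTC starting at window index i
    start = 0
    while True:
        i = w.find("GTTTC", start)
        if i == -1:
            break
        start = i + 1
        if i < 2 or i + 6 > wlen:
            continue  # 8-mer context does not fit
        spacer = wlen - i - 6
        occurrences.append((i, spacer))

    if not occurrences:
        at_edge = wlen < 8
        anchor_g = wlen - FALLBACK_G_OFFSET  # window index aligned to the motif G
        motif_start = _window_index_to_genomic(locus, wlen, anchor_g - 2)
        return MotifCall(
            locus_id=locus.species_id,
            chrom=locus.chrom,
            strand=locus.strand,
            has_gtttc=False,
            motif_start=motif_start,
            core_8mer="",
            five_prime_nt="NM",
            spacer_length=None,
            in_canonical_range=False,
            truncated_window=truncated,
            at_edge=at_edge,
        )

    if select == "nearest39":
        i, spacer = min(occurrences, key=lambda o: (abs(o[1] - OPTIMAL_SPACER), o[1]))
    elif select == "leftmost":
        i, spacer = occurrences[0]
    elif select == "rightmost":
        i, spacer = occurrences[-1]
    else:
        raise ValueError(f"unknown selection rule {select!r}")

    core = w[i - 2 : i + 6]
    return MotifCall(
        locus_id=locus.species_id,
        chrom=locus.chrom,
        strand=locus.strand,
        has_gtttc=True,
        motif_start=_window_index_to_genomic(locus, wlen, i - 2),
        core_8mer=core,
        five_prime_nt=core[0],
        spacer_length=spacer,
        in_canonical_range=CANONICAL_SPACER[0] <= spacer <= CANONICAL_SPACER[1],
        truncated_window=truncated,
    )


def scan_loci(
    loci: Iterable[PiRNALocus],
    genome: Mapping[str, str],
    window: int = 60,
    select: str = "nearest39",
    unique_only: bool = True,
) -> list[MotifCall]:
    """Scan a collection of loci; multi-mapping loci are excluded by default
    (their upstream sequences are ambiguous)."""
    calls = []
    for locus in loci:
        if unique_only and not locus.unique:
            continue
        calls.append(scan_upstream(locus, genome, window=window, select=select))
    return calls


def calls_to_frame(calls: Sequence[MotifCall]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(c) for c in calls])
    if not df.empty:
        df = df.set_index("locus_id")
    return df


# ---------------------------------------------------------------------------
# class-level analytics
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MotifClassSummary:
    contingency: pd.DataFrame  # enrichment class x {C, A, G, T, NM}
    chi2_stat: float
    chi2_p: float
    spacer_histograms: dict[str, pd.Series]


def classify_motifs(
    calls: Sequence[MotifCall], classification: pd.Series
) -> MotifClassSummary:
    """Cross-tabulate motif 5'-nt classes against enrichment classes.

    Raises on degenerate tables (a single enrichment class or a single motif
    category), where the chi-squared test is undefined.
    """
    rows = []
    for call in calls:
        cls = classification.get(call.locus_id)
        if cls is None or cls not in ("male", "female", "non_enriched"):
            continue
        rows.append((cls, call.five_prime_nt, call.spacer_length))
    if not rows:
        raise ValueError("no calls with usable enrichment classifications")
    df = pd.DataFrame(rows, columns=["class", "five_prime_nt", "spacer"])
    contingency = (
        pd.crosstab(df["class"], df["five_prime_nt"])
        .reindex(columns=["C", "A", "G", "T", "NM"], fill_value=0)
        .dropna(axis=1, how="all")
    )
    nonzero = contingency.loc[
        (contingency.sum(axis=1) > 0), contingency.columns[contingency.sum(axis=0) > 0]
    ]
    if nonzero.shape[0] < 2 or nonzero.shape[1] < 2:
        raise ValueError("degenerate contingency table: chi-squared undefined")
    chi2, p, _, _ = stats.chi2_contingency(nonzero.to_numpy(), correction=False)
    hists = {
        cls: sub["spacer"].dropna().astype(int).value_counts().sort_index()
        for cls, sub in df.groupby("class")
    }
    return MotifClassSummary(contingency, float(chi2), float(p), hists)


@dataclasses.dataclass
class AbundanceByMotifClass:
    stats: pd.DataFrame  # per 5'-nt class: n, mean RPM, SEM
    pairwise_welch: pd.DataFrame  # p-values, NaN where not testable
    excluded_classes: list[str]  # singleton classes (SEM undefined)


def abundance_by_motif_class(
    calls: Sequence[MotifCall], abundance: pd.Series
) -> AbundanceByMotifClass:
    """Mean abundance +/- SEM per motif 5'-nt class, with pairwise Welch tests.

    `abundance` maps species id -> mean RPM over the library subset under
    study (5'-monophosphate-dependent and -independent libraries are compared
    separately, so callers pass one subset at a time).
    """
    groups: dict[str, list[float]] = defaultdict(list)
    for call in calls:
        if call.locus_id in abundance.index:
            groups[call.five_prime_nt].append(float(abundance[call.locus_id]))
    order = [c for c in ("C", "A", "G", "T", "NM") if c in groups]
    rows = {}
    excluded = []
    for cls in order:
        vals = np.asarray(groups[cls])
        sem = float(stats.sem(vals)) if vals.size >= 2 else np.nan
        rows[cls] = {"n": vals.size, "mean_rpm": float(vals.mean()), "sem": sem}
        if vals.size < 2:
            excluded.append(cls)
    table = pd.DataFrame(rows).T
    pw = pd.DataFrame(np.nan, index=order, columns=order)
    for a, b in itertools.combinations(order, 2):
        if a in excluded or b in excluded:
            continue
        res = stats.ttest_ind(groups[a], groups[b], equal_var=False)
        pw.loc[a, b] = pw.loc[b, a] = float(res.pvalue)
    return AbundanceByMotifClass(table, pw, excluded)


# ---------------------------------------------------------------------------
# motif matrices (background-corrected information content)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MotifMatrix:
    freq: pd.DataFrame  # positions x {A, C, G, T}
    background: dict[str, float]
    info: pd.Series  # bits per position, relative entropy vs background

    def to_tsv(self, path) -> None:
        out = self.freq.copy()
        out["bits"] = self.info
        out.index.name = "position"
        out.to_csv(path, sep="\t")


def genome_background(genome: Mapping[str, str]) -> dict[str, float]:
    counts = {b: 0 for b in "ACGT"}
    for seq in genome.values():
        s = seq.upper()
        for b in "ACGT":
            counts[b] += s.count(b)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty genome")
    return {b: c / total for b, c in counts.items()}


def aligned_upstream_windows(
    calls: Sequence[MotifCall],
    loci_by_id: Mapping[str, PiRNALocus],
    genome: Mapping[str, str],
    span: tuple[int, int] = (-10, 10),
    window: int = 60,
) -> list[str]:
    """Extract upstream windows aligned on the central T of the motif's TTT.

    The core 8-mer is [N][N][G][T][T][T][C][N]; the alignment point is its
    index-4 T. NM calls use the fallback anchor (G at -44, so the central T
    at -42). Windows running past the upstream window are skipped.
    """
    lo, hi = span
    out = []
    for call in calls:
        locus = loci_by_id[call.locus_id]
        w = upstream_window(locus, genome, window)
        wlen = len(w)
        if call.has_gtttc:
            # GTTTC starts at window index wlen - 6 - spacer; central T is +2
            center = (wlen - 6 - call.spacer_length) + 2
        else:
            center = (wlen - FALLBACK_G_OFFSET) + 2
        if center + lo < 0 or center + hi + 1 > wlen:
            continue
        out.append(w[center + lo : center + hi + 1])
    return out


def motif_matrix(
    windows: Sequence[str],
    background: Mapping[str, float],
    offsets: Sequence[int] | None = None,
) -> MotifMatrix:
    """Position frequency matrix and per-position information content.

    Information content is the relative entropy sum_b f_b log2(f_b / q_b)
    against the supplied background composition (>= 0 by definition).
    """
    if not windows:
        raise ValueError("no aligned windows")
    length = len(windows[0])
    if any(len(w) != length for w in windows):
        raise ValueError("aligned windows must share one length")
    if offsets is None:
        offsets = list(range(length))
    mat = np.zeros((length, 4))
    bases = "ACGT"
    for w in windows:
        for pos, base in enumerate(w.upper()):
            if base in bases:
                mat[pos, bases.index(base)] += 1
    totals = mat.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    freq = mat / totals
    q = np.array([background[b] for b in bases])
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freq > 0, freq * np.log2(freq / q), 0.0)
    info = terms.sum(axis=1)
    freq_df = pd.DataFrame(freq, columns=list(bases), index=list(offsets))
    return MotifMatrix(freq_df, dict(background), pd.Series(info, index=list(offsets)))


# ---------------------------------------------------------------------------
# k-mer density
# ---------------------------------------------------------------------------

def count_occurrences(seq: str, kmer: str) -> int:
    """Sliding-window (overlap-allowing) occurrence count."""
    count = 0
    start = 0
    while True:
        i = seq.find(kmer, start)
        if i == -1:
            return count
        count += 1
        start = i + 1


def kmer_density(
    genome: Mapping[str, str],
    regions: Iterable[Interval],
    kmer: str = "GTTTC",
    both_strands: bool = True,
) -> float:
    """Occurrences of `kmer` per kilobase within `regions` (both strands by
    default; reverse-strand hits counted as forward occurrences of the
    reverse complement)."""
    kmer = kmer.upper()
    total_occ = 0
    total_len = 0
    rc = revcomp(kmer)
    for region in regions:
        sub = genome[region.chrom][region.start : region.end].upper()
        total_len += len(sub)
        total_occ += count_occurrences(sub, kmer)
        if both_strands and rc != kmer:
            total_occ += count_occurrences(sub, rc)
        elif both_strands and rc == kmer:
            total_occ += count_occurrences(sub, kmer)
    if total_len == 0:
        raise ValueError("regions have zero total length")
    return 1000.0 * total_occ / total_len
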