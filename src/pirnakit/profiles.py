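"""Anchor-centred metaprofiles of per-nucleotide signal tracks.

A metaprofile averages a genomic signal (e.g. Pol II ChIP input-normalized
occupancy or nucleosome occupancy) across a set of anchors: piRNA-locus
5'-T positions, transcription start sites, or random non-overlapping
intergenic windows. Windows are oriented 5'->3' on the anchor strand
(minus-strand windows reversed); anchors whose window runs past a chromosome
edge are skipped and counted rather than zero-padded.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np

from pirnakit.io import Interval


@dataclasses.dataclass(frozen=True)
class Anchor:
    chrom: str
    position: int
    strand: str = "+"
    value: float = 0.0  # abundance (RPM) or expression, used for filters/quartiles


@dataclasses.dataclass
class MetaProfile:
    offsets: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_anchors: int
    n_skipped_edge: int = 0
    n_filtered: int = 0


def metaprofile(
    track: Mapping[str, np.ndarray],
    anchors: Iterable[Anchor],
    half_width: int = 500,
    min_value: float | None = None,
) -> MetaProfile:
    """Average signal per offset in [-half_width, +half_width] across anchors.

    `min_value` drops anchors whose `value` (abundance/expression) is below
    the threshold before averaging.
    """
    offsets = np.arange(-half_width, half_width + 1)
    rows = []
    skipped = 0
    filtered = 0
    for anchor in anchors:
        if min_value is not None and anchor.value < min_value:
            filtered += 1
            continue
        arr = track.get(anchor.chrom)
        if arr is None:
            raise KeyError(f"track has no chromosome {anchor.chrom!r}")
        lo = anchor.position - half_width
        hi = anchor.position + half_width + 1
        if lo < 0 or hi > arr.size:
            skipped += 1
            continue
        window = np.asarray(arr[lo:hi], dtype=float)
        if anchor.strand == "-":
            window = window[::-1]
        rows.append(window)
    if rows:
        mat = np.vstack(rows)
        mean = mat.mean(axis=0)
        sem = (
            mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
            if mat.shape[0] >= 2
            else np.full(offsets.size, np.nan)
        )
    else:
        mean = np.full(offsets.size, np.nan)
        sem = np.full(offsets.size, np.nan)
    return MetaProfile(offsets, mean, sem, len(rows), skipped, filtered)


def quartile_profiles(
    track: Mapping[str, np.ndarray],
    anchors: Sequence[Anchor],
    half_width: int = 500,
) -> tuple[MetaProfile, MetaProfile]:
    """Profiles for the top and bottom 25% of anchors by abundance.

    Quartile membership is by abundance rank; ties are broken by stable
    anchor order. Returns (top quartile, bottom quartile).
    """
    anchors = list(anchors)
    n = len(anchors)
    if n < 4:
        raise ValueError("need at least 4 anchors for quartiles")
    k = n // 4
    order = sorted(range(n), key=lambda i: (-anchors[i].value, i))
    top = [anchors[i] for i in order[:k]]
    bottom = [anchors[i] for i in order[-k:]]
    return (
        metaprofile(track, top, half_width=half_width),
        metaprofile(track, bottom, half_width=half_width),
    )


def build_intergenic_windows(
    annotations: Iterable[Interval],
    chrom_lengths: Mapping[str, int],
    window: int = 1000,
    seed: int | None = None,
) -> list[Anchor]:
    """Random non-overlapping windows in unannotated genomic space.

    Each unannotated gap of length L holds floor(L / window) windows placed
    at a random offset within the gap; anchors mark window centres.
    Deterministic given seed; empty (with no error) on a fully annotated
    genome.
    """
    rng = np.random.default_rng(seed)
    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    for iv in annotations:
        if iv.chrom in by_chrom:
            by_chrom[iv.chrom].append((iv.start, iv.end))
    anchors = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        merged = []
        for start, end in sorted(by_chrom[chrom]):
            if merged and start <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], end))
            else:
                merged.append((start, end))
        gaps = []
        prev = 0
        for start, end in merged:
            if start > prev:
                gaps.append((prev, start))
            prev = max(prev, end)
        if prev < length:
            gaps.append((prev, length))
        for lo, hi in gaps:
            n_fit = (hi - lo) // window
            if n_fit == 0:
                continue
            slack = (hi - lo) - n_fit * window
            offset = int(rng.integers(0, slack + 1)) if slack else 0
            for j in range(n_fit):
                start = lo + offset + j * window
                anchors.append(Anchor(chrom, start + window // 2, "+"))
    return anchors


def profile_to_tsv(path, profile: MetaProfile) -> None:
    with open(path, "w") as fh:
        fh.write("offset\tmean\tsem\n")
        for off, m, s in zip(profile.offsets, profile.mean, profile.sem):
            fh.write(f"{off}\t{m:.6g}\t{s:.6g}\n")
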