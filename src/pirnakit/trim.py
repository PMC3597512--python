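"""3'-linker removal cascade for small-RNA reads.

The cascade searches, in strict order: (1) a perfect occurrence of the full
linker anywhere in the read (leftmost wins); (2) a full-linker occurrence with
exactly one mismatch; then anchored suffix matches between the last k nt of
the read and the first k nt of the linker for k = 5, 4, 3, each first with 0
then with 1 mismatch. The first rule satisfied determines the trim point; the
insert is the read prefix before it. Reads matching no rule are discarded.

N bases count as mismatches. The 1-mismatch variant at k = 3 is nearly
vacuous (it accepts any read whose last three bases share one base with the
linker start) and can be disabled with ``allow_1mm_k3=False``.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Iterable

from pirnakit import io as pio

VALID_BASES = frozenset("ACGTN")

STATUSES = (
    "trimmed_full_0mm",
    "trimmed_full_1mm",
    "trimmed_suffix_5_0mm",
    "trimmed_suffix_5_1mm",
    "trimmed_suffix_4_0mm",
    "trimmed_suffix_4_1mm",
    "trimmed_suffix_3_0mm",
    "trimmed_suffix_3_1mm",
    "discarded",
)


@dataclasses.dataclass(frozen=True)
class TrimResult:
    insert: str | None
    status: str
    trim_position: int | None

    @property
    def discarded(self) -> bool:
        return self.status == "discarded"


def _check_bases(seq: str, what: str) -> None:
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"{what} contains non-ACGTN characters: {sorted(bad)}")


def _hamming(a: str, b: str) -> int:
    # N never matches anything, including N
    return sum(x != y or x == "N" for x, y in zip(a, b))


def _leftmost_occurrence(read: str, linker: str, mismatches: int) -> int | None:
    """Leftmost start of a full-length linker occurrence with exactly
    `mismatches` mismatches, or None."""
    L = len(linker)
    for i in range(len(read) - L + 1):
        if _hamming(read[i : i + L], linker) == mismatches:
            return i
    return None


def trim_read(read: str, linker: str, allow_1mm_k3: bool = True) -> TrimResult:
    """Apply the linker-removal cascade to one read."""
    read = read.upper()
    linker = linker.upper()
    _check_bases(read, "read")
    _check_bases(linker, "linker")
    if len(linker) < 5:
        raise ValueError("linker must be at least 5 nt")
    if len(read) < 1:
        raise ValueError("read must be at least 1 nt")

    # rules 1-2: full linker anywhere, 0 then 1 mismatch, leftmost occurrence
    for mm in (0, 1):
        pos = _leftmost_occurrence(read, linker, mm)
        if pos is not None:
            return TrimResult(read[:pos], f"trimmed_full_{mm}mm", pos)

    # rules 3-8: read suffix of length k vs linker prefix of length k
    for k in (5, 4, 3):
        if len(read) < k:
            continue
        suffix = read[-k:]
        prefix = linker[:k]
        for mm in (0, 1):
            if k == 3 and mm == 1 and not allow_1mm_k3:
                continue
            if _hamming(suffix, prefix) == mm:
                return TrimResult(read[:-k], f"trimmed_suffix_{k}_{mm}mm", len(read) - k)

    return TrimResult(None, "discarded", None)


def trim_reads(
    reads: Iterable[tuple[str, str, str]], linker: str, allow_1mm_k3: bool = True
) -> tuple[list[tuple[str, str, str]], Counter]:
    """Trim an iterable of (id, seq, qual) reads; returns kept reads + status counts.

    Discarded reads and reads with empty inserts are dropped from the output.
    """
    kept = []
    counts: Counter = Counter({s: 0 for s in STATUSES})
    for name, seq, qual in reads:
        result = trim_read(seq, linker, allow_1mm_k3=allow_1mm_k3)
        counts[result.status] += 1
        if not result.discarded and result.insert:
            kept.append((name, result.insert, qual[: len(result.insert)]))
    return kept, counts


def trim_library(
    fastq_in, linker: str, fastq_out, report_path=None, allow_1mm_k3: bool = True
) -> "dict[str, int]":
    """Trim a FASTQ library on disk; optionally write a TSV status report."""
    reads = pio.read_fastq(fastq_in)
    kept, counts = trim_reads(reads, linker, allow_1mm_k3=allow_1mm_k3)
    pio.write_fastq(fastq_out, kept)
    total = sum(counts.values())
    if report_path is not None:
        with open(report_path, "w") as fh:
            fh.write("status\tcount\tfraction\n")
            for status in STATUSES:
                frac = counts[status] / total if total else 0.0
                fh.write(f"{status}\t{counts[status]}\t{frac:.6f}\n")
    return dict(counts)
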