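"""Small shared nucleotide-sequence helpers."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# numeric encoding used for vectorised Hamming scans
_CODE = np.full(256, 4, dtype=np.uint8)
for i, base in enumerate("ACGT"):
    _CODE[ord(base)] = i
    _CODE[ord(base.lower())] = i


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 (A=0 C=1 G=2 T=3, anything else 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def random_seq(rng: np.random.Generator, length: int, gc_fraction: float = 0.5) -> str:
    """Random sequence with the given expected GC fraction."""
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    p_at = (1.0 - gc_fraction) / 2.0
    p_gc = gc_fraction / 2.0
    bases = rng.choice(np.array(list("ACGT")), size=length, p=[p_at, p_gc, p_gc, p_at])
    return "".join(bases)


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def sliding_mismatches(pattern: str, subject: str) -> np.ndarray:
    """Hamming distance of `pattern` against every window of `subject`.

    Returns an int array of length len(subject) - len(pattern) + 1 (empty if
    the subject is shorter than the pattern). Positions encoded as 4 (N etc.)
    never match.
    """
    m, n = len(pattern), len(subject)
    if n < m:
        return np.zeros(0, dtype=np.int64)
    p = encode(pattern)
    s = encode(subject)
    windows = np.lib.stride_tricks.sliding_window_view(s, m)
    mism = (windows != p) | (windows == 4) | (p == 4)
    return mism.sum(axis=1)
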