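"""Readers/writers for on-disk formats, the library manifest, and run config.

All genomic coordinates are 0-based half-open (BED-native) throughout the
package. Count tables store raw counts and normalized abundances (RPM: reads
per million mapped reads, each read additionally weighted by the reciprocal
of its number of mapped genomic loci) side by side.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ParseError(ValueError):
    """A malformed record; carries file and line context."""

    def __init__(self, path, lineno, message):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


# ---------------------------------------------------------------------------
# sequence formats (Biopython-backed)
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ParseError(path, -1, f"duplicate FASTA id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(path, records: Mapping[str, str]) -> None:
    seqs = (SeqRecord(Seq(s), id=name, description="") for name, s in records.items())
    SeqIO.write(seqs, str(path), "fasta")


def read_fastq(path) -> list[tuple[str, str, str]]:
    """Read FASTQ into a list of (id, sequence, quality-string) tuples."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq).upper(), qual))
    return out


def write_fastq(path, reads: Iterable[tuple[str, str, str]]) -> None:
    def _records():
        for name, seq, qual in reads:
            rec = SeqRecord(Seq(seq), id=name, description="")
            rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
            yield rec

    SeqIO.write(_records(), str(path), "fastq")


# ---------------------------------------------------------------------------
# interval formats
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Interval:
    """A BED interval: 0-based half-open, optional name/score/strand."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"interval end {self.end} <= start {self.start}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")


def read_bed(path) -> list[Interval]:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError(path, lineno, "BED line has fewer than 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(path, lineno, f"non-integer coordinate: {exc}") from None
            if end <= start:
                raise ParseError(path, lineno, f"end {end} <= start {start}")
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            intervals.append(Interval(fields[0], start, end, name, score, strand))
    return intervals


def write_bed(path, intervals: Iterable[Interval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
            )


def read_bedgraph(path) -> list[tuple[str, int, int, float]]:
    """Read bedGraph lines into (chrom, start, end, value) tuples."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(path, lineno, "bedGraph line needs 4 fields")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(path, lineno, f"bad bedGraph field: {exc}") from None
            if end <= start:
                raise ParseError(path, lineno, f"end {end} <= start {start}")
            out.append((fields[0], start, end, value))
    return out


def write_bedgraph(path, entries: Iterable[tuple[str, int, int, float]]) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in entries:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def bedgraph_to_arrays(entries, chrom_lengths: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Expand bedGraph intervals to dense per-nucleotide float arrays."""
    tracks = {c: np.zeros(n, dtype=float) for c, n in chrom_lengths.items()}
    for chrom, start, end, value in entries:
        if chrom not in tracks:
            raise KeyError(f"bedGraph chrom {chrom!r} not in chrom_lengths")
        tracks[chrom][start:end] = value
    return tracks


def arrays_to_bedgraph(tracks: Mapping[str, np.ndarray]) -> list[tuple[str, int, int, float]]:
    """Run-length-encode dense per-nucleotide arrays into bedGraph entries."""
    entries = []
    for chrom in tracks:
        arr = np.asarray(tracks[chrom], dtype=float)
        if arr.size == 0:
            continue
        change = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [arr.size]))
        for s, e in zip(starts, ends):
            entries.append((chrom, int(s), int(e), float(arr[s])))
    return entries


# ---------------------------------------------------------------------------
# library design manifest
# ---------------------------------------------------------------------------

class Sex(str, enum.Enum):
    male = "male"
    female = "female"
    embryo = "embryo"
    mixed = "mixed"


class Protocol(str, enum.Enum):
    monoP_dependent = "monoP_dependent"
    monoP_independent = "monoP_independent"


@dataclasses.dataclass(frozen=True)
class LibraryMeta:
    id: str
    sex: str
    protocol: str
    genotype: str = "N2"
    stage: str = "adult"
    total_mapped_reads: int = 1_000_000

    def __post_init__(self):
        Sex(self.sex)
        Protocol(self.protocol)
        if self.total_mapped_reads < 0:
            raise ValueError("total_mapped_reads must be non-negative")


@dataclasses.dataclass
class LibraryDesign:
    """The manifest of sequencing libraries.

    Germline libraries are those with sex 'male' or 'female'; the Enrichment
    Score compares every male against every female library within the same
    5'-monophosphate protocol group.
    """

    libraries: list[LibraryMeta]

    def __post_init__(self):
        ids = [lib.id for lib in self.libraries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate library ids: {dupes}")

    def __iter__(self):
        return iter(self.libraries)

    def __len__(self):
        return len(self.libraries)

    @property
    def ids(self) -> list[str]:
        return [lib.id for lib in self.libraries]

    def get(self, lib_id: str) -> LibraryMeta:
        for lib in self.libraries:
            if lib.id == lib_id:
                return lib
        raise KeyError(lib_id)

    def subset(self, sex=None, protocol=None, genotype=None, stage=None) -> list[LibraryMeta]:
        out = self.libraries
        if sex is not None:
            out = [l for l in out if l.sex == sex]
        if protocol is not None:
            out = [l for l in out if l.protocol == protocol]
        if genotype is not None:
            out = [l for l in out if l.genotype == genotype]
        if stage is not None:
            out = [l for l in out if l.stage == stage]
        return list(out)

    def germline_ids(self) -> list[str]:
        return [l.id for l in self.libraries if l.sex in ("male", "female")]

    def embryo_ids(self) -> list[str]:
        return [l.id for l in self.libraries if l.sex == "embryo"]

    def comparisons(self) -> list[tuple[str, str]]:
        """All within-protocol (male library, female library) pairs."""
        pairs = []
        for proto in Protocol:
            males = self.subset(sex="male", protocol=proto.value)
            females = self.subset(sex="female", protocol=proto.value)
            pairs.extend((m.id, f.id) for m in males for f in females)
        return pairs

    def validate_counts(self, table: "CountTable") -> None:
        unknown = set(table.libraries) - set(self.ids)
        if unknown:
            raise ValueError(
                f"count table references libraries absent from the manifest: {sorted(unknown)}"
            )

    @classmethod
    def from_tsv(cls, path) -> "LibraryDesign":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"id", "sex", "protocol"}
        missing = required - set(df.columns)
        if missing:
            raise ParseError(path, 1, f"manifest missing columns: {sorted(missing)}")
        libs = []
        for _, row in df.iterrows():
            libs.append(
                LibraryMeta(
                    id=row["id"],
                    sex=row["sex"],
                    protocol=row["protocol"],
                    genotype=row.get("genotype", "N2") or "N2",
                    stage=row.get("stage", "adult") or "adult",
                    total_mapped_reads=int(row.get("total_mapped_reads", 1_000_000)),
                )
            )
        return cls(libs)

    def to_tsv(self, path) -> None:
        pd.DataFrame([dataclasses.asdict(l) for l in self.libraries]).to_csv(
            path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

class CountTable:
    """Per-species raw counts and normalized abundances across libraries.

    `raw` and `norm` are DataFrames indexed by species_id with one column per
    library id. Normalized abundance is RPM after dividing each read count by
    the species' number of mapped genomic loci.
    """

    def __init__(self, raw: pd.DataFrame, norm: pd.DataFrame):
        raw = raw.astype(float)
        norm = norm.astype(float)
        if not raw.index.equals(norm.index) or not raw.columns.equals(norm.columns):
            raise ValueError("raw and normalized tables must share index and columns")
        if (raw < 0).any().any() or (norm < 0).any().any():
            raise ValueError("counts and abundances must be non-negative")
        zero_mismatch = (raw == 0) != (norm == 0)
        if zero_mismatch.any().any():
            raise ValueError("normalized abundance must be 0 exactly where raw count is 0")
        self.raw = raw
        self.norm = norm

    @property
    def species(self) -> list[str]:
        return list(self.raw.index)

    @property
    def libraries(self) -> list[str]:
        return list(self.raw.columns)

    @classmethod
    def from_raw(
        cls,
        raw: pd.DataFrame,
        total_mapped: Mapping[str, float] | pd.Series | None = None,
        n_loci: Mapping[str, float] | pd.Series | None = None,
    ) -> "CountTable":
        """Normalize raw counts to RPM.

        total_mapped maps library id -> total mapped reads (defaults to the
        per-library column sums); n_loci maps species -> number of genomic
        loci the species maps to (defaults to 1, i.e. unique mappers).
        """
        raw = raw.astype(float)
        if total_mapped is None:
            totals = raw.sum(axis=0)
        else:
            totals = pd.Series(dict(total_mapped)).reindex(raw.columns)
        if totals.isna().any() or (totals <= 0).any():
            raise ValueError("every library needs a positive total_mapped_reads")
        if n_loci is None:
            loci = pd.Series(1.0, index=raw.index)
        else:
            loci = pd.Series(dict(n_loci)).reindex(raw.index).fillna(1.0)
        weighted = raw.div(loci, axis=0)
        norm = weighted.mul(1e6 / totals, axis=1)
        return cls(raw, norm)

    def to_tsv(self, path) -> None:
        out = pd.DataFrame(index=self.raw.index)
        for lib in self.libraries:
            out[f"{lib}.raw"] = self.raw[lib]
            out[f"{lib}.rpm"] = self.norm[lib]
        out.index.name = "species_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col="species_id")
        raw_cols = [c for c in df.columns if c.endswith(".raw")]
        rpm_cols = [c for c in df.columns if c.endswith(".rpm")]
        libs = [c[:-4] for c in raw_cols]
        if libs != [c[:-4] for c in rpm_cols]:
            raise ParseError(path, 1, "mismatched .raw/.rpm column pairs")
        raw = df[raw_cols].copy()
        raw.columns = libs
        norm = df[rpm_cols].copy()
        norm.columns = libs
        return cls(raw, norm)

    def equals(self, other: "CountTable") -> bool:
        return self.raw.equals(other.raw) and self.norm.equals(other.norm)


read_counts = CountTable.from_tsv


def write_counts(path, table: CountTable) -> None:
    table.to_tsv(path)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "seed": 0,
    "thresholds": {
        "fold": 5.0,
        "score": 3,
        "upstream_window": 60,
        "spacer_min": 35,
        "spacer_max": 42,
        "target_mismatches": 3,
        "proximity_nt": 40,
    },
    "paths": {},
}


def load_config(path=None) -> dict:
    """Load run configuration (YAML), merged over the package defaults."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
    return cfg


def save_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
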