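"""Core domain types and exceptions shared by every stage of the pipeline.

All coordinates are 0-based half-open throughout the package; conversion
to/from 1-based closed conventions (GTF/GFF3, wiggle) happens only at I/O
boundaries in :mod:`rdna4c.io_formats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np


class Rdna4cError(Exception):
    """Base class for all package errors."""


class ValidationError(Rdna4cError):
    """An object violates a structural invariant."""


class ParseError(Rdna4cError):
    """A file could not be parsed; message names the offending line."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}:"
        if line is not None:
            loc += f"{line}: "
        elif path is not None:
            loc += " "
        super().__init__(loc + message)
        self.path = path
        self.line = line


class ParameterError(Rdna4cError):
    """A caller-supplied parameter is out of range."""


class NormalizationError(Rdna4cError):
    """Normalization impossible (zero library size, no all-positive gene)."""


class InsufficientDataError(Rdna4cError):
    """Too little data survives filtering to compute the statistic."""


class CapacityError(Rdna4cError):
    """The simulated genome cannot hold the requested features."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chromosome name is empty")
        if self.start < 0:
            raise ValidationError(f"interval start {self.start} < 0")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end {self.end} <= start {self.start} on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """True if ``other`` lies entirely within this interval."""
        return (
            self.chrom == other.chrom
            and other.start >= self.start
            and other.end <= self.end
        )

    def distance_to(self, other: "GenomicInterval") -> int:
        """Edge-to-edge gap in bp; 0 when the intervals touch or overlap."""
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across chromosomes")
        if self.start < other.end and other.start < self.end:
            return 0
        return max(self.start - other.end, other.start - self.end, 0)


@dataclass(frozen=True)
class BedGraphRecord:
    interval: GenomicInterval
    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValidationError(
                f"negative bedGraph value {self.value} at "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )


def _check_sorted_disjoint(records: Sequence[BedGraphRecord]) -> None:
    for prev, cur in zip(records, records[1:]):
        a, b = prev.interval, cur.interval
        if (a.chrom, a.start) > (b.chrom, b.start):
            raise ValidationError(
                f"records out of order: {a.chrom}:{a.start} before {b.chrom}:{b.start}"
            )
        if a.chrom == b.chrom and b.start < a.end:
            raise ValidationError(
                f"overlapping records on {a.chrom}: [{a.start},{a.end}) and "
                f"[{b.start},{b.end})"
            )


@dataclass
class ContactTrack:
    """Sorted, per-chromosome non-overlapping coverage records for one sample."""

    records: list[BedGraphRecord]
    sample_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.records = sorted(
            self.records, key=lambda r: (r.interval.chrom, r.interval.start)
        )
        _check_sorted_disjoint(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[BedGraphRecord]:
        return iter(self.records)

    def chromosomes(self) -> list[str]:
        return sorted({r.interval.chrom for r in self.records})

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per-chromosome ``(starts, ends, values)`` arrays, sorted by start."""
        out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom in self.chromosomes():
            recs = [r for r in self.records if r.interval.chrom == chrom]
            out[chrom] = (
                np.array([r.interval.start for r in recs], dtype=np.int64),
                np.array([r.interval.end for r in recs], dtype=np.int64),
                np.array([r.value for r in recs], dtype=float),
            )
        return out

    def total_reads(self, exclude_chroms: Iterable[str] = ()) -> float:
        excl = set(exclude_chroms)
        return float(
            sum(r.value for r in self.records if r.interval.chrom not in excl)
        )


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    symbol: str
    interval: GenomicInterval
    strand: str
    exons: tuple[GenomicInterval, ...] = ()
    utr5: tuple[GenomicInterval, ...] = ()
    utr3: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        for sub in (*self.exons, *self.utr5, *self.utr3):
            if not self.interval.contains(sub):
                raise ValidationError(
                    f"gene {self.gene_id}: sub-feature {sub} outside gene body"
                )

    @property
    def tss(self) -> int:
        """Transcription start position (strand-aware, 0-based)."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        """Transcription end position (strand-aware, 0-based)."""
        return self.interval.end - 1 if self.strand == "+" else self.interval.start


class GeneSet:
    """Collection of genes with unique ids and fast per-chromosome access."""

    def __init__(self, genes: Iterable[GeneRecord]):
        self._genes: dict[str, GeneRecord] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
            self._genes[g.gene_id] = g
        self._by_chrom: dict[str, list[GeneRecord]] | None = None

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self._genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._genes[gene_id]

    def gene_ids(self) -> list[str]:
        return list(self._genes)

    def by_chrom(self) -> dict[str, list[GeneRecord]]:
        if self._by_chrom is None:
            out: dict[str, list[GeneRecord]] = {}
            for g in self._genes.values():
                out.setdefault(g.interval.chrom, []).append(g)
            for lst in out.values():
                lst.sort(key=lambda g: g.interval.start)
            self._by_chrom = out
        return self._by_chrom


@dataclass(frozen=True)
class RepeatRecord:
    interval: GenomicInterval
    family: str = ""
    repeat_class: str = "other"

    VALID_CLASSES = ("LTR", "LINE", "SINE", "low_complexity", "other")

    def __post_init__(self) -> None:
        if self.repeat_class not in self.VALID_CLASSES:
            raise ValidationError(
                f"unknown repeat class {self.repeat_class!r} "
                f"(expected one of {self.VALID_CLASSES})"
            )


@dataclass(frozen=True)
class StateSegment:
    interval: GenomicInterval
    state: int

    def __post_init__(self) -> None:
        if not 1 <= self.state <= 9:
            raise ValidationError(f"chromatin state {self.state} outside 1..9")


class StateAnnotation:
    """Labeled chromatin-state segments, sorted and non-overlapping per chromosome.

    Stored internally as per-chromosome ``(starts, ends, states)`` arrays so
    that the permutation machinery can reshuffle thousands of times cheaply.
    """

    def __init__(self, segments: Iterable[StateSegment]):
        segs = sorted(segments, key=lambda s: (s.interval.chrom, s.interval.start))
        self._arrays: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[StateSegment]] = {}
        for s in segs:
            by_chrom.setdefault(s.interval.chrom, []).append(s)
        for chrom, lst in by_chrom.items():
            for a, b in zip(lst, lst[1:]):
                if b.interval.start < a.interval.end:
                    raise ValidationError(
                        f"overlapping state segments on {chrom} at {b.interval.start}"
                    )
            self._arrays[chrom] = (
                np.array([s.interval.start for s in lst], dtype=np.int64),
                np.array([s.interval.end for s in lst], dtype=np.int64),
                np.array([s.state for s in lst], dtype=np.int64),
            )

    @classmethod
    def from_arrays(
        cls, arrays: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    ) -> "StateAnnotation":
        obj = cls.__new__(cls)
        obj._arrays = {
            chrom: (
                np.asarray(s, dtype=np.int64),
                np.asarray(e, dtype=np.int64),
                np.asarray(st, dtype=np.int64),
            )
            for chrom, (s, e, st) in arrays.items()
        }
        return obj

    def arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        return self._arrays

    def chromosomes(self) -> list[str]:
        return sorted(self._arrays)

    def __len__(self) -> int:
        return sum(len(s) for s, _, _ in self._arrays.values())

    def segments(self) -> Iterator[StateSegment]:
        for chrom in self.chromosomes():
            starts, ends, states = self._arrays[chrom]
            for s, e, st in zip(starts, ends, states):
                yield StateSegment(GenomicInterval(chrom, int(s), int(e)), int(st))

    def state_lengths(self) -> dict[int, int]:
        """Total bp covered by each state genome-wide."""
        out: dict[int, int] = {}
        for starts, ends, states in self._arrays.values():
            for st in np.unique(states):
                out[int(st)] = out.get(int(st), 0) + int(
                    (ends - starts)[states == st].sum()
                )
        return out


@dataclass
class SignalTrack:
    """A (possibly sparse) real-valued signal: sorted non-overlapping records."""

    records: list[BedGraphRecord]
    name: str = ""

    def __post_init__(self) -> None:
        self.records = sorted(
            self.records, key=lambda r: (r.interval.chrom, r.interval.start)
        )
        _check_sorted_disjoint(self.records)

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        chroms = sorted({r.interval.chrom for r in self.records})
        for chrom in chroms:
            recs = [r for r in self.records if r.interval.chrom == chrom]
            out[chrom] = (
                np.array([r.interval.start for r in recs], dtype=np.int64),
                np.array([r.interval.end for r in recs], dtype=np.int64),
                np.array([r.value for r in recs], dtype=float),
            )
        return out
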