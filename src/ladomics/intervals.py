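"""Genomic interval model, BED I/O, and overlap / nearest-distance queries.

All coordinates are 0-based, half-open (the BED convention): an interval
``[start, end)`` covers ``end - start`` bases, and ``[0, 100)`` does not
overlap ``[100, 200)``.  One-based point coordinates (e.g. array-manifest
CpG positions) are converted to ``[pos - 1, pos)`` on ingest via
:func:`point_interval`.

Strand is carried but ignored by every query; annotation-track overlaps in
this package are strand-agnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "AnnotationTrack",
    "BedParseError",
    "read_bed",
    "write_bed",
    "overlaps_any",
    "nearest_distance",
    "point_interval",
    "normalize_chrom",
]


class BedParseError(ValueError):
    """Raised for malformed BED input; the message names the line number."""


def normalize_chrom(name: str) -> str:
    """Map bare chromosome names onto the UCSC ``chr``-prefixed dialect.

    ``"1" -> "chr1"``; names already carrying the prefix are returned
    unchanged.  Mitochondrial aliases ``MT``/``chrMT`` map to ``chrM``.
    """
    name = name.strip()
    if name in ("MT", "chrMT"):
        return "chrM"
    if not name.startswith("chr"):
        return "chr" + name
    return name


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start under half-open coordinates, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in (None, "+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


class AnnotationTrack:
    """A named, per-chromosome sorted collection of :class:`GenomicInterval`.

    Overlapping member intervals are permitted; nothing is merged
    implicitly.  Internally each chromosome holds start/end arrays sorted
    by start plus a running maximum of ends, which turns both overlap and
    nearest-distance queries into binary searches.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), name: str = ""):
        self.name = name
        self._intervals: list[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        self._index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._build_index()

    def _build_index(self) -> None:
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in self._intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        self._index = {}
        for chrom, ivs in by_chrom.items():
            starts = np.array([iv.start for iv in ivs], dtype=np.int64)
            ends = np.array([iv.end for iv in ivs], dtype=np.int64)
            # ivs already sorted by start; prefix max of ends supports
            # "any interval left of x reaching past y" queries
            self._index[chrom] = (starts, ends, np.maximum.accumulate(ends))

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self._intervals[i]

    @property
    def intervals(self) -> list[GenomicInterval]:
        return list(self._intervals)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._index)

    def add(self, interval: GenomicInterval) -> None:
        """Insert an interval, re-establishing sorted order."""
        self._intervals.append(interval)
        self._intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
        self._build_index()

    def total_bases(self) -> int:
        """Sum of interval lengths (overlaps counted multiply)."""
        return int(sum(len(iv) for iv in self._intervals))

    def normalized(self) -> "AnnotationTrack":
        """Copy of the track with chromosome names mapped to ``chrN``."""
        return AnnotationTrack(
            (
                GenomicInterval(
                    normalize_chrom(iv.chrom), iv.start, iv.end,
                    iv.name, iv.score, iv.strand,
                )
                for iv in self._intervals
            ),
            name=self.name,
        )

    # -- queries -------------------------------------------------------------
    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        idx = self._index.get(chrom)
        if idx is None:
            return False
        starts, _ends, maxends = idx
        k = int(np.searchsorted(starts, end, side="left"))
        if k == 0:
            return False
        return bool(maxends[k - 1] > start)

    def distance(self, chrom: str, start: int, end: int) -> float:
        """Gap in bases to the nearest same-chromosome interval.

        0 when overlapping or abutting; NaN when the chromosome is absent
        from the track ("undefined").
        """
        idx = self._index.get(chrom)
        if idx is None:
            return math.nan
        starts, _ends, maxends = idx
        k = int(np.searchsorted(starts, end, side="left"))
        if k > 0 and maxends[k - 1] > start:
            return 0.0
        best = math.inf
        if k > 0:  # nearest interval ending at or left of `start`
            best = min(best, start - int(maxends[k - 1]))
        j = int(np.searchsorted(starts, end, side="left"))
        if j < len(starts):  # nearest interval starting at or right of `end`
            best = min(best, int(starts[j]) - end)
        return float(max(best, 0.0))


def point_interval(chrom: str, pos_1based: int, **kw) -> GenomicInterval:
    """A 1-based point coordinate as the half-open interval ``[pos-1, pos)``."""
    return GenomicInterval(chrom, pos_1based - 1, pos_1based, **kw)


def overlaps_any(
    queries: Sequence[GenomicInterval] | Iterable[GenomicInterval],
    track: AnnotationTrack,
) -> np.ndarray:
    """Boolean flag per query: shares >= 1 base with some track interval."""
    return np.array(
        [track.overlaps(q.chrom, q.start, q.end) for q in queries], dtype=bool
    )


def nearest_distance(
    queries: Sequence[GenomicInterval] | Iterable[GenomicInterval],
    track: AnnotationTrack,
) -> np.ndarray:
    """Distance in bases to the nearest same-chromosome track interval.

    0 for overlapping queries; NaN for queries on chromosomes absent from
    the track (callers exclude these from medians).  An entirely empty
    track is an error.
    """
    if len(track) == 0:
        raise ValueError("nearest_distance requires a non-empty track")
    return np.array(
        [track.distance(q.chrom, q.start, q.end) for q in queries], dtype=float
    )


def read_bed(path: str | Path, name: str | None = None) -> AnnotationTrack:
    """Read BED3/BED6 into an :class:`AnnotationTrack`.

    Comment (``#``), ``track`` and ``browser`` header lines are skipped.
    Coordinates are preserved verbatim (0-based half-open).  Malformed rows
    raise :class:`BedParseError` naming the offending line.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{fields[1]!r}/{fields[2]!r}"
                ) from exc
            iv_name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(
                        f"{path}:{lineno}: non-numeric score {fields[4]!r}"
                    ) from exc
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-", ".") else None
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, iv_name, score, strand)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return AnnotationTrack(intervals, name=name if name is not None else path.stem)


def write_bed(track: AnnotationTrack, path: str | Path) -> None:
    """Write a track as BED; emits 6 columns when any interval carries
    name/score/strand, else plain BED3."""
    path = Path(path)
    six = any(
        iv.name is not None or iv.score is not None or iv.strand is not None
        for iv in track
    )
    with path.open("w") as fh:
        for iv in track:
            if six:
                score = "." if iv.score is None else format(iv.score, "g")
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                    f"{iv.name or '.'}\t{score}\t{iv.strand or '.'}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
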