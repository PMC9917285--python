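"""Core genomic data types and readers/writers shared by all pipeline stages.

Coordinate convention: everything in memory is 0-based, half-open (the BED
convention). Formats that use other conventions are converted at the
boundary.

The canonical on-disk track dialect is bedGraph (text-exact, diffable);
bigWig is supported as an optional encoder over the same runs when pyBigWig
is importable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

VALID_STRANDS = {"+", "-", "."}


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


class ValidationError(ValueError):
    """Raised when parsed data violates a domain invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic region.

    Attributes
    ----------
    chrom : chromosome name.
    start : 0-based inclusive start.
    end : 0-based exclusive end; must be > start.
    strand : one of ``+``, ``-``, ``.``.
    score : optional numeric score (BED column 5).
    name : optional feature name (BED column 4).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: Optional[float] = None
    name: Optional[str] = None

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class ChromSizes(dict):
    """Mapping of chromosome name -> length in bp. Lengths must be positive."""

    def __setitem__(self, key: str, value: int):
        value = int(value)
        if value <= 0:
            raise ValidationError(f"chromosome {key} has non-positive length {value}")
        super().__setitem__(key, value)

    @classmethod
    def from_dict(cls, d: Dict[str, int]) -> "ChromSizes":
        cs = cls()
        for k, v in d.items():
            cs[k] = v
        return cs


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval`, sorted by (chrom, start).

    Backed per chromosome by numpy start/end arrays so overlap queries and
    coverage computations are vectorized.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        self._intervals: List[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __getitem__(self, i):
        return self._intervals[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self._intervals == other._intervals

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)})"

    def chroms(self) -> List[str]:
        return sorted({iv.chrom for iv in self._intervals})

    def for_chrom(self, chrom: str) -> "IntervalSet":
        return IntervalSet(iv for iv in self._intervals if iv.chrom == chrom)

    def arrays(self, chrom: str):
        """(starts, ends) int64 arrays of this set's intervals on `chrom`."""
        ivs = [iv for iv in self._intervals if iv.chrom == chrom]
        starts = np.array([iv.start for iv in ivs], dtype=np.int64)
        ends = np.array([iv.end for iv in ivs], dtype=np.int64)
        return starts, ends

    def merged_arrays(self, chrom: str):
        """(starts, ends) of the union of this set's intervals on `chrom`."""
        starts, ends = self.arrays(chrom)
        if len(starts) == 0:
            return starts, ends
        m_starts, m_ends = [], []
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                m_starts.append(cur_s)
                m_ends.append(cur_e)
                cur_s, cur_e = s, e
        m_starts.append(cur_s)
        m_ends.append(cur_e)
        return np.array(m_starts, dtype=np.int64), np.array(m_ends, dtype=np.int64)

    def overlaps_point(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Boolean mask: does the 0-width point fall inside any interval?"""
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        starts, ends = self.merged_arrays(chrom)
        if len(starts) == 0:
            return np.zeros(len(pos), dtype=bool)
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = idx >= 0
        inside[inside] &= pos[inside] < ends[idx[inside]]
        return inside

    def overlap_bp(self, chrom: str, q_start: np.ndarray, q_end: np.ndarray) -> np.ndarray:
        """Per query interval, total bp of overlap with the union of this set."""
        q_start = np.asarray(q_start, dtype=np.int64)
        q_end = np.asarray(q_end, dtype=np.int64)
        starts, ends = self.merged_arrays(chrom)
        out = np.zeros(len(q_start), dtype=np.int64)
        if len(starts) == 0:
            return out
        # cumulative covered bp before each merged interval start
        lens = ends - starts
        cum = np.concatenate([[0], np.cumsum(lens)])

        def covered_before(p):
            """Total covered bp in [0, p)."""
            i = np.searchsorted(starts, p, side="right") - 1
            base = np.where(i >= 0, cum[np.maximum(i, 0)], 0)
            partial = np.where(
                i >= 0,
                np.clip(p - starts[np.maximum(i, 0)], 0, lens[np.maximum(i, 0)]),
                0,
            )
            return base + partial

        return covered_before(q_end) - covered_before(q_start)

    def subtract_overlapping(self, other: "IntervalSet") -> "IntervalSet":
        """Remove every interval that overlaps `other` by >= 1 bp."""
        kept = []
        for iv in self._intervals:
            ov = other.overlap_bp(iv.chrom, [iv.start], [iv.end])[0]
            if ov == 0:
                kept.append(iv)
        return IntervalSet(kept)


@dataclass
class SignalTrack:
    """Dense per-base signal over named chromosomes.

    `values` maps chromosome name to a float vector with one entry per bp.
    `normalization` records the processing state: ``raw`` (counts),
    ``rp20m`` (depth-scaled), or ``minmax`` (robust min-max to [0, 1]).
    """

    values: Dict[str, np.ndarray]
    normalization: str = "raw"

    def __post_init__(self):
        for chrom, v in self.values.items():
            v = np.asarray(v, dtype=np.float64)
            if v.ndim != 1:
                raise ValidationError(f"track for {chrom} is not 1-D")
            if np.any(v < 0):
                raise ValidationError(f"track for {chrom} has negative values")
            self.values[chrom] = v
        if self.normalization == "minmax":
            for chrom, v in self.values.items():
                if v.size and v.max() > 1.0 + 1e-9:
                    raise ValidationError(
                        f"minmax track for {chrom} has values > 1"
                    )

    def chroms(self) -> List[str]:
        return sorted(self.values)

    def chrom_sizes(self) -> ChromSizes:
        return ChromSizes.from_dict({c: len(v) for c, v in self.values.items()})

    def copy(self) -> "SignalTrack":
        return SignalTrack(
            {c: v.copy() for c, v in self.values.items()}, self.normalization
        )


@dataclass(frozen=True)
class Fragment:
    """One sequencing fragment from a fragments TSV (10x dialect).

    Ends are already Tn5-corrected in this dialect; `count` is the number of
    duplicate fragments observed for the barcode.
    """

    chrom: str
    start: int
    end: int
    barcode: str
    count: int = 1

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(
                f"fragment {self.chrom}:{self.start}-{self.end} has start >= end"
            )
        if self.count < 1:
            raise ValidationError(f"fragment count must be positive, got {self.count}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> ChromSizes:
    """Read a two-column ``name\\tlength`` chrom.sizes file."""
    cs = ChromSizes()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected name<TAB>length")
            try:
                cs[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad length {parts[1]!r}") from exc
    return cs


def write_chrom_sizes(chrom_sizes: ChromSizes, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(chrom_sizes):
            fh.write(f"{chrom}\t{chrom_sizes[chrom]}\n")


def read_bed(path, chrom_sizes: Optional[ChromSizes] = None) -> IntervalSet:
    """Parse a 3+ column BED file into a sorted :class:`IntervalSet`.

    Columns 4-6 (name, score, strand) are kept when present. Malformed lines
    raise :class:`ParseError` naming the line number; start >= end raises
    :class:`ValidationError`.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = None
            if len(parts) > 4 and parts[4] not in (".", ""):
                score = float(parts[4])
            strand = parts[5] if len(parts) > 5 and parts[5] in VALID_STRANDS else "."
            try:
                iv = GenomicInterval(parts[0], start, end, strand, score, name)
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            if chrom_sizes is not None and iv.chrom in chrom_sizes:
                if iv.end > chrom_sizes[iv.chrom]:
                    raise ValidationError(
                        f"{path}:{lineno}: interval exceeds length of {iv.chrom}"
                    )
            intervals.append(iv)
    return IntervalSet(intervals)


def write_bed(intervals: IntervalSet, path) -> None:
    """Write intervals as BED; emits 6 columns when name/score/strand set."""
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                cols += [
                    iv.name if iv.name is not None else ".",
                    format(iv.score, "g") if iv.score is not None else ".",
                    iv.strand,
                ]
            fh.write("\t".join(cols) + "\n")


def read_fragments(path, chrom_sizes: Optional[ChromSizes] = None) -> List[Fragment]:
    """Read a 5-column fragments TSV (chrom, start, end, barcode, count).

    Header lines starting with ``#`` are ignored. When `chrom_sizes` is
    supplied, fragments on unknown chromosomes are dropped (the count of
    dropped records is logged).
    """
    fragments: List[Fragment] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ParseError(f"{path}:{lineno}: expected 5 columns")
            try:
                start, end, count = int(parts[1]), int(parts[2]), int(parts[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field") from exc
            if chrom_sizes is not None and parts[0] not in chrom_sizes:
                dropped += 1
                continue
            fragments.append(Fragment(parts[0], start, end, parts[3], count))
    if dropped:
        logger.info("read_fragments: dropped %d fragments on unknown chromosomes", dropped)
    return fragments


def write_fragments(fragments: Sequence[Fragment], path) -> None:
    with open(path, "w") as fh:
        for fr in fragments:
            fh.write(f"{fr.chrom}\t{fr.start}\t{fr.end}\t{fr.barcode}\t{fr.count}\n")


def _track_runs(v: np.ndarray):
    """Yield (start, end, value) runs of constant nonzero value."""
    if v.size == 0:
        return
    change = np.flatnonzero(np.diff(v) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [v.size]])
    for s, e in zip(starts, ends):
        if v[s] != 0:
            yield int(s), int(e), float(v[s])


def write_track(track: SignalTrack, path, format: str = "bedGraph") -> None:
    """Write a :class:`SignalTrack` as bedGraph (default) or bigWig.

    Zero runs are omitted, following bedGraph sparse convention.
    """
    if format == "bedGraph":
        with open(path, "w") as fh:
            for chrom in track.chroms():
                for s, e, val in _track_runs(track.values[chrom]):
                    fh.write(f"{chrom}\t{s}\t{e}\t{val:.10g}\n")
    elif format == "bigWig":
        import pyBigWig

        bw = pyBigWig.open(str(path), "w")
        sizes = [(c, len(track.values[c])) for c in track.chroms()]
        bw.addHeader(sizes)
        for chrom in track.chroms():
            runs = list(_track_runs(track.values[chrom]))
            if runs:
                bw.addEntries(
                    [chrom] * len(runs),
                    [s for s, _, _ in runs],
                    ends=[e for _, e, _ in runs],
                    values=[v for _, _, v in runs],
                )
        bw.close()
    else:
        raise ValueError(f"unknown track format {format!r}")


def read_track(
    path,
    chrom_sizes: ChromSizes,
    format: str = "bedGraph",
    normalization: str = "raw",
) -> SignalTrack:
    """Read a bedGraph or bigWig file into a dense :class:`SignalTrack`.

    Overlapping bedGraph intervals and intervals exceeding the chromosome
    length are errors.
    """
    values = {c: np.zeros(chrom_sizes[c], dtype=np.float64) for c in chrom_sizes}
    if format == "bedGraph":
        covered = {c: np.zeros(chrom_sizes[c], dtype=bool) for c in chrom_sizes}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
                chrom, start, end, val = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
                if chrom not in chrom_sizes:
                    raise ValidationError(f"{path}:{lineno}: unknown chromosome {chrom}")
                if end > chrom_sizes[chrom]:
                    raise ValidationError(
                        f"{path}:{lineno}: interval exceeds length of {chrom}"
                    )
                if covered[chrom][start:end].any():
                    raise ValidationError(f"{path}:{lineno}: overlapping bedGraph intervals")
                covered[chrom][start:end] = True
                values[chrom][start:end] = val
    elif format == "bigWig":
        import pyBigWig

        bw = pyBigWig.open(str(path))
        for chrom in chrom_sizes:
            if chrom in bw.chroms():
                v = np.nan_to_num(
                    np.asarray(bw.values(chrom, 0, chrom_sizes[chrom]), dtype=np.float64)
                )
                values[chrom] = v
        bw.close()
    else:
        raise ValueError(f"unknown track format {format!r}")
    return SignalTrack(values, normalization)


def read_fasta(path) -> Dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


_ONE_HOT = {
    "A": np.array([1, 0, 0, 0], dtype=np.float32),
    "C": np.array([0, 1, 0, 0], dtype=np.float32),
    "G": np.array([0, 0, 1, 0], dtype=np.float32),
    "T": np.array([0, 0, 0, 1], dtype=np.float32),
}


def one_hot_encode(seq: str) -> np.ndarray:
    """One-hot encode a DNA string as a (4, L) array; non-ACGT rows are zero."""
    out = np.zeros((4, len(seq)), dtype=np.float32)
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    for i, base in enumerate(b"ACGT"):
        out[i, arr == base] = 1.0
    return out
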