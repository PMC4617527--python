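"""Per-library position x event read-count matrices.

Each pooled-plaque library (one animal, one PCR replicate) is reduced to a
matrix of read counts per 1-based reference position and *event*: a base
substitution, an insertion anchored to the position immediately preceding the
inserted bases, or a deletion anchored at its first deleted base.  Indels are
left-aligned against the reference so that identical events in different
libraries share a key.  Strand is collapsed throughout -- the reporter is a
fixed-orientation transgene.

Counts arrive either from samtools pileup text (the thin parser here) or from
the package's own count-TSV dialect, which round-trips bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

logger = logging.getLogger(__name__)

COUNT_TSV_MAGIC = "# plaquecall-counts v1"


class PileupParseError(ValueError):
    pass


class CountTableError(ValueError):
    pass


class EventKey(NamedTuple):
    """A mutation event: (1-based position, kind, detail).

    detail is the alternate base for ``sub``, the inserted sequence for
    ``ins`` and the deleted length in bp (int) for ``del``.
    """

    position: int
    kind: str  # "sub" | "ins" | "del"
    detail: object

    def describe(self) -> str:
        return f"{self.kind}@{self.position}:{self.detail}"


def is_indel(event: EventKey) -> bool:
    return event.kind in ("ins", "del")


@dataclass
class PositionCountMatrix:
    """Read depth and event counts for one library over positions 1..length."""

    library_id: str
    length: int
    depth: np.ndarray = None
    counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.depth is None:
            self.depth = np.zeros(self.length, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.shape != (self.length,):
            raise ValueError("depth array length does not match gene length")
        if (self.depth < 0).any():
            raise ValueError("negative depth")

    def depth_at(self, position: int) -> int:
        return int(self.depth[position - 1])

    def add(self, event: EventKey, n: int = 1) -> None:
        if n < 0:
            raise ValueError("negative count")
        if not 1 <= event.position <= self.length:
            raise ValueError(f"event position {event.position} outside 1..{self.length}")
        self.counts[event] = self.counts.get(event, 0) + n

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PositionCountMatrix)
            and self.library_id == other.library_id
            and self.length == other.length
            and np.array_equal(self.depth, other.depth)
            and {k: v for k, v in self.counts.items() if v}
            == {k: v for k, v in other.counts.items() if v}
        )


@dataclass
class ProportionMatrix:
    """Per-event read proportions (count/depth) with depth carried through.

    Zero-depth positions keep proportion 0 and are flagged in
    ``zero_depth`` so noise medians stay positionally aligned.
    """

    library_id: str
    length: int
    depth: np.ndarray
    props: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)

    @property
    def zero_depth(self) -> np.ndarray:
        return self.depth == 0

    def get(self, event: EventKey) -> float:
        return self.props.get(event, 0.0)


def to_proportions(matrix: PositionCountMatrix) -> ProportionMatrix:
    """Elementwise count/depth; zero-depth positions yield proportion 0."""
    props = {}
    for event, count in matrix.counts.items():
        depth = matrix.depth[event.position - 1]
        props[event] = count / depth if depth > 0 else 0.0
    return ProportionMatrix(
        library_id=matrix.library_id, length=matrix.length, depth=matrix.depth, props=props
    )


# --- indel normalization -------------------------------------------------

def left_align_insertion(sequence: str, anchor: int, inserted: str) -> tuple[int, str]:
    """Left-align an insertion (anchored after 1-based position ``anchor``).

    Standard rotation: while the base at the anchor equals the last inserted
    base, rotate the inserted sequence right and move the anchor left.
    ``anchor`` 0 means an insertion before the first base.
    """
    inserted = inserted.upper()
    while anchor >= 1 and sequence[anchor - 1] == inserted[-1]:
        inserted = inserted[-1] + inserted[:-1]
        anchor -= 1
    return anchor, inserted


def left_align_deletion(sequence: str, start: int, length: int) -> int:
    """Left-align a deletion of ``length`` bp whose first deleted base is ``start``."""
    while start > 1 and sequence[start - 2] == sequence[start + length - 2]:
        start -= 1
    return start


# --- samtools pileup text ------------------------------------------------

def read_pileup(path, gene, min_depth: int = 0) -> PositionCountMatrix:
    """Parse 6-column samtools pileup text into a count matrix.

    Read-base syntax handled: ``.``/``,`` reference match, ``ACGTacgt``
    substitutions (case merged), ``+n<seq>`` insertions, ``-n<seq>``
    deletions (anchored and left-aligned), ``*`` deleted-base placeholder,
    ``^q`` read start (mapping-quality byte skipped) and ``$`` read end.
    Positions with depth below ``min_depth`` are zeroed and flagged.
    """
    seq = gene.sequence
    matrix = PositionCountMatrix(library_id=str(path), length=len(seq))
    n_lines = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                fields = line.split()
            if len(fields) < 5:
                raise PileupParseError(f"line {lineno}: expected >=5 columns")
            chrom, pos_s, ref_base, depth_s, bases = fields[:5]
            if chrom != gene.name:
                raise PileupParseError(
                    f"line {lineno}: chromosome {chrom!r} does not match gene {gene.name!r}"
                )
            try:
                position = int(pos_s)
                depth = int(depth_s)
            except ValueError as exc:
                raise PileupParseError(f"line {lineno}: bad position/depth") from exc
            if not 1 <= position <= len(seq):
                raise PileupParseError(f"line {lineno}: position {position} outside 1..{len(seq)}")
            matrix.depth[position - 1] = depth
            _parse_base_column(matrix, seq, position, bases, lineno)
            n_lines += 1
    if n_lines == 0:
        logger.warning("pileup file %s is empty; all-zero matrix returned", path)
    if min_depth > 0:
        low = matrix.depth < min_depth
        if low.any():
            matrix.depth[low] = 0
            matrix.counts = {
                event: n for event, n in matrix.counts.items() if not low[event.position - 1]
            }
    return matrix


def _parse_base_column(matrix, seq, position, bases, lineno) -> None:
    i = 0
    n = len(bases)
    while i < n:
        ch = bases[i]
        if ch == "^":
            i += 2  # read start + mapping quality byte
            continue
        if ch in "$.,*><":
            i += 1
            continue
        if ch in "ACGTNacgtn":
            alt = ch.upper()
            if alt != "N" and alt != seq[position - 1]:
                matrix.add(EventKey(position, "sub", alt))
            i += 1
            continue
        if ch in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupParseError(f"line {lineno}: indel without length at column {i}")
            length = int(bases[i + 1 : j])
            inserted = bases[j : j + length].upper()
            if len(inserted) != length:
                raise PileupParseError(f"line {lineno}: truncated indel sequence")
            if ch == "+":
                anchor, norm = left_align_insertion(seq, position, inserted)
                matrix.add(EventKey(max(anchor, 1), "ins", norm))
            else:
                start = left_align_deletion(seq, position + 1, length)
                matrix.add(EventKey(start, "del", length))
            i = j + length
            continue
        raise PileupParseError(f"line {lineno}: unexpected pileup character {ch!r}")


# --- count TSV dialect ---------------------------------------------------

def write_count_tsv(matrix: PositionCountMatrix, path) -> None:
    """Write the internal count dialect (versioned header; '.' rows carry depth)."""
    by_position: dict[int, list[tuple[EventKey, int]]] = {}
    for event, count in sorted(matrix.counts.items(), key=lambda kv: (kv[0].position, kv[0].kind, str(kv[0].detail))):
        by_position.setdefault(event.position, []).append((event, count))
    with open(path, "w") as handle:
        handle.write(f"{COUNT_TSV_MAGIC}\tlibrary={matrix.library_id}\tlength={matrix.length}\n")
        handle.write("position\tdepth\tevent_kind\tdetail\tcount\n")
        for position in range(1, matrix.length + 1):
            depth = matrix.depth[position - 1]
            events = by_position.get(position, [])
            if not events:
                handle.write(f"{position}\t{depth}\t.\t.\t0\n")
            for event, count in events:
                handle.write(f"{position}\t{depth}\t{event.kind}\t{event.detail}\t{count}\n")


def read_count_tsv(path) -> PositionCountMatrix:
    """Read the internal count dialect written by :func:`write_count_tsv`."""
    with open(path) as handle:
        header = handle.readline().rstrip("\n")
        if not header.startswith(COUNT_TSV_MAGIC):
            raise CountTableError(f"{path}: missing count-TSV magic header")
        meta = dict(item.split("=", 1) for item in header.split("\t")[1:])
        length = int(meta["length"])
        matrix = PositionCountMatrix(library_id=meta.get("library", str(path)), length=length)
        colnames = handle.readline().rstrip("\n").split("\t")
        if colnames != ["position", "depth", "event_kind", "detail", "count"]:
            raise CountTableError(f"{path}: unexpected column header {colnames}")
        seen: set[EventKey] = set()
        for lineno, line in enumerate(handle, start=3):
            line = line.rstrip("\n")
            if not line:
                continue
            pos_s, depth_s, kind, detail, count_s = line.split("\t")
            position, depth, count = int(pos_s), int(depth_s), int(count_s)
            if count < 0:
                raise CountTableError(f"{path} line {lineno}: negative count")
            if not 1 <= position <= length:
                raise CountTableError(f"{path} line {lineno}: position out of range")
            matrix.depth[position - 1] = depth
            if kind == ".":
                continue
            event = EventKey(position, kind, int(detail) if kind == "del" else detail)
            if event in seen:
                raise CountTableError(f"{path} line {lineno}: duplicate event {event.describe()}")
            seen.add(event)
            matrix.add(event, count)
    return matrix
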