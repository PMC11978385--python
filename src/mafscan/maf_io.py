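"""Reading of UCSC Multiple Alignment Format (MAF) files.

A MAF file is a sequence of alignment blocks.  Each block starts with an
``a`` line (optionally carrying ``key=value`` attributes such as ``score``)
followed by one ``s`` line per aligned sequence::

    a score=23.0
    s hg38.chr1   10 5 + 248956422 AC-GTT
    s mm39.chr19   3 6 + 61420004  ACAGTT

``s`` fields are: source name, strand-relative 0-based start, ungapped
size, strand, full source length, and the gapped alignment text.  ``i``,
``e`` and ``q`` annotation lines are tolerated and skipped.  Blocks are
independent units: downstream searches never cross a block boundary, which
is also what makes byte-range chunking for parallel workers safe.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from typing import IO, Iterator, List, Sequence, Tuple

logger = logging.getLogger(__name__)

GAP = "-"

__all__ = [
    "GAP",
    "AlignedSequence",
    "AlignmentBlock",
    "ChunkPlan",
    "MafParseError",
    "parse_maf",
    "parse_maf_path",
    "parse_maf_range",
    "chunk_maf",
    "write_maf",
]


class MafParseError(ValueError):
    """Raised for structurally invalid MAF content; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class AlignedSequence:
    """One ``s`` line of a MAF block.

    ``start`` and ``size`` follow the MAF convention: 0-based,
    strand-relative, with ``size`` counting non-gap characters only.
    """

    src: str
    start: int
    size: int
    strand: str
    src_size: int
    text: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} for {self.src}")
        ungapped = len(self.text) - self.text.count(GAP)
        if ungapped != self.size:
            raise ValueError(
                f"{self.src}: declared size {self.size} != {ungapped} non-gap characters"
            )
        if self.start < 0 or self.start + self.size > self.src_size:
            raise ValueError(
                f"{self.src}: start {self.start} + size {self.size} exceeds srcSize {self.src_size}"
            )

    @property
    def genome(self) -> str:
        """Genome identifier: the part of ``src`` before the first dot."""
        return self.src.split(".", 1)[0]

    @property
    def chromosome(self) -> str:
        """Sequence/chromosome name after the first dot; ``src`` if undotted."""
        parts = self.src.split(".", 1)
        return parts[1] if len(parts) == 2 else self.src


@dataclass(frozen=True)
class AlignmentBlock:
    """An alignment block; ``sequences[0]`` is the block's reference."""

    sequences: Tuple[AlignedSequence, ...]
    score: float | None = None
    file_offset: int = 0

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("alignment block must contain at least one sequence")
        width = len(self.sequences[0].text)
        for seq in self.sequences[1:]:
            if len(seq.text) != width:
                raise ValueError(
                    f"sequence {seq.src} has width {len(seq.text)}, expected {width}"
                )

    @property
    def reference(self) -> AlignedSequence:
        return self.sequences[0]

    @property
    def width(self) -> int:
        return len(self.sequences[0].text)


@dataclass(frozen=True)
class ChunkPlan:
    """Half-open byte ranges covering a MAF file, aligned to block starts."""

    ranges: Tuple[Tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        prev_end = None
        for start, end in self.ranges:
            if start >= end:
                raise ValueError(f"empty or inverted range ({start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValueError("chunk ranges overlap or are out of order")
            prev_end = end


def _is_block_start(line: str) -> bool:
    stripped = line.rstrip("\n")
    return stripped == "a" or line.startswith("a ") or line.startswith("a\t")


def _parse_s_line(line: str, line_number: int) -> AlignedSequence:
    fields = line.split()
    if len(fields) != 7:
        raise MafParseError(
            f"'s' line has {len(fields)} fields, expected 7", line_number
        )
    _, src, start_s, size_s, strand, src_size_s, text = fields
    try:
        start, size, src_size = int(start_s), int(size_s), int(src_size_s)
    except ValueError:
        raise MafParseError(
            f"non-integer coordinate field in 's' line: {line.rstrip()!r}",
            line_number,
        ) from None
    try:
        return AlignedSequence(
            src=src, start=start, size=size, strand=strand,
            src_size=src_size, text=text,
        )
    except ValueError as exc:
        raise MafParseError(str(exc), line_number) from None


def _parse_a_line(line: str, line_number: int) -> float | None:
    score = None
    for token in line.split()[1:]:
        if "=" not in token:
            raise MafParseError(f"malformed 'a' attribute {token!r}", line_number)
        key, value = token.split("=", 1)
        if key == "score":
            try:
                score = float(value)
            except ValueError:
                raise MafParseError(
                    f"non-numeric score {value!r}", line_number
                ) from None
    return score


def parse_maf(
    stream: IO[str],
    *,
    byte_offset: int = 0,
    first_line_number: int = 1,
) -> Iterator[AlignmentBlock]:
    """Parse a MAF text stream, yielding blocks in file order.

    Comment (``#``)/``track`` lines and ``i``/``e``/``q`` annotation lines
    are skipped; any number of blank lines may separate blocks.  An empty
    stream yields nothing.  ``byte_offset`` seeds ``file_offset`` tracking
    when the stream is a slice of a larger file.
    """
    pos = byte_offset
    block_score: float | None = None
    block_offset = 0
    block_line = 0
    sequences: List[AlignedSequence] = []
    in_block = False

    def flush() -> AlignmentBlock | None:
        nonlocal in_block, sequences, block_score
        if not in_block:
            return None
        in_block = False
        if not sequences:
            logger.debug("block at offset %d has no 's' lines; skipped", block_offset)
            sequences = []
            return None
        try:
            block = AlignmentBlock(
                sequences=tuple(sequences), score=block_score,
                file_offset=block_offset,
            )
        except ValueError as exc:
            raise MafParseError(str(exc), block_line) from None
        sequences = []
        return block

    for line_number, line in enumerate(stream, start=first_line_number):
        line_start = pos
        pos += len(line)
        stripped = line.strip()
        if not stripped:
            block = flush()
            if block is not None:
                yield block
            continue
        if stripped.startswith("#") or stripped.startswith("track"):
            continue
        tag = stripped.split(None, 1)[0]
        if tag == "a":
            block = flush()
            if block is not None:
                yield block
            block_score = _parse_a_line(stripped, line_number)
            block_offset = line_start
            block_line = line_number
            in_block = True
        elif tag == "s":
            if not in_block:
                raise MafParseError("'s' line outside of a block", line_number)
            sequences.append(_parse_s_line(stripped, line_number))
        elif tag in ("i", "e", "q"):
            logger.debug("skipping %r annotation line %d", tag, line_number)
        else:
            raise MafParseError(f"unrecognized line type {tag!r}", line_number)
    block = flush()
    if block is not None:
        yield block


def parse_maf_path(path: str | os.PathLike) -> Iterator[AlignmentBlock]:
    """Parse a whole MAF file from disk."""
    with open(path, "r", encoding="utf-8") as handle:
        yield from parse_maf(handle)


def parse_maf_range(path: str | os.PathLike, start: int, end: int) -> List[AlignmentBlock]:
    """Parse the blocks contained in byte range ``[start, end)`` of a file.

    The range must be block-aligned (as produced by :func:`chunk_maf`).
    Line numbers in error messages are relative to the range start.
    """
    with open(path, "rb") as handle:
        handle.seek(start)
        data = handle.read(end - start)
    text = data.decode("utf-8")
    return list(parse_maf(io.StringIO(text), byte_offset=start))


def chunk_maf(path: str | os.PathLike, n_chunks: int) -> ChunkPlan:
    """Split a MAF file into at most ``n_chunks`` block-aligned byte ranges.

    Naive byte boundaries at ``i * size / n`` are advanced to the start of
    the next ``a`` line, so every block falls in exactly one range and the
    per-range parses concatenate to the whole-file parse.
    """
    if n_chunks < 1:
        raise ValueError("n_chunks must be >= 1")
    file_size = os.path.getsize(path)
    if file_size == 0:
        return ChunkPlan(ranges=())

    boundaries = [0]
    with open(path, "rb") as handle:
        for i in range(1, n_chunks):
            naive = file_size * i // n_chunks
            handle.seek(naive)
            if naive > 0:
                handle.readline()  # drop the partial line
            boundary = None
            while True:
                line_start = handle.tell()
                line = handle.readline()
                if not line:
                    break
                token = line.split(None, 1)[0] if line.strip() else b""
                if token == b"a":
                    boundary = line_start
                    break
            if boundary is not None and boundary > boundaries[-1]:
                boundaries.append(boundary)
    boundaries.append(file_size)
    ranges = tuple(
        (lo, hi) for lo, hi in zip(boundaries[:-1], boundaries[1:]) if lo < hi
    )
    return ChunkPlan(ranges=ranges)


def write_maf(blocks: Sequence[AlignmentBlock], stream: IO[str]) -> None:
    """Serialize blocks back to MAF text (used by the synthetic generator)."""
    stream.write("##maf version=1\n")
    for block in blocks:
        if block.score is not None:
            stream.write(f"a score={block.score}\n")
        else:
            stream.write("a\n")
        src_w = max(len(s.src) for s in block.sequences)
        for seq in block.sequences:
            stream.write(
                f"s {seq.src:<{src_w}} {seq.start} {seq.size} {seq.strand} "
                f"{seq.src_size} {seq.text}\n"
            )
        stream.write("\n")
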