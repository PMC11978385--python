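"""Motif search within alignment blocks and coordinate mapping.

Searches run on the ungapped text of the searched sequence of each block.
Raw hits are then mapped back to gapped block columns (for conservation
scoring against the other aligned sequences) and to forward-strand
genomic coordinates (for BED output).

Matching is case-insensitive throughout — MAF files use lowercase for
soft-masked regions — while reported matched sequences preserve the
original case and are always given in forward-strand orientation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from ._ahocorasick import AhoCorasick
from .conservation import (
    ConservationRecord,
    block_conservation,
    conservation_percent,
    similarity_vector,
)
from .maf_io import GAP, AlignedSequence, AlignmentBlock
from .motif_models import (
    BASES,
    KmerSet,
    Pwm,
    RegexSet,
    empirical_p_value,
    reverse_complement,
    reverse_complement_pwm,
)
from .output_writers import MotifHit

logger = logging.getLogger(__name__)

MotifSource = Union[KmerSet, RegexSet, Sequence[Pwm]]

__all__ = [
    "GapIndex",
    "RawHit",
    "SearchOptions",
    "build_gap_index",
    "map_to_gapped",
    "find_kmer_hits",
    "find_pwm_hits",
    "find_regex_hits",
    "search_block",
    "to_genomic",
]


@dataclass(frozen=True)
class GapIndex:
    """Ungapped projection of a gapped text plus index map back to columns."""

    gapped: str
    ungapped: str
    u2g: Tuple[int, ...]


@dataclass(frozen=True)
class RawHit:
    """A motif occurrence on the ungapped searched text, pre-mapping."""

    motif_id: str
    motif_kind: str
    u_start: int
    u_end: int
    strand_of_match: str
    matched_sequence: str
    score: Optional[float] = None
    p_value: Optional[float] = None


@dataclass(frozen=True)
class SearchOptions:
    """Per-run search behaviour shared by all blocks."""

    search_src: str = "reference"
    rc: bool = False
    genome_ids: Optional[Tuple[str, ...]] = None


def build_gap_index(text: str) -> GapIndex:
    u2g = tuple(i for i, c in enumerate(text) if c != GAP)
    ungapped = "".join(c for c in text if c != GAP)
    return GapIndex(gapped=text, ungapped=ungapped, u2g=u2g)


def map_to_gapped(index: GapIndex, u_start: int, u_end: int) -> Tuple[int, int]:
    """Map an ungapped half-open span to gapped block columns."""
    if not (0 <= u_start < u_end <= len(index.ungapped)):
        raise ValueError(
            f"span [{u_start}, {u_end}) out of range for ungapped length "
            f"{len(index.ungapped)}"
        )
    return index.u2g[u_start], index.u2g[u_end - 1] + 1


def _sorted_hits(hits: List[RawHit]) -> List[RawHit]:
    return sorted(hits, key=lambda h: (h.u_start, h.motif_id, h.strand_of_match, h.u_end))


def find_kmer_hits(kmers: KmerSet, seq: str, rc: bool = False) -> List[RawHit]:
    """All occurrences of all k-mers (overlaps included) via Aho–Corasick.

    With ``rc`` the reverse complement of each k-mer is also matched and
    reported with strand "-"; matched sequences stay in forward
    orientation with original case.
    """
    patterns: List[Tuple[str, Tuple[str, str]]] = []
    for kid, kseq in kmers.kmers:
        patterns.append((kseq.upper(), (kid, "+")))
        if rc:
            patterns.append((reverse_complement(kseq).upper(), (kid, "-")))
    automaton = AhoCorasick(patterns)
    hits = [
        RawHit(
            motif_id=kid,
            motif_kind="kmer",
            u_start=start,
            u_end=end,
            strand_of_match=strand,
            matched_sequence=seq[start:end],
        )
        for start, end, (kid, strand) in automaton.iter_matches(seq.upper())
    ]
    return _sorted_hits(hits)


_BASE_LOOKUP = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _BASE_LOOKUP[ord(_b)] = _i
    _BASE_LOOKUP[ord(_b.lower())] = _i


def _window_scores(log_odds: np.ndarray, seq: str) -> Tuple[np.ndarray, np.ndarray]:
    """Scores and validity of every length-L window; invalid windows contain
    characters outside {A,C,G,T}."""
    L = log_odds.shape[1]
    idx = _BASE_LOOKUP[np.frombuffer(seq.encode("latin-1"), dtype=np.uint8)]
    n = len(seq) - L + 1
    if n <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    cols = np.arange(L)
    safe = np.clip(idx, 0, 3)
    for j in range(L):
        window_col = idx[j : j + n]
        valid &= window_col >= 0
        scores += log_odds[safe[j : j + n], cols[j]]
    return scores, valid


def find_pwm_hits(pwm: Pwm, seq: str, rc: bool = False) -> List[RawHit]:
    """Windows scoring at or above the calibrated threshold.

    Each hit carries its log-odds score and add-one empirical p-value from
    the PWM's null sample.  Windows containing non-ACGT characters are
    skipped.  With ``rc`` the reverse-complement matrix is also scanned.
    """
    if pwm.threshold is None or pwm.null_scores is None:
        raise ValueError(f"PWM {pwm.name!r} is not calibrated")
    matrices = [(pwm.log_odds, "+")]
    if rc:
        matrices.append((reverse_complement_pwm(pwm).log_odds, "-"))
    hits: List[RawHit] = []
    for log_odds, strand in matrices:
        scores, valid = _window_scores(log_odds, seq)
        for start in np.flatnonzero(valid & (scores >= pwm.threshold)):
            start = int(start)
            end = start + pwm.length
            score = float(scores[start])
            hits.append(
                RawHit(
                    motif_id=pwm.name,
                    motif_kind="pwm",
                    u_start=start,
                    u_end=end,
                    strand_of_match=strand,
                    matched_sequence=seq[start:end],
                    score=score,
                    p_value=empirical_p_value(score, pwm.null_scores),
                )
            )
    return _sorted_hits(hits)


def find_regex_hits(patterns: RegexSet, seq: str, rc: bool = False) -> List[RawHit]:
    """Leftmost non-overlapping matches per pattern (scan-and-resume).

    Different patterns are independent and may overlap each other.
    Zero-length matches are discarded.  With ``rc`` the reverse complement
    of the sequence is also scanned and spans mapped back to forward
    coordinates with strand "-".
    """
    hits: List[RawHit] = []
    n = len(seq)
    targets = [(seq, "+")]
    if rc:
        targets.append((reverse_complement(seq), "-"))
    for pid, pattern in patterns.patterns:
        compiled = re.compile(pattern, re.IGNORECASE)
        for text, strand in targets:
            for match in compiled.finditer(text):
                if match.start() == match.end():
                    continue
                if strand == "+":
                    u_start, u_end = match.start(), match.end()
                else:
                    u_start, u_end = n - match.end(), n - match.start()
                hits.append(
                    RawHit(
                        motif_id=pid,
                        motif_kind="regex",
                        u_start=u_start,
                        u_end=u_end,
                        strand_of_match=strand,
                        matched_sequence=seq[u_start:u_end],
                    )
                )
    return _sorted_hits(hits)


def to_genomic(
    aseq: AlignedSequence, u_start: int, u_end: int
) -> Tuple[str, int, int]:
    """Convert an ungapped span to 0-based half-open forward-strand coordinates.

    MAF starts are strand-relative: on "-" the span is measured from the
    reverse-complemented source, so the forward interval is reflected
    through ``src_size``.
    """
    if not (0 <= u_start < u_end <= aseq.size):
        raise ValueError(f"span [{u_start}, {u_end}) outside sequence of size {aseq.size}")
    if aseq.strand == "+":
        fwd_start = aseq.start + u_start
    else:
        fwd_start = aseq.src_size - (aseq.start + u_end)
    return aseq.chromosome, fwd_start, fwd_start + (u_end - u_start)


def _select_searched(block: AlignmentBlock, search_src: str) -> Optional[int]:
    if search_src == "reference":
        return 0
    for i, seq in enumerate(block.sequences):
        if seq.src == search_src or seq.genome == search_src:
            return i
    return None


def _conservation_records(
    block: AlignmentBlock,
    searched_index: int,
    g_start: int,
    g_end: int,
    genome_ids: Optional[Tuple[str, ...]],
) -> Tuple[Tuple[ConservationRecord, ...], Optional[float]]:
    searched = block.sequences[searched_index]
    ref_slice = searched.text[g_start:g_end]
    records: List[ConservationRecord] = []
    for i, other in enumerate(block.sequences):
        if i == searched_index:
            continue
        if genome_ids is not None and other.genome not in genome_ids and other.src not in genome_ids:
            continue
        vector = similarity_vector(ref_slice, other.text[g_start:g_end], other.src)
        if len(vector) == 0:
            logger.warning(
                "hit span [%d, %d) vs %s is entirely both-gap; "
                "conservation undefined", g_start, g_end, other.src,
            )
            percent = None
        else:
            percent = conservation_percent(vector)
        records.append(
            ConservationRecord(compared_src=other.src, vector=vector, percent=percent)
        )
    return tuple(records), block_conservation(records)


def search_block(
    block: AlignmentBlock,
    motifs: MotifSource,
    options: SearchOptions = SearchOptions(),
    block_index: int = 0,
) -> List[MotifHit]:
    """Run the appropriate finder on one block and resolve full hits.

    Returns hits sorted by (gapped start, motif id); blocks lacking the
    requested search source yield an empty list (logged at debug level).
    """
    searched_index = _select_searched(block, options.search_src)
    if searched_index is None:
        logger.debug(
            "block %d lacks search source %r; skipped", block_index, options.search_src
        )
        return []
    searched = block.sequences[searched_index]
    index = build_gap_index(searched.text)

    if isinstance(motifs, KmerSet):
        raw_hits = find_kmer_hits(motifs, index.ungapped, rc=options.rc)
    elif isinstance(motifs, RegexSet):
        raw_hits = find_regex_hits(motifs, index.ungapped, rc=options.rc)
    else:
        raw_hits = []
        for pwm in motifs:
            raw_hits.extend(find_pwm_hits(pwm, index.ungapped, rc=options.rc))
        raw_hits = _sorted_hits(raw_hits)

    hits: List[MotifHit] = []
    for raw in raw_hits:
        g_start, g_end = map_to_gapped(index, raw.u_start, raw.u_end)
        chrom, fwd_start, fwd_end = to_genomic(searched, raw.u_start, raw.u_end)
        records, block_avg = _conservation_records(
            block, searched_index, g_start, g_end, options.genome_ids
        )
        hits.append(
            MotifHit(
                genome=searched.genome,
                chromosome=chrom,
                fwd_start=fwd_start,
                fwd_end=fwd_end,
                strand_of_match=raw.strand_of_match,
                motif_kind=raw.motif_kind,
                motif_id=raw.motif_id,
                matched_sequence=raw.matched_sequence,
                g_start=g_start,
                g_end=g_end,
                u_start=raw.u_start,
                u_end=raw.u_end,
                block_index=block_index,
                score=raw.score,
                p_value=raw.p_value,
                records=records,
                block_conservation=block_avg,
            )
        )
    hits.sort(key=lambda h: (h.g_start, h.motif_id, h.strand_of_match, h.g_end))
    return hits
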