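"""Per-hit conservation scoring between aligned gapped sequences.

For the gapped span of a motif hit, each alignment column of the searched
sequence is compared with the same column of another sequence in the block:

* both gaps                      -> column ignored
* searched gap vs. a character   -> "–"  (insertion relative to the hit)
* characters equal (case-insens) -> "1"
* anything else (incl. cmp gap)  -> "0"

The conservation percentage is 100 * #("1") / vector length, where "0" and
"–" both count in the denominator; the block-level value is the unweighted
mean over compared sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

GAP = "-"
REF_GAP_SYMBOL = "–"  # "–": searched-sequence gap aligned to a character

__all__ = [
    "REF_GAP_SYMBOL",
    "SimilarityVector",
    "ConservationRecord",
    "similarity_vector",
    "conservation_percent",
    "block_conservation",
]


@dataclass(frozen=True)
class SimilarityVector:
    """Comparison string over {"1", "0", "–"} for one compared sequence."""

    symbols: str
    compared_src: str = ""

    def __post_init__(self) -> None:
        allowed = {"1", "0", REF_GAP_SYMBOL}
        bad = set(self.symbols) - allowed
        if bad:
            raise ValueError(f"invalid similarity symbols {sorted(bad)!r}")

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class ConservationRecord:
    """Similarity vector plus its percentage for one compared sequence.

    ``percent`` is ``None`` when the hit span is entirely both-gap against
    this sequence (no comparable columns); such records are excluded from
    the block average.
    """

    compared_src: str
    vector: SimilarityVector
    percent: Optional[float]


def similarity_vector(
    ref_slice: str, cmp_slice: str, compared_src: str = ""
) -> SimilarityVector:
    """Apply the per-column comparison rules to two equal-length gapped slices."""
    if len(ref_slice) != len(cmp_slice):
        raise ValueError(
            f"slice lengths differ: {len(ref_slice)} vs {len(cmp_slice)}"
        )
    symbols = []
    for r, c in zip(ref_slice, cmp_slice):
        r_gap, c_gap = r == GAP, c == GAP
        if r_gap and c_gap:
            continue
        if r_gap:
            symbols.append(REF_GAP_SYMBOL)
        elif not c_gap and r.upper() == c.upper():
            symbols.append("1")
        else:
            symbols.append("0")
    return SimilarityVector(symbols="".join(symbols), compared_src=compared_src)


def conservation_percent(vector: SimilarityVector | str) -> float:
    """100 * count("1") / length; "0" and "–" count in the denominator."""
    symbols = vector.symbols if isinstance(vector, SimilarityVector) else vector
    if not symbols:
        raise ValueError("conservation percent undefined for an empty vector")
    return 100.0 * symbols.count("1") / len(symbols)


def block_conservation(records: Sequence[ConservationRecord]) -> Optional[float]:
    """Unweighted mean of the defined percentages; ``None`` if none defined."""
    defined = [r.percent for r in records if r.percent is not None]
    if not defined:
        return None
    return sum(defined) / len(defined)
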