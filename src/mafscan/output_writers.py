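"""Serialization of motif hits to BED (default), JSON, and CSV.

All three formats carry the same hit set; BED holds the compact
forward-strand intervals, while JSON and CSV additionally expose the
MAF-native gapped/ungapped block offsets, per-genome similarity vectors,
and (for PWM hits) score, p-value, and FDR.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import IO, Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .conservation import ConservationRecord

__all__ = ["MotifHit", "write_bed", "write_json", "write_csv", "summary_stats"]


@dataclass
class MotifHit:
    """One motif instance in one block, fully resolved.

    Coordinates: ``fwd_start``/``fwd_end`` are 0-based half-open on the
    forward strand of the searched source; ``u_start``/``u_end`` index the
    ungapped searched text of the block; ``g_start``/``g_end`` are gapped
    block columns.  ``score``/``p_value``/``fdr`` are PWM-only.
    """

    genome: str
    chromosome: str
    fwd_start: int
    fwd_end: int
    strand_of_match: str
    motif_kind: str  # kmer | pwm | regex
    motif_id: str
    matched_sequence: str
    g_start: int
    g_end: int
    u_start: int
    u_end: int
    block_index: int
    score: Optional[float] = None
    p_value: Optional[float] = None
    fdr: Optional[float] = None
    records: Tuple[ConservationRecord, ...] = field(default_factory=tuple)
    block_conservation: Optional[float] = None

    def __post_init__(self) -> None:
        if self.motif_kind not in ("kmer", "pwm", "regex"):
            raise ValueError(f"invalid motif_kind {self.motif_kind!r}")
        if self.strand_of_match not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand_of_match!r}")
        if self.u_end - self.u_start != self.fwd_end - self.fwd_start:
            raise ValueError("ungapped and forward spans disagree in length")

    @property
    def motif_length(self) -> int:
        return self.u_end - self.u_start

    @property
    def json_key(self) -> str:
        return (
            f"hit_{self.block_index}_{self.g_start}_{self.motif_id}_"
            f"{self.strand_of_match}"
        )


def _bed_score(hit: MotifHit) -> int:
    if hit.block_conservation is None:
        return 0
    return max(0, min(1000, round(hit.block_conservation)))


def write_bed(hits: Sequence[MotifHit], stream: IO[str]) -> None:
    """BED6: chrom, start, end, ``motif_id|kind|block``, conservation, strand."""
    ordered = sorted(hits, key=lambda h: (h.block_index, h.fwd_start, h.motif_id))
    for hit in ordered:
        name = f"{hit.motif_id}|{hit.motif_kind}|{hit.block_index}"
        stream.write(
            f"{hit.chromosome}\t{hit.fwd_start}\t{hit.fwd_end}\t{name}\t"
            f"{_bed_score(hit)}\t{hit.strand_of_match}\n"
        )


def _hit_payload(hit: MotifHit) -> dict:
    payload = {
        "genome": hit.genome,
        "chromosome": hit.chromosome,
        "fwd_start": hit.fwd_start,
        "fwd_end": hit.fwd_end,
        "strand": hit.strand_of_match,
        "motif_kind": hit.motif_kind,
        "motif_id": hit.motif_id,
        "motif_length": hit.motif_length,
        "matched_sequence": hit.matched_sequence,
        "g_start": hit.g_start,
        "g_end": hit.g_end,
        "u_start": hit.u_start,
        "u_end": hit.u_end,
        "block_index": hit.block_index,
        "conservation": {
            rec.compared_src: {
                "vector": rec.vector.symbols,
                "percent": rec.percent,
            }
            for rec in hit.records
        },
        "block_conservation": hit.block_conservation,
    }
    if hit.motif_kind == "pwm":
        payload["score"] = hit.score
        payload["p_value"] = hit.p_value
        payload["fdr"] = hit.fdr
    return payload


def write_json(
    hits: Sequence[MotifHit],
    stream: IO[str],
    metadata: Optional[dict] = None,
) -> None:
    """Top-level object: run ``metadata`` plus one entry per hit.

    Hit keys follow ``hit_<block>_<g_start>_<motif_id>_<strand>``; a
    numeric suffix disambiguates in the rare case of a collision.
    """
    hits_obj: Dict[str, dict] = {}
    for hit in hits:
        key = hit.json_key
        suffix = 2
        while key in hits_obj:
            key = f"{hit.json_key}_{suffix}"
            suffix += 1
        hits_obj[key] = _hit_payload(hit)
    document = {"metadata": metadata or {}, "hits": hits_obj}
    json.dump(document, stream, ensure_ascii=False, indent=2)
    stream.write("\n")


CSV_COLUMNS = [
    "genome",
    "chromosome",
    "fwd_start",
    "fwd_end",
    "strand",
    "motif_kind",
    "motif_id",
    "motif_length",
    "matched_sequence",
    "g_start",
    "g_end",
    "u_start",
    "u_end",
    "block_index",
    "score",
    "p_value",
    "fdr",
    "block_conservation",
    "compared_src",
    "similarity_vector",
    "conservation_percent",
]


def write_csv(hits: Sequence[MotifHit], stream: IO[str]) -> None:
    """One row per (hit, compared sequence); hits with no comparisons get
    one row with empty comparison columns."""
    writer = csv.writer(stream, lineterminator="\n")
    writer.writerow(CSV_COLUMNS)
    for hit in hits:
        base = [
            hit.genome,
            hit.chromosome,
            hit.fwd_start,
            hit.fwd_end,
            hit.strand_of_match,
            hit.motif_kind,
            hit.motif_id,
            hit.motif_length,
            hit.matched_sequence,
            hit.g_start,
            hit.g_end,
            hit.u_start,
            hit.u_end,
            hit.block_index,
            "" if hit.score is None else repr(hit.score),
            "" if hit.p_value is None else repr(hit.p_value),
            "" if hit.fdr is None else repr(hit.fdr),
            "" if hit.block_conservation is None else repr(hit.block_conservation),
        ]
        if hit.records:
            for rec in hit.records:
                writer.writerow(
                    base
                    + [
                        rec.compared_src,
                        rec.vector.symbols,
                        "" if rec.percent is None else repr(rec.percent),
                    ]
                )
        else:
            writer.writerow(base + ["", "", ""])


def summary_stats(hits: Sequence[MotifHit]) -> pd.DataFrame:
    """Per-motif hit counts and block-conservation summary.

    Means/min/max ignore hits with missing conservation; motifs with no
    hits are absent.
    """
    rows: List[dict] = []
    by_motif: Dict[str, List[MotifHit]] = {}
    for hit in hits:
        by_motif.setdefault(hit.motif_id, []).append(hit)
    for motif_id in sorted(by_motif):
        group = by_motif[motif_id]
        values = [h.block_conservation for h in group if h.block_conservation is not None]
        rows.append(
            {
                "motif_id": motif_id,
                "n_hits": len(group),
                "mean_block_conservation": sum(values) / len(values) if values else None,
                "min_block_conservation": min(values) if values else None,
                "max_block_conservation": max(values) if values else None,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "motif_id",
            "n_hits",
            "mean_block_conservation",
            "min_block_conservation",
            "max_block_conservation",
        ],
    )
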