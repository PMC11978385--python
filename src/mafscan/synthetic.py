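"""Synthetic MAF generation with motifs planted at known coordinates.

Blocks contain one searched ("ref") genome plus compared genomes derived
from it by an explicit per-plant edit plan (substitutions, compared-side
gaps, searched-side gap-column insertions).  Ground truth — coordinates,
similarity vectors, percentages — is derived directly from the edit plan
by independent bookkeeping, so end-to-end pipeline output can be checked
exactly without consulting the modules under test.

Background sequence is rejection-sampled so that no motif occurs anywhere
it was not planted.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .maf_io import AlignedSequence, AlignmentBlock, write_maf

__all__ = [
    "GenomeEdit",
    "PlantSpec",
    "GroundTruthHit",
    "generate_maf",
    "truth_table",
]

_BASES = "ACGT"
REF_GAP_SYMBOL = "–"


@dataclass(frozen=True)
class GenomeEdit:
    """Edits applied to one compared genome within one plant's motif span.

    Offsets are 0-based positions within the motif.  ``substitutions`` and
    ``cmp_gaps`` mark mismatch / deletion columns ("0" in the vector);
    ``ref_gap_insertions`` insert a gap column into the searched genome
    before the given offset with a character in this genome ("–"), and
    must lie strictly inside the motif (1..len-1) to fall within the
    hit's gapped span.
    """

    genome: str
    substitutions: Tuple[int, ...] = ()
    cmp_gaps: Tuple[int, ...] = ()
    ref_gap_insertions: Tuple[int, ...] = ()


@dataclass(frozen=True)
class PlantSpec:
    """One motif planted at a known ungapped position of one block."""

    motif: str
    motif_id: str
    block_index: int
    u_position: int
    edits: Tuple[GenomeEdit, ...] = ()

    def __post_init__(self) -> None:
        L = len(self.motif)
        if L == 0:
            raise ValueError("planted motif must be nonempty")
        seen = set()
        for edit in self.edits:
            if edit.genome in seen:
                raise ValueError(f"duplicate edit plan for genome {edit.genome!r}")
            seen.add(edit.genome)
            if set(edit.substitutions) & set(edit.cmp_gaps):
                raise ValueError("substitution and cmp gap at the same offset")
            for off in (*edit.substitutions, *edit.cmp_gaps):
                if not 0 <= off < L:
                    raise ValueError(f"edit offset {off} outside motif of length {L}")
            for off in edit.ref_gap_insertions:
                if not 1 <= off <= L - 1:
                    raise ValueError(
                        f"ref gap insertion offset {off} must be strictly inside the motif"
                    )

    def expected_vector(self, genome: str) -> str:
        """Similarity vector implied by the edit plan for one compared genome."""
        symbols = ["1"] * len(self.motif)
        edit = next((e for e in self.edits if e.genome == genome), None)
        if edit is None:
            return "".join(symbols)
        for off in edit.substitutions:
            symbols[off] = "0"
        for off in edit.cmp_gaps:
            symbols[off] = "0"
        for off in sorted(edit.ref_gap_insertions, reverse=True):
            symbols.insert(off, REF_GAP_SYMBOL)
        return "".join(symbols)

    def expected_percent(self, genome: str) -> float:
        vector = self.expected_vector(genome)
        return 100.0 * vector.count("1") / len(vector)


@dataclass(frozen=True)
class GroundTruthHit:
    """Expected pipeline output for one planted motif."""

    motif_id: str
    motif: str
    block_index: int
    u_start: int
    u_end: int
    g_start: int
    g_end: int
    chromosome: str
    fwd_start: int
    fwd_end: int
    vectors: Dict[str, str] = field(default_factory=dict)  # compared src -> symbols
    percents: Dict[str, float] = field(default_factory=dict)
    block_conservation: Optional[float] = None


class FixtureError(ValueError):
    """Raised when a plant plan cannot be realised."""


def _draw_sequence(rng: np.random.Generator, n: int, base_freqs: Sequence[float]) -> List[str]:
    return [_BASES[i] for i in rng.choice(4, size=n, p=np.asarray(base_freqs))]


def _substitute(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in _BASES if b != base.upper()]
    return choices[rng.integers(len(choices))]


def _planted_spans(plants: Sequence[PlantSpec]) -> List[Tuple[int, int]]:
    spans = sorted((p.u_position, p.u_position + len(p.motif)) for p in plants)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise FixtureError(f"overlapping plants at [{s1},{e1}) and [{s2},{e2})")
    return spans


def _occurrences(text: str, motif: str) -> List[int]:
    found, start = [], 0
    while True:
        pos = text.find(motif, start)
        if pos < 0:
            return found
        found.append(pos)
        start = pos + 1


def generate_maf(
    n_blocks: int,
    n_genomes: int,
    block_width: int,
    plants: Sequence[PlantSpec],
    seed: int = 0,
    base_freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    max_redraws: int = 1000,
) -> Tuple[str, List[GroundTruthHit]]:
    """Build a MAF text plus the exact expected hit set.

    The searched genome is ``ref.chr1``; compared genomes are ``g1.chr1``
    .. ``g<n-1>.chr1``.  Background blocks are redrawn until no motif of
    the full plant set occurs at an unplanted position of the searched
    genome, so a k-mer search for the planted motifs recovers exactly the
    ground truth.
    """
    if n_genomes < 2:
        raise FixtureError("need at least 2 genomes (searched + 1 compared)")
    motif_seqs = sorted({p.motif.upper() for p in plants})
    genome_names = ["ref"] + [f"g{i}" for i in range(1, n_genomes)]
    by_block: Dict[int, List[PlantSpec]] = {}
    for plant in plants:
        if not 0 <= plant.block_index < n_blocks:
            raise FixtureError(f"plant block {plant.block_index} outside 0..{n_blocks - 1}")
        if plant.u_position + len(plant.motif) > block_width:
            raise FixtureError(f"plant {plant.motif_id!r} does not fit in block width")
        for edit in plant.edits:
            if edit.genome not in genome_names[1:]:
                raise FixtureError(f"edit references unknown genome {edit.genome!r}")
        by_block.setdefault(plant.block_index, []).append(plant)

    rng = np.random.default_rng(seed)
    blocks: List[AlignmentBlock] = []
    truth: List[GroundTruthHit] = []
    starts = {g: 0 for g in genome_names}  # running per-genome start coordinate

    for b in range(n_blocks):
        block_plants = sorted(by_block.get(b, []), key=lambda p: p.u_position)
        spans = _planted_spans(block_plants)

        ref = None
        for _ in range(max_redraws):
            candidate = _draw_sequence(rng, block_width, base_freqs)
            for plant in block_plants:
                motif = plant.motif.upper()
                candidate[plant.u_position : plant.u_position + len(motif)] = list(motif)
            text = "".join(candidate)
            planted_here = {
                (m, s)
                for plant in block_plants
                for m, s in [(plant.motif.upper(), plant.u_position)]
            }
            spurious = any(
                (motif, pos) not in planted_here
                for motif in motif_seqs
                for pos in _occurrences(text, motif)
            )
            if not spurious:
                ref = candidate
                break
        if ref is None:
            raise FixtureError(
                f"block {b}: could not draw a background free of spurious motif "
                f"occurrences in {max_redraws} attempts"
            )

        # compared genome characters per base column
        columns: Dict[str, List[str]] = {g: list(ref) for g in genome_names}
        for plant in block_plants:
            for edit in plant.edits:
                col = columns[edit.genome]
                for off in edit.substitutions:
                    col[plant.u_position + off] = _substitute(rng, ref[plant.u_position + off])
                for off in edit.cmp_gaps:
                    col[plant.u_position + off] = "-"

        # searched-side gap-column insertions: (ref position, genome, plant)
        insertions: List[Tuple[int, str]] = []
        for plant in block_plants:
            for edit in plant.edits:
                for off in edit.ref_gap_insertions:
                    insertions.append((plant.u_position + off, edit.genome))
        insertions.sort()
        ins_positions = [pos for pos, _ in insertions]

        texts: Dict[str, List[str]] = {g: [] for g in genome_names}
        ins_i = 0
        for pos in range(block_width + 1):
            while ins_i < len(insertions) and insertions[ins_i][0] == pos:
                _, owner = insertions[ins_i]
                for g in genome_names:
                    if g == owner:
                        texts[g].append(_BASES[rng.integers(4)])
                    else:
                        texts[g].append("-")
                ins_i += 1
            if pos < block_width:
                for g in genome_names:
                    texts[g].append(columns[g][pos])

        sequences = []
        for g in genome_names:
            gapped = "".join(texts[g])
            size = len(gapped) - gapped.count("-")
            sequences.append(
                AlignedSequence(
                    src=f"{g}.chr1",
                    start=starts[g],
                    size=size,
                    strand="+",
                    src_size=starts[g] + size + 10,
                    text=gapped,
                )
            )
            starts[g] += size
        blocks.append(AlignmentBlock(sequences=tuple(sequences), score=float(b)))

        ref_start = sequences[0].start
        for plant in block_plants:
            u_start = plant.u_position
            u_end = u_start + len(plant.motif)
            n_before = sum(1 for p in ins_positions if p <= u_start)
            n_within = sum(1 for p in ins_positions if u_start < p <= u_end - 1)
            g_start = u_start + n_before
            g_end = (u_end - 1) + n_before + n_within + 1
            vectors = {f"{g}.chr1": plant.expected_vector(g) for g in genome_names[1:]}
            percents = {f"{g}.chr1": plant.expected_percent(g) for g in genome_names[1:]}
            truth.append(
                GroundTruthHit(
                    motif_id=plant.motif_id,
                    motif=plant.motif.upper(),
                    block_index=b,
                    u_start=u_start,
                    u_end=u_end,
                    g_start=g_start,
                    g_end=g_end,
                    chromosome="chr1",
                    fwd_start=ref_start + u_start,
                    fwd_end=ref_start + u_end,
                    vectors=vectors,
                    percents=percents,
                    block_conservation=sum(percents.values()) / len(percents),
                )
            )

    buffer = io.StringIO()
    write_maf(blocks, buffer)
    return buffer.getvalue(), truth


def truth_table(truth: Sequence[GroundTruthHit]) -> pd.DataFrame:
    """Flatten ground truth to one row per (hit, compared genome), mirroring
    the CSV writer's comparison columns."""
    rows = []
    for hit in truth:
        for src, vector in hit.vectors.items():
            rows.append(
                {
                    "motif_id": hit.motif_id,
                    "block_index": hit.block_index,
                    "chromosome": hit.chromosome,
                    "fwd_start": hit.fwd_start,
                    "fwd_end": hit.fwd_end,
                    "g_start": hit.g_start,
                    "g_end": hit.g_end,
                    "u_start": hit.u_start,
                    "u_end": hit.u_end,
                    "compared_src": src,
                    "similarity_vector": vector,
                    "conservation_percent": hit.percents[src],
                    "block_conservation": hit.block_conservation,
                }
            )
    return pd.DataFrame(rows)
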