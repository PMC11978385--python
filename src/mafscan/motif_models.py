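"""Motif representations: k-mer lists, JASPAR PWMs, and regex pattern sets.

PWM scoring uses log2-odds against a user-supplied background; the hit
threshold is calibrated empirically by sampling random windows from that
same background and taking a conservative tail quantile at the requested
p-value.  The sampled null scores are retained so every reported hit gets
an add-one empirical p-value, and Benjamini–Hochberg converts the p-values
of one run into q-values (FDR).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import IO, List, Sequence, Tuple

import numpy as np

__all__ = [
    "BASES",
    "KmerSet",
    "Pwm",
    "RegexSet",
    "MotifParseError",
    "parse_kmer_file",
    "parse_jaspar",
    "build_log_odds",
    "calibrate_threshold",
    "empirical_p_value",
    "reverse_complement_pwm",
    "reverse_complement",
    "benjamini_hochberg",
    "validate_background",
    "UNIFORM_BACKGROUND",
]

BASES = "ACGT"
UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)

_COMPLEMENT = str.maketrans("ACGTRYKMBVDHNacgtrykmbvdhn", "TGCAYRMKVBHDNtgcayrmkvbhdn")

DEFAULT_PSEUDOCOUNT = 0.1
DEFAULT_N_SAMPLES = 100_000
DEFAULT_P_VALUE = 1e-4


class MotifParseError(ValueError):
    """Raised when a motif input file cannot be parsed."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def validate_background(freqs: Sequence[float] | None) -> Tuple[float, float, float, float]:
    """Validate A/C/G/T background frequencies; ``None`` means uniform."""
    if freqs is None:
        return UNIFORM_BACKGROUND
    values = tuple(float(f) for f in freqs)
    if len(values) != 4:
        raise ValueError(f"background needs 4 frequencies (A C G T), got {len(values)}")
    if any(v < 0 for v in values):
        raise ValueError("background frequencies must be non-negative")
    total = sum(values)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"background frequencies must sum to 1, got sum {total}")
    return values  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# k-mers


@dataclass(frozen=True)
class KmerSet:
    """A set of literal motifs, each ``(id, sequence)``."""

    kmers: Tuple[Tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen = set()
        for kid, seq in self.kmers:
            if not seq:
                raise ValueError(f"k-mer {kid!r} is empty")
            if "-" in seq or "." in seq:
                raise ValueError(f"k-mer {kid!r} contains gap characters")
            if kid in seen:
                raise ValueError(f"duplicate k-mer id {kid!r}")
            seen.add(kid)

    def __len__(self) -> int:
        return len(self.kmers)


def parse_kmer_file(stream: IO[str]) -> KmerSet:
    """Parse a k-mer list: one motif per line, optionally ``id<TAB>sequence``.

    Sequences are uppercased; lines without an explicit id are named
    ``kmer_<lineno>``.  Blank lines and ``#`` comments are skipped.
    """
    kmers: List[Tuple[str, str]] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if "\t" in line:
            kid, _, seq = line.partition("\t")
            kid, seq = kid.strip(), seq.strip()
            if not kid:
                kid = f"kmer_{lineno}"
        else:
            kid, seq = f"kmer_{lineno}", line.strip()
        if "-" in seq or "." in seq:
            raise MotifParseError(f"line {lineno}: k-mer {seq!r} contains a gap character")
        if any(c.isspace() for c in seq):
            raise MotifParseError(f"line {lineno}: whitespace inside k-mer {seq!r}")
        if not seq:
            raise MotifParseError(f"line {lineno}: empty k-mer sequence")
        kmers.append((kid, seq.upper()))
    try:
        return KmerSet(kmers=tuple(kmers))
    except ValueError as exc:
        raise MotifParseError(str(exc)) from None


# ---------------------------------------------------------------------------
# PWMs


@dataclass
class Pwm:
    """A nucleotide position weight matrix (rows A, C, G, T).

    ``counts`` holds the raw JASPAR counts; ``log_odds`` the derived
    log2-odds scoring matrix.  ``threshold``/``null_scores`` are populated
    by :func:`calibrate_threshold`.
    """

    name: str
    counts: np.ndarray
    background: Tuple[float, float, float, float] = UNIFORM_BACKGROUND
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    log_odds: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    threshold: float | None = None
    null_scores: np.ndarray | None = field(default=None, repr=False)
    p_value_target: float | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError(f"PWM {self.name!r}: counts must be a 4 x L matrix")
        if (self.counts < 0).any():
            raise ValueError(f"PWM {self.name!r}: negative counts")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.log_odds is None:
            self.log_odds = build_log_odds(self.counts, self.background, self.pseudocount)

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())

    def score(self, window: str) -> float:
        """Score one window of length L (must contain only A/C/G/T)."""
        if len(window) != self.length:
            raise ValueError(f"window length {len(window)} != PWM length {self.length}")
        idx = [BASES.index(c) for c in window.upper()]
        return float(self.log_odds[idx, np.arange(self.length)].sum())

    def calibrated(
        self,
        p_value: float = DEFAULT_P_VALUE,
        n_samples: int = DEFAULT_N_SAMPLES,
        seed: int = 0,
    ) -> "Pwm":
        """Return a copy with threshold and null sample set."""
        threshold, null_scores = calibrate_threshold(self, p_value, n_samples, seed)
        return replace(
            self,
            log_odds=self.log_odds,
            threshold=threshold,
            null_scores=null_scores,
            p_value_target=p_value,
        )


_JASPAR_ROW = re.compile(
    r"^\s*([ACGTacgt])\s*\[?\s*([-0-9.eE+\s]*?)\s*\]?\s*$"
)


def parse_jaspar(stream: IO[str]) -> List[Pwm]:
    """Parse JASPAR plain-text PWM records (counts only; calibration deferred).

    Each record is a ``>ID name`` header followed by four rows like
    ``A  [ 4 19 0 ]`` in any base order; bracket-less rows are tolerated.
    """
    pwms: List[Pwm] = []
    name: str | None = None
    rows: dict[str, List[float]] = {}

    def flush() -> None:
        nonlocal name, rows
        if name is None:
            return
        missing = [b for b in BASES if b not in rows]
        if missing:
            raise MotifParseError(f"record {name!r}: missing rows for {','.join(missing)}")
        lengths = {len(rows[b]) for b in BASES}
        if len(lengths) != 1:
            raise MotifParseError(f"record {name!r}: rows of unequal length {sorted(lengths)}")
        counts = np.array([rows[b] for b in BASES], dtype=float)
        if (counts < 0).any():
            raise MotifParseError(f"record {name!r}: negative counts")
        pwms.append(Pwm(name=name, counts=counts))
        name, rows = None, {}

    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].strip() or f"pwm_{lineno}"
            rows = {}
            continue
        match = _JASPAR_ROW.match(line)
        if match is None or name is None:
            raise MotifParseError(f"line {lineno}: unrecognized JASPAR content {line!r}")
        base = match.group(1).upper()
        if base in rows:
            raise MotifParseError(f"record {name!r}: duplicate {base} row")
        try:
            rows[base] = [float(x) for x in match.group(2).split()]
        except ValueError:
            raise MotifParseError(
                f"line {lineno}: non-numeric count in {base} row"
            ) from None
    flush()
    return pwms


def build_log_odds(
    counts: np.ndarray,
    background: Sequence[float],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """log2( column-normalised (counts + pseudocount) / background ).

    Each column of ``counts + pseudocount`` is normalised to sum to 1
    before dividing by the per-base background frequency.
    """
    background = validate_background(background)
    counts = np.asarray(counts, dtype=float)
    if (np.asarray(background) <= 0).any():
        raise ValueError("background frequencies must be > 0 for log-odds")
    padded = counts + pseudocount
    probs = padded / padded.sum(axis=0, keepdims=True)
    return np.log2(probs / np.asarray(background)[:, None])


def calibrate_threshold(
    pwm: Pwm,
    p_value: float,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
) -> Tuple[float, np.ndarray]:
    """Empirically calibrate a score threshold to a target p-value.

    Draws ``n_samples`` i.i.d. windows of length L with per-position base
    probabilities equal to the PWM background, scores them, and returns
    the smallest sampled score ``t`` such that the fraction of samples
    ``>= t`` is at most ``p_value`` (a conservative tail quantile), along
    with the sorted null scores.  When score ties are too coarse for any
    sampled score to satisfy that bound (short or degenerate matrices),
    the highest tie class is used instead.  Deterministic given ``seed``.
    """
    if not (0.0 < p_value <= 1.0):
        raise ValueError(f"p_value must be in (0, 1], got {p_value}")
    if n_samples < 1000:
        raise ValueError("n_samples must be >= 1000 for a stable tail quantile")
    rng = np.random.default_rng(seed)
    draws = rng.choice(4, size=(n_samples, pwm.length), p=np.asarray(pwm.background))
    scores = pwm.log_odds[draws, np.arange(pwm.length)].sum(axis=1)
    null_scores = np.sort(scores)

    max_tail = int(np.floor(p_value * n_samples))
    values, first_index = np.unique(null_scores, return_index=True)
    tails = n_samples - first_index  # count of samples >= each distinct value
    attainable = np.flatnonzero(tails <= max_tail)
    if attainable.size:
        threshold = values[attainable[0]]
    else:
        # ties are too coarse for the requested p-value (short/degenerate
        # PWMs): fall back to the top tie class, the best attainable cutoff
        threshold = values[-1]
    return float(threshold), null_scores


def empirical_p_value(score: float, null_scores: np.ndarray) -> float:
    """Add-one empirical tail probability of ``score`` under the null sample."""
    null_scores = np.asarray(null_scores)
    if null_scores.size == 0:
        raise ValueError("null_scores must be nonempty")
    n = null_scores.size
    n_ge = n - int(np.searchsorted(null_scores, score, side="left"))
    return (1 + n_ge) / (1 + n)


def reverse_complement_pwm(pwm: Pwm) -> Pwm:
    """Reverse the columns and swap A<->T, C<->G rows; log-odds rebuilt.

    Calibration (threshold, null sample) carries over: scores of a window
    under the reverse-complement matrix equal the scores of the window's
    reverse complement under the original matrix.
    """
    rc_counts = pwm.counts[::-1, ::-1].copy()
    return Pwm(
        name=pwm.name,
        counts=rc_counts,
        background=pwm.background,
        pseudocount=pwm.pseudocount,
        log_odds=build_log_odds(rc_counts, pwm.background, pwm.pseudocount),
        threshold=pwm.threshold,
        null_scores=pwm.null_scores,
        p_value_target=pwm.p_value_target,
    )


def benjamini_hochberg(p_values: Sequence[float]) -> List[float]:
    """Standard step-up q-values mapped back to input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


# ---------------------------------------------------------------------------
# regexes


@dataclass(frozen=True)
class RegexSet:
    """Named regular-expression patterns; all must compile at construction."""

    patterns: Tuple[Tuple[str, str], ...]

    def __post_init__(self) -> None:
        for pid, pattern in self.patterns:
            try:
                re.compile(pattern)
            except re.error as exc:
                raise ValueError(f"pattern {pid!r} does not compile: {exc}") from None

    def __len__(self) -> int:
        return len(self.patterns)


def parse_regexes(patterns_csv: str) -> RegexSet:
    """Build a RegexSet from a comma-separated pattern string."""
    raw = [p.strip() for p in patterns_csv.split(",")]
    patterns = tuple(
        (f"regex_{i + 1}", p) for i, p in enumerate(raw) if p
    )
    if not patterns:
        raise MotifParseError("no regular-expression patterns given")
    try:
        return RegexSet(patterns=patterns)
    except ValueError as exc:
        raise MotifParseError(str(exc)) from None
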