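"""Minimal Aho–Corasick automaton for multi-pattern exact matching.

Builds the classic goto/failure/output automaton once and streams the text
through it, reporting every occurrence of every pattern (overlaps included)
in a single pass — O(text + total pattern length + matches).
"""

from __future__ import annotations

from collections import deque
from typing import Iterator, List, Sequence, Tuple


class AhoCorasick:
    """Automaton over a list of (pattern, payload) pairs.

    Matching is exact and case-sensitive; callers normalise case. The same
    pattern may be added multiple times with different payloads.
    """

    def __init__(self, patterns: Sequence[Tuple[str, object]]):
        self._goto: List[dict] = [{}]
        self._out: List[List[Tuple[int, object]]] = [[]]  # (pattern length, payload)
        for pattern, payload in patterns:
            if not pattern:
                raise ValueError("empty pattern not allowed")
            self._insert(pattern, payload)
        self._build_links()

    def _insert(self, pattern: str, payload: object) -> None:
        state = 0
        for ch in pattern:
            nxt = self._goto[state].get(ch)
            if nxt is None:
                nxt = len(self._goto)
                self._goto[state][ch] = nxt
                self._goto.append({})
                self._out.append([])
            state = nxt
        self._out[state].append((len(pattern), payload))

    def _build_links(self) -> None:
        fail = [0] * len(self._goto)
        queue: deque[int] = deque()
        for state in self._goto[0].values():
            queue.append(state)
        while queue:
            state = queue.popleft()
            for ch, nxt in self._goto[state].items():
                queue.append(nxt)
                f = fail[state]
                while f and ch not in self._goto[f]:
                    f = fail[f]
                fail[nxt] = self._goto[f].get(ch, 0)
                if fail[nxt] == nxt:
                    fail[nxt] = 0
                self._out[nxt].extend(self._out[fail[nxt]])
        self._fail = fail

    def iter_matches(self, text: str) -> Iterator[Tuple[int, int, object]]:
        """Yield ``(start, end, payload)`` for every occurrence in ``text``."""
        goto, fail, out = self._goto, self._fail, self._out
        state = 0
        for i, ch in enumerate(text):
            while state and ch not in goto[state]:
                state = fail[state]
            state = goto[state].get(ch, 0)
            for length, payload in out[state]:
                yield i + 1 - length, i + 1, payload
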