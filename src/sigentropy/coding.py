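"""Message layer: signal-event sequences as symbol strings.

A signalling history is a whitespace-separated message of symbols
``X<k>`` (case-insensitive, 1-based step indices), e.g.
``"X1 X3 X2 X3 X1 X2 X3 X5 X3 X4 X3"``.  Symbol counts N_j determine the
multinomial multiplicity of the message and hence its mixing entropy;
indices may be sparse (a message over only X1 and X5 is legal), and
``n_distinct`` counts the indices actually present.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .entropy import log_multiplicity

__all__ = [
    "EventSequence",
    "parse_event_sequence",
    "format_event_sequence",
    "sequence_multiplicity",
    "sample_sequences",
]

_TOKEN_RE = re.compile(r"^[Xx]([0-9]+)$")


@dataclass(frozen=True)
class EventSequence:
    """An ordered symbol message with its per-symbol counts."""

    symbols: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("event sequence must contain at least one symbol")
        if any(s < 1 for s in self.symbols):
            raise ValueError("symbol indices are 1-based positive integers")

    @property
    def length(self) -> int:
        return len(self.symbols)

    @property
    def counts(self) -> dict[int, int]:
        """Occurrences N_j of each symbol index present."""
        out: dict[int, int] = {}
        for s in self.symbols:
            out[s] = out.get(s, 0) + 1
        return out

    @property
    def n_distinct(self) -> int:
        return len(set(self.symbols))

    def count_vector(self) -> np.ndarray:
        """Counts as a dense vector of length max(index)."""
        v = np.zeros(max(self.symbols), dtype=np.int64)
        for s in self.symbols:
            v[s - 1] += 1
        return v


def parse_event_sequence(text: str) -> EventSequence:
    """Parse a symbol message, rejecting malformed tokens with positions."""
    tokens = text.split()
    if not tokens:
        raise ValueError("empty event sequence")
    symbols = []
    for i, tok in enumerate(tokens):
        m = _TOKEN_RE.match(tok)
        if m is None or int(m.group(1)) < 1:
            raise ValueError(
                f"malformed token {tok!r} at position {i + 1}: "
                "expected X<positive integer>"
            )
        symbols.append(int(m.group(1)))
    return EventSequence(symbols=tuple(symbols))


def format_event_sequence(seq: EventSequence) -> str:
    """Inverse of parse: round-trips any valid sequence."""
    return " ".join(f"X{s}" for s in seq.symbols)


def sequence_multiplicity(seq: EventSequence) -> float:
    """ln of the multinomial coefficient length!/prod N_j!.

    Depends only on the counts, so it is invariant under any permutation
    of the message.  A pure symbol message has no active-form counts.
    """
    return log_multiplicity(seq.count_vector(), np.zeros(max(seq.symbols), dtype=int))


def sample_sequences(
    p, length: int, n_samples: int, seed: int
) -> list[EventSequence]:
    """Draw i.i.d. symbol messages from occurrence probabilities ``p``.

    ``p[j]`` is the selection probability of symbol X(j+1); it must be
    normalised to 1 within 1e-9.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("p must be a 1-D probability vector")
    if np.any(p < 0):
        raise ValueError("probabilities must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities must sum to 1, got {p.sum()!r}")
    if length < 1 or n_samples < 1:
        raise ValueError("length and n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.choice(np.arange(1, p.size + 1), size=(n_samples, length), p=p / p.sum())
    return [EventSequence(symbols=tuple(int(s) for s in row)) for row in draws]
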