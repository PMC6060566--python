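"""Plain-text permutation parsing/formatting and seeded instance generation.

The accepted permutation format is one permutation per line: whitespace
separated signed integers, optionally wrapped in parentheses, e.g.
``(+4 +2 +3 -1 -5)``.  Unsigned input may omit the signs.  Operations are
serialized as ``r(i,j)`` / ``t(i,j,k)``, with a trailing ``*`` for cyclic
application.
"""

from __future__ import annotations

import random
import re
from typing import List, Tuple

from .errors import ParseError
from .oracle import ModelSpec, legal_operations
from .perm import (
    CIRCULAR,
    LINEAR,
    REVERSAL,
    SIGNED,
    TRANSPOSITION,
    UNSIGNED,
    Operation,
    SignedPermutation,
    identity,
)

__all__ = [
    "parse_permutation",
    "format_permutation",
    "parse_operation",
    "format_operation",
    "scramble",
]

_TOKEN = re.compile(r"^[+-]?\d+$")
_OP = re.compile(r"^([rt])\((\d+(?:,\d+)*)\)(\*?)$")


def parse_permutation(
    text: str, signed: bool = True, circular: bool = False
) -> SignedPermutation:
    """Parse a whitespace-separated permutation, validating that the
    absolute values are exactly {1..n}."""
    stripped = text.strip()
    if stripped.startswith("(") and stripped.endswith(")"):
        stripped = stripped[1:-1]
    tokens = stripped.split()
    if not tokens:
        raise ParseError("empty permutation")
    entries: List[int] = []
    for tok in tokens:
        if not _TOKEN.match(tok):
            raise ParseError(f"malformed token {tok!r}")
        v = int(tok)
        if v == 0:
            raise ParseError(f"token {tok!r}: 0 is not a permutation element")
        if not signed and v < 0:
            raise ParseError(f"token {tok!r}: negative element in unsigned input")
        entries.append(v)
    n = len(entries)
    seen = set()
    for tok, v in zip(tokens, entries):
        if abs(v) in seen:
            raise ParseError(f"token {tok!r}: duplicate element {abs(v)}")
        if abs(v) > n:
            raise ParseError(f"token {tok!r}: element exceeds n={n} (gap in 1..n)")
        seen.add(abs(v))
    return SignedPermutation(
        tuple(entries),
        CIRCULAR if circular else LINEAR,
        SIGNED if signed else UNSIGNED,
    )


def format_permutation(pi: SignedPermutation) -> str:
    return str(pi)


def parse_operation(text: str) -> Operation:
    m = _OP.match(text.strip())
    if not m:
        raise ParseError(f"malformed operation {text!r}")
    letter, body, star = m.groups()
    positions = tuple(int(p) for p in body.split(","))
    kind = REVERSAL if letter == "r" else TRANSPOSITION
    return Operation(kind, positions, cyclic=bool(star))


def format_operation(op: Operation) -> str:
    return str(op)


def scramble(
    n: int, k: int, model: ModelSpec, seed: int
) -> Tuple[SignedPermutation, Tuple[Operation, ...]]:
    """Apply k uniformly random allowed SSOs to the identity.

    Reproducible by seed; the returned permutation's model distance is at
    most k (every applied operation is invertible by one allowed operation).
    """
    if k < 0:
        raise ParseError(f"operation count k must be >= 0, got {k}")
    rng = random.Random(seed)
    moves = legal_operations(n, model)
    pi = identity(n, model.topology, model.signedness)
    applied: List[Operation] = []
    for _ in range(k):
        op = rng.choice(moves)
        # Operations are defined on the linear representative.
        lin = SignedPermutation(pi.entries, LINEAR, pi.signedness)
        pi = SignedPermutation(op.apply(lin).entries, pi.topology, pi.signedness)
        applied.append(op)
    return pi, tuple(applied)
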