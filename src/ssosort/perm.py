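"""Signed-permutation algebra and super short operations (SSOs).

A genome without duplicated genes is modelled as a signed permutation
``pi = (pi_1 ... pi_n)``: the absolute values are exactly ``{1..n}`` (gene
identity) and the sign records the strand the gene lies on.  Sorting ``pi``
means transforming it into the positive identity ``(+1 +2 ... +n)`` with a
minimum number of allowed rearrangement events.

The events considered here are the *super short operations*:

* a 1-reversal flips the sign of a single element,
* a 2-reversal exchanges two adjacent elements and flips both signs,
* a 2-transposition exchanges two adjacent elements without sign changes.

Any SSO that is not a 1-reversal is called a *swap*.  *Cyclic* variants may
act across the boundary between positions ``n`` and ``1`` of a linear
permutation, which is how a circular chromosome is emulated on a linear
representation.

All positions at this public interface are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence, Tuple

from .errors import (
    ModelError,
    PositionError,
    SequenceError,
    SizeError,
    TopologyError,
)

LINEAR = "linear"
CIRCULAR = "circular"
SIGNED = "signed"
UNSIGNED = "unsigned"

REVERSAL = "reversal"
TRANSPOSITION = "transposition"

__all__ = [
    "LINEAR",
    "CIRCULAR",
    "SIGNED",
    "UNSIGNED",
    "REVERSAL",
    "TRANSPOSITION",
    "SignedPermutation",
    "Operation",
    "SortingSequence",
    "identity",
    "compose",
    "inverse",
    "apply_reversal",
    "apply_transposition",
    "classify_z",
    "circular_linearizations",
]


@dataclass(frozen=True)
class SignedPermutation:
    """A (possibly circular, possibly unsigned) signed permutation of {1..n}.

    Unsigned permutations are stored as all-positive signed permutations;
    operations that would introduce a sign are rejected on them.
    """

    entries: Tuple[int, ...]
    topology: str = LINEAR
    signedness: str = SIGNED

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(int(v) for v in self.entries))
        n = len(self.entries)
        if n == 0:
            raise SizeError("a permutation needs at least one element")
        if self.topology not in (LINEAR, CIRCULAR):
            raise TopologyError(f"unknown topology {self.topology!r}")
        if self.signedness not in (SIGNED, UNSIGNED):
            raise ModelError(f"unknown signedness {self.signedness!r}")
        if sorted(abs(v) for v in self.entries) != list(range(1, n + 1)):
            raise SizeError(
                f"absolute values must be exactly 1..{n}, got {self.entries}"
            )
        if self.signedness == UNSIGNED and any(v < 0 for v in self.entries):
            raise ModelError("unsigned permutations carry all-positive entries")

    @property
    def n(self) -> int:
        return len(self.entries)

    @property
    def is_circular(self) -> bool:
        return self.topology == CIRCULAR

    def is_identity(self) -> bool:
        return self.entries == tuple(range(1, self.n + 1))

    def negatives(self) -> Tuple[int, ...]:
        """The negative elements of the permutation, in position order."""
        return tuple(v for v in self.entries if v < 0)

    def with_entries(self, entries: Sequence[int]) -> "SignedPermutation":
        return SignedPermutation(tuple(entries), self.topology, self.signedness)

    def __str__(self) -> str:
        if self.signedness == UNSIGNED:
            body = " ".join(str(v) for v in self.entries)
        else:
            body = " ".join(f"{v:+d}" for v in self.entries)
        return f"({body})"

    def __iter__(self) -> Iterator[int]:
        return iter(self.entries)


def identity(n: int, topology: str = LINEAR, signedness: str = SIGNED) -> SignedPermutation:
    """The identity permutation ``(+1 +2 ... +n)``."""
    return SignedPermutation(tuple(range(1, n + 1)), topology, signedness)


def compose(pi: SignedPermutation, sigma: SignedPermutation) -> SignedPermutation:
    """Composition ``pi . sigma``: ``alpha_i = -pi_{|sigma_i|}`` if ``sigma_i < 0``
    else ``pi_{sigma_i}``."""
    if pi.n != sigma.n:
        raise SizeError(f"length mismatch: {pi.n} vs {sigma.n}")
    out = []
    for s in sigma.entries:
        v = pi.entries[abs(s) - 1]
        out.append(-v if s < 0 else v)
    return pi.with_entries(out)


def inverse(sigma: SignedPermutation) -> SignedPermutation:
    """The inverse ``sigma^-1``, satisfying ``compose(sigma^-1, sigma) = identity``."""
    out = [0] * sigma.n
    for pos, v in enumerate(sigma.entries, start=1):
        out[abs(v) - 1] = -pos if v < 0 else pos
    return sigma.with_entries(out)


def _check_position(p: int, n: int) -> None:
    if not 1 <= p <= n:
        raise PositionError(f"position {p} out of range 1..{n}")


def apply_reversal(
    pi: SignedPermutation, i: int, j: int, cyclic: bool = False
) -> SignedPermutation:
    """Reverse the block of positions i..j (wrapping through n..1 when
    ``cyclic`` and ``i > j``), flipping every sign in the block.

    On unsigned permutations the block order is reversed but no signs are
    introduced; a 1-reversal, whose only effect is a sign flip, is rejected
    there.
    """
    n = pi.n
    _check_position(i, n)
    _check_position(j, n)
    if i > j and not cyclic:
        raise PositionError(f"reversal needs i <= j when not cyclic, got ({i},{j})")
    if i <= j:
        idx = list(range(i - 1, j))
    else:
        idx = list(range(i - 1, n)) + list(range(0, j))
    if pi.signedness == UNSIGNED:
        if len(idx) == 1:
            raise ModelError("1-reversals are sign flips; rejected on unsigned input")
        flip = 1
    else:
        flip = -1
    vals = [pi.entries[p] for p in idx]
    new = list(pi.entries)
    for p, v in zip(idx, reversed(vals)):
        new[p] = flip * v
    return pi.with_entries(new)


def apply_transposition(
    pi: SignedPermutation, i: int, j: int, k: int, cyclic: bool = False
) -> SignedPermutation:
    """Exchange two blocks of adjacent elements; transpositions never change signs.

    Non-cyclic pattern ``1 <= i < j < k <= n+1`` exchanges blocks ``i..j-1``
    and ``j..k-1``.  The cyclic extension also allows (a) ``k < i < j``
    (second block wraps through the end) and (b) ``j < k <= i`` (first block
    wraps through the end).
    """
    n = pi.n
    if 1 <= i < j < k <= n + 1:
        block1 = list(range(i - 1, j - 1))
        block2 = list(range(j - 1, k - 1))
    elif cyclic and 1 <= k < i < j <= n:
        # second block wraps: {pi_j..pi_n, pi_1..pi_{k-1}}
        block1 = list(range(i - 1, j - 1))
        block2 = list(range(j - 1, n)) + list(range(0, k - 1))
    elif cyclic and 1 <= j < k <= i <= n and (k < i or (k == i == n and j == 1)):
        # first block wraps: {pi_i..pi_n, pi_1..pi_{j-1}}.  The k == i branch
        # only covers n = 2, where the wrap swap tau*(2,1,2) has no strict
        # j < k < i representation.
        block1 = list(range(i - 1, n)) + list(range(0, j - 1))
        block2 = list(range(j - 1, k - 1))
    else:
        raise PositionError(
            f"invalid transposition index pattern ({i},{j},{k}) for n={n}"
            + ("" if cyclic else " (non-cyclic)")
        )
    region = block1 + block2
    content = [pi.entries[p] for p in block2] + [pi.entries[p] for p in block1]
    new = list(pi.entries)
    for p, v in zip(region, content):
        new[p] = v
    return pi.with_entries(new)


@dataclass(frozen=True)
class Operation:
    """A reversal or transposition, possibly cyclic, with 1-based positions.

    ``rho(i,j)`` is ``Operation("reversal", (i, j))``;
    ``tau(i,j,k)`` is ``Operation("transposition", (i, j, k))``;
    the cyclic variants ``rho*``/``tau*`` carry ``cyclic=True``.
    """

    kind: str
    positions: Tuple[int, ...]
    cyclic: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", tuple(int(p) for p in self.positions))
        if self.kind == REVERSAL:
            if len(self.positions) != 2:
                raise PositionError("a reversal takes positions (i, j)")
            i, j = self.positions
            if i > j and not self.cyclic:
                raise PositionError(f"non-cyclic reversal needs i <= j, got ({i},{j})")
        elif self.kind == TRANSPOSITION:
            if len(self.positions) != 3:
                raise PositionError("a transposition takes positions (i, j, k)")
            i, j, k = self.positions
            if not self.cyclic and not i < j < k:
                raise PositionError(
                    f"non-cyclic transposition needs i < j < k, got ({i},{j},{k})"
                )
        else:
            raise PositionError(f"unknown operation kind {self.kind!r}")
        if any(p < 1 for p in self.positions):
            raise PositionError(f"positions are 1-based, got {self.positions}")

    def apply(self, pi: SignedPermutation) -> SignedPermutation:
        if self.kind == REVERSAL:
            i, j = self.positions
            return apply_reversal(pi, i, j, cyclic=self.cyclic)
        i, j, k = self.positions
        return apply_transposition(pi, i, j, k, cyclic=self.cyclic)

    def z(self, n: int) -> int:
        return classify_z(self, n)[0]

    def is_super_short(self, n: int) -> bool:
        return classify_z(self, n)[1]

    def swap_left_position(self, n: int) -> int | None:
        """For a swap (2-reversal / 2-transposition) acting on the adjacent
        pair ``(p, p mod n + 1)``, the left position ``p``; None for 1-reversals."""
        z, super_short = classify_z(self, n)
        if not super_short or (self.kind == REVERSAL and z == 1):
            return None
        return self.positions[0]

    def __str__(self) -> str:
        letter = "r" if self.kind == REVERSAL else "t"
        star = "*" if self.cyclic else ""
        return f"{letter}({','.join(str(p) for p in self.positions)}){star}"


def classify_z(op: Operation, n: int) -> Tuple[int, bool]:
    """Size class ``z`` of an operation and whether it is super short.

    A z-reversal has ``z = j - i + 1 (mod n)`` (taken in 1..n) and is super
    short iff ``z`` is 1 or 2; a z-transposition has
    ``z = ((j - i) mod n) + ((k - j) mod n)`` and is super short iff ``z = 2``.
    """
    for p in op.positions[: (2 if op.kind == REVERSAL else 2)]:
        _check_position(p, n)
    if op.kind == REVERSAL:
        i, j = op.positions
        z = ((j - i) % n) + 1
        return z, z in (1, 2)
    i, j, k = op.positions
    if k > n + 1:
        raise PositionError(f"position {k} out of range 1..{n + 1}")
    z = ((j - i) % n) + ((k - j) % n)
    return z, z == 2


@dataclass(frozen=True)
class SortingSequence:
    """An ordered sequence of operations that sorts its origin permutation."""

    ops: Tuple[Operation, ...]
    origin: SignedPermutation

    def __post_init__(self) -> None:
        object.__setattr__(self, "ops", tuple(self.ops))
        final = self.replay()[-1]
        if not final.is_identity():
            raise SequenceError(
                f"sequence does not sort {self.origin}: ends at {final}"
            )

    def __len__(self) -> int:
        return len(self.ops)

    def replay(self) -> Tuple[SignedPermutation, ...]:
        """All intermediate permutations, starting at origin, ending at identity."""
        states = [self.origin]
        for op in self.ops:
            states.append(op.apply(states[-1]))
        return tuple(states)

    def __str__(self) -> str:
        return " ".join(str(op) for op in self.ops) if self.ops else "(empty)"


def circular_linearizations(pi: SignedPermutation) -> Tuple[SignedPermutation, ...]:
    """The 2n linear representations of a circular permutation.

    The circle can be cut at any of its n adjacencies and read in either
    orientation.  Reading forward gives the n rotations; reading backward
    flips the strand of every gene, so the n reflections negate all signs
    (signs are untouched for unsigned input).  Duplicates are possible and
    preserved: exactly 2n candidates are returned, rotations first, starting
    from the input's first entry.
    """
    if not pi.is_circular:
        raise TopologyError("circular_linearizations requires a circular permutation")
    e = pi.entries
    n = pi.n
    out = []
    for r in range(n):
        out.append(SignedPermutation(e[r:] + e[:r], LINEAR, pi.signedness))
    neg = 1 if pi.signedness == UNSIGNED else -1
    rev = tuple(neg * v for v in reversed(e))
    for r in range(n):
        out.append(SignedPermutation(rev[r:] + rev[:r], LINEAR, pi.signedness))
    return tuple(out)
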