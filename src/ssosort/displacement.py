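"""Displacement-vector (VD-vector) calculus.

A sorting scenario made of cyclic swaps moves every element some net number
of positions to the right (``v = R - L``).  Collecting these per-element net
moves gives a *displacement vector* ``X``.  ``X`` is *valid* for ``pi`` when
it sums to zero (each rightward unit move is matched by a leftward one) and
``|pi_i| - x_i == i (mod n)`` for all i (every element ends in its correct
position, possibly after wrapping around the boundary).

The *crossing value* ``c_ij(X)`` is the signed minimum number of times
elements ``pi_i`` and ``pi_j`` must be swapped in any scenario realizing
``X``; the *crossing number* ``cn(X) = (1/2) sum |c_ij|`` is then the minimum
number of swaps of such a scenario.  The transformation ``T_{i,j}`` shifts a
whole turn of the cycle (n positions) from entry i to entry j while keeping
the vector valid; repeatedly applying *strictly contracting* transformations
(``x_i - x_j > n``) reaches the minimum crossing number over all valid
vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

from .errors import SequenceError, SizeError, ValidityError
from .perm import SignedPermutation, SortingSequence

__all__ = [
    "DisplacementVector",
    "initial_vd",
    "validate_vd",
    "crossing_value",
    "crossing_matrix",
    "crossing_number",
    "transform",
    "contraction_type",
    "minimize_crossing",
    "swap_update",
    "sequence_displacement",
    "NONE",
    "CONTRACTING",
    "STRICTLY_CONTRACTING",
]

NONE = "none"
CONTRACTING = "contracting"
STRICTLY_CONTRACTING = "strictly_contracting"


@dataclass(frozen=True, order=True)
class DisplacementVector:
    """An integer displacement vector; hashable so candidate sets can hold it."""

    x: Tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", tuple(int(v) for v in self.x))
        if sum(self.x) != 0:
            raise ValidityError(f"displacement entries must sum to zero, got {self.x}")

    @property
    def n(self) -> int:
        return len(self.x)

    def __getitem__(self, i: int) -> int:
        """1-based entry access, matching the x_i notation."""
        if not 1 <= i <= self.n:
            raise IndexError(f"entry index {i} out of range 1..{self.n}")
        return self.x[i - 1]

    def __str__(self) -> str:
        return "(" + ",".join(str(v) for v in self.x) + ")"


def initial_vd(pi: SignedPermutation) -> DisplacementVector:
    """The straight-line displacement vector ``x_i = |pi_i| - i``.

    It is automatically valid for ``pi``: entries sum to zero because both
    ``|pi_i|`` and ``i`` enumerate 1..n.
    """
    return DisplacementVector(tuple(abs(v) - i for i, v in enumerate(pi.entries, 1)))


def validate_vd(X: DisplacementVector, pi: SignedPermutation) -> bool:
    """True iff X sums to zero and ``|pi_i| - x_i == i (mod n)`` for all i."""
    if X.n != pi.n:
        raise SizeError(f"length mismatch: vector {X.n} vs permutation {pi.n}")
    n = pi.n
    if sum(X.x) != 0:
        return False
    return all(
        (abs(v) - x - i) % n == 0 for i, (v, x) in enumerate(zip(pi.entries, X.x), 1)
    )


def _count_multiples(a: int, b: int, n: int) -> int:
    """Number of multiples of n in the closed interval [a..b] (a <= b)."""
    return b // n - (a - 1) // n


def crossing_value(X: DisplacementVector, i: int, j: int) -> int:
    """Signed crossing value ``c_ij(X)``.

    With ``r = i - j`` and ``s = (i + x_i) - (j + x_j)``, counts the
    multiples of n in [r..s] when ``r <= s`` and the negated count in [s..r]
    otherwise.  Positive sign means pi_i sits to the left of pi_j when their
    swap happens.
    """
    if i == j:
        raise ValidityError("c_ii is undefined")
    n = X.n
    r = i - j
    s = (i + X[i]) - (j + X[j])
    if r <= s:
        return _count_multiples(r, s, n)
    return -_count_multiples(s, r, n)


def crossing_matrix(X: DisplacementVector) -> Dict[Tuple[int, int], int]:
    """All crossing values keyed by ordered pair (i, j), i != j."""
    n = X.n
    out: Dict[Tuple[int, int], int] = {}
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            c = crossing_value(X, i, j)
            out[(i, j)] = c
            out[(j, i)] = -c
    return out


def crossing_number(X: DisplacementVector) -> int:
    """``cn(X) = (1/2) sum_{i != j} |c_ij(X)|``, the minimum swap count."""
    n = X.n
    return sum(
        abs(crossing_value(X, i, j))
        for i in range(1, n + 1)
        for j in range(i + 1, n + 1)
    )


def transform(X: DisplacementVector, i: int, j: int) -> DisplacementVector:
    """``T_{i,j}(X)``: subtract n from x_i and add n to x_j.

    Validity for the same permutation is preserved since both changes are
    0 mod n and cancel in the sum.
    """
    if i == j:
        raise ValidityError("T_{i,i} is undefined")
    n = X.n
    x = list(X.x)
    x[i - 1] -= n
    x[j - 1] += n
    return DisplacementVector(tuple(x))


def contraction_type(X: DisplacementVector, i: int, j: int) -> str:
    """Classify ``T_{i,j}`` on X: strictly contracting iff ``x_i - x_j > n``,
    contracting iff ``>= n``.

    In the regime where pi_i crosses every other element at most once to the
    right, pi_j at most once to the left, and ``c_ij = 1``, the crossing
    number obeys the conservation law
    ``cn(T_{i,j}(X)) = cn(X) + 2(n - x_i + x_j)``, so contracting moves do
    not increase cn and strictly contracting moves decrease it.  (The law is
    exact only under those conditions, which hold wherever the minimization
    below relies on it; see the methods note.)
    """
    if i == j:
        return NONE
    d = X[i] - X[j]
    if d > X.n:
        return STRICTLY_CONTRACTING
    if d == X.n:
        return CONTRACTING
    return NONE


def minimize_crossing(X: DisplacementVector) -> DisplacementVector:
    """Apply strictly contracting transformations until none exists.

    The fixed point attains the minimum crossing number over all valid
    vectors for the underlying permutation.  Each round moves a full turn
    from the current maximum entry to the current minimum entry (lowest
    index on ties).  Termination: each such move changes the potential
    ``sum x_k^2`` by ``2n(n - (x_i - x_j)) < 0``, so the loop ends after
    finitely many rounds with ``max(X) - min(X) <= n``.
    """
    n = X.n
    while True:
        x = X.x
        i = max(range(1, n + 1), key=lambda p: (x[p - 1], -p))
        j = min(range(1, n + 1), key=lambda p: (x[p - 1], p))
        if x[i - 1] - x[j - 1] <= n:
            return X
        X = transform(X, i, j)


def swap_update(X: DisplacementVector, p: int) -> DisplacementVector:
    """Update X after the induced swap at the adjacency ``(p, p mod n + 1)``.

    The swap exchanges the elements at positions p and q = p mod n + 1 (the
    element at p moving one step right, wrapping from n to 1).  It is
    *induced* by X iff ``c_pq(X) > 0``; the updated vector has
    ``x'_p = x_q + 1`` and ``x'_q = x_p - 1`` and its crossing number is
    exactly one less.
    """
    n = X.n
    q = p % n + 1
    if q == p:
        raise ValidityError("no adjacency exists for n = 1")
    if crossing_value(X, p, q) <= 0:
        raise ValidityError(
            f"swap at ({p},{q}) is not induced: c_{p}{q}(X) = "
            f"{crossing_value(X, p, q)} is not positive"
        )
    x = list(X.x)
    x[p - 1], x[q - 1] = X[q] + 1, X[p] - 1
    return DisplacementVector(tuple(x))


def sequence_displacement(pi: SignedPermutation, S: SortingSequence) -> DisplacementVector:
    """Replay a sorting sequence and record each element's net displacement.

    Every swap moves its left element one position to the right (+1) and its
    right element one to the left (-1); 1-reversals move nothing.  The result
    is reported in the order of ``pi``'s positions, i.e. entry i is the
    displacement of ``pi_i``.
    """
    n = pi.n
    disp = {abs(v): 0 for v in pi.entries}
    cur = pi
    for op in S.ops:
        p = op.swap_left_position(n)
        if p is not None:
            q = p % n + 1
            disp[abs(cur.entries[p - 1])] += 1
            disp[abs(cur.entries[q - 1])] -= 1
        cur = op.apply(cur)
    if not cur.is_identity():
        raise SequenceError(f"sequence does not sort {pi}")
    return DisplacementVector(tuple(disp[abs(v)] for v in pi.entries))
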