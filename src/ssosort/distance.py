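"""Sorting distance of signed permutations under cyclic super short operations.

For a signed linear permutation ``pi`` and any valid displacement vector X,
the minimum number of cyclic SSOs realizing X is ``d(pi, X) = cn(X) + cc-``
(swaps pay for the crossings, one 1-reversal per odd component of the
cp-graph fixes the leftover signs).  The sorting distance is the minimum of
``d(pi, X)`` over all valid vectors, and that minimum is always attained in

* ``S``   - the vectors with minimum crossing number ``cn(pi)``, or
* ``S'``  - the one-transformation images of S members outside S.

The polynomial algorithm therefore reduces the initial vector by strictly
contracting transformations, enumerates S by single-step contracting moves
(stopping early if some S member has a one-component cp-graph, in which case
that member is already optimal), otherwise adds S' and minimizes over the
union.  A signed *circular* permutation is handled by cutting the circle at
each of its n adjacencies in both orientations and taking the best of the
2n linear representations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Set, Tuple

from . import cpgraph
from .displacement import (
    DisplacementVector,
    crossing_number,
    crossing_value,
    initial_vd,
    minimize_crossing,
    swap_update,
    transform,
    validate_vd,
)
from .errors import SSOSortError, TopologyError, ValidityError
from .perm import (
    REVERSAL,
    TRANSPOSITION,
    Operation,
    SignedPermutation,
    SortingSequence,
    circular_linearizations,
)

__all__ = [
    "DistanceResult",
    "vd_distance",
    "enumerate_S",
    "enumerate_S_prime",
    "full_S_closure",
    "linear_cyclic_distance",
    "circular_distance",
    "reconstruct_sequence",
]


@dataclass(frozen=True)
class DistanceResult:
    """A sorting distance together with its witnesses."""

    distance: int
    witness_vector: DisplacementVector
    witness_linearization: Optional[SignedPermutation] = None
    sequence: Optional[SortingSequence] = None

    def to_record(self) -> dict:
        """Structured serialization (distance, witnesses, r/t operation list)."""
        rec = {
            "distance": self.distance,
            "witness_vector": list(self.witness_vector.x),
        }
        if self.witness_linearization is not None:
            rec["witness_linearization"] = str(self.witness_linearization)
        if self.sequence is not None:
            rec["sequence"] = [str(op) for op in self.sequence.ops]
        return rec


def vd_distance(pi: SignedPermutation, X: DisplacementVector) -> int:
    """``d(pi, X) = cn(X) + cc-(G^X_pi)``."""
    g = cpgraph.build(pi, X)
    return crossing_number(X) + cpgraph.odd_components(g)


def enumerate_S(X_min: DisplacementVector) -> Set[DisplacementVector]:
    """Single-step contracting images of a minimum-cn fixed point, plus itself.

    ``T_{i,j}`` keeps the crossing number exactly when ``x_i - x_j = n``.
    This mirrors the O(n^2) generation loop of the polynomial algorithm:
    either it yields all of S, or some generated member has a one-component
    cp-graph and the early exit applies.
    """
    n = X_min.n
    out = {X_min}
    for i in range(1, n + 1):
        for j in range(1, n + 1):
            if i != j and X_min[i] - X_min[j] == n:
                out.add(transform(X_min, i, j))
    return out


def enumerate_S_prime(S: Set[DisplacementVector]) -> Set[DisplacementVector]:
    """All single-transformation images of S members that leave S."""
    out: Set[DisplacementVector] = set()
    for X in S:
        n = X.n
        for i in range(1, n + 1):
            for j in range(1, n + 1):
                if i != j:
                    Y = transform(X, i, j)
                    if Y not in S:
                        out.add(Y)
    return out


def full_S_closure(X_min: DisplacementVector, max_size: int = 100000) -> Set[DisplacementVector]:
    """Breadth-first closure of S under cn-preserving (x_i - x_j = n) moves.

    Debug / cross-validation helper: unlike :func:`enumerate_S` this reaches
    every minimum-cn vector, at a potentially exponential price.
    """
    seen = {X_min}
    frontier = [X_min]
    while frontier:
        nxt: List[DisplacementVector] = []
        for X in frontier:
            n = X.n
            for i in range(1, n + 1):
                for j in range(1, n + 1):
                    if i != j and X[i] - X[j] == n:
                        Y = transform(X, i, j)
                        if Y not in seen:
                            seen.add(Y)
                            nxt.append(Y)
        if len(seen) > max_size:
            raise SSOSortError(f"S closure exceeded {max_size} vectors")
        frontier = nxt
    return seen


def linear_cyclic_distance(
    pi: SignedPermutation,
    with_sequence: bool = False,
    debug_full_minimization: bool = False,
) -> DistanceResult:
    """Sorting distance of a signed linear permutation under cyclic SSOs.

    ``debug_full_minimization`` skips the one-component early exit and
    minimizes over all of S union S' regardless, for cross-validation.
    """
    if pi.is_circular:
        raise TopologyError("linear_cyclic_distance expects a linear permutation")
    X0 = minimize_crossing(initial_vd(pi))
    S = enumerate_S(X0)
    best: Optional[Tuple[int, DisplacementVector]] = None
    if not debug_full_minimization:
        for X in sorted(S):
            if cpgraph.build(pi, X).component_count == 1:
                best = (vd_distance(pi, X), X)
                break
    if best is None:
        candidates = S | enumerate_S_prime(S)
        for X in sorted(candidates):
            d = vd_distance(pi, X)
            if best is None or d < best[0]:
                best = (d, X)
    dist, X_star = best
    seq = reconstruct_sequence(pi, X_star) if with_sequence else None
    return DistanceResult(dist, X_star, sequence=seq)


def circular_distance(
    pi: SignedPermutation, with_sequence: bool = False
) -> DistanceResult:
    """Sorting distance of a signed circular permutation under SSOs.

    Minimum of the cyclic-SSO linear distance over the 2n linearizations;
    the first winner in rotation-then-reflection order is reported.
    """
    if not pi.is_circular:
        raise TopologyError("circular_distance expects a circular permutation")
    best: Optional[Tuple[DistanceResult, SignedPermutation]] = None
    for lin in circular_linearizations(pi):
        res = linear_cyclic_distance(lin)
        if best is None or res.distance < best[0].distance:
            best = (res, lin)
    res, lin = best
    seq = reconstruct_sequence(lin, res.witness_vector) if with_sequence else None
    return DistanceResult(res.distance, res.witness_vector, lin, seq)


def _pick_induced_swap(X: DisplacementVector) -> Optional[int]:
    """First position p (ascending) whose adjacency (p, p mod n + 1) carries
    an induced swap, i.e. c_pq(X) > 0; None when cn(X) = 0."""
    n = X.n
    for p in range(1, n + 1):
        q = p % n + 1
        if q != p and crossing_value(X, p, q) > 0:
            return p
    return None


def _swap_operation(kind: str, p: int, n: int) -> Operation:
    """The swap of the given kind acting on adjacency (p, p mod n + 1)."""
    if p < n:
        if kind == REVERSAL:
            return Operation(REVERSAL, (p, p + 1))
        return Operation(TRANSPOSITION, (p, p + 1, p + 2))
    if kind == REVERSAL:
        return Operation(REVERSAL, (n, 1), cyclic=True)
    return Operation(TRANSPOSITION, (n, 1, 2), cyclic=True)


def reconstruct_sequence(
    pi: SignedPermutation, X_star: DisplacementVector
) -> SortingSequence:
    """An explicit minimum-length sequence realizing X_star.

    Repeatedly applies an induced swap (first available adjacency in
    ascending order of the left position).  The swap type defaults to a
    2-transposition and is switched to a 2-reversal whenever the default
    would split an even component into two odd halves; this keeps the odd
    component count constant, so after all edges are consumed exactly
    ``cc-`` negative elements remain, each fixed by one 1-reversal.  The
    total length is ``cn(X_star) + cc- = d(pi, X_star)``.
    """
    if not validate_vd(X_star, pi):
        raise ValidityError(f"{X_star} is not a valid displacement vector for {pi}")
    cur = pi
    X = X_star
    n = pi.n
    ops: List[Operation] = []
    cc_minus = cpgraph.build(cur, X).odd_component_count()
    while True:
        p = _pick_induced_swap(X)
        if p is None:
            break
        X_next = swap_update(X, p)
        chosen = None
        for kind in (TRANSPOSITION, REVERSAL):
            op = _swap_operation(kind, p, n)
            cand = op.apply(cur)
            if cpgraph.build(cand, X_next).odd_component_count() == cc_minus:
                chosen = (op, cand)
                break
        if chosen is None:  # pragma: no cover - ruled out by theory
            raise SSOSortError("no parity-preserving swap type at adjacency "
                               f"({p},{p % n + 1})")
        op, cur = chosen
        ops.append(op)
        X = X_next
    # cn is now 0, so every element sits at |pi_i| = i; flip the leftovers.
    for i, v in enumerate(cur.entries, 1):
        if v < 0:
            ops.append(Operation(REVERSAL, (i, i)))
            cur = ops[-1].apply(cur)
    return SortingSequence(tuple(ops), pi)
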