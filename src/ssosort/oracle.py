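"""Brute-force breadth-first-search distances over the full state space.

Ground truth for the algorithmic modules at small n.  Every SSO is
invertible by an SSO of the same kind, so the move graph is undirected and
one BFS from the identity yields the distance of every state; the table is
cached per (n, model).  Circular states are canonicalized to the
lexicographically smallest representative among all rotations and
reflect-and-negate rotations.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Set, Tuple

from .errors import CapacityError, ModelError, TopologyError
from .perm import (
    CIRCULAR,
    LINEAR,
    REVERSAL,
    SIGNED,
    TRANSPOSITION,
    UNSIGNED,
    Operation,
    SignedPermutation,
)

__all__ = [
    "ModelSpec",
    "MAX_SIGNED_N",
    "MAX_UNSIGNED_N",
    "SSO",
    "SSR_ONLY",
    "legal_operations",
    "neighbors",
    "distance_table",
    "bfs_distance",
    "canonical_circular",
    "exhaustive_check",
    "CheckReport",
]

SSO = "sso"
SSR_ONLY = "ssr_only"

# State-space guards: 2^7 * 7! ~ 6.5e5 signed states, 8! ~ 4e4 unsigned.
MAX_SIGNED_N = 7
MAX_UNSIGNED_N = 8


@dataclass(frozen=True)
class ModelSpec:
    """Which sorting problem the oracle (or a scramble) should emulate."""

    topology: str = LINEAR
    signedness: str = SIGNED
    moves: str = SSO
    cyclic_moves: bool = True

    def __post_init__(self) -> None:
        if self.topology not in (LINEAR, CIRCULAR):
            raise TopologyError(f"unknown topology {self.topology!r}")
        if self.signedness not in (SIGNED, UNSIGNED):
            raise ModelError(f"unknown signedness {self.signedness!r}")
        if self.moves not in (SSO, SSR_ONLY):
            raise ModelError(f"unknown move set {self.moves!r}")
        if self.topology == CIRCULAR and not self.cyclic_moves:
            raise ModelError("circular topology implies cyclic moves")
        if self.signedness == UNSIGNED and self.moves == SSR_ONLY:
            raise ModelError("on unsigned permutations reversals and "
                             "transpositions coincide; use moves='sso'")

    @property
    def max_n(self) -> int:
        return MAX_SIGNED_N if self.signedness == SIGNED else MAX_UNSIGNED_N


def legal_operations(n: int, model: ModelSpec) -> List[Operation]:
    """Every allowed SSO for an n-element permutation under the model."""
    ops: List[Operation] = []
    signed = model.signedness == SIGNED
    if signed:
        ops += [Operation(REVERSAL, (i, i)) for i in range(1, n + 1)]
    for p in range(1, n):
        if signed:
            ops.append(Operation(REVERSAL, (p, p + 1)))
        if model.moves == SSO or not signed:
            ops.append(Operation(TRANSPOSITION, (p, p + 1, p + 2)))
    if model.cyclic_moves and n >= 2:
        if signed:
            ops.append(Operation(REVERSAL, (n, 1), cyclic=True))
        if model.moves == SSO or not signed:
            ops.append(Operation(TRANSPOSITION, (n, 1, 2), cyclic=True))
    return ops


def canonical_circular(state: Tuple[int, ...], signedness: str = SIGNED) -> Tuple[int, ...]:
    """Lexicographically smallest representative of a circular state among
    all rotations and reversed (sign-negated, if signed) rotations."""
    n = len(state)
    neg = 1 if signedness == UNSIGNED else -1
    rev = tuple(neg * v for v in reversed(state))
    return min(
        min(state[r:] + state[:r] for r in range(n)),
        min(rev[r:] + rev[:r] for r in range(n)),
    )


def _state_perm(state: Tuple[int, ...], model: ModelSpec) -> SignedPermutation:
    # Neighbor generation always acts on a linear representative.
    return SignedPermutation(state, LINEAR, model.signedness)


def neighbors(pi: SignedPermutation, model: ModelSpec) -> Set[SignedPermutation]:
    """All states one allowed operation away, deduplicated; circular states
    are canonicalized by rotation/reflection."""
    if pi.n > model.max_n:
        raise CapacityError(f"n={pi.n} exceeds oracle bound {model.max_n}")
    out: Set[Tuple[int, ...]] = set()
    for op in legal_operations(pi.n, model):
        state = op.apply(_state_perm(pi.entries, model)).entries
        if model.topology == CIRCULAR:
            state = canonical_circular(state, model.signedness)
        out.add(state)
    topo = model.topology
    return {SignedPermutation(s, topo, model.signedness) for s in out}


@lru_cache(maxsize=None)
def distance_table(n: int, model: ModelSpec) -> Dict[Tuple[int, ...], int]:
    """BFS distances from the identity (class) to every reachable state."""
    if n > model.max_n:
        raise CapacityError(f"n={n} exceeds oracle bound {model.max_n}")
    circular = model.topology == CIRCULAR
    sgn = model.signedness
    ident = tuple(range(1, n + 1))
    start = canonical_circular(ident, sgn) if circular else ident
    # Decompose the legal SSOs into raw tuple edits: sign flips at one
    # 0-based index, and adjacent-pair swaps (0-based, possibly negating).
    flips: List[int] = []
    swaps: List[Tuple[int, int, bool]] = []
    for op in legal_operations(n, model):
        p = op.swap_left_position(n)
        if p is None:
            flips.append(op.positions[0] - 1)
        else:
            negate = op.kind == REVERSAL and sgn == SIGNED
            swaps.append((p - 1, p % n, negate))
    swaps = sorted(set(swaps))
    dist = {start: 0}
    queue = deque([start])
    while queue:
        s = queue.popleft()
        d = dist[s] + 1
        for i in flips:
            t = s[:i] + (-s[i],) + s[i + 1:]
            if circular:
                t = canonical_circular(t, sgn)
            if t not in dist:
                dist[t] = d
                queue.append(t)
        for a, b, negate in swaps:
            lst = list(s)
            if negate:
                lst[a], lst[b] = -s[b], -s[a]
            else:
                lst[a], lst[b] = s[b], s[a]
            t = tuple(lst)
            if circular:
                t = canonical_circular(t, sgn)
            if t not in dist:
                dist[t] = d
                queue.append(t)
    return dist


def bfs_distance(pi: SignedPermutation, model: ModelSpec) -> int:
    """Shortest number of allowed operations from pi to the identity (class)."""
    table = distance_table(pi.n, model)
    state = pi.entries
    if model.topology == CIRCULAR:
        state = canonical_circular(state, model.signedness)
    return table[state]


def all_states(n: int, model: ModelSpec) -> List[SignedPermutation]:
    """Every state of the model's space (canonical classes when circular)."""
    if model.topology == CIRCULAR:
        return [
            SignedPermutation(s, CIRCULAR, model.signedness)
            for s in sorted(distance_table(n, model))
        ]
    out = []
    for base in itertools.permutations(range(1, n + 1)):
        if model.signedness == UNSIGNED:
            out.append(SignedPermutation(base, LINEAR, UNSIGNED))
            continue
        for signs in itertools.product((1, -1), repeat=n):
            out.append(
                SignedPermutation(tuple(s * v for s, v in zip(signs, base)), LINEAR)
            )
    return out


@dataclass
class CheckReport:
    """Outcome of an exhaustive algorithm-vs-BFS comparison."""

    n: int
    model: ModelSpec
    checked: int = 0
    mismatches: List[Tuple[SignedPermutation, int, int]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.mismatches

    def __str__(self) -> str:
        head = f"n={self.n} {self.model.signedness} {self.model.topology} " \
               f"{self.model.moves}{' cyclic' if self.model.cyclic_moves else ''}: " \
               f"{self.checked} states checked"
        if self.ok:
            return head + ", no mismatches"
        lines = [head + f", {len(self.mismatches)} MISMATCHES"]
        for pi, expect, got in self.mismatches[:20]:
            lines.append(f"  {pi}: bfs={expect} algorithm={got}")
        return "\n".join(lines)


def algorithmic_distance(pi: SignedPermutation, model: ModelSpec) -> int:
    """The polynomial/closed-form distance matching the model."""
    from . import distance as dist_mod
    from . import related

    if model.topology == CIRCULAR:
        if model.signedness == SIGNED and model.moves == SSO:
            return dist_mod.circular_distance(pi).distance
        raise ModelError(f"no algorithmic counterpart wired for {model}")
    if model.signedness == UNSIGNED:
        if model.cyclic_moves:
            return related.unsigned_cyclic_distance(pi)
        return related.inversion_count(pi)
    if model.moves == SSR_ONLY:
        if model.cyclic_moves:
            return related.cyclic_ssr_distance(pi)
        raise ModelError(f"no algorithmic counterpart wired for {model}")
    if model.cyclic_moves:
        return dist_mod.linear_cyclic_distance(pi).distance
    return related.linear_signed_sso_distance(pi)


def exhaustive_check(n: int, model: ModelSpec) -> CheckReport:
    """Compare the algorithmic distance against BFS on every state of size n."""
    report = CheckReport(n, model)
    for pi in all_states(n, model):
        expect = bfs_distance(pi, model)
        got = algorithmic_distance(pi, model)
        report.checked += 1
        if got != expect:
            report.mismatches.append((pi, expect, got))
    return report
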