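"""Closed-form SSO distances for the previously solved model variants.

Four problems around the core cyclic-SSO model have classical solutions:

* unsigned linear, SSOs: the inversion count ``inv(pi)`` (Knuth);
* signed linear, SSOs: ``inv(pi)`` plus the number of odd components of the
  inversion graph (Galvao et al.);
* unsigned linear, cyclic SSOs: the minimum crossing number ``cn(pi)`` over
  all valid displacement vectors (Jerrum);
* signed linear, cyclic super short reversals only: ``cn(X) + k`` where k
  counts elements that are negative with even ``|x_i|`` or positive with odd
  ``|x_i|`` (Galvao et al.).

These serve both as standalone distances and as cross-checks for the cyclic
SSO algorithm.
"""

from __future__ import annotations

from typing import FrozenSet, Tuple

import networkx as nx

from .displacement import (
    DisplacementVector,
    crossing_number,
    initial_vd,
    minimize_crossing,
)
from .distance import full_S_closure
from .perm import SignedPermutation

__all__ = [
    "inversion_count",
    "inversion_graph",
    "linear_signed_sso_distance",
    "unsigned_cyclic_distance",
    "cyclic_ssr_distance",
    "sign_parity_classes",
]


def inversion_count(pi: SignedPermutation) -> int:
    """Number of pairs i < j with ``|pi_i| > |pi_j|`` (signs ignored)."""
    a = [abs(v) for v in pi.entries]
    return sum(
        1 for i in range(len(a)) for j in range(i + 1, len(a)) if a[i] > a[j]
    )


def inversion_graph(pi: SignedPermutation) -> nx.Graph:
    """IG(pi): vertices are the signed elements, edges are the inversion pairs."""
    g = nx.Graph()
    g.add_nodes_from(pi.entries)
    e = pi.entries
    for i in range(len(e)):
        for j in range(i + 1, len(e)):
            if abs(e[i]) > abs(e[j]):
                g.add_edge(e[i], e[j])
    return g


def _odd_components(g: nx.Graph) -> int:
    return sum(
        1 for c in nx.connected_components(g)
        if sum(1 for v in c if v < 0) % 2 == 1
    )


def linear_signed_sso_distance(pi: SignedPermutation) -> int:
    """Signed linear SSO distance: ``inv(pi)`` swaps plus one 1-reversal per
    odd component of the inversion graph."""
    return inversion_count(pi) + _odd_components(inversion_graph(pi))


def unsigned_cyclic_distance(pi: SignedPermutation) -> int:
    """Unsigned cyclic-SSO distance: the minimum crossing number ``cn(pi)``."""
    return crossing_number(minimize_crossing(initial_vd(pi)))


def sign_parity_classes(
    X: DisplacementVector, pi: SignedPermutation
) -> Tuple[FrozenSet[int], FrozenSet[int]]:
    """``neven``: negative elements with even |x_i|; ``podd``: positive
    elements with odd |x_i|.  Each such element needs a sign-fixing
    1-reversal when only reversals are allowed (a 2-reversal flips the sign
    at every move, so an element's final sign is set by the parity of its
    move count)."""
    neven = frozenset(
        v for v, x in zip(pi.entries, X.x) if v < 0 and abs(x) % 2 == 0
    )
    podd = frozenset(
        v for v, x in zip(pi.entries, X.x) if v > 0 and abs(x) % 2 == 1
    )
    return neven, podd


def cyclic_ssr_distance(pi: SignedPermutation) -> int:
    """Signed cyclic super-short-reversal distance: ``cn(X) + |neven u podd|``
    for a minimum-cn vector X.

    Because ``|neven u podd|`` may depend on which minimum-cn vector is
    chosen, the value is minimized over the whole set of minimum-cn vectors
    (reachable from the contracted fixed point by cn-preserving moves);
    this is never larger than the value of any single choice.
    """
    X0 = minimize_crossing(initial_vd(pi))
    cn = crossing_number(X0)
    best = None
    for X in full_S_closure(X0):
        neven, podd = sign_parity_classes(X, pi)
        k = len(neven | podd)
        if best is None or k < best:
            best = k
    return cn + best
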