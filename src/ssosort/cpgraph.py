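"""The cyclic permutation graph (cp-graph).

The displacement-vector calculus ignores signs.  The cp-graph ``G^X_pi``
puts them back: its vertices are the signed elements of ``pi`` and two
elements are joined (with weight ``|c_ij(X)|``) whenever the chosen vector
makes them cross.  The total edge weight equals ``cn(X)``.  A connected
component is *odd* if it contains an odd number of negative elements; each
odd component costs exactly one extra 1-reversal in any scenario realizing
X, so the sorting distance attached to X is ``cn(X) + cc-``, where ``cc-``
counts odd components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Tuple

import networkx as nx

from .displacement import DisplacementVector, crossing_value, validate_vd
from .errors import ValidityError
from .perm import SignedPermutation

__all__ = ["CPGraph", "build", "odd_components", "to_dot"]


@dataclass(frozen=True)
class CPGraph:
    """Weighted cp-graph together with its component decomposition.

    Vertices are identified by signed element value (as in the figures of
    the literature on this problem), not by position.
    """

    permutation: SignedPermutation
    vector: DisplacementVector
    graph: nx.Graph

    @property
    def components(self) -> Tuple[FrozenSet[int], ...]:
        return tuple(frozenset(c) for c in nx.connected_components(self.graph))

    @property
    def component_count(self) -> int:
        return nx.number_connected_components(self.graph)

    def weight_sum(self) -> int:
        return sum(w for _, _, w in self.graph.edges.data("weight"))

    def odd_component_count(self) -> int:
        return sum(
            1 for c in nx.connected_components(self.graph)
            if sum(1 for v in c if v < 0) % 2 == 1
        )


def build(pi: SignedPermutation, X: DisplacementVector) -> CPGraph:
    """Build ``G^X_pi``: edge {pi_i, pi_j} with weight |c_ij| for every
    crossing pair (c_ij(X) > 0 in the positively-signed orientation)."""
    if not validate_vd(X, pi):
        raise ValidityError(f"{X} is not a valid displacement vector for {pi}")
    g = nx.Graph()
    g.add_nodes_from(pi.entries)
    n = pi.n
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            c = crossing_value(X, i, j)
            if c != 0:
                g.add_edge(pi.entries[i - 1], pi.entries[j - 1], weight=abs(c))
    return CPGraph(pi, X, g)


def odd_components(g: CPGraph) -> int:
    """``cc-``: number of components with an odd count of negative elements."""
    return g.odd_component_count()


def to_dot(g: CPGraph) -> str:
    """Export the weighted graph in DOT format (for figure reproduction)."""
    lines = ["graph cp {"]
    for v in g.graph.nodes:
        lines.append(f'  "{v:+d}";')
    for u, v, w in g.graph.edges.data("weight"):
        lines.append(f'  "{u:+d}" -- "{v:+d}" [label={w}];')
    lines.append("}")
    return "\n".join(lines)
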