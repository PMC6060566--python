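# Methods

## Model and assumptions

A genome is a signed permutation of `{1..n}`: no duplicated genes, one
chromosome, gene orientation encoded by the sign.  The allowed events are
the super short operations (SSOs): 1-reversals (one sign flip),
2-reversals (adjacent exchange, both signs flip) and 2-transpositions
(adjacent exchange, no sign change).  *Cyclic* SSOs may also act on the
pair formed by positions `n` and `1`.  The sorting distance of a model is
the length of a shortest sequence of allowed operations reaching the
positive identity.  Six model variants are implemented:

| model                      | distance                                                 |
|----------------------------|----------------------------------------------------------|
| unsigned linear, SSOs      | inversion count `inv(π)`                                 |
| unsigned linear, cyclic    | minimum crossing number `cn(π)`                          |
| signed linear, SSOs        | `inv(π)` + odd components of the inversion graph         |
| signed linear, cyclic SSRs | `cn(X) + |neven ∪ podd|`, minimized over minimum-cn `X`  |
| signed linear, cyclic SSOs | `min cn(X) + cc⁻(G^X_π)` over `S ∪ S′` (the core method) |
| signed circular, SSOs      | min of the previous row over the `2n` linearizations     |

The first four rows are classical closed forms and serve as standalone
features and cross-checks; the last two are the package's core algorithm.

## Displacement vectors and crossing numbers

A valid displacement vector (VD-vector) `X` for `π` satisfies `Σxᵢ = 0`
and `|πᵢ| − xᵢ ≡ i (mod n)`.  The crossing value `c_ij(X)` counts the
multiples of `n` in the closed interval between `r = i − j` and
`s = (i + xᵢ) − (j + xⱼ)` (negated when `r > s`); `cn(X) = ½Σ|c_ij|`.
All positions are 1-based at every public interface.  Crossing values are
always recomputed from scratch after a vector mutation (an `O(n²)` cost
that is irrelevant at the sizes this tool targets); the incremental
`swap_update` rule is validated against full recounts in the tests.

**Induced swaps are directional.**  The swap on the adjacency
`(p, q = p mod n + 1)` is induced by `X` iff `c_pq(X) > 0` *strictly*.  A
negative `c_pq` means the crossing between those two elements happens in
the other cyclic direction; applying the swap at `(p, q)` in that case
*increases* the crossing number (e.g. `X = (−1, 1)` on `(2 1)`, `n = 2`:
the sorting swap is the wrap move at adjacency `(2, 1)`, not the direct
one at `(1, 2)`).

## The conservation law and its validity regime

The transformation `T_{i,j}` shifts `xᵢ` by `−n` and `xⱼ` by `+n`.  The
classical conservation law

```
cn(T_{i,j}(X)) = cn(X) + 2(n − xᵢ + xⱼ)
```

is exact **only** when, before the move, `πᵢ` crosses every other element
at most once and only rightward (`c_ib ∈ {0,1}`), `πⱼ` at most once and
only leftward (`c_jb ∈ {−1,0}`), and `c_ij = 1`.  This follows from
summing the per-pair changes `|c ∓ 1| − |c|`, and the package's tests
verify it both ways: the law holds on every random vector/pair meeting the
side conditions, and a concrete counterexample outside them is pinned as a
regression test — transforming the zero vector of `ι₃` by `T_{1,2}` gives
`(−3, 3, 0)` with true crossing number 4 (elements 1 and 2 loop once
around the circle and cross each other twice, and each crosses element 3
once), not the 6 the unrestricted law would predict.  Outside the regime
even "strictly contracting implies cn decreases" can fail.

The algorithm never leaves the validity regime, and the package relies
only on properties that hold without caveats:

* **Termination of the minimization.**  Moving a full turn from the
  current maximum entry to the current minimum entry changes the potential
  `Σxₖ²` by `2n(n − (xᵢ − xⱼ)) < 0` whenever `xᵢ − xⱼ > n`, so the loop
  terminates regardless of what `cn` does along the way.
* **Minimality of the fixed point.**  A vector admitting no strictly
  contracting move (`max(X) − min(X) ≤ n`) attains the minimum crossing
  number; this classical result is confirmed here against brute-force BFS
  on every unsigned permutation of `n ≤ 5` and every signed permutation of
  `n ≤ 5` (via the distance formula), plus random `n ∈ {6, 7}`.
* **Laws at the minimum.**  From a minimized vector, transformations with
  `xᵢ − xⱼ = n` preserve `cn` exactly and all others strictly increase it
  (property-tested; no violation in ~1.5 × 10⁵ randomized probes during
  development).  These are the only two facts the candidate-set
  enumeration needs.

## The core algorithm

1. Start from the straight-line vector `xᵢ = |πᵢ| − i` and minimize its
   crossing number by strictly contracting transformations.  Move
   selection: `(argmax x, argmin x)` each round, lowest index on ties —
   any valid selection terminates; this one is deterministic and needs the
   fewest rounds.
2. Enumerate `S` as the fixed point plus its single-step contracting
   images (`xᵢ − xⱼ = n`).  This may miss minimum-cn vectors that need two
   or more transformations, but in exactly those situations some generated
   member has a one-component cp-graph, and such a member is already
   optimal (early exit).  The early exit is bypassed by a debug flag that
   minimizes over the full union, and a BFS closure over cn-preserving
   moves (`full_S_closure`) provides the complete `S` for cross-checks.
3. Otherwise add `S′` (all single-transformation images leaving `S`) and
   return `min cn(X) + cc⁻(G^X_π)` over `S ∪ S′`.  Ties are broken by the
   lexicographically smallest vector, for reproducible witnesses.

Circular permutations: the circle is cut at each of its `n` adjacencies
and read in both orientations.  Reading backward flips the strand of every
gene, so the reflected linearizations negate all signs — the natural
convention for circular DNA, adopted here explicitly since either choice
of "left extremity" must be fixed.  The distance is the minimum over the
`2n` candidates, reporting the first winner in rotation-then-reflection
order.

## Sequence reconstruction

Given any valid vector, a realizing sequence of length
`cn(X) + cc⁻(G^X_π)` is built greedily: scan adjacencies in ascending left
position, apply the first induced swap, preferring a 2-transposition and
switching to a 2-reversal exactly when the default would split an even
component into two odd halves (one of the two types always keeps `cc⁻`
unchanged, because the two types differ only in flipping the signs of the
two touched elements, one per resulting component).  When no induced swap
remains, every element is in place and the leftover negatives — one per
original odd component — are fixed by 1-reversals.  The scan order is an
implementation choice; the contract is the length, not the particular
sequence, and the tests replay every emitted sequence to the identity and
compare its per-element displacement against the witness vector.

## Cyclic super-short-reversal distance

The closed form `cn(X) + |neven(X,π) ∪ podd(X,π)|` reads as if any
minimum-cn vector may be used, but the sign/parity mismatch count can in
principle depend on the choice.  The implementation minimizes over the
complete set of minimum-cn vectors (BFS closure over cn-preserving moves,
with a capacity guard), which is never larger than any single choice; the
exhaustive `n ≤ 4` sweep against the reversal-only BFS oracle confirms the
resulting distances.

## Oracle and scrambles

The BFS oracle runs once from the identity per `(n, model)` and caches the
full distance table (every SSO is undone by an SSO of the same kind, so
the move graph is undirected).  States are signed tuples; circular states
are canonicalized to the lexicographically smallest among all rotations
and sign-negated reflections.  Capacity bounds (`n ≤ 7` signed, `n ≤ 8`
unsigned, ~6.5 × 10⁵ states) fail fast with a dedicated error rather than
exhausting memory.

The scramble generator applies `k` uniformly random legal operations to
the identity from a single seeded stream, so a generated instance has
model distance at most `k`.  Scrambles emulate rearrangement scenarios
only in move *count*: real genomes have biased operation usage and hotspots,
so passing distance tests on scrambles says nothing about biological
realism — correctness against the exhaustive state-space sweeps is the
load-bearing evidence.

## Problem sizes used by the test suite

Exhaustive oracle equivalence covers all 3840 signed linear permutations
of `n = 5` and all circular classes of `n ≤ 5`; 200 random instances cover
`n ∈ {6, 7}` (the full `n = 7` table has 645 120 states and builds in a
few seconds).  The reconstruction contract runs on 500 seeded scrambles
with `n ≤ 10` and up to `3n` operations.  Conservation-law and graph
properties use vectors up to `n = 12`.  These sizes keep the whole suite
under a minute while exhausting the state spaces where exhaustion is
feasible.

## Known limitations

* No multichromosomal genomes, duplicated genes, or unbounded-length
  reversals/transpositions.
* The candidate enumeration is `O(n⁶)` in the worst case, as in the
  underlying theory; fine for gene-order instances of realistic size, not
  tuned for `n` in the thousands.
* `cyclic_ssr_distance` enumerates all minimum-cn vectors; the closure is
  tiny in practice but has no polynomial bound here (capacity-guarded).
* The oracle is a validation device, not a scalable solver.
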