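# ssosort

Sorting distances for signed permutations under **super short operations**
(SSOs) — the genome rearrangements that touch at most two adjacent genes.

## The problem

In comparative genomics, a chromosome without duplicated genes is modelled
as a signed permutation `π = (π₁ π₂ … πₙ)`: `|πᵢ|` identifies the gene,
the sign its strand.  The evolutionary distance between two such genomes is
the minimum number of allowed rearrangements turning one into the other,
which (after relabelling) is the minimum number of operations that *sort* a
permutation into the identity `ιₙ = (+1 +2 … +n)`.  Short rearrangements
are the most frequent in several lineages, which motivates the model where
every event touches at most two adjacent genes:

* **1-reversal** `ρ(i,i)` — flips the sign of one element;
* **2-reversal** `ρ(i,i+1)` — exchanges two adjacent elements, flipping both signs;
* **2-transposition** `τ(i,i+1,i+2)` — exchanges two adjacent elements, signs unchanged.

*Cyclic* variants (`ρ*`, `τ*`) may act across the boundary between
positions `n` and `1`, which is how a circular chromosome is handled: a
circular genome cut at any adjacency, in either orientation, gives `2n`
linear representations, and its distance is the best cyclic-SSO linear
distance among them.

`ssosort` computes exact minimum distances and explicit minimum-length
sorting scenarios for every SSO model variant: linear/circular, signed/
unsigned, with or without transpositions.

## The method

For a sorting scenario made of cyclic swaps, record each element's net
rightward displacement.  A **valid displacement vector** (VD-vector) for π
is any `X ∈ ℤⁿ` with `Σxᵢ = 0` and `|πᵢ| − xᵢ ≡ i (mod n)`.  The
**crossing value**

```
c_ij(X) = ±|{k ∈ [r..s] : k ≡ 0 (mod n)}|,   r = i−j,  s = (i+xᵢ) − (j+xⱼ)
```

counts how often elements `πᵢ, πⱼ` must be swapped in any scenario
realizing X, and the **crossing number** `cn(X) = ½ Σ|c_ij|` is the
scenario's minimum swap count.  The **cp-graph** `G^X_π` joins crossing
elements (edge weight `|c_ij|`); a component is *odd* if it holds an odd
number of negative elements, and each odd component costs one extra
1-reversal.  The distance attached to a vector is

```
d(π, X) = cn(X) + cc⁻(G^X_π)
```

and the sorting distance `d(π)` is its minimum over all valid vectors.
The transformation `T_{i,j}` (shift `xᵢ` by `−n`, `xⱼ` by `+n`) walks the
space of valid vectors; repeatedly applying *strictly contracting* moves
(`xᵢ − xⱼ > n`) reaches the minimum crossing number `cn(π)`, and the
optimal vector always lies in `S` (minimum-cn vectors) or `S′` (their
single-transformation images), which makes the whole computation
polynomial.  The interesting phenomenon — and the reason brute-force
minimum-cn reasoning is not enough — is that the optimal vector may lie
strictly outside `S` (see the 14-element example below).

## Worked example

```
$ ssosort compare "(+5 +4 -2 -1 +3)"
signed-linear-sso         8
signed-linear-cyclic-ssr  6
signed-linear-cyclic-sso  4
signed-circular-sso       2
```

One permutation, four models: 8 SSOs are needed when nothing wraps, 4 when
operations may act across the ends, and only 2 when the genome is circular —
the circular optimum is reached by relinearizing as `(−2 −1 +3 +5 +4)`.

```
$ ssosort sort "(+5 +4 -2 -1 +3)" --model signed-circular-sso
distance: 2
linearization: (-2 -1 +3 +5 +4)
sequence: r(1,2) t(4,5,6)
```

The 14-element permutation
`(-1 -2 +12 -4 -5 -6 -7 +3 +9 +10 +11 +8 -13 -14)` shows why the algorithm
must look beyond minimum-crossing-number vectors:

```python
>>> from ssosort import parse_permutation, linear_cyclic_distance
>>> pi = parse_permutation("(-1 -2 +12 -4 -5 -6 -7 +3 +9 +10 +11 +8 -13 -14)")
>>> res = linear_cyclic_distance(pi)
>>> res.distance
18
>>> res.witness_vector
DisplacementVector(x=(0, 0, -5, 0, 0, 0, 0, -5, 0, 0, 0, 10, 0, 0))
```

Both minimum-cn vectors cost `16 + 4 = 20`; the winning vector spends two
extra swaps (`cn = 18`) to merge every odd component away.

A brute-force BFS oracle double-checks everything at small sizes:

```
$ ssosort oracle --n 5
n=5 signed linear sso cyclic: 3840 states checked, no mismatches
```

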