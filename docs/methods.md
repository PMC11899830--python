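# Methods

## The connection number and the descriptor family

For a simple connected undirected graph Ω = (V, E) — here always a
hydrogen-suppressed molecular graph, vertices = heavy atoms, edges = bonds —
the *connection number* of a vertex v is

    con(v) = |{ u ∈ V : dis(v, u) = 2 }|,

the count of vertices at shortest-path distance exactly two.  The package
computes con(v) with a two-level breadth-first sweep (union of the neighbors'
neighborhoods, minus N(v) and v), which avoids materializing the distance
matrix; the distance-matrix definition is retained as an independent oracle
in the test suite and in the acceptance script's self-check.

For graphs with girth ≥ 5 (all benzenoids: girth 6) the identity
con(v) = Σ_{u∈N(v)} deg(u) − deg(v) holds and is asserted as a fixture
invariant.

Sixteen descriptors are built on con.  Writing (x, y) = (con(i), con(j)) for
an edge ij, the edge functionals are

| id       | per-edge term               | id    | per-edge term              |
|----------|-----------------------------|-------|----------------------------|
| MC1      | x + y                       | AZIC  | (xy / (x+y−2))³            |
| MC2      | x·y                         | GAC   | 2√(xy) / (x+y)             |
| PC1      | Π (x + y)  (product)        | AGC   | (x+y) / 2√(xy)             |
| PC2      | Π x·y  (product)            | RRC   | √(xy)                      |
| RC       | 1/√(xy)                     | RRRC  | √((x−1)(y−1))              |
| RC_Bβ    | (xy)^β                      | SOC   | √(x² + y²)                 |
| SCC      | 1/√(x+y)                    | MDC1  | Σ_v deg(v)·con(v) (vertex) |
| SCC_Bβ   | (x+y)^β                     |       |                            |

RC ≡ RC_B(−1/2), SCC ≡ SCC_B(−1/2); at β = 1 the families reduce to MC2 and
MC1 respectively (asserted as exact integer equalities).  β is any nonzero
real; the conventional screening grid is β ∈ {±1, ±2}.

### Numerical conventions

* MC1, MC2, PC1, PC2 and MDC1 are evaluated in exact integer arithmetic.
  PC values reach ~2·10³⁶ on coronene; they are kept as Python integers
  end-to-end and written to CSV as full decimal numerals (object dtype).
* Integer-β family members are accumulated as exact rationals
  (`fractions.Fraction`) and converted once at the end; non-integer β and the
  irrational functionals are summed as floats **over the sorted edge list**,
  so repeated runs are bit-identical.
* Undefined edge terms (con product 0 under a negative exponent or a division,
  con sum 2 for AZIC, con sum 0 for GAC, con < 1 for RRRC): `strict` mode
  (default) raises a domain error naming the offending edge and connection
  pair; `permissive` mode skips the edge and reports the skip count.  Strict
  is the default because silent skipping corrupts cross-compound comparisons
  unnoticed.  The packaged benzenoid set never triggers either path (its
  connection numbers are all ≥ 2).

## The benzenoid fixture set

The 22 lower benzenoid hydrocarbons are packaged as plain-text edge lists
generated from hexagonal-lattice cell layouts (axial coordinates; adjacent
cells share an edge, shared corners are merged).  The layouts live in
`conntopo.fixtures.BH_CELLS` and a test regenerates every packaged file
byte-identically.  Linear acenes additionally have a direct constructor
(`build_acene`: two paths of 2n+1 vertices plus n+1 rungs) that is checked
isomorphic to the cell-built graphs.

Each skeleton was validated against the published reference table of
Mc1/Mc2/Πc1/Πc2 values: integer equality for the plain indices, agreement at
the six printed significant digits for the multiplicative ones.  All 22 rows
reproduce exactly, with one exception:

**Anthanthrene.**  The published reference row for anthanthrene repeats
anthracene's values (Mc1 = 104 on a C22H12 skeleton is impossible: the correct
graph, 22 vertices / 27 edges, gives Mc1 = 216, Mc2 = 454).  The package
therefore ships both the correct skeleton (default) and an `as-published`
variant that substitutes anthracene's graph, selected via
`load_bh22(anthanthrene=...)`.  Every statistic of the original screening
study that involves recomputed descriptors (ρ = 0.9336, r² = 0.8716,
s = 0.2644, LOOCV RMSE = 0.2800 for SCc at β = −1) reproduces at printed
precision **only** with the as-published variant — with the corrected
skeleton ρ rises to 0.9915 — so the original analysis demonstrably used the
erroneous structure.  The acceptance script reports the as-published values
for those targets and the test suite evaluates both variants.

Two further published numbers do not survive recomputation and are treated as
data errors (documented, excluded from assertions): the screening correlation
printed for RC (0.7947; the defining formula gives 0.9335, which would place
RC second in the descriptor ranking), and the Δhf term of the printed SCc−1
regression model (printed 0.0018 ± 0.0094; recomputation of the same model —
whose every other coefficient, CI, r² and s match — gives 0.0056 ± 0.0055).
Likewise the published worked augmented-Zagreb example is internally
inconsistent: on the caption's 8-vertex graph the terminal edge has
connection pair (1, 1), so the AZIC term divides by zero; only the worked
connection number con(v4) = 3 is used as ground truth.

The 25-compound coumarin property table (11 physicochemical properties) is
packaged as CSV; the corresponding structures exist only as drawings in the
source material and are therefore accepted as user-supplied edge lists rather
than packaged.  Both CSVs are frozen by checksum tests.

## Statistical battery

* **MLC screening.**  The multiple linear correlation of a descriptor Y
  against the two test properties (normal boiling point ρbp in °C and
  standard heat of formation Δhf) is ρ = √R² of the OLS fit
  Y = a + b·ρbp + c·Δhf.  The direction (descriptor as response) follows the
  published model equations.  The equivalent pairwise-correlation closed form
  √((r²_y1 + r²_y2 − 2 r_y1 r_y2 r_12)/(1 − r²_12)) is a test oracle, not the
  implementation.
* **MLR.**  OLS with intercept (statsmodels); 95% confidence intervals are
  t-based half-widths t(0.975, n−p−1)·SE; s² = SSE/(n−p−1);
  F = (R²/p)/((1−R²)/(n−p−1)).
* **LOOCV.**  Explicit refit loop: each sample is predicted from an OLS fit
  on the remaining n−1; RMSE over the n held-out errors.  The hat-matrix
  shortcut e_i/(1−h_ii) is kept exclusively as an independent oracle
  (agreement ≤ 1e−10 asserted).
* **Polynomial models.**  Degrees 1–3 on raw powers of the descriptor, so
  reported coefficients read directly as the printed model equations;
  orthogonalization is deliberately not used.  A design condition number
  above 1e10 triggers a warning (expected for the huge multiplicative
  indices).  R² grids over (descriptor × property × degree) record failed
  cells as NaN with reasons.  Model nesting (R² non-decreasing in degree) is
  asserted as a property test.
* **Ranking.**  Descending ρ, ties broken by descriptor registry order.  No
  multiple-testing correction is applied anywhere (none in the reproduced
  analysis).

## Synthetic test-data generator

`random_connected_graph(n, m, seed)` draws a random recursive tree plus
uniformly chosen extra edges — reproducible per seed, guaranteed connected
and simple.  It emulates only the *graph-theoretic* preconditions of the
descriptors (connectivity, simplicity, size); it makes no attempt at chemical
realism (no degree cap, no planarity, no ring-size constraints), so property
tests passing on it demonstrate algorithmic correctness, not chemical
validity of the descriptors.  Oracle sweeps use ~100 graphs of up to 12
vertices, where the distance-matrix reference is instant.

## Problem sizes and runtime

All reproduced statistics use the full 22-compound benzenoid set (graphs of
6–24 vertices); descriptor evaluation is microseconds per graph and the
entire battery plus test suite completes in a few seconds on one CPU.  No
downloads are performed at any point; every input is packaged or generated.

## Known limitations

* The dibenzo[a,h]/[a,i]pyrene and dibenzo[a,h]/[a,j]anthracene pairs are
  index-degenerate (identical values for every packaged reference column), so
  their name-to-layout assignment rests on the drawn geometry alone.
* The coumarin modeling machinery is fully implemented and tested on
  synthetic data, but the published coumarin R² grids cannot be reproduced
  without the 25 structures, which are not machine-readable in the source.
* Descriptors are undefined on edges with zero connection numbers (K2 and
  stars are the smallest offenders); strict mode surfaces this rather than
  defining the terms to 0.
* The SMILES adapter ignores bond order, charge and stereochemistry by
  design; it is a convenience for skeleton extraction only.
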