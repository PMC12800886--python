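# Nestedness and specialization metrics: frozen definitions

This file fixes the exact formulas, constants and tie rules implemented
in `grazenet.nestedness` and `grazenet.specialization`. The hand-worked
oracles in the test suite are computed from these statements.

Throughout, the input is a non-negative matrix `W` (rows = grazers,
columns = ASVs); `B = (W > 0)` is its binary form; a row/column *fill*
is its number of nonzero cells, its *total* the sum of its weights.

## NODF (binary; `nodf`)

For every positional pair i < j of rows (and of columns), the pair term
is

    0                                  if fill(j) >= fill(i) or fill(j) = 0
    100 * |B_i AND B_j| / fill(j)      otherwise (strictly decreasing fill)

NODF is the mean of all `nr(nr-1)/2 + nc(nc-1)/2` pair terms.
`variant="as_is"` scores the matrix in the given order; `"sorted"` (the
NODF2 dialect) first sorts rows and columns by decreasing fill, ties
broken by original index (stable sort).

## Weighted NODF (`weighted_nodf`)

Rows and columns are sorted by decreasing fill, ties by decreasing
total, remaining ties by original index. The pair term keeps the
strictly-decreasing-fill gate of NODF, but the poorer member scores the
fraction of its links *strictly dominated* by the richer member:

    100 * |{k : 0 < W_jk < W_ik}| / fill(j)

Equal-weight overlaps therefore score zero. (This reproduces the
fill-sorted, strict-inequality convention of vegan's `nestednodf`
`weighted=TRUE`, against which the implementation was cross-checked.)

## WNODA (`wnoda`)

Same strict-domination pair term, but pairs are ranked directly by
marginal totals — decreasing abundance — with no positional sorting
requirement: for each unordered pair, the member with the strictly
smaller total is the "poorer" one; pairs with equal totals score 0.
Mean over all row pairs and column pairs, range [0, 100].

## WINE (`wine`)

1. Canonically order rows and columns by decreasing totals (ties by
   descending lexicographic content, iterated to a fixed point), so the
   generalist corner is at (0, 0).
2. Every link at sorted position (i, j) (0-indexed) has Euclidean
   distance `d_ij = sqrt(i^2 + j^2)` to the corner.
3. `d_w    = sum(W_ij * d_ij) / sum(W_ij)` over links (observed).
   `d_rnd  = mean(d_ij over all cells)` (random placement expectation).
   `d_pack = ` same statistic with the link weights packed maximally:
   heaviest weights assigned to the cells with smallest distances.
4. `eta = (d_rnd - d_w) / (d_rnd - d_pack)`: ~1 maximally nested,
   ~0 random, negative anti-nested; undefined (None) when
   `d_rnd = d_pack`.

Both the raw `d_w` and `eta` are reported; published WINE values on
other scales are not directly comparable.

## Matrix temperature (`matrix_temperature`)

Cell (i, j) of an r x c matrix sits at normalised position
`x = (j+0.5)/c`, `y = (i+0.5)/r` from the packed top-left corner. The
isocline of perfect nestedness at fill phi is the superellipse
`x^p + y^p = 1` with p solved (Brent) from the filled area
`Gamma(1+1/p)^2 / Gamma(1+2/p) = phi`. A cell is *unexpected* if it is
a presence outside the filled side or an absence inside it; its
contribution is `u = (d/D)^2`, with d the distance to the isocline
along the cell's (1,1) diagonal and D that diagonal's length inside
the unit square. The temperature of an ordering is

    T = 100 * sum(u) / (0.04145 * r * c)     (clamped to [0, 100])

with 0.04145 the Atmar-Patterson normalisation constant. Rows and
columns are reordered to minimise T: decreasing-fill warm start, then
simulated annealing over random row/column swaps (geometric schedule
0.5 -> 1e-4, default 20 000 proposals, seeded generator). Temperature
implementations in the literature differ in isocline geometry and
packing; values here are internally consistent and deterministic given
a seed, and satisfy T = 0 for perfectly nested matrices and T > 50 for
checkerboards.

## Discrepancy (`discrepancy`)

With columns in a fixed order, a row with k presences should occupy the
first k columns; the discrepancy is the number of presences outside
those positions, summed over rows — the minimum number of presences to
relocate to reach perfect nestedness with row fills conserved.
`variant="fixed_order"` keeps the given column order; `"fill_sorted"`
(the discrepancy2 dialect) first sorts columns by decreasing totals,
ties by original index. No tie-order optimisation is performed.

## H2' (`h2_prime`)

Weights are scaled to `precision` (default 1000) total units and
rounded; H2 = Shannon entropy of the integer matrix. H2_max / H2_min
are the extreme entropies over all non-negative integer matrices with
the same marginals, found by greedy construction (proportional fill for
the max; pack-largest-cells-first for the min) followed by steepest
2x2-swap refinement, additionally seeded from the observed matrix; the
observed entropy always brackets the result. H2' =
(H2_max - H2)/(H2_max - H2_min), clipped to [0, 1]; undefined when
H2_max = H2_min. Exhaustive enumeration over all integer matrices with
total <= 12 confirms the search in the test suite.

## d' (`d_prime`)

For row i: `d_i = sum_j p_ij ln(p_ij / q_j)` with `p_ij = W_ij / A_i`
(the row's interaction distribution) and `q_j = C_j / W` (partner
availability). `d'_i = d_i / ln(W / A_i)`, clipped to [0, 1]; the
continuous lower bound d_min = 0 is used (a row with continuous weights
can always match availability exactly). Rows with no interactions are
undefined (NaN), as is a row that constitutes the entire network.
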