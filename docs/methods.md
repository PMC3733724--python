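# Methods

## Setting

Two raters independently classify the same n items into the same k
ordered categories, giving a square table with cells n_ij, row marginals
n_i. (rater A), column marginals n_.j (rater B) and total n. The package
estimates chance-corrected agreement and draws the agreement chart; it
deliberately stops short of inference (no standard errors, confidence
intervals or hypothesis tests) and of multi-rater generalisations.

All statistics assume the category order is meaningful: partial credit
and the chart both use the index distance d = |i - j|, which is the only
defensible disagreement metric on an ordinal scale. Permuting categories
changes the weighted statistics and the chart (the unweighted kappa and
B are permutation-invariant; the test suite asserts both directions).

## Statistics

Observed and chance agreement: Po = sum_i n_ii / n,
Pe = sum_i n_i. n_.i / n^2.

Cohen's kappa: (Po - Pe)/(1 - Pe). The weighted form substitutes
Po_w = sum_ij w_ij n_ij / n and Pe_w = sum_ij w_ij n_i. n_.j / n^2.

Bangdiwala's B: sum_i n_ii^2 / sum_i n_i. n_.i. The weighted form
credits the incremental partial-agreement band areas: the order-b
rectangle for category i spans the cells at most b categories off the
diagonal (width = column cells, height = row cells), A_0i = n_ii^2, and
A_bi is the area increment from order b-1 to b; then
B_w = sum_i (n_ii^2 + sum_{b>=1} w_b A_bi) / sum_i n_i. n_.i. The band
areas telescope to the marginal rectangle area, so B_w = 1 under an
all-ones weight vector and B_w = B under the unweighted scheme.

Weight schemes (`WeightScheme`): unweighted (identity), linear
(Cicchetti-Allison, w = 1 - d/(k-1)) and quadratic (Fleiss-Cohen,
w = 1 - d^2/(k-1)^2). Quadratic is the package default and the scheme
under which the bundled reference values were published; the same band
weights w_b govern both weighted kappa and weighted B. Custom weight
matrices are accepted if symmetric, unit-diagonal, in [0, 1] and a
function of d only.

Degenerate input: when both raters put every item in one and the same
category, Pe = 1 and kappa is 0/0. `cohen_kappa` raises
`DegenerateTableError`; `summarize`/`fit` return a flagged result with
kappa = None rather than NaN. B remains defined (and equals 1) there.

## Qualitative labels

`interpret` maps a statistic to a label via a configurable band table.
The defaults (<=0 poor, then slight / fair / moderate / substantial /
almost perfect in 0.2 steps) follow the common agreement-strength
convention; they are a documented stand-in, not a universal standard,
and callers can supply their own cutoffs.

## Chart geometry

Axis convention, fixed once: column rater on x, row rater on y, origin
bottom-left, categories increasing up and to the right. Rectangle i has
width n_.i and height n_i., its lower-left corner at the previous
rectangle's upper-right corner, so the rectangles tile the diagonal
corridor from (0,0) to (n,n). The dark square of side n_ii sits inside
rectangle i offset by the preceding off-diagonal cells
(sum_{j<i} n_ji along x, sum_{j<i} n_ij along y); band rectangles nest
around it with strictly lighter shading per unit of distance. Geometry
is kept in exact count units — rounding happens only at render time — so
two area identities hold to machine precision and are enforced in tests:
the dark-area ratio of a layout equals B, and the shade-weighted area
ratio under a scheme's band weights equals B_w.

Bias: the path of rectangles is the polyline through the rectangle
corners, i.e. through the joint cumulative marginals
(sum_{j<=i} n_.j, sum_{j<=i} n_i.). `bias_deviation` integrates the
signed area between the path and the 45-degree diagonal and normalises
by n^2/2, so it lies in [-1, 1]: positive means the path runs above the
diagonal (the row rater accumulates counts in the lower categories
faster), zero iff the raters' marginals are homogeneous at every
category cut; transposing the table flips the sign. Published verbal
chart readings for these datasets describe each figure relative to
whichever rater the narrative names, and the two directions cannot both
be mapped onto one fixed convention; the signed statistic here is the
unambiguous replacement, with the convention above locked and
documented.

Rendering: SVG is written directly (stdlib ElementTree) with
`class`/`data-*` attributes on every element so charts are testable by
parsing; zero-count marginal rectangles are drawn zero-width (never
dropped) and zero-sided dark squares are omitted. PNG goes through
matplotlib. Styles (shade ramp endpoints, colors, pixel size) are a
small dataclass settable from key=value options.

## Simulator

`RatingModel` is a joint probability matrix p_ij over category pairs; a
table is one multinomial draw of n items into the k^2 cells
(numpy default_rng / PCG64, seed recorded in the model metadata).
Helpers build the two structures the tests rely on: rater independence
(p_ij = p_i q_j, population kappa exactly 0) and diagonal inflation (a
mixture putting probability `agreement` on exact agreement). Population
values of every statistic come from evaluating the same formulas
directly on p_ij — valid because all statistics are invariant to scaling
the cells by a positive constant — and sample statistics converge to
them; tests check recovery at n = 1e5 with tolerance 0.02, consistent
with multinomial sampling error at that size. The simulator emulates
exchangeable items with a common joint distribution; it does not model
item-difficulty heterogeneity, rater drift over time, or missing
ratings, so passing recovery tests says nothing about those features of
real data.

## Numerical and testing choices

- Statistics are computed in double precision from exact integer counts;
  the geometry/statistic identities are asserted at 1e-12.
- An independent brute-force oracle (pure Python loops, no shared code)
  must agree with the vectorized implementations to 1e-12 on 1000 random
  tables with k in 2..7; statsmodels' kappa implementation serves as an
  external cross-check for the kappa path.
- Random tables in tests draw cells uniformly on 0..30 and resample the
  rare degenerate cases (empty, Pe = 1).
- CSV I/O round-trips the bundled tables bit-exactly; a trailing "Total"
  row/column is accepted only if it matches the computed marginals.

## Published reference values

The eight bundled tables come with published summary statistics, which
the acceptance tests reproduce at printed precision. The publications do
not state their rounding rule, and two values are consistent only with
truncation (the Winnipeg-series weighted B, 0.825829 printed as 0.825,
and the elderly-deaths B, 0.745001 printed as 0.74), so the comparison
accepts either round-half-up or truncation. Two further printed values
cannot be derived from their printed tables under any rounding rule and
are documented failures rather than silently matched: the Wolfe-scale
weighted kappa (printed 0.84; the table yields 0.8345 under quadratic
weights, the scheme that reproduces every other weighted value) and the
Boyd-scale kappa (printed 0.68; the table yields exactly
73199/108449 = 0.674962, consistent with the source having double-rounded
an intermediate 0.675). Both look like artifacts of values being carried
over from earlier publications computed on slightly different data or
precision.

## Known limitations

- Ordinal scales only; nominal data would need an ordering choice that
  the chart and weighted statistics are sensitive to.
- Two raters, one table at a time; no variance estimation.
- The qualitative label cutoffs are conventional defaults, not a
  calibrated standard.
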