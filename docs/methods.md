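# Methods

## Model and estimand

Given n samples of two continuous variables X1, X2 and a discrete class
label Y with P levels, the interaction information

    I(X1; X2; Y) = I(X1,X2; Y) − I(X1; Y) − I(X2; Y)
                 = I(X2; Y | X1) − I(X2; Y)
                 = I(X1; Y | X2) − I(X1; Y)

is positive when the pair predicts the class better than its parts
(synergy) and negative when the variables duplicate each other's
information (redundancy). All information quantities are plug-in
(maximum-likelihood) estimates on a discretizing grid, in bits, with
`0·log 0 ≡ 0`.

The signed three-variable MIC is the extremal normalized interaction over
grids: cut x1 into `x1` bins and x2 into `x2` bins (the class axis stays at
P), subject to a sample-size budget, and report the entry of maximal
absolute value with its sign. Normalizing by `log2(min(free bins, P))`
bounds the score in [−1, 1]: a noiseless XOR-type label attains +1, a fully
redundant pair (X2 = X1, Y a noiseless threshold of X1) attains −1, and for
any noiseless Y = f(X1, X2) the *joint effect*
`mic3 + mic2(X1;Y) + mic2(X2;Y)` is close to 1.

## Search strategy

A full grid search is infeasible; the estimator fixes one axis and
optimizes the other exactly:

1. **Fixed axis.** For each bin count `x1 = 2, 3, …` the fixed axis is
   equipartitioned: a greedy sweep places (as nearly as possible) n/x1
   points per bin without ever splitting tied values, re-targeting
   `remaining points / remaining bins` after each cut.
2. **Superclumps.** With the fixed partition and the class given, the data
   are sorted by the free axis and collapsed into maximal runs sharing
   (class, fixed-axis bin). Tied free-axis values are atomic; a tie block
   mixing classes forms a unit of its own. An optimal partition never needs
   to cut inside such a run. If more than `c · max_free_bins` runs result
   (default `c = 5`), adjacent runs are merged by the same greedy
   equipartition applied to run masses.
3. **Dynamic programming.** With the fixed partition frozen, the
   interaction decomposes as a partition-independent constant
   `K = H(X1,Y) − H(X1) − H(Y)` plus a sum of per-column scores
   (see `micsynergy/_dp.py`), so the optimum over all free-axis partitions
   into l columns with cuts on superclump boundaries is found exactly by
   the standard last-cut recursion — run twice, maximizing (synergy) and
   minimizing (redundancy). For each matrix entry the signed normalized
   value of larger magnitude is kept. A partition into fewer nonempty
   columns is realizable at any larger column count via empty columns, so
   entries take the running envelope over l.
4. **Orientations.** The whole sweep is repeated with the roles of X1 and
   X2 exchanged, making the estimator symmetric.

Grid budgets: with `x1` fixed bins the free sub-grid obeys
`x2 · y ≤ (n/x1)^a` with `a = 0.6`, i.e. `x2 ≤ (n/x1)^a / P`. The fixed
axis itself sweeps `2 … n^a / 2` — the total-grid budget `x1 · x2 ≤ n^a`
applied to the two continuous axes, the exact analogue of the two-variable
estimator's row sweep to `B(n)/2`. This bound matters statistically, not
just computationally: the plug-in interaction acquires an
`O(x1·(x2−1)·(P−1) / n)` bias, so sweeping the fixed axis toward its
combinatorial limit (`x1 ≈ n/10`) inflates the score of *independent* data
(measured: null mean 0.096 instead of 0.063 at n = 20000). The cap is
exposed as `max_fixed_bins` for sensitivity analysis. Superclumps breaking
on fixed-axis bin changes as well as class changes (the stricter reading)
is the default; `class_only_superclumps=True` gives the looser variant —
the two differ negligibly on the benchmark suite.

The two-variable `mic2` uses the same machinery with a 2-D column score
(`I = H(Q) + Σ φ2`): one axis equipartitioned into q bins, the other
optimized over clump boundaries within `x · y ≤ n^a`, both orientations,
capped at P bins on a discrete axis (labels with ≤ 10 distinct values are
treated as discrete by default; override with `discrete_y`).

## Numerical conventions

- Logarithms base 2 throughout; scores are quoted in bits.
- Ties: tied values never straddle a bin boundary (cuts must correspond to
  realizable measurement thresholds); the equipartition greedy closes a bin
  as soon as overshooting the running target is at least as bad as stopping
  short.
- Tie between grids with equal |score|: the smaller total grid wins, then
  the x1-fixed orientation — `best_grid` reporting is deterministic.
- Degenerate inputs: a constant continuous variable yields score 0 with a
  warning; fewer than 10 samples is an error; a sample too small to admit
  any grid under the budget is an error for `mic3` and a warned 0 for
  `mic2`.
- Entries are clipped to [−1, 1] to absorb floating-point overshoot of the
  normalization bound (sub-1e-12 effect).

## Synthetic data

The `simdata` module generates the benchmark constructions: continuous
variables are uniform on their stated domains (domains from the benchmark
table; the XOR scenario uses [10, 30]); continuous responses are binarized
at the sample median with the deterministic tie rule *strictly greater →
class 1*, keeping classes balanced to within one sample; the independence
scenarios binarize an independent uniform draw. Functions with isolated
undefined points (division, log of an absolute difference) redraw offending
samples, keeping the noiseless-function property exact. Every generator is
a pure function of (parameters, seed).

These generators emulate the published simulation study, not real
expression data: real microarray profiles have heavy tails, correlated
genes, batch effects and class imbalance, none of which are modeled here.
Passing the benchmark suite therefore validates the *estimator* (its
extremes, null level and functional generality), not end-to-end marker
discovery on real cohorts.

## Calibration results and known deviations

Measured with this package (seeds fixed; means over ≥ 50–200 replicates):

- XOR synergy, n = 1000: mic3 ≈ 0.999. Exactly 1.0 is unattainable for the
  plug-in estimator on sampled data — the marginal grid MIs at the best
  grid are not exactly zero in a finite sample — and the observed value
  matches the published "1" to printed precision. The ideal XOR
  *distribution* (the 2×2×2 tensor) gives exactly +1 bit, and full
  redundancy gives exactly −1.0 because all marginal counts align.
- Independence null: mic3 mean 0.146 (n = 200) falling to 0.063
  (n = 20000), against published 0.1562 and 0.0596. The large-n value
  discriminates sharply between fixed-axis sweep rules and motivated the
  `n^a/2` cap above; the residual ≈ 6% gap at n = 200 is attributed to
  unrecoverable details of the original pseudo-code.
- The two-variable null at n = 200 with a binary label measures ≈ 0.204
  here versus a published 0.1702 obtained with the original closed-source
  2-D tool. A null level near 0.2 at this sample size is consistent with
  the documented small-sample bias of grid-maximized MI; the gap is a
  property of the reference tool's unpublished internals, not of the
  dynamic program (which is verified exactly against exhaustive search).
- Noiseless-function benchmark, n = 1000, 50 replicates: mean mic3 0.365 /
  0.821 / 0.704 for the sum, absolute-difference and double-fold functions
  (published 0.3667 / 0.8222 / 0.7080); all ten joint effects fall in the
  published 0.97–1.17 band.

Replicate counts are reduced from the published 500–1000 to 50–200 (5 at
n = 20000); at these counts the standard error of every reported mean is
well below the agreement tolerances used in the tests.

## Complexity and problem sizes

One mic3 evaluation is O(Σ over fixed-axis sizes of [n + cap² · l_max])
per orientation: milliseconds at n = 100–200, ≈ 0.2 s at n = 1000, ≈ 15 s
at n = 20000 (single CPU). All-pairs screening is O(G²) evaluations —
embarrassingly parallel over pairs with a deterministic merge; genome-scale
screens (10⁴ genes) are cluster-scale and out of scope for the test suite,
which validates recovery on planted-pair matrices of up to ~50 genes.

## Design choices on genuinely open points

- The published definition's "maximal" is read as maximal *absolute* value
  with sign retained; it is the only reading consistent with a reported
  score of −1 for the fully redundant example.
- Pair ranking defaults to the signed score descending (synergy first);
  `rank_by="abs"` ranks by magnitude. Ties break lexicographically on the
  id pair so output files are reproducible.
- The independence scenarios binarize an auxiliary uniform at its median
  rather than drawing Bernoulli(1/2) labels; the two are asymptotically
  equivalent for the statistic, and the median variant keeps classes
  exactly balanced.
- Expression matrices follow the microarray convention (genes in rows);
  an orientation flag transposes on read.
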