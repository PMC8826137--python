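# Methods

This note records the model, the numerical choices, and the design
decisions behind `biogeodec`, in the spirit of a statistical package's
methods appendix.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## State space and anagenetic process

Ranges are subsets of an ordered list of single-letter area codes fixed
by the geography file header; bit *i* of a range mask is area *i*, and
every downstream index derives from this single ordering.  States are
enumerated null first, then by range size and lexicographic area order,
which makes MAP tie-breaking and all tables deterministic.  An optional
`max_range_size` caps range sizes (default: no cap, so six areas give 63
nonempty states).

The anagenetic generator has expansion rates
`q(G → G∪{b}) = d·Σ_{a∈G} m_s[a,b]` and contraction rates
`q(G → G\{a}) = e`; the null range is absorbing and is never observed at
tips.  `d` and `e` are in events per lineage per Myr; the multipliers
`m_s` are dimensionless scalings per ordered area pair and time slice,
with unit diagonals.  Slices are intervals of Ma before present
(present = 0); all internal computation uses node ages, with branch
lengths derived.  A branch crossing a slice boundary is propagated
segment by segment with the slice-specific matrix.

## Cladogenesis

Given an ancestor range `G`:

* **DEC** — single-area ranges are copied to both daughters; widespread
  ranges split by *subset sympatry* (one daughter a single occupied
  area, the other the full range) or *strict vicariance* (one daughter a
  single area, the other the remainder), in both daughter orders,
  duplicates removed.
* **DIVALIKE** — single-area copy, otherwise every ordered bipartition
  of `G` into two nonempty disjoint parts (`2^|G|−2` events).
* **BAYAREALIKE** — the range is copied unchanged at any size.

Weights are uniform over the allowed events of each ancestor.  A
founder-event weight `j` is accepted by the API (jump dispersal to an
unoccupied single area, relative weight `j` against 1 per standard
event) but is 0 by default, which reproduces the three classic families.

## Likelihood, root prior, optimization

Felsenstein pruning with per-node rescaling; tip partials are indicators
of the observed range.  The root likelihood is the flat average over the
nonempty states of the space — a documented convention; other root
priors shift lnL by a constant for fixed state space and should be kept
in mind when comparing absolute likelihoods across software.  Impossible
data (e.g. incompatible tips under zero rates) report `lnL = −∞`.

Matrix exponentials use dense scaling-and-squaring; inside the
optimizer, each slice generator is eigendecomposed once per parameter
value and branches are propagated by two small matrix–vector products,
with an automatic fallback to `expm` when the eigendecomposition does
not reconstruct the generator to 1e−9 relative accuracy.

`(d, e)` are fitted by L-BFGS-B from the fixed start `(0.01, 0.01)`
within box bounds `[1e−9, 5]`.  The search runs on log-rates: the
likelihood surface is smooth but extremely flat in `e` near its lower
bound, and the raw-scale line search can terminate abnormally there
while the log-scale search does not.  The optimizer contract (tested) is
that the returned optimum is never below the start point.  `n_obs` for
AICc is the number of tips.

## Survival-conditioned likelihood (`condition_survival`)

The forward simulator redraws any branch path that contracts into the
null range, because an observed dataset cannot contain extinct-in-place
lineages.  Data generated that way never "pay" the probability mass the
plain DEC likelihood assigns to extinction, and fitting the plain
likelihood to such data drives `ê` to the boundary: in pilot runs of the
recovery design the median `ê` was exactly 0 under truth `e = 0.01`.
The engine therefore offers `condition_survival=True`, which censors the
generator against the null range (zeroing the column into null produces
the sub-generator of paths that avoid it) and renormalizes each branch
kernel by its survival probability — exactly the branch law of the
redraw simulator, analogous to conditioning birth–death tree priors on
non-extinction.  The recovery experiment fits with this option; headline
data analyses and stochastic mapping use the standard unconditioned
likelihood.

## Ancestral states

Marginal posteriors come from the standard down–up pass: downpass
partials from pruning, outside likelihoods pushed tipward through the
cladogenesis table and transposed branch propagators, product
renormalized per node.  They match a brute-force enumeration over all
joint node-state and cladogenetic-event assignments to 1e−14 on small
instances (the enumeration oracle lives in `tests/oracles.py` and shares
no code with the implementation).  Two "single most probable area"
conventions are emitted per node: the MAP range state (ties broken by
the deterministic state order) and the argmax of per-area summed mass;
the MAP range is the default.

## Stochastic mapping

Root state from its joint posterior; cladogenetic events sampled
conditional on the ancestor state and the daughters' branch-top
partials; branch endpoints from endpoint-conditioned transition
probabilities (with intermediate states sampled at epoch boundaries via
suffix products of segment matrices); within-segment paths by
uniformization with the rate bound `1.02·max|Q_ii|`, cached powers of
the uniformized matrix, and a forward-simulation rejection fallback
capped at 1000 tries per branch.  Only real (state-changing) jumps are
recorded.  Tip ranges of every sampled history equal the observations by
construction and by hard assertion.  The sampler is validated against
the marginals (node-state frequencies at 10,000 samples within 3 Monte
Carlo standard errors) and against a quadrature expectation for the
event count on a single endpoint-conditioned branch.

## Event counting and rates

A range expansion adding area `b` from prior range `G` counts one
dispersal into `b`; the source mass is split `1/|G|` over the occupied
areas, which conserves `Σ_X df_X = Σ_Y dt_Y` exactly (an alternative
full-attribution rule is available).  A cladogenetic event counts as in
situ speciation in `X` when the ancestor occupies `X` and at least one
daughter retains it (a stricter both-daughters rule is available).
Contractions are tallied separately.

Rates are computed per replicate history with the four ratio formulas,
using the whole tree's branch length in the bin as the denominator of
`c`, `E` and `I` (an area-restricted denominator is available behind a
flag) and the lineage count at the bin's older edge for `λ`.  The
default bin width is 0.5 Myr and is configurable; bins with a zero
denominator are emitted as missing.  Cross-replicate summaries are the
median and the 0.25/0.75 quantiles, as plotted in the ribbon figures;
`relay_summary` can instead rank areas by the cross-replicate *mean*,
which is the better detector when early bins have few lineages and
per-history counts of 0 or 1 make the median degenerate at zero (the
regime-shift detection experiment uses the mean for exactly that
reason).

## Pseudoreplicate trees

Dating uncertainty is emulated by multiplying each internal node age by
`exp(cv·z)`, `z ~ N(0,1)`, in preorder with children clamped strictly
below their parent; missing taxa are grafted at a uniform-random age on
a uniform-random branch within (or on the stem of) a stated attachment
clade, with a user-supplied range — ranges of unsampled species cannot
be invented.  At full scale the study design is 1000 trees × 100
mappings = 100,000 histories; tests and examples default to far smaller
replicate counts with the same structure.

## The forward simulator

Chronograms are constant-rate birth–death trees conditioned on the
number of extant tips (dendropy's generator, which stops at the n-th
birth; terminal branches are extended by a draw from the waiting time to
the next event to remove the zero-length sister pair) and rescaled to
the crown-age target.  Ranges evolve forward with the slice-specific
generators and the cladogenesis table; the complete truth log uses the
same event schema as BSM histories, so truth and inference are directly
comparable.  Null-range outcomes are handled by per-branch redraw by
default (see above; a whole-realization rejection would require
astronomically many retries on large trees) or retained and flagged
extinct-in-place for stress testing, in which case the affected tips are
omitted from the geography table.

What the simulator does *not* emulate: sampling fractions below 100%,
phylogenetic or range observation error, diversification rates that
depend on the occupied area, and within-area geography.  Passing tests
therefore demonstrate internal consistency of the estimator and the
mapping machinery under the model, not robustness to those real-data
complications.

## Study-condition presets

* `hawkmoth` — the design of the radiation the package was built
  around: 134 tips, crown 8.6 Ma, six areas, the packaged two-slice
  multiplier matrices (boundaries 11/7/0 Ma), DEC with the published
  constrained-model point estimates `d = 0.16`, `e = 0.0`, root range B
  (Caribbean-Mesoamerica).  Birth 0.55 / death 0.05 per Myr give a
  realistic tree shape; only the shape matters because ages are rescaled
  to the crown target.
* `recovery` — 300 tips, truth `d = 0.02`, `e = 0.01`.  The remaining
  conditions are package choices made once: four areas (keeps 100
  replicates comfortably cheap at an interior-state space of 15),
  crown 25 Ma and root range AB (long enough, and widespread enough at
  the root, for extirpation to be identifiable at all — `e` is informed
  only through the frequency of widespread tip ranges).
* `two-phase` — the power experiment for relay detection: three areas,
  source row A = 1 in the old slice and source row C = 1 in the young
  slice against a 0.01 background, switch at 5 Ma, crown 10 Ma,
  `d = 0.3`, `e = 0.1`, root AC.  The strong contrast is the point of
  the scenario; the root occupies both designated sources so the
  injected pattern exists in every realization, and the brisk turnover
  keeps ranges narrow so each dispersal's source is crisply attributed.

## Known limitations

* `e` is weakly identified from tip ranges under DEC-style cladogenesis
  (which constantly resets daughters to single areas); expect boundary
  estimates on real datasets of this shape.
* DIVALIKE here weights all vicariant bipartitions uniformly; software
  packages differ in how they weight widespread vicariance, so absolute
  lnL values are comparable only under matching event definitions
  (likewise for the root prior).
* The uniformization sampler assumes the fitted rates are moderate
  (`μt` up to a few tens); pathological parameter values fall back to
  rejection sampling and may be slow.
* Exact expected event counts by linear algebra are deliberately out of
  scope — summaries are Monte Carlo, as in the study design the package
  follows.
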