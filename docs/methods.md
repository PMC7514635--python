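# Methods

## Models

The package studies coarse-grained lattice polymers on the square lattice
in which self-avoidance acts on lattice *bonds*: a walk may never traverse
a bond twice but may occupy a site up to twice (a *trail*).  Each doubly
occupied site hosts two complete passages of the walk and is classified
geometrically:

* **crossing** — both passages run straight through, one occupying the two
  x-bonds, the other the two y-bonds;
* **collision** — every other pairing: two touching corners, a straight
  passage next to a walk endpoint, or a closed-loop touch.  Sites with
  fewer than four distinct incident bonds cannot cross, so
  endpoint-degenerate configurations (the head resting on an occupied
  site, a loop closing onto the start) count as collisions.

Boltzmann weights: `tau_c` per collision, `tau_x` per crossing, a
stiffness weight `p` per singly occupied straight vertex, and — in the
half-plane geometry — an attraction `omega` per surface contact.  One
weight is attached per vertex configuration: the straight passages inside
a doubly occupied site do not acquire extra factors of `p`.  Variants:

* **ISAT** (interacting self-avoiding trail): `tau_c = tau_x = tau`;
* **VISAW** (vertex-interacting self-avoiding walk): crossings are
  illegal *moves* — they are excluded from the atmosphere, not merely
  weighted zero — and collisions carry `tau`;
* **generalized**: independent `tau_c`, `tau_x`, `p`.

The collapse transition of the square-lattice ISAT is known exactly at
`tau* = 3` (the kinetic-growth point), which makes the model a clean
benchmark: every production claim in this package is checked against it.

### Conventions that the literature leaves open

* **Surface contacts.**  Two countings coexist: the number of *steps* both
  of whose endpoints lie on the wall `y = 0` (default here), and the
  number of distinct visited wall *sites* excluding the anchored start.
  Both are implemented (`surface_convention = "steps" | "sites"`), the
  choice is recorded in every table header and manifest, and the exact
  enumeration oracle covers both.  The headline adsorption numbers use the
  step convention.
* **Walk anchoring.**  Bulk walks start at the origin of the free plane;
  surface walks start on the wall.  The wall is the line `y = 0`; there
  are no periodic boundaries.
* **Departing a doubly occupied site.**  A walk that has returned to its
  start (e.g. `E,N,W,S`) may leave again through an unused bond: the
  occupancy of the site stays two.  Forbidding such moves would forbid all
  pass-through collisions and change the model, so the standard trail rule
  is used throughout.

## Exact enumeration (the oracle)

`enumerate_trails` performs a depth-first search over direction choices
with incremental bond/occupancy state and exact undo on backtrack — no
memoization, no transfer matrices; correctness over speed.  Every DFS node
of length `n` contributes one count at its feature tuple
`(n_coll, n_cross, n_straight, n_surface)`, so the table carries all
lengths up to `N_max` at once.  In the bulk the four-fold rotational
symmetry can be exploited (fix the first step, multiply by 4); the wall
breaks that symmetry, so surface enumerations are always unreduced.
Practical ceiling on one core: `N_max ~ 20` bulk (minutes), `~ 14` with a
wall.  The enumeration itself is validated at small `N` against a
brute-force iteration over all `4^N` direction strings that shares no code
with the DFS kernel.

## FlatPERM sampling

Flat-histogram pruned-and-enriched Rosenbluth sampling estimates the same
coefficient tables far beyond enumeration reach.  A tour grows the walk
from the anchored start; at length `n` the atmosphere `a_n` (number of
legal continuations) multiplies the Rosenbluth weight, one continuation is
chosen uniformly, and every visit to a histogram cell `(n, m)` adds the
current weight `W` to an accumulator `C` and one to a visit counter `S`.
After `T` tours the coefficient estimate is `C[n, m] / T`.

Pruning/enrichment arithmetic (constants the literature leaves open; the
exactness is enforced by the oracle tests, not by matching any reference
implementation line by line): with `Wbar = C[n,m] / t` the running mean
weight at tour `t` and `r = W / Wbar`,

* `r < 1`: the branch survives with probability `r` at weight `Wbar`
  (expectation preserved exactly);
* `r > 1`: the branch splits into `c = min(ceil(r), a_n)` copies of weight
  `W / c`, each choosing its continuation independently;
* a cell's very first visit neither prunes nor enriches (`r` treated as 1).

Bin axes: bulk runs flatten in `(n, N_I)` with `N_I` the number of doubly
occupied sites; surface runs flatten in `(n, N_S)` while carrying the
fixed `tau` (and `p`) as multiplicative growth weights — this directly
estimates the *effective coefficients* of the surface polynomial
`P_N(omega)`; the generalized model can flatten in the
`(n_coll, n_cross)` pair.  Stiffness `p != 1` is always carried as a
growth weight.  Both parities of `N` are recorded; the analysis layer
filters parity.

Reproducibility: one master seed; per-replicate streams derived by NumPy
`SeedSequence` spawning and recorded in the run manifest, together with
tour and growth-step counts (so either reading of an "iteration" can be
compared).  Replicates are the parallelism unit; a single tour is
recursion-free (explicit copy stack) and bit-reproducible.

At the scales used here the Rosenbluth weights stay far below the range of
double precision (ln W ~ 250 at N ~ 150), so no log-domain arithmetic is
needed; pushing toward N ~ 400+ would require it.

## Partition polynomials and zeros

`Z_N(tau) = sum_NI c_{N,NI} tau^NI` (bulk) and `P_N(omega) = sum_NS
ctilde_NS omega^NS` (surface) are assembled from the tables with the
remaining weights fixed.  Coefficients grow exponentially in `N`, so
before root finding the coefficient vector is normalized by its maximum
and the variable rescaled by `s = (c_0 / c_d)^(1/d)`, which balances the
companion matrix.  The production solver is the balanced companion
eigensolver; every root is then *certified* by the relative backward error

    |P(z)| / sum_k |c_k| |z|^k  <  1e-10,

evaluated in extended precision (working digits = max(50, coefficient
log-range + 20)).  On failure the roots are Newton-polished and, if
needed, re-solved with an independent Aberth simultaneous iteration at
doubled precision; persistent failure raises rather than returning
uncertified roots.  Root sets of these positive-coefficient polynomials
must be conjugate-symmetric and keep off the nonnegative real axis; both
are asserted.

The *leading zero* is the root closest to the positive real axis: minimal
`Im` among roots with `Im > 0` and `Re` in a configurable positive window
(default `(0, 20)`, wide enough not to bias the physical locus while
excluding far-field spurious roots).  A continuity rule (nearest to the
previous length's zero) is available for noisy trajectories.  Stochastic
coefficient noise is guarded by the replicate-superposition diagnostic:
the leading zero must superpose across independent replicates while deeper
zeros may scatter.

## Finite-size scaling

The leading zero approaches the real axis as `Im z0 ~ A N^-phi` and
`|Re z0 - z*| ~ N^-phi`.  Estimators (all ordinary least squares on the
stated transformed coordinates; no weighting, matching common practice):

* **ratio estimator**: `phi_eff(N1, N2) = -ln(Im z0(N1)/Im z0(N2)) /
  ln(N1/N2)` at matched parity (strong even/odd effects), extrapolated
  linearly in `1/N`;
* **log-log slope** of `ln Im z0` vs `ln N`.  "The most asymptotic part of
  the line" is operationalized as the largest window whose slope drift
  between nested windows falls below the slope's standard error;
* **critical point**: polynomial fit of `Re z0` against `Im z0`; because
  `Im z0 -> 0`, the constant term estimates `z*`.  Default degree 4 in the
  bulk and 3 at the surface (the degrees that fit best in practice),
  configurable 1-6;
* `alpha = 2 - 1/phi` converts to the specific-heat exponent.

Uncertainties are reported three ways — half-range across replicates,
half-range across fit windows/degrees ("extremal fits"), and the half
range of their union — rather than committing to a single noise model.

## Problem sizes and what the tests show

Acceptance-level runs use walk lengths to `N = 128` (bulk) and `N = 96`
(surface) with 3 replicates of 8e4 / 4e4 tours — a deliberately reduced
scale that one core completes in minutes.  At this scale the package
reproduces `tau* = 3.0 +/- ~0.1` (quartic intercept), `phi ~ 0.83-0.86`,
`omega* ~ 2.4-2.5` and `phi_S` near 0.5, with uncertainties several times
wider than a production study; VISAW and integrable-point runs at this
scale show the zeros pinching in the right region but are not expected to
resolve the printed error bars.

The synthetic-trajectory generator used to validate the estimators draws
`Im = A N^-phi` with 1-2% multiplicative noise and a quadratic `Re(Im)`
locus.  It emulates the magnitude and smoothness of real leading-zero
trajectories but not their parity structure, correction-to-scaling terms,
or the correlated noise that FlatPERM induces across neighbouring `N` —
estimator-recovery results on it therefore bound statistical, not
systematic, errors.

## Known limitations

* Single-variable zeros only: grand-canonical (fugacity-plane) zeros and
  density-of-zeros/impact-angle analyses are out of scope.
* No separate estimate of `nu` or `nu_2`; only their ratio `phi` is
  measured.
* Correction-to-scaling exponents are not fitted; window drift is reported
  instead.
* The float64 weight representation caps practical walk lengths around
  `N ~ 300-400` for the default weights (see above).
* Enumeration and sampling are single-threaded by design; replicates are
  the unit of parallelism.
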