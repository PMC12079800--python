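# Methods

This note documents the models, estimators and numerical conventions
implemented in `pathppa`, the choices made where the design was genuinely
open, and what the synthetic benchmarks do and do not establish.

## Predictive capacity

For a query λ_A ≤ λᶜ ≤ λʳ ≤ λ_B, every sampled path whose maximum order
parameter reaches λᶜ contributes exactly one data point: the CV vector Ψ
at its *first* stored frame with λ ≥ λᶜ, weighted by the path's
statistical weight, and labelled reactive iff the path maximum reaches λʳ
(ties count as reactive).  No interpolation between stored frames is
performed: the crossing convention is honest at the stored time
resolution, and a path that already starts beyond λᶜ crosses at frame 0.

With densities r (reactive), u (unreactive), t = r + u, the capacity is

    𝒫 = (1/p̄) ∫ r²/t = 1 − O/p̄,   O = ∫ r·u/t,   p̄ = ∫ r.

Both algebraic forms are computed; the implementation asserts their
agreement to 1e-9 on the guarded domain (below).  p̄ at the density level
(∫r) is cross-checked against the sample-level reactive weight fraction;
a discrepancy beyond 1e-3 raises a diagnostics warning, not an error,
since mild disagreement is expected at small n.

## Savitzky–Golay density estimation

Binning r and u directly fails when bins hold 0–1 points per label: the
per-bin product r·u collapses to zero and 𝒫 is overestimated.  The
estimator therefore works on integrated distributions:

1. **Weighted CDFs.** R(CV(i)) = Σ_{j∈r, j≤i} w_j / W at the sorted
   sample CV values (U analogous); duplicate CV values merge into one
   step of summed weight so the CDF is well defined.
2. **Regridding.** Linear interpolation onto n_gp = 2000 equally spaced
   points spanning exactly [min, max] of the sampled CVs.  Queries
   outside the sampled range have density 0.
3. **Plateau padding.** round(pad_fraction · n_gp) points are prepended
   at height 0 and appended at the final height (500 per side at the
   defaults), removing the filter's boundary artefacts.
4. **SG derivative.** A Savitzky–Golay filter of polynomial order 2 and
   window length sg_window(n_gp, 1/16) — the nearest odd integer to
   n_gp/16, clamped to ≥ 5, i.e. 125 at the defaults — is applied to R
   and U; its first derivative on the unpadded grid gives r and u, with
   units 1/CV-unit (the derivative uses the regular grid spacing).

Polynomial orders above 2 can produce negative density lobes and are
refused unless explicitly overridden.  Slightly negative SG values are
*not* clipped; instead the overlap integrand r·u/t is set to 0 wherever
t < 1e-8 · max(t) (the ε_t guard), which also resolves the 0/0 tails.
Because the guard excludes the same far-tail set from ∫r²/t and ∫ru/t
but not from ∫r, the internal identity check compares
∫r²/t + ∫ru/t against ∫r restricted to the guarded domain; the excluded
reactive mass is of order the guard threshold itself (~1e-9 for Gaussian
tails) and is the reason the check is formulated this way.

Properties verified by the test suite: mass conservation (∫t = 1 ± 1e-3
after filtering), exact reproduction of linear and quadratic integrated
curves (1e-10), affine equivariance of the whole pipeline (the grid
scales with the data; the overlap is invariant to 1e-12), sup-norm
convergence to generating densities with growing n, and overlap
stability within 0.02 across window fractions {1/32, 1/16, 1/8}.
Negating the CV mirrors the estimate only up to the right-continuity of
the step CDFs, so Ψ → −Ψ reproduces the overlap to ~1e-4 at the default
grid, not to machine precision.

The binned estimator (`binned_densities`) is retained as the
failure-mode reference: a weighted histogram on equal-width bins,
integrated with the rectangle rule.

## WHAM path reweighting

Ensemble `[j+]` contains paths required to cross λ_j; its bias is a step
function of the path maximum m.  Step biases admit a non-iterative
weighted-histogram solution: a path with maximum m gets

    w(m) = 1 / Σ_{k: λ_k ≤ m} n_k / P̂(λ_k|λ_A),

with n_k the path count of ensemble `[k+]`.  P̂ is built left to right:
P̂(λ_0) = 1, and P̂(λ_{k+1}) = P̂(λ_k) · N_{≥λ_{k+1}} / N_{≥λ_k}
counted over paths of ensembles with interface index ≤ k.  Conditioned
on m ≥ λ_k those pool paths are identically distributed, so the weighted
ratio reduces to this count ratio — the "already-weighted paths"
recursion in closed form.  Weights are normalized to mean 1 over the
`[i+]` paths; `[0−]` paths pass through unchanged.  An ensemble with no
path crossing its own interface (or a member path below it) raises a
degenerate-ensemble error rather than being silently dropped.

The crossing curve reports P(λ) = Σ{w : m ≥ λ} / Σw only up to the
largest reached λ; beyond it the curve is undefined rather than 0 (log
plots, WHAM stability).  The initial flux is f_A = 1/(⟨τ⟩₀₋ + ⟨τ⟩₀₊)
with τ = t_last − t_first, so durations of consecutive segments of a
chopped trajectory telescope to the total time; single-frame `[0−]`
segments (touch-and-go visits to A at the stored resolution) carry zero
duration and *must* be counted for the flux identity to hold exactly —
consequently `flux_estimate` rejects only ensembles whose mean duration
is zero, not individual zero-duration paths.  Rates convert via
1 ns = 10⁶ fs at the reporting layer only; the analysis itself is
unit-agnostic.

The contract for all of this is the direct-counting oracle, not the
formula: on the synthetic double well the weighted λ_max histogram must
be χ²-indistinguishable (α = 0.01) from brute-force counting on the
uncut trajectory, and flux × total crossing probability must match the
directly counted transition rate.  The χ² uses per-bin variances
estimated from replicate subsettings; the naive fixed-weight ratio
variance ignores the dominant uncertainty in the recursively estimated
weights and would wildly overstate significance.

## Descriptors

**IIDM.** Rows are the anchor's neighbors sorted by species (canonical
order = the key order of the counts mapping, counterion first by
convention) then by distance to the anchor, truncated per species (e.g.
counterion:1, O:15, H:30).  Columns of row atom Yᵢ re-sort the *pool* —
the anchor plus all row atoms — by species and distance to Yᵢ.  Entry
names follow XYᵢZⱼ; XYᵢ names the anchor row.  Distance ties break on
coordinates lexicographically so the matrix is bit-identical under any
permutation of the input atom order.  Hydrogens within 1.2 Å of a row
oxygen are treated as intramolecular and excluded from that row's H
columns by default (`exclude_intramolecular_h=False` restores the raw
ranking), so `NaO6H4` measures hydrogen *bonding* compression around the
O6 oxygen rather than its own protons.  The pool convention for columns
is one of several defensible readings of "sorted in the same manner";
it is fixed and documented rather than inferred, and no truncation
convention tried reproduces externally quoted total-distance counts
exactly, so feature identity — not count — is the tested contract.

**Bridging count.** N_B = Σ f(d_Na)·f(d_Cl) over candidate oxygens with
the logistic switch f(d) = 1/(1 + exp(s·(d − r₀))): f(0) ≈ 1,
f(r₀) = 1/2, monotone decreasing, so a water exactly at r₀ from both
ions contributes 1/4 and the count is fractional by construction.  The
exact functional form in the literature set this mirrors is not pinned
down; the form is therefore a parameter of the operation, with the
hard-cutoff limit (s → ∞) tested against direct counting.

**Angles.** largest_cosine maximizes cos∠(arm, candidate) at the apex
over candidates of a species within a hard shell radius of the apex
(configurable center); the radius is a free parameter, default supplied
by the caller.

**Axial maps.** Cylindrical (z, ρ) histograms of the k closest atoms of
a species to the first anchor, with z along the anchor–anchor axis,
normalized so Σ density · cell area = k per configuration.

## Synthetic ground truth

The double-well generator integrates overdamped (Euler–Maruyama)
dynamics on V(x, y) = h(x²−1)² + y²/2 + g·x·y at kT = 1, λ = x,
recording the coupled coordinate y (predictive of crossing by
construction when g ≠ 0) and an independent standard-normal noise
channel (uninformative by construction).  Defaults h = 3, g = 1,
γ = 1, dt = 10⁻³, λ_A = −0.7, λ_B = 0.7: the wells sit near x = ±1.08,
the effective barrier after integrating out y is ≈ 4.6 kT, and A→B
transitions are rare on the segment scale (~1 per 160 segments) while
still countable in minutes on one CPU.  Chopping emits strictly
alternating `[0−]`/`[0+]` segments sharing junction frames, plus
direct-count summaries (segment maxima, durations, transition count)
that serve as the oracles above.  `tis_like_subsets` emulates nested
ensembles either by overlapping Bernoulli subsampling at recorded rates
(the default, matching how one path can satisfy several ensembles'
conditions) or by a randomized disjoint partition (`disjoint=True`),
which emulates statistically independent per-ensemble simulations and is
what the χ² comparisons use.  The oracle fixtures place the intermediate
interface at −0.5, giving local crossing probabilities in the 0.1–0.5
band that interface placement heuristics recommend.

Mixture fixtures draw Ψ from t = r + u (Gaussian mixtures) and label
each sample reactive with probability r(Ψ)/t(Ψ), so the true capacity
follows from adaptive quadrature.  The reference corpus spans
separations 0 → 6.5 between half-weighted unit Gaussians.  The widest
pair doubles as the sparse-binning fixture: at n = 50,000 and 10,000
equal-width bins the expected per-bin count near the density crossing is
μ ≈ 2.5·φ(d/2)·range ≈ 0.07, i.e. nearly every bin there holds zero or
one point of each label — the regime in which the binned overlap
collapses while the SG estimate does not.  That μ ≲ 0.25 requires
d ≳ 6 was derived from this expression before freezing the fixture.

What the toys do *not* emulate: molecular force fields, momenta and
velocity-dependent CVs, MC-move correlations between successive sampled
paths (segments of one long trajectory are nearly independent; real
TIS chains are not), or multimodal order-parameter dynamics.  Passing
tests establish the correctness of the estimators under their stated
assumptions, not the physics of any particular molecular system.

## Numerical conventions and edge cases

- Text writers emit 10 significant digits; read∘write is bit-stable at
  analysis tolerance.  Subsampling keeps rank 0 of each ensemble's MC
  chain (ceil(N/stride) survivors).
- Capacity maps mark cells undefined (never throw) when lc > lr, fewer
  than n_min = 200 samples survive, no sample is reactive, or the CV
  support degenerates; diagonal cells (λᶜ = λʳ) are exactly P = 1,
  𝒫 = 1 since u ≡ 0.
- The annealer optimizes coefficients in [−1, 1]ⁿ, L1-normalized before
  every evaluation, loss = overlap integral (p̄ does not depend on the
  CV, so minimizing O maximizes 𝒫).  Subset screening enumerates
  combinations of the top-k screened CVs (default 10); 3 restarts per
  subset with seeds derived from the master seed keep the search
  deterministic; the best subset gets a Nelder–Mead refinement.  The
  initial temperature (default 26,150) is an opaque scale of the
  underlying generalized-annealing scheme; the recovery test on planted
  combinations, not the schedule, is the contract.  Reported combos
  canonicalize the largest-|coefficient| to be positive (𝒫 is invariant
  under Ψ → −Ψ) and are also reported rescaled by the largest prefactor.
- Problem sizes used by the test suite and the acceptance script — 8·10⁶
  integrator steps (~47,000 segments), 200 random mixture specs at
  n = 10⁴, ten reference specs at n = 5·10⁴, planted recovery at
  n = 2·10⁴, 30×30 capacity maps — were chosen so the whole stack
  re-runs from scratch in a few minutes on one CPU while keeping every
  statistical check far from its tolerance.

## Known limitations

- The SG estimator is one-dimensional by design; multi-CV hypotheses
  enter only through linear combinations.
- Capacity estimates at small n (≲ a few hundred samples) carry upward
  bias; the n_min guard reports such cells as undefined in maps, but
  scalar queries on few samples will show it (visible as the noise
  channel scoring slightly above p̄ in the README example).
- WHAM assumes nested step biases on λ_max; junction-smoothing variants
  of path reweighting are not implemented.
- The XYZ reader handles orthorhombic boxes only.
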