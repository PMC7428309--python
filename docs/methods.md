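# Methods

## The decision problem

A nucleus at position x (percent egg length, %EL) senses the Bicoid
concentration L(x) = L0·exp(−(x−x0)/λ), with L0 = 5.6 molecules·μm⁻³ at
the half-maximum *hunchback* point x0 (45 %EL by default; only x − x0
matters) and decay length λ = 20 %EL.  The anterior/posterior fate
decision is modeled as a binary test between the concentrations at the
two edges of a border region of width δx = 2 %EL: L1 = L(x0 − δx/2) ≈
5.89 and L2 = L(x0 + δx/2) ≈ 5.33 μm⁻³, a relative difference of
exp(δx/λ) − 1 ≈ 10.5%.  The geometric mean of (L1, L2) is L0 exactly.
The error budget e sets the symmetric log-likelihood thresholds
K = log((1−e)/e); the default e = 0.32 (the two-sided Gaussian
one-standard-deviation level, 31.7%) gives K ≈ 0.754.

## Promoter model

A promoter with N Bicoid-binding sites is an (N+1)-state birth–death
chain over the number of bound molecules; binding step i has propensity
mu[i]·L (mu in μm³·s⁻¹, kept separate from concentration so one
architecture can be evaluated anywhere on the gradient) and unbinding
step i has rate nu[i].  The gene is ON when ≥ k sites are bound.
Diffusion-limited arrival caps the binding steps at
mu[i] ≤ mu_max·(N+1−i), with mu_max·L0 = 0.124 s⁻¹.

The baseline "independent identical sites" architecture used for the
fixed-time anchors places the per-site rates (0.124 s⁻¹ on at L0,
0.0154 s⁻¹ off) so that site occupancies are i.i.d. with
p = 0.124/(0.124+0.0154); the all-or-nothing activation probability is
p⁶ ≈ 0.495 at the boundary — half activation — and the activation Hill
coefficient is 4·6·p⁶(1−p) ≈ 1.31 there.

ON and OFF episode durations are phase-type laws: the sub-generator is
the chain generator restricted to the ON (OFF) class, entered through
the stationary probability flux across the k−1 ↔ k boundary.  For
birth–death chains the entry law is a point mass (state k for ON, k−1
for OFF); the general flux law is used for the enhancer product chain,
which is not birth–death.  This renewal entry convention makes the
identity P_ON = τ_ON/(τ_ON + τ_OFF) exact, which the tests verify to
1e−8 on random architectures.

## Sequential readout

Each completed episode multiplies the likelihood ratio by the ratio of
its duration density under (L1, L2); a censored running episode
contributes the survival-function ratio.  Traces start with an empty
promoter by default (mitotic reset); the stationary-entry convention is
available.  For close hypotheses log R(t) is drift–diffusion with

* drift V = [ΔKL_OFF + ΔKL_ON]/(τ_ON + τ_OFF), where ΔKL is the
  difference of Kullback–Leibler divergences of the true-concentration
  dwell law from the two hypothesized laws;
* diffusivity D, computed three ways:
  * `identity` — D = V, exact in the close-hypothesis limit (the
    Bayesian-update argument: the expected change of the posterior
    must vanish);
  * `analytic` — the renewal–reward asymptotic variance
    D = Var(X − V·τ_cycle)/(2·E[τ_cycle]) with X the per-cycle
    log-likelihood increment, evaluated by quadrature;
  * `montecarlo` — weighted regression of Var[log R(t)] against 2t over
    a simulated ensemble.

V = D is an asymptotic identity: on random six-site architectures the
relative gap shrinks linearly with the separation (≈ 2.5·δL/L), i.e.
a few percent at the 10% separation and below 1% only within ~0.5%.
Mean decision time ⟨T⟩ = (K/V)·tanh(VK/2D), diffusive limit K²/(2D);
absorption at +K with probability e^{VK/D}/(1+e^{VK/D}).

The episode-wise discrete walk overshoots ±K; ensembles record the
overshoot.  The overshoot biases the realized error below the nominal e
and lengthens decisions when single-episode increments (~log(L1/L2) ≈
0.1) are not small against K; agreement with the drift–diffusion
formulas to Monte Carlo precision therefore holds at stricter error
levels (K ≳ 2), where the tests place it.

### Error profiles along the embryo

`error_and_time_profile` evaluates, at each position outside the border
mask (half-width δx/2), the wrong-boundary absorption probability and
mean time at the problem's fixed K from V(x), D(x) at the local
concentration.

`error_profile_at_budget` instead answers "what error is achievable in a
fixed average time": at each position the threshold K(x) is raised until
⟨T⟩ = T_budget (270 s, the cycle-11 interphase), and the error is the
wrong-boundary probability at that K.  Two conventions specific to this
embryo-wide accounting:

* V(x) and D(x) are computed with episodes right-censored at the
  budget: an episode the window never completes contributes its
  (nearly deterministic) survival-ratio evidence rather than the
  enormous variance the uncensored renewal asymptotics would assign to
  rare multi-hour dwells of saturated anterior promoters.  This leaves
  boundary values unchanged and restores the correct near-zero error
  far from the border.
* The mask half-width defaults to δx (one full border width per side)
  rather than δx/2.  A nucleus within one internuclear distance of the
  border carries a concentration within the stated resolution of the
  hypotheses; a data-processing bound on the drift (every
  diffusion-limited arrival carries at most log(L1/L2)+(L2−L1)/L1 ≈
  0.0048 nats, and the arrival flux under the caps with half
  activation is ≤ ~0.72 s⁻¹) caps V at ≈ 0.0035 s⁻¹, so the error of
  a nucleus at the δx/2 edge cannot fall below ~0.15 in 270 s and no
  architecture could make the embryo-wide count small under the
  narrower mask.  Pass `border_mask_halfwidth` explicitly to override.

With the optimized k = 1 architecture this yields ≈ 0.44 misclassified
nuclei among the 1024 of cycle 11, against ≈ 49 for the fixed-time
readout of the baseline architecture at the same budget.

## Fixed-time (Berg–Purcell) benchmark

A fixed-time reader averages the activity indicator over T and
thresholds the average.  Var[Â] = c/T with two conventions for c:

* `telegraph` (default): c = 2P²(1−P)²(τ_ON+τ_OFF), the two-state
  reduction of the activity signal — exact when dwell times are
  exponential.  It reproduces the printed anchors (the six-site
  all-or-nothing baseline needs ≈ 42 min for 10% resolution at the
  one-sigma level).
* `spectral`: c = 2τ_c·Var[A] with τ_c the exact integrated
  autocorrelation time from the chain spectrum (a Poisson-equation
  solve).  For the baseline this gives ≈ 47 min: contiguous OFF
  episodes of the six-site chain are positively autocorrelated beyond
  the two-state picture.

`_half` variants drop the factor 2.  Misclassification is Gaussian in
*activity* units — the distance of P_ON(L(x)) to the activity at the
nearest border hypothesis over σ = √(c/T) — because the lnL-space map
through dP_ON/dlnL is singular where the activation curve saturates
and would report error 0.5 for deep-posterior nuclei that in fact
decide trivially (the lnL-space variant is available via
`error_space="loglik"`).  The single-site baseline is Poisson arrival
counting, T = 1/(mu·L·δ²) — 13.4 min for δ = 10% at 0.124 s⁻¹.

The claim "the sequential readout beats any fixed-time readout of the
same architecture at equal error" is tested against the spectral
convention: the telegraph reduction can understate the fixed-time noise
by orders of magnitude for strongly non-exponential architectures and
then lose to SPRT spuriously.

## Stochastic simulation

Single trajectories are exact Gillespie samples of the occupancy chain.
Ensembles (first-passage times, Monte Carlo diffusivity, RNA circuits)
sample whole episodes from the phase-type laws instead — exact for the
telegraph statistics and vectorizable.  Phase-type sampling simulates
the embedded jump chain in vectorized batches.  Per-molecule DNA-bound
times track individual molecules with uniform choice of which bound
molecule unbinds (LIFO available); cooperative architectures with slow
deep-state unbinding give heavy-tailed bound times (median ≪ mean), as
observed in single-molecule imaging.

All generators take explicit seeds; identical seeds give identical
event sequences.

## Architecture search

Objective: the worst-side drift–diffusion decision time
max(⟨T⟩ at truth L1, ⟨T⟩ at truth L2) with the identity D = V.
Constraints: P_ON(L0) = 0.5 enforced exactly by solving for the
activation step's detailed-balance ratio in closed form (stationary
weights are products of r_j = mu_j·L0/nu_j, and every ON-class weight is
proportional to r_k); the mu caps by clipping; nu ∈ [1e−4, 10] s⁻¹
(including the analytically eliminated rate); an optional Hill floor by
a multiplicative hinge penalty with a feasibility filter (H ≥ H_min −
0.05).  The Hill coefficient is the local log-slope at half activation,
4·dP_ON/dlnL, exact on Hill functions; a least-squares fit is the
cross-check.

Minimization is multi-start Nelder–Mead in log-rate space (the clipped
caps make the objective non-smooth at the boundary, where
finite-difference descent stalls), with four structured warm starts
(binding at the caps, one common unbinding scale) plus log-uniform
random starts, all with recorded seeds.  The k = 1 optimum under half
activation and the diffusion caps is ≈ 118 s for the 10% problem at
e = 0.32, consistently across seeds and rate families; the
full-information bound above (~78 s) shows this is within a factor 1.5
of any conceivable readout under the same constraints.

Binding-site mutants truncate the chain at N′ states keeping the
remaining rates (the last binding steps are deleted; other conventions
selectable); removing sites under a fixed rule shifts the
half-activation point toward the anterior.

## Reduced models and enhancer

The two-site cycle models use the printed closed-form densities as
analytic tests of the generic phase-type machinery (hypoexponential OFF
times for all-or-nothing, concentration-dependent hypoexponential ON
times for one-or-more).  The k = 1 and k = 2 rules perform equally on
the locus L·mu1 = nu (verified to < 1%), k = 2 wins for L·mu1 ≫ nu,
k = 1 for L·mu1 ≪ nu.  Phase diagrams optimize per grid point
(Nelder–Mead for the equilibrium two-site comparison, bounded scalar
minimization for the ordered-binding weak-site question); failed points
are flagged, never filled.  Under these conventions the weak-second-site
advantage is marginal (relative time gains ~1e−4 at low L and slow nu);
the classification threshold flags only clearly interior optima.

The enhancer is an independent two-state switch (ON rate mu_e·L,
diffusion-limited for one site); the gene transcribes when promoter and
enhancer are both ON.  The joint dwell laws come from the product chain
with the general flux entry law and feed the same SPRT machinery; an
always-ON enhancer reduces exactly to the promoter-only statistics, and
the joint ON-episode law matches a simulated AND of independent
promoter/enhancer telegraphs (KS test).

## RNA likelihood proxy

The per-episode log-likelihood is asymptotically linear in the episode
duration, so a circuit that produces RNA at r_on = 0.805 s⁻¹ once the
gene has been continuously ON for d_on = 0.047 s, at basal
r_b = 0.2 s⁻¹ once continuously OFF for d_off = 1.6 s, and degrades at
a constant (enzyme-saturated) r_deg = 0.5 s⁻¹, accumulates a signed
level that tracks log R (correlation > 0.9 on long traces for suitable
architectures).  The delays are continuous-residence filters: episodes
shorter than their delay never flip the production state.  RNA
accounting is deterministic given the telegraph trace (the level is a
likelihood proxy, not a copy number, and may go negative).

Decisions threshold the level against a pair c1(t) > c2(t).  The
default pair runs parallel to the *empirical mean level path under the
boundary concentration* (estimated once on a calibration ensemble),
offset by ±a: production starts basal after the mitotic reset, so the
level departs from zero along a curved burn-in that constant-slope
thresholds mis-handle.  The offset a is calibrated as the smallest value
meeting the target error on an ensemble.  Because the fixed circuit
kinetics suit some near-optimal architectures better than others (d_off
interacts with the OFF-duration statistics), the circuit/architecture
combination is selected jointly over the search's feasible multi-start
candidates — the same existential procedure the quantitative claims
about the circuit refer to.  The selected k = 1, H > 4 candidate decides
at 28.8% error in ≈ 149 s.

The delayed dynamics do *not* steepen the RNA-production profile beyond
the activity profile for any optimized k = 1, H > 4 candidate found
here (RNA Hill 4.15–4.26 vs activity 4.49–4.62): with the first binding
at the diffusion cap, boundary OFF episodes (~1.3 s) are shorter than
d_off and the OFF-inertia extends the anterior production plateau
posteriorly, flattening the transition, while d_on is too short to
suppress posterior ON episodes.  Steepening does occur for slower
promoters (six i.i.d. sites at 0.07/0.08 s⁻¹ with k = 2: RNA Hill 4.13
vs activity 3.51).  The corresponding acceptance check is left failing
rather than weakened; the steepness amplification depends on promoter
rates that are not published.

## Numerical choices

* Phase-type densities/survivals via cached eigendecomposition with an
  `expm` fallback when the eigenbasis is ill-conditioned (condition
  number > 1e10, e.g. equal-rate hypoexponentials).
* KL divergences and increment moments by composite Gauss–Legendre
  quadrature on geometric panels anchored to the *spectrum* of the
  sub-generators (two decades below the fastest timescale out to 40
  slowest timescales): dwell laws of cooperative promoters mix decay
  rates spanning many decades, and mean-anchored grids silently lose
  slow mixture components.
* Budget-censored moments add the survival atom at the window edge.
* Hill/half-activation root finding by bisection in log-concentration;
  derivatives by central differences with step 1e−5 in lnL.
* First-passage safety horizon: 100× the analytic expected number of
  cycles; censored replicates are reported, never dropped silently.
* Default ensemble sizes (10³–10⁴ replicates; 30–60 ks trajectories)
  keep Monte Carlo standard errors at the few-percent level matching
  the 3-SE test criteria; all are arguments, so larger runs are one
  keyword away.

## What the tests do and do not show

The synthetic data here are the model's own trajectories: simulation
validates the analytics (and vice versa) but cannot validate the model
against real embryos.  Known idealizations: episodes are treated as
independent renewals (site-identity correlations are subsumed into the
occupancy chain); no internuclear coupling or averaging; no Hunchback
feedback or other maternal inputs; 1-D nuclei placement, uniform along
the axis; no yolk-nucleus losses; deterministic RNA accounting without
copy-number noise.  The embryo-wide error counts inherit the
drift–diffusion approximation near the border and the budget-censoring
convention away from it; both are stated above because the published
headline numbers depend on them.
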