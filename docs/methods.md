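# Methods

## Reaction dynamics

The per-location dynamics combine frequency-dependent selection with
density-dependent regulation: each strategy's mean payoff (hawk:
p_H = P s + T (1−s); dove: p_D = S s + R (1−s), with hawk fraction
s = u/(u+v)) is a per-capita net growth rate, and a crowding term
κ(u+v) removes individuals of either strategy at a rate proportional to the
total local density.  An empty location is assigned payoff 0 for both
strategies, so every demographic and movement weight degenerates gracefully:
no individuals means no events, and an empty neighbor is weighted f(0) = 1
under both movement rules.

For a hawk–dove ranked matrix the interior equilibrium is

    u0 = (T−R)(ST−RP) / (κ (S+T−R−P)²),
    v0 = (S−P)(ST−RP) / (κ (S+T−R−P)²),

which for the resource-contest matrix (T, R, S, P) = (V, V/2, 0, (V−C)/2)
reduces to u0 = (C−V)V²/(2κC²), v0 = V(C−V)²/(2κC²).  κ sets only the
population scale; the hawk fraction, the reaction Jacobian, and every
stability threshold are κ-free.  The Jacobian is evaluated from the exact
payoff partials rather than hard-coded for the contest family, so arbitrary
hawk–dove ranked matrices are supported; the contest closed forms serve as
the test oracle.  The sign structure matters: the dove diagonal entry b2 is
positive exactly when C < 2V, which makes doves the activator and hawks the
inhibitor — the precondition for any diffusion-driven instability.

## Stochastic lattice model

Integer counts live on a 1-D chain of N patches with nearest-neighbor
coupling and no wraparound.  Event propensities per patch: birth at rate
n·max(p, 0), payoff death at n·max(−p, 0) (the sign of the payoff decides
birth versus death), crowding death at κ·n·(u+v), and movement at per-capita
rate μ with the destination chosen among existing neighbors proportionally
to f(w·p_neighbor), f either exp(·) or 1 + (·).  Because the weights
normalize over existing neighbors, a boundary patch routes its entire μ to
its single neighbor; the per-patch movement outflow is therefore exactly
μ·n everywhere (zero-flux lattice).  An affine weight that becomes
non-positive anywhere aborts the run with a diagnostic rather than being
clamped.

Simulation is the exact Gillespie direct method — no tau-leaping — with
per-patch propensity caches.  An event changes rates only in its own patch
and the patches whose movement weights read its payoff (the two neighbors,
plus the destination's neighborhood for a hop), so updates are O(1) in N;
patch selection is an O(N) scan, acceptable at the N ≤ 100 scales used.
The running total rate is refreshed from the cache every 10⁶ events to
stop floating-point drift.  The compiled kernel (numba) and the Python-level
rate functions share the same jitted propensity helpers, so the reference
implementation tested directly is the one the production loop runs.

State is recorded on a fixed snapshot grid (default Δt = 0.5) rather than
per event, bounding memory and matching the analysis protocol: per-patch
means over the last 5% of the horizon (configurable), payoffs computed per
snapshot and then averaged.  Replicates get independent streams spawned from
the master seed; a fixed seed replays bit-identically.  A replicate that
goes fully extinct before the averaging window opens is excluded from the
ensemble means and counted in the summary — averaging in an all-zero
profile would bias the window means toward zero.  Default study conditions
follow the standard regime (V = 4, C = 6, κ = 10⁻³, 100 patches, horizon
100, initial counts 444/222 plus integer-uniform noise on [−5, 5]); the
bundled acceptance run scales this to 30 patches, horizon 30, and 5
replicates, which keeps the run in minutes while the window means still
resolve a 5% deviation from the equilibrium.

What the lattice generator emulates — demographic noise, discrete counts,
payoff-biased hopping — and what it does not: real populations have
off-lattice movement, heterogeneous patches, and non-instantaneous
interactions.  Tests passing on this generator validate the model's internal
consistency (rates, conservation, convergence to the mean-field fixed
point), not ecological realism.

## Local PDE

The continuum model pairs diffusion with advection up the strategy's own
payoff gradient in conservative form:

    u_t = −∂x J_u + u (p_H − κ(u+v)),
    J_u = −D_u ∂x u + 2 D_u w_u u g_u(w_u p_H) ∂x p_H,

g = f′/f of the movement weight (≡ 1 for the exponential rule,
1/(1 + w p) for the affine rule), and analogously for doves.  Setting
w = 0 recovers plain reaction-diffusion.

Discretization is finite-volume on cell centers: diffusive and taxis fluxes
on faces (central averages; an upwind option for the taxis term exists for
steep-gradient robustness but the central scheme is the tested default),
zero flux imposed at the domain ends, reactions at centers.  With reactions
disabled the scheme conserves both totals to integrator tolerance by
construction.  Time stepping is scipy's BDF with the analytic Jacobian
sparsity (tridiagonal blocks), tolerances rtol = 10⁻⁶, atol = 10⁻⁸ —
diffusivity ratios up to ~50 and the stiff fast eigenbranch make explicit
stepping impractical.  Three terminal events guard the integration: a
steady-state exit when ‖rhs‖∞ < 10⁻⁹, a blow-up diagnostic when any density
magnitude exceeds 10⁸, and a negativity diagnostic when any density falls
below −10·atol.  Negativity is never clipped: it signals either an
under-resolved run or a genuinely short-wave-unstable regime, both of which
must surface.

Default resolution n = 400 on length 40 (dx = 0.1) resolves the m = 12
pattern with ~67 cells per wavelength; halving dx leaves the dominant mode
unchanged and moves the saturated amplitude by under 2%.  Near-threshold
growth rates are tiny (σ ≈ 2.7×10⁻⁴ at D_u = 4.93), so pattern runs
integrate to t = 2×10⁵ with the steady-state exit typically firing around
t ≈ 10⁵ — a scaled-down horizon chosen because the single unstable mode has
long since saturated; nothing changes later.

## Nonlocal PDE

Individuals sense the average log movement weight over an interval of
half-width ρ, so the advective drift is the centered difference
[log f(w p(x+ρ)) − log f(w p(x−ρ))]/(2ρ) inside the same conservative
divergence, on a periodic domain (the shifted evaluation makes periodicity
the natural boundary condition).  ρ is required to be an integer number of
grid cells: the shifts then land on grid points, no interpolation is
involved, and the discrete linearization reproduces the analytic sensing
factor sin(2mπρ/l)/ρ exactly.  A misaligned ρ is rejected rather than
silently rounded.

## Linear stability

Dispersion matrices: A(m) for the local model on zero-flux cosine modes
cos(mπx/l), B(m) for the nonlocal model on periodic modes cos(2mπx/l); at
m = 0 both equal the reaction Jacobian.  det A is a quadratic in
q = (mπ/l)², det A = αq² + βq + γ, and for the exponential rule α and β are
affine in w_v while γ is the (constant, positive) reaction determinant.
Every threshold therefore reduces to roots of linear or quadratic
expressions:

* **Turing (w = 0):** instability requires b2 > 0 and is feasible only for
  m < m_c = (l/π)√(b2/D_v); mode m destabilizes when D_u exceeds
  D_u*(m), and the continuum marginal ratio d* solves
  (a1 + d b2)² = 4 d (a1 b2 − a2 b1), taking the larger root.
* **Payoff-driven:** w_v^I opens the trace route (the trace's q-coefficient
  turns positive — infinitely many unstable modes), w_v^II makes α negative
  (determinant negative at all large q — again short-wave), w_v^IIIa makes
  β negative, and w_v^IIIb is the smallest w_v ≥ 0 with β < 0 and
  β² − 4αγ ≥ 0, computed from the exact quadratic-in-w_v discriminant with
  candidate roots checked in order (no closed form is used beyond that
  structure).  A finite band exists only in the window
  max(IIIa, IIIb) < w_v < min(I, II); with D_u = D_v the identities
  w_v^IIIa = w_v^I and w_v^IIIa > w_v^II close that window for every
  contest game — only short-wave instability is possible there.
* **Onset reporting:** the continuum onset w_v* is the infimum over both
  routes.  On a finite interval only integer modes exist, so the package
  also reports the first integer-mode determinant onset (det A(m) is affine
  in w_v per mode, giving closed-form per-mode roots); at the standard
  mixed regime (D_u = 4.2, D_v = 0.1, w_u = 0.05) the continuum onset is
  0.8475 and the first integer mode (m = 17) destabilizes at 0.8479.

Short-wave verdicts are always certified analytically from the asymptotic
coefficient signs (trace slope, α), never from a finite mode scan — a scan
cannot certify an infinite band.  Conversely the nonlocal band scan is
provably complete: |sin(kρ)/ρ| ≤ 1/ρ bounds every taxis term, so a root
bound on the dominating quartic/quadratic envelope gives an explicit mode
index beyond which tr < 0 and det > 0 are guaranteed, and the scan covers it.

## Pattern diagnostics

Dominant modes are read off the DCT-II (zero-flux) or real FFT (periodic)
of the mean-centered profile, which is exactly the matching cosine basis at
cell centers.  "Full peaks" are counted on the 3-point-smoothed profile as
interior maxima above the spatial mean (plateau-aware), plus one half for
each boundary maximum: a pure cos(mπx/l) profile with even m then counts
m/2 full peaks regardless of its sign.  Counting boundary maxima as halves
is deliberate — with strict interior counting the +cosine phase of the
m = 12 pattern would report five peaks and the −cosine phase six, making the
diagnostic phase-dependent.  Density-weighted average payoffs
⟨p⟩ = ∫p·n dx / ∫n dx are reported as NaN for a strategy absent everywhere
rather than 0.

## Known limitations

* 1-D only; nearest-neighbor lattice connectivity only.
* The local payoff-taxis model is short-wave unstable in the equal-
  diffusivity regime; simulations there correctly abort with blow-up or
  negativity diagnostics rather than producing (spurious) saturated states.
  Strongly aggregating nonlocal regimes (e.g. w_v = 10 with small ρ) can
  also drive dove valleys to zero and trigger the negativity guard under the
  central scheme; the threshold analysis, which is the quantitative content
  there, does not depend on those runs.
* The quantitative map between the lattice movement rate μ and the continuum
  diffusivity D (D = μ/2 for unit patch spacing) is implied, not enforced:
  both are exposed as independent parameters.
* Threshold closed forms assume the exponential movement rule; the affine
  rule is supported in the simulators and sensitivity constants but not in
  the w_v threshold calculus.
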