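# Methods

## Model

Standing balance in the sagittal plane is modelled as a single inverted
pendulum pivoting about the ankles. Linearizing the torque balance about the
equilibrium ankle angle Θ₀ gives

    θ̈ = θ / τ_mech²,        τ_mech = √( J / (m g L cos Θ₀ − k) ),

where J is the rotational inertia about the ankles, m g L cos Θ₀ the
gravitational toppling stiffness, and k the ankle stiffness. The passive
restoring torque cancels the toppling torque exactly at the critical
stiffness K_crit = m g L cos Θ₀. All computation is carried out in
normalized units: stiffness as the fraction k_frac = k / K_crit, torques
divided by the weight torque, and feedback gains per unit inertia. With
human-scale anthropometrics (J ≈ m L², L ≈ 1 m, upright equilibrium) the
base mechanical time constant is τ_m,0 = 1/√g ≈ 0.319 s; the package keeps
the exact value 1/√9.81 rather than the rounded 0.32 s, because the
strategy-table gains are only reproduced at that precision.

Neural feedback acts after a response delay τ_delay (default 0.14 s, the
earliest muscular response to a stance perturbation). During the delay the
body falls freely; the closed-form hyperbolic solution shows that a
perturbation is amplified by exp(S), where

    S = τ_delay / τ_mech

is the *relative speed*, the single dimensionless number coupling mechanics
and delay. Feedback is a delayed proportional–derivative (PD) law, optionally
extended with undelayed mechanical damping, delayed acceleration feedback
(PDA), or delayed integral feedback (PID).

## Stability charts

In dimensionless gains P = p τ_delay², D = d τ_delay, the PD loop's stable
region in the (P, D) plane is bounded by the static line P = S² and the
oscillatory boundary P(x) = (x² + S²) cos x, D(x) = (x² + S²) sin x / x,
x > 0. Membership is decided geometrically: the first arc of the parametric
curve is sampled on 2000 points up to its return to the static line (found
by bracketed root finding on a cancellation-stable form of the crossing
equation), closed along the static line into a polygon, and point-in-polygon
plus boundary distance are delegated to shapely. The region is empty for
S ≥ √2. The geometric verdict is validated in the test suite against an
independent delay-differential-equation (DDE) oracle: a vectorized
Runge–Kutta method-of-steps integration of gain grids, classifying decay vs
growth of the response envelope over 30 delay periods, with points within
5% of the boundary excluded as numerically neutral. Near S = √2 the loop is
sluggish on both sides of the boundary, so fewer grid points resolve within
the horizon; the agreement requirement applies to all decisive points.

## Generalized critical damping

The delay exp(−X) in the characteristic equation (X = τ_delay λ) is replaced
by a Padé approximant — first order, (1 − X/2)/(1 + X/2), for PD, damped-PD
and PID; second order for PDA, where the extra polynomial order is needed to
absorb the acceleration term. Criticality of the resulting order-n
polynomial is defined as a unique negative root −ω₀ of multiplicity n,
generalizing the double root of ordinary critical damping; the recovery time
constant is τ_balance = τ_delay / ω₀ (the root lives in delay-normalized
time). For PD the coefficient matching has the closed form

    ω₀ = −2 + (16 − 4 S²)^{1/3},
    D_crit = 8 − 3 (16 − 4 S²)^{1/3},
    P_crit = 4 − S² + 6 (16 − 4 S²)^{1/3} − 3 (16 − 4 S²)^{2/3},

taking the real cube-root branch; ω₀ > 0 requires S < √2, the same bound as
region non-emptiness. The damped, PDA and PID variants solve their 3- or
4-equation coefficient-matching systems with a damped Newton iteration
(forward-difference Jacobian, backtracking line search, tolerance 1e−12,
at most 200 iterations), seeded from the PD closed form with A = 0 and
I = ω₀⁴/2. Seeding from the PD solution selects, by continuity, the branch
connected to PD as the extra gain vanishes; the PID branch automatically has
I = ω₀⁴/2 ≥ 0. Every returned solution is verified by re-expanding
(X + ω₀)ⁿ against the assembled polynomial; the constructor refuses to
return a solution whose maximum coefficient residual exceeds 1e−10.

Two inverse solvers support the co-adaptation strategies: bracketed root
finding on k_frac for the stiffness at which a prescribed per-inertia
proportional gain is exactly critical (P_crit/τ_delay² is strictly monotone
in k_frac), and the closed form k_frac = 1 − (τ_m,0 S/τ_delay)² for the
stiffness keeping S constant under a delay change. An S target of exactly 0
is realized by k_frac = 1, the critical-stiffness boundary of the model's
domain, and is returned as such rather than rejected.

## DDE simulation

The closed loop is integrated by the method of steps: the step is chosen so
the delay is an exact multiple of it (default τ_delay/200), making every
delayed quantity within an interval a known, already-computed history, and a
classical 4th-order Runge–Kutta step applies. Half-step history lookups use
4-point Lagrange interpolation on the uniform grid with stencils clamped to
the delay interval, so the cubic never spans the contraction-onset kinks at
multiples of τ_delay. The perturbation convention is an instantaneous unit
angle offset at t = 0 with zero velocity and identically-zero pre-history;
the controller output is therefore exactly zero until t = τ_delay. Two
one-sided-limit details are load-bearing for accuracy: history lookups that
land exactly on the perturbation instant use the limit consistent with the
interval being integrated (left limit 0 for the interval ending there, right
limit 1 for the one starting there), and for PDA the stored acceleration
history — which jumps at multiples of the delay — is patched to its left
limit at the right edge of the interval being read. Without these the scheme
degrades to roughly second order (observed self-convergence error ~1.5e−4
for the reference scenario); with them the grid-halving error is ~8e−14.
The `convergence_check` operation exposes this estimate; the test suite
requires < 1e−6 at the default step.

Torque decomposition (all normalized to weight): the weight torque equals θ
itself, the stiffness component of the ground reaction is k_frac·θ, and the
contraction component is τ_m,0²·(feedback law), since m g L cos Θ₀ = J/τ_m,0².
The centre-of-pressure trace is their sum. Peaks are signed maxima over the
run (the published traces are positive at their peaks); the integral state
of PID control accumulates the delayed angle from t = 0. Unstable runs are
flagged, not raised: integration stops when |θ| exceeds 1e6 and peaks are
reported up to that time.

Default horizon is 6 s (≈ 43 delay periods at the reference delay), which is
ample for the settling or divergence of every scenario considered; scenario
peaks occur within the first second.

## Strategy tables and sweeps

The reference system is 50% critical stiffness, 0.14 s delay, critical PD
gains. The gain-decrease/co-adaptation family cuts the proportional gain by
15%; the co-adapted stiffness is the inverse solve above, and both rows share
the co-adapted critical gain pair — the gain-decrease row is the same
controller applied at the un-adapted stiffness, which is the only reading
that reproduces the published derivative-gain cell. The delay family raises
the delay 20%; no-adaptation keeps the old gains, gain-adaptation recomputes
critical gains, co-adaptation keeps S constant. Percent changes are always
recomputed from unrounded values. Recomputation matches every published cell
at its printed precision except for three cells where the source's own
rounding is internally inconsistent at the last digit (its change columns
match our unrounded values); the tests compare those cells within one print
ulp and the discrepancy is documented there.

Sweep grids fill recovery-time, critical-gain and (optionally) peak-excursion
surfaces over a stiffness × delay grid; cells with S ≥ √2 are left undefined
(NaN). Note the "CoP peak decreases with delay" behaviour is local — it holds
from 0.14 s to roughly 0.17 s at 50% stiffness and reverses at longer delays.

## Modal reduction

A multi-joint linearized model τ_delay² θ̈ = M θ − C is reduced to
independent scalar problems by diagonalizing Mᵀ: each left eigenvector e_i
(M ᵀ e_i = s_i e_i) defines a modal coordinate α_i = e_i·θ with its own
relative speed S_i = √s_i for unstable modes; modes with s_i ≤ 0 do not
topple and are flagged rather than fed to the critical-gain solver. Only the
generic real-diagonalizable case is handled: complex eigenvalue pairs or an
eigenbasis with condition number above 1e8 raise an explicit error. Modes
are ordered by descending eigenvalue with a deterministic sign convention
(first nonzero component positive). Physical-coordinate gain matrices are
recombined as K = E⁻¹ diag(gain_i) E with E the matrix of left eigenvectors
as rows, acting as C = K_p θ(t−τ) + K_d τ_delay θ̇(t−τ). Equivalence of the
coupled vector DDE and the recombined scalar simulations is property-tested
on random diagonalizable 2×2 and 3×3 systems with positive eigenvalues of
spread ≤ 10 (agreement to 1e−8).

## What the defaults emulate, and limitations

The defaults are the published study conditions: τ_m,0 = 1/√9.81 s,
τ_delay = 0.14 s, 50% critical stiffness, unit angle perturbation. The model
is a linearization: constant ankle stiffness, unbounded CoP (no foot-length
saturation), no sensor noise, no torque limits, no stepping — so passing
tests demonstrate the linear closed-loop behaviour, not responses to large
perturbations where stiffness varies with sway amplitude. Criticality is
defined through the Padé polynomial, not the exact transcendental
characteristic equation; the critical gains are therefore approximations
whose quality is confirmed behaviourally (non-oscillatory, fast recovery in
simulation) rather than spectrally. Stability boundaries are implemented for
the pure PD loop only.

## Numerical choices at a glance

| Quantity | Value | Why |
|---|---|---|
| Integrator step | τ_delay/200 | grid-halving error ≪ 1e−6 |
| Horizon | 6 s | ≫ settling time of all scenarios |
| Newton tolerance / iterations | 1e−12 / 200 | small polynomial systems |
| Multiple-root residual bound | 1e−10 | hard constructor guarantee |
| Boundary arc samples | 2000 | grid error ≪ 1e−6 membership tolerance |
| Eigenbasis condition limit | 1e8 | "generic diagonalizable" cut-off |
| Divergence flag | \|θ\| > 1e6 | unstable runs reported, not raised |
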