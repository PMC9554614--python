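# Model and methods

`nanosyn` simulates a single glutamatergic synapse as three coupled pieces:
particle-based glutamate diffusion in the cleft, Markov-chain AMPA-receptor
gating, and a quasi-static finite-volume solve of the cleft electric
potential.  This note records the model equations, the numerical choices, and
the points where the design was genuinely open.

## Geometry and release

The cleft is a cylinder of radius `R` = 1000 nm and height `H_c` (default
20 nm, physiological range ~5–50 nm).  The presynaptic membrane is the plane
z = 0, the postsynaptic membrane (carrying the receptors) z = `H_c`.  At
t = 0 a vesicle of radius `r_ves` = 20 nm releases `nnt` glutamate molecules
instantaneously: initial positions are area-uniform on a disk of radius
`r_ves` at z = 0, centred `release_offset` nm from the synapse centre.  A
20 nm vesicle holds ≈3.35×10⁻²³ m³; at vesicular concentrations of
50–300 mM that is ~10³–6×10³ molecules, which motivates the 200–20,000
range of `nnt`.

## Glutamate diffusion

Each free molecule performs a fixed-step random walk: per time step
`dt` (default 50 ns) it moves a distance √(6 D dt) — 9.49 nm at
D = 0.3 μm²/ms — along an isotropic unit vector drawn as
(sin φ cos θ, sin φ sin θ, cos φ) with θ = 2πa, φ = arccos(1−2b),
a, b ~ U[0,1).  Boundaries: reflection at both membranes (z < 0 → |z|;
z > H_c → 2H_c − z; an overshoot beyond one extra reflection aborts with an
error advising a smaller step), absorption at the rim (x² + y² ≥ R²,
modelling astrocytic clearance).  A fixed-length step reproduces free-space
Brownian statistics at this resolution; the test suite and the acceptance
script verify MSD(t) = 6Dt by linear fit.

### Nanocolumn hindrance

Trans-synaptic filaments inside the nanocolumn zone (diameter `D_ani`,
centred on the synapse axis) are homogenized into an anisotropy coefficient
`ani` ∈ [0, 1): while a molecule's pre-step (x, y) lies inside the zone, the
lateral components of its displacement (Brownian and electrophoretic) are
multiplied by (1 − ani); z motion is unaffected.  Note this scales the
lateral *displacement*, hence the lateral diffusion *coefficient* by
(1 − ani)² — the helper `displacement_to_diffusion_reduction` converts
between the two conventions, which the literature sometimes conflates.

The link to obstacle density: for regularly spaced cylindrical obstacles
filling a fraction σ of the plane, the effective lateral diffusion is reduced
by 1 − σ (dilute) or by 2√(π/4 − σ) / (π^{3/2}(1 − π/4)) (dense).
`diffusion_reduction_from_filling` switches branch at their intersection
(σ ≈ 0.765) so the factor is continuous; the inverse solves the dense branch
by bracketed root finding (tolerance 10⁻⁶).  A 90 % lateral reduction
corresponds to σ ≈ 0.78.

## Receptor placement

`n_c` nanocolumn receptors have radial distance drawn as −`R_std`·ln(1 − u)
(angle uniform), `n_r` receptors are area-uniform over the PSD disk
(diameter `D_dr` = 400 nm).  The radial rule is implemented verbatim; note
that although the source literature describes the cluster as a
two-dimensional Gaussian of standard deviation `R_std`, the stated sampling
formula is an exponential radial law (mean `R_std`), which places more
receptors near the centre than a Rayleigh/Gaussian profile would.  A
hard-core constraint keeps receptor centres ≥ 10 nm apart (receptor
footprint); positions violating it are redrawn, with a 10,000-redraw bound
per receptor so infeasible packings fail deterministically instead of
hanging.  Nanocolumn receptors are not confined to the PSD (only to the
cleft radius); the uniform group is confined to the PSD by construction.

## Binding

A receptor is a point (x, y) on the postsynaptic membrane with a binding
radius `b_rad` = 5 nm, matching the ~5 nm protrusion and ~7 nm footprint of
the real channel.  A molecule is capture-eligible when it is inside the
volume the receptor physically occupies: lateral distance ≤ `b_rad` and
within `b_rad` of the postsynaptic membrane (a 5 nm cylinder).  The
bimolecular rates (M⁻¹s⁻¹) are converted to per-step probabilities through
the equivalent concentration of one molecule in the binding half-sphere,
C_eq = 1/(N_A · (2/3)π b_rad³) ≈ 6.34 mM, giving

    p_capt = k_on · C_eq · dt

per eligible (molecule, receptor) pair and step (≈5.8×10⁻³ for the first
binding step at 50 ns).  An error is raised if this product reaches 1.
Eligible molecules are visited in randomized order with at most one binding
per molecule and per receptor per step.  A bound molecule is frozen; on
unbinding it reappears at the receptor centre, 0.1 nm beneath the
postsynaptic membrane, which makes immediate recapture possible and is the
main driver of the slow decay tail.

Two rejected alternatives, for the record: a hemispherical eligibility
region (3D distance to the receptor centre at z = H_c) reproduces only
~60–80 % of the reference capture statistics, and an xy-only criterion with
no z window (the full cleft column) overshoots them by ~2×; both were
checked against an exact well-mixed association-rate calibration (the
particle scheme reproduces k_on·C to <1 % at equilibrium) and an independent
mean-field continuum model, so the choice is a geometry question, not a
rate-calibration one.

## Receptor gating

Nine states: C0, C1, C2 (closed, 0/1/2 glutamates), O2 (open), D1
(desensitized, 1), D2a–D2d (desensitized, 2).  Edges and rates (binding in
M⁻¹s⁻¹, everything else s⁻¹):

| edge | rates (fwd / back) |
|---|---|
| C0 ⇌ C1 | K1 = 1.8412×10⁷ / K−1 = 4323 |
| C1 ⇌ C2 | K2 = 4.000×10⁶ / K−2 = 17201 |
| C2 ⇌ O2 | β = 51690 / α = 10082 |
| C1 ⇌ D1 | K4 = 885.99 / K−4 = 280.35 |
| D1 ⇌ D2a | K3 = 1.9863×10⁷ / K−3 = 1168 |
| C2 ⇌ D2a | K5 = 449.03 / K−5 = 1.944 |
| D2a ⇌ D2b | K6 = 2.797 / K−6 = 0.0395 |
| C2 ⇌ D2b | K7 = 1380 / K−7 = 421.85 |
| C2 ⇌ D2c | K9 = 51.7 / K−9 = 29.164 |
| D2c ⇌ D2d | K8 = 848.14 / K−8 = 538.92 |
| O2 ⇌ D2d | K10 = 939 / K−10 = 24.463 |

The wiring of the desensitized branch is constrained rather than fully
determined by the published description; this transcription satisfies every
stated structural property — exactly three binding edges (K1, K2, K3), a
single open state, glutamate count conserved on all conformational edges,
C0 the unique absorbing state without ligand — and places the slow
desensitization exits on K−7, K−9, K−10, consistent with the ~25 ms average
dwell in the desensitized pool.  Quantities dominated by the certain part of
the scheme (binding, β/α, K−1/K−2) are insensitive to the residual
ambiguity; desensitization time courses in long trains are the most exposed.

Per step each receptor takes at most one non-binding transition, chosen by a
single categorical draw over its outgoing edges with probabilities
rate·dt (stay probability 1 − Σ rate·dt; an error is raised if the sum
reaches 1; at the default dt every rate·dt < 3×10⁻³).  The sampled dynamics
are tested against the matrix exponential of the generator under fixed
ligand concentration.  `affinity_scale` multiplies K1 and K2 only
(pharmacological affinity changes); K3 is deliberately untouched.

## Cleft potential and current

With capacitive currents neglected, charge balance in each 20 nm × 20 nm
element (i, j) of the cleft disk reads

    n_ij g_unit (v_ij − E) = −[4 v_ij − v_{i−1,j} − v_{i+1,j} − v_{i,j−1} − v_{i,j+1}] · H_c / Res

with n_ij the open channels in the element, g_unit = 25 pS, Res = 200 Ω·cm,
and Dirichlet v = 0 on the out-of-disk ring.  The sign convention follows
the parameter table (E = 65 mV): v ≥ 0 is the cleft depolarization, the
effective driving force of an open channel is E − v, and the total current
is I = Σ n_ij g_unit (E − v_ij) — 1.625 pA per channel when the field is
disabled.  An element belongs to the disk iff its centre is within R.

`solve_potential` solves the sparse system directly.  The engine instead
uses an exactly equivalent reduced path: the Green's-function block
W = Uᵀ K⁻¹ U of the Dirichlet Laplacian at the receptor-occupied elements is
precomputed from one sparse LU factorisation, and each open-configuration
change solves the small dense system (I + W C) v_S = W C E (C = diag of
n·g_unit), giving the source potentials, the injected currents
q = C(E − v_S), and — when electrophoretic drift is on — the full grid
potential by one triangular solve on the sparse source vector.  The solve is
repeated only on steps where the open-channel configuration changed; both
paths are asserted equal in the tests.  The discrete maximum principle
guarantees the spatial maximum of v sits on a source element, which is how
the per-repetition maximal depolarization is tracked.

Charged glutamate (valence −1) feels the lateral field: the per-step drift
is dt · (1−ani) · ∇v · D F/(Rg T), with ∇v from centred differences
(one-sided at the rim).  The term is retained by default although its effect
on the current is below 1 %.

## Engine

All Monte Carlo repetitions of a scenario advance together as one batched
state; the per-molecule inner loop (move, reflect, absorb, collect binding
draws) is a single numba kernel call per time step, so Python overhead is
independent of the repetition count (~35–40 ns per molecule-step on one
core).  Randomness uses three streams spawned from the root seed — layout,
molecules+binding, receptors — making runs bit-reproducible for a fixed
seed.  Layout policy: redrawn per repetition by default, shareable via
`fixed_layout` (the opening-statistics protocol fixes the layout so
per-receptor counts are comparable across repetitions).

Release trains (`run_train`) re-release `nnt` molecules every 1/f seconds
with receptor states, molecule pools and layouts persisting across events.
Optional receptor lateral diffusion uses a 10 nm exclusion lattice: per step
a receptor attempts a move with probability 4·D_r·dt/h² (2×10⁻⁴ at
D_r = 0.1 μm²/s) in one of four directions, succeeding only onto a free
cell; a receptor stepping off the synapse is replaced by a fresh closed
receptor at a random rim cell (its cargo released in place).  A confined
variant keeps each receptor group on its side of the nanocolumn edge so the
in/out proportions stay fixed.  Default single-release duration is 3 ms;
trains run n_events/f.

## Current analysis

Summary metrics are taken from the ensemble-mean trace: peak current, peak
conductance (n_open·g_unit), total charge Q by trapezoidal integration
(pA·ms = fC), effective driving force (peak I / peak g), and the proportion
of neurotransmitter captured (PNC: fraction of released molecules with at
least one capture).  The biexponential template

    I(t) = Q/(τ_decay − τ_rise) · (e^{−t/τ_decay} − e^{−t/τ_rise})

is fitted by Levenberg–Marquardt least squares on (Q, log τ_rise, θ) with
τ_decay = τ_rise + e^θ, which enforces the ordering that resolves the
rise/decay interchange symmetry.  Initialisation: τ_rise from half the time
to peak, τ_decay from a log-linear tail fit, Q from the trapezoidal
integral; five jittered restarts guard against the symmetry-induced local
optima.  Q is reported both from the fit and from the integral; they agree
within a few percent on well-converged ensemble means.

## Problem sizes

The test suite runs the single-release protocols at 4–20 repetitions and the
acceptance script at 8–60 (fractions over (receptor, repetition) pairs have
Monte Carlo standard errors well under a percentage point at these sizes;
charges and peak ratios carry a few percent).  Peak-only protocols use
0.7–0.8 ms horizons since the transient peaks before 0.4 ms; charge and
opening-count protocols use the full 3 ms.  Ratios of peak currents between
two diffusion coefficients are computed as a paired design: both runs share
one seed, so receptor layouts and random-number sequences are common and
most of the between-run variance cancels in the ratio.

## What the model does and does not capture

The simulated conditions are those of the reference synapse model: quantal
release is instantaneous, the intracellular potential is clamped (no spine
depolarization), the rim is perfectly absorbing (astrocytic uptake is not
modelled beyond it), filaments are homogenized rather than geometric
obstacles, receptors outside/inside the nanocolumn differ only in placement,
and NMDA or other receptor classes are absent.  Passing tests therefore
demonstrate internal consistency with this idealised synapse, not agreement
with any particular experimental recording.  Known quantitative limitations:
the desensitized-branch wiring is a constrained transcription (see above),
and the peak *simultaneous* open count is capped near β/(α+β) ≈ 0.84 of the
receptor pool, so cleft depolarizations corresponding to a fully open
configuration are approached but not reached by the stochastic dynamics.
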