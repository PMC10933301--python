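# Methods

## Model overview and assumptions

`reefconn` treats coral larvae as positively buoyant, otherwise passive
surface drifters: no vertical migration, swimming, diffusion term or
wind/Stokes drift.  A particle released at a reef cell represents a large
cohort of larvae whose physiological state evolves along the trajectory
through a two-compartment linear system — pre-competent L₁ and competent
L₂ — with competency acquired at rate α only after a minimum period t_c,
lost at rate β, mortality μ_m(t) acting on both compartments, and
settlement removing competent larvae at rate μ_s·F_r(t) whenever the
occupied cell carries reef habitat (F_r > 0).  All reef habitat is assumed
equally suitable; there is no post-settlement mortality or density
dependence, so the resulting potential connectivity is an upper bound on
realised per-generation exchange.

Potential connectivity is accumulated per spawning date as
C[source, destination] = settled / released, at reef-cell or reef-group
level; group aggregation weights rows by released larvae (ρ·A_i), which
conserves totals exactly.  Dispersal is highly stochastic, so single-date
matrices are resampled into an ensemble of "short-term" matrices (mean of
k random spawning dates each), every replicate is partitioned by the
two-level map equation, and the consistency of the resulting modules
across the ensemble is read off a PCA of the membership matrix.

## Parameters

| parameter | meaning | unit | default | note |
|---|---|---|---|---|
| α | competency acquisition rate | d⁻¹ | 0.33 (preset) | zero before t_c |
| t_c | minimum competency period | d | 3.2 (preset) | step split exactly at t_c |
| β | competency loss rate | d⁻¹ | 0.147 (preset) | lost larvae leave the system |
| μ_s | settling rate over full reef | d⁻¹ | 1.0 | scales all S_j linearly |
| μ_m(t) | mortality | d⁻¹ | Weibull(λ=0.055, ν=0.85) | constant mode available |
| ρ | fecundity | larvae m⁻² | 1 | cancels in proportional connectivity |
| N | particles per reef cell | – | 4 | summed connectivity independent of N |
| T_max | drift cap | d | 120 (30 in the demo) | |
| max_events | settling events kept per particle | – | 60 | earliest first |
| dt | advection/fate step | d | 0.02 | RK4; convergence verified |
| season | spawning months | – | Oct–Mar | seasonal subset |
| n_rep × k | bootstrap ensemble | – | 1000 × 10 (100 × 10 in the demo) | with replacement |
| τ_tel | teleportation probability | – | 0.01 | uniform, unrecorded |
| n_restarts | optimiser restarts | – | 10 | seeded; ties → lowest id |

The two shipped larval presets (`platygyra_daedalea`, `acropora_valida`)
are representative literature-scale values for broadcast-spawning
scleractinians — direct measurements for *Porites lutea* do not exist —
with *A. valida* given the lower mortality (λ=0.040, ν=0.74) and the
longer competency window (β=0.033) of the two.  They are defaults to be
overridden, not species claims; no test or reported quantity depends on
their exact values.

## Numerical scheme

**Advection.** Classic fixed-step RK4 on velocities interpolated
bilinearly between cell centres (clamped at the domain edge, nearest
sampling on single-cell axes) and linearly in time; periodic fields wrap
the query time modulo their period.  On solid-body rotation — where the
interpolation is exact — the global error contracts ≥ 8× per dt halving,
the RK4 signature.  Cell occupancy uses 0-based indices and half-open
intervals [edge_k, edge_{k+1}) on both axes.  Boundary policy: a particle
whose cell is land sticks (fate dynamics continue); a particle leaving the
open boundary is frozen and flagged, and the remainder of its record
counts as off-reef.  Sticking rather than reflecting avoids inventing
momentum the flow field never had.

**Larval fate.** F_r and μ_m are piecewise-constant per trajectory step
(F_r at the step start; μ_m through its average hazard
(H(t₁)−H(t₀))/(t₁−t₀), which keeps pure-mortality survival exact even for
Weibull hazards).  Within each step the exact 2×2 linear propagator and
the exact step integrals ∫L₁, ∫L₂ are evaluated; the step containing t_c
is split internally so α switches on at exactly t_c.  Consequently the
mass balance — settled + dead + competency-lost + drifting = released —
closes to ~1e-15 relative, and settling integrals agree with adaptive
quadrature of closed forms to the same precision.  The difference
quotients in the propagator are computed in cancellation-free expm1-based
forms (extended precision for the integral term), with explicit limit
expressions when |g−a|·h < 1e-12; Weibull hazards with shape < 1 have an
integrable singularity at t = 0 whose *rate* is capped at 1e6 d⁻¹ (logged
once) while the cumulative hazard stays exact.  A settling event ends
when the particle changes grid cell — each event needs a single F_r — and
at most 60 events are kept per particle, earliest first.

**Map equation.** The stationary distribution comes from power iteration
on the row-normalised weights mixed with uniform teleportation (dangling
nodes redistribute uniformly), converged at L1 change < 1e-12 (hard cap
1e5 iterations, error on failure).  Teleportation is *unrecorded*: it
smooths visit rates, but only link transitions — q_ij = (1−τ)·p_i·W_ij/W_i
— carry codelength.  The two-level codelength uses base-2 logs with
0·log 0 = 0; a one-module partition with no teleportation reduces to the
entropy of the visit rates (exactly 2 bits on the uniform 4-cycle).  The
optimiser alternates greedy node-moving sweeps (candidates: modules of
in/out neighbours; accept strict decreases > 1e-13; ties to the lowest
module id) with best-pair module merges until a local minimum, over
seeded restarts with shuffled node order.  On every ≤ 8-node fixture
graph it attains the exhaustive-enumeration optimum; no hierarchical
recursion is attempted (two-level only).

**Membership PCA.** Module ids are arbitrary per replicate, so before the
PCA each replicate's modules are renumbered 1..K by decreasing total
stationary flow (ties to the lowest original id) — this leaves
co-assignment structure untouched and makes the integer labels comparable
across replicates.  The PCA is centred but not scaled; a membership
matrix with no variance at all is flagged degenerate instead of emitting
NaNs.  Encoding categorical module ids as integers mirrors the
membership-vector-PCA approach this pipeline quantifies; a co-membership
alternative can be built from the same partitions if robustness checks
are wanted.

## Generations to a common ancestor

No standard formula exists for "how many generations until two reefs
share a common ancestor" from a connectivity matrix, so the package
defines one explicitly: threshold the matrix at ε (edge source→destination
where C ≥ ε, i.e. at least the chosen per-generation colonisation), let
d(k, i) be the BFS step count k→i, and set
g(i, j) = min_k max(d(k, i), d(k, j)).  A node is its own lag-0 ancestor
only through self-recruitment (C[k,k] ≥ ε); otherwise its self-distance is
its shortest return cycle (infinite if none) — a population with no
inflow cannot persist to be anyone's ancestor.  The suggested ε is
1/(ρ·ΣA_i), "at least one expected larva", a package choice stated here
rather than a fixed constant of the method.

## Synthetic study conditions

The generators emulate the *structure* of real inputs — a gridded
hindcast, satellite-derived reef fractions, daily spawning calendars,
assignment-method migration matrices — not their content:

- **Ocean**: analytic fields (uniform, solid-body, double gyre) on a flat
  Cartesian 2000 × 1000 m box with 50 m cells.  The double gyre
  (amplitude 0.05 m s⁻¹, period 10 d) is the canonical two-cell flow with
  an impermeable separatrix at perturbation 0 and a weakly leaking one at
  perturbation 0.05 (cross-gyre connectivity roughly an order of
  magnitude below within-gyre exchange under these conditions).
- **Reefs**: four planted clusters of four cells, two per gyre, placed
  mirror-symmetric on a shared orbit near the separatrix so that the pair
  exchanges larvae in steady flow and the perturbed flow leaks between
  the halves.  Reef fractions are Beta(2, 2) draws — the distribution of
  satellite-derived fractions is unknown, this is a stand-in, not an
  inference.
- **Calendar**: daily dates restricted to October–March; the demo thins
  to every 9th day (≈ 20 dates per season).
- **Gene flow**: row-stochastic matrices with configurable
  self-recruitment diagonal (high values, 0.77–0.84, are typical of
  assignment estimates on reef corals), block-structured off-diagonal
  bias and log-normal noise; the closed-loop variant is built directly
  from the modelled ensemble mean.

Demo/acceptance problem sizes, chosen as desk-scale study conditions: 16
reef cells × 4 particles, 30-day drift at dt = 0.02 d, ~20 spawning
dates, 100-replicate ensembles for clustering (the 1000 × 10 ensemble
statistics are exercised where only resampling, not clustering, is
needed).  What passing tests show is that every stage is *correct* —
against closed forms, quadrature, enumeration and planted truth.  What
they cannot show: realism of mesoscale ocean variability (the gyre's
stochasticity is a single deterministic oscillation sampled at different
phases), reef-scale bathymetric steering, larval behaviour, or the
sampling noise of real genetic assignment — so quantitative outputs are
method demonstrations, not predictions for any real reef system.

## Determinism

Every random choice flows from one master seed, split per generator/stage
by a CRC-based deterministic derivation (children < 2³¹).  Artifacts are
NetCDF3 (scipy backend — byte-stable), CSV and sorted-key JSON; the
pipeline manifest records package version, seeds and SHA-256 hashes of
every artifact, and an identical configuration reproduces it byte for
byte.

## Known limitations

- Flat Cartesian geometry by default; the spherical mode applies only the
  cos(latitude) metric, no projection subtleties.
- Land is a zero-velocity mask; no coastline geometry, bathymetry or
  tides.
- The greedy optimiser guarantees a local map-equation minimum (global on
  the tested small graphs); very large graphs would want the aggregation
  phase of a full Infomap implementation.
- Gene-flow comparison is deliberately scale-free (orders of magnitude,
  feasible ranges): no demographic conversion from potential connectivity
  to per-generation migration is attempted.
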