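# Methods

## Model

The spatial inspection game is a pairwise game on an L × L square
lattice with periodic boundary conditions (a torus) and von Neumann
(four-neighbor) interactions. Three roles compete: ordinary people O,
criminals C, and punishers of rank r ∈ {1/3, 2/3, 1} (labelled L, M and
H in the heterogeneous model; the uniform model's single punisher P is
the r = 1 punisher under another name). Per pairwise interaction, with
punishment cost α, temptation/victim-loss β, punishing reward γ and the
fine normalized to 1, the focal player's payoff is

| focal \ opponent | O      | C          | rank-r′ punisher |
|------------------|--------|------------|------------------|
| O                | 0      | −β         | 0                |
| C                | β      | 0          | β − r′           |
| rank-r punisher  | −r·α   | r·(γ − α)  | −r·α             |

Three conventions close gaps the parameter description leaves open, and
are validated empirically (see *Validation*): punishers do not suffer
the victim loss when meeting criminals (their net gain is the reward
minus cost); punishers pay the inspection cost in **every** interaction,
reflecting cost-of-inspection semantics rather than a per-criminal fee;
and the fine scales with rank like the cost and reward do, so criminals
can exploit milder punishers. Criminals exchange nothing with each
other. Payoffs are summed over the four neighbors without
normalization.

Variants: `three_strategy` {O, C, P}, `five_strategy` {O, C, L, M, H},
and `minimal_CLM`, the five-strategy matrix restricted to {C, L, M},
which isolates the interface dynamics between the criminal domain and
the two punisher domains.

## Update protocol

Random sequential update: each elementary step draws a site x uniformly
at random (with replacement, not a permutation sweep), computes Π_x
fresh from the current grid, draws one of its four neighbors y
uniformly, computes Π_y the same way, and lets x adopt s_y with the
Fermi probability W = 1/(1 + exp[(Π_x − Π_y)/K]). Self-imitation (s_y =
s_x) is allowed and is a no-op; payoffs are never cached. One Monte
Carlo step (MCS) is L² elementary steps. The noise K = 0.5 throughout:
better-performing neighbors are readily imitated but errors remain
possible. The exponent is clamped at |arg| = 700 so extreme payoff gaps
saturate to probability 0/1 instead of overflowing.

## Implementation and reproducibility

Two engines run identical dynamics: a numba-compiled kernel and a
literal pure-Python transcription of the rule above. Both consume the
same pre-drawn random stream — per elementary step one site index, one
neighbor pick and one acceptance uniform, generated per sampling block
by a single PCG64 generator seeded from the run seed (which also seeds
the initial state). For a given configuration the two engines therefore
produce bit-identical trajectories; the test suite asserts this on 8×8
lattices over 100 MCS for all three variants, which validates the
kernel against the plainly-readable reference. Replicate r of a run
uses seed `base_seed + r`. Homogeneous lattices are absorbing, so a run
that fixates stops early and pads the remaining samples.

A further engine oracle: with all payoffs forced to zero the Fermi rule
reduces to neutral (voter-model) imitation, whose fixation probability
equals the initial density because the density is a martingale; 2000
10×10 runs started at density 1/2 must land within 3σ of 1/2.

## Initial states

`uniform_random` draws every site independently and uniformly over the
variant's strategies (the default protocol); `weighted_random` uses
given per-strategy probabilities; `blocks` tiles vertical stripes. The
prepared state for the minimal-model interface experiment is equal-width
L | M | C stripes — the published snapshot layout is not described in
text, but the stationary outcomes are insensitive to the initial
arrangement (the tests verify that uniform-random starts reach the same
stationary fractions), so any layout that brings all three interfaces
into contact serves.

## Stationarity, phases, sweeps

The stationary state is declared when the per-strategy mean fractions
of two consecutive non-overlapping windows (default 100 MCS each)
differ by at most tol = 0.01. This two-window criterion is a *trailing*
detector: it can fire no earlier than two windows after the drift
actually stopped. `Stationarity` therefore reports both the detection
time (`onset_mcs`) and the start of the demonstrated stationary stretch
(`reached_mcs` = detection − 2 windows, clipped at the series start);
the latter is the quantity to compare against statements of how fast a
stationary state is reached. A series shorter than two windows is
inconclusive, distinct from "not stationary".

A strategy survives a replicate when its final site count is positive
and its time-averaged fraction over the final 200 MCS exceeds
eps_extinct = 10⁻³ (the finite-lattice noise floor at L ≈ 100–200). A
phase point takes the majority surviving set over replicates; a tie
escalates the replicate count once (2×) before the point is flagged
unresolved, as is any point where no replicate reaches stationarity.
Transitions along a sweep are reported at the midpoint between adjacent
grid values whose surviving sets differ; no bisection refinement is
attempted and second-order transition points are not localized
precisely. Pairwise invasion runs start from two half-lattice blocks so
that interface motion, not mixing noise, decides the outcome.

## Problem sizes and defaults

Production-scale studies of this model use lattices of 600² up to 9000²
sites and relaxation times up to 10⁵ MCS near boundaries. This package
runs the same protocol at desk scale, chosen so every reported number
is stable across seeds: the minimal C+L+M model at L = 150 with 10
replicates of 1000 MCS (its three stationary outcomes form within ~400
MCS and replicate standard deviations are below 0.005); phase sweeps at
L = 100–120 with 3000–4000 MCS and 2–3 replicates on grids whose points
sit away from phase boundaries. Close to a boundary, accidental
extinctions on small lattices can misclassify a point — the escalation
knobs (larger L, longer budget, more replicates) are exposed but the
default grids avoid the issue instead.

## Validation of the payoff reconstruction

The payoff table above is accepted because it reproduces, without any
tuning, the published behavior it must explain: the sign structure at
α = 0.5, γ = 1.5 (M invades C at β = 0.5 while C coexists with L, C
coexists with M at β = 0.9; L always beats M head-to-head); the minimal
model's three stationary criminal fractions f_C ≈ 0.46 / 0.40 / 0.27 at
β = 0.5 / 0.9 / 0.7 (measured 0.460 / 0.386 / 0.270 at L = 150); the
six-transition phase sequence (O+C+L) → (C+L) → (C+L+M) → (C+M) →
(C+M+H) → (C+H) → (C) along β at γ = 1.5; the three-strategy cross
sections O+C+P → C+P → C (β ascending at γ = 0.8) and C → C+P → O+C+P
(γ ascending at β = 0.8); and the cyclic dominance loop C beats O, P
beats C, O beats P inside the coexistence region. Note that the cycle
is a statement about the O+C+P phase: at parameter points inside the
C+P phase (e.g. β = 0.8, γ = 0.8) the pair P/C genuinely coexists in
head-to-head competition, which is what makes that a coexistence phase.

## Known limitations

* Only the square lattice with von Neumann neighborhoods is
  implemented; no other topologies or update rules (birth–death,
  permutation sweeps).
* Desk-scale lattices cannot resolve transition points sharply or
  support finite-size scaling; transition locations are grid midpoints.
* The synthetic dynamics are exactly the model — there is no real-world
  crime data in the loop, so agreement of tests says the *simulator*
  reproduces the model's published phenomenology, not that the model
  describes empirical crime statistics.
* Whether the published implementation re-drew the neighbor when
  s_y = s_x is unknown; the choice only rescales time and does not
  affect stationary states.
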