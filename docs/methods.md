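# Methods

## Model

A population of N players occupies the vertices of a simple, connected,
k-regular graph with adjacency indicator w_ij (k ≥ 3; degree-2 graphs are
cycles, whose pair approximation is qualitatively different, and are
rejected everywhere).  Each player carries a pure strategy from
{A_1, …, A_n}; the payoff structure is an *ecological field*: an n×n
matrix a^{ij} for every ordered pair of neighbors, with a^{ij}_{rs} the
payoff to the player at i using A_r against the neighbor at j using A_s.
A player's realized payoff is the sum over its k neighbors, and fitness is
f_β(π) = e^{βπ} with selection intensity β ≥ 0.

Four elementary update processes are implemented.  Death-birth: a uniform
player dies and its neighbors compete for the vacancy proportionally to
fitness.  Birth-death: a player reproduces proportionally to fitness over
the whole population and the offspring replaces a uniform neighbor.
Imitation: a uniform focal player keeps or adopts a strategy with
probabilities proportional to fitness over the k+1 candidates (itself and
its neighbors).  Pairwise comparison: a uniform focal player adopts a
uniform neighbor's strategy with the Fermi probability
1/(1+e^{β(π_f−π_m)}).  Death-birth and birth-death are *genetic* (the
replaced vertex receives the parent's genotype along with its strategy);
imitation and pairwise comparison are *cultural* (genotypes are immutable
vertex attributes).

Simulated payoffs are always realized sums over the actual neighborhood
configuration; expected payoffs against equilibrium neighbor distributions
appear only in the analytic layer.  This matters: the processes act on
configurations, and the analytic expectation is a derived description.

## Pair approximation and the averaged game

Writing p_r for strategy frequencies and q_{s|r} for conditional neighbor
frequencies, weak selection separates time scales: pair frequencies reach
the local equilibrium q_{r|s} = p_r + (δ_sr − p_r)/(k−1) at order one,
while strategy frequencies move at order β.  At that equilibrium the exact
first-order expected change per elementary update depends on the field
only through its edge average ā_st = (1/kN) Σ_ij w_ij a^{ij}_st:

- death-birth:  E[Δp_r] = β (k−2) p_r / (k(k−1)N) · B_DB(p)
- imitation:    E[Δp_r] = β k(k−2) p_r / ((k−1)(k+1)²N) · B_IM(p)
- pairwise:     E[Δp_r] = β (k−2) p_r / (2(k−1)N) · B_PC(p)
- birth-death:  E[Δp_r] ∝ β p_r · B_BD(p)

where each bracket B is an explicit quadratic in p built from ā (see
`pairapprox._bracket`).  Each bracket factors exactly as a positive
constant times the replicator form Σ_s p_s(ā_rs + b̄_rs) − φ with the
corrections stated in the README; this identity is asserted numerically in
the test suite for random matrices, degrees, and simplex points.  A
documented subtlety: the death-birth correction is the (k+1)-weighted one
and birth-death/pairwise comparison share the simple (k−2) form — this is
the assignment consistent with the derivation endpoints, with the b̄/c̄ > k
death-birth threshold, and with the genotypic increase conditions below;
sources sometimes present the two genetic corrections with swapped labels.

The birth-death prefactor contains the total population fitness, which has
no closed form; birth-death predictions are therefore *proportional-only*
(unit constant, flag raised, and the profile overlay refuses to run unless
the caller supplies a constant — a least-squares fit against a simulated
profile is the intended way to obtain one).

Spatial additivity (a^{ij}_rs = x^i_rs + y^j_rs) makes ā — and hence every
weak-selection prediction — independent of the wiring.  The additivity
tester fits the decomposition per entry by sparse least squares over the
directed edges; the model is identifiable only up to a constant shift per
entry, fixed by the gauge Σ_j y^j_rs = 0.  The additivity tolerance
defaults to 1e−9 absolute because every built-in field is an exact closed
form; the donation field and the half-split Snowdrift field are additive,
the fair-split Snowdrift field is not once two adjacent costs differ.

Genotypic asymmetry reduces to ecological asymmetry under cultural rules
(M^{ij} = M^{u(i)u(j)}, genotypes never move) and to a larger symmetric
game over composite (genotype, strategy) pairs under genetic rules.
Composite strategies with exactly identical payoff rows and columns are
merged without tolerance (the merge is exact by construction); for the
Donation Game all defector composites collapse, leaving ℓ+1 strategies.
For that merged game the death-birth sign condition reduces algebraically
to k(c_u − Σ_v c_v p_v) < b_u − Σ_v b_v p_v and the birth-death condition
to c_u < Σ_v c_v p_v; the tests verify sign agreement between these
predicates and the composite-matrix expectation on random parameter grids.

## Simulation protocol

The profile protocol mirrors the reference experiments: each cycle draws a
density d ~ U[0,1], seeds every vertex as a cooperator independently with
probability d, and runs to fixation; after every sweep of N elementary
updates the change in cooperator frequency is recorded against the
starting frequency.  Cycles repeat until every target interior bin has the
requested number of samples; exhausting the cycle budget instead yields a
"partial" profile with per-bin counts and a warning, never an exception.
Two protocol details the source experiments leave open are exposed as
configuration: the per-cycle update cap (default 10^4·N, chosen because
neutral absorption at desk scale is of order N² pair updates) and the
target bin set (default: all interior bins).  Because every sweep record
is an unbiased draw of the conditional per-sweep change given the starting
bin, capping a cycle early changes how samples are allocated across bins
but not the quantity each bin estimates; the cap is deliberately lowered
(a few hundred sweeps) for strongly selected Snowdrift runs, where a
metastable interior attractor makes absorption times astronomically long.

Engine internals: payoffs are cached and updated incrementally (a flip at
v touches only v and its neighbors; an audit test compares against a full
recompute every few hundred updates); fitness-proportional choices use
cumulative sums over the small candidate sets; birth-death normalizes by
the exactly computed population fitness.  One top-level seed drives
everything: per-cycle kernel seeds are drawn from a seeded generator, so
every output is bit-reproducible from its configuration, and the CLI
writes a JSON manifest (configuration echo plus versions) next to every
output table.

## Problem sizes and what the tests show

The bundled experiments run at desk scale: N=100, k=3, 500–1000 samples
per interior bin, with N=500 used only for exact (non-simulation) edge
averages.  The weak/strong selection contrast uses the equal-split
Snowdrift family (b=5.0, costs 34/13 and 70/13, pure or mixed half/half)
under death-birth: at β=0.01 the mixed-cost profile is statistically
indistinguishable (3 SE) from the pointwise average of the two pure-cost
profiles on ≥95% of bins, while at β=0.5 the same comparison fails by tens
of standard errors — the averaged-game description is genuinely a weak
selection statement.  The neutral checks (martingale to 1e−12, single
mutant fixation probability 1/N) are exact properties of the update rules,
not of the games.

The synthetic generators emulate the study conditions exactly: uniform
random regular graphs (pairing model, regenerated until connected, since a
disconnected component would make fixation ill-defined), Gaussian traits
(untruncated; negative draws are legal and logged, matching the stated
distributions), and two-valued cost splits with exactly round(qN) low-cost
vertices.  They do not emulate degree heterogeneity, weighted or directed
interactions, mutation, or trait-strategy correlations; agreement between
simulation and pair approximation here therefore says nothing about
networks with broad degree distributions, where the regular-graph closure
is known to degrade.

## Numerical choices

Exact one-step expectations enumerate all N·k (or N·(k+1)) outcomes in
float64; the β=0 zero is then exact to ~1e−16 and asserted at 1e−12.
Replicator trajectories use adaptive RK (rtol 1e−10, atol 1e−12) with a
simplex-drift guard at 1e−8 followed by renormalization; the dynamics at
n ≤ 4 are not stiff.  Ties in all uniform choices are resolved by the
generator directly.  Gaussian trait draws may produce negative costs;
they are accepted (the field definitions remain valid) and logged.

## Known limitations

- Birth-death analytic predictions are proportional-only (no closed-form
  time scale).
- The pair approximation is itself an approximation on any finite graph;
  simulated profiles show small systematic deviations near the absorbing
  boundaries (a single deviant player's fitness advantage makes the
  expected change weakly negative there for any β > 0 — reproduced
  exactly by the enumeration oracle).
- No Wright–Fisher or best-response updating, no mutation, no k=2 cycles,
  no heterogeneous-degree or two-graph structures.
- Fixation probabilities are estimated by simulation only; no transfer
  matrix computation is provided.
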