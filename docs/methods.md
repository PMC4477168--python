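# Methods

`cpmdiff` simulates the emergence of spatial cell differentiation in an
aggregate of initially indistinguishable cells, coupling three layers: a
Cellular Potts (Glazier–Graner–Hogeweg, GGH) description of cell shape and
movement, an identical two-node activator–inhibitor network inside every
cell, and a diffusing extracellular inhibitor field. This note documents the
model and its assumptions, the numerical scheme, every tunable parameter
with its default and rationale, the calibration that froze those defaults,
and the limits of what the shipped simulations demonstrate.

## 1. Model

### 1.1 Cell layer (Cellular Potts)

The lattice is a 2-D pixel grid; each pixel belongs to the medium (id 0), to
one of `n` cells (ids 1..n), or to a one-pixel non-flux frontier ring at the
grid edge that never exchanges material. The effective energy is

    H = Σ_{⟨p,q⟩} J(τ(σ_p), τ(σ_q)) · [σ_p ≠ σ_q]  +  Σ_σ λ (v_σ − v_tg)²,

with unordered 4-neighbour pixel pairs counted once, `τ` the cell type
(blue, red, or medium), `σ` the cell id, `v_σ` the pixel count and `v_tg`
the target volume. Contact energies are type-blind between cells
(differentiation in this model is chemical, not adhesive): `J` is set by the
adhesion regime, not by blue/red identity. A surface-area term is
deliberately not implemented (volume-only elasticity).

Dynamics are Metropolis index copies: per Monte-Carlo step (MCS), `width ×
height` attempts each pick a random interior pixel and a random neighbour
from the Moore (8-) neighbourhood; if the owners differ and neither cell is
fixed, the copy is accepted with probability 1 for `ΔH ≤ 0` and
`exp(−ΔH/T)` otherwise. Boundary-energy pairs and cell-cell contacts use the
von Neumann (4-) neighbourhood; copy targets use the Moore neighbourhood so
cells can move diagonally — standard GGH practice, and both choices are
visible in `core.py` (`VON_NEUMANN`, `MOORE`). A copy that would erase a
cell's last pixel is always rejected: the population size is a fixed feature
of every scenario. In the high-adhesion regime all cells are fixed and no
copy attempts are made at all, so the owner map is bit-identical for the
whole run.

### 1.2 Intracellular network and communication

Every cell carries the same circuit:

    dA/dt = k1 A²/I − k2 A
    dI/dt = k3 A² − k4 I + s (I_ext − I) + d (Σ_{n∈N} I_n − #N · I)

The activator autocatalyses and induces the inhibitor; the inhibitor
represses the activator and is the *only* mobile species (no receptors, pure
diffusion). Direct communication exchanges `I` between cells in physical
contact (rate `d`; the contact set `N` is recomputed from the owner map
every MCS); indirect communication exchanges `I` with the medium at the
cell's boundary (rate `s`, `I_ext` = mean field value over the distinct
medium pixels 4-adjacent to the cell; cells with no medium contact have a
zero indirect term, by construction rather than by NaN accident).
Communication mode is encoded purely by which rates are nonzero: direct
(s=0), indirect (d=0), mixed (both), none (neither — the uncoupled control).

A cell is blue if `A ≥ I` (ties blue), red otherwise. Types are always
derived from concentrations, never stored.

Two floors guard the state. The inhibitor floor (1e-9) is a numerical
positivity guard — `dA/dt` divides by `I` — and every clamp event is counted
and flags the run's report. The activator floor (`a_floor = 0.01` a.u.) is a
*model* feature, not a guard: it represents basal (leaky) activator
expression, bounds how deeply a suppressed cell's activator can fall, and
thereby makes the red state conditional — a red cell re-activates once the
inhibition it receives decays below ≈ `(k2/k1)·a_floor`. Without it,
suppression is absorbing (A decays exponentially forever) and no
de-differentiation is possible at any adhesion level.

### 1.3 Extracellular field

The inhibitor field lives on medium pixels only:

    ∂I_ext/∂t = D ∇²I_ext − k5 I_ext  (+ boundary exchange)

discretised with the explicit 5-point Laplacian; fluxes exist only between
two medium pixels, so both the lattice frontier and cell–medium interfaces
are reflecting (non-flux) except for the explicit exchange term. With
`k5 = 0` and `s = 0` total field mass is conserved to machine precision.

**Exchange discretisation.** The cell side applies the concentration rate
`s (I_ext_σ − I_σ)` once per cell (using the boundary mean); the medium side
moves the matching *amount* `v_σ · s (I_ext_σ − I_σ) · dt`. Uptake is drawn
from the cell's boundary pixels in proportion to their content (which cannot
overdraw them) and is additionally capped at 20 % of the boundary mass per
sub-step, with the cap mirrored on the cell side through an effective
boundary concentration — the exchange is therefore exactly antisymmetric in
amount, and the quantity `Σ_σ I_σ·v_σ + Σ_medium I_ext` changes only through
reactions and degradation (asserted by a dedicated test). Secretion is
deposited uniformly over the boundary pixels.

**Pixel conversions.** When a cell advances over a medium pixel, the pixel's
field mass is displaced into the adjacent medium pixels (if the pixel is an
enclosed pocket with no medium neighbour, the cell takes the trapped mass
up); when a cell retracts, the vacated pixel draws a proportional share from
each adjacent medium pixel. Both rules are mass-neutral for the field, and
intracellular concentrations are intensive — pixel moves never change them.
The membrane is impermeable except through the explicit `s` exchange: with
`s = 0`, moving cells and the field cannot influence each other chemically.
(The obvious alternative — transferring the converted pixel's mass into the
cell's inhibitor pool — makes every moving cell a sponge even with
communication off and systematically reddens the no-communication control;
we rejected it for that reason.)

### 1.4 Cycle structure and integration

Each MCS runs one cycle in a fixed order: (1) index-copy sweep (skipped
when all cells are fixed); (2) `ode_substeps` interleaved sub-steps, each
computing the per-cell boundary concentrations from the current field,
advancing the field (diffusion + degradation + exchange) and then the cell
network by one forward-Euler step of `dt_ode`, both sides of the exchange
using the same pre-step values; (3) the type update. The contact graph and
boundary map are recomputed once per MCS (after the copy sweep); for fixed
populations they are computed once.

One MCS corresponds to `dt_ode · ode_substeps = 0.05` time units: the
lattice time scale is a modelling choice exposed in the configuration, with
cell movement slow relative to network kinetics (k's of order 1). `dt_ode =
0.005` sits at 10 % of the explicit diffusion stability bound `1/(4D)` for
the default `D` (the constructor enforces the bound) and well inside the
stiffness limit of the network equations (fastest rate ≈ `k4 + s + d·#N` ≈
9 per time unit).

## 2. Parameters

| parameter | default | units | role / rationale |
|---|---|---|---|
| k1, k2 | 1.0, 1.2 | 1/time | activator autocatalysis and decay; any positive steady state has A/I = k2/k1 = 1.2, so isolated cells are solidly blue |
| k3, k4 | 1.0, 2.0 | 1/time | inhibitor production and decay; k2 < k4 makes the uncoupled fixed point A\*=k1k4/(k2k3)=1.667, I\*=1.389 stable |
| d | 0.7 | 1/time | contact coupling; destabilises the uniform state of a contacted population (lateral inhibition) for d·μ > k4 with μ the contact-graph Laplacian eigenvalue |
| s | 4.0 | 1/time | medium exchange; fast enough that the rim bath can trap border cells (see §3) |
| D | 5.0 | px²/time | medium diffusion; large enough to resupply the rim from the far field on the trapping time scale |
| k5 | 0.05 | 1/time | medium degradation; sets the bath memory (τ = 20 time units): long enough to pattern the rim, short enough that an isolated cell's bath clears and the cell re-activates |
| λ, v_tg | 2.0, 36 px | — | volume elasticity; 6×6-px cells |
| J (high/low) | cell–cell 4, cell–medium 8 | energy | cohesive: J_cc < 2 J_cm |
| J (none) | cell–cell 16, cell–medium 5 | energy | dispersive: J_cc ≥ 2 J_cm, separating two cells lowers H |
| T | 5 (low), 8 (none) | energy | membrane fluctuation amplitude; high adhesion fixes cells outright |
| A0, I0 | 1.5, 1.25 | a.u. | identical initial concentrations slightly below the fixed point, on the A-nullcline ray I = (k1/k2)A |
| init noise | 1 % | — | seeded multiplicative log-normal jitter on (A0, I0); see §3 |
| I_ext(0) | 12 | a.u. | inhibitor-loaded initial medium; see §3 |
| a_floor | 0.01 | a.u. | basal activator expression (§1.2) |
| i_floor | 1e-9 | a.u. | positivity guard, clamp-counted |
| mcs_total | 3000 (scenarios) | MCS | 150 time units; every scenario records a type-label Hamming convergence diagnostic between successive samples, and the shipped run lengths leave the final window fully converged for the fixed-cell scenarios |
| n_cells / lattice | 49 cells (7×7), 100×100 | — | desk-scale study conditions; robustness probes double the count to 98 |

The scenario grid and all of the above are frozen in
`src/cpmdiff/configs/*.yaml`; the classifier thresholds
(`ClassifyThresholds`: homogeneous majority 0.95, spaced z ≤ −2, blue-core
z ≥ +2, α = 0.05) are versioned in `metrics.py`.

## 3. Calibration and where multistability actually lives

The kinetic constants, communication rates and initial conditions are not
dictated by the model family; they were fixed by a coarse grid search (the
`cpmdiff calibrate` subcommand reproduces a scaled-down version) selecting
the smallest parameter set that reproduces all of the qualitative outcomes
at once: single cell blue under every communication mode; uncoupled
population all blue; indirect-communication population heterogeneous; and
the three high-adhesion patterns (spaced / radial / central clusters).
Three findings from that calibration shape the defaults and deserve
emphasis:

1. **An isolated network is monostable; red is a property of coupled
   cells.** Every positive steady state of the isolated circuit has
   A/I = k2/k1, so an isolated cell is always blue; the red state is
   A ≈ a_floor with I sustained by *imported* inhibitor — it exists only
   while neighbours or the medium keep supplying it. Bistability is a
   property of the coupled system (a winner cell pumping inhibitor into a
   suppressed loser is a stable pair), not of one cell.

2. **Direct coupling destabilises the uniform state; bath coupling does
   not.** Linearising around the uniform state shows contact coupling goes
   Turing-unstable when `d·μ > k4` — so under direct communication an
   arbitrarily small inhomogeneity grows into the spaced pattern. For pure
   medium coupling the same calculation shows the bath-shifted uniform state
   is *always* locally stable: the quadratic autocatalysis re-equilibrates A
   upward exactly enough to compensate any common bath load. Two
   consequences follow. First, the initial population must be statistically
   (not mathematically) homogeneous: the default 1 % seeded jitter on
   (A0, I0) is the seed the direct-mode instability amplifies — with
   mathematically identical cells the uniform state is an exact solution
   and, with cells fixed, nothing can ever pattern. Second, the patterned
   branch of the indirect scenarios must be reached by a finite
   perturbation.

3. **The loaded medium is that finite perturbation.** Scenarios start in an
   inhibitor-rich environment (I_ext(0) = 12 a.u.): cells touching the
   medium absorb inhibitor and are pushed into the suppressed state, while
   interior cells — sealed off from the medium — relax to the blue fixed
   point unharmed. As the bath decays through the marginal range, rim cells
   re-activate asynchronously, and the earliest re-activators become
   *pumpers* whose exported inhibitor keeps their rim neighbours suppressed:
   the rim self-organises into the stable mixed (pumper/suppressed) state.
   Position relative to the medium, not any pre-assigned identity, decides
   fate — an isolated cell, having no pumper neighbours, always escapes to
   blue once its bath clears, which is why the same initial conditions give
   a blue single-cell control and a red-rimmed aggregate.

## 4. Pattern statistics

All statistics treat a cell as one observation. The report is computed on
the final sampling window (last 10 % of samples, at least two): headline
values (blue fraction, border/interior counts) come from the final snapshot;
the permutation statistics — blue-blue contact-edge count, red border
enrichment, red-minus-blue centroid-distance gap — pool the observed
quantity over the window samples and compare it against 999 label
permutations. Each permutation replicate assigns cells random rank slots
(one shared shuffle for all window samples, attached to cells in a
geometry-canonical order so the statistics are exactly invariant under cell
relabelling); at each sample the lowest `n_blue` slots are blue. This
respects per-sample label counts and maximally preserves label persistence
under the null — a conservative choice for mobile runs; for fixed cells it
reduces to ordinary single-snapshot permutation tests. Statistics that are
undefined for a run (single-type populations, empty contact graphs) are
reported as None with an explicit reason.

The classifier maps a report to one of five classes by ordered rules
(homogeneous → radial → central-clusters → spaced → unpatterned-
heterogeneous, else unclassified); thresholds are documented constants. A
`spaced` call requires blue to be the minority and the pooled blue-blue
adjacency z ≤ −2; `radial` requires a contiguous blue core (z ≥ +2) plus
significant red border enrichment; `central-clusters` a significant positive
centrality gap without a contiguous core.

## 5. What the shipped simulations do and do not show

The generator produces the study conditions: identical 6×6-pixel cells tiled
into a compact centred aggregate (or scattered, for the non-adhesive
scenarios), identical parameters, 1 % initial-concentration jitter, loaded
medium. Within those conditions the package reproduces: blue single-cell
controls under all three communication modes; an all-blue uncoupled
population; a heterogeneous but spatially unstructured dispersed population
under indirect communication; and the three high-adhesion patterns with
their statistics strongly significant, robust to doubling the aggregate and
to a transient reset of 20 % of the cells (implemented as a one-step reset
of A, I to their initial values — one interpretation of "transient
perturbation" among several possible).

Two claims are *not* reproduced under these conditions, and the test suite
says so rather than hiding it:

* **Low-adhesion direct communication does not classify as `spaced`.** The
  blue minority persists, but moving blue cells shear into contact and — for
  `2d < k4` — a touching blue pair is linearly stable, so a few persistent
  blue-blue contacts always survive and the adjacency z saturates around
  −1.5, overlapping the z distribution of genuinely unpatterned dispersed
  runs. The pair-resolving regime (`2d > k4`) collapses the mobile winner
  fraction to ~0.1, where the statistic has no power at 49 cells. Visual
  inspection of such runs still shows a drifting spaced-like arrangement;
  the documented threshold simply cannot certify it.

* **Low-adhesion mixed communication is not less label-stable than its
  high-adhesion counterpart.** In the mixed mode the rim is doubly
  suppressed (bath plus contact feed from interior blue cells: a rim red
  adjacent to a blue receives I ≈ 0.09 a.u., far above the ≈ 0.012
  re-activation threshold), so no rim competition survives and per-cell
  labels freeze even while the cells themselves keep moving. The instability
  of the low-adhesion patterns in this regime is decoherence of the
  *arrangement* — positions scramble — which a per-cell label-agreement
  index cannot register. (For indirect communication, where rim pumpers do
  exist, label turnover is present and the low < high stability comparison
  holds.)

Other limitations: 2-D lattice only; no cell growth, division, or
chemotaxis; no surface-area constraint; no stochastic gene-expression noise
beyond the initial jitter; adhesion is type-blind, so no differential-
adhesion sorting; the medium field does not exist under cells; and the
activator floor, loaded medium and all rate constants are calibration
choices of this implementation, exposed in configuration rather than derived
from measurements.
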