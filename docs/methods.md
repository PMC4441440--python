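# Methods

## The model

`epigrain` simulates the morphogenesis of a single-layered epithelium on a
spherical support with a discrete-element ("divided media") model.  Each
cell is a set of solid spherical particles (*grains*): internal grains
represent cytoplasm and resist compression only; an ordered ring of
peripheral grains linked by tension-only elastic *cables* represents the
plasma membrane.  All grain centres are geometrically constrained to the
support: a grain of radius *r* sits at distance *R + r* from the centre of
the support sphere of radius *R*, i.e. grains roll on the outside of the
support.  Within this plane-like shell a cell can deform into a wide
variety of polygonal shapes while keeping its area roughly fixed.

Forces:

* **grain/grain contact** — unilateral linear elasticity in compression
  (stiffness `Egg = 20`) with Kelvin–Voigt damping (`Cgg = 5`) on the
  normal relative velocity, clamped so the total normal force is never
  attractive.  It acts between grains of the same cell and between
  peripheral grains of different cells (membrane/membrane contact).
  Cable-bonded ring neighbours are excluded: consecutive membrane grains
  are spaced by their cable (down to `Lmin = 2`, far below the sum of
  their radii), so the membrane chain is a bonded bead chain, not a
  contact pair.
* **grain/cable contact** — compressive linear elasticity (`Egc = 13`)
  with the same style of damping, between a cell's internal grains and its
  own membrane cables, and between peripheral grains and foreign cables.
  The cable is a thick segment (diameter 3.0); the reaction is distributed
  to the cable's endpoint grains by barycentric weights.
* **cable tension** — traction-only linear elasticity (`Ec = 5e-3`) on the
  elongation beyond rest length.  Rest lengths are *regulated*: whenever a
  cable's tension leaves the band `[Tmin, Tmax] = [0.05, 0.30]` its rest
  length is re-solved at the violated band edge (`rest = L − T_edge/Ec`),
  so membrane tension stays quasi-constant as the cell grows.  With these
  stiffnesses a band tension corresponds to elongations of 10–60 length
  units, so regulated rest lengths are strongly negative; that is simply
  the consistent consequence of the published constants and is harmless
  for a traction-only element.
* **cadherin junctions** — the model has contact *and at-distance*
  interactions: when the membranes of two unadhered cells come within the
  adhesion distance (13), the pair becomes a candidate and, with
  probability ½ per stage, a *permanent* junction forms ("once two cells
  interact they do not dissociate").  A junction is an attraction-only
  spring anchored at the closest peripheral-grain pair at creation, with
  rest length equal to the sum of the two grain radii (surface contact),
  stiffness `adhesion_stiffness = 1.0`, and force saturated at `Tmax` — a
  junction can pull membranes together but can never out-pull the
  membrane's own tension ceiling.  Junction formation is line-of-sight
  gated: a third cell's membrane between the anchor points blocks it.

Units are dimensionless model units that preserve the published parameter
values and ratios exactly; no unit system in which micrometre lengths,
newton-scale forces and a 0.004 time step are simultaneously consistent
exists at cell scale, so the numbers are taken as printed.

## Time integration and the stage loop

The second-order dynamics `ẍ = F/m` (grain mass = density 0.9 × sphere
volume) is integrated with classic RK4 at `dt = 0.004`; after each full
step every grain is radially projected back to its constraint radius and
the radial velocity component is removed.  Neighbour lists (uniform
spatial hashing, cell size twice the largest grain diameter, 1.0 skin)
are rebuilt every 20 steps.

Biology happens at discrete *stages* separated by relaxation blocks of
`organization_rate = 500` integration steps.  At each stage, in fixed
order: growth (every `growth_period = 2` stages each immature cell adds
one internal grain near its barycentre, radius following the cyclic
sequence 2.5, 2.8, 3.0, 3.3, 3.5, indexed by the current grain count;
a cell is flagged mature when it reaches 41 grains), scenario events,
membrane remodeling (cables longer than `Lmax = 5.5` split with a
midpoint grain; shorter than `Lmin = 2` removed with their endpoints
merged; mature membranes are frozen — a mature cell keeps its 41-grain
complement), adhesion creation, and tension regulation.

Two dynamical regimes are used, chosen per scenario and exposed in the
configuration:

* **accretion** runs quasi-statically: velocities are zeroed at each
  stage boundary (a standard discrete-element settling device) and a
  small numerical viscosity (`global_damping = 0.1`) acts during blocks.
  With the published masses and damping constants the free dynamics is
  strongly underdamped (dissipation time ≈ 2–3×10³ steps); without the
  quench, growth injects kinetic energy faster than contacts drain it and
  membranes jitter outward, which corrupts both the packing and the
  coverage accounting.
* **proliferation** runs in an overdamped-flow regime (no quench,
  `global_damping = 0.2`): colony spreading is pressure-driven, and the
  front must advance continuously between stages, which the quench would
  suppress.

The loop stops when the epithelium covers ≥ 99 % of the support surface
(accretion additionally requires every cell mature); a stage budget
(default 400) bounds runaway configurations and yields a warning-tagged
result rather than an error.  After the stop, a few event-free settling
stages (relaxation + adhesion formation only, default 5; 8 for the
proliferation presets) let the terminal tissue tighten before it is
censused.

## Scenarios

**Accretion** (no mitosis, no apoptosis): the process begins with a
cohort of 15 small cells already contacting the support, then up to two
new cells arrive per stage, each placed at a random collision-free
position (100 trials; among the collision-free trials the one farthest
from existing cell barycentres is used, which makes the arrival point
process blue-noise-like).  The initial grain count of the *i*-th arrival
interpolates linearly from 3 (first) to 15 (at the cell limit) — the
later the cell arrives, the bigger it is.  Fresh cells are built as a
compact ring (cable spacing just above `Lmin`) around a sunflower layout
of internal grains so they can wedge into late gaps and expand afterwards.
The ascidian-egg preset (`ciona-accretion`) uses a cell limit of 60.

**Proliferation**: 15 six-grain cells are seeded at random collision-free
positions; cells grow to maturity, and at every stage
`round(0.07 × n_mature)` mature cells divide while
`round(ratio × n_mitoses)` further mature cells enter apoptosis
(ratio presets 1/3, 1/5, 0).  Division runs a contractile filament
through the cell barycentre along the shortest diameter (the peripheral
grain pair minimising chord length plus a barycentre-distance penalty),
partitions internal grains by side of the axis plane with counts balanced
to within two grains, and closes each daughter ring along the chord with
new peripheral grains (logged).  Daughters keep their share of the parent
and grow back to maturity.  Apoptotic cells lose one grain per stage
(internal first, then peripheral with the ring kept closed) until
deleted; their rest lengths are not regulated, giving the characteristic
slack, twisted membrane.

## Support radius

The support radius is derived, not assumed: a single isolated cell is
grown to maturity on a locally flat support and relaxed, its in-plane
membrane footprint *A* is measured (ring polygon + Minkowski margin of
the membrane), and *R* solves `N·A = 4πR²` for the target cell count
*N* (60 for the ascidian preset; at least 12, since no closed polygonal
tiling of the sphere exists with fewer pentagon-capable cells).  The
calibration is deterministic given the configuration and a calibration
seed, and cached.

## Topology and coverage

The polygon class of a cell is its number of neighbours.  Neighbours are
detected as membrane/membrane proximity — any peripheral grain or cable
of one cell within the contact tolerance (0.5 × smallest grain radius) of
the other's — *union* the cadherin-junction bonds: a junction is a
physical membrane bridge, and in jammed packings roughly a tenth of true
borders sit a few units apart at the moment of the census.  Cells with
fewer than three neighbours are tallied in a separate boundary/immature
bucket and excluded from censuses; apoptotic remnants are excluded by
default.

Coverage is sampled on a deterministic Fibonacci lattice (10⁴ points) so
the stop rule is reproducible.  A point is covered if it lies inside a
cell's peripheral-ring spherical polygon (gnomonic projection, so polygon
edges are exact great-circle tests) or within the local membrane
footprint — the local grain radius plus the contact tolerance — of the
ring path; the tolerance term counts seams between membranes in contact
as interior tissue surface.

The cap-restricted census reproduces the published counting rule for
spherical epithelia: only cells whose barycentre lies within the centred
cap holding 80 % of the half-sphere surface (boundary colatitude
`arccos(1 − fraction)`) are counted; classes still come from the full
graph.

Analytic fixtures: Goldberg polyhedra GP(m, 0) (duals of m-fold
subdivided icosahedra) provide complete spherical tilings with
`10m² + 2` cells, exactly 12 pentagons and the rest hexagons.  For every
closed 3-valent tiling `Σ(6 − class) = 12` (Euler balance); a complete
60-cell tiling of pentagons and hexagons therefore carries exactly 12
pentagons — hexagon frequency exactly 80 %.

## Statistics

Shape distributions are compared across conditions with a fixed-effects
joint binomial likelihood-ratio test.  The multinomial response is
reduced to a trinomial one — hexagons, the second most common class
(determined on the pooled data; ties broken toward the smaller class and
logged), and the remainder — and fitted as two nested binomial responses:
hexagon vs rest, and second vs rest-excluding-hexagons.  Each component
is a G statistic (`2 Σ O ln(O/E)`, convention `0·ln 0 = 0`) with `n − 1`
df; the components are independent and add, so the joint test has
`2(n − 1)` df, with zero-margin conditions dropped from a component (df
reduced, flagged).  P-values come from the χ² upper tail.

The per-individual random effect of a mixed-model analysis is *not*
re-implemented; replicate-level uncertainty is provided instead by a
bootstrap companion (resampling replicates with replacement, percentile
intervals of per-class frequency differences).  The synthetic census
generator draws replicate censuses multinomially and can add a
logit-normal between-replicate random effect (`overdispersion` = standard
deviation of i.i.d. normal noise on the log-probabilities) to emulate
per-individual heterogeneity.

## What the simulations do and do not show

The accretion preset robustly reproduces the *structural* headline: the
epithelium closes at ≥ 99 % coverage with exactly 60 mature cells, a
unimodal neighbor-class distribution centred on six, and adhesion
partnerships that never dissolve.  The degree of hexagonal *order* it
reaches (hexagon fraction ≈ 0.5, with a small tail of 4- and 8-neighbor
cells) is below the ≈ 0.8 of the real ascidian epithelium: with permanent
adhesions the neighbour topology is frozen at first contact, so the final
order is essentially the order of the arrival point process, and the
published parameter set provides no neighbour-exchange (T1) mechanism
that could anneal 5–7 defect pairs away.  The proliferation presets
reproduce the broadening of the distribution — the terminal tissue
carries 120–170 cells of widely mixed sizes, with classes spanning
roughly 3–10 (recently divided cells contribute the sub-4 classes) and
hexagons no longer dominant — which is the headline contrast between the
two scenarios, though with more small-cell classes than a real
proliferative epithelium shows.

The synthetic census generator emulates multinomial counting noise and
between-individual overdispersion; it does not emulate spatial
correlations between neighbouring cells' classes, so statistical tests
validated on it show calibration under independence, not under the
spatial dependence of a real epithelium (which the published analysis
handled with a per-individual random effect).

## Numerical choices

* time step 0.004 (published); RK4; projection-after-step constraint.
* relaxation block 500 steps/stage; growth every 2 stages; early
  equilibrium exit when the fastest grain falls below 5×10⁻⁴
  length/time.
* neighbour rebuild every 20 steps with skin 1.0 (displacements per
  rebuild interval are well below the skin).
* coverage lattice 10⁴ points; stage budget 400; settling 5–8 stages.
* degenerate inputs: coincident grain centres and zero-length cables
  raise; division requires a mature cell with at least 6 ring grains;
  remodeling refuses to shrink a ring below 3 grains (skipped instead
  during apoptosis and inside the stage loop).
* determinism: a single seeded generator owned by the state drives every
  stochastic choice; identical (config, seed) give identical event logs.

## Problem sizes

The shipped panels use the full 60-cell ascidian scale (5 seeds per
scenario); unit and property tests run on reduced supports (12–16 cells)
and small clusters, which exercise every code path at a fraction of the
cost.  A complete 60-cell accretion run takes on the order of a minute on
one CPU core; a proliferation run two to three minutes.
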