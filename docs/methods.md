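# Methods

## Model overview

The simulator is a discrete event system over a finite 3D integer lattice.
Model time advances in unit ticks; one transition processes every event due
at the current tick. Events belong to logical objects (cells or spatial
marks) and are instances of *signaling pathways*: built-in mechanisms
parametrized by a cyclic period, a predicate guard over local factor
concentrations, an optional probability gate, and mechanism-specific
parameters. Nothing else can attach behavior to a cell; a configuration is
therefore a complete, declarative description of an experiment.

Determinism is a contract, not an accident: all randomness flows through a
single seeded generator, events execute in a canonical order (independent
events by insertion; interdependent events by priority with one random
tie-break key per owner, drawn in sorted-owner order), and every container
iterates in insertion order. Two runs of the same configuration and seed
produce byte-identical event logs; this is enforced by tests.

### Event interdependence and conflicts

Two events due at the same tick are interdependent iff they share an owner
or their coordinate footprints (the owner's position plus, for movement and
division, its radius-1 neighborhood) intersect. Independent events commute
and run in queue order. Interdependent events run afterwards, ordered by
priority — death (0) < division (1) < differentiation (2) < locomotion (3)
< growth (4) < secretion (5), configurable per pathway — so destructive
events win conflicts. A mover that loses a coordinate race is blocked and
retries the next tick; no coordinate ever acquires two cell bodies within a
transition (asserted by the occupancy bookkeeping, which refuses double
placement outright).

### Interruption semantics

Division *pauses* the owner's other pathways: their events freeze and are
replayed, in original relative order, when division completes.
Differentiation *disrupts*: pending events are removed and the new type's
initial pathways launch fresh. Death *terminates*: all events are removed
and the owner can never be scheduled again. A cell whose division finds no
vacant neighbor defers the attempt to the next cycle without pausing; if
the placement found at trigger time disappears before completion, the
division is cancelled and the cyclic pathway retries. Keeping such cells
paused indefinitely would silently freeze their entire behavioral
repertoire (observed as a stuck progenitor pool in early development runs).

Initial and relaunched cyclic pathways fire one full period after launch
(period-1 pathways immediately). This gives a freshly divided cell a full
cell cycle before its next division and prevents a division event from
perpetually pre-empting same-owner, same-tick pathways.

## Space

Coordinates are 0-based integer triples on a cube with hard walls; there is
no wrap-around (the experiment grows a compact structure from a central
seed, so the boundary is never load-bearing). The metric is Chebyshev: a
unit displacement reaches any of up to 26 neighbors. A cell body occupies
exactly one coordinate exclusively; axon segments and spatial marks are
sizeless and never block anything. Physical pushes (a mover displacing a
paused cell) relocate the occupant to a uniformly chosen vacant neighbor,
one level deep — no recursive push chains, whose termination would
otherwise need extra machinery.

## Factor fields

Each factor has an emission radius r_f (significant-action radius), a
per-secretion signal power, a propagation rate and a degradation rate. The
field is a dense lattice-sized array (sparse-map semantics at the API:
unset coordinates read 0, sub-1e-12 entries are pruned to exactly 0), and
its support is truncated to the union of Chebyshev-r_f balls around past
sources. One tick applies a separable 3×3×3 discrete-Gaussian convolution
with per-axis weights ∝ exp(−1/(2σ²)), σ² = propagation rate (a delta
kernel at rate 0), then multiplicative decay. The kernel sums to one, so
mass is conserved except for truncation and boundary leakage; the test
suite checks agreement with a brute-force dense convolution to 1e−9 and
mass conservation away from the boundary. Convolution is restricted to the
support's bounding box, which is what keeps ~15 active fields on a 64³
lattice at a few milliseconds per tick.

Gradient-following (cell chemotaxis and axon growth) picks uniformly among
neighbor candidates that satisfy the rule's concentration band, preferring
strict improvers along the configured direction and falling back to
same-concentration candidates on plateaus — a flat field therefore still
permits uniform wandering, while a zero field with a positive-signal
requirement yields no move. Growth cones ignore cell-body occupancy (axons
are sizeless processes); cell locomotion respects it.

Absorption ("gathering") of factors by receiving cells is not implemented:
guards read fields without consuming mass. The bundled configurations never
rely on depletion, and a consuming read would make guard evaluation
order-dependent within a tick.

## The organoid configurations

All numeric thresholds, radii, probabilities and periods are original to
this package; they were chosen so that a scale-1 run (64³ lattice, ~1.4k
cells, 1,200 ticks, well under a minute of compute) reproduces the
qualitative developmental structure. The `scale` knob multiplies radii, the
lattice edge and the tick budget by scale^(1/3) and adjusts the NSCF
source so the structure radius scales accordingly; only scale 1 is
exercised by the tests.

**Stage 1 — proliferation.** The NSC at the lattice center secretes NSCF
every tick (power 50, propagation 0.6, decay 0.02), producing a screened
point-source profile with steady concentration ≈18 at the center, 0.5 at
radius ~6 and 0.28 at radius ~7.5. The NSC divides asymmetrically (period
8) into NPCs; NPCs divide symmetrically (period 6) while NSCF ≥ 0.5, so
the dividing ball stops growing at the 0.5-contour. NPCs in the boundary
band (NSCF between 0.28 and 0.5) start secreting NPCF; any NPC seeing NPCF
≥ 0.15 joins the chain. NPCF is deliberately short-ranged (radius 2, power
0.25, decay 0.25): the chain reaction then travels as a thin inward wave
rather than igniting everywhere at once. NPCs with NPCF ≥ 0.25
differentiate (gate 0.5, period 3) into basal progenitors (weight 0.16) or
radial glia (0.84) — the weights set the final glia:neuron ratio. NPCs
below NSCF 0.28 have been pushed out of the structure and undergo
apoptosis.

**Stage 2 — differentiation.** BPC → NRPC and RGC → GRPC (keeping the NPCF
wave alive by secreting it). NRPCs map their local NSCF onto intersecting
intervals: L1 [0.28, 0.72], L2 [0.64, 1.2], L3 [1.1, 2.6], L4 [2.4, ∞)
(variant II: L3 [1.1, 2.0], L4 [1.85, ∞)); within an overlap the target is
drawn uniformly. Because NSCF decreases with radius, layers order
radially, and because the NPCF wave arrives rim-first, the layers
differentiate sequentially L1 → L2 → L3 → L4 (verified on 8/8 seeds).
GRPCs choose type-1 astrocytes with a weight that is larger deep inside
the structure (two nested NSCF intervals), or an intermediate OT2APC that
yields oligodendrocytes anywhere and type-2 astrocytes only in the
low-NSCF periphery — giving the configured centripetal T1A and centrifugal
T2A density trends with roughly uniform ODC between.

**Stage 3 — compartments.** A neuron lacking GNF (≥ 0.15 within radius 2)
emits NF; glia seeing NF ≥ 0.08 nearby and unsaturated GNF secrete GNF;
once GNF suffices the neuron sprouts its neurites and stops emitting NF
(negative feedback). L1 neurons grow only an axon, L4 only a dendritic
tree, L2/L3 both — matching the afferent/inter/efferent roles.

**Stage 4 — wiring.** Dendrite-bearing neurons emit a guidance factor and
an arrest factor specific to their own type (L3NeuronAGF/L3NeuronACF,
etc.). Arrest factors are per-type rather than a single shared ACF: a
shared one would arrest cones beside wrong-layer neurons whose spines can
never be valid partners, deadlocking those terminals. A growth cone with
guidance signal in reach but no arrest signal extends one coordinate up
the gradient (traversing cell bodies); with the arrest signal in reach it
freezes and forms a terminal. The terminal secretes TFF; a target neuron
sensing TFF forms a dendritic spine and emits DSFF and DSCF; the terminal
sensing DSFF forms the synapse with a uniformly chosen spine-bearing
neuron of the target type within radius 3, and the connection is recorded
with its repetition class (sequentially repeated if the partner equals the
immediately previous one, non-sequentially repeated if seen earlier).
Afterwards the cone travels against the gradient and releases with
hysteresis — it resumes the forward search once guidance falls below twice
the presence threshold, i.e. while still inside the presence region. A
literal same-threshold release would park every cone exactly at the
presence contour of a steady field forever; with hysteresis cones shuttle
between targets, which is also what produces repeated connections.

Variant I differs from variant II only in the L3/L4 intervals above and in
guidance radii (variant I's L2NeuronAGF radius is 1.5× variant II's,
L4NeuronAGF 1.4×, L3NeuronAGF smaller by one coordinate). Both variants
run identical histories up to the first neuron-restricted fate decision
that evaluates the differing intervals — their event logs share that exact
prefix under a common seed.

## Analysis conventions

The structure center is the founding stem cell's coordinate. Radial
distributions use Euclidean distances normalized by the maximum over all
neurons, binned into 20 equal-width bins on [0, 1]; distribution entropy is
Shannon entropy with the natural logarithm (0 for a point mass, ln 20 for
uniform). Connection rates use compartment denominators: the axon
(dendrite) connection rate of a layer is the fraction of its
axon-(dendrite-)forming neurons with at least one outgoing (incoming)
connection; the interneuron rate counts neurons with both, among those
that formed both compartments. Glia are assigned to a layer band as the
10th–90th percentile of that layer's neuron radial distances. Replicate
aggregation reports mean and sample standard deviation per scalar metric
(SD 0 with an n = 1 flag for a single replicate).

## What the fixtures do and do not emulate

The configurations reproduce the qualitative developmental program —
bounded growth with an S-shaped population curve, a persistent single stem
cell, transient progenitor waves, radially ordered layers, glial density
trends, type-restricted wiring with repeated connections — at roughly a
thousandth of the published experiment's cell count. Absolute cell counts,
per-layer connection-rate values and axon-length distributions are
scale-dependent and are not calibration targets. Cells do not migrate in
these configurations (the locomotion mechanism, including A* routing, is
implemented and tested but unused); dendritic trees have no spatial
extent beyond spine sites at the soma; neuronal activity, neurotransmission,
chemical reactions between factors, osmosis and cell volumes are out of
scope. At desk scale the multipotent pool declines to roughly a third of
its peak rather than almost vanishing: the NPCF wave is thin, and NPCs
that miss it persist quietly inside the structure.

## Numerical and degenerate-input choices

Threshold comparisons are inclusive (≥ / ≤) everywhere. Guard evaluation
is pure and re-evaluated at execution time, so displaced or stale events
cannot act on outdated premises. A guard referencing a factor whose field
is empty logs a single warning per factor. Tie-breaks — equal-priority
interdependent events across owners, gradient candidates, daughter
placement, synapse partners — are uniform PRNG draws; within one owner,
equal-priority events keep insertion order (this is what makes
pause/release order-preserving). The A* router breaks frontier ties
lexicographically. The event log at the default "summary" verbosity records
every state-changing execution (placements, divisions, differentiations,
deaths, moves, sprouting, terminals, spines, synapses, pathway switches);
"full" adds every guarded retry and secretion.

## Problem sizes used in validation

The test suite runs both organoid variants at scale 1 (64³ lattice, 1,200
ticks, ~1.4k cells each), isolated stage configurations (400–800 ticks), a
20³ two-layer slab for wiring, diffusion-oracle grids up to 31³, one
hundred 15³ random obstacle mazes for the pathfinding oracle, and 10⁴-trial
binomial checks for the stochastic gates. The acceptance script re-runs the
scale-1 variant-I organoid from scratch under the caller's seed.
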