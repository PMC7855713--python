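# organoidsim

A discrete-event simulator of neural tissue development on a 3D integer
lattice. It grows an organoid-like, layered, synaptically connected neural
structure from a single stem cell, driven entirely by declaratively
configured signaling pathways: morphogen secretion and diffusion,
predicate-guarded cell division, differentiation and death, axon guidance by
chemical gradients, and a factor handshake for synapse formation. It is
aimed at computational biologists who want tractable, fully reproducible
*in silico* experiments on tissue self-organization, where every event for
every cell is recorded and analyzable.

## The model

The simulator is a discrete event system. The state
Ω_t = [lattice occupancy, logical objects, factor fields, event queue]
advances by a transition function Π: Ω_{t+1} = Π(Ω_t, E_t), where E_t is
the set of events due at tick t. Events are owner-bound and prioritized;
independent events (disjoint footprints) commute and run in queue order,
interdependent events run in priority order with a seeded PRNG tie-break,
so a run is a pure function of (configuration, seed).

Space is a cubic integer lattice with the Chebyshev metric
d(a, b) = max(|Δx|, |Δy|, |Δz|): a unit displacement reaches any of the 26
neighbors, a cell body occupies exactly one coordinate exclusively, while
axon segments and spatial marks are sizeless pass-through occupants.

Extracellular factors live in per-factor concentration fields. Secretion
deposits `signalPower` at the source; spreading is a truncated 3×3×3
discrete-Gaussian convolution per tick; degradation is exponential decay;
each field is zeroed beyond the union of Chebyshev balls of radius r_f
around its sources (the significant-action neighborhood N_f).

Cell behavior is attached exclusively through **signaling pathways**: a
built-in mechanism (divide symmetrically/asymmetrically, differentiate,
apoptose/necrose, move by A* or chemotaxis, sprout neurites, grow an axon,
form terminal/spine/synapse, secrete, transduce) plus a cyclic period, an
AND/OR predicate tree over local factor concentrations, and an optional
probability gate. The bundled organoid configuration implements four
developmental stages: NSCF-bounded proliferation with an NPCF chain
reaction, interval-coded differentiation of neuron-restricted progenitors
into layers L1–L4 (outer layers match lower NSCF), an NF/GNF
neuron–glia negative-feedback handshake gating neurite sprouting, and
gradient-guided axon growth wiring L1→L3, L3→L2, L2→L4 through the
TFF/DSFF/DSCF synaptogenesis handshake.

## Worked example

```python
import organoidsim as osim

doc = osim.make_organoid_config(scale=1, variant="I", seed=1)
result = osim.run_simulation(doc, out_dir="run1")
m = result.metrics()
print("live cells:", m["live_cells"])
print("clusters:", m["counts_by_cluster"])
print("layers:", {t: m["counts_by_type"].get(t, 0)
                  for t in ("L1N", "L2N", "L3N", "L4N")})
print("synapses:", m["n_synapses"])
print("median radial distance:",
      {k: round(v, 2) for k, v in m["radial_median"].items()})
```

prints

```
live cells: 1396
clusters: {'MP': 369, 'NP': 0, 'GP': 0, 'NC': 189, 'GC': 838}
layers: {'L1N': 94, 'L2N': 40, 'L3N': 41, 'L4N': 14}
synapses: 1218
median radial distance: {'L1N': 0.87, 'L2N': 0.68, 'L3N': 0.54, 'L4N': 0.32}
```

Reading this: the structure grew from one neural stem cell to ~1.4k cells
and reached a quiescent plateau; exactly one NSC remains inside the MP
(multipotent progenitor) cluster; all transient committed progenitors (NP,
GP clusters) have differentiated away; glia (GC) outnumber neurons (NC)
several-fold; and the four neuron layers are radially ordered — L1
outermost (median normalized distance 0.87) down to L4 innermost (0.32).
The 1,218 synapses connect only the configured layer pairs. `run1/` holds
the event log (`events.jsonl`), final cell/synapse/axon tables, metrics and
a manifest that reproduces the run bit-identically.

The same experiment is scriptable from a shell:

```bash
organoidsim run --config fixture:organoid:I --seed 1 --out run1
organoidsim replicate --config fixture:organoid:II --seeds 1,2,3 --out reps
```

## Layout

- `src/organoidsim/space.py` — lattice, Chebyshev geometry, occupancy, pushes
- `src/organoidsim/signals.py` — factor fields, diffusion, gradient choice
- `src/organoidsim/events.py` — the discrete-event engine and predicates
- `src/organoidsim/mechanisms.py` — the built-in mechanism set
- `src/organoidsim/configuration.py` — YAML configs, validation, Ω₀
- `src/organoidsim/fixtures.py` — the staged organoid configurations
- `src/organoidsim/analysis.py` — censuses, layering, connectivity metrics
- `src/organoidsim/runner.py`, `cli.py` — orchestration and the CLI

See `docs/methods.md` for the modeling assumptions, parameter rationale and
known limitations.
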