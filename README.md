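# wirevo

Multi-objective evolution of recurrent reservoir wiring patterns that
maximize stimulus-to-readout information transfer while minimizing wiring
cost and connection density — with a full structural and dynamical
characterization suite for the evolved circuits.

## The problem

Sensory circuits arrive at birth with wiring already specialized for their
modality. One hypothesis for how such structure arises is that evolution
solves a multi-objective optimization problem: transmit as much stimulus
information as possible downstream while paying as little as possible for
long axons (wiring cost) and for maintaining synapses (density). `wirevo`
implements that hypothesis as a runnable experiment for researchers in
computational neuroscience and reservoir computing:

- a 48-unit echo-state reservoir whose units split into three subtypes —
  16 **input** units (receive the stimulus), 16 **hidden** units, and 16
  **RC-readout** units (project to a linear readout); no unit both receives
  input and feeds the readout;
- **NSGA-II** evolution acting directly on the recurrent weight matrix
  *W* with 2×2-block crossover and block delete/refill mutation;
- **transfer entropy** (binned, Schreiber form) from each input signal to
  each RC-readout activation as the information objective;
- **coupling cost** and **density** as the constraint objectives;
- subtractive-normalized **Hebbian plasticity** for prenatal-style tuning of
  *W* under spontaneous activity and for unsupervised readout training;
- a characterization suite (PCA trajectory embedding, box-counting fractal
  dimension, k-means/NMI stimulus separation, trajectory volume, TE maps,
  subtype-resolved strength distributions).

## Model

State update of reservoir unit *i* (leaky-tanh dynamics):

    x_i(t+1) = (1 − α) x_i(t) + α ( Σ_j W_ij r_j(t) + β u_i(t) + σ ξ )

with r = tanh(x), α = 0.1, β = 1.0, σ = 0.01, ξ ~ N(0, 1); readout
z(t+1) = W_out x̂(t+1) from the RC-readout activations. *W* starts sparse
(20% nonzero, Uniform[−0.5, 0.5]) and is always rescaled to spectral
radius ρ(W) = 1.

Objectives, all on the trained pattern:

- TE(X→Y) = Σ p(y_{t+1}, y_t, x_t) log₂ [ p(y_{t+1}|y_t, x_t) /
  p(y_{t+1}|y_t) ], summed over the 16×16 input×readout pairs (maximized);
- C = Σ_ij |W_ij| · D_ij with D the shortest-path distance on the 3-layer
  4×4 unit grid, Warshall-Floyd over distance-1 adjacencies (minimized);
- density = nonzero fraction of W (minimized).

Hebbian rule (forward Euler, τ = 0.1): τ dw/dt = v·u − v(n·u)n/N, whose
every increment sums to zero over the N upstream units.

Stimuli are synthetic: surrogate natural images (1/f spatial spectrum)
clipped into 4×4 windows by random saccade-like shifts, one clip per
timestep; characterization uses eight oriented bar patterns with uniform
[0, 0.1] noise, held for n steps with blank intervals.

## Worked example

```bash
python examples/03_structure_metrics.py
```

```
coupling cost C = sum |W_ij| D_ij : 251.9
density (nonzero fraction)        : 0.196
Newman modularity Q (greedy)      : 0.195
directed clustering coefficient   : 0.202
mean shortest path length (hops)  : 1.933
modules found                     : 6
forward-path connections 148, backward-path connections 149
```

A freshly initialized pattern costs ≈250 coupling-cost units (|W| times
grid distance, summed over its ≈460 connections), sits at the target
density 0.2, and its binarized connection graph has clustering ≈0.2 and a
mean shortest path of ≈2 hops. Evolution under the baseline objectives
(TE↑, C↓) pushes cost down and TE up while the density-neutral variation
operators keep density near 0.2 — run `examples/04_evolution.py` for the
generational table and `examples/05_characterization.py` for the
probe-response comparison of random / top-TE / bottom-TE entities
(fractal dimension, separation NMI, trajectory volume).

The other examples cover stimulus generation (`01_stimuli.py`) and the
single-pattern developmental pipeline (`02_reservoir_dynamics.py`).

## Layout

- `src/wirevo/stimuli.py` — surrogate images, saccade series, probe bars
- `src/wirevo/reservoir.py` — circuit model, spectral normalization, runs
- `src/wirevo/plasticity.py` — subtractive-normalized Hebbian rule
- `src/wirevo/info.py` — TE / MI / NMI estimators, the TE objective
- `src/wirevo/structure.py` — grid layout, cost, density, modularity, graphs
- `src/wirevo/evolution.py` — NSGA-II sorting, crowding, operators, loop
- `src/wirevo/dynamics.py` — PCA embedding, FD, separation, volumes, maps
- `src/wirevo/runner.py` — the seven objective conditions, presets, manifests
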