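# sticcc

Inference of **reversible and irreversible single-cell state transitions**
from a gene expression matrix and a signed regulator→target network.

Single-cell snapshots show *where* cells sit in expression space but not
*where they are going*. This package exploits the time delay inherent in
gene regulation — a regulator's activity changes before its targets
respond — to recover per-cell transition directions without pseudotime,
splicing information, or kinetic parameters. It is aimed at systems
biologists studying gene-regulatory circuit dynamics (multistability,
oscillation, signal-driven switching) from single-cell transcriptomics or
from simulated circuit ensembles.

## Method

For cells *i*, *j* and a network of edges *k* = 1..E with regulator
r(k), target t(k) and sign s(k) ∈ {+1, −1}, the **cross-cell correlation**

> ρ(i→j) = corr( e_R(i) ⊙ s , e_T(j) ),  with e_R(i)[k] = x_{i,r(k)},
> e_T(j)[k] = x_{j,t(k)}

measures how well cell *j*'s target expression matches what cell *i*'s
(sign-adjusted) regulator state predicts — a propensity for *i* to evolve
into *j*. Within a radius-bounded neighborhood of each cell, the local
gradient of ρ with respect to relative position X(j,·) = x_j − x_i is
estimated by least squares:

> v₁ = (XᵀX)⁻¹ Xᵀ y₁,  y₁ⱼ = ρ(i→j) − ρ(i→i)   (outgoing: likely future)
> v₂ = −(XᵀX)⁻¹ Xᵀ y₂,  y₂ⱼ = ρ(j→i) − ρ(i→i)   (incoming: away from likely past)

and decomposed into **net flow** (v₁+v₂)/2 — the irreversible component —
and **reversibility** (v₁−v₂)/2 — the bidirectional component. The
sampling radius (default 0.15 × the maximum pairwise distance) can be
optimized by maximizing coverage/MAPE over an 11-point grid on
[0.05, 0.30].

A bundled simulator generates single-cell-like data from small circuits
(repressilator `REP`, coupled toggle switch `CTS`, incoherent feedforward
loop `IFFL`, toggle switch/repressilator `TSREP`): shifted-Hill ODE
ensembles with uniformly sampled kinetics, Euler–Maruyama stochastic
trajectories, trapezoidal signal schedules, an unspliced/spliced variant,
log/z-score normalization and a quantile-threshold dropout model.
Post-inference tools provide PCA projection, inverse-distance grid
smoothing, density-peak basin estimation, edge-sensitivity analysis and
validation against simulated trajectories (von Mises angle peaks,
nearest-peak cosine scores).

## Worked example

```sh
sticcc simulate --circuit REP --n-models 2000 --seed 11 -o rep.tsv
sticcc run --circuit REP --expression rep.tsv --space pca:2 -o rep_run/
```

which logs, on this seed:

```
transition inference: 1996/2000 valid cells (99.8%), median |net|=0.401,
median |rev|=0.0419, 0.62s
valid cells: 1996/2000
```

The repressilator oscillates, and the numbers say exactly that: nearly
every cell gets a vector, the irreversible net flow is an order of
magnitude larger than the reversibility, and (see `rep_run/vectors.tsv`)
the net-flow field circulates around the centroid of the PCA projection —
over 99% of cells share the sign of the cross product between position
and net flow. Running the same pipeline on `--circuit CTS` reverses the
regime: median net flow drops *below* median reversibility, because the
coupled toggle switch hops reversibly between its stable states instead
of cycling.

The same library calls are available in Python:

```python
import sticcc as st

topo = st.builtin_circuit("REP")
raw = st.simulate_steady_states(topo, st.SimulationConfig(n_models=2000, seed=11))
log = st.normalize_log(raw)
space, pca = st.embedding_from_pca(log, 2)
tv = st.run_sticc(topo, log, space, radius_fraction=0.15)
net, rev = tv.net_flow[tv.valid], tv.reversibility[tv.valid]
```

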