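# Methods

## Transition-vector inference

The method assumes regulatory causality is visible as a time delay: a
cell whose sign-adjusted regulator profile correlates with another cell's
target profile is likely to evolve toward that cell. The cross-cell
correlation ρ(i→j) is a Pearson correlation over network *edges* (not
genes): edge k contributes the regulator's expression in cell i, with the
sign flipped for inhibitions, paired against the target's expression in
cell j. At least two edges are therefore required, and a profile with
zero variance across edges makes the correlation undefined — such
neighbors are dropped from the regression, and a center cell with an
undefined self-correlation is marked invalid (`degenerate_center`).

Per cell, the gradient of relative CCC with respect to relative position
is fitted by ordinary least squares in a user-chosen embedding (network
genes, principal components, or supplied coordinates); CCCs themselves
are always computed on network-gene expression. The solver is
`numpy.linalg.lstsq`, i.e. the minimum-norm solution when XᵀX is
singular, with a rank-deficiency flag. Cells with fewer than
`min_neighbors` (default 15, matching the coverage threshold) usable
neighbors are flagged (`insufficient_neighborhood`) rather than fitted
unstably. Exact identities net+rev = v₁ and net−rev = v₂ hold for every
valid cell and are tested at 1e−12.

Neighborhoods are Euclidean balls of radius `radius_fraction` × the
maximum pairwise distance in the embedding. The optimizer grid-searches
11 evenly spaced fractions on [0.05, 0.30], scoring each by
coverage / MAPE, where coverage is the fraction of cells meeting the
neighbor minimum and MAPE is the median over covered cells of the
per-cell median absolute percentage error of the outgoing regression
(|y| < 1e−9 excluded to avoid division blow-ups). Ties break toward the
smaller radius; 0.15 is the default when optimization is skipped.

## Circuit simulator

Snapshot ensembles follow the random-kinetics convention: per model,
production G ~ U[1, 100], degradation k ~ U[0.1, 1], Hill coefficient
uniform on {1..6}, fold change λ ~ U[1, 100] for activation and
1/U[1, 100] for inhibition, and each edge's threshold uniform on
[0.02·M, 1.98·M] with M = G/(2k) of the regulator (half-functional rule).
Production multiplies shifted Hill factors λ + (1−λ)/(1+(B/B0)^n) over
in-edges, and G is divided by λ over *activating* edges only, so that G
is the maximum production rate — attained under full activation and no
inhibition. (Dividing by inhibitory λ < 1 as well would make the zero-
inhibitor rate G/λ exceed the nominal maximum and, in practice, push
repressilator fixed points so deep into Hill saturation that sampled
models never oscillate; with the activator-only convention a scan of 40
sampled repressilator models reliably contains sustained oscillators.)

Integration is fixed-step Euler (default h = 0.02, total time 100),
states clipped at zero; a per-model convergence flag records whether
max |dA/dt| fell below 1e−6 at the end — oscillatory models legitimately
never converge and are retained, since their late-time states sample the
limit cycle at random phase. Initial conditions are uniform on [0, G/k]
per gene. Stochastic trajectories use Euler–Maruyama with per-gene noise
amplitude ξ_A = `noise_level` × a per-gene expression scale; by default
that scale is the time-average of a deterministic run of the same model
(well-defined for limit cycles, where no steady state exists), and an
explicit `noise_scale` array accepts ensemble-derived scales instead.
With `noise_level = 0` the SDE path reduces exactly to deterministic
Euler, which is tested bitwise.

The splicing variant integrates dU/dt = production(S) − βU and
dS/dt = βU − kS with regulators reading the spliced track; β defaults to
0.7. At stationarity of an isolated gene U* = G/β and S* = G/k, and as
β → ∞ the spliced track approaches the base model — both are tested.

Signal schedules multiply one gene's production by a trapezoid s(t):
linear rise 1 → fold, hold, linear fall back to 1.

Dropout acts on raw values before log-normalization: per gene, entries
strictly below the empirical `drop_quantile` (type-7 linear-interpolation
quantile) are zeroed independently with probability `drop_prob`.
Log-normalization is log2(x+1); z-scoring uses ddof = 1 and drops
zero-variance genes with a warning.

## Expression scale

Matrices are used exactly as supplied. The ensemble pipelines operate on
log2(x+1) values. Single-model trajectory snapshots are additionally
z-scored per gene before inference: with only a handful of edges, static
offsets between gene scales would otherwise dominate the edge-wise
correlation and mask the phase signal — on a repressilator trajectory
this is the difference between a uniform vector field and a clean
rotation.

## Post-inference analysis

PCA is centered but not scaled (inputs are already normalized), with a
deterministic sign convention (largest-|loading| entry positive).
Grid smoothing uses inverse-distance weights 1/(d+δ)^power with δ = 1e−9,
default 20 × 20 grid, power 2, influence radius one grid spacing or the
sampling radius. Basins of attraction are estimated as *peaks* of a
Gaussian KDE (Scott bandwidth) on a 100×100 grid — local maxima over the
8-neighborhood, discarding peaks below 10% of the global maximum as
spurious. Field comparisons report ‖Δv‖ per cell (primary), |Δ‖v‖| and
the absolute angle change of the first two coordinates; the shuffled
null pairs each cell with a uniformly drawn different cell. Edge
sensitivity re-runs inference per perturbed topology on identical data
and radius, records median ‖Δnet‖ and ‖Δrev‖, flags the top 15% by
combined change, and reports perturbations leaving < 2 edges as
degenerate without computing them.

## Trajectory validation

Observed vectors near a query point are displacements coords[t+lag] −
coords[t] over all trajectory passages within 2% of the maximum pairwise
trajectory distance. The lag is chosen so the start→end RMSD is closest
to a per-dataset target (the repressilator analyses here use 0.65 in
z-scored PC space); the scan bound is 200 steps. Angle distributions are
summarized by a von Mises kernel density (κ = 8, 360-point grid,
circular local maxima above 20% of the peak; wrap-around handled), and
predictions are scored by cosine similarity to the nearest peak —
reversibility vectors score both ends, having no preferred sign. In slow
segments of a noisy limit cycle the short-time dynamics are genuinely
noise-dominated and locally reversible, so observed-angle distributions
there can be bimodal; this is a property of the dynamics, not an
estimator artifact.

## Problem sizes

The bundled analyses use 2,000-model ensembles, 40-model oscillator
scans, and stochastic trajectories of 2,000–10,000 time units
subsampled to 2,000 snapshots. These sizes give stable regime statistics
(rotation consistency, net/reversibility ratios, basin counts) across
seeds while keeping a full pipeline run on one CPU under a minute.

## What the synthetic data does and does not show

The simulator emulates parameter heterogeneity across cells, intrinsic
noise, splicing, signals and quantile dropout. It does not model library
size, amplification noise, batch effects, or unmeasured regulators —
passing tests demonstrate correctness of the algorithm and its regimes on
circuit-generated data, not performance guarantees on experimental
scRNA-seq, where the provided network may be incomplete and expression
only proxies regulator activity.

## Known limitations

- All-pairs CCC is O(n² · E) memory/time; datasets ≫ 10⁴ cells need
  chunking (not implemented).
- The regression is linear and local; strongly curved flow inside one
  neighborhood biases vectors toward the chord.
- Basin estimation works in the first two PCs only and can merge basins
  that separate in higher components.
- Per-cell validity depends on the radius; sparse regions of expression
  space yield flagged (not imputed) cells.
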