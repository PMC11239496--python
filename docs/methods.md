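# Methods

This note records the models implemented in `fatechain`, the numerical
choices behind them, and what the synthetic benchmarks do and do not
establish.

## Markov-chain view of differentiation

Cells are states of a discrete-time Markov chain; a kernel maps one data
view onto transition probabilities supported on a kNN similarity graph.
All kernels guarantee the same contract — non-negative entries, rows
summing to 1 within 1e-8, no empty rows — enforced at construction.
Matrices missing the tolerance are renormalized once and re-checked, then
rejected. Kernels combine convexly (`T = αT¹ + (1−α)T²`), and initial
states are analysed on the transposed, re-row-normalized chain, which
describes transitions toward putative ancestors.

## Pseudotime kernel

Edges are reweighted by `f(Δt_jk)` with `Δt_jk = t_k − t_j` (neighbor minus
reference). The soft branch is implemented as `2/(1+e^{−bΔt})^{1/ν}` for
`Δt < 0`: this is the sign convention under which the multiplier decays
toward the deep past, which is the only reading consistent with
downweighting backward edges; the often-quoted form with `e^{+bΔt}` grows
to 2 as `Δt → −∞` and would invert the bias. The function is deliberately
discontinuous at 0 (left limit `2^{1−1/ν}`, value 1), kept as stated and
tested explicitly. Defaults `b = 10`, `ν = 0.5` (dimensionless; Δt is in
whatever units the pseudotime carries — only the product `bΔt` matters, so
pseudotimes should be scaled to order 1). The hard scheme keeps all
future-pointing edges and, per cell, the `frac_retain` fraction of
past-pointing edges with smallest |Δt|, never leaving a row empty.

## Developmental-potential (CytoTRACE-style) kernel

Correlations with the expressed-gene count are computed on the unsmoothed
normalized matrix; smoothing (unweighted first-order moments over
`N(j) ∪ {j}`, hence idempotent on constants) enters only when aggregating
the top-L genes. Two deliberate departures from the printed construction:
the aggregate uses the mean rather than the sum (the factor 1/L cancels in
scaling), and scaling is `(c̃ − min c̃)/(max c̃ − min c̃)` — the printed
denominator `max c̃` alone does not map to [0, 1] unless `min c̃ = 0`.
Zero-variance genes get correlation 0; ties at the L-th rank break by gene
index so builds are deterministic.

## Time-course kernel

Couplings between consecutive snapshots come either from files (an external
solver such as WOT always takes precedence) or from the built-in balanced
Sinkhorn solver: squared-Euclidean cost, uniform marginals,
`ε = 0.05 × median cost`, log-domain iterations, marginal tolerance 1e-6,
10⁴-iteration cap. Growth rates and unbalanced transport are out of scope;
couplings are row-normalized as given. The global chain places couplings on
the first off-diagonal and row-normalized intra-time similarity on the
diagonal, mixed per row with `conn_weight = 0.2` on the similarity part;
final-time rows carry similarity only (`self_transitions='none'` gives them
pure self-loops instead). Intra-time similarity should be built per time
point (`per_timepoint_graph`, Gaussian-decayed kNN weights): a global kNN
graph can leave a final-time cell with no contemporaneous neighbor.

Adaptive sparsification uses the largest threshold that leaves every
targeted row non-empty, `τ = min_j max_k T_jk`, zeroing entries strictly
below τ and renormalizing. By default the rule targets only the coupling
entries — entropic regularization is what makes them dense, while the
similarity blocks are kNN-sparse already; `target='chain'` applies it to
whole rows. Re-applying auto thresholding is a recorded no-op, making the
operation idempotent.

The real-time-informed pseudotime symmetrizes the chain
(`S = rownorm(T + Tᵀ)`), takes the top eigenpairs excluding the stationary
one (identified as the eigenvalue closest to 1; any other eigenvalue
numerically ≥ 1 is an error pointing at a disconnected chain), forms
diffusion components `M_j = (λ_i/(1−λ_i))ψ_i(j)` and returns
`‖M_j − M_root‖₂`. Default 15 components; on strongly clustered desk-scale
chains a handful of components is usually cleaner.

## Metabolic-labeling estimator

Kinetics are linear per gene, `ṙ = α − γr`, with closed forms: pulse
`r_l = (α/γ)(1−e^{−γτ})`; chase labeled `r_l = r0 − (α/γ)(1−e^{−γτ})`
clipped at 0, with `exact_decay=True` switching to the exact ODE solution
`r0·e^{−γτ}` (the two agree exactly when wash-out starts at steady state,
`r0 = α/γ`). Units: α in molecules/hour, γ in 1/hour, τ in hours. In the
clipped regime (`r0` well below the washed-out mass) the printed form
destroys information and the parameters are not identifiable from the
clipped durations; fixtures therefore wash out at or above steady state,
which is also the standard experimental design (label to saturation, then
chase).

Observations for a (cell, gene) fit are neighbor-smoothed labeled counts,
smoothed strictly within each (experiment, duration) stratum — smoothing
across durations corrupts the kinetic signal. Neighborhoods per duration
extend to the 20th cell with strictly positive (smoothed) expression by
PCA-space Euclidean distance, interleaved zero-count cells included; a
stratum with fewer expressing cells falls back to the whole stratum with a
counted warning. Pulse fitting needs ≥ 2 distinct durations, chase ≥ 3;
both arms are fitted jointly when present.

The quadratic loss is minimized by a deterministic profile search: for
fixed γ the model is linear in `(β = α/γ, r0)` and solved by non-negative
least squares (with a short active-set iteration handling the clip), so the
optimization reduces to one dimension — a 60-point log-spaced γ grid on
[1e-4, 50] followed by bounded scalar refinement. This replaces a
multi-start nonlinear least-squares design: it is ~100× faster, has no
start-point sensitivity, and recovers noiseless parameters to machine
precision. Entries that cannot be fitted are NaN, never silently zero, and
missingness propagates through `v = α − γr` to the velocity field.

## GPCCA estimator

Schur vectors are computed densely with eigenvalues sorted by modulus;
a requested count that would split a complex conjugate pair is bumped by
one with a warning. The package uses the dense path throughout — it is
intended for chains up to a few thousand cells, where dense Schur is both
faster and more robust than sparse partial decompositions. The leading
invariant subspace is rotated so its first basis vector is the constant
vector, vertices are found by the inner-simplex search, and the rotation is
refined by Nelder–Mead maximization of the crispness
`Σ_j (AᵀA)_jj / A_0j` under the feasibility filling that keeps χ on the
simplex; if refinement does not improve on the initialization, the
initialization is returned with a warning. Coarse-graining uses uniform
weights, `T_c = (χᵀχ)⁻¹χᵀTχ`, clipped and renormalized. With a single
macrostate the membership is trivially uniform; its representative cells
are ranked by the stationary distribution so that the one state summarizes
the chain's long-run behaviour — this is what makes identification curves
meaningful at n = 1.

Terminal states are macrostates with coarse self-transition ≥ 0.96 — the
margin is chosen so an absorbing block with up to 4% leakage still
qualifies; consequently a transient block must leak more than ~4% to be
excluded, which bounds how fine a distinction the default threshold can
make. Representative cells (`n_f = 30`, ties broken by cell index) of each
terminal state are aggregated into a single absorbing pseudo-state before
solving `(I−Q)F = S` (GMRES with ILU preconditioning, direct sparse
fallback); aggregation is mathematically identical to summing
per-representative absorption probabilities and is asserted to 1e-8 in the
tests. Driver ranking is a per-gene Pearson correlation with a fate column
under an optional cell mask, with optional t-distribution p-values and
Benjamini–Hochberg q-values; gene trends are any injected weighted smoother
on a 200-point grid, defaulting to a weighted least-squares cubic spline
with a weighted-polynomial fallback for degenerate supports.

## Synthetic data: what it emulates, and what it does not

The branching manifold places cells on a rooted tree (trunk to a split at
maturity 0.3, then diverging rays) with three gene classes: *decay* genes
switching off at per-gene thresholds — producing the monotone
expressed-gene-count decline the potential score needs — per-branch
*driver* genes ramping from maturity 0.35, and shared ramp genes. A quarter
of cells are pooled in the terminal maturity band (≥ 0.85), emulating
accumulation at attractors; without a populated terminal state,
30-representative macrostates cannot describe one. The time course redraws
such populations with the maturity center advancing per snapshot
(default 0.25 per step, spread 0.12 — four snapshots spanning the whole
trajectory). The pulse/chase generator plants per-cell α (drivers elevated
on-branch) and per-gene γ, sets total RNA to lag its moving steady state by
0.25 maturity units (so rate-derived velocities point along the manifold),
and draws Poisson counts unless noise is disabled. Planted-block chains
give GPCCA and the absorption solver exact combinatorial ground truth.

None of this mimics the depth, dropout, batch structure or doublets of
real scRNA-seq. Passing tests establish that the algorithms recover
structure they are designed to see when it is present; they do not
establish robustness to technical artifacts of real data.

One benchmark is known not to reach its nominal bar at desk scale: after
auto-thresholding the time-course chain, per-lineage fate-probability
correlations on the 4-snapshot × 200-cell fixture measure ≈ 0.984–0.993
rather than ≥ 0.99 uniformly. With only four snapshots spanning the whole
trajectory, cells straddling the lineage split carry genuinely diffuse
coupling rows, and the sub-threshold entries the rule removes encode real
fate ambiguity. Dense, large time series (many close snapshots) do not
have this property; the corresponding test is left asserting the nominal
bar and fails by ~0.001 at the default seed.

## Determinism and degenerate inputs

Every stochastic step takes an explicit seed (generators, random walks);
fits, decompositions and thresholds are deterministic given their inputs.
Degenerate inputs error early with the offending cells named: all-zero
rows in normalization, cells unreachable under the forward chain when
transposing, transient cells with no path to any terminal set, constant
expressed-gene counts, zero-variance fate columns. Silent fallbacks
(uniform velocity rows, dropped CBC cells, neighborhood fallbacks) always
warn with counts.
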