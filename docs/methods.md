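# Methods

## Model

Let `y` be an `N × G` matrix of binary expression calls over voxels on an
integer 3-D grid, and let `G = (V, E)` be the 6-neighborhood graph over the
voxels (two voxels are adjacent iff their coordinates differ by one unit
along exactly one axis; surface voxels simply have fewer neighbors — energy
sums run over existing edges only, with no padding or wraparound).

Latent labels `z ∈ {1..K}^N` follow a discrete Markov random field with
Gibbs measure `P(z|β) = W(β)^{-1} exp(−U(z))` and pairwise energy

    U(z) = − Σ_{(i,j)∈E} β_{z_i} · 1[z_i = z_j].

This is the Potts model generalized so that each cluster `k` carries its own
interaction strength `β_k ≥ 0`: a compact tissue can be strongly cohesive
while an infiltrating or dispersed cell type is essentially unsmoothed.
With all `β_k` equal the standard Potts energy is recovered, and with all
`β_k = 0` the labels are independent and the model reduces to a Bernoulli
mixture with uniform weights.

Emissions are conditionally independent Bernoulli per gene:
`p(y_i | z_i = k) = Π_g θ_{kg}^{y_ig} (1−θ_{kg})^{1−y_ig}`.  This assumes
the gene panel has been curated for largely orthogonal expression patterns;
with many co-regulated genes the independence assumption fails and a
correlated emission model would be needed (out of scope here).

## Inference

`W(β)` sums over all `K^N` labelings and is intractable beyond toy sizes
(`gibbs_log_partition_exact` exists as an enumeration oracle for graphs with
at most 10^6 states, used only in tests).  Fitting therefore uses mean-field
EM:

- **E-step** — `t_{ik} ∝ p(y_i|θ_k) · exp(β_k s_{ik})` with
  `s_{ik} = Σ_{j∈N(i)} t_{jk}` the neighbor posterior mass, normalized over
  `k` per voxel and computed in log space.  The default sweep is
  synchronous (all voxels updated from the previous iteration's
  posteriors); a `checkerboard` option two-colors the grid by coordinate
  parity (the 6-neighborhood graph is bipartite) and lets the second color
  see fresh values, a deterministic Gauss–Seidel sweep that damps the
  oscillations synchronous updates can show at strong interaction.
- **θ M-step** — voxels are hard-assigned by maximum posterior marginal
  (MPM; ties to the lowest cluster index), then
  `θ_{kg} = n_{kg}/n_k` (expressing voxels over cluster size).  A soft,
  responsibility-weighted variant is available (`theta_update="soft"`).
- **β M-step** — projected gradient ascent on the mean-field field
  objective `F(β) = Σ_i [Σ_k t_{ik} β_k s_{ik} − log Σ_k exp(β_k s_{ik})]`,
  whose gradient is `Σ_i (t_{ik} − p_{ik}) s_{ik}` with `p` the per-voxel
  softmax of `β·s`.

The fit is scored and traced by the mean-field surrogate log-likelihood
`Σ_i log Σ_k π_{ik} p(y_i|θ_k)` with `π_{ik} = softmax_k(β_k s_{ik})`; the
same quantity enters the BIC.

## Numerical choices

- `θ` is clipped to `[1e-6, 1−1e-6]` after every M-step (finite counts make
  boundary estimates routine; clipping keeps log-emissions finite).
- Empty clusters are re-seeded from a randomly chosen voxel's profile,
  keeping K fixed.
- `β` is constrained to `[0, 10]`; an uncapped interaction strength lets the
  field degenerate to a frozen labeling.  The cap is configurable.
- The gradient ascent uses backtracking step halving from a base step of
  0.01, and doubles the base step after a cleanly accepted move (the field
  objective is extremely shallow near its optimum; a fixed small step
  crawls and stops far from stationarity).  Default budget: 60 inner
  iterations, projected-gradient tolerance 1e-3 — β is warm-started across
  EM iterations, so full inner convergence per call is unnecessary
  (generalized EM); these defaults reproduce the BICs of a 200-iteration /
  1e-5 budget to five significant digits on the standard sweep fixture at a
  third of the cost.
- EM stops when the relative change of the surrogate log-likelihood falls
  below 1e-6 (default) or after 500 iterations; a stall detector also stops
  runs whose best value has not improved for ~15 iterations, which catches
  the short limit cycles synchronous mean-field updates can enter at strong
  interaction in degenerate fits.
- Random initialization samples hard labels uniformly, computes θ from
  them, and starts all `β_k = 0.1`.  By default 5 independent restarts are
  run and the best surrogate log-likelihood wins; EM on this likelihood has
  many local maxima, and best-of-restarts selection reliably identifies the
  global optimum when any restart reaches it.  All randomness flows from a
  single seed through numpy `SeedSequence` spawning.
- Monotonicity: for the returned (best) fit the surrogate trace is
  non-decreasing up to a relative tolerance of 1e-6 in practice, but
  mean-field EM carries no monotonicity guarantee — the E-step changes the
  neighbor sums that define the surrogate, and the hard θ update maximizes
  the classification objective rather than the mixture bound.  Runs stuck
  in poor local optima (a dying cluster, a limit cycle) can show transient
  decreases; those runs lose the restart selection.

## Model selection

BIC = `−2·logL + d·log N` on the mean-field surrogate, with
`d = K·G + K` (θ entries plus per-cluster interaction strengths) for the
spatial model; the independent mixture counts `K·G + (K−1)` (profiles plus
free mixing weights).  Two rules are reported: the argmin of the BIC curve,
and a plateau rule that returns the smallest K after which every subsequent
relative improvement `(BIC_{K−1} − BIC_K)/|BIC_{K−1}|` stays below 0.5%
(configurable).  The plateau rule exists for near-symmetric tissues: left
and right copies of the same tissue keep splitting as K grows, improving
the likelihood just enough to flatten — rather than turn up — the curve.
If the curve is still improving at the end of the sweep the rule falls back
to the argmin with a warning.

## Synthetic data and validation

Sampling a Potts field by MCMC is expensive at tissue scale, so validation
uses structured references instead:

- `make_synthetic_reference` partitions a full grid into K contiguous
  regions by multi-source BFS from K random seed voxels (graph-distance
  Voronoi; ties go to the earlier seed in the BFS round, which keeps every
  region connected).  Profiles are either uniform random or **separated**:
  bits of binary codewords with pairwise Hamming fraction > 1/2 (rows of a
  Sylvester–Hadamard matrix with the constant column removed, tiled across
  genes) mapped to two levels `0.5 ± span/2`, with the span chosen as the
  smallest achieving a requested minimum pairwise mean absolute difference
  `delta` — so larger `delta` means cleaner profiles and less per-gene
  noise.  An optional `min_region_size` redraws seed placements that
  produce degenerate slivers.
- `simulate_from_reference` draws each voxel's genes independently
  Bernoulli(θ of its cluster), keeping coordinates — simulated data inherit
  the reference's spatial layout.
- `simulate_coherent_from_reference` additionally makes the *within*-cluster
  variation spatial: for each cluster and gene, a contiguous patch of
  `round(θ·n_k)` voxels (BFS growth inside the cluster) expresses the gene,
  plus a small flip noise (default 5%).  Per-cluster frequencies still match
  θ, but partially-expressed genes form coherent sub-regions, as they do in
  real tissue.  Plain Bernoulli resimulation destroys exactly this
  sub-structure; fitting to resimulated data therefore *underestimates* the
  interaction strengths relative to the reference fit.  Wrapping a fit as a
  new reference (`second_generation_reference`) and resimulating removes
  the bias: the second-generation refit recovers the first generation's β.
- The spatial-randomization control (`permute_coordinates`) reassigns
  coordinates uniformly at random, destroying the spatial component while
  preserving the coordinate multiset and degree sequence; refitting should
  then find β near 0 and no advantage over the independent mixture.

What the generator does *not* emulate: light contamination between voxels,
probe efficiency differences, gene–gene correlation, irregular (non-grid,
non-convex) tissue shapes, and left/right tissue symmetry.  Passing tests
on this synthetic data show that the estimator recovers the model's own
structure; they do not certify performance on real stained tissue.

## Standard experiment protocols (`hmrfclust.experiments`)

All validation experiments run on a 12×12×8 grid (1,152 voxels; a
deliberately scaled-down analogue of a ~32,000-voxel tissue map) with 28
genes and separated profiles, over five replicate seeds derived from one
master seed:

- **Recovery** — K=5 references at `delta=0.5`; refit at the true K with 10
  restarts; report per-replicate Jaccard and matched-θ RMSE.  (10 restarts
  because this experiment probes estimator consistency, not optimizer
  variance.)
- **Spatial benefit** — K=7 at `delta=0.4`; HMRF vs independent mixture on
  spatial data and on coordinate-randomized data, 10 restarts per arm.
- **β generations** — reference fit on coherent-sub-structure data, then
  generation-1 and generation-2 resimulation fits plus the randomized
  control, 3 replicates.
- **BIC selection** — K=7 truth, sweep K=2..12 with 3 restarts per K;
  majority argmin-BIC over replicates.

## Known limitations

- The β estimator absorbs cluster-size imbalance: the weightless Potts
  field is the only mechanism available to explain unequal cluster volumes,
  so on spatially randomized data with very unequal clusters the fitted
  mean β settles slightly above zero (≈0.1 at K=7 with sizes ranging
   ~60–500) rather than exactly at it.  Adding mixing weights to the field
  prior would decouple size from cohesion but changes the model.
- Mean-field EM is a biased approximation; on tiny graphs the
  fixed-point marginals can deviate visibly from exact enumeration
  (documented by a test that reports the total-variation gap).
- Binary emissions discard quantitative signal by design (the data that
  motivate the model are only semi-quantitative); a count-emission variant
  would replace the Bernoulli likelihood without touching the field.
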