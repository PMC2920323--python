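# Methods

## The model

`cropdispersal` infers where a domesticated crop originated and how it
spread by confronting a single spatial model with two (optionally three)
independent lines of evidence: calibrated radiocarbon ages of
archaeobotanical crop remains, per-accession heterozygosity of modern
landraces, and pairwise genetic distances between accessions.

### Landscape conductance

The landscape is a regular lon/lat grid whose cells form a graph: adjacent
cells (queen's case by default) are joined by edges carrying a
*conductance* — the ease of crop movement, the reciprocal of
resistance/friction. The model used here has two free parameters beyond
the origin location:

* land–land edges have conductance 1 (the reference);
* edges touching a water cell decay with mean distance from the coast
  `d̄` (km) of the two cells (a land cell contributes 0):

      c = p1 · 2^(−d̄ / p2)

  `p1` (dimensionless, ≥ 0) is the conductance of coastal water relative
  to land; `p2` (km, > 0) is the half-value distance of the decay. The
  water sub-matrix is symmetrically normalized (D^−1/2 M D^−1/2) before
  being merged with the land sub-matrix, following the construction order
  of the original analysis. Every merged entry is finally divided by the
  great-circle distance between the two cell centres, which simultaneously
  corrects the diagonal-vs-straight bias of 8-neighbour moves and the
  poleward shrinking of W–E spacing. All geodesics use the spherical Earth
  approximation (haversine, R = 6371.0088 km); distance-to-coast is the
  great-circle distance from a water cell centre to the nearest land cell
  centre (KD-tree on unit-sphere coordinates).

An edge with one land and one water endpoint is treated as a water edge:
the coast must be crossable, and the land endpoint contributes d = 0 to
`d̄`.

### Distance and trajectory metrics

* **Least-cost distance** — minimum over paths of Σ 1/c along edges
  (Dijkstra on the reciprocal matrix). Predicts arrival ages (age declines
  linearly with cost-distance from the origin at the dispersal speed) and
  heterozygosity (serial founder effect: diversity declines with
  cost-distance).
* **Randomized shortest paths (RSP)** — the dispersal trajectory to an
  accession is modelled as a Boltzmann-tilted random walk between a pure
  random walk (θ = 0) and the deterministic least-cost path (θ → ∞).
  With reference walk `P_ref[i,j] = c_ij/Σ_k c_ik`, per-step costs
  `1/c_ij`, tilted weights `W = P_ref ∘ exp(−θ/c)` and the destination
  made absorbing, the fundamental matrix `Z = (I−W)^−1` gives expected
  edge passages `n_ij = z[o,i]·W[i,j]·z[j,d] / z[o,d]`; the *net* passage
  is `max(n_ij − n_ji, 0)`. Net passages below 1e−12 are dropped to keep
  the matrices sparse.
* **Path overlap / divergence** — with `R = 1/c` on existing edges,
  overlap of two trajectories from a common origin is
  `Σ (P_a ∘ P_b) ∘ R`; divergence uses `hi = max(P_a, P_b)`,
  `lo = min(P_a, P_b)`, `d = hi·(1−lo)` counted only where `d > lo`, and
  sums `Σ d ∘ R` over those edges. Overlap predicts genetic similarity,
  divergence genetic distance.

Numerical note: because per-step costs are on a km scale, `exp(−θ/c)`
underflows for θ beyond ≈ 2–5 on continental grids; the solver raises a
clear error (`z[o,d] = 0`) rather than returning garbage. θ values used in
practice (0.01–2) are safe, and the θ → ∞ limit is available exactly as
the least-cost path.

### Goodness of fit

Ages and heterozygosity are fitted by **weighted linear quantile
regression** at τ = 0.8: only the oldest remains / most diverse
accessions of an area carry the dispersal signal, later dates and
recently-bottlenecked samples fall below the quantile line. The fit
minimizes Σ w_i ρ_τ(y_i − b0 − b1 x_i) as a linear program (HiGHS) and is
scored with the Koenker–Machado pseudo-R², `R1 = 1 − V/V0`, where V0 is
the check-loss of the best intercept-only model (the weighted τ-quantile).
Site observations are weighted by 1/(number of observations within 100 km,
self included) to counter spatial clustering; heterozygosity observations
are unweighted. R1 is invariant to positive rescaling of the weights.

Genetic distances (−ln of the mean proportion of shared alleles over
co-scored loci; a zero shared proportion is floored at 1/(4L) to stay
finite) are regressed on path overlap and divergence by OLS on the
vectorized lower triangles, with significance from a Mantel-style
permutation of the response matrix's row/column order,
`p = (1 + #{perm R² ≥ observed})/(n_perm + 1)` (999 permutations by
default; collinear predictors are dropped with a warning).

### Multi-criteria search

The origin (lon, lat) and (p1, p2) are fitted by NSGA-II (population 200,
200 generations by default — improvements beyond 200 are typically
negligible; both knobs are configuration parameters), maximizing
(R1_age, R1_het) simultaneously. p1 and p2 are searched on a log10 scale
because plausible values span orders of magnitude (defaults: p1 ∈ [1e−3,
1e2], p2 ∈ [1e2, 1e4] km). Origin genes are continuous and snapped to the
containing (or nearest land) cell at evaluation; origins disconnected from
more than half the sites receive −∞ objectives and are dominated away.
The result is a Pareto front: solutions that cannot improve one fit
without worsening the other. A pointed, convex front signals consilience
between the archaeological and genetic evidence; `front_select` picks k
representative solutions by objective-space arc length (extremes always
included). Per-generation front hypervolume is logged when requested;
it generally increases but small dips are possible because crowding-based
truncation can exchange interior points of a continuous front.

## Synthetic data

The generator produces the three inputs with the statistical structure the
method assumes — no more:

* **Landmass** — a Gaussian-smoothed random field thresholded at the
  requested land fraction; the largest connected component is the mainland
  on which sites and accessions are placed, smaller components are
  islands.
* **Ages** — arrival(s) = age0 − costdist/speed; the observed age is
  arrival − Exponential(mean = age_noise). The noise is one-sided because
  a site can only record a crop at or after its arrival — exactly the
  rationale for fitting a high quantile.
* **Genotypes** — serial founder simulation on the least-cost route tree:
  Dirichlet(1) founder frequencies (8 alleles/locus), and per route edge
  `bottleneck × edge_cost` binomial founder events (stochastic rounding),
  each resampling frequencies from 2 × founder_size allele copies.
  Accessions reached through shared route segments share that drift
  history, so genetic distance rises with route divergence and falls with
  overlap — the signal the trajectory metrics are designed to capture.
  Applying drift along the least-cost tree rather than the full RSP
  ensemble is a deliberate simplification for speed.

Defaults are chosen to mirror a realistic continental crop study: 193
accessions × 99 loci (the size of the published maize SSR panel), 200
sites, a 40 × 40 grid of 0.5° cells, age0 = 9000 BP, speed = 1 km/yr,
age_noise = 300 yr, p1 = 0.5, p2 = 1000 km, bottleneck = 0.01 events/km
with founder_size 10 (giving heterozygosity declines of roughly half
across the grid).

What passing tests on this generator do **not** show: robustness to
radiocarbon calibration error structure, introgression from wild
relatives, selection (e.g. strongly bottlenecked subpopulations such as
Northern flints), long-distance post-dispersal gene flow, or
model-misspecified landscapes — all present in real data.

## Numerical and design choices

* Cell indexing is row-major from the north-west corner; coordinates are
  cell centres; points on cell boundaries belong to the cell whose
  west/north edge they lie on. These conventions are fixed so results are
  bit-reproducible.
* The water decay formula `p1·2^(−d̄/p2)` is the unique exponential form
  consistent with a constant decay rate and a named half-value distance;
  `d̄` is averaged before applying the decay. Normalization applies to the
  water sub-matrix only, before merging and distance correction.
* Quantile regression: coefficients at an LP optimum need not be unique,
  but the achieved check-loss — hence R1 — is. A constant predictor
  returns slope 0 and R1 = 0 by convention.
* Net passage is clipped at zero (the net flow has one direction per
  edge), and R is only ever evaluated on edges that exist in the
  landscape, avoiding 0·∞.
* θ = 0 (pure random walk) is accepted only when the absorbing chain is
  proper; otherwise a singular-matrix error is raised.
* Deliberately scaled problem sizes: the end-to-end recovery study and
  the acceptance script run NSGA-II at population 60 × 40 generations on
  the 40 × 40 default scenario, and the genetic-distance regressions use
  a 40-accession subsample with 199 permutations. These sizes were chosen
  as the package's own compromise between statistical resolution and a
  comfortable desk-scale runtime; the library defaults remain population
  200 × 200 generations and 999 permutations.

## Limitations

* A single conductance matrix serves both "travel time" (ages) and
  "travel cost" (genetics); a separate genetic conductance matrix is a
  known refinement and out of scope here.
* Only adjacent cells are connected: no long-distance "leap-frog"
  movements, no anisotropy, no additional environmental layers.
* Heterozygosity of single plants at SSR loci is a noisy diversity proxy;
  the τ = 0.8 quantile mitigates but does not remove this.
* Radiocarbon calibration is taken as given; the package consumes
  calibrated ages BP.
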