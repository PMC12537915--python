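# Methods

This note records the model as implemented, the defaults and why they were
chosen, the numerical conventions, and what the synthetic benchmarks do
and do not demonstrate.

## Pipeline and assumptions

The pipeline is normalize → weight → aggregate → rank → group. All stages
operate on a validated decision matrix: m ≥ 2 alternatives, n ≥ 1
criteria, finite entries, unique identifiers, and a benefit/cost direction
per criterion. Directions are a data-model responsibility: normalization
folds them in, and every later stage can then assume "larger = better".

### Normalization

* **Logistic (default).** Benefit: `1/(1+e^-x)`; cost: `1/(1+e^x)`. The
  decreasing form is the published one; applied verbatim to benefit
  criteria it would invert merit order, so the package orients the sigmoid
  by direction and offers `strict_verbatim=True` to audit the decreasing
  form on every column. Columns are z-scored first
  (`standardize_first=True`, sd with ddof=1) because raw indicators differ
  by orders of magnitude and a sigmoid of raw values saturates to 0/1,
  destroying discrimination; the toggle exists because the choice is a
  convention, not a theorem. Zero-variance columns are an error in this
  mode.
* **Fuzzy quantization** = linear min-max membership,
  `(x−min)/(max−min)` (reversed for cost). The simplest standard fuzzy
  quantizer; constant columns are an error. Its column minimum is exactly
  0, which interacts with the weighted product (below).
* **Decimal scaling** divides each column by the smallest power of ten
  bringing `max|x|` to ≤ 1 (all-zero columns pass through); cost columns
  are then flipped `1 − v`. Outputs can be negative for negative inputs —
  callers feeding decimal scaling into WASPAS need non-negative data.
* **Vector** divides by the column Euclidean norm; cost columns flipped
  `1 − v`.

All four are monotone within a column, and flipping a criterion's
direction reverses the induced order — these are tested properties.

### DCRITIC weighting

`w_j ∝ t_j · Σ_j' (1 − dCor(o_j, o_j'))` on the *normalized* columns
(weighting after normalization, matching the pipeline order). Conventions:

* sample sd with denominator m−1 (the printed formula has the square
  outside the sum, which is identically zero and plainly a typo);
* distance correlation is the classical biased V-statistic with
  double-centered distance matrices, not the bias-corrected U-statistic —
  the definition used by the distance-correlation CRITIC literature; the
  brute-force oracle in the tests pins this choice to 1e-12;
* the redundancy sum includes the self term j' = j (it contributes 0);
* dCor with a constant column is defined as 0 (such a column has t_j = 0
  and hence zero weight regardless, and this avoids 0/0);
* if every criterion has zero information content (all columns mutually
  affine) the weights are undefined and a degeneracy error is raised.

Entropy weights (`1 − e_j` shares) and MEREC (removal-effect shares,
values required in (0, 1], uniform fallback behind an explicit flag when
no criterion has any removal effect) serve the robustness harness.

### WASPAS, TOPSIS, VIKOR

`WQ = λ·WS + (1−λ)·WP` with λ = 0.5 by default — the symmetric WASPAS
convention; the source pipeline never states its λ, so it is a visible
config knob. With weights summing to 1 and positive values, AM-GM gives
WP ≤ WS, so WQ is monotone in λ; both identities are tested. The weighted
product is computed in the log domain; non-positive values are an error by
default, and `allow_zero=True` (used by the pipeline when a min-max
normalized matrix is fed in) evaluates the exact limit `0^w = 0` instead
of erroring on the column minimum. Ranks are competition ranks
(1, 2, 2, 4) on descending score; ties share the smallest rank, so the
identifier tiebreak affects presentation order only.

TOPSIS and VIKOR consume the *same* normalized matrix as WASPAS, so in
the robustness harness the aggregator is the only varying factor. VIKOR
uses v = 0.5 and defines a degenerate spread term (S* = S⁻) as 0; its Q
ranks ascending.

### Graph-seeded k-means

Similarity `S_ij = exp(−‖x_i−x_j‖²/2σ²)`, unnormalized Laplacian
`L = D − S` (the self-similarity cancels in D − S, tested), eigenvectors
of the k smallest eigenvalues ascending with a deterministic sign
convention (largest-magnitude entry positive), then a deterministic
k-means on the embedding rows seeded farthest-first (first seed = row
nearest the embedded centroid; ties to the lowest index). The embedded
*assignment* — not the embedded centers — is transferred back: each
initial center is the original-space mean of one embedded cluster, which
makes the subsequent original-space Lloyd iterations well-typed. Lloyd
runs with tol 1e-10, max_iter 300, argmin ties to the lowest center
index, and a deterministic empty-cluster repair (reseed with the point
farthest from its assigned center). Inertia is asserted non-increasing
across iterations except across a repair.

**Bandwidth.** σ defaults to "auto". For a bare similarity graph this is
the median pairwise distance. When the number of groups k is known —
always the case inside `cluster_graph_kmeans` — auto-σ is instead the
median over points of the distance to their (⌈m/k⌉−1)-th nearest
neighbor: the farthest within-group neighbor of a balanced group. The
global median is an order of magnitude too wide once groups are well
separated (it measures between-group spread, not within-group scale) and
blurs the similarity graph until the embedding cannot separate the
groups; the k-aware scale recovers well-separated blobs exactly and lets
the spectral seeding start Lloyd at (or next to) the fixed point —
median 1 iteration vs ~4 for random seeding in the benchmark. Any
numeric σ overrides the heuristic.

The grouping step is fully deterministic given (points, k, σ): repeated
runs are bit-identical. Classical seedings (random, k-means++ implemented
locally with a seeded generator, farthest-first) exist solely as
benchmark comparators.

### Robustness harness and analytics

Rank agreement uses tie-corrected Spearman ρ (Pearson correlation of rank
values); group agreement uses the V-measure with β = 1 and natural-log
entropies, computed from the contingency table, with 0/0 ratios defined
as 1 and V = 0 when homogeneity + completeness = 0. Both are
cross-checked against scipy/scikit-learn in the tests. Externally
produced labelings (e.g. DBSCAN or GMM groups) can be compared by passing
them straight to `vmeasure`; those algorithms are deliberately not
re-implemented.

Score deconstruction attributes `w_j·x_ij` to each criterion; the change
decomposition between two time points uses a *single* caller-chosen
weight vector, because with time-varying weights the decomposition is no
longer additive. Both conserve exactly (residuals ≤ 1e-12, tested).
The additive convention applies to WS, not WQ: WQ mixes WS and WP and
has no exact additive split.

## Synthetic data

The generators emulate the case-study shape — default m = 35, n = 15,
k = 6 groups, two time points — with controllable equicorrelation
(Gaussian copula), exponential-tilt skew, scale-inflated outlier rows,
and Gaussian score blobs (centers 10 apart, sd 1 by default, i.e.
separation 10× noise; the noisy stability benchmark uses sd 1.5).
Everything is a pure function of the spec including its seed, and each
generator draws from its own named substream, so adding a generator never
perturbs another's output.

What passing the synthetic benchmarks shows: the implementation is
internally correct (oracle agreement, conservation, determinism,
recovery under clean separation). What it does not show: behaviour on
real indicator data, whose margins are not Gaussian, whose group
structure is not spherical, and whose criteria dependencies are richer
than an equicorrelated copula.

## Benchmark and test sizes

The stability benchmark uses 50 datasets × 20 repeats (m = 35, 1-D,
k = 6); recovery uses 20 seeded datasets; the distance-correlation oracle
comparison uses 200 pairs with m ≤ 12; the weighting contracts use 100
seeded matrices. These sizes give stable medians and extremes while
keeping the whole suite in seconds.

## Known limitations

* The case-study fixtures carry printed scores, ranks and groups only;
  the raw indicator values are not public, so the headline country
  scores cannot be recomputed from source — the printed scores are the
  input for everything downstream (re-ranking them reproduces the
  printed ranks exactly).
* The printed grouping cannot be reproduced exactly either: the
  published bandwidth σ is unknown, and a σ sweep against the printed
  groups tops out at a V-measure of ≈ 0.33-0.34, so agreement is
  reported, never asserted. A one-dimensional k-means partition is
  highly sensitive to σ and k, and the printed group identifiers may
  also be permuted arbitrarily (the V-measure is permutation-invariant,
  so that part is handled).
* One published robustness claim does not hold against the published
  rank columns themselves: the minimum Spearman ρ between weighting
  variants, recomputed from the printed table, is 0.661 — below the
  claimed 0.8. The package reports the recomputed value rather than the
  claim; the corresponding acceptance test is left failing by design.
* Fuzzy quantization is implemented as linear min-max membership — the
  simplest standard quantizer; the source leaves the definition open.
* No missing-data handling (validation rejects non-finite cells), no
  subjective/hybrid weighting, no automatic selection of k.
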