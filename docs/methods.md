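# Methods

This note documents the statistical models, numerical choices, and known
limitations of `ccnorm`.  Coordinates are 0-based half-open throughout;
all genomic distances are measured between element midpoints.

## Partitioning

A restriction digest splits each chromosome at every occurrence of the
recognition site (IUPAC ambiguity codes expand to character classes;
overlapping occurrences count) offset by the enzyme's cut position.  Each
fragment contributes two fends.  A fend's midpoint is defined as the
midpoint of the fragment half it represents — left fend at
⌊(start + mid)/2⌋, right fend at ⌊(mid + stop)/2⌋.  An alternative
convention places the fend midpoint at the fragment end coordinate; the
half-midpoint convention is used consistently everywhere distances are
computed, and nothing downstream depends on the choice beyond a bounded
(quarter-fragment) shift of all distances.

5C partitions come from a BED file whose strand column carries the primer
orientation.  When the file has no explicit region labels, regions are
inferred by splitting at inter-fragment gaps larger than 1 Mb
(configurable): 5C regions are experiment-defined contiguous probe blocks,
and any gap that large cannot lie inside one.

## Filtering

Phase one removes invalid read pairs.  5C: only fragments probed with
opposite-orientation primers can form a sequenceable ligation product, so
same-orientation pairs are discarded.  HiC: a pair is kept when (a) the
summed insert size — the distance from each mate's 5′ position to the cut
site it points toward — is at most the user limit, and (b) the fragments
are non-adjacent, or adjacent with both mates in the same orientation
(adjacent opposite-orientation products are dominated by undigested or
re-ligated templates).  Same-fragment pairs are always discarded; read
assignment sends a `+` mate to its fragment's right fend and a `-` mate to
the left fend (the fend whose cut site the read points toward).

Phase two iteratively removes elements with fewer than `min_interactions`
surviving interaction partners (distinct partners by default; a switch
thresholds on summed reads instead), repeating until every survivor meets
the threshold.  The fixed point is the unique maximal subset closed under
the degree condition — removal order cannot matter, because the union of
any two closed subsets is closed — and the tests verify this against an
exhaustive search over subsets.  The default threshold of 20 partners is a
pragmatic value for real libraries; tests and simulations use lower values
scaled to their smaller problem sizes.

The valid set *A* used by every estimator consists of cis pairs whose
elements both survive phase two and whose midpoint separation lies within
the configured limits, excluding structurally unobservable pairs (the two
fends of one fragment) and, for 5C, zero counts (which cannot be
log-transformed; the binary distance variant exists precisely to retain
that information for HiC).  Corrections are learned on cis pairs and
applied unchanged to trans expected values, whose model contains no
distance term.

## Distance-dependence signal

5C: ordinary least squares of ln c on ln d over valid non-zero intra-region
pairs, giving D(d) = γ·ln d + μ.  Inter-region 5C pairs are not used for
fitting.

HiC: the distance range is partitioned into `n_bins` log-distance bins —
the first spanning (0, `smallest_bin_upper`], the rest of equal log width
up to `max_distance` (default: the largest valid separation; package
defaults `n_bins = 90`, `smallest_bin_upper = 40 kb`).  Each non-empty bin
contributes an anchor at its mean ln-distance with value ln(mean count),
the mean taken over *all* valid pairs in the bin including unobserved
zeros; a parallel binary variant stores the fraction of pairs observed.
Zeros are included because the binary variant exists separately — dropping
them would conflate the two signals.  Empty bins (or bins whose mean count
is zero) are dropped and their neighbors connected directly, which keeps
anchors meaningful at extreme distances where occupancy is thin.
Evaluation interpolates linearly in (ln d, value) space and extends the
terminal segments beyond the first and last anchors; binary-variant values
are clipped to (1e−6, 1−1e−6) for probability use.  Counts-variant values
are stored in log space so that e^D is on count scale.

## Correction models and the gauge

Expected values are E = e^{D+θ}·f_i·f_j (HiC) and E = D + θ + f_i + f_j
(5C).  The global intercept θ is not in the minimal model but makes the
gauge exact: the map (f, θ) → (f/s, θ + 2 ln s) leaves every E unchanged,
so after any fit the corrections are rescaled to geometric mean 1 (HiC) or
arithmetic mean 0 (5C) with the scale absorbed into θ.  Without θ the
gauge constraint and the fixed-point/ML conditions could not hold
simultaneously, because the data pin the overall scale.

A further identifiability caveat specific to 5C: the pair graph is
bipartite (forward primers only pair with reverse primers) and regions are
disconnected components, so within each region a constant can be added to
all forward corrections and subtracted from all reverse corrections
without changing any expected value.  The algorithms return one point of
this gauge orbit deterministically; comparisons against ground truth (and
any cross-dataset comparison of raw correction values) should demean per
region × orientation.  Expected values, residuals, and heatmaps are
unaffected.

### Express (weighted balancing)

Jacobi sweeps f_i′ = f_i·sqrt(Σ_{j∈A_i} c_ij/E_ij ÷ |A_i|) for HiC and
f_i′ = f_i + Σ(ln c − E) / (2|A_i|) for 5C, every element updated from the
same incoming f (order independence; sweeps are partitionable by element,
so a multi-process backend can be added without changing results).  After
each sweep the corrections are regauged as above.  Convergence is declared
when the largest per-element change falls below `tol` (default 1e−8).
Dividing by |A_i| rather than a fixed row target is what tolerates
filtered elements, distance cutoffs, and non-uniform restriction-site
density without skewing corrections.  When the distance signal is not
removed (`remove_distance=False`), D ≡ 0 and θ absorbs the mean count
level.

### ExpressKR (Knight–Ruiz)

The dense symmetric count matrix over valid elements (optionally divided
by e^D) is balanced by the Knight–Ruiz inner–outer Newton iteration
(conjugate-gradient inner solves with the published δ = 0.1 / Δ = 3
safeguards and forcing sequence) to row sums of 1; corrections are stored
as f = 1/x and regauged.  Rows with zero support raise an error naming the
offending elements — balancing has no solution there and more aggressive
filtering is the remedy.

### Probability

HiC-Poisson models c_ij ~ Poisson(E_ij) with the counts-variant distance
signal; HiC-binomial models the observed indicator with
p_ij = clamp(f_i·f_j·p_D, 1e−6, 1−1e−6) and the binary variant; 5C models
ln c ~ Normal(E_ij, σ²) with σ² re-estimated from residuals.  All are
optimized in ln f (keeping f > 0 without constraints) by gradient descent
with Armijo backtracking: a step f − r·∇ is accepted when
C(f′) ≤ C(f) − 10⁻⁴·r·‖∇‖², r halves until acceptance and doubles (capped
at 2¹⁰) after a first-try acceptance.  Two numerical choices matter:

* θ is profiled out in closed form each evaluation (Poisson:
  e^θ = Σc / ΣE₀; lognormal: mean residual), which removes the dominant
  ill-conditioned direction;
* the gradient is Jacobi-preconditioned by the diagonal curvature (Σ_j
  E_ij for Poisson; 2|A_i| for the lognormal), without which plain descent
  stalls far from the optimum because row expected sums span orders of
  magnitude under power-law decay.

Stopping: relative cost change below `tol` or gradient infinity-norm below
`gtol`.  On data generated exactly from the model, Poisson-Probability and
Express recover the same corrections to < 1e−6 (log scale), as the theory
requires.

### Binning (combinatorial)

Each feature's values over valid elements are cut into equal-occupancy
quantile ranges (degenerate cuts fall back to rank-based assignment with a
warning).  The model multiplies a symmetric positive grid cell per feature
into a Bernoulli observation probability with the binary distance variant
(or the overall observed fraction) as prior.  One round optimizes each
feature's grid in turn by BFGS on the log-grid parameters, holding the
other features fixed; rounds stop when the likelihood gain falls below
`tol`.  Grids multiply across features (the product model); fitting them
strictly sequentially per round gives the same optimum when features are
independent and is not separately implemented.  Pseudo-counts enter as a
per-combination regularizer pc·(ln G − G + 1) — equivalent to adding pc
reads to both the observed and expected tallies of every combination under
a Poisson approximation — whose maximum is at G = 1, so pc → ∞ forces all
grid values to 1.  The tests check the fitted grid against an independent
per-combination likelihood grid search (exact for a single feature with a
flat prior, where the likelihood separates by combination).

## Heatmaps

A pair contributes to the bin pair containing its two midpoints (half-open
bins); observed grids sum counts, expected grids sum E over all valid set-A
pairs, with the distance term included on request.  5C expected values are
exponentiated before summation so both assays yield count-scale grids and
a single observed/expected convention.  Resolution 0 produces one bin per
element (fragment-resolution 5C maps).  Dynamic binning grows each
under-threshold bin by complete Chebyshev rings (never partial rings, for
determinism and isotropy), aggregating observed and expected together so
ratios are preserved; bins still below threshold at the radius limit are
invalidated.  Correlation between aligned maps is the Pearson correlation
of ln(observed/expected) over bin pairs valid and non-zero in both, overall
and within 10 log-spaced cis distance strata (resolution to map span) by
default; strata with fewer than 3 shared bins are reported as undefined
rather than 0.

## Synthetic data

The generators produce the structure the models assume, plus known ground
truth for recovery scoring.  HiC: fragment lengths jittered 25% around the
mean, lognormal(0, σ_bias) fend biases (geometric mean 1), intensities
s·b_i·b_j·d^γ with γ = −1 by default, Poisson counts, and no same-fragment
pairs (so generated data satisfy the filters' contract).  `depth` sets the
mean expected reads per fend.  5C: regions of alternating primer
orientation; ln-counts are μ + γ·ln d + f_i + f_j + Normal(0, σ_noise)
exponentiated and rounded, with μ = 14 so typical counts are in the
hundreds and rounding is a sub-percent perturbation; `round_counts=False`
gives the exact log-linear model for algebraic tests.  The paired-digest
generator draws two partitions over one coordinate space, one shared
symmetric block-level log-enrichment field (the "biology"), and
per-dataset biases with a spatially smooth component (70% of log-variance,
interpolated from a 400 kb block track) — emulating GC/mappability-like
tracks that vary slowly along the genome and therefore do not average out
under binning.  The smooth component is also emitted as an observable
covariate so the Binning model has a feature that actually carries bias
information, playing the role a mappability track plays for real data.

Problem sizes in the tests and the acceptance script (100–110 fragments,
200–220 fends, 8–10 Mb chromosomes) are chosen so every pipeline runs in
seconds while each estimator remains in its informative regime.  Depths
are set by a power calculation: the shot-noise floor on ln f is roughly
(reads per fend)^{−1/2}, so recovery experiments use ~600 reads per fend
(floor ≈ 0.04–0.08 against a bias spread of 0.3) and neutrality checks,
which bound the *maximum* deviation over all fends, use ~10⁴.

What passing these tests does and does not show: the simulations contain
no topological domains, compartments, loops, trans structure, mappability
gaps, or PCR artifacts, so they validate the estimators against their own
model class and the qualitative claim that fend-level correction improves
cross-dataset agreement — not performance on any particular real library.

## Serialization and CLI

Partitions, distance functions, and filter states are stored as versioned
JSON text containers (bit-exact for integer coordinates), counts and
corrections as TSV.  The CLI mirrors the library stage for stage, keeps a
JSON-lines provenance log of every command and parameter, and skips a
stage whose parameter-and-input hash is unchanged.  Everything is
single-process; the element-wise structure of all sweeps is the contract
that keeps a parallel backend possible without changing results.

## Known limitations

* Dense cis-pair enumeration is O(n²) per chromosome; fine for the
  supported fragment counts and for 5C, but a genome-scale HiC run would
  need the pair streams chunked (the algorithms themselves only consume
  per-pair arrays).
* The binomial HiC model saturates when nearly all pairs are observed;
  its recovery is correspondingly weaker than Poisson on dense simulations.
* Inter-region 5C pairs receive no distance term (D from the intra-region
  fit would extrapolate far outside its support).
* KR balancing operates on the dense valid submatrix; extremely sparse
  matrices should be filtered first (zero-support rows are an error by
  design).
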