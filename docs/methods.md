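# Methods

## Modular response analysis

The package assumes the measured biological system is governed by an unknown
continuously differentiable dynamical system `ẋ = f(x, p)`, with one
intrinsic, perturbable parameter per module, and that every measurement —
basal or perturbed — is taken after the system has settled into a steady
state (`ẋ = 0`). Under these assumptions, a first-order expansion of the
implicit steady-state map relates the observed global responses `R` to the
local interaction strengths `r` through the homogeneous relations

    R[i,k] = Σ_{j≠i} r[i,j] R[j,k]          (k ≠ i)

and the self-perturbation relation

    R[i,i] = Σ_{j≠i} r[i,j] R[j,i] + P[i,i],

which, with the normalization `r[i,i] = −1`, combine into `r R = −P` with
`P` diagonal. `r` is what a biologist wants: the direct influence of gene
*j* on gene *i*, netted of all paths through the rest of the network.

**What MRA does not give.** Perturbation magnitudes `Δp_k` never enter the
equations — only steady states do — so the dataset container does not store
them, and only the product `(∂x_i/∂p_i)(Δp_i/x_i)` in `P[i,i]` is
identifiable, never its two factors separately. No confidence intervals on
`r` are produced.

### The global response estimator

On positive abundances, `R[i,k] = 2(x'−x)/(x'+x)` (range [−2, 2]); on
signed z-score scales (consensus-signature data), the denominator is
`|x'|+|x|` to avoid near-zero denominators from opposed signs. A 0/0 cell is
defined as 0 ("no observable change"), the continuity limit. This symmetric
relative difference is more robust than `Δx/x` but carries a bias of order
the perturbation strength; consequently inference error grows with
knockdown strength even on noise-free linear systems (measured: max
relative error ≈ strength), which is exactly the regime behavior the
degradation benchmark quantifies. With the raw `Δx/x` response, recovery on
linear systems is exact at any strength — a property the test suite uses to
validate the solvers independently of the estimator.

Replicates are handled by averaging per-replicate `R` matrices (the
default, matching plate-wise processing of real screens); averaging raw
expression first is exposed as an alternative (`average_datasets`).

### Solvers and numerics

- **Closed form**: `r = −[diag(R⁻¹)]⁻¹ R⁻¹`. A 1-norm condition estimate is
  computed first and the solver refuses inputs above a configurable cap
  (default 1e12) rather than silently regularizing; an optional ridge term
  exists for exploratory use only and is off by default.
- **Blockwise**: the n homogeneous systems (dimension n−1, one per row of
  `r`) are solved independently by LU factorization with partial pivoting.
  This avoids a full inversion, scales to ~1,000 modules, and parallelizes;
  joblib threads are used because LAPACK releases the GIL. Rows are
  reassembled in fixed order, so the result is **bit-identical for any
  worker count**. A singular subsystem raises an error naming the row.
  Diagnostics carry the condition estimate, a count of small-pivot warnings
  (min |U_ii| < 1e−12 · max |U_ii|), and per-subsystem residuals.
- The diagonal of `r` is overwritten with −1 exactly after solving: it is a
  definition, not an estimate.
- Sensitivities are recovered as `P[i,i] = R[i,i] − Σ_{j≠i} r[i,j] R[j,i]`,
  the unique sign convention consistent with `r R = −P` (the equivalent
  form `P = −diag(rR)` is what the code evaluates).

### CLR-adapted pruning (MRA+CLR)

Row/column z-scores of `r` with sign preservation:
`Z[i,j] = sign(r[i,j]) √(z_row² + z_col²)`. Choices that were genuinely
open and how they were fixed:

- Row/column statistics include all n entries (the −1 diagonal included),
  matching the printed definition of the transform; the diagonal is then
  excluded from edge selection and evaluation, since it is a normalization
  constant rather than an inference.
- The standard deviation uses the n−1 denominator (the convention of the
  R/spreadsheet ecosystem this transform originates from).
- A zero-variance row or column contributes z = 0 (no infinities).
- The max{0, ·} clamp of MI-CLR is **not** applied — sign information is
  the point of the adaptation — but a clamped variant is available
  (`clamp=True`).

Edge selection symmetrizes by the dominant direction,
`score(i,j) = max{|M[i,j]|, |M[j,i]|}` with the sign taken from the larger
entry, and keeps the top `⌈fraction · n(n−1)/2⌉` pairs. The fraction
universe is the full set of unordered off-diagonal pairs, making MRA and
the undirected MI methods comparable. Ties break deterministically (score
descending, then identifier pair); if fewer nonzero scores exist than
requested, the selection returns what exists and flags the shortfall.

## MI baselines

Expression across the perturbation panel (basal + n perturbed conditions)
is the sample set. Discretization is per-gene, equal-frequency by default
with `⌈√m⌉` bins (equal-width available); entropies are plug-in estimates
with natural logarithms and `MI = H(X_i) + H(X_j) − H(X_i, X_j)`.

- **CLR**: per-gene z-scores of MI clamped at 0 (diagonal self-information
  excluded from the background statistics — it would dominate them),
  combined as a root-sum-of-squares.
- **MRNET**: per-target maximum-relevance-minimum-redundancy forward
  selection; the first partner is the MI argmax, later candidates are
  scored relevance-minus-mean-redundancy against the already-selected set,
  selection stops when the best score is ≤ 0, and the directed score
  matrix is symmetrized by max. The published sketch of the greedy strategy
  leaves these details open; this is the standard MRMR reading.
- **ARACNE**: threshold at `tau`, then data-processing-inequality pruning.
  An edge is removed only when it is the *strictly* weakest of a triplet
  (`M[i,j] < min{M[i,k], M[k,j]} − eps`, strict at the default `eps = 0`,
  so exact three-way ties survive). All decisions are computed on the
  original matrix and applied at once — no cascade — so the result is
  order-independent.

## Ground-truth simulator

The simulator emulates steady-state regulatory network generators used for
benchmarking: `n_tf` regulators (which may regulate each other — feedback
loops are allowed) and `n_ta` pure targets with no outgoing edges. Edges
are sampled uniformly over (regulator, target) pairs with mean in-degree
`mean_degree` (default 2, a sparse regime typical of transcriptional
networks); signs are activating with probability 0.6 (activators modestly
outnumber repressors in curated regulatory networks); weight magnitudes are
uniform in [0.5, 1.5], basal synthesis rates in [2, 4], degradation rates
in [0.5, 1.5] (arbitrary time units; only ratios matter at steady state).

**Linear mode** (`dx/dt = b + Wx − Dx`) computes the exact fixed point. After
sampling, weights are shrunk by a global factor until (i) the spectral
abscissa of `W − D` is ≤ −0.05, guaranteeing a stable steady state, and
(ii) the basal state and, for every gene, all *other* genes' activities
remain positive under a full knockout. Because the fixed point is affine in
the perturbed synthesis rate, positivity at strengths 0 and 1 implies
positivity at every intermediate knockdown. A fully knocked-out gene with
net inhibitory input has a negative linear fixed point; its readout is
floored at 0, as an abundance measurement would be. The true local response
for benchmarking is the normalized Jacobian at the basal state,
`r[i,j] = W[i,j] x_j / (d_i x_i)`.

**Hill mode** replaces linear regulation with saturating terms
(activation `w·x^h/(K^h+x^h)`, repression `w·K^h/(K^h+x^h)`, `h = 2`,
`K` set to each regulator's unregulated scale `b/d`), keeping all synthesis
nonnegative and bounded, and integrates from the basal condition until
`‖dx/dt‖∞ < 1e−10`.

Perturbing gene *k* scales its basal synthesis `b_k` by (1 − strength):
strength 1 emulates CRISPR-style full KO, small strengths shRNA-style
knockdowns. Observation noise is multiplicative log-normal (preserves
positivity, the standard model for expression data); the default is
noise-free because the benchmarks isolate estimator and algorithm behavior.
Everything is reproducible per seed.

**What the simulator does not emulate**: measurement-platform artifacts
(hallmark-gene imputation, consensus-signature construction), off-target
perturbation effects, batch structure, or realistic biological noise
spectra. Passing benchmarks on these synthetic screens demonstrates
correctness of the algebra and the expected algorithm ordering under ideal
steady-state conditions, not performance on any particular real platform.

`generate_linear_mra_instance` provides the pure-algebra oracle: a sparse
`r_true` (diagonal −1, off-diagonal spectral radius ≤ 0.8) and diagonal
`P_true` (|entries| ≥ 0.5) yield `R = −r_true⁻¹ P_true`; both solvers must
reproduce `r_true` and `P_true` to 1e−8.

## Evaluation harness

Evaluation is undirected over unordered pairs (references and MI methods
carry no direction or sign). Reference networks are filtered at
score > threshold (the > 0 / > 0.5 / > 0.8 regimes). Confusion counts
partition the n(n−1)/2-pair universe; the overlap significance is the
upper-tail hypergeometric probability P(X ≥ TP) including the observed
value (the enrichment convention; the tail choice was open and is fixed
here). `compare_algorithms` runs all five algorithms with identical
top-fraction selection (defaults 5/10/20/30/40%), skipping and flagging an
algorithm at a level where it returned fewer nonzero scores than requested.

## Benchmark problem sizes

The shipped benchmarks use forward-constructed instances up to n = 500,
solver-equivalence checks up to n = 938 (the largest real screen scale this
method targets), ten seeded 100-gene knockdown screens for the
algorithm-ordering comparison, and five seeds × five strengths for the
degradation curve — sizes chosen so the whole suite reruns in minutes on a
single CPU while still covering the large-system regime the blockwise
solver exists for.

## Known limitations

- MRA needs one perturbation per module and a steady state; unsteady or
  incomplete screens are out of scope.
- The symmetric relative-difference estimator biases `r` by O(strength);
  full-KO data sit at the edge of the linearization's validity (the
  degradation benchmark quantifies this).
- Ill-conditioned `R` is refused, not regularized; noisy near-singular
  screens will error out by design.
- The plug-in MI estimator is biased at small sample counts; the baselines
  reproduce specific published algorithm definitions rather than the best
  available MI estimators.
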