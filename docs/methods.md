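# Methods

## The imputation problem

Chromosome-conformation assays (dilution Hi-C, in situ Hi-C, micro-C, DNase
Hi-C, ChIA-PET, PLAC-seq, DNA SPRITE, ...) each produce, per biosample, a
binned contact map: a symmetric matrix `M` whose entry `M[i, j]` counts 3D
contacts between genomic bins `i` and `j` of one chromosome. Collections
such as the 4D Nucleome portal can be arranged as a biosample × assay grid
of such maps, most of whose cells are empty because running every assay in
every biosample is infeasible. `hicgrid` predicts those missing maps from
the observed ones.

## The factorization model

Every biosample `b`, assay `a`, genomic bin `p` and bin separation `d` gets
a learned embedding vector. A query `(b, a, i, j)` is canonicalised to
`i ≤ j`; the concatenation

    [ B[b] ; A[a] ; P[i] ; P[j] ; D[j − i] ]

feeds a multilayer perceptron (ReLU hidden layers, linear scalar output)
that regresses the normalized log contact value. Canonicalising the
positions before lookup makes the prediction exactly symmetric in `(i, j)`;
whole-map prediction evaluates the upper triangle and reflects it, so the
output matrix equals its transpose bit for bit. Diagonal predictions
(separation 0) are extrapolations — training samples only off-diagonal
entries — and are emitted but should be treated with caution.

Default hyperparameters are the best configuration found by random search
over the seven-dimensional grid (learning rate, dropout, biosample / assay /
position factor counts, layers, nodes): 16 biosample factors, 128 assay,
128 position and 128 distance factors, 4 × 256 hidden units, dropout 0.4,
Adam at learning rate 1e-4 (conventional β₁ = 0.9, β₂ = 0.999, ε = 1e-8),
batches of 10,000 uniformly resampled off-diagonal training entries, 526
batches per epoch, at most 50 epochs. After each epoch the full validation
MSE (all off-diagonal upper-triangle entries of every validation map) is
computed and the parameter snapshot with the lowest validation MSE is
returned. The loss is plain MSE — the same quantity used for evaluation.

Design choices the architecture description leaves open, resolved here:
hidden nonlinearity is ReLU with dropout after each hidden activation; the
distance table has one row per raw bin separation (no log-binning);
embeddings initialise standard normal and linear layers uniform ±1/√fan_in;
all arithmetic is float32 driven by a single seeded generator, so training
is bit-reproducible for a fixed seed on a fixed BLAS. Negative whole-map
predictions are clipped to zero, since contact values are non-negative.

The optional convolutional position encoder replaces each raw position row
by a learned reduction of the 21 rows centred on it (10 each side, zero
rows beyond the chromosome ends): a 1→3-channel convolution with kernel
length 21 along the window axis followed by a 3→1-channel 1×1 convolution.
No nonlinearity is inserted between the two convolutions — the stated
architecture names none — so the encoder is a learned linear smoothing; it
is isolated behind `conv_window` and off by default.

## Preprocessing

Each map is (1) transformed entrywise by natural `log(x+1)`; (2) bins whose
marginal (full-row sum) lies more than `k_mad = 10` absolute deviations
from the median marginal **in any training map** are removed from every
map; (3) each map is rescaled so its full-matrix entry sum (both triangles
plus diagonal) equals `1e5`. The deviation scale is the raw median absolute
deviation by default (`mad_kind="mean"` switches to the mean absolute
deviation; the two readings coexist in the field's usage and both are
exposed). When a map's MAD is zero — near-uniform marginals, common in
clean synthetic data — that map discards nothing, rather than discarding
every off-median bin. Marginals are computed after the log transform,
following the pipeline's stated step order. Deriving the mask from training
maps only is a leakage guard and is verified metamorphically in the tests.

Splitting is per assay: the assay's experiments are shuffled once with the
seeded generator (assays processed in sorted label order) and assigned
cyclically train, test, validation, ... — so a two-experiment assay always
contributes one training and one test map and every assay with at least one
experiment has a training example.

## Baselines

Row mean = elementwise average of reference maps sharing the target's
assay; column mean = sharing its biosample; cross mean = the union of both
pools (each map once, unweighted — maps are already depth-normalized). The
target's own map never enters a pool. When a split is supplied the pool is
restricted to training experiments (the comparison the model is trained
under); without a split all observed maps qualify, the mode used when
imputing a full grid for downstream analysis.

## Contact-map features

* **Contact decay profile**: mean value along each diagonal, indexed by bin
  separation; length `n_bins`; diagonal included at `d = 0`.
* **Compartment eigenvector**: unit-norm eigenvector of the symmetric map
  for the largest-magnitude eigenvalue, computed on the normalized map
  itself by default. Eigenvector sign is arbitrary, so it is fixed to
  correlate non-negatively with the marginal vector (first nonzero
  component positive on exact ties). The conventional A/B pipeline —
  observed/expected ratio, then the correlation matrix, then the leading
  eigenvector — is available as `oe_correlation=True`; on synthetic maps
  with planted compartments it is this variant that recovers the planted
  ±1 profile (the raw leading eigenvector is dominated by the uniform
  distance-decay mode), and the test suite checks recovery through it.
* **Insulation score**: mean of sliding `window × window` diagonal-anchored
  submatrices (default window 30, step 1 bin), length
  `n_bins − window + 1`. These windows hug the diagonal rather than
  straddling it; dips mark domain boundaries.

## Evaluation and cross-entity analysis

MSE between predicted and observed maps is averaged over the off-diagonal
upper triangle (flag to include the diagonal). Per-distance Pearson
correlation is reported as missing where a diagonal has fewer than two
entries or zero variance. Test-map MSE is regressed (OLS) on the number of
training experiments sharing the assay, the biosample, or either.

Entity correlations: for two biosamples, the feature-profile Pearson
correlation is averaged over assays observed for both (and symmetrically
for assays over shared biosamples). Zero-variance profiles contribute
missing values that are excluded from the mean rather than silently
becoming 0. On unimputed grids, entity pairs with no shared experiments are
missing; imputing the grid completes the matrix and enables agglomerative
clustering, done with average linkage on the distance `1 − r` (linkage
method exposed; entities processed in lexicographic order so equal-height
merges are deterministic).

## Synthetic grids

The generator builds an intensity surface per grid cell as the product of a
per-biosample power-law distance kernel `(1+d)^(−γ_b)`, a per-assay
positive distance-bias curve, a compartment term (`1+β_b` for same-sign
bins of a planted ±1 profile, `1−β_b/2` otherwise), a TAD term (`τ_b`
within a planted segment), and a rank-one multiplicative interaction
`exp(s·u_b·v_a)` with standard-normal latent scalars. The surface is scaled
to an expected per-map depth and counts are drawn Poisson per unordered bin
pair and mirrored (or taken noise-free). A random cell subset is hidden,
re-drawn until every biosample and assay keeps ≥ 2 observed maps.

The interaction term is the planted signal that makes imputation
non-trivial: it cannot be written as a row effect plus a column effect, so
the cross-mean baseline is provably suboptimal while the factorization
model can recover it compositionally. Randomly drawn parameters span values
typical of mammalian chromosomes at 100 kb: decay exponents 0.8–1.6,
compartment blocks of 10–25 bins with strength 0.2–0.6, TAD segments of
8–25 bins enriched 1.5–3×, mild per-assay distance tilts
(`(1+d)^(−δ_a)`, δ ∈ [−0.3, 0.3]), interaction strength 0.5.

What the generator does **not** emulate: restriction-fragment and mappability
bias, ligation artifacts, protocol-specific cluster-size effects (SPRITE),
trans contacts, and translocations. Passing tests on these grids therefore
demonstrate correctness of the algorithms and the recoverability of planted
grid structure, not performance on real portal data.

## The pinned scaled-down study

The acceptance study uses a 6 biosample × 5 assay × 120 bin grid, Poisson
noise at depth 2e5 per map, interaction strength 0.5, 30 % of cells hidden,
and the default model hyperparameters at reduced training scale: batches of
2,000 examples, 100 batches per epoch, 12 epochs (validation-based snapshot
selection as always). Problem sizes were chosen so the whole study — three
training seeds plus baselines and the correlation analysis — runs in
minutes on a single CPU core while leaving a wide margin between the
model's validation MSE and the cross-mean baseline's. On this grid the sum
normalization to 1e5 over 120² entries puts map values on a scale of ~7, so
MSE values are two orders of magnitude larger than they would be on a
~550-bin chromosome normalized to the same total; only comparisons between
methods on the same grid are meaningful.

## Known limitations

* Position and distance embeddings are chromosome-specific; nothing
  transfers across chromosomes or resolutions.
* Diagonal predictions are extrapolations (see above).
* Training determinism holds for a fixed BLAS/thread configuration;
  different BLAS builds may round differently.
* The model gives no uncertainty estimates; imputed maps should be treated
  as drafts to prioritise experiments, not substitutes for them.
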