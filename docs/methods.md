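# Methods

## The biophysical binding model

A transcription factor bound to a DNA window S of length L is treated as
a two-state system. The binding free energy (k_BT units) is

    E(S) = Σ_{i=1..L} E[i, S_i]  +  Σ_{j=1..L−1} D[j, (S_j, S_{j+1})]

where `E` is the position-specific mononucleotide energy matrix (L×4,
columns A,C,G,T) and `D` the optional adjacent-dinucleotide correction
((L−1)×16, pair (a,b) indexed as 4·code(a)+code(b)). Restricting pair
terms to adjacent positions keeps the correction at 16(L−1) parameters
instead of 16L². Occupancy follows the Fermi–Dirac form

    P(S) = 1 / (1 + exp(E(S) − μ)),

with the chemical potential μ set by TF concentration: P = ½ when
E(S) = μ, and lower energy binds more strongly. A probe's predicted
intensity sums window occupancies over every sliding window of the probe
and, by default, its reverse complement (PBM probes are double-stranded;
the flag `both_strands` exposes the single-strand variant), through one
linear output unit:

    Y = w₁ · Σ_windows P(S) + b₁.

This is the minimal network consistent with a learned output layer: the
energies enter nonlinearly through P, while w₁, b₁ absorb the affine
scale of the normalized intensities. Energies are unconstrained during
fitting (no anchoring of the consensus row to zero); the motif-level
summary `energy_level` = ln(−median of the negative entries) consumes
the signed matrix as fitted and tracks motif information content.

The logistic is evaluated through `scipy.special.expit`, which is
saturation-safe for |E−μ| of hundreds.

## Normalization

All intensities are normalized by the z-score of the natural log
(sample, n−1, standard deviation). The log base is immaterial — the
z-score divides it out — and the choice is stated so tests can assert
exact values. Probes with ambiguous bases are dropped at load: the
energy model has no ambiguity states.

8-mer median intensities summarize an array as the median normalized
signal over all probes containing each 8-mer; a probe contributes at
most once per 8-mer, and by default an 8-mer and its reverse complement
are pooled under the lexicographically smaller of the two (standard PBM
practice; a flag disables collapsing since some published median tables
may keep strands separate).

## The PCA control ellipse

Given two paired measurement vectors (signal/background in MA
coordinates, or the z-scored shared 8-mer medians of an array pair), the
sample covariance S is eigendecomposed, U'SU = diag(l₁, l₂). Each
observation's conformance is its Hotelling statistic, computed through
unit-variance y-scores and equal to the Mahalanobis distance
T² = (x−x̄)ᵀS⁻¹(x−x̄). The control limit at tail probability p (default
0.0027, the three-sigma convention) is

    UCL = [2(n−1)(n+1) / (n(n−2))] · F_{1−p}(2, n−2),

replaced by the χ²_{1−p}(2) quantile for n > 5000 (difference < 1e−3,
numerically stabler). Semi-axis i is √(l_i·UCL); reported axis *lengths*
are full axes (2× semi-axis) — a fixed convention, since only relative
comparisons between arrays matter. Axis slopes follow V = U·diag(√l):
major V₂₁/V₁₁, minor −V₁₁/V₂₁. The MA transform is the standard
microarray convention M = log₂(signal/background),
A = ½·log₂(signal·background).

Outliers are points with T² above the limit *and* at least one
coordinate below its sample mean: high-side excursions reflect strong
specific binding, not poor quality. A singular covariance (perfect
agreement) is reported as a degenerate ellipse with minor length 0
rather than an error; outlier scoring then uses the pseudo-inverse along
the major axis only.

Regression slopes are OLS with intercept, oriented M on A (single array)
and array 2 on array 1 (pairs).

## Sparse Bayesian fitting

The objective is

    F = β·E_D + Σ_g α_g·E_{w,g},   E_D = ½Σ(T_i − Y_i)²,  E_{w,g} = ½Σ_{j∈g} w_j²,

with parameter groups {output (w₁,b₁)}, {μ}, {E}, {D}; the ½ factors
make the evidence updates textbook-standard. Point estimates come from
resilient backpropagation (Rprop with weight backtracking: per-parameter
steps grow ×1.2 on repeated gradient sign, shrink ×0.5 with retraction
on a flip, clamped to [1e−6, 50], initial step 0.1), which is robust to
the objective's scale and needs no learning-rate tuning. Gradients are
analytic, chained through the Fermi–Dirac window sums; the map from the
(E, D) block to window energies is linear and stored once as a sparse
count matrix, so an epoch is two sparse matrix–vector products.

Every 10 epochs the hyperparameters are re-estimated by the evidence
approximation: with the Gauss–Newton Hessian H = β·JᵀJ + diag(α)
(J = ∂Y/∂θ; a single dense solve, ≤ ~150 parameters at PBM scale),

    γ_g = N_g − α_g·Σ_{j∈g} [H⁻¹]_jj,   α_g ← γ_g / (2E_{w,g}),
    β ← (N − Σ_g γ_g) / (2E_D),

with α clipped to [1e−6, 1e6] and β to [1e−6, 1e8]. A group whose α
reaches the prune threshold (1e6) is frozen at zero — the mechanism that
suppresses the dinucleotide block when the data carry no
interdependence. After each update the Rprop sign memory is reset, since
the objective scale changed. Convergence: relative objective change
below 1e−6 between consecutive epochs within an update segment sustained for five
consecutive epochs (single sub-tolerance epochs are transient Rprop
stalls), or the epoch cap (default 2500 — Rprop on a 10,000-probe array
needs a couple of thousand epochs to reach the noise floor).

**Interaction coding.** The raw (E, D) parametrization is not
identifiable: any separable per-base component of a 4×4 pair block is
exactly representable by the energy matrix plus μ, and a quadratic
penalty actively prefers smearing mononucleotide structure across the
larger D block (it costs less squared norm there). Fitting therefore
constrains each pair block to zero row and column means — the standard
ANOVA interaction coding — by projecting both the gradient and the
iterate; the energy matrix then carries all separable structure. The
public model types remain unconstrained, so user-built models with
arbitrary D are scored exactly as written.

Restarts (default 5) start from E, D ~ U(−0.1, 0.1), μ=0, w₁=1, b₁=0,
with seeds `config.seed + r`; runs are ranked by final training error
E_D — each restart adapts its own β, so objectives are on different
scales and not comparable across restarts — and
optima whose aligned energy correlation exceeds 0.95 are collapsed so
the reported first/second motifs are genuinely distinct. Alignment
maximizes Pearson correlation over window phase (±3) and strand after
per-position centering (a per-position constant is gauge, absorbed by
μ). The motif-length scan (default 7–13) selects the candidate with the
highest held-out prediction correlation; ties break toward the shorter
motif, then the better-ranked optimum.

μ is fitted within its own shrinkage group rather than fixed per array —
TF concentration is unknown for synthetic and real arrays alike.

## Quality classification

Arrays (or TFs) described by QC parameters — typically the major/minor
axis lengths, standardized per column — are partitioned by a fuzzy
neural gas: prototypes adapt under rank-based soft-max weights
h(r) = exp(−r/λ) with λ annealed geometrically from k/2 to 0.01 over 100
epochs (a winner-take-all limit), and final memberships follow the fuzzy
c-means rule u_ij ∝ (1/d²_ij)^{1/(m−1)} with fuzzifier m=2 and an
ε=1e−12 distance guard. These hyperparameters are conventional for
neural gas and frozen for reproducibility. Ten runs with consecutive
seeds are aligned by prototype matching and consolidated by majority
vote; the cluster with the larger mean major-axis length (smaller minor
on ties) is labeled *good*.

## Genomic affinity scanning

Peaks (BED, 0-based half-open) are scanned over the central 200 bp
(midpoint ⌊(start+end)/2⌋ ± 100, clipped; whole peak if shorter) with
w₁=1, b₁=0 so the score is a pure occupancy sum over both strands;
windows containing ambiguous bases are skipped. Tag counts are regressed
on affinities by OLS with intercept (statsmodels); the slope t-value and
√R² summarize the dependence, evaluated on top-n plus bottom-n peaks by
tag count (stable ties) or on all peaks. PWMs convert to energies via
E[i,a] = ln((f[i,a]+ε)/(max_b f[i,b]+ε)), ε=1e−6: entries ≤ 0 with the
consensus at 0, the sign convention the energy-level summary expects.
For scanning a converted PWM, μ defaults to 0 and is a CLI flag — how to
set TF concentration outside fitting is genuinely open.

## Synthetic data: what it emulates and what it does not

`simulate_pbm` builds probe intensities on the normalized (log) scale:
latent T_i = Y_i(truth) + ε_i with ε ~ N(0, noise_sd²), stored as
exp(latent − mean) so signals are positive and z-of-log normalization
recovers the latent scale exactly. Background is independent noise plus
a small bleed-through fraction (0.1) of the signal latent. Defaults:
10,000 probes of 35 bp, noise sd 0.2 — the scale of the fitting studies.
Truth models draw mismatch penalties uniformly; the default
(0.5–1.5 k_BT, μ=L/2) is a moderate-affinity motif whose occupancy
varies smoothly across random probes, the regime where regression-based
fitting is well-posed.

`simulate_paired_pbm` produces a training/testing pair on disjoint probe
designs from one truth. Bad quality is an 8-mer-level multiplicative
bias: every canonical 8-mer draws a log-scale bias, and a probe shifts
by the sum over its constituent 8-mers divided by √(#8-mers), giving a
per-probe disturbance of sd `array_bias_sd` correlated across probes
sharing 8-mers — the simplest mechanism that selectively destroys paired
8-mer agreement while preserving each array's own dynamic range. The
canonical paired-agreement conditions (`paired_qc_config`) use
40,000-probe arrays (the scale of real universal designs), a
high-specificity truth (2.5–3.5 k_BT penalties), noise sd 0.02, and bias
sd 1: per-8-mer medians are only well determined when coverage is high
and binding is concentrated in a limited 8-mer set, which is exactly how
real universal arrays are engineered. Under these conditions a good pair
shows a long narrow ellipse (measured ≈ 9.5/2.0, correlation ≈ 0.92) and
a bad pair a wide one (≈ 7.3/6.4, correlation ≈ 0.14).

The dinucleotide-benefit study (`interdependent_truth`) plants one
−2 k_BT pair energy on a *non-consensus* dinucleotide at the motif core
with μ = 2.5. Both choices are load-bearing: planted on the consensus
pair at μ = L/2 the interaction is invisible, because the windows it
affects are already occupancy-saturated; a non-consensus pair creates an
alternative recognition mode (as reported for nuclear-receptor half
sites) that no separable mononucleotide matrix can express, and the
lower μ keeps near-consensus windows in the responsive region.

What the generators do **not** emulate: spatial array artifacts,
saturation nonlinearity, sequence-composition bias in probe design
(real universal arrays are de Bruijn-like with guaranteed 8-mer
coverage; ours sample probes i.i.d., so 8-mer coverage is Poisson), or
position effects along the probe. Passing the synthetic studies
therefore shows the estimators and the optimizer are correct and
well-calibrated under the stated noise model — not that any particular
real array is well measured.

## Verification experiments and problem sizes

`pbmkit.benchmarks` fixes the study conditions shared by
`tests/test_acceptance.py` and `scripts/acceptance.py`. The ground-truth
models are part of those conditions and stay fixed; the caller's seed
drives probe sampling, measurement noise, and optimizer restarts, so
repeated runs measure sampling variability around one canonical study
rather than redrawing the study itself:

- Ellipse coverage: 200,000 bivariate-normal points vs the 99.73% limit.
- T² oracle: 20 random covariances × 1000 points against the explicit
  Mahalanobis form (agreement to 1e−10).
- Gradient oracle: 30 random models, L ∈ {3,5,8}, with and without pair
  blocks, 50 probes each, central differences at h=1e−5 (relative error
  < 1e−5).
- Model reduction: D ≡ 0 vs independent on 1000 probes (≤ 1e−12).
- Recovery: L=8 truth, 10,000 training probes, 5,000 held out, noise sd
  0.2, two restarts; aligned energy correlation and held-out prediction
  correlation.
- Dinucleotide benefit and its control arm (the sparsity study): same
  array scale, one restart per fit; the benefit is the held-out
  correlation gap, the control fits a dependent model on
  independent-truth data and reports mean|D|/mean|E|.
- Clustering: 200 items, 10-sd separation, 10-run consensus.
- Paired contrast: the canonical 40,000-probe conditions above.

Single-length (L=8) fits and small restart counts keep the full suite in
the minutes range on one CPU; the experiments measure calibration, not
throughput.

## Known limitations

- The evidence approximation uses a Gauss–Newton Hessian; for strongly
  non-quadratic regions early in a run the γ estimates are rough (they
  are clipped to [0, N_g]).
- Rprop ignores gradient magnitudes, so objective traces are not
  monotone step-to-step; convergence is judged on segment-relative
  change and the best restart is selected by final objective.
- The first/second-motif deduplication threshold (aligned correlation
  0.95) is heuristic; near-palindromic motifs may collapse two genuinely
  distinct strand modes.
- Fitting assumes equal-length probes (PBM designs are); mixed lengths
  fall back to a slower per-probe path in prediction only.
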