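# Methods

This note documents the models, estimators, parameter choices, and known
limitations of `rhythmnet`. It describes what the code computes; every
number quoted here is produced by the test suite or `scripts/acceptance.py`.

## Synthetic signals

Recordings are realized as stable VAR(p) processes
x[t] = Σ_k A_k x[t−k] + ε[t], ε ~ N(0, Σ). Each site is an AR(2)
oscillator: a complex pole pair at the rhythm frequency f with radius r
gives coefficients (2r·cos(2πf/fs), −r²). Defaults: fs = 200 Hz, pole
radius 0.92 in the pipeline (0.9 in the oracle test models; radii in
0.9–0.98 give band-limited peaks of physiological width — FWHM ≈
fs(1−r)/(πr) ≈ 5 Hz at r = 0.92). Directed coupling from site i to j
enters at a single lag (default 3 samples, i.e. 15 ms conduction +
synaptic delay at 200 Hz) with magnitude c·exp(−λ_FC·d_ij); the FC decay
rate default λ_FC = 0.04/mm sits in the middle of the 0.01–0.08/mm range
that functional connectivity decay spans in large-scale cortical
recordings. Incoming coupling is normalized by in-degree so that total
drive per site — and hence stability — is roughly independent of network
size; `VarModel.require_stable` enforces a companion-matrix spectral
radius < 1 and every simulation call re-checks it. Epochs are independent
realizations (separate 500-sample burn-in each), matching the treatment of
non-overlapping epochs as exchangeable samples by all estimators. An
optional instantaneous mixing matrix provides a volume-conduction
surrogate.

Because the generator is a VAR, its spectra are available in closed form:
H(f) = (I − Σ_k A_k e^(−2πifk/fs))⁻¹, S = HΣH*, and Geweke's pairwise GC
from the 2×2 blocks of H and Σ (exact for 2-site and block-diagonal
models, which is how the oracle is used). This gives a ground truth that
is independent of the Wilson-factorization estimation path it validates.

What the generator does *not* emulate: 1/f broadband background,
cross-frequency coupling, nonstationarity within or across epochs,
measurement noise with spatial correlation, and realistic cortical
geometry. Passing tests therefore demonstrate correctness of the
estimators and inference machinery under the stated model, not robustness
to every property of real recordings.

## Synthetic anatomy

For each injected (target) area, expected projection weights over source
areas follow the exponential distance rule w ∝ exp(−λd)·exp(σz),
z ~ N(0,1). Defaults λ = 0.202/mm (the white-matter decay rate the EDR
literature reports for macaque), σ = 1, and 10⁵ labeled neurons per
injection; counts are one multinomial draw per target, so FLNe sums to
exactly 1 over extrinsic sources and small distant projections naturally
fall below the 10-neuron reliability filter. The supragranular count is
binomial with probability logistic(s·(level_target − level_source)),
slope s = 1.5 per hierarchy-level unit, so projections up the hierarchy
are feedforward-like (SLN > 0.5) with a graded strength. A
`sample_counts=False` mode emits expected (real-valued) counts for exact
noise-free recovery checks. Recovery: the mean fitted λ over 100 sampled
tables at λ = 0.202 is within 10% of the generating value; the small
downward bias comes from the count filter selectively removing weak
distant projections.

## Spectral estimation

Epochs are tapered with K = 3 Slepian (DPSS) tapers at time–bandwidth
NW = (K+1)/2, i.e. ±2 Hz half-bandwidth on 1-s epochs, and Fourier
transformed; 0.5-s epochs can be zero-padded to 1 s for an interpolated
1-Hz grid. Coefficients carry a √(2/fs) scaling so averaged products are
one-sided spectral densities (Parseval verified to 5% on white noise).
Line components are removed by zeroing the DFT bin of each listed
frequency per epoch and site (off-bin frequencies snap to the nearest bin
with a warning). Coherence is the *magnitude* of the coherency, not its
square — the convention of the standard toolboxes for this analysis; a
config switch is unnecessary since squaring is monotone and downstream
statistics are rank- or log-based. Power correlation is the Spearman
correlation across epochs of taper-averaged single-epoch power, per
frequency bin; the orthogonalized variant projects each site's coefficient
onto the component orthogonal to the partner site per epoch and taper
before computing power, averaging both directions, which removes zero-lag
(instantaneously mixed) contributions. Orthogonalized power that is pure
floating-point residue (signals identical up to real scaling) is treated
as fully removed and reported as 0.

## Wilson factorization and GC

The nonparametric GC path factorizes each pair's 2×2 CSD on the uniform
grid [0, Nyquist] into S = HΣH* by Wilson's iteration: the CSD is extended
two-sidedly, the factor is initialized from the upper Cholesky factor of
the lag-0 covariance, and each step multiplies by the causal part of
ψ⁻¹Sψ⁻* + I (zero lag halved, upper triangle kept). Defaults: relative
tolerance 1e-9, 100 iterations; non-convergence returns
`converged=False`, and pairs whose factorization fails are masked and
logged rather than aborting the run. On analytic VAR cross-spectra with
513 one-sided bins the recovered GC matches the parametric oracle to
~1e-12 (criterion 1e-6) and the innovation covariance to 1e-5. Negative
numerical GC values are clipped at zero. GC is computed bivariately per
pair, not conditionally on the full multivariate model: a full
218-channel factorization is numerically ill-conditioned, and pairwise
matrices are what the downstream network statistics consume.

A note on convergence targets: the multitaper estimator's expectation is
the true CSD convolved with the average DPSS spectral window, so at a
sharp spectral peak the estimated GC converges (in epochs) to the GC of
the *smoothed* CSD, which at ±2 Hz smoothing sits ~10% below the
unsmoothed value for a pole radius of 0.9. Convergence checks therefore
compare against the window-convolved oracle (1000-epoch deviation ≈ 2%).

## Bands and significance

Peaks are detected blindly on lightly smoothed spectra (boxcar ±2 bins;
prominence threshold 10% of the spectrum's range, making detection
amplitude-scale invariant), with FWHM from linear interpolation of the
half-prominence crossings. A rhythm band is PF ± FWHM. Spectra lacking a
peak contribute nothing to that rhythm — the pipeline pools per-site
peaks and falls back to the generator's nominal band only when no site
shows the rhythm. Cross-subject averaging aligns spectra to each
subject's PF by integer bin shifts and averages over the overlapping
support.

FC significance uses an epoch-shuffle null: each site's epoch order is
permuted independently (destroying cross-site dependence, preserving
marginal spectra), the maximum band FC over all site pairs per
randomization forms the null (default 100 randomizations), and a pair is
significant above the 97.5th percentile — a max-statistic family-wise
test. Calibration on independent channels: family-wise false-positive
rate 2.5% over 200 replicate null datasets at the nominal 2.5% level.

## Network statistics

Distinctiveness D = 1 − R² is computed on log₁₀ FC values by default (FC
is analyzed and displayed on log scales throughout; a raw-scale option is
retained), over all valid site pairs, with an optional partial correlation
controlling for inter-site distance in both matrices. Node strength is
the mean FC of a site with all partners beyond a 2-mm exclusion radius
(residual volume-conduction guard; interareal averages use a stricter
4-mm rule, both exposed as parameters). The strength null permutes the
edge-weight multiset — a random graph with exactly the empirical weight
distribution — and per-site permutation p-values are corrected by
Benjamini–Hochberg at q = 0.2 (the `alpha` parameter records the nominal
per-test level; BH on permutation p-values is the operative correction,
as the interplay of the two numbers in the original description is
ambiguous). Calibration: mean false-discovery proportion 0.015 on
i.i.d.-weight graphs at q = 0.2.

Consensus modularity collects Louvain partitions over 25 logarithmically
spaced resolutions in [0.1, 10] × 10 restarts × all band matrices
(directed GC symmetrized as (W+Wᵀ)/2 for clustering only), forms the
co-assignment agreement matrix, thresholds at τ = 0.25, and re-clusters
at resolution 1 (100 restarts) until all restarts agree. q is Newman
modularity of the consensus partition at resolution 1, reported per band;
tests verify q against a direct evaluation of the Newman formula. A
planted 3-module, 30-node structure is recovered exactly (adjusted
Rand 1.0) and a constant matrix yields |q| < 0.02.

## Structure–function statistics

FLNe and SLN come from labeled-neuron counts with intrinsic projections
excluded from the denominator; the undirected variant averages the two
directions (counts summed for the reliability filter, which drops entries
below 10 neurons, boundary exclusive). EDR fits regress ln(weight) on
distance (natural log, as decay rates are conventionally reported);
FC~FLNe regressions use log₁₀ on both sides, report slope, R², p against
a Bonferroni family of m = 12 (3 FC types × 4 bands, threshold
0.05/12 ≈ 4.17e-3), and the fold change 10^(slope·range) with 99.9%
percentile bootstrap CIs from FC recomputed on epochs resampled with
replacement (the fast path resamples cached epoch-level spectra). Zero or
masked FC values are excluded from log regressions rather than floored,
with the usable count reported.

The multiple regression of log₁₀(FLNe) on band-wise log₁₀(FC) plus
untransformed distance reports raw and standardized coefficients (both,
since either convention is defensible for the coefficient panel), t
statistics, VIFs from auxiliary regressions, and ΔR² from refitting
without each predictor. R² decompositions operate on the all-subsets R²
lattice (refused above 12 predictors): commonality coefficients by Möbius
inversion C(S) = Σ_{T⊆S} (−1)^{|S|−|T|}[R²(full) − R²(full∖T)] — the
standard construction, adopted because printed closed-form commonality
formulas in the applied literature are frequently garbled — with negative
commons identifying suppressors; general dominance as the mean
conditional contribution over subset sizes; relative importance weights
by the SVD orthogonal-approximation method. Each decomposition sums to
the full-model R² to 1e-10, verified against a brute-force subset-R²
oracle.

The SLN split selects strongly feedforward (SLN > 0.7) and strongly
feedback (SLN < 0.3) projections, computes each group's fold-change
spectrum, and forms the asymmetry index (FF − FB)/(FF + FB), bounded in
[−1, 1] for positive spectra; a threshold sweep over alternative cutoffs
is available. Groups with fewer than 3 projections are skipped and
logged. GC inflow normalization divides each directed entry by its
target's total inflow, paralleling FLNe's per-target normalization.

## Degenerate inputs and tie-breaks

Zero auto-spectra flag coherence bins undefined (NaN); constant power
series yield power correlation 0 with a degeneracy flag; zero-variance
distinctiveness inputs return NaN flagged; all-equal edge weights make no
site significant; zero-inflow columns are NaN after normalization;
bootstrap resamples on which a statistic is undefined are redrawn and
counted. All generators and all permutation/bootstrap machinery take
explicit seeds and are bit-reproducible.

## Problem sizes

The shipped tests and the acceptance script run on deliberately small
problems chosen to estimate each quantity stably: 2-node oracle models
with 513-bin grids, 500–1000-epoch simulations for GC convergence, 200
replicate null datasets (5 sites × 60 epochs) for mask calibration, 100
replicate 12-node graphs for FDR calibration, 30-node planted partitions,
and 100 replicate 10-area anatomies for λ recovery. The full pipeline
demonstration uses 4–6 areas × 2–3 sites and 60–200 epochs.

## Known limitations

- Bivariate (not conditional) GC: common-input structure among triplets is
  not disentangled.
- The broadband-artifact exclusion of the original acquisition protocol is
  inherently visual; no algorithmic equivalent is claimed. Site-pair
  masks accept externally supplied exclusions.
- Time-resolved (sliding-window) FC and cross-frequency coupling are out
  of scope.
- The synthetic theta oscillator at 4 Hz produces a peak that can merge
  with the low-frequency shoulder, in which case the theta band falls
  back to its nominal definition in the pipeline — an honest reflection
  of how low-frequency peaks behave in blind detection.
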