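# Methods

This note documents the model, the default parameters, and the numerical
choices made in `dgdecode`. Units throughout: time in ms, voltage in mV,
current in pA, resistance in MΩ, rates in Hz unless stated otherwise.

## 1. Stimulus generators (`dgdecode.stimulus`)

**Ornstein–Uhlenbeck (OU).** The normalized stimulus η(t) is a stationary
zero-mean, unit-variance OU process with time constant τ (default 3 ms),
sampled by the exact AR(1) recursion

    η[t+1] = β η[t] + √(1 − β²) ε[t],   β = exp(−dt/τ),  ε ~ N(0,1),

with η[0] drawn from the stationary distribution. The recursion is
evaluated with `scipy.signal.lfilter`, which is bit-identical to the
scalar loop. The physical current is i(t) = μ + σ η(t) (`ScalingSpec`);
per-cell μ and σ are set by rate calibration (§6).

**Theta-modulated stimulus.** Samples are drawn from the Gaussian process
with autocovariance

    C(Δ) = σ² cos(2π f Δ) exp(−Δ/τ),   f = 8 Hz, τ = 100 ms by default,

by dense Cholesky factorization of the Toeplitz covariance (one factor
shared across trials; a small escalating diagonal jitter guards against
loss of positive definiteness at large n; trace length is capped at
2·10⁵ samples because the factorization is O(n³)).

**Correlated pairs.** Pairs (η₁, η₂) for the discrimination task are a
bivariate OU process driven by innovations with covariance
K = [[1, ρ], [ρ, 1]]; each marginal is a stationary unit-variance OU
process and the instantaneous cross-correlation is ρ. The named
separation levels are ρ = 0.9997 ("low"), 0.999 ("medium"), 0.99
("high") — higher ρ means *less* separable. Variance-preserving
corruption with noise level ν replaces η by √(1−ν²) η + ν ξ with an
independent OU draw ξ.

**Estimators.** The OU decay constant is measured by a least-squares
single-exponential fit (`scipy.optimize.curve_fit`) to the empirical
autocorrelation up to 30 ms lag; a log-linear fit was rejected because
the noise-dominated tail biases it. The theta spectral peak is the
maximum of the trial-averaged periodogram after symmetric Gaussian
smoothing (0.5 Hz sd), refined by the vertex of a quadratic fit to
log-power over a ±2 Hz window (log-parabolic interpolation). The raw
argmax alone is unreliable because the ~3 Hz-wide Lorentzian-type peak is
sampled with substantial periodogram noise.

## 2. Spike response model (`dgdecode.srm`)

Subthreshold voltage and conditional intensity:

    v(t)  = v_b + Σ_u k[u] i(t−u) + Σ_spikes h_v(t − t_s)
    λ(t)  = (1/ms) · exp( (v(t) − v_th − Σ_spikes h_th(t − t_s)) / Δv )

Spiking is Bernoulli per bin with probability 1 − exp(−λ(t) dt). All
filters live on rectangular bases:

| filter | bins × width | support    | units of coefficients |
|--------|--------------|------------|-----------------------|
| k      | 44 × 8 ms    | 0–352 ms   | mV per (pA · sample): per-sample gains; rescaled by dt ratio when evaluated on another grid |
| h_v    | 17 × 25 ms   | 25–450 ms  | mV (first 25 ms handled by the fitting mask, not the filter) |
| h_th   | 18 × 25 ms   | 0–450 ms   | mV |

Basis-bin edges are converted to integer sample indices once
(`round(edge/dt)`), and the simulator, the design matrices, and the
kernel evaluation all use these same integer edges — mixing float and
integer binning produced inconsistencies at the 1e−4 level during
development. Filters act on strictly past spikes (lag ≥ 1 bin). The
simulation loop is JIT-compiled with `numba`; the exponent of λ is
clipped at +20 purely as an overflow guard, and the number of clipped
bins is reported.

Spike times are binned with `floor(t/dt + 1e−9)`; the epsilon absorbs
float dust when times were themselves produced as bin multiples.

## 3. Fitting (`dgdecode.fitting`)

**Stage 1 — subthreshold.** Linear least squares of the recorded voltage
on [1, stimulus-basis columns, spike-history columns], restricted to
samples more than 25 ms after the last spike (the post-spike mask
excludes the action-potential shape that the model does not describe).
Solved by SVD (`lstsq`), not normal equations. Identically-zero columns
(e.g. history columns of a spike-free recording) get zero coefficients;
any other rank deficiency raises with the offending columns named.

**Stage 2 — threshold.** With v̂ fixed from stage 1, the threshold
parameters are fitted by maximizing the point-process log-likelihood

    L(θ) = Σ_t n_t z_t − dt Σ_t exp(z_t),   z_t = y(t)ᵀθ,

over θ = (1/Δv)(1, v_th, c₁ … c_M) with rows y(t) = (v̂(t), −1,
−history sums). The history columns carry a minus sign so that the same
sign convention as the simulator's h_th applies; the likelihood is
concave in θ. A first-difference smoothness penalty −α Σ (θ_{m+1} −
θ_m)² acts on the filter tail of θ (quadratic, so concavity is
preserved; penalizing θ-space instead of c-space only rescales α by
Δv²). α is chosen from a small grid (default 0, 0.1, 1, 10, 100, 1000)
by unpenalized log-likelihood on validation trials. The maximizer is a
safeguarded Newton method with step halving (tolerance 1e−6 on the
gradient norm, 100 iterations); failures raise with the step trajectory
attached. Reported model quality is the normalized log-likelihood in
bits per spike relative to a homogeneous Poisson process at the
empirical rate (unit-invariant).

At low rates (≈2 Hz, 99 s) the h_th filter is close to unidentifiable —
few spikes fall inside other spikes' 450 ms history window — and the
unpenalized MLE can drift to large compensating coefficients while Δv
and v_th remain accurate. This is genuine maximum-likelihood behavior,
not a solver defect; the smoothness penalty and validation-based α
selection are the built-in mitigations, and recovery tests use a 5 Hz
calibration where the filter is identified.

**Filter summaries.** τ and R of the membrane filter are obtained by an
exponential fit A exp(−t/τ) to the filter in MΩ/ms (coefficients ×
1000/dt), skipping the first bins that contain the fast pipette
component; R = A·τ.

## 4. MAP decoding (`dgdecode.decoding`)

The decoder reconstructs the normalized stimulus η on a decode grid
(default 1 ms, deliberately coarser than the 0.1 ms simulation grid: the
OU prior decimates exactly to an AR(1) on any grid, and the likelihood
loses little at 1 ms while the banded solves get 10× smaller).

**Prior.** The stationary AR(1) precision is tridiagonal with corners
1/(1−β²), interior (1+β²)/(1−β²) and off-diagonal −β/(1−β²); its inverse
is verified against the exact covariance β^{|i−j|} in the tests.

**Posterior mode.** The log posterior (prior + point-process likelihoods
of all trains in the bank, each cell contributing through its own fitted
filter scaled by σ/Δv) has a banded Hessian with bandwidth equal to the
k-filter support on the decode grid (352 bins at 1 ms). Newton's method
with banded Cholesky solves (`scipy.linalg.solveh_banded`) converges in
a handful of iterations (tolerance 1e−6 on max |gradient|). The Hessian
blocks KᵀWK are assembled per off-diagonal offset with batched FFT
convolutions rather than forming K.

**Uncertainty and information.** The Laplace approximation uses the
banded Cholesky factor for log-determinants, and the diagonal of the
posterior covariance is computed by a block-tridiagonal selected
inversion (RGF recursion, block size = bandwidth) — no sparse-Cholesky
library with selected inversion is available, so this is hand-written
and oracle-tested against dense inverses. Mutual information is the
Gaussian entropy difference I = ½ (log|C⁻¹| − log|Σ⁻¹|)/ln 2 bits, with
C the posterior and Σ the prior covariance.

**Trial equalization.** When populations mix cells of different rates,
each cell contributes round(n_spikes_target / (rate · T)) trials (floor
1), so cells enter with approximately equal spike counts rather than
equal trial counts.

## 5. Populations and discrimination

**Greedy construction** starts from a fixed (mature) cell and repeatedly
adds the pool cell — with replacement — whose addition maximizes the mean
decoding r² over a set of fresh stimuli. Common random numbers: at every
step all candidates are scored on the same stimulus draws and the same
per-candidate spike seeds (derived from (seed, step, repeat, CRC32 of
the candidate id) via `SeedSequence`; string hashes are never taken from
`hash()`, which is process-randomized). Ties are broken toward the
lowest cell id and logged. The constrained variant restricts the first
m steps to mature cells. The random baseline draws uniform selections
under the same evaluation. `selection_census` tallies per-cell counts
and per-step age fractions and reports the uniform expectation
n_pops·(K−1)/pool_size. Group comparisons use a bootstrap of the ratio
of group-mean MSEs (95% percentile interval).

**Discrimination.** For each pair, one member (alternating with pair
index, to cancel asymmetry) is encoded by the population — optionally
after per-cell corruption with level ν — and both members are scored by
the MSE between their decode-grid values and the MAP reconstruction
computed under the *uncorrupted* model. The lower MSE wins; exact ties
count as incorrect (conservative). Accuracy is reported with its
binomial standard error.

## 6. Synthetic cohorts (`dgdecode.synthetic`)

Age-group parameter centers (package design choices that reproduce the
qualitative maturation trends — slower filters, higher resistance,
weaker adaptation and lower threshold in young cells — not measured
values):

| parameter | 4w  | 5w   | mature | units |
|-----------|-----|------|--------|-------|
| τ_k       | 55  | 40   | 25     | ms    |
| R         | 450 | 350  | 250    | MΩ    |
| h_v(1)    | −0.5| −1.5 | −3     | mV    |
| h_th(1)   | 2   | 4    | 6      | mV    |
| v_th      | −53 | −51.5| −50    | mV    |
| Δv        | 1.4 | 1.2  | 1.0    | mV    |

Positive-valued parameters disperse log-normally (relative sd 0.15 by
default), voltages normally. Both post-spike filters decay with a 100 ms
time constant on their bases; the membrane filter adds a fast pipette
transient (20 MΩ/ms amplitude, 1 ms decay). Each cell's stimulus scaling
is calibrated by bisection on μ (σ = μ/2 fixed) to a target rate
(default 2 Hz, tolerance 10%) on a 20 s calibration stimulus;
calibration outside 0.5–10 Hz raises. Default pool sizes are 20/17/18
cells for 4w/5w/mature.

The default protocol is one 99 s training trial plus nine 10 s
validation trials at dt = 0.1 ms, with one validation stimulus template
shared across cells (scaled per cell) and 0.3 mV Gaussian voltage
observation noise.

`load_real` maps a local copy of the study's deposited recordings into
the same `Recording` containers; it is optional, defensive about layout,
and nothing else depends on it.

## 7. Coincidence metrics (`dgdecode.metrics`)

Two spikes coincide when |t_a − t_b| ≤ Δ/2 with Δ = 8 ms (closed
window). C(S,S′) is the mean pairwise coincidence count normalized by
the mean spike count; within-set reliability R(S) excludes the diagonal;
the Md similarity normalizes the cross-set coincidences by the geometric
mean of the two reliabilities, so Md(A,A) = 1 only for perfectly
reliable sets. The chance reliability of a Poisson train at rate r is
r·Δ. PSTHs use a per-spike boxcar whose mass is renormalized at the
edges so total spike count is conserved exactly.

## 8. Problem sizes, tolerances, reproducibility

* Default grids: simulation dt = 0.1 ms, decode dt = 1 ms, coincidence
  window 8 ms, OU τ = 3 ms.
* Newton tolerances 1e−6 (both fitting and decoding); banded algorithms
  oracle-tested to ≤1e−6 against dense linear algebra at n ≤ 500 and to
  machine precision at small n.
* All randomness flows through `numpy.random.Generator` /
  `SeedSequence`; string ids enter seeds via CRC32. Fixed seeds
  reproduce files bit-for-bit.
* Desk-scale sizes used in the validation suite (minutes, one CPU):
  10⁶-sample OU traces; 100 × 10 s theta traces (the 10⁴² Cholesky is
  the single most expensive step, ~25 s); 200 × 10 s stimulus pairs;
  99 s training fits (~25 s each); decode problems up to 10⁴ bins.

## 9. Limitations

* The synthetic cohorts match the *ordering* of maturation trends, not
  absolute measured parameters; conclusions about real cells require
  fitting the deposited recordings (`load_real`).
* The theta sampler's dense Cholesky limits single traces to 2·10⁵
  samples.
* h_th is weakly identified at low firing rates (§3).
* The discrimination task implements only the temporal (correlated-pair)
  formulation of pattern separation, not spatial/contextual variants.
* `srm.simulate` assumes the stimulus is given on the filter grid; no
  resampling of recorded currents beyond integer decimation is provided.
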