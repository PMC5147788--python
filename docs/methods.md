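# Methods

## Model

The generative model for an N×T data matrix **Y** has three parts.

**Observation model.** Given a partition π of nodes into K clusters and
latent cluster timecourses **X** (K×T),
y_{n,t} ~ N(x_{π_n,t}, (τ φ_t)^{-1}). The overall precision τ carries an
uninformative Gamma(a₀ = 1, b₀ = 0.01) prior (appropriate when node
timecourses are standardized to unit variance, which `fit` does by
default, per node). The time-specific factors φ_t carry
2φ_t ~ Gamma(ν/2, ν/2) with ν = 4 fixed, i.e. φ_t ~ Gamma(2, rate 4) in
shape–rate form; marginalising φ_t makes the noise Student-t with 4
degrees of freedom, down-weighting time points hit by scanner artefacts
or motion.

**Timecourse prior.** Each x_k is a zero-mean GP evaluated at the scan
times (seconds). The Matérn order 3/2 kernel is used in its closed form
σ_m²(1 + η|r|)e^{−η|r|}, η = √3/l, and through the generic Bessel-function
form for other orders; both paths are cross-checked in the tests. The
defaults σ_m² = 0.1 and l = 3.6 s encode, respectively, a prior signal
share of about 10% of unit variance and the autocorrelation scale of the
canonical haemodynamic response. Length-scales are in seconds and the
kernel is evaluated at absolute scan times, so the same prior means the
same thing at any TR. The `independent` kind (σ_m² δ(r), default
magnitude 1) is the temporally independent special case, useful as a
baseline and on pre-filtered data.

**Partition prior.** The dd-CRP draws one link per node with probability
proportional to A_{n,m} = f(d_{n,m}); the implemented decay is the hard
cutoff f(d) = 1[d ≤ cutoff] (grid Euclidean distances, or mesh hop
distance where sharing a triangle edge means distance 1, giving at most
six non-self targets on a regular triangulation). f(0) = `self_weight`
(default 1) is exposed as a concentration-like dial: large values favour
many small clusters; at 0 every cluster has at least two members, because
the smallest cycle in a link graph without self-links is a 2-cycle. The
optional size prior multiplies in exp(−(d−s_k)²/2w²) for each cluster
smaller than d (defaults d = 200, w = 5 when enabled; disabled by
default), softly bounding parcel sizes from below.

## Inference

Collapsed Gibbs over links: removing λ_i may split i's cluster; the full
conditional over admissible targets weighs the link prior by the marginal
likelihood ratio L(C_i ∪ C_m)/(L(C_i)L(C_m)) for merges (1 within the
current cluster) plus the size-prior change. Because X is integrated out,
this performs split-merge moves with ordinary single-site updates.

**Batch cache.** With Σ = diag(1/(τφ_t)) fixed during a link sweep, one
eigendecomposition Σ^{-1/2}KΣ^{-1/2} = V diag(d) Vᵀ and the rotated
whitened data Z = (Σ^{-1/2}Y)V reduce any cluster marginal to an O(T)
expression in the cached per-cluster sums (n, s = Σ_m Z_m, Σ_m‖Z_m‖²).
Per-size tables of Σ_i log(1+nd_i) and d_i/(1+nd_i) are memoised.
Eigenvalues are clipped at 1e-12 before entering the log domain. A module
counter of decompositions lets the tests assert that link sweeps perform
no cubic-cost work; the cache is rebuilt exactly once per noise update.

**Hyperparameter sweep.** X is sampled from its Gaussian conditional per
cluster (diagonal in the rotated basis), then τ and φ from their
conjugate gamma conditionals:
τ | · ~ Gamma(a₀ + NT/2, b₀ + ½Σφ_t r²_{n,t}) and
φ_t | · ~ Gamma(ν/2 + N/2, ν + τ/2 Σ_n r²_{n,t}), r = y − x_assigned.
τ is updated before φ within a sweep. GP hyperparameters ψ = {σ_m², l}
stay fixed; they have clear interpretations and the sampler is not
sensitive to them on simulated data.

**Chain protocol.** Each iteration = one hyperparameter sweep then one
shuffled-order link sweep. Defaults: 50 burn-in iterations, 100 retained
partition samples, co-assignment matrix as the mean over all retained
samples, consensus partition by joining spatially adjacent pairs
co-assigned in > 0.9 of samples, then 50 further sweeps at the fixed
consensus partition for timecourse posteriors (posterior means averaged
over draws, variances combined by the law of total variance).

**Population Monte Carlo.** J chains (default 50) run rounds of one
hyperparameter sweep plus 11 link sweeps, the first link sweep at
temperature 1000 (conditional log-probabilities multiplied by 1/1000;
hyperparameter sweeps are never tempered). Each chain's end-of-round
state is a sample; chains are then reinitialised by multinomial
resampling with weights exp(log posterior − accumulated log transition
densities), where the accumulator includes the Gibbs conditional
densities of every link choice and of the X/τ/φ draws since the last
reinitialisation, and is reset on reinitialisation. Weight normalisation
is done in the log domain by max subtraction. The highest-posterior
sample approximates the MAP parcellation. With one chain, one link sweep
per round and no tempering, the population sampler reduces bitwise to the
plain chain under the same seed (chains draw from seed-sequence-spawned
independent streams; the resampling step has its own stream).

## Synthetic data

The simulator emulates resting-state-like measurements with known
structure: (1) a random spatially contiguous partition by region growing
from K uniformly chosen seeds (default 15×15 grid, K = 10); (2) per
cluster a neuronal signal at 200 Hz from an exact-discretisation
Ornstein-Uhlenbeck process (Matérn order 1/2, σ_m² = 1, l = 2 s, hence
mean-reversion rate η = 0.5/s), convolved with the canonical double-gamma
HRF (peak delay 6 s, undershoot delay 16 s, dispersions 1 s,
peak:undershoot 6, 32 s support, unit-sum; mode ≈ 5 s); (3) pure
decimation to 0.5 Hz (every 400th sample — no anti-alias filter, matching
an instantaneous-sampling view of the scanner) plus iid Gaussian noise.
The cluster signal is scaled so it carries `signal_share` of unit total
variance (default 0.1, so σ_noise = √0.9 ≈ 0.949). Not emulated:
physiological noise spectra, spatially correlated noise, inter-subject
variability, drift — so passing tests show correct inference under the
model's assumptions plus HRF-induced smoothness, not robustness to every
real-data artefact.

Default problem sizes in the tests (15×15 grid, T = 450, five
replicates) were chosen as the smallest configuration that exercises the
full protocol while keeping the suite quick on a single CPU.

## Numerical and design choices

- Cluster ids are the smallest member index; partition bookkeeping is
  incremental (component traversal on unlink, set union on link) with a
  full-recompute audit every 100 mutations that raises on drift.
- The joint log posterior is updated incrementally from the ratio of
  unnormalised conditional weights; a non-finite delta triggers a full
  recompute. The incremental value is asserted against full recomputation
  in tests at 1e-6.
- Categorical sampling uses inverse-CDF on the chain's own stream; ties
  need no special handling.
- AMI uses the hypergeometric-model expected MI and the max(H₁,H₂)
  normaliser; MI is computed as H₁+H₂−H₁₂ so identical partitions score
  exactly 1.0 in floating point. Cross-checked against scikit-learn's
  implementation (max averaging) at 1e-10.
- Timecourse RMSE is computed per node against the node's true noiseless
  signal, avoiding cluster matching and remaining well defined for any
  estimated K. Explained variance uses per-node mean-centred data.
- The low-pass baseline is a 4th-order Butterworth applied forward and
  backward (zero phase); only the 0.1 Hz cutoff is prescribed, the order
  and zero-phase application are this package's choice.
- Degenerate inputs: a 1×1 grid yields a single self-linked node; zero
  residuals still give valid (prior-dominated) noise draws; a zero
  self-weight makes self-links inadmissible and is rejected as an initial
  state only if actually used.

## Known limitations

State-space/Kalman evaluation of the GP likelihood (linear in T) is not
implemented; the batch method assumes T below roughly 10⁴. Per-node
heteroscedastic noise, non-Matérn kernels, geodesic (rather than hop)
mesh distances, adaptive temperature ladders and GP-hyperparameter
sampling are out of scope; a Metropolis update for ψ could be added
behind the existing cache-rebuild hook.
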