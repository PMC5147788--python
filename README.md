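# caesar — spatially constrained Bayesian clustering of fMRI timecourses

`caesar` parcellates node-by-time functional measurements (fMRI voxels or
surface-mesh vertices) into spatially contiguous clusters while jointly
estimating each cluster's underlying timecourse. It is aimed at
neuroimaging researchers who want a parcellation whose number and shapes of
clusters are learned from the data, together with denoised cluster signals
and calibrated uncertainty, rather than a fixed-K clustering of
correlation profiles.

## Model

Observations are noisy copies of latent cluster timecourses,

    y_{n,t} | x_{π_n,t} ~ N(x_{π_n,t}, (τ φ_t)^{-1}),

with τ ~ Gamma(a₀, b₀) an overall noise precision and
2φ_t ~ Gamma(ν/2, ν/2) time-specific deviations that make the noise
marginally Student-t (ν = 4). Cluster timecourses get independent
Gaussian-process priors x_k ~ N(0, K) with a Matérn covariance

    κ(r) = σ_m² 2^{1-ν_gp}/Γ(ν_gp) (ηr)^{ν_gp} K_{ν_gp}(ηr),   η = √(2ν_gp)/l,

(defaults ν_gp = 3/2, σ_m² = 0.1, l = 3.6 s); the δ-covariance
κ(r) = σ_m² δ(r) recovers the temporally independent (IT) special case.

The partition prior is a distance-dependent Chinese restaurant process:
each node draws one link λ_n to a spatial neighbour (or itself) with
probability ∝ A_{n,m} = f(d_{n,m}), and clusters are the connected
components of the link graph. With a hard cutoff f(d) = 1[d ≤ 1] clusters
are spatially contiguous by construction; the self-link weight f(0) acts
like a concentration parameter. An optional improper prior
∏_k exp(−(d−s_k)²/2w²) for s_k < d softly bounds cluster sizes from below.

Inference is collapsed Gibbs sampling over links — X is integrated out
analytically, so resampling one link performs implicit split-merge moves —
with conjugate sweeps for (X, τ, φ). A noise-whitened eigendecomposition
of the GP prior is cached once per hyperparameter state, making each
cluster-marginal evaluation O(T); all O(T³) work happens outside link
sweeps. For hard problems a population Monte Carlo mode runs many chains
in rounds and resamples chain states by importance weight
(posterior / accumulated transition densities), with a tempered first
sweep per round.

## Worked example

Simulate a 15×15 grid with 10 contiguous clusters, 15 min at 0.5 Hz and a
0.1/0.9 signal-to-noise split, fit the GP model, and score the result:

```sh
caesar simulate --rows 15 --cols 15 --k 10 --duration 900 --snr 0.1 \
    --seed 7 --out demo/sim
printf '[spatial]\nrows = 15\ncols = 15\n' > demo/run.toml
caesar fit --data demo/sim/Y.tsv --config demo/run.toml --seed 7 \
    --out demo/fit
caesar evaluate --truth demo/sim --fit demo/fit --out demo/report.json
```

which prints

```
wrote 225x450 dataset to demo/sim
10 clusters -> demo/fit
{
  "ami": 1.0,
  "n_clusters": 10,
  "rmse": 0.12687439903293085,
  "explained_variance_pct": 11.932545894760228
}
```

AMI 1.0 means the consensus partition (pairs co-assigned in > 90% of 100
post-burn-in samples) reproduces the ground-truth parcellation exactly.
The RMSE of 0.127 is the per-node error of the posterior-mean cluster
timecourses against the noiseless signal (whose standard deviation is
√0.1 ≈ 0.316, so roughly 60% of the signal amplitude is recovered), and
the explained variance of ≈ 11.9% is consistent with a true signal share
of 10% of unit total variance plus the fitted timecourses absorbing a
little noise.

`caesar fit --popmc --chains 50 --rounds R` switches to the population
sampler; mesh inputs are given as a triangle-list TSV and arbitrary graphs
as an edge list (see `[spatial]` config keys).

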