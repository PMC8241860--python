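# Methods

## The problem

Thermal proteome profiling (TPP) heats aliquots of cells or lysate to a
ladder of temperatures (here ten points spanning 37–67 °C), quantifies the
protein remaining in the soluble fraction at each temperature by multiplexed
mass spectrometry, and expresses it as *relative solubility* — soluble
abundance normalized to the lowest temperature, so values start near 1 and
canonically decay in a sigmoidal "melting curve".  Comparing melting curves
between a vehicle and a drug-treated condition identifies proteins whose
thermal stability the treatment changes: direct drug targets are typically
stabilised, downstream and complex-level effects can destabilise.

`tppbayes` scores each protein by comparing two models: **M0**, a single
mean curve shared by both conditions, and **M1**, condition-specific
curves.  Three detection routes are implemented on identical protein
subsets: a frequentist F-test (NPARC-style), a Bayesian sigmoid model, and
a Bayesian semi-parametric model that relaxes the sigmoid shape assumption
with a Gaussian-process deviation term.

## Models

### Sigmoid mean function

    S_{a,b,p}(T) = (1 − p) / (1 + exp(b − a/T)) + p

with shape parameters `a, b > 0` (temperatures in °C; the midpoint where
S = (1+p)/2 sits at T = a/b) and lower plateau `p ∈ (0, 1)`.  The Bayesian
sigmoid observation model is y ~ N(S(T), σ²), i.i.d. over temperatures and
replicates, with one parameter block under M0 (both conditions pooled) and
one block per condition under M1.

Priors: `a ~ Gamma(7, rate 0.01)` (mean 700), `b ~ Gamma(7, rate 0.4)`
(mean 17.5), `p ~ Beta(1, 20)`, `σ ~ FoldedNormal(0, scale 0.05)`.  The
gamma rates keep a and b on the scale of typical least-squares fits; the
folded-normal prior shrinks residuals towards zero so that treatment
effects must be explained by the mean function rather than inflated noise.
The second gamma parameter is interpreted as a **rate** and the folded
distributions' spread parameters as **scales** (standard-deviation-like);
both conventions are configurable through `PriorSpec` should a user prefer
other readings.

### Semi-parametric extension

Real melting curves deviate from the sigmoid (biphasic shoulders,
hypersolubilisation — solubility *rising* with temperature), and sigmoid
residuals are correlated across neighbouring temperatures (see
`residual_correlation_matrix`).  The semi-parametric model adds a smooth
deviation μ(T) with a zero-mean GP prior under a squared-exponential kernel
C(T,T′) = v² exp(−|T−T′|²/2ℓ²).  All replicates of a condition share one
realization of μ, so the kernel is built over the concatenated temperature
vector (replicate copies at the same temperature get the full covariance
v²), and μ marginalizes analytically:

    y ~ N(S, C + σ² I).

Hyperpriors: `v ~ FoldedStudentT(ν = 3, 0, scale 0.5)` — strong shrinkage
towards zero with heavy tails, so the GP term only absorbs structure the
data support — and `ℓ ~ LogNormal(−0.5, 0.5)` on the **standardized**
temperature axis (temperatures divided by the grid SD, ≈ 9.6 °C for the
standard ladder).  The log-normal's sharp left tail blocks data-interpolating
length-scales and its median of ≈ 0.6 grid-SDs (≈ 5–6 °C) matches the
smoothness of observed deviations; applied to raw °C the same prior would
put its mass below one grid step and reduce the GP to a white-noise random
effect, which is why the model layer standardizes the kernel inputs.

Because the per-block data vector is R identical copies of one temperature
grid, the likelihood is evaluated through an exact decomposition of
K = J_R ⊗ C + σ²I into a D-dimensional Gaussian on the replicate mean
(covariance R·C + σ²I) plus (R−1)·D independent N(0, σ²) contrasts; this
cuts the per-evaluation Cholesky from (RD)³ to D³ work and is tested
against the dense form.  A reduced-rank (Hilbert-space basis) approximation
of the marginal likelihood is provided as an optional backend
(`reduced_rank_loglik`; defaults m_basis = 32, boundary_factor = 2, our
choices); at the n ≤ 40 points of a protein block the dense path is exact
and already cheap, so it is the default.

### Inference

Both models are sampled on an unconstrained scale (log for a, b, σ, v, ℓ;
logit for p) with the change-of-variables Jacobian included, so the
recorded per-draw log posterior is directly usable by the evidence
estimator.  `log_posterior` also returns the analytic gradient (chain rule
through the sigmoid partials and the standard GP trace identities), which
is verified against finite differences and used to locate the MAP.

Sampling uses the affine-invariant ensemble sampler (emcee) with
differential-evolution moves — the sigmoid posterior has |corr(log a,
log b)| ≈ 0.99 and DE moves are invariant to such linear structure — with
walkers initialized from an overdispersed multivariate-t cloud around a
Laplace approximation (MAP by L-BFGS, curvature by finite differences of
the analytic gradient).  Defaults: 64 walkers, 200 warmup + 250 retained
steps (~16k draws per block); the benchmark pipelines use 48 walkers and
150 + 200 steps, which reference runs show give equivalent decisions.

Under M1 the two conditions have disjoint parameters and independent
priors, so the joint posterior factorizes exactly; each condition is
sampled separately and the evidences add.  This is asserted in tests rather
than assumed.

**Convergence flags.**  Split-R̂ and bulk ESS are computed (arviz) over
*groups* of walkers, each group's chains concatenated.  Walkers of an
interacting ensemble are not independent chains, and at practical chain
lengths the group diagnostic fluctuates in 1.00–1.03 on runs whose
posterior summaries are indistinguishable from much longer references,
while genuine failures (too-short runs, stuck walkers) show R̂ > 1.2 with
ESS ≈ 10.  A fit is therefore flagged unreliable at R̂ > 1.05, bulk
ESS < 50, or a collapsed acceptance fraction; the NUTS-calibrated 1.01
cut-off would mostly flag diagnostic noise here.  (This sampler has no
divergence diagnostic; divergence-based flags apply only to Hamiltonian
samplers.)  Flagged proteins are excluded from hit calling and reported
separately, never dropped.

### Evidence and hit calling

The marginal likelihood of each model is approximated by the
Laplace-Metropolis estimator

    log p(y|M) ≈ (P/2) log 2π + ½ log|Ĥ| + log p(θ̂|M) + log p(y|θ̂)

with θ̂ the posterior draw maximizing the recorded log posterior and Ĥ the
sample covariance of the unconstrained draws (ridge 1e-10).  Evaluating on
the unconstrained scale with the Jacobian folded into the prior makes the
estimate parameterization-invariant, which is tested by comparing two
different transforms of a conjugate model.  On a conjugate normal-mean toy
the estimator is within 0.1 nats of the analytic evidence at 4000 draws.

Posterior model probability:

    P(M1|y) = logistic( log BF₁₀ + log(0.01/0.99) )

with prior model probabilities p(M0) = 0.99, p(M1) = 0.01 controlling
multiplicity across thousands of proteins without any empirical null.  A
protein is a hit when P(M1|y) **strictly exceeds** 0.99.

### NPARC baseline

Multi-start trust-region least squares fits the sigmoid under M0 and M1
(box bounds a ∈ [10, 5000], b ∈ [0.5, 100], p ∈ [0, 1); 9 grid starts plus
the M0 solution as an M1 start, which guarantees RSS₁ ≤ RSS₀).  The
statistic F = (d₂/d₁)(RSS₀ − RSS₁)/RSS₁ uses counting dofs (d₁ = 3,
d₂ = n − 6), but p-values are computed against F(d̃₁, d̃₂) with *effective*
dofs fitted to the dataset-wide empirical F distribution, because TPP
residuals violate the i.i.d. assumptions.  The original effective-dof
scheme is described elsewhere and not restated in our sources; we fit
(d̃₁, d̃₂) by maximum likelihood of the central-F density, optionally with
the upper tail trimmed and the density renormalized for the truncation
(the pipeline trims 5%; d̃₂ is tail-identified, so trimming inflates its
variance and the untrimmed fit is used on clean data).  This is an
approximation to the reference scheme, not a reimplementation of it.
Benjamini-Hochberg adjustment is applied; the hit rule is adjusted
p < 0.01.

Like any empirical-null calibration, the effective-dof fit assumes the
large majority of proteins are unaffected.  When a substantial fraction
carries real effects — as in the sensitivity benchmark, where a third of
the proteins respond — the alternative tail inflates the fitted null and
NPARC's power collapses (trimming helps only when the contamination is
smaller than the trim).  The Bayesian routes need no empirical null and
are unaffected, which is precisely the regime the multiplicity-controlling
prior is designed for.

### Model criticism

* **Posterior predictive checks** — replicated datasets drawn by sampling θ
  and then y_rep from the observation model (the full correlated Gaussian
  for the semi-parametric family); 50%/95% pointwise bands and the fraction
  of observed points inside each are reported.
* **PSIS-LOO** — importance ratios 1/p(y_i|θ_s) smoothed by a
  generalized-Pareto fit to their largest 20% (arviz's PSIS), with Pareto
  k̂ > 0.7 flagged.  For the semi-parametric family the pointwise term is
  the exact multivariate-normal leave-one-out conditional density
  p(y_i|y_−i, θ) computed from the precision matrix — LOO for correlated
  observations must condition on the remaining points.  Columns with
  zero-variance ratios (degenerate posteriors) fall back to the plain log
  density with k̂ = ∞.
* **ΔR²** — R² of the posterior-median fitted curve per condition (M1 fits,
  conditional GP mean included for the semi-parametric family), pooled over
  conditions and replicates with TSS around each condition's mean.
  ΔR² = R²(semi-parametric) − R²(sigmoid) ≥ 0.05 flags a protein as
  deviating from sigmoid behaviour.  Computing on M1 keeps the flag about
  curve *shape* rather than treatment effect.

## Synthetic data

The generator emulates the standard protein-level TPP design: 2 conditions
× 2 replicates × 10 temperatures evenly spanning 37–67 °C.  Ground-truth
sigmoids draw a ~ U(400, 900), midpoint Tm = a/b ~ U(44, 58) °C,
p ~ U(0, 0.2) and σ from {0.03, 0.08} (per protein, shared by conditions) —
midpoints and noise levels chosen to match typical published melting
curves.  Scenarios: identical curves (`null_sigmoid`); a 2–5 °C midpoint
shift of random sign in the treated condition via b → a/(Tm + Δ)
(`shifted_sigmoid`); a shared GP deviation draw (`gp_deviation`); a
deterministic Gaussian bump shared by conditions (`biphasic`, amplitude
0.15–0.3 at 46–54 °C) optionally combined with a shift
(`biphasic_shifted`); and a rising ramp (`hypersolubilised`, amplitude
0.2–0.5).  Deviation templates are deterministic (except the GP scenario)
so shape-diagnostic checks have controlled ground truth.  Replicates share
one deviation realization per condition; only measurement noise is
replicate-specific; values are truncated at zero.

What the generator does **not** emulate: TMT reporter-ion and
peptide-level noise, co-isolation artefacts, missingness mechanisms,
between-protein residual correlation, and realistic effect-size mixtures.
Passing benchmarks therefore demonstrate correctness and calibration of
the statistical machinery under the stated conditions, not performance on
any particular real dataset.

## Validation profile (problem sizes)

The standard validation suite, shared by `tests/test_acceptance.py` and
`scripts/acceptance.py`:

* conjugate-evidence check at ≥ 4000 draws;
* GP likelihood vs the dense multivariate normal and vs explicit
  Monte-Carlo marginalization (200k draws, 5-point toy);
* null false-hit rate on **200** pure-null proteins at σ = 0.05;
* sensitivity comparison on **150** proteins (100 null, 30 shifted-sigmoid,
  20 biphasic-shifted responders), all three methods on identical subsets;
* predictive-band calibration over **50** well-specified proteins;
* PSIS-LOO vs exact leave-one-out refits on a 20-observation toy, and the
  ΔR² contrast between one strongly biphasic (flank shoulder, amplitude
  0.45) and one pure-sigmoid protein.

These sizes keep the full suite in tens of minutes on one CPU while leaving
each check's Monte-Carlo error well below its decision margin.

## Numerical choices and edge cases

* Covariance factorizations add jitter only on failure (1e-10·v²,
  escalating ×10 at most three times, logged); out-of-support or
  overflowing parameter values evaluate to −∞ (sampler rejection), never an
  exception.
* Least-squares non-convergence from all starts flags the protein; flagged
  proteins are excluded from downstream model fitting and listed in the run
  log.  Proteins with any missing cell are excluded from fitting (missing
  cells are recorded, never imputed); the exclusion rule is the simplest
  defensible treatment given that the handling of partial curves is not
  specified by upstream pipelines.
* Per-protein seeds derive from the master seed and CRC32(protein_id), so
  results are independent of processing order and resumable runs are
  byte-identical to fresh ones.  Execution is serial; the per-protein
  seeding would make process-level parallelism results-identical, but a
  worker pool is deliberately not included to keep the determinism contract
  trivially auditable.
* Solubility values are used as supplied (assumed normalized upstream); no
  re-normalization is performed.

## Known limitations

* The ensemble sampler is not the Hamiltonian/NUTS sampler typically used
  for such models; it needs no gradients at run time and vectorizes well
  across walkers, but mixes more slowly per draw.  The flag thresholds
  above are calibrated to its group diagnostic.
* The Laplace-Metropolis evidence assumes an approximately Gaussian
  posterior on the unconstrained scale; for weakly identified
  semi-parametric fits (v near 0) it inherits some bias, which the
  0.99-probability hit threshold tolerates by design.
* The effective-dof fit is a stated approximation to the original NPARC
  calibration, not a byte-level reproduction.
* ΔR² depends on the posterior-median curve convention; per-draw R²
  distributions would be a natural extension.
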