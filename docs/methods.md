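# Methods

## Scope and model families

The package fits three approximate-Bayesian binary classifiers to tabular
data and scores every prediction with logit-space uncertainty measures.
All three share one supervised backbone family: fully connected ReLU
networks with Kaiming-uniform initialization (bound `gain·sqrt(6/fan_in)`
on each weight matrix's input dimension), trained with Adam on minibatches
and early-stopped on a hold-out validation loss (the returned parameters
are always the best-validation state seen). The engine is plain numpy with
hand-written backpropagation; networks at this scale (tens of inputs,
widths ≤ 128) run in seconds per fit on one CPU core.

**Deep ensemble (ENN).** M networks differ only in their initialization
and shuffling seeds (no bagging — the minimal diversity mechanism; data
subsampling exists in the literature but is off by default). Member
logits at a query point are treated as M draws from an implicit
functional posterior. M = 1 is allowed and degenerates to zero epistemic
spread.

**Radial variational BNN.** Each layer's weights-plus-bias vector w gets
the posterior `w = μ + σ ⊙ (ε/‖ε‖)·r` with ε standard normal of the
layer dimension and r scalar standard normal; σ is kept positive through
a softplus parameterization. The training objective is the negative ELBO

```
L = E_q[−log p(y|x,w)]  +  λ_KL · KL(q‖p),     p = N(0, s²I)
```

with the likelihood term the mean Bernoulli cross entropy over the batch
averaged over `mc_draws` weight draws (default 1 per step), and the KL
assembled from the radial family's analytic entropy
(Σ log σᵢ plus a dimension-only constant involving log Γ(D/2) and
E[log |N(0,1)|]) and a Monte-Carlo cross entropy against the Gaussian
prior evaluated at the same sampled weights. `λ_KL` defaults to
1/n_train, the standard minibatch ELBO scaling. Early stopping monitors
the posterior-predictive validation NLL (mean sigmoid over 20 fixed-seed
weight draws) so that the selected state reflects the averaged predictor,
not the posterior mean alone. Gradients flow through the reparameterized
sample; the implementation is verified against central finite differences
to 1e−9 on small networks.

**SNGP.** The backbone is an input projection plus residual blocks
`h ← h + relu(Wh + b)`, every weight matrix spectrally normalized to a
bound c < 1 (power iteration with warm-started vectors during training,
converged projection on the final state, exactness asserted via SVD in
tests). The GP head maps the backbone output through frozen random
Fourier features `φ(h) = sqrt(2/D)·cos(Ωh + b)`, Ω ~ N(0, I)/ℓ, whose
inner products approximate an RBF kernel with length scale ℓ. The head
weights β are trained jointly with the backbone by cross entropy plus the
ridge penalty λ‖β‖²/2 (scaled per record); after training the latent
covariance is set by the Laplace form

```
P = λI + Σᵢ pᵢ(1−pᵢ)·φᵢφᵢᵀ,   var(x) = φ(x)ᵀ P⁻¹ φ(x),
```

inverted once by Cholesky and cached, so query cost is independent of the
training-set size. Predictive probabilities use the variance-adjusted
sigmoid `σ(m/√(1+(π/8)v))` by default (a plain sigmoid mode exists).

*GP-input normalization.* By default the backbone output is normalized
per sample (zero mean, unit variance across features) before the RFF map,
as in standard SNGP implementations. The discriminative objective
otherwise stretches feature space along the decision direction, and the
combination of that stretch with the pᵢ(1−pᵢ) weights makes the latent
variance mirror loss curvature — exactly the artifact the architecture is
meant to avoid. With normalization the variance tracks training-data
density; the cost is that an unbounded ray in input space maps to a
bounded arc in feature space, so the trained model's latent mean
saturates along such rays instead of decaying all the way to the prior
mean, while its variance still rises monotonically toward the prior
variance. The reversion property itself is exact in the head's own
geometry, which is how it is asserted: the RFF head with the identity
backbone reverts fully (mean to the prior within the RFF Monte-Carlo
error, variance to 1/λ), and the exact GP oracle reverts to 1e−6.

## Uncertainty measures

With ℓ₁ = log(n₁/n₀) from the training labels and a per-instance
posterior over the latent log-odds (sample form or Gaussian form):
ES = |E[ℓ₁|ₓ] − ℓ₁|, u_tot = exp(−k·ES), u_epi = 1 − exp(−k·Var[ℓ₁|ₓ]).
Sample variance uses the unbiased (M−1) denominator, which matters at the
reduced draw counts used at desk scale; M = 1 yields u_epi = 0 with a
warning. The decay rate k (default 1, dimensionless) affects only the
display scale: all rank-based analyses are provably k-invariant, which
the property tests assert. Class relabeling (negating all log-odds and
ℓ₁) leaves every measure unchanged.

## Synthetic data

**Toy law.** Unit square; class probability `p1(x0) = clip(α+β·x0, 0, 1)`
with α = 0, β = 1; training density along x₁ linear, `w(x1) = 0.25 +
1.5·x1` (positive, integrating to 1; the dense edge carries 7× the sparse
edge's mass, sampled by inverse CDF); labels i.i.d. Bernoulli(p1). The
test law shares p1 but is uniform in both coordinates. Because p1 depends
only on x₀ and density only on x₁, the ground-truth epistemic signal
(density) and aleatoric signal (p1(1−p1)) are statistically independent.
Sample sizes default to 4000/4000. The exact slopes are design choices —
they give clearly separated density strata while keeping the class
problem learnable.

**Synthetic cohort.** 7664 records at 7 % target prevalence, six
categorical features (staging-, grade-, treatment-, demographic-style,
2–5 levels, mildly non-uniform frequencies) and five continuous ones,
with missing-completely-at-random rates of 0–20 % applied after label
generation; the ground-truth logit is linear in the generating variables
and its intercept is calibrated by root finding so the expected
prevalence hits the target (unreachable targets raise). True logits and
probabilities are stored as `truth` columns invisible to models; the
generator self-calibrates (binned ECE of its own probabilities → 0 with
n, asserted at 1e4). Effect sizes were chosen so that the true-risk AUROC
is ≈ 0.86, matching the discrimination regime of the motivating clinical
task. What this cohort does *not* emulate: informative missingness,
feature correlations of real registries, survival-time outcomes, and the
genuine feature list of any real study — conclusions about those require
real data.

## Preprocessing

Categorical features expand to one indicator per level observed in the
fitting subset plus a "missing" indicator (unseen levels at transform
time fall into it with a logged warning); continuous features are
standardized with fitting-subset statistics only, missing values imputed
at 0 (the post-standardization mean) and flagged with a companion binary
column. The cross-validation plan is a stratified permutation into six
blocks: fold k tests on block k, validates on block k+1 (cyclic), trains
on the remaining four — 4:1:1 with pairwise-disjoint test folds covering
all records. Single-block subsets conserve prevalence to rounding; the
four-block training subsets can accumulate two block remainders, so their
worst-case prevalence deviation is 2/|subset|.

## Experiments and problem sizes

The desk configuration — ensemble M = 50, BNN prediction draws 200, RFF
D = 1024, backbones 2×32, batch 128, ≤ 40 epochs with patience 5, cohort
n = 7664, toy 4000/4000 — completes both experiments in a few minutes on
one CPU core. The `full` preset restores the study-scale settings
(M = 500, D = 4096, 3×128 backbones) behind the same interface. SNGP's
desk operating point (ℓ = 2.5 on the normalized GP input, λ = 1, spectral
bound 0.5) was selected on the toy law as this package's stand-in for the
original architecture search; the module-level defaults remain ℓ = 2.0,
bound 0.95 for users starting fresh. BNN: prior scale 1.0, initial
posterior scale σ₀ = 0.1.

Stratification follows the sliding-window recipe: instances sorted
ascending by the uncertainty measure (stable ties), window = ⌊n/3⌋,
stride 1 in instances; per-window mean and sum NLL are both exported (the
Spearman between window rank and window NLL is identical for either).
A structural caveat the synthetic cohort makes visible: at 7 % prevalence
the expected NLL is *not* monotone in evidential strength — predictions
moderately above the prior carry entropy up to ln 2, while the
highest-u_tot windows sit near the prior's entropy H(0.07) ≈ 0.25 — so
the top third of the window curve is flat to slightly declining and the
resulting Spearman fluctuates with the label realization (the generator's
own true probabilities score anywhere from 0.6 to 1.0 across seeds at
n = 7664). Window-ranked NLL curves should therefore be read alongside
the curve itself, not reduced to the single coefficient.

## Numerical choices

NLL probabilities are clipped at 1e−12; ECE uses 10 equal-width bins with
empty bins dropped; kernel matrices get 1e−8 jitter before Cholesky;
spectral norms use power iteration (tolerance 1e−12, exact SVD in tests);
the exact-GP Laplace fit and the RFF head's MAP fit share the numerically
stable `B = I + W^{1/2}KW^{1/2}` formulation; the RFF head's dual Newton
solve is exact for n ≪ D and makes the head/oracle comparison a pure test
of the kernel approximation. All randomness flows through
`numpy.random.Generator` seeded from explicit seed sequences; experiment
outputs are byte-identical across reruns on one machine.

## Limitations

The comparison inherits the usual caveats of a three-family study: one
architecture and training protocol per family, desk-scale sizes, and
synthetic data whose independence structure is cleaner than any registry.
The exact GP oracle conditions through a Gaussian pseudo-likelihood with
pᵢ(1−pᵢ) weights (the Laplace form), matching the SNGP head it validates,
not a full non-Gaussian GP classifier. Mean reversion for the trained
SNGP holds in its feature geometry; models without explicit functional
priors (ENN, BNN) are not expected to revert and are only recorded, never
asserted, on that property.
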