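# Methods

This note documents the models, the synthetic data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## Data model and preprocessing

A dataset is a grid of weekly tuples, one per (region, week). Each tuple
holds a real-valued indicator vector with one component per
(food, contaminant) pair and an explicit missing mask (NaN in memory, absent
rows in the on-disk long format), per-disease incidence counts, and the
resident population. Morbidity — the supervised target — is derived as
incidences/population, so population changes remain representable. Weeks are
0-indexed from the first study week; lags are whole weeks.

Supervised pairs for disease *d* at lag *ℓ* join the feature vector at week
*t − ℓ* with the morbidity at week *t*, within a region only; weeks missing
from a region simply produce no pair. Repeated within-week measurements of
one indicator are collapsed to their arithmetic mean.

**Imputation and scaling.** Missing cells are filled with the per-column mean
of *observed training cells*; after filling, every column is z-scored with
training mean/sd. Columns with no observed training entries, or zero
variance, map to the constant 0 (the standardized prior mean). Both rules are
fit per cross-validation fold on the training folds only — the test fold
never contributes a statistic. Standardization is required by the
Gaussian-visible bottom RBM layer (unit-variance energy) and gives the
evolutionary weight search comparable bounds across features; no scaling
convention is standard for these indicator tables, so this is a package
design choice.

**Cross-validation.** Folds are uniform random at the pair level with a
fixed seed (sizes differ by at most one). Temporal blocking is deliberately
not the default — plain equal-size random folds are the baseline protocol
here. This choice is optimistic for autocorrelated data; see Limitations.

## Models

**MLR.** y = a₀ + a·x, fitted by least squares with a ridge guard of 1e-8 on
the coefficients (never the intercept). At study scale the feature dimension
far exceeds the sample count, so the normal equations are singular; the
guard selects the minimum-norm solution deterministically. For n > N the
equivalent dual (N × N) system is solved instead.

**Shallow ANN.** One sigmoid hidden layer with thresholds
(z_j = s(Σᵢ w_ij xᵢ − θ_j)), a sigmoid output unit, minibatch SGD on squared
error, and the epoch-best snapshot by training RMSE returned. Hidden width
defaults to round(√n): an n-unit hidden layer over tens of thousands of
indicators with under two thousand training tuples would be severely
over-parameterized, so the square-root rule is used and the width left
configurable.

**RBM / DBN.** Standard energy with bias terms −bᵀx − cᵀz − xᵀWz; the bottom
layer of a stack uses the Gaussian-visible variant Σ(xᵢ−bᵢ)²/2 − cᵀz − xᵀWz
(unit variances after standardization), upper layers are Bernoulli.
Pretraining is CD-1: sample hidden given visible, reconstruct with the
conditional mean, recompute hidden probabilities, apply positive-minus-
negative statistics. Stacking uses deterministic mean-field codes
s(c + Wᵀx).

**Autoencoders.** Encode z = s(Wx + b), decode x′ = s(W′z + b′), loss =
mean ‖x − x′‖² against the *clean* input. The denoising variant corrupts the
encoder input by masking components to zero independently with rate ρ
(default 0.2); masking is the canonical corruption for this architecture
family and Gaussian-additive corruption is intentionally out of scope here.
At ρ = 0 the denoising code path consumes no random draws, which makes
DAE and DDAE(ρ=0) bit-identical under shared seeds — a property the test
suite asserts parameter-for-parameter.

**GMM output head.** A K-component (default K = 3) full-covariance Gaussian
mixture fitted by EM (scikit-learn, reg_covar = 1e-6 on diagonals) over the
joint vector (top-layer code z, target y). Prediction is the conditional
expectation under the fitted joint — responsibility-weighted per-component
linear-Gaussian regressors. With K = 1 this reduces exactly to joint-Gaussian
linear regression, which the tests verify against the closed form to 1e-8.
The analytic gradient ∂E[y|z]/∂z is implemented so the squared error can be
back-propagated through the head into the encoder; it is checked against
finite differences to 1e-4. A mixture-density-network formulation would be an
alternative way to condition the head; the joint-fit-with-conditional-mean
construction is this package's choice (simpler, and exactly linear at K = 1).

## Training regimes

**Gradient.** Layerwise pretraining (each layer on the previous layer's
codes; later layers never see raw features), then fine-tuning: full-batch
gradient descent through the encoder and head, the head refit on current
codes every `head_refresh` epochs (default 5) and frozen in between. The
training-RMSE-best snapshot is returned, so fine-tuning can only match or
improve on the pretrained starting point.

**Evolutionary (WWO).** Layerwise WWO over each layer's full parameter
vector in a per-parameter box of [−4, 4] (covering the useful sigmoid
operating range after standardization), fitness = negative reconstruction
error. The exact RBM layer log-likelihood requires the partition function and
is intractable; negative one-step mean-field reconstruction error is the
standard tractable surrogate used here. For denoising layers one corruption
mask is drawn per layer and frozen during that layer's optimization so that
candidate fitness is deterministic and comparable; the gradient regime, by
contrast, redraws corruption every epoch.

Whole-network fine-tuning then runs WWO over the flattened *encoder*
parameters (layer weights and hidden biases; RBM visible biases and
autoencoder decoders do not enter the prediction path), fitness =
1/(training RMSE + 1e-12). One initial wave is seeded from the pretrained
parameters. The head is refit once per WWO generation on the current best
wave's codes and frozen within the generation (per-candidate refits would
multiply cost by the population size without changing within-generation
rankings). The returned model is the better — by training RMSE — of the best
wave (under a freshly refit head) and the pretrained model as handed in, so
evolutionary fine-tuning never degrades training fitness; this is asserted on
every run in the tests.

## Water wave optimization

Each candidate ("wave") carries a wavelength shrunk multiplicatively each
generation by α^(−(f−f_min+ε)/(f_max−f_min+ε)) with α = 1.0026, λ₀ = 0.5 and
ε = 1e-12 guarding equal-fitness populations. Propagation perturbs every
dimension by λ·U(−1,1)·Lᵢ; out-of-bound components are re-drawn uniformly in
range (avoiding boundary pile-up). A propagated wave replaces its parent
only if fitter (elitism). A strict improvement of the population best
triggers breaking: k ~ U{1..min(12, D)} solitary waves, each perturbing one
distinct random dimension by N(0,1)·β·Lᵢ, with β decaying linearly
0.25 → 0.001 over the evaluation budget; the best of {input, solitary waves}
survives. A wave that fails to improve for h_max = 6 consecutive
propagations is *refracted*: resampled per dimension from
N((x*ᵢ+xᵢ)/2, |x*ᵢ−xᵢ|/2) toward the population best, keeping its evolved
wavelength — the published fitness-ratio wavelength rescale assumes positive
fitness and misbehaves for the negated losses used here. Refraction is what
delivers late-stage precision: without it the propagate/break loop stalls at
~1e-2-scale residuals on a 2-D sphere at a 5,000-evaluation budget, while the
full operator set reaches ~1e-7 in the median.

The wavelength update can be read as compounding across generations or as
restarting from λ₀ each generation; the compounding form is the default and
`recompute_from_init` switches to the other reading. The
evaluation budget counts objective calls after the initial population.

## Synthetic data generator

The generator defines the study conditions for all desk-scale results.
Per region and indicator column, contamination follows an AR(1) latent
process with coefficient 0.7 and unit innovations (weekly environmental
levels are autocorrelated, and lag identifiability requires temporal
structure). The stored feature table is the latent level plus N(0, 0.3)
measurement noise, observed under an independent Bernoulli(0.18) mask —
0.18 ≈ 4,955/27,013, the observed fraction of the full-scale schema.
Morbidity for disease *d* at week *t* is

  clip₀₁( scale_d · link(Σ w·x_active(t − ℓ_d)) + N(0, σ) ),

computed from the *uncorrupted* latent features, then converted to integer
incidence counts against a per-region population drawn once from
[50,000, 150,000] (so dataset morbidity is the planted value quantized at
1/population; the generator's ground-truth object keeps the exact values).
Defaults: 12 × 20 = 240 indicator columns, 4 regions × 60 weeks, 8 active
columns per disease, sigmoid link, target noise σ = 0.02, six diseases with
lags (1, 3, 3, 4, 1, 1) and signal scales (0.25, 0.20, 0.20, 0.004, 0.30,
0.22) — the near-zero fourth scale encodes the tumor-like disease whose
coupling to contamination is too weak to learn. Effect weights are drawn
with mixed signs and magnitudes scaled so the link argument has O(1) spread.
Full-scale generation (27,013 columns) is supported but not the default.

What the generator does **not** emulate: mechanistic dose–response,
outbreak point processes, seasonality and holidays, reporting delays,
spatially correlated contamination across regions, and non-Gaussian
measurement error. Passing tests therefore demonstrate correctness of the
pipeline and the *relative* behavior of the models under the assumed
structure — not epidemiological validity on real surveillance data, for
which no distributional reference is available.

## Evaluation

RMSE is the objective metric. The reported "prediction accuracy" percentage
is 100·max(0, 1 − Σ|yᵢ − ŷᵢ|/Σŷᵢ) — the complement of total absolute
relative error — chosen because it yields 0–100% values, is scale-invariant,
and tolerates individual zero targets; when the target total is zero it is
100 for a perfect all-zero prediction and 0 otherwise. Published accuracy
percentages for this task do not come with a formula, so this is a declared
stand-in and any comparison to externally reported percentages is
qualitative only. The lag sweep evaluates cross-validated RMSE for lags 1–8 and reports
the argmin, ties resolved toward the smaller lag (parsimony and earlier
actionability). The default per-disease lag policy fixes lag 1 for the three
acute diseases, lag 3 for chronic gastroenteritis and ulcers, and per-model
argmin for tumors.

Desk-scale benchmark sizes (a light 24-8 stack, 400/300 WWO evaluations per
stage, five seeds, a 75/25 split per seed) are the package's default
problem sizes for the comparative experiments; study-scale widths
(3860/550/80/12 for the DBN, 4500/640/80/12 for the autoencoder stacks) are
configurable through the same interfaces.

## Known limitations

- Random (non-temporal) CV folds leak autocorrelation between train and test
  weeks; a time-blocked splitter would give more conservative estimates.
- The WWO budgets used at desk scale are far below what study-scale encoder
  dimensions (~10⁵–10⁷ parameters) would need; evolutionary variants at desk
  scale are demonstrations of the mechanism, not tuned competitors.
- The accuracy formula is a stand-in; orderings are comparable within this
  package but absolute percentages are not comparable to other definitions.
- The sigmoid decoder of the autoencoder layers cannot reproduce z-scored
  inputs outside (0, 1); pretraining still orders parameters usefully, but
  reconstruction losses do not approach zero on standardized data.
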