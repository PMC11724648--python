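# Methods

## Joint mixture model and conditioning

The regression engine models the concatenated vector z = [x, y] — latent
coordinates x of a molecule and its property vector y — with a K-component
full-covariance Gaussian mixture. Full covariances are essential: the
cross-block Σ^oi is exactly what makes conditioning informative, so tied,
diagonal or spherical structures are not offered. Both blocks are
standardized per column to zero mean and unit variance before fitting
(latents and properties such as logP/QED/SAS live on very different scales
and EM is scale-sensitive); the affine transforms are stored on the model
and inverted on every public output, so user-facing values are always on
the raw scale. A zero-variance column aborts standardization with the
column named.

Fitting uses expectation-maximization (scikit-learn's `GaussianMixture`)
with k-means++ initialization under the caller's seed and the best of 10
restarts by log-likelihood. A ridge term (default 1e-6) is added to every
covariance diagonal after fitting to guarantee positive-definiteness of the
stored model.

Conditioning on either block uses the conditional multivariate-normal
formulas per component (conditional mean via a Cholesky solve against the
conditioned block's covariance, conditional covariance as the Schur
complement, symmetrized exactly) with component weights proportional to
π_k times the component's marginal density of the query. Weights are
computed in log space and normalized with log-sum-exp, so queries far into
the tails keep well-defined weights; only a query whose log-density is −inf
under every component raises a degenerate-query error. The identical code
path serves p(y|x) and p(x|y) — the X/Y symmetry that makes inverse
analysis "direct" — and a block-swap helper exists purely so tests can
assert that symmetry.

Two point estimators collapse a conditional mixture: the weighted mean of
the component means, and the mean of the heaviest component (ties broken by
lowest component index). The weighted mean is the default for forward
prediction; for inverse queries against multimodal conditionals the
heaviest-component rule is often preferable, since the weighted mean of two
distant modes can land in a low-density valley. Batch generation bypasses
point estimates entirely and samples the conditional mixture (component
index from the weights, then a Gaussian draw), which is how the design
pipeline obtains many distinct latents for one target.

## Hyperparameter selection

`select_hyperparameters` scores (K, ridge) candidates by mean held-out
forward-prediction R² (K-fold CV, folds and EM seeded identically for every
candidate, R² averaged over property columns). Small candidate sets are
searched exhaustively; larger ones by Bayesian optimization with a
Gaussian-process surrogate (RBF + white noise on min-max-scaled (K, log10
ridge)) maximizing expected improvement over the not-yet-evaluated
candidates. A candidate that cannot be fitted on some fold (e.g. more
components than fold samples) scores −inf rather than aborting the search.
The default space is K ∈ {1..30}, ridge log-spaced in [1e-8, 1e-3]. The
returned cv score is recomputable bit-for-bit from the returned config and
the same seed.

## Reference codec and joint training

The codec contract is deliberately minimal: `encode` maps molecules to a
posterior mean and variance per latent dimension, `decode` maps any finite
latent to a molecule string and never raises (an invalid-molecule sentinel
is allowed and is what downstream attempt accounting counts). A
full-featured graph VAE can be wrapped behind this contract; the package's
reference codec instead makes validity a property of the *representation*:
a fragment alphabet (chain atoms C/N/O/S, a benzene ring, a branch methyl,
a carbonyl) chosen so that every concatenation of tokens is a parseable
SMILES string. Decoding takes the argmax token per position and truncates
at the first padding symbol; an all-padding decode falls back to methane.
Validity of decoded molecules is therefore 100% by construction, mirroring
at desk scale the behaviour of validity-guaranteed graph decoders, while
identity round trips (decode(encode(m)) == m) are explicitly *not* part of
the contract at desk scale.

The codec is a feedforward one-hot token VAE rather than a recurrent one:
position-wise encoder/decoder MLPs with a diagonal-Gaussian latent
(reparameterization trick), implemented in numpy with hand-written
backpropagation and Adam (lr 1e-3, standard betas). At the fixture sequence
lengths (≤ 8 tokens) recurrence buys nothing the contract needs, and the
feedforward form keeps gradients simple and the training bit-reproducible
under a single seed.

Joint training minimizes `(reconstruction CE + KL) + λ · MSE(head(z), y)`.
The property head is an MLP with three hidden layers of 67 neurons, ReLU,
dropout 0.15 (inverted, training mode only), linear output — one output per
property. Properties are standardized internally for training (the scaler
is stored on the head and inverted by `predict`), so λ = 1 weighs each
property equally regardless of units; the per-epoch history reports the
property MSE in those standardized units. KL annealing is available but off
by default. The random stream consumed per batch (shuffling, reparameter-
ization noise, dropout masks) is identical for every λ at a fixed seed, so
λ-ablations differ only through the gradient contribution of the property
term. The latent representation handed to the mixture model is the
posterior mean; posterior sampling is available but the mean is what makes
downstream encoding deterministic.

Desk-scale defaults used in tests and in the acceptance script: 200
fixture molecules, hidden width 64, latent dimension 6, 30–40 epochs, batch
32. The config dataclass defaults (hidden/embedding 250, latent 32) mirror
the reference full-scale configuration and are what a wrapped graph codec
would use.

## Design pipeline

Targets are declarative per property: a fixed value, or the training-data
maximum/minimum (resolved against the training property table — e.g. logP
fixed at 2.00, QED at the dataset maximum, SAS at the dataset minimum).
Generation draws latents from p(x | y\*), decodes, counts every decoder
invocation as one attempt, and keeps valid molecules until the requested
count is reached or the attempt budget (default 500 × requested) is
exhausted — exhaustion yields a truncated partial result with a flag, not
an exception. Duplicate molecules are kept in all counts (generation
accounting counts outputs); a deduplicated view is provided for reporting.

Hits are molecules inside every closed threshold interval (reference
window 1 ≤ logP ≤ 3, QED ≥ 0.8, SAS ≤ 3.0; boundary values pass).
Diversity is the mean pairwise Tanimoto distance over the *hit* set using
Morgan fingerprints (radius 2, 2048 bits — community defaults, as the
choice is not otherwise pinned down); fewer than two hits make diversity
undefined rather than zero. Tanimoto distance is implemented directly as
1 − |a∧b|/|a∨b| with the all-zero/all-zero pair defined as distance 0
(identical empty bit sets). Novelty is the fraction of generated molecules
whose canonical SMILES is absent from the training set; molecule identity
throughout the package is canonical-SMILES string equality.

## Oracle-guided loop

The campaign abstraction targets expensive black-box scores (docking-style,
kcal/mol, lower is better). Initialization draws n_init (default 30)
distinct molecules from a pool, encodes and scores them. Each cycle refits
a fresh mixture on the *entire* archive of (latent, score) pairs, estimates
the latent at the fixed target score (default −12.2) by direct inverse
analysis, decodes one molecule — falling back to up to 10 conditional
samples if decodes fail, after which the cycle is recorded as failed — then
scores and appends it. In the 30–80-sample regime the component count is
capped at floor(n/10) and selected by per-cycle cross-validation by
default. The oracle call count is exactly n_init plus the number of
successful cycles; failed cycles append a marker record so the archive
length stays n_init + cycles. An adaptive target mode ("current best minus
margin") was considered and rejected as a default: a fixed target keeps
campaigns comparable across cycles and seeds.

The external-tool contract is documented by `CommandOracle` (SMILES on
stdin, one float on stdout); no docking software is invoked by the package
and all tests use synthetic oracles.

## Synthetic stack: what it emulates and what it does not

Ground-truth mixtures place component means at a guaranteed pairwise
separation with banded X–Y cross-covariance of chosen magnitude, so
inverse conditioning is informative by construction and fits can be scored
against known parameters. The mock codec is a bijection between a fixture
molecule set and latent anchor points (scrambled-Sobol grid by default,
random placement for stress tests); encode returns the anchor with zero
variance, decode snaps any finite latent to the nearest anchor, and an
optional failure schedule forces chosen decode calls to return the invalid
sentinel for attempt-accounting tests. Synthetic oracles (Gaussian well,
quadratic bowl) are smooth functions of the anchor latent with a known
optimum location and value (−12.2 by default, matching the loop's target
geometry).

The fixture molecule set is generated, not curated: token strings over the
validity-guaranteed alphabet are enumerated, canonicalized, deduplicated
and subsampled under a fixed seed (~300 distinct small molecules). These
are synthetic stand-ins — small, low-QED, and chemically monotonous
compared with drug-like libraries.

What passing tests therefore show: the conditioning mathematics is exact,
the inverse direction recovers in-range targets, joint property training
shapes latents measurably, accounting and metrics are precise, and the
loop improves on random sampling when the latent space is informative
about the score. What they do not show: that a *particular* deep graph
codec trained on a real library yields latents with these properties —
chemical realism of the latent geometry is explicitly out of scope for the
fixtures. Where an end-to-end check needs an informative latent space
(design hit-fraction direction, the acceptance generation run), anchors
are placed along noisy standardized property coordinates, emulating a
property-trained codec; this regime dependence is a finding, not an
artifact: with property-blind anchor placement the forward R² collapses
and inverse design is uninformative, which is the same qualitative
contrast the joint-training ablation measures on the real codec.

## Numerical choices and problem sizes

- Conditional covariances are symmetrized exactly; PSD is asserted in
  tests down to −1e-10 on the smallest eigenvalue.
- Conditional weights: log-space with log-sum-exp; renormalized after
  exponentiation to absorb rounding.
- Model serialization is a single JSON document; Python's float repr
  round-trips IEEE doubles exactly, so save/load is bit-exact.
- Acceptance-scale problem sizes (chosen once as desk-scale study
  conditions): 5000 draws for parameter recovery; 1200 draws × 10 seeds
  for model selection; 200 molecules × 40 epochs for the training
  ablation; 1000-molecule generation runs; 20 campaigns × (30 + 50)
  oracle calls for the loop comparison, with per-cycle CV lightened to
  2 folds and single-restart EM inside campaigns.

## Known limitations

- The reference codec's chemistry is intentionally tiny; QED ≥ 0.8 is
  unreachable within its alphabet, so the reference threshold window
  yields zero hits at desk scale (wider windows are used for desk-scale
  hit statistics).
- The feedforward codec does not model variable-length structure beyond
  padding, and identity round trips degrade as sequences lengthen.
- Mixture regression inherits the usual GMR failure mode: weighted-mean
  point estimates of strongly multimodal conditionals can fall between
  modes; use the heaviest-component estimate or conditional sampling.
- Per-property (rather than joint) mixtures are configurable but
  untested against the joint default at scale; the joint fit is what
  simultaneous multi-target design requires.
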