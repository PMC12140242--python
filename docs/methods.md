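# Methods

## Model

The package predicts the 21 BDI-II item scores of a user from their post
history with a retrieval-then-predict head over a frozen sentence encoder.

For each (user, item) pair with retrieved post embeddings `RP` (k'×d), item
description embedding `D` (d), and choice embeddings `C` (4×d):

- attention: `α = softmax(D·RPᵀ)`, context `CA = α·RP`;
- sub-model A: `CS_l = cos(CA, C_l)`, `p_A = softmax(τ·CS)` with trainable
  temperature `τ`;
- combined representation: `Σ_l p_A,l · C_l + (1/k')·Σ_i α_i · RP_i`;
- sub-model B: `p_B = softmax(W_out·combined + b_out)`;
- ensemble: `p_final = softmax(W_ens·[p_A ‖ p_B] + b_ens)`.

The per-item prediction is `argmax p_final` (ties toward the lower score,
the conservative severity reading); the user's overall score is the sum of
the 21 item predictions and is banded into Minimal/Mild/Moderate/Severe at
0–13 / 14–19 / 20–28 / ≥29. An alternative screening banding
(0–9 / 10–18 / 19–29 / ≥30) is available but not used in evaluation.

Training minimizes `λ_A·CE(p_A) + λ_final·CE(p_final)` (both λ default to 1)
by mini-batch Adam. Because the encoder is frozen, `α`, `CA`, and `CS` are
fixed features per instance; they are computed once, and only
`(W_out, b_out, W_ens, b_ens, τ)` are updated with analytically derived
gradients. A user-level 10% slice of the training instances drives early
stopping (patience 25); the parameters with the best validation loss are
returned.

## Assumptions

- Posts relevant to an item are lexically/semantically close to that item's
  *description* under the chosen embedding backend; raw dot product is an
  adequate relevance score (no retriever training).
- Top-20 posts suffice to summarize a user's evidence per item; posts
  shorter than 3 whitespace tokens carry no usable signal and are dropped.
- Item scores are exchangeable enough across users that a single global head
  (no per-user parameters) can map retrieved evidence to scores.
- Gold labels are complete: every training user carries all 21 item scores.

## Parameter defaults and rationale

| parameter | default | rationale |
|---|---|---|
| `k` (retrieval depth) | 20 | evidence budget per item; users with fewer posts contribute all of them |
| `min_words` | 3 | "more than two words" usability filter for posts |
| `dim` (mock backend) | 64 | enough buckets that the 21·(1+4) synthetic token pools rarely collide |
| `τ` init | 1.0 | plain softmax over cosines before training |
| init scale | 0.01 | near-uniform initial probabilities; symmetric start |
| epochs / batch / lr | 200 / 256 / 0.05 | Adam on a ≤ few-hundred-parameter head; converges in seconds |
| `λ_A`, `λ_final` | 1, 1 | equal weight on the auxiliary and final cross-entropies |
| `val_fraction` / patience | 0.1 / 25 | user-level early stopping against overfitting the small head |
| test fraction | 0.2 | 80/20 user-level split, disjoint by construction |

Two documented ambiguities in the combined representation are exposed as
explicit switches rather than silently resolved: `combine_mode` selects the
choice weights (`"softmax"`, sub-model A's probabilities — the default — or
`"cosine"`, the raw similarities), and `post_denominator` selects the
normalizer of the post term (`"retrieved"` = the actual k', the default, or
`"fixed_k"` = the nominal k even when fewer posts exist).

## Synthetic cohort generator (emulation targets and fidelity)

Real annotated cohorts are access-restricted, so generated cohorts emulate
the published summary statistics:

- **Post counts**: lognormal with `μ = ln(median)` and `σ` solved (Brent's
  method) so the analytic standard deviation equals the target
  (defaults: median 165, std 265). A two-parameter lognormal cannot match
  median, mean, and std simultaneously; matching median+std leaves the
  implied mean ≈ 244, about 11% below the reference 274. This
  re-parametrization was chosen because the std drives the heavy-tail
  behaviour the pipeline must tolerate.
- **Item scores**: one-factor Gaussian copula. Each user draws a latent
  severity `z`; item latents `√ρ·z + √(1−ρ)·ε` are cut at the normal
  quantiles of the configured marginals (default 25/35/23/17% for scores
  0–3), so marginals hold in expectation for any inter-item correlation
  `ρ`. `ρ = 0.8` reproduces Cronbach's α ≈ 0.98; `ρ = 0.6` gives ≈ 0.95 —
  the ≥ 0.9 regime of the reference instrument.
- **Posts**: synthetic token sequences, not natural language. Each post
  picks a topic item; with probability `signal_strength` it draws 85% of
  its tokens from that item's description + the user's gold-choice text
  (distinct items and choices use disjoint token sets), otherwise from a
  noise vocabulary. 5% of noise posts are 1–2 words long to exercise the
  length filter. Every post carries a provenance tag
  (`signal:<item>` / `noise`) so retrieval can be audited.

`cohort_fidelity` checks a generated cohort against the reference summary
(relative tolerances 25–30% on the post-count shape, absolute 0.06 on
marginals, 15-per-100-users on category counts); the defaults pass at
n = 500 and a deliberately mis-specified generator fails the marginal
checks. What synthetic cohorts demonstrate is **parameter recovery** — the
pipeline finds signal that is present and finds nothing when it is absent —
not performance on real language; headline numbers from the real
access-restricted data are out of reach by construction.

## Numerical choices

- Softmax is computed shift-invariantly (`x − max(x)`); cross-entropies are
  clamped with `ε = 1e-12` inside the log.
- Retrieval ties break by ascending post index (`lexsort`), argmax ties by
  the lowest score; both make every run fully deterministic.
- Sample statistics use the n−1 convention throughout (post-count std,
  item variances in Cronbach's α, item-total correlations).
- All randomness flows through `numpy.random.default_rng(seed)`; the run
  manifest records every seed and SHA-256 hashes of every output file, and
  reruns are byte-identical.
- The mock backend hashes tokens with BLAKE2b into signed buckets and
  L2-normalizes, so embeddings are deterministic across machines and
  sessions without any model download.

## Problem sizes used in tests

Unit and acceptance tests run cohorts with the study-condition marginals,
signal, and correlation but a reduced posts-per-user scale (median 30,
std 48 — the reference 165/265 shape scaled ~5.5×) so the whole suite
completes in well under a minute of training time. Fidelity checks use the
full default scale at n = 500 users.

## Limitations

- Synthetic posts are bags of planted tokens; results quantify recovery of
  a known generative signal under the hashed-bag backend, not linguistic
  generalization. No empirical claim is made about real-data performance.
- The category-level margin over the majority baseline is seed-sensitive at
  n = 200 (40 test users): the baseline accuracy itself varies roughly
  0.35–0.52 across splits, so the margin averaged over 5 seeds can land
  below 0.15 for some seed families even when item-level accuracy is
  stable around 0.6.
- A zero-signal cohort drives a cross-entropy head toward the constant
  modal score, so its raw item accuracy equals the modal frequency
  (≈ 0.35), not 0.25; "chance" is therefore asserted as balanced accuracy
  (mean per-score recall) ≈ 0.25 plus raw accuracy at or below the
  no-information rate.
- The lognormal post-count model reproduces median and std but not the
  reference mean exactly (see above), and the one-factor copula reproduces
  marginals and internal consistency, not the exact joint distribution
  behind the reference per-category user counts.
- The head has no access to post order or timestamps; temporal dynamics of
  symptoms are out of scope.
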