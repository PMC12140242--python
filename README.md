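# ensembert

Infer per-item and overall **Beck Depression Inventory-II (BDI-II)** scores
from a user's social-media post history, with a retrieval-then-predict
pipeline built on frozen sentence embeddings.

## The scientific problem

The BDI-II is a 21-item self-report depression instrument. Each item probes
one symptom (sadness, pessimism, loss of energy, ...) through four choices
scored 0–3; the overall score is the sum (0–63) and is banded into four
severity categories (Minimal 0–13 / Mild 14–19 / Moderate 20–28 / Severe ≥29).
Given only a user's post history, the task is to predict the score of every
item, the overall score, and the severity category — the setting of the eRisk
shared tasks, where annotated users come with hundreds of highly variable
posts (reference cohort: mean 274, median 165, std 265 posts per user).

## The model

For each (user, item) pair:

1. **Zero-shot dense retrieval** — every post is embedded by a frozen
   sentence encoder; the top *k* = 20 posts by raw dot product with the item
   *description* embedding are retained (ties break by ascending post index).
2. **Cross-attention** — the description embedding attends over the
   retrieved posts: `α = softmax(D·RPᵀ)`, context `CA = α·RP`.
3. **Sub-model A** — cosine similarities between `CA` and the four choice
   embeddings, softmaxed with a trainable temperature, give a first
   probability vector over the scores 0–3.
4. **Sub-model B** — the choice embeddings weighted by sub-model A's
   probabilities, plus the attention-weighted post mean, pass through a
   linear + softmax output layer.
5. **Ensemble** — an affine + softmax map over the concatenated sub-model
   probabilities yields the final distribution; the predicted score is its
   argmax (ties break toward the lower score).

Only the small head (output layer, ensemble layer, temperature) is trained,
by mini-batch gradient descent on `λ_A·CE(p_A) + λ_final·CE(p_final)`. The
encoder stays frozen, so attention weights and choice cosines are fixed
features — the whole head runs in NumPy with hand-derived gradients and an
Adam optimizer, no deep-learning framework required. Attention weights are
exported per prediction for interpretability.

Because the annotated eRisk data are access-restricted, the package ships a
first-class **synthetic cohort generator** that emulates the published
summary statistics (lognormal post counts, 25/35/23/17% score marginals via
a one-factor Gaussian copula, Cronbach's α in the 0.9+ regime) and plants a
controllable semantic signal in the posts, so the full pipeline can be
validated by parameter recovery.

## Worked example

```python
from ensembert.model import TrainConfig
from ensembert.pipeline import RunConfig, run_experiment
from ensembert.psychometrics import cronbach_alpha
from ensembert.synthetic_data import CohortConfig, generate_cohort

config = RunConfig(
    workdir="example_run",
    synthetic=CohortConfig(
        n_users=200,
        post_count_median=30.0,   # reference shape (165/265) scaled ~5.5x down
        post_count_std=48.0,
        signal_strength=0.8,
        inter_item_correlation=0.6,
        seed=7,
    ),
    k=20,
    split_seed=7,
    train=TrainConfig(epochs=120, seed=7, patience=20),
)
report, manifest = run_experiment(config)
print(report.to_table())
print(f"majority baseline: {report.baseline_accuracy:.3f} ({report.baseline_category.label})")

alpha = cronbach_alpha(generate_cohort(config.synthetic).score_matrix())
print(f"Cronbach's alpha of the generated scores: {alpha:.3f}")
```

Output (deterministic for these seeds):

```
MAE_item	MSE_item	MAE_overall	RMSE_overall	ACC_category	F1_category	MSE_category
0.610	1.071	7.050	9.279	0.550	0.510	1.025
majority baseline: 0.200 (Severe)
Cronbach's alpha of the generated scores: 0.948
```

On this planted-signal cohort the trained head reaches category accuracy
0.550 against a 0.200 majority-class baseline, with item-level MAE 0.610 on
the 0–3 scale. `example_run/` receives the trained parameters, per-item and
per-user predictions, attention weights, the evaluation report, and a
manifest with SHA-256 hashes of every output (reruns are byte-identical).

The same pipeline is available from the command line:

```bash
ensembert simulate --n-users 100 --seed 0 --out data/
ensembert run --config run_config.json
ensembert psychometrics --scores data/gold_scores.csv --out reliability.csv
```

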