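# Methods

This note documents the modelling choices, defaults and limitations of
the package, in the order the pipeline runs.

## Data model and standardization

Interactions are (user, recipe, rating 0–5, order) records; ratings are
validated on load, duplicate (user, recipe) pairs keep the first
occurrence, and within-user order follows file row order (or the `date`
column in the Food.com dialect). Recipe nutrition is always held in the
canonical component order *calories, total fat, saturated fat, sodium,
protein, sugar, carbohydrates*; the Food.com bracketed-list order is
remapped on ingestion. Nutrient units are treated as unitless reals —
standardization and correlation are both scale-covariant, so mixed
units (kcal plus %DV) change nothing downstream.

Standardization is column-wise (x − μ)/σ with the **population** σ over
the whole recipe corpus; a zero-variance column maps to zeros rather
than dividing by zero. The same fitted (μ, σ) transform is reused for
user profiles so recipe and user nutrition features share one scale.

## Similarity graph

Cosine similarity is computed on the **standardized** vectors, and a
pair is linked when cos > 0.98 (strict). Standardized vectors can have
negative components; the signed cosine is thresholded as-is. A recipe
sitting exactly at every column mean standardizes to the zero vector,
whose cosine is undefined; it is assigned similarity 0 and can never
enter the graph (logged). The all-pairs computation runs blockwise above
20 000 recipes to bound memory; blockwise and exact results are
identical by construction and by test.

Similar edges carry weight 1 by default (`cosine_weights=True` switches
to the cosine); rated edges carry the 0–5 rating (`rating_weights=False`
switches to 1).

## Preference profiles

λ_u is every recipe the user rated 5, in interaction order; users with
no 5-star rating fall back to their single first-interacted recipe. The
profile is the arithmetic mean of λ_u's raw nutrient vectors. Profiles
are computed from **training-partition interactions only**, so no
held-out pair leaks into the features used to predict it. Users that
appear only in validation/test receive the global mean profile (logged).
The raw-scale profile feeds the Pearson fit analysis; the standardized
variant feeds the model.

## Fusion

The product r ⊙ ϑ in the fusion stage is dimensionally impossible with
a 7-component ϑ and a width-16 recipe vector, so both nutrient inputs
pass through learned bias-free linear projections 7 → d_model (one for
recipe nutrients, one for user profiles). The three fused views —
[r_ϑ‖r], [r_ϑ‖ϑ], and their element-wise sum — form a 3-token sequence
processed by multi-head self-attention (Q = K = V), and the three output
tokens are **mean-pooled** into r̃; pooling is our choice, made because a
single vector is required downstream and the 3-token set has no order
semantics (hence also no positional encoding). `attention_mode="cross"`
instead uses the first view as query, the second as key and the sum as
value. Per-head width is d_k = 2·d_model/h. Defaults: d_model = 16
(the hidden size at which the hyperparameter study peaks), h = 2.

## Graph convolution and training

The node update is x′_i = W₁x_i + W₂ₜ Σ_{j∈Nₜ(i)} e_{j,i} x_j summed
over edge types t ∈ {rated, similar}, with a shared self-weight W₁ per
layer; a node with no neighbors keeps only its self term. Two layers
with a ReLU between them (the update rule itself is linear; the
activation between layers is standard practice and is not applied after
the last layer). During training each layer sees an independently
subsampled graph with at most `fanout = 5` neighbors per node and edge
type; evaluation uses the full graph.

Two stabilizations matter on weighted heterogeneous graphs: (a) each
row of the adjacency is normalized by its weighted degree
(`normalize_adjacency=True`), turning the neighbor sum into a weighted
mean — without it, rating-weighted sums (weight 5 × fanout 5 × 2
layers) scale activations by ~10² per layer and saturate the sigmoid;
(b) the optimization loss is the algebraically identical logit-space
form softplus(s) − y·s, which keeps gradients alive where σ(s)
saturates. The probability-space `bce_loss` and `score` functions are
the reported quantities. The final conv layer's initialization is
damped ×0.1 so random-init scores start near 0 and the initial loss
sits at ln 2 for balanced batches.

Negative sampling is 1:1 per positive, uniform over the recipes the
user never interacted with in **any** partition; training negatives are
resampled every epoch, validation/test negatives are frozen once per
fit. Optimization is Adam at lr = 10⁻² (full-batch updates on small
graphs converge within tens of epochs at this rate) for 60 epochs, with
the best-validation-AUC checkpoint restored at the end. Scores are
clamped to (10⁻⁷, 1 − 10⁻⁷); hard labels use threshold 0.5. All
randomness (split, init, neighbor and negative sampling) derives from
`random_state` via independent spawned generators, making fits
bit-reproducible.

Ablations: `NRKG-G` removes every nutrition input — plain learned
embeddings on the bipartite rating graph (the similarity edges are
nutrition-derived, so they are removed too); `NRKG-U` adds only
user profiles; `NRKG-R` adds only recipe-nutrient fusion plus the
similarity edges; `NRKG` is the full model. Widths are identical across
variants (ablated halves are replaced by free embeddings), so
differences reflect information content, not capacity. The model is
implemented on an in-package reverse-mode autodiff core over numpy
(`nrkg.autodiff`), verified by finite-difference gradient checks.

## Metrics

AUC is the tie-aware rank statistic (ties half-credited), equal to the
trapezoidal ROC area; both implementations ship and are cross-checked,
with scikit-learn as an independent oracle in tests. Precision, recall
and F1 define 0/0 as 0 (logged). Pearson correlation is the 7-component
textbook formula; the fit analysis always uses **raw-scale** profiles
and nutrients, since a correlation on standardized columns answers a
different question.

## Synthetic data generator

The generator emulates the statistical structure the preference module
assumes: users whose 5-star ratings concentrate on nutritionally
similar recipes. `n_archetypes = 4` nutritional regimes (high-protein,
high-sugar, high-fat, light) each get an anchor 7-vector drawn
log-normally — real nutrient data are right-skewed and non-negative, so
log-normal anchors give realistic standardization behavior. Each recipe
is its anchor plus Gaussian noise with per-component sd = 0.10 × the
anchor component (relative noise; a single absolute sd would be
negligible for calories and overwhelming for sugar), clipped at 0.

Each user belongs to one archetype and draws 12 distinct recipes,
picking from their own archetype with probability 0.7 (uniform
otherwise); an interaction is rated 5 with probability 0.7 when
archetypes match and 0.1 otherwise, other ratings uniform on 1–4. The
interaction bias is what makes held-out links predictable at all — with
archetype-blind interaction choice, held-out positives would be
statistically identical to sampled negatives and no model could exceed
AUC 0.5. Twelve interactions per user keeps the regime sparse (real
recipe-review data average ~3 per user) so that nutrition features
carry signal beyond pure collaborative filtering, while still giving
profiles a few 5-star recipes to average.

Defaults are 200 users × 300 recipes, the sizes used throughout the
tests and the acceptance script; the profile-recovery check runs at
500 × 800. What the generator does **not** emulate: recipe popularity
skew, temporal drift, rating noise correlated with exposure, text/
ingredient structure, and cold-start recipes. Passing tests therefore
demonstrate that the method recovers planted nutrition-driven
preference structure, not that it attains any particular accuracy on
real Food.com data.

## Known limitations

- Dense adjacency matrices bound practical graph size to a few thousand
  nodes; the design target is desk-scale experiments, not the full
  180k-recipe corpus.
- The ablation margins on synthetic data depend on interaction
  sparsity; at high interactions-per-user, collaborative signal alone
  approaches the full model.
- Absolute metric values under implicit-feedback evaluation depend on
  the negative-sampling protocol and are not comparable across
  protocols.
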