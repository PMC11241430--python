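# nrkg — nutrition-aware heterogeneous-graph food recommendation

`nrkg` implements a nutrition-related knowledge-graph recommender for
recipes. Classical recommenders learn only from who-interacted-with-what
and tend to recycle a user's past tastes; this method injects the
*nutritional content* of recipes into a graph neural link predictor, so
recommendations reflect both collaborative signal and each user's
nutritional preferences. It is aimed at researchers in food/nutrition
informatics and recommender systems who want a self-contained, CPU-only
reference implementation with a fully synthetic benchmark (no dataset
download needed).

## The model

Inputs are a user–recipe interaction table Θ (user, recipe, rating 0–5)
and a recipe table Z with a 7-component nutrient vector per recipe
(calories, total fat, saturated fat, sodium, protein, sugar,
carbohydrates).

1. **Recipe nutritional components ϑ** — the raw nutrient matrix θ is
   column-standardized, x_std = (x − μ)/σ (population σ; flat columns map
   to 0).
2. **Nutrition similarity graph ϰ** — recipes whose standardized vectors
   have cosine similarity above 0.98 are linked; together with the rated
   user–recipe edges (weighted by the rating T) this forms a
   heterogeneous undirected graph G.
3. **User preference profiles P** — for each user, the mean nutrient
   vector over their preferred recipes λ_u: every recipe rated 5, or the
   first-interacted recipe if they never rated a 5.
4. **Attention fusion** — each recipe's learned vector r is merged with
   its projected nutrients: r_ϑ = r ⊙ ϑ, then the three views
   [r_ϑ‖r], [r_ϑ‖ϑ] and their sum pass through multi-head scaled
   dot-product attention, softmax(QKᵀ/√d_k)V, giving the recipe embedding
   r̃. The user embedding is ũ = [u ‖ W·p_u].
5. **Graph convolution & scoring** — two layers of
   x′_i = W₁x_i + W₂ Σ_{j∈N(i)} e_{j,i} x_j (one neighbor weight per edge
   type) refine all node embeddings; a link scores
   ŷ = σ(ũ · r̃), trained with binary cross-entropy against observed
   interactions (y = 1) and per-user uniformly sampled non-interactions
   (y = 0).

Evaluation uses AUC, accuracy, precision, recall and F1 on held-out
interactions (6:2:2 record-level split), plus a Pearson-correlation
analysis of how well each user's profile matches the nutrients of
recipes they choose. Ablation variants isolate the two nutrition
modules: `NRKG-G` (neither), `NRKG-U` (profiles only), `NRKG-R`
(recipe nutrients only), `NRKG` (both).

## Worked example

```python
from nrkg import SyntheticConfig, generate_dataset, NRKGRecommender, pearson

data = generate_dataset(SyntheticConfig(seed=0))        # planted archetypes
model = NRKGRecommender(random_state=0).fit(data["interactions"], data["recipes"])
report = model.evaluate("test")
print(f"held-out AUC={report.auc:.4f}  ACC={report.acc:.4f}  F1={report.f1:.4f}")

pairs = [("u0", "r10"), ("u0", "r11")]
for pair, p in zip(pairs, model.predict_proba(pairs)):
    print(pair, f"interaction probability {p:.3f}")

rho = pearson((453, 39, 59, 19, 39, 45, 11), (95, 12, 0, 1, 0, 15, 1))
print(f"preference fit rho={rho:.4f}")
```

prints

```
held-out AUC=0.7446  ACC=0.7260  F1=0.7138
('u0', 'r10') interaction probability 0.772
('u0', 'r11') interaction probability 0.135
preference fit rho=0.9833
```

The AUC says the trained model ranks a random held-out interaction above
a random non-interaction ~74% of the time on the default synthetic
conditions; the two probabilities show a recipe matching u0's nutritional
archetype scoring far above a mismatched one; the last line is the
Pearson fit between a user preference profile and a recipe's nutrient
vector — values near 1 indicate the user gravitates toward recipes whose
nutrition mirrors their profile.

The same pipeline is scriptable from a shell:

```sh
nrkg simulate --seed 3 --out data/
nrkg build-graph --in data/ --out graph/
nrkg profiles --in data/ --out profiles.csv
nrkg train --in data/ --seed 3 --out ckpt/
nrkg evaluate --ckpt ckpt/ --report report.json
nrkg run --seed 3 --out run/        # all of the above in one go
```

Real data in the Kaggle Food.com export layout is supported via
`nrkg ingest --dialect foodcom`.

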