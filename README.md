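# kglink

Knowledge-graph link prediction for ontology-harmonized survey cohorts,
with a classical logistic-regression arm for comparison.

Surveys of health, diet and environmental exposures — the kind collected
by large environmental-health cohorts — can be harmonized to biomedical
ontologies (Mondo, HPO, FoodOn, ChEBI, ECTO, MAxO) and represented as a
heterogeneous knowledge graph: respondents and ontology terms are nodes,
and every positive answer is a typed edge such as
`Person:1234 —affected_by→ lansoprazole (CHEBI:6375)`.  `kglink`
implements a two-arm hypothesis-generation analysis over such graphs for
female reproductive disorders (FRDs: endometriosis, uterine fibroids,
ovarian cysts):

1. **Knowledge-graph arm.**  The largest component of the merged graph is
   embedded by DeepWalk (uniform random walks + skip-gram with negative
   sampling).  A random forest (501 trees, depth 15) classifies Hadamard
   edge embeddings of true edges against sampled non-edges — evaluated by
   AUROC on a connectivity-preserving 70/30 edge holdout — and, retrained
   on the full graph, scores every (disorder, variable) pair; scores
   above 0.8 become predicted links.
2. **Regression arm.**  Female respondents completing all three surveys
   are imputed with a missForest-style iterative random forest, reduced by
   elastic-net + permutation-importance feature selection, and fitted with
   a joint logistic model per disorder: odds ratios exp(β), Wald 95%
   intervals, Bonferroni-adjusted p-values, prevalence/missingness and
   variance inflation factors.

The two result sets are intersected per disorder by strict CURIE identity
(**exact matches**).  Because the original survey data are restricted, a
first-class synthetic-data module generates the study conditions: three
surveys with binary, ordinal-frequency (0–5) and free-text questions,
correlated answers via latent lifestyle profiles, partial completion,
missingness, comorbidity structure, and planted exposure→disorder effects
with known odds ratios (defaults 3.0 / 2.0 / 0.4) through an additive-logit
model, `logit P(D=1|Z) = a + Σ log(OR_k) Z_k`.

See `docs/methods.md` for the model details and design decisions.

## Worked example

```python
from kglink import SyntheticConfig, run_all

result = run_all(SyntheticConfig(seed=1), out_dir="out")
print(f"graph: {result.graph.n_nodes} nodes, {result.graph.n_edges} edges, "
      f"{result.components.n_components} components")
print(f"test AUROC: {result.auroc:.3f}")
print(f"predicted links (score > 0.8): {result.n_significant_links}")
print(f"exact matches with regression: {result.n_exact_matches}")
```

prints, for the standard bundle (2000 respondents, 300-term ontology):

```
graph: 2300 nodes, 12998 edges, 32 components
test AUROC: 0.992
predicted links (score > 0.8): 53
exact matches with regression: 1
```

2300 nodes are the 2000 respondents plus 300 ontology terms; beyond the
giant component, the 31 remaining components are the 31 respondents
(1.6%) with no mapped positive answer, which the largest-component step
removes.  AUROC 0.992 says held-out person–term
edges are almost perfectly separated from random non-edges.  Of the 53
above-threshold predicted links, one — the planted odds-ratio-3.0
environmental exposure on uterine fibroids in this seed's regression arm
(fitted OR 2.98, adjusted p = 1.3 × 10⁻⁴, cohort n = 430) — is also
Bonferroni-significant, giving one exact match.

The same pipeline is scriptable stage by stage:

```bash
kglink synth   --seed 1 --out bundle/
kglink build-kg --responses bundle/responses.tsv \
    --respondents bundle/respondents.tsv \
    --ontology-nodes bundle/ontology_nodes.tsv \
    --ontology-edges bundle/ontology_edges.tsv \
    --translation-key bundle/translation_key.tsv \
    --supplemental bundle/supplemental_links.tsv --out kg/
kglink embed   --graph kg/ --dim 32 --seed 13 --out emb.tsv
kglink predict --graph kg/ --emb emb.tsv --frd MONDO:0000002 --threshold 0.8 \
    --out predictions.tsv
kglink run-all --seed 1 --out out/      # everything at once
```

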