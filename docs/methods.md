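# Methods

`kglink` implements, end to end, a two-arm analysis for generating
hypotheses about exposures and comorbidities associated with female
reproductive disorders (FRDs: endometriosis, uterine fibroids, ovarian
cysts) from ontology-harmonized survey data, together with a synthetic
cohort generator that stands in for the restricted survey data the design
targets.

## The two arms

**Knowledge-graph arm.** Survey answers are translated into
(person, predicate, term) assertions through a curated translation key;
binary questions assert on affirmative answers, food-frequency questions
are binarized at any consumption, finite categorical questions map each
response option, and free-text answers (medication names) are resolved by
a deterministic lexical matcher over ontology labels and exact synonyms.
Assertions are merged with the full content of the ontologies (every term,
answered or not, plus all `subclass_of` edges) and with supplemental
food→agricultural-chemical (`applied_with`) and food→nutrient
(`contains_nutrient`) tables, restricted to foods actually probed by a
survey question.  The largest connected component — merging full
ontologies leaves many disconnected terms, and respondents with no mapped
positive answer are isolated person nodes — is embedded by DeepWalk-style
uniform random walks fed to a skip-gram model with negative sampling.  A
random forest (501 trees, maximum depth 15) is trained to discriminate
element-wise (Hadamard) combinations of endpoint vectors for true edges
versus uniformly sampled non-edges, evaluated by AUROC on a
connectivity-preserving 70/30 edge holdout, then retrained on the full
graph; every (disorder, candidate term) pair is scored and pairs above
0.8 are reported as predicted links.

**Regression arm.** The cohort is restricted to female respondents who
completed all three surveys.  Item missingness is imputed with an
iterative random-forest scheme (missForest): mean/mode initialization,
columns revisited in increasing-missingness order, per-column forests with
mtry = √p, stopping when the imputation-difference statistic (continuous
and categorical parts tracked separately) first increases.  Features are
then reduced in two stages — an elastic-net-penalized logistic regression
(mixing parameter 0.5, penalty strength by 5-fold cross-validation)
retains nonzero coefficients, and a class-weight-balanced random forest
ranks the survivors by permutation importance (20 permutations) on a
held-out third — and a single joint maximum-likelihood logistic model per
disorder reports exp(β) odds ratios, Wald 95% intervals and p-values,
Bonferroni-adjusted over the features actually fitted.  Ordinal
food-frequency items keep their 0–5 coding here (their reported mean
prevalence can exceed 1); the KG arm sees them binarized.  Variance
inflation factors come from regressing each fitted feature on the others;
singular designs leave the VIF unreported.

**Comparison.** For each disorder, predicted destinations and
Bonferroni-significant regression features are intersected by strict CURIE
identity ("exact matches").  An ancestor-aware mode exists but is off by
default and excluded from all acceptance checks.

## Synthetic cohort generator

The generator separates *instrument* randomness from *population*
randomness.  The instrument — the ontology (six rooted is_a DAGs: disease,
phenotype, food, chemical, environmental exposure, medical action; 50
terms per branch), the question plan (12 health, 10 internal, 8 external
questions by default), each question's response distribution, the
comorbidity wiring, and the supplemental link tables — is drawn once from
a fixed design seed (1842), so different population seeds replay the same
survey on a fresh cohort, as in a replication study.  The population —
2000 respondents by default, 67.1% female, independent per-survey
completion (health 0.95, internal 0.55, external 0.60, giving ≈31%
completing all three), exposures, disorder status, answers, and 2% MCAR
item missingness (an optional MAR mode ties missingness to the first
planted exposure, for stressing the imputer) — is drawn from the run seed.
A fixed seed therefore yields a byte-identical bundle.

Answers are correlated: each respondent belongs to one of five latent
lifestyle/health profiles, and every question's response probability gets
a per-profile logit shift (s.d. 1.5).  Without such correlation a survey
knowledge graph is an unlearnable random bipartite graph; with it, held-out
person–term edges become predictable, which is the regime the method
assumes (real cohorts exhibit strong co-answer structure).  Each disorder
additionally elevates two comorbid phenotype answers (conditional odds
ratio 4), mirroring the comorbidity signal that dominates real survey
analyses of these disorders.

Disorder status follows an additive-logit model restricted to female
respondents,

    logit P(D=1 | Z) = a_d + Σ_k log(OR_k) · Z_k,

with the intercept solved by root bisection so the marginal prevalence
among females matches its configured baseline exactly (the expectation is
taken over the exact exposure distribution, including its profile
structure).  Default baselines are 0.104 / 0.224 / 0.194 among females,
i.e. roughly 7% / 15% / 13% of the whole two-thirds-female population.
Planted exposures are Bernoulli per profile — each exposure's
per-profile logit shifts are part of the fixed instrument, reflecting how
exposures cluster with lifestyle — with the intercept solved so the
marginal exposure prevalence is exact.  Because the profiles
affect only exposure propensity and never enter the disorder model, the
marginal 2×2 odds ratio of each planted effect equals its conditional
odds ratio; this is verified to three decimals at n = 50000 in the test
suite.  The default effects plant odds ratios 3.0, 2.0 and 0.4 at
exposure prevalence 0.3: the strong environmental exposure on the most
prevalent disorder (uterine fibroids), a dietary association on
endometriosis, and a protective medication association (reached through a
free-text question and the lexical matcher) on ovarian cysts.

Free-text medication answers emit the chemical's label or its registered
brand-name synonym, with 5% typographical noise; the noisy answers are
expected to land in the unmapped-response report, exercising that path.

### What the generator does not emulate

No demographics beyond sex, no question-specific real-world marginals, no
survey logic (skip patterns), no longitudinal structure, no genetic data,
and no attempt to match the real instrument's 1842 questions — the
synthetic instrument has 30.  Passing tests therefore demonstrate that the
pipeline recovers known structure under the stated statistical assumptions
at desk scale, not that it would reproduce any specific finding on the
restricted data.

## Numerical and design choices

- **Skip-gram window = 2.**  The survey KG is essentially bipartite
  (persons ↔ terms); a window of 2 concentrates co-occurrence mass on
  shared-respondent (2-hop) paths, which carry the association signal the
  link-prediction arm must recover.  Wider windows blur this into diffuse
  community structure and measurably degrade both holdout AUROC and
  planted-signal recovery; a window of 1 destroys it entirely (adjacent
  walk positions are existing edges, so candidate center–center products
  carry no signal).
- **Embedding defaults**: dimension 32, 10 walks per node, walk length 40,
  5 negatives per positive (unigram^0.75 via alias sampling), 5 epochs,
  initial learning rate 0.025 with linear decay, word2vec-style dynamic
  window shrink.  Training is a single-threaded numba kernel with its own
  xorshift RNG; a fixed seed reproduces the matrix bit for bit.  Sigmoid
  and log-loss use a 2048-entry lookup table clipped at |x| = 8.
- **Edge classifier**: negatives are uniformly sampled non-edges at 1:1 by
  default (type-matched and degree-weighted samplers are available as
  config); each of the 501 trees fits on a 50% bootstrap subsample
  (subagging), a variance/efficiency tradeoff sized for single-CPU runs.
- **AUROC** is the Mann–Whitney rank statistic with half-credit for ties
  (exactly the exhaustive positive–negative pair count).
- **Connectivity-preserving holdout**: a seeded shuffled union-find pass
  pins a random spanning forest in the training set; any subset of the
  remaining edges is removable without changing the component count, so
  the achieved test fraction is capped at (E − V + c)/E and reaches the
  30% target on all standard bundles (mean degree ≈ 11).
- **Logistic fits** use Newton–Raphson (tol 1e-10) with L-BFGS and weakly
  regularized fallbacks; estimated |log-odds| SEs above 50 (or |β| > 20)
  are flagged as separation and reported with unbounded intervals rather
  than dropped.
- **Bonferroni m** is the number of features in the fitted model for that
  disorder, i.e. the tests actually performed.
- **Imputation defaults in the pipeline** are 50 trees and at most 5
  sweeps (the standalone function defaults to 100/10); on the standard
  cohort the stopping rule triggers after 2–4 sweeps.
- **Ties**: largest-component ties resolve to the component containing the
  lexicographically smallest node id; predictions sort by descending score
  then destination id; feature rankings break importance ties by CURIE.

## Problem sizes

Default analyses run at 2000 respondents (≈13000 edges, ≈2300-node
largest component), embedding in a few seconds and each forest fit in
under a minute on one CPU.  Parameter-recovery checks use 20000
respondents with a reduced question set; imputation benchmarks use
1000 × 10 mixed-type tables at 20% missingness.

## Known limitations

- The lexical matcher is exact-match after normalization; misspelled
  free-text answers are reported unmapped, not fuzzily resolved.
- Prediction scores are uncalibrated forest vote fractions; the 0.8
  threshold is a screening rule, and many candidates cluster near it
  ("many equally high scores" is an inherent property of this design).
- The regression arm fits no demographic covariates (none exist in the
  synthetic cohort beyond sex, which the cohort filter fixes).
- Directionality of predicted links is not inferable from the KG arm;
  only the regression arm reports signed (odds-ratio) effects.
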