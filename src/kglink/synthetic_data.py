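"""Synthetic survey cohort with planted exposure→disorder effects.

The generator emulates the statistical structure the two analysis arms
assume: three surveys (health, internal exposome, external exposome) with
binary, ordinal-frequency (0–5) and free-text questions; partial survey
completion; item missingness; a six-branch ontology (diseases, phenotypes,
foods, chemicals, environmental exposures, medical actions) with an is_a
DAG per branch; supplemental food→chemical and food→nutrient link tables;
and a set of planted disorder–exposure associations with stated odds
ratios.

Disorder status follows an additive-logit model

    logit P(D=1 | Z) = a_d + Σ_k log(OR_k) · Z_k

with independent Bernoulli exposures Z_k and the intercept a_d solved
numerically so that the marginal disorder prevalence (among female
respondents) matches the configured baseline.  Three disease terms play
the role of the female reproductive disorders of interest (labelled
endometriosis, uterine fibroid and ovarian cyst); planted exposures are
wired through ordinary survey questions so every effect is recoverable by
both the knowledge-graph arm and the regression arm.

Everything is driven by a single integer seed: a fixed seed yields a
byte-identical bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .ontology import BRANCHES, BRANCH_PREFIXES, Ontology, Term
from .ontology_mapping import (
    KeyEntry,
    ResponseRecord,
    ResponseType,
    SurveyQuestion,
    TranslationKey,
)

FRD_LABELS = ("endometriosis", "uterine fibroid", "ovarian cyst")

_BRANCH_WORDS = {
    "disease": "disease",
    "phenotype": "phenotype",
    "food": "food",
    "chemical": "chemical",
    "exposure": "exposure",
    "medical_action": "procedure",
}

_PREDICATE_BY_BRANCH = {
    "disease": "has_disease",
    "phenotype": "has_phenotype",
    "food": "consumes",
    "chemical": "affected_by",
    "exposure": "exposed_to",
    "medical_action": "undergone",
}


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedEffect:
    """A ground-truth disorder–exposure association."""

    disorder: str       # disease CURIE
    exposure: str       # exposure/food/chemical CURIE reachable from a question
    odds_ratio: float
    prevalence: float   # P(exposed)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe the standard desk-scale bundle: 2000 respondents,
    two-thirds female, survey completion rates asymmetric in favour of the
    health survey (≈31% complete all three), a 300-term ontology, and three
    planted effects with odds ratios 3.0 / 2.0 / 0.4 at exposure
    prevalence 0.3.
    """

    n_respondents: int = 2000
    female_fraction: float = 0.671
    survey_completion_probs: dict = field(
        default_factory=lambda: {"health": 0.95, "internal": 0.55, "external": 0.60}
    )
    n_ontology_terms: dict = field(
        default_factory=lambda: {b: 50 for b in BRANCHES}
    )
    max_parents: int = 2
    n_questions: dict = field(
        default_factory=lambda: {"health": 12, "internal": 10, "external": 8}
    )
    #: None -> three default effects (ORs 3.0, 2.0, 0.4 at prevalence 0.3)
    planted_effects: list | None = None
    #: latent respondent profiles driving answer correlations
    n_profiles: int = 5
    profile_effect_sd: float = 1.5
    #: comorbid phenotype answers per disorder, and their conditional OR
    n_comorbid_per_disorder: int = 2
    comorbidity_or: float = 4.0
    #: scalar applied to every disorder, or a sequence aligned with the FRD
    #: list; defaults give whole-population prevalences of roughly 7%, 15%
    #: and 13% once the two-thirds-female composition is applied
    baseline_prevalence: object = (0.104, 0.224, 0.194)
    missing_rate: float = 0.02
    missing_mechanism: str = "mcar"  # "mcar" | "mar"
    ordinal_max: int = 5
    #: population seed: respondents, exposures, disorders, answers, missingness
    seed: int = 0
    #: instrument seed: ontology, question plan, per-question response
    #: distributions, supplemental tables.  Fixed by default so that
    #: different population seeds replay the same survey instrument on a
    #: fresh cohort, as in a replication study.
    instrument_seed: int = 1842

    def validate(self) -> None:
        probs = [self.female_fraction, self.missing_rate,
                 *self.survey_completion_probs.values()]
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("all probabilities must lie in [0, 1]")
        if any(n < 1 for n in self.n_ontology_terms.values()):
            raise ConfigurationError("each ontology branch needs at least one term")
        if any(n < 0 for n in self.n_questions.values()):
            raise ConfigurationError("question counts must be non-negative")
        if self.planted_effects:
            for e in self.planted_effects:
                if e.odds_ratio <= 0:
                    raise ConfigurationError(f"odds ratio must be positive: {e}")
                if not 0.0 <= e.prevalence <= 1.0:
                    raise ConfigurationError(f"exposure prevalence outside [0,1]: {e}")
        if self.missing_mechanism not in ("mcar", "mar"):
            raise ConfigurationError(f"unknown missing mechanism {self.missing_mechanism!r}")
        if self.n_profiles < 1:
            raise ConfigurationError("n_profiles must be >= 1")
        if self.profile_effect_sd < 0 or self.comorbidity_or <= 0:
            raise ConfigurationError("profile/comorbidity parameters out of range")


@dataclass
class SyntheticBundle:
    """Everything one run of the pipeline consumes, plus the ground truth."""

    ontology: Ontology
    questions: list
    translation_key: TranslationKey
    responses: list
    respondents: pd.DataFrame
    supplemental_links: list   # (food CURIE, relation, chemical CURIE)
    truth: list                # list[PlantedEffect]
    frd_curies: list
    comorbidities: dict = field(default_factory=dict)  # question_id -> disorder

    def responses_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"respondent_id": r.respondent_id, "survey": r.survey,
                 "question_id": r.question_id,
                 "value": "" if r.value is None else r.value}
                for r in self.responses
            ],
            columns=["respondent_id", "survey", "question_id", "value"],
        )


def generate_ontology(config: SyntheticConfig) -> Ontology:
    """Six rooted is_a DAGs, one per branch, with unique CURIEs.

    Non-root terms draw one parent (occasionally two, giving a genuine DAG)
    uniformly from earlier terms of the same branch, so every ancestor
    closure terminates at the branch root.  The first three disease terms
    are labelled as the reproductive disorders of interest; chemicals carry
    one brand-name synonym each to exercise the lexical matcher.
    """
    config.validate()
    rng = np.random.default_rng([config.instrument_seed, 0])
    onto = Ontology()
    for branch in BRANCHES:
        n = config.n_ontology_terms[branch]
        prefix = BRANCH_PREFIXES[branch]
        word = _BRANCH_WORDS[branch]
        curies = [f"{prefix}:{i:07d}" for i in range(n)]
        for i, curie in enumerate(curies):
            if i == 0:
                onto.add(Term(curie, f"{word} root", branch))
                continue
            n_parents = 1
            if config.max_parents >= 2 and i >= 2 and rng.random() < 0.15:
                n_parents = 2
            idx = rng.choice(i, size=n_parents, replace=False)
            parents = tuple(sorted(curies[j] for j in idx))
            if branch == "disease" and 1 <= i <= len(FRD_LABELS):
                label = FRD_LABELS[i - 1]
            else:
                label = f"{word} {i:04d}"
            synonyms = (f"{word}brand {i:04d}",) if branch == "chemical" else ()
            onto.add(Term(curie, label, branch, parents, synonyms))
    return onto


def frd_curies_of(ontology: Ontology) -> list:
    """CURIEs of the reproductive-disorder terms present in the ontology."""
    by_label = {ontology.resolve(c).label: c for c in ontology.branch_terms("disease")}
    return [by_label[lab] for lab in FRD_LABELS if lab in by_label]


# ---------------------------------------------------------------------------
# question / key construction


@dataclass
class _QuestionPlan:
    question: SurveyQuestion
    branch: str
    curie: str | None          # None for free-text questions
    pool: tuple = ()           # candidate chemicals for free-text questions


def _plan_questions(config: SyntheticConfig, ontology: Ontology, rng) -> tuple[list, list]:
    """Assign each question a survey, response type and target ontology term."""
    frds = frd_curies_of(ontology)
    nonroot = {
        b: [c for c in sorted(ontology.branch_terms(b))
            if ontology.resolve(c).parents]
        for b in BRANCHES
    }
    plans: list[_QuestionPlan] = []

    # health survey: disorder outcomes first, then diseases/phenotypes/procedures
    n_health = config.n_questions.get("health", 0)
    n_frd = min(len(frds), n_health)
    other_disease = [c for c in nonroot["disease"] if c not in frds]
    pools = {"disease": other_disease,
             "phenotype": list(nonroot["phenotype"]),
             "medical_action": list(nonroot["medical_action"])}
    cycle = ("disease", "phenotype", "medical_action")
    for i in range(n_health):
        qid = f"H{i:03d}"
        if i < n_frd:
            curie, branch = frds[i], "disease"
        else:
            branch = cycle[(i - n_frd) % len(cycle)]
            if not pools[branch]:
                raise ConfigurationError(f"branch {branch} too small for question plan")
            j = rng.integers(len(pools[branch]))
            curie = pools[branch].pop(int(j))
        q = SurveyQuestion(qid, "health", ResponseType.binary,
                           topic=ontology.resolve(curie).label)
        plans.append(_QuestionPlan(q, branch, curie))

    # internal survey: food-frequency questions plus free-text medication questions
    n_internal = config.n_questions.get("internal", 0)
    n_med = n_internal // 3
    n_food = n_internal - n_med
    food_pool = list(nonroot["food"])
    chem_pool = list(nonroot["chemical"])
    for i in range(n_food):
        if not food_pool:
            raise ConfigurationError("food branch too small for question plan")
        j = rng.integers(len(food_pool))
        curie = food_pool.pop(int(j))
        q = SurveyQuestion(f"I{i:03d}", "internal", ResponseType.ordinal_frequency,
                           topic=ontology.resolve(curie).label)
        plans.append(_QuestionPlan(q, "food", curie))
    for i in range(n_med):
        k = min(4, len(chem_pool))
        if k == 0:
            raise ConfigurationError("chemical branch too small for question plan")
        idx = rng.choice(len(chem_pool), size=k, replace=False)
        pool = tuple(chem_pool[int(j)] for j in sorted(idx))
        for c in pool:
            chem_pool.remove(c)
        q = SurveyQuestion(f"I{n_food + i:03d}", "internal", ResponseType.free_text,
                           topic="medication use")
        plans.append(_QuestionPlan(q, "chemical", None, pool))

    # external survey: binary environmental-exposure questions
    exp_pool = list(nonroot["exposure"])
    for i in range(config.n_questions.get("external", 0)):
        if not exp_pool:
            raise ConfigurationError("exposure branch too small for question plan")
        j = rng.integers(len(exp_pool))
        curie = exp_pool.pop(int(j))
        q = SurveyQuestion(f"E{i:03d}", "external", ResponseType.binary,
                           topic=ontology.resolve(curie).label)
        plans.append(_QuestionPlan(q, "exposure", curie))

    key = TranslationKey()
    for p in plans:
        predicate = _PREDICATE_BY_BRANCH[p.branch]
        if p.question.response_type is ResponseType.free_text:
            entry = KeyEntry(p.question.question_id, p.question.response_type,
                             predicate, free_text=True)
        else:
            entry = KeyEntry(p.question.question_id, p.question.response_type,
                             predicate, curie=p.curie)
        key.entries[p.question.question_id] = entry
    return plans, key


def default_planted_effects(config: SyntheticConfig, plans: list, frds: list) -> list:
    """Three effects: a strong environmental risk exposure (OR 3) on the
    most prevalent disorder, a moderate dietary association (OR 2), and a
    protective medication association (OR 0.4), all at exposure
    prevalence 0.3."""
    ext = [p for p in plans if p.branch == "exposure"]
    foods = [p for p in plans if p.branch == "food"]
    meds = [p for p in plans if p.pool]
    effects = []
    # frds order is (endometriosis, uterine fibroid, ovarian cyst); the
    # strong exposure effect goes on the fibroid outcome, whose higher
    # prevalence mirrors where the largest odds ratios are reported
    if len(frds) > 1 and ext:
        effects.append(PlantedEffect(frds[1], ext[0].curie, 3.0, 0.3))
    elif frds and ext:
        effects.append(PlantedEffect(frds[0], ext[0].curie, 3.0, 0.3))
    if frds and foods:
        effects.append(PlantedEffect(frds[0], foods[0].curie, 2.0, 0.3))
    if len(frds) > 2 and meds:
        effects.append(PlantedEffect(frds[2], meds[0].pool[0], 0.4, 0.3))
    return effects


def _solve_intercept(effects: list, baseline: float, profile_probs=None) -> float:
    """Intercept of the additive-logit model matching a marginal prevalence.

    The marginal is the exact expectation over the 2^k exposure combinations
    (Bernoulli per latent profile when ``profile_probs`` — one row of
    per-profile exposure probabilities per effect — is given, with uniform
    profile weights); solved by root bisection.
    """
    if not 0.0 < baseline < 1.0:
        raise ConfigurationError(f"baseline prevalence must be in (0,1): {baseline}")
    k = len(effects)
    combos = np.array(np.meshgrid(*[[0, 1]] * k)).T.reshape(-1, k) if k else np.zeros((1, 0))
    log_ors = np.array([np.log(e.odds_ratio) for e in effects])
    if profile_probs is None:
        probs = np.array([[e.prevalence for e in effects]])       # (1, k)
    else:
        probs = np.asarray(profile_probs).T                       # (K, k)

    def marginal(a: float) -> float:
        # average over profiles of the exact expectation over combinations
        w = np.prod(np.where(combos[None, :, :] == 1,
                             probs[:, None, :], 1 - probs[:, None, :]), axis=2)
        return float((w * expit(a + combos @ log_ors)[None, :]).sum(axis=1).mean()) - baseline

    return brentq(marginal, -30.0, 30.0)


def _solve_exposure_intercept(prev: float, delta: np.ndarray) -> float:
    """Intercept making mean-over-profiles of expit(a + delta) equal ``prev``."""
    if prev <= 0.0 or prev >= 1.0:
        raise ConfigurationError(f"exposure prevalence must be in (0,1): {prev}")
    return brentq(lambda a: float(np.mean(expit(a + delta))) - prev, -30.0, 30.0)


# ---------------------------------------------------------------------------
# population


def _typo(text: str, rng) -> str:
    """One random character insertion, for lexical-matcher stress."""
    i = int(rng.integers(len(text) + 1))
    ch = chr(ord("a") + int(rng.integers(26)))
    return text[:i] + ch + text[i:]


def generate_population(config: SyntheticConfig, ontology: Ontology) -> SyntheticBundle:
    """Draw a full respondent population and package it as a bundle.

    Exposure indicators are Bernoulli(prevalence); disorder indicators come
    from the additive-logit model (females only — the disorders modelled are
    female reproductive disorders); survey completion is independent per
    survey; answered items are missing completely at random at
    ``missing_rate`` (or MAR, tied to the first planted exposure).
    """
    config.validate()
    # instrument stream: survey design, response distributions, link tables
    irng = np.random.default_rng([config.instrument_seed, 1])
    # population stream: everything respondent-level
    rng = np.random.default_rng([config.seed, 2])
    n = config.n_respondents

    plans, key = _plan_questions(config, ontology, irng)
    frds = frd_curies_of(ontology)

    effects = config.planted_effects
    if effects is None:
        effects = default_planted_effects(config, plans, frds)
    question_curies = {p.curie for p in plans if p.curie} | {
        c for p in plans for c in p.pool
    }
    bad = [e for e in effects
           if e.exposure not in question_curies or e.disorder not in ontology.terms]
    if bad:
        raise ConfigurationError(
            "planted effects reference CURIEs not reachable from any question "
            "or absent from the ontology: "
            + "; ".join(f"{e.disorder}←{e.exposure}" for e in bad)
        )

    # respondents
    ids = np.array([f"P{i:05d}" for i in range(n)])
    female = rng.random(n) < config.female_fraction
    completed = {
        s: rng.random(n) < config.survey_completion_probs.get(s, 1.0)
        for s in ("health", "internal", "external")
    }
    respondents = pd.DataFrame(
        {"respondent_id": ids,
         "sex": np.where(female, "female", "male"),
         "completed_health": completed["health"],
         "completed_internal": completed["internal"],
         "completed_external": completed["external"]}
    )

    # latent lifestyle/health profiles drive correlations between answers,
    # exposures (and through them disorders); disorders additionally elevate
    # a couple of comorbid phenotype answers
    profiles = rng.integers(config.n_profiles, size=n)

    # planted exposures, in effect order: Bernoulli per profile (each
    # exposure's lifestyle dependence is part of the fixed instrument),
    # intercept solved so the marginal prevalence is exact
    exposure_z: dict[str, np.ndarray] = {}
    exposure_profile_probs: dict[str, np.ndarray] = {}
    for e in effects:
        if e.exposure not in exposure_z:
            delta = irng.normal(0.0, config.profile_effect_sd, size=config.n_profiles)
            a = _solve_exposure_intercept(e.prevalence, delta)
            exposure_profile_probs[e.exposure] = expit(a + delta)
            exposure_z[e.exposure] = (
                rng.random(n) < exposure_profile_probs[e.exposure][profiles]
            )

    # disorder indicators from the additive-logit model (female respondents)
    baselines = config.baseline_prevalence
    if np.isscalar(baselines):
        baselines = [float(baselines)] * len(frds)
    disorder_d: dict[str, np.ndarray] = {}
    for d, base in zip(frds, baselines):
        d_effects = [e for e in effects if e.disorder == d]
        pz = [exposure_profile_probs[e.exposure] for e in d_effects]
        a = _solve_intercept(d_effects, float(base), pz if pz else None)
        logits = np.full(n, a)
        for e in d_effects:
            logits += np.log(e.odds_ratio) * exposure_z[e.exposure]
        disorder_d[d] = (rng.random(n) < expit(logits)) & female

    # instrument-level response distributions: a base rate per question and
    # a per-profile logit shift, drawn once for the instrument
    def _question_logits(base_lo: float, base_hi: float) -> np.ndarray:
        base = irng.uniform(base_lo, base_hi)
        delta = irng.normal(0.0, config.profile_effect_sd, size=config.n_profiles)
        return logit(base) + delta

    question_logits: dict[str, np.ndarray] = {}
    for p in plans:
        q = p.question
        if q.response_type is ResponseType.binary:
            question_logits[q.question_id] = _question_logits(0.05, 0.4)
        elif q.response_type is ResponseType.ordinal_frequency:
            question_logits[q.question_id] = _question_logits(0.4, 0.8)
        else:
            question_logits[q.question_id] = _question_logits(0.1, 0.3)

    # which phenotype questions are comorbid with which disorder is part of
    # the simulated biology and stays fixed with the instrument
    comorbid: dict[str, str] = {}  # question_id -> disorder CURIE
    avail = [p for p in plans
             if p.branch == "phenotype" and p.curie not in exposure_z]
    for d in frds:
        for _ in range(config.n_comorbid_per_disorder):
            if not avail:
                break
            j = int(irng.integers(len(avail)))
            comorbid[avail.pop(j).question.question_id] = d

    # answers, question by question in plan order
    values: dict[str, np.ndarray] = {}
    for p in plans:
        q = p.question
        if q.response_type is ResponseType.binary:
            if p.curie in disorder_d:
                yes = disorder_d[p.curie]
            elif p.curie in exposure_z:
                yes = exposure_z[p.curie]
            else:
                logits = question_logits[q.question_id][profiles]
                if q.question_id in comorbid:
                    logits = logits + np.log(config.comorbidity_or) * disorder_d[
                        comorbid[q.question_id]]
                yes = rng.random(n) < expit(logits)
            values[q.question_id] = np.where(yes, "Yes", "No").astype(object)
        elif q.response_type is ResponseType.ordinal_frequency:
            if p.curie in exposure_z:
                consuming = exposure_z[p.curie]
            else:
                consuming = rng.random(n) < expit(question_logits[q.question_id][profiles])
            freq = 1 + rng.binomial(config.ordinal_max - 1, 0.45, size=n)
            values[q.question_id] = np.where(consuming, freq, 0).astype(object)
        else:  # free text medication question
            planted = [c for c in p.pool if c in exposure_z]
            using = rng.random(n) < expit(question_logits[q.question_id][profiles])
            choice_idx = rng.integers(len(p.pool), size=n)
            use_synonym = rng.random(n) < 0.3
            add_typo = rng.random(n) < 0.05
            out = np.empty(n, dtype=object)
            for i in range(n):
                curie = None
                if planted and exposure_z[planted[0]][i]:
                    curie = planted[0]
                elif using[i]:
                    others = [c for c in p.pool if c not in planted]
                    if others:
                        curie = others[choice_idx[i] % len(others)]
                if curie is None:
                    out[i] = ""
                    continue
                term = ontology.resolve(curie)
                text = term.synonyms[0] if (use_synonym[i] and term.synonyms) else term.label
                if add_typo[i]:
                    text = _typo(text, rng)
                out[i] = text
            values[q.question_id] = out

    # missingness among answered (completed-survey) items
    if config.missing_rate > 0:
        if config.missing_mechanism == "mar" and effects:
            z = exposure_z[effects[0].exposure]
            prev = effects[0].prevalence
            hi = min(1.0, 2.0 * config.missing_rate)
            lo = max(0.0, (config.missing_rate - hi * prev) / max(1e-12, 1 - prev))
            p_miss = np.where(z, hi, lo)
        else:
            p_miss = np.full(n, config.missing_rate)
        missing = {
            p.question.question_id: rng.random(n) < p_miss for p in plans
        }
    else:
        missing = {p.question.question_id: np.zeros(n, dtype=bool) for p in plans}

    by_survey: dict[str, list] = {"health": [], "internal": [], "external": []}
    for p in plans:
        by_survey[p.question.survey].append(p.question)

    responses: list[ResponseRecord] = []
    for i in range(n):
        rid = ids[i]
        for survey in ("health", "internal", "external"):
            if not completed[survey][i]:
                continue
            for q in by_survey[survey]:
                qid = q.question_id
                val = None if missing[qid][i] else values[qid][i]
                responses.append(ResponseRecord(rid, survey, qid, val))

    # supplemental link tables: agricultural chemicals applied to crops and
    # per-food nutrient content (nutrient tables are dense — each food
    # carries several nutrient entries)
    chems = sorted(c for c in ontology.branch_terms("chemical")
                   if ontology.resolve(c).parents)
    supplemental = []
    for food in sorted(ontology.branch_terms("food")):
        if not ontology.resolve(food).parents or not chems:
            continue
        n_applied = irng.poisson(2.0)
        n_nutrient = irng.poisson(6.0)
        for relation, count in (("applied_with", n_applied),
                                ("contains_nutrient", n_nutrient)):
            if count == 0:
                continue
            idx = irng.choice(len(chems), size=min(count, len(chems)), replace=False)
            for j in sorted(idx):
                supplemental.append((food, relation, chems[int(j)]))

    return SyntheticBundle(
        ontology=ontology,
        questions=[p.question for p in plans],
        translation_key=key,
        responses=responses,
        respondents=respondents,
        supplemental_links=supplemental,
        truth=list(effects),
        frd_curies=frds,
        comorbidities=comorbid,
    )


def generate_bundle(config: SyntheticConfig) -> SyntheticBundle:
    """Convenience wrapper: ontology + population in one call."""
    return generate_population(config, generate_ontology(config))


# ---------------------------------------------------------------------------
# serialization


def write_bundle(bundle: SyntheticBundle, out_dir) -> dict:
    """Write all bundle artifacts as TSV files; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ontology_nodes": out / "ontology_nodes.tsv",
        "ontology_edges": out / "ontology_edges.tsv",
        "questions": out / "questions.tsv",
        "translation_key": out / "translation_key.tsv",
        "responses": out / "responses.tsv",
        "respondents": out / "respondents.tsv",
        "supplemental": out / "supplemental_links.tsv",
        "truth": out / "truth.tsv",
    }
    bundle.ontology.write_tsv(paths["ontology_nodes"], paths["ontology_edges"])
    pd.DataFrame(
        [{"question_id": q.question_id, "survey": q.survey,
          "response_type": q.response_type.value, "topic": q.topic}
         for q in bundle.questions]
    ).to_csv(paths["questions"], sep="\t", index=False)
    bundle.translation_key.write_tsv(paths["translation_key"])
    bundle.responses_frame().to_csv(paths["responses"], sep="\t", index=False)
    bundle.respondents.to_csv(paths["respondents"], sep="\t", index=False)
    pd.DataFrame(bundle.supplemental_links,
                 columns=["subject", "predicate", "object"]
                 ).to_csv(paths["supplemental"], sep="\t", index=False)
    pd.DataFrame(
        [{"disorder": e.disorder, "exposure": e.exposure,
          "odds_ratio": e.odds_ratio, "prevalence": e.prevalence}
         for e in bundle.truth]
    ).to_csv(paths["truth"], sep="\t", index=False)
    return paths
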