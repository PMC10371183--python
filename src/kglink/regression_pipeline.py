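"""Comparison arm: cohort cleaning, imputation, selection, logistic ORs.

Mirrors a classical epidemiological workflow over the same ontology-aligned
survey variables the knowledge-graph arm consumes:

1. restrict to female respondents who completed all three surveys;
2. impute item missingness with an iterative random-forest scheme
   (missForest-style: per-column forests, increasing-missingness column
   order, stop when the imputation-difference statistic first increases);
3. select features with an elastic-net-penalized logistic stage followed by
   permutation importance of a class-weighted random forest on a held-out
   third;
4. fit one joint maximum-likelihood logistic model per disorder and report
   per-feature odds ratios, Wald confidence intervals and p-values,
   Bonferroni-adjusted p-values, observed prevalence/missingness, and
   variance inflation factors.

Feature values keep their ordinal 0–5 coding (food-frequency items) or 0/1
coding (everything else); the outcome is the binary self-reported disorder
status.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import (
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import train_test_split

from .ontology import Ontology
from .ontology_mapping import ResponseType, TranslationKey, match_free_text

logger = logging.getLogger(__name__)

TABLE_COLUMNS = [
    "Odds", "95% CI lower limit", "95% CI upper limit", "Standard Error",
    "Survey question topic", "Class ID", "p-value", "Mean prevalence",
    "Sd prevalence", "Missingness rate", "Mean VIF",
]


class CohortError(ValueError):
    pass


@dataclass
class FeatureTable:
    """Respondent-by-feature matrix with outcomes and pre-imputation state.

    ``features`` holds current (possibly imputed) values with NaN for
    missing cells; ``raw`` preserves the pre-imputation matrix so observed
    prevalence and missingness are always reported from the data actually
    collected.  ``kinds`` maps each feature CURIE to "binary" or "ordinal".
    """

    features: pd.DataFrame
    outcomes: pd.DataFrame
    kinds: dict
    raw: pd.DataFrame | None = None
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.raw is None:
            self.raw = self.features.copy()

    @property
    def n(self) -> int:
        return len(self.features)

    def missingness(self) -> pd.Series:
        return self.raw.isna().mean()


@dataclass
class RegressionResult:
    feature: str
    label: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    standard_error: float
    p_raw: float
    p_adjusted: float
    mean_prevalence: float
    sd_prevalence: float
    missingness_rate: float
    mean_vif: float | None
    separation_flag: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError(
                f"inconsistent CI for {self.feature}: "
                f"{self.ci_low} <= {self.odds_ratio} <= {self.ci_high} fails"
            )


def results_frame(results) -> pd.DataFrame:
    """Render regression results in the standard report column layout."""
    rows = []
    for r in results:
        rows.append({
            "Odds": r.odds_ratio,
            "95% CI lower limit": r.ci_low,
            "95% CI upper limit": r.ci_high,
            "Standard Error": r.standard_error,
            "Survey question topic": r.label,
            "Class ID": r.feature,
            "p-value": r.p_adjusted,
            "Mean prevalence": r.mean_prevalence,
            "Sd prevalence": r.sd_prevalence,
            "Missingness rate": r.missingness_rate,
            "Mean VIF": r.mean_vif,
        })
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


# ---------------------------------------------------------------------------
# cohort construction


def clean_cohort(
    respondents: pd.DataFrame,
    responses,
    key: TranslationKey,
    ontology: Ontology,
    outcome_curies,
) -> FeatureTable:
    """Female, all-three-surveys cohort over KG-aligned features.

    ``respondents`` needs ``respondent_id``, ``sex`` and per-survey
    ``completed_*`` flags.  Binary questions code Yes/No as 1/0;
    ordinal-frequency questions keep their 0–5 level; free-text questions
    expand into one binary feature per lexically resolved CURIE.  Questions
    whose CURIE is an outcome become outcome columns instead of features.
    """
    frame = respondents.copy()
    required = {"respondent_id", "sex", "completed_health",
                "completed_internal", "completed_external"}
    missing_cols = required - set(frame.columns)
    if missing_cols:
        raise CohortError(f"respondent table lacks columns: {sorted(missing_cols)}")

    females = frame[frame["sex"] == "female"]
    if females.empty:
        raise CohortError("cohort empty after the female-only filter")
    complete = females[
        females["completed_health"]
        & females["completed_internal"]
        & females["completed_external"]
    ]
    if complete.empty:
        raise CohortError("cohort empty after the all-three-surveys filter")
    ids = list(complete["respondent_id"])
    id_set = set(ids)

    outcome_curies = list(outcome_curies)
    binary_cols: dict[str, dict] = {}
    ordinal_cols: dict[str, dict] = {}
    freetext_cols: dict[str, dict] = {}
    freetext_missing: dict[str, set] = {}
    labels: dict[str, str] = {}

    for rec in responses:
        if rec.respondent_id not in id_set or rec.question_id not in key:
            continue
        entry = key[rec.question_id]
        val = rec.value
        is_missing = val is None or (isinstance(val, float) and pd.isna(val))
        if entry.response_type is ResponseType.binary:
            col = binary_cols.setdefault(entry.curie, {})
            if is_missing:
                col.setdefault(rec.respondent_id, np.nan)
            else:
                norm = val.strip().casefold() if isinstance(val, str) else val
                col[rec.respondent_id] = 1.0 if norm in ("yes", "y", "true", "1", 1, True) else 0.0
        elif entry.response_type is ResponseType.ordinal_frequency:
            col = ordinal_cols.setdefault(entry.curie, {})
            if is_missing:
                col.setdefault(rec.respondent_id, np.nan)
            else:
                col[rec.respondent_id] = float(val)
        elif entry.response_type is ResponseType.free_text:
            if is_missing:
                freetext_missing.setdefault(rec.question_id, set()).add(rec.respondent_id)
                continue
            curie = match_free_text(str(val), ontology)
            if curie is not None:
                freetext_cols.setdefault(curie, {"_questions": set()})
                freetext_cols[curie][rec.respondent_id] = 1.0
                freetext_cols[curie]["_questions"].add(rec.question_id)

    data: dict[str, pd.Series] = {}
    kinds: dict[str, str] = {}
    for curie, col in binary_cols.items():
        data[curie] = pd.Series(col, dtype=float)
        kinds[curie] = "binary"
    for curie, col in ordinal_cols.items():
        data[curie] = pd.Series(col, dtype=float)
        kinds[curie] = "ordinal"
    for curie, col in freetext_cols.items():
        qids = col.pop("_questions")
        s = pd.Series(0.0, index=ids)
        s.update(pd.Series(col, dtype=float))
        # answers lost to missingness stay unknown rather than negative
        for qid in qids:
            missing_ids = freetext_missing.get(qid, set())
            s.loc[s.index.isin(list(missing_ids)) & (s == 0.0)] = np.nan
        data[curie] = s
        kinds[curie] = "binary"

    features = pd.DataFrame(index=pd.Index(ids, name="respondent_id"))
    for curie in sorted(data):
        features[curie] = data[curie].reindex(ids)
        labels[curie] = ontology.resolve(curie).label if curie in ontology else curie

    outcomes = pd.DataFrame(index=features.index)
    for curie in outcome_curies:
        if curie in features.columns:
            outcomes[curie] = features.pop(curie)
        else:
            raise CohortError(f"outcome {curie} has no corresponding question column")
    return FeatureTable(features=features, outcomes=outcomes, kinds=kinds, labels=labels)


# ---------------------------------------------------------------------------
# missForest-style imputation


def impute_missforest(
    table: FeatureTable,
    max_iter: int = 10,
    n_trees: int = 100,
    seed: int = 0,
) -> FeatureTable:
    """Iterative random-forest imputation of the feature matrix.

    Missing cells are initialized with the column mean (ordinal) or mode
    (binary); columns are then revisited in order of increasing missingness,
    each fitted on all other columns over its observed rows and predicted
    over its missing rows.  Iteration stops as soon as the imputation
    difference statistic rises — separately tracked for the continuous part
    (normalized squared change) and the categorical part (fraction of
    changed cells) — and the matrix from just before the degradation is
    returned.  Observed cells are never modified; all-missing columns are
    dropped with a warning.
    """
    X = table.features.copy()
    mask = X.isna()
    all_missing = [c for c in X.columns if mask[c].all()]
    if all_missing:
        warnings.warn(f"dropping all-missing columns: {all_missing}", stacklevel=2)
        X = X.drop(columns=all_missing)
        mask = mask.drop(columns=all_missing)
    if not mask.to_numpy().any():
        return FeatureTable(features=X, outcomes=table.outcomes,
                            kinds=table.kinds, raw=table.raw, labels=table.labels)

    kinds = {c: table.kinds.get(c, "ordinal") for c in X.columns}
    for c in X.columns:
        if not mask[c].any():
            continue
        observed = X.loc[~mask[c], c]
        if kinds[c] == "binary":
            fill = observed.mode().iloc[0] if not observed.mode().empty else 0.0
        else:
            fill = observed.mean()
        X.loc[mask[c], c] = fill

    order = [c for c in mask.mean().sort_values(kind="stable").index if mask[c].any()]
    cont_cols = [c for c in order if kinds[c] != "binary"]
    cat_cols = [c for c in order if kinds[c] == "binary"]
    n_cat_missing = int(mask[cat_cols].to_numpy().sum()) if cat_cols else 0

    rng = np.random.default_rng(seed)
    best = X.copy()
    prev_cont = np.inf
    prev_cat = np.inf
    for _ in range(max_iter):
        X_old = X.copy()
        for c in order:
            others = [o for o in X.columns if o != c]
            obs = ~mask[c]
            model_seed = int(rng.integers(2**31 - 1))
            # mtry = sqrt(p), as in the reference missForest implementation
            if kinds[c] == "binary":
                y_obs = X.loc[obs, c]
                if y_obs.nunique() < 2:
                    continue
                model = RandomForestClassifier(
                    n_estimators=n_trees, max_features="sqrt",
                    random_state=model_seed, n_jobs=1)
                model.fit(X.loc[obs, others], y_obs)
                X.loc[mask[c], c] = model.predict(X.loc[mask[c], others])
            else:
                model = RandomForestRegressor(
                    n_estimators=n_trees, max_features="sqrt",
                    random_state=model_seed, n_jobs=1)
                model.fit(X.loc[obs, others], X.loc[obs, c])
                X.loc[mask[c], c] = model.predict(X.loc[mask[c], others])

        # missForest stopping statistics
        if cont_cols:
            num = ((X[cont_cols] - X_old[cont_cols]) ** 2).to_numpy().sum()
            den = (X[cont_cols] ** 2).to_numpy().sum()
            d_cont = num / den if den > 0 else 0.0
        else:
            d_cont = 0.0
        if n_cat_missing:
            changed = (X[cat_cols] != X_old[cat_cols]).to_numpy() & mask[cat_cols].to_numpy()
            d_cat = changed.sum() / n_cat_missing
        else:
            d_cat = 0.0
        if d_cont > prev_cont or d_cat > prev_cat:
            X = X_old
            break
        best = X.copy()
        prev_cont, prev_cat = d_cont, d_cat
        if d_cont == 0.0 and d_cat == 0.0:
            break

    return FeatureTable(features=best, outcomes=table.outcomes,
                        kinds=table.kinds, raw=table.raw, labels=table.labels)


# ---------------------------------------------------------------------------
# feature selection


def select_features(
    table: FeatureTable,
    outcome: str,
    seed: int = 0,
    method: str = "elasticnet",
    n_permutations: int = 20,
    cv_folds: int = 5,
) -> list:
    """Two-stage supervised feature selection.

    Stage 1 fits an elastic-net-penalized logistic regression (mixing
    parameter 0.5, penalty strength by cross-validation) and keeps features
    with nonzero coefficients; ``method="univariate"`` swaps in a simple
    per-feature association filter.  Stage 2 fits a class-weight-balanced
    random forest on two thirds of the cohort and ranks the retained
    features by permutation importance on the held-out third; features with
    positive importance are returned, most important first.
    """
    y = table.outcomes[outcome]
    keep_rows = y.notna()
    y = y[keep_rows].astype(int)
    X = table.features.loc[keep_rows]
    if X.isna().any().any():
        raise ValueError("feature selection requires an imputed (complete) table")
    if y.nunique() < 2:
        raise ValueError(f"outcome {outcome} has a single class; cannot select features")
    if X.shape[1] < 2:
        raise ValueError("need at least two candidate features")

    if method == "elasticnet":
        scaler_sd = X.std(ddof=0).replace(0.0, 1.0)
        Xs = (X - X.mean()) / scaler_sd
        enet = LogisticRegressionCV(
            solver="saga", l1_ratios=[0.5],
            Cs=10, cv=cv_folds, max_iter=3000, random_state=seed,
            scoring="neg_log_loss", n_jobs=1,
        )
        enet.fit(Xs.to_numpy(), y.to_numpy())
        retained = [c for c, b in zip(X.columns, enet.coef_[0]) if abs(b) > 1e-8]
    elif method == "univariate":
        retained = []
        for c in X.columns:
            r = np.corrcoef(X[c], y)[0, 1]
            if np.isfinite(r) and abs(r) > 2.0 / np.sqrt(len(y)):
                retained.append(c)
    else:
        raise ValueError(f"unknown selection method {method!r}")

    if not retained:
        warnings.warn(f"elastic net retained no features for {outcome}", stacklevel=2)
        return []

    X_tr, X_ho, y_tr, y_ho = train_test_split(
        X[retained], y, test_size=1 / 3, random_state=seed, stratify=y)
    forest = RandomForestClassifier(
        n_estimators=200, class_weight="balanced", random_state=seed, n_jobs=1)
    forest.fit(X_tr, y_tr)
    imp = permutation_importance(
        forest, X_ho, y_ho, n_repeats=n_permutations, random_state=seed, n_jobs=1)
    ranked = sorted(
        zip(retained, imp.importances_mean), key=lambda t: (-t[1], t[0]))
    return [c for c, v in ranked if v > 0]


# ---------------------------------------------------------------------------
# logistic model, multiplicity, collinearity


def compute_vif(features: pd.DataFrame, columns=None) -> dict:
    """Variance inflation factors, VIF_j = 1 / (1 - R²_j).

    Each feature is regressed (with intercept) on the remaining features;
    singular or degenerate fits yield None, mirroring the convention that a
    VIF is left unreported when there is inadequate information.
    """
    columns = list(columns) if columns is not None else list(features.columns)
    if len(columns) < 2:
        return {c: None for c in columns}
    out: dict = {}
    X = features[columns].to_numpy(dtype=float)
    for j, c in enumerate(columns):
        yj = X[:, j]
        others = np.delete(X, j, axis=1)
        design = np.column_stack([np.ones(len(yj)), others])
        coef, *_ = np.linalg.lstsq(design, yj, rcond=None)
        resid = yj - design @ coef
        tss = ((yj - yj.mean()) ** 2).sum()
        if tss <= 0:
            out[c] = None
            continue
        r2 = 1.0 - (resid ** 2).sum() / tss
        if r2 > 1.0 - 1e-10:
            out[c] = None
        else:
            out[c] = float(1.0 / (1.0 - r2))
    return out


def bonferroni_adjust(pvals, m: int | None = None) -> list:
    """p_adj_i = min(1, m * p_i), order preserved."""
    pvals = list(pvals)
    if any((not np.isfinite(p)) or p < 0 or p > 1 for p in pvals):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(pvals) if m is None else m
    return [min(1.0, m * p) for p in pvals]


_SEPARATION_SE = 50.0  # |log-odds| SE above this is treated as separation


def fit_logistic(
    table: FeatureTable,
    outcome: str,
    features,
    adjust: bool = True,
) -> list:
    """Joint maximum-likelihood logistic fit with per-feature OR reporting.

    Returns one :class:`RegressionResult` per feature with OR = exp(b),
    Wald 95% CI exp(b ± 1.96·SE), raw and Bonferroni-adjusted p-values
    (m = number of fitted features), observed prevalence and missingness
    from the pre-imputation matrix, and the VIF in the joint design.
    Features whose estimates blow up (perfect separation) are flagged and
    reported with unbounded CIs instead of being dropped.
    """
    features = list(features)
    y = table.outcomes[outcome]
    keep = y.notna()
    y = y[keep].astype(int)
    X = table.features.loc[keep, features]
    if len(y) <= len(features):
        raise ValueError("need more observations than features")
    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y.to_numpy(), design)
        try:
            fit = model.fit(disp=0, maxiter=100, method="newton", tol=1e-10)
        except Exception:
            try:
                fit = model.fit(disp=0, maxiter=500, method="lbfgs")
            except Exception:
                fit = model.fit_regularized(disp=0, alpha=1e-8, maxiter=500)
    params = np.asarray(fit.params)[1:]
    try:
        bse = np.asarray(fit.bse)[1:]
    except Exception:
        bse = np.full(len(params), np.inf)
    pvalues = 2 * (1 - _normal_cdf(np.abs(params / np.where(bse > 0, bse, np.inf))))

    vifs = compute_vif(table.features.loc[keep], features)
    missingness = table.missingness()
    adj = bonferroni_adjust(list(pvalues)) if adjust else list(pvalues)

    results = []
    for i, c in enumerate(features):
        b, se = float(params[i]), float(bse[i])
        separated = (not np.isfinite(se)) or se > _SEPARATION_SE or abs(b) > 20
        if separated:
            ci_low, ci_high = 0.0, np.inf
            p_raw = p_adj = 1.0
        else:
            ci_low = float(np.exp(b - 1.96 * se))
            ci_high = float(np.exp(b + 1.96 * se))
            p_raw = float(pvalues[i])
            p_adj = float(adj[i])
        observed = table.raw[c].dropna() if c in table.raw.columns else pd.Series(dtype=float)
        odds = float(np.exp(np.clip(b, -700, 700)))
        results.append(RegressionResult(
            feature=c,
            label=table.labels.get(c, c),
            odds_ratio=odds,
            ci_low=min(ci_low, odds),
            ci_high=max(ci_high, odds),
            standard_error=se,
            p_raw=p_raw,
            p_adjusted=p_adj,
            mean_prevalence=float(observed.mean()) if len(observed) else float("nan"),
            sd_prevalence=float(observed.std(ddof=1)) if len(observed) > 1 else float("nan"),
            missingness_rate=float(missingness.get(c, 0.0)),
            mean_vif=vifs.get(c),
            separation_flag=bool(separated),
        ))
    return results


def _normal_cdf(z):
    from scipy.stats import norm

    return norm.cdf(z)


# ---------------------------------------------------------------------------
# orchestration


def run_regression_arm(
    respondents: pd.DataFrame,
    responses,
    key: TranslationKey,
    ontology: Ontology,
    outcome_curies,
    seed: int = 0,
    selection_method: str = "elasticnet",
    impute_iter: int = 5,
    impute_trees: int = 50,
) -> dict:
    """Full comparison arm for every disorder; returns results per outcome."""
    cohort = clean_cohort(respondents, responses, key, ontology, outcome_curies)
    imputed = impute_missforest(cohort, max_iter=impute_iter,
                                n_trees=impute_trees, seed=seed)
    out: dict = {}
    for disorder in outcome_curies:
        try:
            selected = select_features(imputed, disorder, seed=seed,
                                       method=selection_method)
        except ValueError as err:
            logger.warning("selection failed for %s: %s", disorder, err)
            out[disorder] = []
            continue
        if not selected:
            out[disorder] = []
            continue
        out[disorder] = fit_logistic(imputed, disorder, selected)
    return out
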