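"""Cross-arm comparison: exact matches between predicted links and
significant regression features, plus report rendering.

A match is strict CURIE identity between a predicted destination and a
regression feature that is Bonferroni-significant for the same disorder.
An ancestor-aware mode (counting a prediction as matched when it hits an
is_a ancestor or descendant of a significant feature) exists for
exploration but is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .ontology import Ontology


@dataclass
class ComparisonResult:
    disorder: str
    kg_only: set
    regression_only: set
    exact_matches: dict = field(default_factory=dict)
    # exact_matches: CURIE -> (prediction score, RegressionResult)

    def __post_init__(self) -> None:
        matched = set(self.exact_matches)
        if matched & self.kg_only or matched & self.regression_only:
            raise ValueError("match sets must be pairwise disjoint")

    @property
    def n_matches(self) -> int:
        return len(self.exact_matches)


def exact_match(
    predictions,
    results,
    disorder: str,
    alpha: float = 0.05,
    ontology: Ontology | None = None,
    ancestor_aware: bool = False,
) -> ComparisonResult:
    """Compare the two arms for one disorder.

    ``predictions`` are scored links (only those with the given disorder as
    source are considered); ``results`` are regression rows carrying
    Bonferroni-adjusted p-values, restricted here to p_adjusted < alpha.
    """
    kg_scores: dict[str, float] = {}
    for p in predictions:
        if p.source == disorder:
            prev = kg_scores.get(p.destination)
            if prev is None or p.score > prev:
                kg_scores[p.destination] = p.score
    significant = {r.feature: r for r in results if r.p_adjusted < alpha}

    matched = set(kg_scores) & set(significant)
    if ancestor_aware and ontology is not None:
        for dest in set(kg_scores) - matched:
            if dest not in ontology:
                continue
            related = ontology.ancestors(dest)
            for feat in significant:
                if feat in related or (feat in ontology and dest in ontology.ancestors(feat)):
                    matched.add(dest)
                    significant.setdefault(dest, significant[feat])
                    break

    return ComparisonResult(
        disorder=disorder,
        kg_only=set(kg_scores) - matched,
        regression_only=set(significant) - matched,
        exact_matches={c: (kg_scores[c], significant[c]) for c in sorted(matched)},
    )


def render_report(comparisons, metrics: dict, out_dir, ontology: Ontology | None = None) -> dict:
    """Write per-disorder TSVs and a markdown summary; returns path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict = {}
    lines = ["# Knowledge-graph vs logistic-regression comparison", ""]
    if metrics:
        lines.append("## Run metadata")
        for k in sorted(metrics):
            lines.append(f"- {k}: {metrics[k]}")
        lines.append("")
    total = 0
    for comp in comparisons:
        label = comp.disorder
        if ontology is not None and comp.disorder in ontology:
            label = f"{ontology.resolve(comp.disorder).label} ({comp.disorder})"
        n_kg = len(comp.kg_only) + comp.n_matches
        n_reg = len(comp.regression_only) + comp.n_matches
        total += comp.n_matches
        lines.append(f"## {label}")
        lines.append(f"- predicted links: {n_kg}")
        lines.append(f"- significant regression features: {n_reg}")
        lines.append(f"- exact matches: {comp.n_matches}")
        for curie, (score, row) in comp.exact_matches.items():
            lines.append(
                f"    - **{curie}** ({row.label}): score={score:.3f}, "
                f"OR={row.odds_ratio:.2f} "
                f"[{row.ci_low:.2f}, {row.ci_high:.2f}], "
                f"adjusted p={row.p_adjusted:.2e}"
            )
        lines.append("")
        if comp.n_matches or comp.kg_only or comp.regression_only:
            frame = _per_disorder_frame(comp)
            path = out / f"comparison_{comp.disorder.replace(':', '_')}.tsv"
            frame.to_csv(path, sep="\t", index=False)
            paths[comp.disorder] = path
    lines.append(f"## Total exact matches across disorders: {total}")
    summary = out / "comparison_summary.md"
    summary.write_text("\n".join(lines) + "\n")
    paths["summary"] = summary
    return paths


def _per_disorder_frame(comp: ComparisonResult) -> pd.DataFrame:
    rows = []
    for curie, (score, r) in comp.exact_matches.items():
        rows.append({"Class ID": curie, "set": "exact_match",
                     "prediction score": score, "Odds": r.odds_ratio,
                     "p-value": r.p_adjusted, "bold": True})
    for curie in sorted(comp.kg_only):
        rows.append({"Class ID": curie, "set": "kg_only",
                     "prediction score": None, "Odds": None,
                     "p-value": None, "bold": False})
    for curie in sorted(comp.regression_only):
        rows.append({"Class ID": curie, "set": "regression_only",
                     "prediction score": None, "Odds": None,
                     "p-value": None, "bold": False})
    return pd.DataFrame(rows, columns=["Class ID", "set", "prediction score",
                                       "Odds", "p-value", "bold"])
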