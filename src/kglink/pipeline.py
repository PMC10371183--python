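"""End-to-end driver chaining both analysis arms.

synthetic cohort → ontology mapping → knowledge graph → largest component
→ DeepWalk/skip-gram embeddings (train split and full graph) → random
forest edge classification (AUROC on the connectivity-preserving holdout)
→ full retrain and disorder-sourced link prediction → regression arm
(cleaning, imputation, selection, logistic ORs with Bonferroni) → exact
match comparison and report.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import kg_build
from .comparison import exact_match, render_report
from .embedding import EmbeddingMatrix, EmbeddingParams, generate_walks, train_skipgram
from .kg_build import KnowledgeGraph
from .link_prediction import (
    ClassifierParams,
    evaluate_auroc,
    predict_frd_links,
    split_edges,
    train_edge_classifier,
    train_full_classifier,
)
from .ontology_mapping import map_responses
from .regression_pipeline import results_frame, run_regression_arm
from .synthetic_data import SyntheticBundle, SyntheticConfig, generate_bundle, write_bundle


@dataclass
class PipelineResult:
    bundle: SyntheticBundle
    graph: KnowledgeGraph
    largest: KnowledgeGraph
    components: kg_build.ComponentSummary
    auroc: float
    achieved_test_fraction: float
    predictions: list
    regression: dict          # disorder -> list[RegressionResult]
    comparisons: list         # list[ComparisonResult]
    unmapped: pd.DataFrame
    runtime_s: dict = field(default_factory=dict)

    @property
    def n_significant_links(self) -> int:
        return len(self.predictions)

    @property
    def n_exact_matches(self) -> int:
        return sum(c.n_matches for c in self.comparisons)


def _drop_test_edges(graph: KnowledgeGraph, test_edges) -> KnowledgeGraph:
    held = set(test_edges)
    return KnowledgeGraph(
        nodes=dict(graph.nodes),
        edges={(s, p, o) for (s, p, o) in graph.edges
               if frozenset((s, o)) not in held},
    )


def run_all(
    config: SyntheticConfig,
    out_dir=None,
    embedding_params: EmbeddingParams | None = None,
    classifier_params: ClassifierParams | None = None,
    test_fraction: float = 0.3,
    alpha: float = 0.05,
    bundle: SyntheticBundle | None = None,
) -> PipelineResult:
    """Run both arms on a synthetic bundle; optionally write all artifacts."""
    t: dict = {}
    clock = time.perf_counter

    t0 = clock()
    if bundle is None:
        bundle = generate_bundle(config)
    t["synthesis"] = clock() - t0

    t0 = clock()
    assertions, unmapped = map_responses(
        bundle.responses, bundle.translation_key, bundle.ontology)
    graph = kg_build.build_graph(
        assertions, bundle.ontology, bundle.supplemental_links,
        respondent_ids=list(bundle.respondents["respondent_id"]),
        question_curies=bundle.translation_key.curies(),
    )
    components = kg_build.connected_components(graph)
    largest = kg_build.extract_largest_component(graph)
    t["kg_build"] = clock() - t0

    eparams = embedding_params or EmbeddingParams(seed=config.seed)
    cparams = classifier_params or ClassifierParams(seed=config.seed)

    t0 = clock()
    split = split_edges(largest, test_fraction, seed=config.seed)
    train_graph = _drop_test_edges(largest, split.test_edges)
    train_emb = train_skipgram(generate_walks(train_graph, eparams), eparams)
    model = train_edge_classifier(split, train_emb, cparams)
    auroc = evaluate_auroc(model, split, train_emb, seed=config.seed)
    t["holdout_evaluation"] = clock() - t0

    t0 = clock()
    full_emb = train_skipgram(generate_walks(largest, eparams), eparams)
    full_model = train_full_classifier(largest, full_emb, cparams)
    frds_present = [f for f in bundle.frd_curies if f in largest.nodes]
    predictions = predict_frd_links(
        largest, full_emb, cparams, frds_present, model=full_model)
    t["link_prediction"] = clock() - t0

    t0 = clock()
    regression = run_regression_arm(
        bundle.respondents, bundle.responses, bundle.translation_key,
        bundle.ontology, bundle.frd_curies, seed=config.seed)
    t["regression"] = clock() - t0

    comparisons = [
        exact_match(predictions, regression.get(d, []), d, alpha=alpha)
        for d in bundle.frd_curies
    ]

    result = PipelineResult(
        bundle=bundle, graph=graph, largest=largest, components=components,
        auroc=auroc, achieved_test_fraction=split.achieved_test_fraction,
        predictions=predictions, regression=regression,
        comparisons=comparisons, unmapped=unmapped, runtime_s=t,
    )
    if out_dir is not None:
        write_artifacts(result, config, eparams, cparams, out_dir,
                        full_emb=full_emb)
    return result


def write_artifacts(
    result: PipelineResult,
    config: SyntheticConfig,
    eparams: EmbeddingParams,
    cparams: ClassifierParams,
    out_dir,
    full_emb: EmbeddingMatrix | None = None,
) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = write_bundle(result.bundle, out / "bundle")

    kg_build.write_kgx(result.graph, out / "kg_nodes.tsv", out / "kg_edges.tsv")
    kg_build.write_component_summary(result.components, out / "components.json")
    paths["kg_nodes"] = out / "kg_nodes.tsv"
    paths["kg_edges"] = out / "kg_edges.tsv"

    if full_emb is not None:
        full_emb.save(out / "embedding.tsv")
        paths["embedding"] = out / "embedding.tsv"

    onto = result.bundle.ontology
    pred_frame = pd.DataFrame(
        [{"source": p.source,
          "source_label": onto.resolve(p.source).label if p.source in onto else "",
          "destination": p.destination,
          "destination_label": (onto.resolve(p.destination).label
                                if p.destination in onto else ""),
          "score": p.score}
         for p in result.predictions],
        columns=["source", "source_label", "destination", "destination_label", "score"],
    )
    pred_frame.to_csv(out / "predictions.tsv", sep="\t", index=False)
    paths["predictions"] = out / "predictions.tsv"

    for disorder, rows in result.regression.items():
        path = out / f"regression_{disorder.replace(':', '_')}.tsv"
        results_frame(rows).to_csv(path, sep="\t", index=False)
        paths[f"regression:{disorder}"] = path

    result.unmapped.to_csv(out / "unmapped_report.tsv", sep="\t", index=False)
    paths["unmapped"] = out / "unmapped_report.tsv"

    metrics = {
        "auroc_test": result.auroc,
        "achieved_test_fraction": result.achieved_test_fraction,
        "n_nodes": result.graph.n_nodes,
        "n_edges": result.graph.n_edges,
        "n_components": result.components.n_components,
        "removed_persons": result.components.removed_persons,
        "removed_fraction": result.components.removed_fraction,
        "n_significant_links": result.n_significant_links,
        "n_exact_matches": result.n_exact_matches,
        "seed": config.seed,
        "embedding_params": asdict(eparams),
        "classifier_params": asdict(cparams),
        "runtime_s": {k: round(v, 2) for k, v in result.runtime_s.items()},
    }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
    paths["metrics"] = out / "metrics.json"

    report_paths = render_report(
        result.comparisons,
        {"seed": config.seed, "alpha": 0.05,
         "auroc_test": round(result.auroc, 4)},
        out / "report", ontology=onto)
    paths.update({f"report:{k}": v for k, v in report_paths.items()})
    return paths
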