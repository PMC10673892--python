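"""End-to-end candidate discovery over one (synthetic or real) study.

Chains the stages in the published order: TPM filtering and metabolite ppm
normalization, the joint gene-metabolite HRR network queried with known
pathway baits, the feed-forward MIA classifier, the latex-proteome
oxidoreductase filter, the physical cluster scan, and the final
locus-level merge / >= 2-method shortlist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .atlas import ExpressionAtlas, MetaboliteMatrix, metabolites_to_ppm, tpm_filter
from .classifier import (
    ClassifierConfig,
    ClassifierReport,
    LabelSet,
    make_features,
    predict_unlabeled,
    train_classifier,
)
from .clusterscan import (
    ClusterRegion,
    adh_family_label,
    assign_mia_orthologs,
    classify_adh_family,
    scan_clusters,
)
from .coexpression import (
    HRRNetwork,
    bait_neighborhood,
    build_network,
    hrr_matrix,
    pearson_matrix,
)
from .evidence import latex_oxidoreductases, merge_candidates, prioritize
from .io_formats import locus_id
from .synthetic_data import SyntheticStudy


@dataclass
class PipelineResult:
    filtered_atlas: ExpressionAtlas
    ppm: MetaboliteMatrix
    network: HRRNetwork
    coexpr_candidates: pd.DataFrame
    classifier_report: ClassifierReport
    predicted_mia: set[str]
    anchors: list
    clusters: list[ClusterRegion]
    proteome_oxidoreductases: pd.DataFrame
    routes: dict[str, set[str]] = field(default_factory=dict)
    candidates: pd.DataFrame | None = None
    venn: dict = field(default_factory=dict)
    shortlist: pd.DataFrame | None = None
    adh_candidates: pd.DataFrame | None = None
    adh_venn: dict = field(default_factory=dict)
    adh_shortlist: pd.DataFrame | None = None
    adh_family: dict[str, str] = field(default_factory=dict)


def run_pipeline(
    study: SyntheticStudy,
    hrr_threshold: int = 30,
    min_methods: int = 2,
    classifier_config: ClassifierConfig | None = None,
    run_cv: bool = False,
) -> PipelineResult:
    """Run the full discovery pipeline on a generated study.

    Baits for the network query are the labelled pathway transcripts; route
    candidate sets are collapsed to locus level before merging.  The
    ADH-restricted merge reproduces the published prioritization (reductase
    candidates seen by >= ``min_methods`` routes, MDR first).
    """
    atlas = ExpressionAtlas(study.tpm, study.sample_meta)
    filtered = tpm_filter(atlas)
    ppm = metabolites_to_ppm(MetaboliteMatrix(study.metabolites))

    combined = pd.concat([filtered.matrix, ppm.matrix])
    corr = pearson_matrix(combined)
    hrr = hrr_matrix(corr)
    kinds = {m: "metabolite" for m in ppm.matrix.index}
    network = build_network(hrr, corr, threshold=hrr_threshold, node_kinds=kinds)

    labels = LabelSet.from_lists(**study.labels)
    baits = set(labels.positives) & network.nodes
    _, coexpr_table = bait_neighborhood(network, baits)

    features = make_features(filtered)
    config = classifier_config or ClassifierConfig()
    model, report = train_classifier(features, labels, config, run_cv=run_cv)
    predicted, scores = predict_unlabeled(model, features, labels, config.threshold)
    report.predicted_mia = predicted
    report.scores = scores

    anchors = assign_mia_orthologs(study.hits)
    clusters = scan_clusters(study.genes, anchors, study.domains)
    proteome_tab = latex_oxidoreductases(study.proteome, study.go_table, study.domains)

    fam_sets = classify_adh_family(study.domains)
    adh_family = {locus_id(g): adh_family_label(f) for g, f in fam_sets.items()}

    routes = {
        "coexpression": {
            locus_id(c)
            for c, kind in zip(coexpr_table["candidate"], coexpr_table["kind"])
            if kind != "metabolite"
        },
        "ml": {locus_id(t) for t in predicted},
        "proteome": set(proteome_tab["gene_id"]),
        "cluster": set().union(*(c.member_gene_ids for c in clusters))
        if clusters
        else set(),
    }
    candidates, venn = merge_candidates(routes)
    shortlist = prioritize(candidates, adh_family, min_methods=min_methods)

    adh_loci = set(adh_family)
    adh_routes = {m: s & adh_loci for m, s in routes.items()}
    adh_candidates, adh_venn = merge_candidates(adh_routes)
    adh_shortlist = prioritize(adh_candidates, adh_family, min_methods=min_methods)

    return PipelineResult(
        filtered_atlas=filtered,
        ppm=ppm,
        network=network,
        coexpr_candidates=coexpr_table,
        classifier_report=report,
        predicted_mia=predicted,
        anchors=anchors,
        clusters=clusters,
        proteome_oxidoreductases=proteome_tab,
        routes=routes,
        candidates=candidates,
        venn=venn,
        shortlist=shortlist,
        adh_candidates=adh_candidates,
        adh_venn=adh_venn,
        adh_shortlist=adh_shortlist,
        adh_family=adh_family,
    )
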