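"""Physical biosynthetic-gene-cluster scanning.

Known-pathway orthologs are anchored onto the genome (BLAST hits passing
the 90% subject-coverage / 60% identity assignment rule), then 100 kb is
scanned on either side of each anchor span for genes carrying one of a
whitelist of biosynthetic Pfam domains (2OG-Fe(II) oxygenase PF03171,
dioxygenase N-terminal PF14226, O-methyltransferase PF00891, ADH GroES-like
PF08240, cytochrome P450 PF00067, berberine-bridge PF08031 and
UDP-glucosyltransferase PF00201).  A region holding the anchor plus at
least one distinct whitelist-domain gene is recorded as a cluster; anchor
windows with overlapping member sets are merged.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .io_formats import BlastHit, DomainAnnotation, GeneModel

#: Pfam domains of interest around an anchor (version-agnostic).
DEFAULT_WHITELIST = frozenset(
    {"PF03171", "PF14226", "PF00891", "PF08240", "PF00067", "PF08031", "PF00201"}
)

#: ADH family definitions.
ADH_FAMILY_PFAM = {
    "MDR": frozenset({"PF00107", "PF08240"}),
    "SDR": frozenset({"PF00106"}),
    "AKR": frozenset({"PF00248"}),
}


@dataclass(frozen=True)
class MiaAnchor:
    """A gene assigned as ortholog of a known pathway protein."""

    gene_id: str
    best_subject: str
    percent_identity: float
    coverage: float

    def __post_init__(self) -> None:
        if self.percent_identity < 60 or self.coverage < 90:
            raise ValueError(
                f"{self.gene_id}: anchor below the 90% coverage / 60% identity rule"
            )


@dataclass(frozen=True)
class ClusterRegion:
    """A merged genomic region of anchors plus whitelist-domain member genes."""

    cluster_id: int
    contig: str
    start: int
    end: int
    anchors: tuple[str, ...]
    members: tuple[tuple[str, str], ...]  # (gene_id, pfam_accession)

    @property
    def n_genes_of_interest(self) -> int:
        return len(set(self.anchors) | {g for g, _ in self.members})

    @property
    def member_gene_ids(self) -> set[str]:
        return {g for g, _ in self.members}


def assign_mia_orthologs(
    hits: list[BlastHit], min_identity: float = 60.0, min_coverage: float = 90.0
) -> list[MiaAnchor]:
    """Per query gene, the best-bitscore hit passing both thresholds becomes
    its anchor record; genes with no passing hit are excluded.  Hits without
    a coverage value cannot pass."""
    by_query: dict[str, list[BlastHit]] = defaultdict(list)
    for h in hits:
        if (
            h.coverage is not None
            and h.percent_identity >= min_identity
            and h.coverage >= min_coverage
        ):
            by_query[h.query_id].append(h)
    anchors = []
    for q in sorted(by_query):
        best = max(
            by_query[q], key=lambda h: (h.bitscore, -h.evalue, h.subject_id)
        )
        anchors.append(
            MiaAnchor(q, best.subject_id, best.percent_identity, best.coverage)
        )
    return anchors


def classify_adh_family(
    domains: list[DomainAnnotation],
) -> dict[str, frozenset[str]]:
    """Map gene id to its ADH family set: MDR for PF00107 or PF08240, SDR for
    PF00106, AKR for PF00248.  Genes matching several families are reported
    as the full set with a warning; non-ADH genes are absent from the map."""
    accs: dict[str, set[str]] = defaultdict(set)
    for d in domains:
        accs[d.gene_id].add(d.pfam_accession)
    out: dict[str, frozenset[str]] = {}
    for gene, seen in accs.items():
        fams = frozenset(
            fam for fam, markers in ADH_FAMILY_PFAM.items() if seen & markers
        )
        if fams:
            out[gene] = fams
            if len(fams) > 1:
                warnings.warn(f"{gene} matches multiple ADH families: {sorted(fams)}")
    return out


def adh_family_label(families: frozenset[str] | None) -> str:
    """Single-label convenience: MDR > SDR > AKR precedence, 'none' otherwise."""
    if not families:
        return "none"
    for fam in ("MDR", "SDR", "AKR"):
        if fam in families:
            return fam
    return "none"


def span_gap(a: GeneModel, b: GeneModel) -> int:
    """Gap in bp between two gene spans on the same contig; 0 if overlapping."""
    return max(0, b.start - a.end, a.start - b.end)


def scan_clusters(
    genes: list[GeneModel],
    anchors: list[MiaAnchor],
    domains: list[DomainAnnotation],
    window: int = 100_000,
    whitelist: frozenset[str] = DEFAULT_WHITELIST,
) -> list[ClusterRegion]:
    """Scan ``window`` bp on either side of each anchor span for whitelist-
    domain genes and report merged cluster regions.

    A gene is a member of an anchor's window when it lies on the same contig
    with a span-to-span gap of at most ``window`` bp and carries a whitelist
    domain.  An anchor with at least one member (so at least two genes of
    interest; the anchor itself never self-satisfies the rule) seeds a
    cluster; anchor windows sharing any gene are merged.  Clusters are
    numbered by (contig, start).  Output is invariant to input gene order.
    Strand is ignored.
    """
    by_id = {g.gene_id: g for g in genes}
    by_contig: dict[str, list[GeneModel]] = defaultdict(list)
    for g in sorted(genes, key=lambda g: (g.contig, g.start, g.gene_id)):
        by_contig[g.contig].append(g)
    gene_whitelist: dict[str, set[str]] = defaultdict(set)
    for d in domains:
        if d.pfam_accession in whitelist:
            gene_whitelist[d.gene_id].add(d.pfam_accession)

    # connect each anchor to its whitelist members; merged clusters are the
    # connected components of the resulting anchor-member graph
    graph = nx.Graph()
    anchor_ids = set()
    for a in anchors:
        gm = by_id.get(a.gene_id)
        if gm is None:
            warnings.warn(f"anchor {a.gene_id} absent from gene models; skipped")
            continue
        members = [
            other
            for other in by_contig[gm.contig]
            if other.gene_id != gm.gene_id
            and other.gene_id in gene_whitelist
            and span_gap(gm, other) <= window
        ]
        if not members:
            continue
        anchor_ids.add(gm.gene_id)
        graph.add_node(gm.gene_id)
        for m in members:
            graph.add_edge(gm.gene_id, m.gene_id)

    regions = []
    for comp in nx.connected_components(graph):
        comp_genes = sorted(comp)
        spans = [by_id[g] for g in comp_genes]
        contig = spans[0].contig
        start = min(g.start for g in spans)
        end = max(g.end for g in spans)
        comp_anchors = tuple(sorted(g for g in comp_genes if g in anchor_ids))
        members = tuple(
            (g, acc)
            for g in comp_genes
            if g in gene_whitelist and g not in anchor_ids
            for acc in sorted(gene_whitelist[g])
        )
        regions.append((contig, start, end, comp_anchors, members))
    regions.sort(key=lambda r: (r[0], r[1]))
    return [
        ClusterRegion(i + 1, contig, start, end, anchors_, members_)
        for i, (contig, start, end, anchors_, members_) in enumerate(regions)
    ]


def clusters_table(regions: list[ClusterRegion]) -> pd.DataFrame:
    rows = [
        {
            "cluster_id": r.cluster_id,
            "contig": r.contig,
            "start": r.start,
            "end": r.end,
            "n_genes": r.n_genes_of_interest,
            "anchors": ",".join(r.anchors),
            "members": ",".join(f"{g}:{acc}" for g, acc in r.members),
        }
        for r in regions
    ]
    return pd.DataFrame(
        rows,
        columns=["cluster_id", "contig", "start", "end", "n_genes", "anchors", "members"],
    )
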