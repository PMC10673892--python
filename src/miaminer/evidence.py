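"""Evidence integration and the study's small summary statistics.

Candidates arriving from the four prediction routes — co-expression
neighbourhood, expression classifier, latex proteome and physical gene
clusters — are collapsed to locus level, merged with per-method flags,
optionally screened for complete coding sequences, and prioritized by the
number of supporting methods (the published shortlist kept candidates seen
by at least two routes, MDRs first).  The module also carries the plain
two-sided Fisher / Benjamini-Hochberg GO enrichment test and the annotation
and orthogroup percentage summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .clusterscan import adh_family_label, classify_adh_family
from .io_formats import DomainAnnotation, locus_id

GO_OXIDOREDUCTASE_TERMS = frozenset({"GO:0055114", "GO:0016491"})

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class ValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# latex proteome filter
# ---------------------------------------------------------------------------


def latex_oxidoreductases(
    proteome: Iterable[str],
    go_table: Mapping[str, set[str]],
    domains: list[DomainAnnotation],
) -> pd.DataFrame:
    """Flag proteome members carrying an oxidoreductase GO term
    (GO:0055114 oxidation-reduction process or GO:0016491 oxidoreductase
    activity) and report their ADH family.

    Returns a table over the oxidoreductase subset with columns
    ``gene_id`` (locus-level) and ``adh_family``.
    """
    fam = classify_adh_family(domains)
    fam_locus = {locus_id(g): f for g, f in fam.items()}
    rows = []
    for gene in sorted(set(proteome)):
        terms = go_table.get(gene, set())
        if terms & GO_OXIDOREDUCTASE_TERMS:
            locus = locus_id(gene)
            rows.append(
                {"gene_id": locus, "adh_family": adh_family_label(fam_locus.get(locus))}
            )
    return pd.DataFrame(rows, columns=["gene_id", "adh_family"])


# ---------------------------------------------------------------------------
# candidate merging, completeness, prioritization
# ---------------------------------------------------------------------------


def merge_candidates(
    sources: Mapping[str, Iterable[str]]
) -> tuple[pd.DataFrame, dict[frozenset[str], int]]:
    """Union candidate ids over methods with per-method evidence flags.

    Ids are collapsed to locus level before merging, so transcript-level
    network candidates and gene-level cluster candidates join correctly.
    Returns ``(candidates, venn)`` where ``candidates`` is indexed by locus
    with one boolean column per method plus ``n_methods``, ordered by
    (n_methods desc, id), and ``venn`` counts every nonempty method
    combination (regions of the Venn diagram).
    """
    methods = sorted(sources)
    collapsed = {m: {locus_id(g) for g in sources[m]} for m in methods}
    union = sorted(set().union(*collapsed.values())) if collapsed else []
    df = pd.DataFrame(
        {m: [g in collapsed[m] for g in union] for m in methods},
        index=pd.Index(union, name="gene_id"),
    )
    df["n_methods"] = df[methods].sum(axis=1).astype(int) if methods else 0
    df = df.sort_values(
        by=["n_methods", "gene_id"], ascending=[False, True], kind="stable"
    )
    venn: dict[frozenset[str], int] = {}
    for r in range(1, len(methods) + 1):
        for combo in combinations(methods, r):
            key = frozenset(combo)
            venn[key] = int(
                sum(
                    1
                    for g in union
                    if {m for m in methods if g in collapsed[m]} == key
                )
            )
    return df, venn


def completeness_filter(
    candidates: pd.DataFrame,
    cds_sequences: Mapping[str, str],
    drop_incomplete: bool = False,
) -> pd.DataFrame:
    """Annotate candidates with CDS completeness; optionally drop incomplete.

    A CDS is complete iff it starts with ATG, ends with a stop codon and has
    a length divisible by 3.  Genes without a provided CDS are retained with
    ``complete_cds`` unknown (NA) — the filter never silently discards
    evidence.  When several isoform CDS are provided per locus the longest
    is evaluated.
    """
    best: dict[str, str] = {}
    for tx, seq in cds_sequences.items():
        locus = locus_id(tx)
        if locus not in best or len(seq) > len(best[locus]):
            best[locus] = seq
    flags = []
    for gene in candidates.index:
        seq = best.get(gene)
        if seq is None:
            flags.append(pd.NA)
        else:
            flags.append(is_complete_cds(seq))
    out = candidates.copy()
    out["complete_cds"] = pd.array(flags, dtype="boolean")
    if drop_incomplete:
        out = out[out["complete_cds"].fillna(True)]
    return out


def is_complete_cds(seq: str) -> bool:
    seq = seq.upper()
    return (
        len(seq) >= 6
        and len(seq) % 3 == 0
        and seq.startswith("ATG")
        and seq[-3:] in STOP_CODONS
    )


def prioritize(
    candidates: pd.DataFrame,
    adh_family: Mapping[str, str] | None = None,
    min_methods: int = 2,
) -> pd.DataFrame:
    """Shortlist candidates supported by at least ``min_methods`` routes,
    ranked by (n_methods desc, MDR first, id) — MDRs lead given their
    preponderant role among characterized pathway reductases."""
    fam = adh_family or {}
    out = candidates[candidates["n_methods"] >= min_methods].copy()
    out["adh_family"] = [fam.get(g, "none") for g in out.index]
    fam_order = {"MDR": 0, "SDR": 1, "AKR": 2, "none": 3}
    out["_fam_rank"] = out["adh_family"].map(fam_order).fillna(3)
    out = out.sort_values(
        by=["n_methods", "_fam_rank", "gene_id"],
        ascending=[False, True, True],
        kind="stable",
    ).drop(columns="_fam_rank")
    return out


# ---------------------------------------------------------------------------
# Fisher / BH enrichment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # term hits in the list
    K: int  # term hits in the universe
    n: int  # list size
    N: int  # universe size
    p: float
    p_adj: float


def fisher_enrichment(
    gene_list: Iterable[str],
    universe: Iterable[str],
    term_map: Mapping[str, set[str]],
) -> list[EnrichmentResult]:
    """Two-sided Fisher exact enrichment of every term over the gene list,
    Benjamini-Hochberg adjusted across the tested terms.

    The 2x2 table per term is (k, n-k, K-k, N-n-K+k).  Terms are tested when
    at least one universe gene carries them.  ``gene_list`` must be a subset
    of ``universe``.
    """
    genes = set(gene_list)
    uni = set(universe)
    if not genes <= uni:
        raise ValidationError(
            f"gene list not contained in universe: {sorted(genes - uni)[:5]}"
        )
    n, N = len(genes), len(uni)
    term_genes: dict[str, set[str]] = {}
    for g in uni:
        for t in term_map.get(g, ()):
            term_genes.setdefault(t, set()).add(g)
    terms = sorted(term_genes)
    raw = []
    for t in terms:
        K = len(term_genes[t])
        k = len(term_genes[t] & genes)
        _, p = fisher_exact(
            [[k, n - k], [K - k, N - n - K + k]], alternative="two-sided"
        )
        raw.append((t, k, K, float(p)))
    if not raw:
        return []
    padj = multipletests([p for _, _, _, p in raw], method="fdr_bh")[1]
    return [
        EnrichmentResult(t, k, K, n, N, p, float(pa))
        for (t, k, K, p), pa in zip(raw, padj)
    ]


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p": r.p,
                "p_adj": r.p_adj,
            }
            for r in results
        ],
        columns=["term", "k", "K", "n", "N", "p", "p_adj"],
    )


# ---------------------------------------------------------------------------
# printed-count summaries
# ---------------------------------------------------------------------------


def summarize_annotation(
    annotation_table: Mapping[str, set[str]] | None = None,
    *,
    n_genes: int | None = None,
    n_any: int | None = None,
    n_all: int | None = None,
    n_databases: int = 4,
) -> tuple[float, float]:
    """Percent of genes annotated by at least one source database and by all
    ``n_databases`` sources, rounded to one decimal.

    Accepts either a gene -> set-of-databases table or raw counts.
    """
    if annotation_table is not None:
        n_genes = len(annotation_table)
        n_any = sum(1 for dbs in annotation_table.values() if len(dbs) >= 1)
        n_all = sum(1 for dbs in annotation_table.values() if len(dbs) >= n_databases)
    if not n_genes:
        raise ValidationError("total gene count required and nonzero")
    pct_any = round(100.0 * (n_any or 0) / n_genes, 1)
    pct_all = round(100.0 * (n_all or 0) / n_genes, 1)
    return pct_any, pct_all


def summarize_orthogroups(
    assignments: Mapping[str, str | None] | None = None,
    *,
    n_total: int | None = None,
    n_assigned: int | None = None,
    n_orthogroups: int | None = None,
) -> tuple[float, float]:
    """Percent of genes assigned to an orthogroup and the mean orthogroup
    size (assigned genes / distinct orthogroups), each to one decimal."""
    if assignments is not None:
        n_total = len(assignments)
        assigned = [og for og in assignments.values() if og is not None]
        n_assigned = len(assigned)
        n_orthogroups = len(set(assigned))
    if not n_total:
        raise ValidationError("total gene count required and nonzero")
    pct = round(100.0 * (n_assigned or 0) / n_total, 1)
    mean_size = (
        round((n_assigned or 0) / n_orthogroups, 1) if n_orthogroups else float("nan")
    )
    return pct, mean_size
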