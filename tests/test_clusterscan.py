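import itertools

import numpy as np
import pytest

from miaminer import (
    BlastHit,
    DomainAnnotation,
    GeneModel,
    MiaAnchor,
    assign_mia_orthologs,
    classify_adh_family,
    scan_clusters,
)
from miaminer.clusterscan import DEFAULT_WHITELIST, span_gap


def hit(q, s="STR", pident=80.0, cov=95.0, bits=300.0, evalue=1e-50):
    return BlastHit(q, s, pident, cov, evalue, bits)


def gene(gid, contig, start, end):
    return GeneModel(gid, (gid + ".1",), contig, start, end, "+")


def brute_force_scan(genes, anchors, domains, window=100_000,
                     whitelist=DEFAULT_WHITELIST):
    """O(n^2) all-pairs oracle: member lists per anchor, then union-find
    merging of anchor windows sharing any gene, clusters by (contig, start)."""
    by_id = {g.gene_id: g for g in genes}
    wl = {}
    for d in domains:
        if d.pfam_accession in whitelist:
            wl.setdefault(d.gene_id, set()).add(d.pfam_accession)
    windows = {}
    for a in anchors:
        gm = by_id.get(a.gene_id)
        if gm is None:
            continue
        members = {
            o.gene_id
            for o in genes
            if o.contig == gm.contig
            and o.gene_id != gm.gene_id
            and o.gene_id in wl
            and span_gap(gm, o) <= window
        }
        if members:
            windows[a.gene_id] = members
    # union-find over anchors sharing genes
    parent = {a: a for a in windows}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for a1, a2 in itertools.combinations(windows, 2):
        g1 = windows[a1] | {a1}
        g2 = windows[a2] | {a2}
        if g1 & g2:
            parent[find(a1)] = find(a2)
    groups = {}
    for a in windows:
        groups.setdefault(find(a), set()).add(a)
    clusters = []
    for group in groups.values():
        anchor_ids = set(group)
        members = set().union(*(windows[a] for a in group)) - anchor_ids
        all_genes = anchor_ids | members
        start = min(by_id[g].start for g in all_genes)
        end = max(by_id[g].end for g in all_genes)
        contig = by_id[next(iter(all_genes))].contig
        clusters.append((contig, start, end, frozenset(anchor_ids), frozenset(members)))
    clusters.sort(key=lambda c: (c[0], c[1]))
    return clusters


def scanner_as_tuples(regions):
    return [
        (r.contig, r.start, r.end, frozenset(r.anchors), frozenset(r.member_gene_ids))
        for r in regions
    ]


def random_layout(rng):
    genes, anchors, domains = [], [], []
    n_contigs = int(rng.integers(1, 4))
    gid = 0
    for c in range(n_contigs):
        pos = 1
        for _ in range(int(rng.integers(3, 18))):
            gid += 1
            g = f"G{gid}"
            length = int(rng.integers(500, 5000))
            genes.append(gene(g, f"ctg{c}", pos, pos + length - 1))
            pos += length + int(rng.integers(1000, 120_000))
            roll = rng.random()
            if roll < 0.2:
                anchors.append(MiaAnchor(g, "STR", 80.0, 95.0))
            elif roll < 0.5:
                acc = sorted(DEFAULT_WHITELIST)[int(rng.integers(len(DEFAULT_WHITELIST)))]
                domains.append(DomainAnnotation(g, acc, "dom"))
    return genes, anchors, domains


class TestAssignOrthologs:
    def test_thresholds_are_inclusive_at_boundaries(self):
        hits = [
            hit("g1", pident=61, cov=92),   # passes
            hit("g2", pident=59, cov=95),   # identity below 60
            hit("g3", pident=60, cov=90),   # exactly at both boundaries: passes
            hit("g4", pident=95, cov=89.9), # coverage below 90
        ]
        anchors = assign_mia_orthologs(hits)
        assert {a.gene_id for a in anchors} == {"g1", "g3"}

    def test_empty_input(self):
        assert assign_mia_orthologs([]) == []

    def test_missing_coverage_cannot_pass(self):
        assert assign_mia_orthologs([BlastHit("g", "s", 99.0, None, 0.0, 500.0)]) == []

    def test_best_bitscore_among_passing_hits_wins(self):
        # brute-force oracle: filter by rule, then argmax bitscore per gene
        hits = [
            hit("g1", s="STR", pident=70, cov=95, bits=200),
            hit("g1", s="GS", pident=65, cov=93, bits=350),
            hit("g1", s="TDC", pident=99, cov=50, bits=999),  # fails coverage
            hit("g2", s="HYS", pident=61, cov=91, bits=120),
            hit("g2", s="SAT", pident=59, cov=99, bits=400),  # fails identity
            hit("g3", s="T3O", pident=50, cov=50, bits=500),  # fails both
        ]
        passing = {}
        for h in hits:
            if h.percent_identity >= 60 and h.coverage >= 90:
                if h.query_id not in passing or h.bitscore > passing[h.query_id].bitscore:
                    passing[h.query_id] = h
        anchors = {a.gene_id: a.best_subject for a in assign_mia_orthologs(hits)}
        assert anchors == {q: h.subject_id for q, h in passing.items()}
        assert anchors["g1"] == "GS"

    def test_anchor_invariant_enforced(self):
        with pytest.raises(ValueError):
            MiaAnchor("g", "s", 59.0, 95.0)


class TestAdhFamilies:
    def test_single_mdr_domain_suffices(self):
        fams = classify_adh_family([DomainAnnotation("g1", "PF00107")])
        assert fams["g1"] == frozenset({"MDR"})
        fams = classify_adh_family([DomainAnnotation("g2", "PF08240")])
        assert fams["g2"] == frozenset({"MDR"})

    def test_non_adh_domain_maps_to_nothing(self):
        fams = classify_adh_family([DomainAnnotation("g1", "PF00067")])
        assert "g1" not in fams

    def test_multi_family_gene_reported_with_warning(self):
        doms = [DomainAnnotation("g1", "PF00106"), DomainAnnotation("g1", "PF00248")]
        with pytest.warns(UserWarning, match="multiple"):
            fams = classify_adh_family(doms)
        assert fams["g1"] == frozenset({"SDR", "AKR"})


class TestScanClusters:
    def test_anchor_without_neighbours_yields_no_cluster(self):
        genes = [gene("a", "c1", 10_000, 12_000), gene("b", "c1", 500_000, 502_000)]
        anchors = [MiaAnchor("a", "STR", 80, 95)]
        domains = [DomainAnnotation("b", "PF00067")]
        assert scan_clusters(genes, anchors, domains) == []

    def test_gap_arithmetic_boundary(self):
        # anchor 10,000-12,000; P450 at 95,000-97,000: gap 83,000 <= 100,000
        genes = [gene("a", "c1", 10_000, 12_000), gene("b", "c1", 95_000, 97_000)]
        anchors = [MiaAnchor("a", "STR", 80, 95)]
        domains = [DomainAnnotation("b", "PF00067")]
        (region,) = scan_clusters(genes, anchors, domains)
        assert region.member_gene_ids == {"b"}
        assert region.n_genes_of_interest == 2
        assert (region.start, region.end) == (10_000, 97_000)
        # moved to 113,000: gap 101,000 > 100,000 -> no cluster
        genes2 = [gene("a", "c1", 10_000, 12_000), gene("b", "c1", 113_000, 115_000)]
        assert scan_clusters(genes2, anchors, domains) == []

    def test_anchor_with_whitelist_domain_does_not_self_satisfy(self):
        genes = [gene("a", "c1", 10_000, 12_000)]
        anchors = [MiaAnchor("a", "STR", 80, 95)]
        domains = [DomainAnnotation("a", "PF08240")]
        assert scan_clusters(genes, anchors, domains) == []

    def test_two_anchors_sharing_member_merge(self):
        genes = [
            gene("a1", "c1", 10_000, 12_000),
            gene("m", "c1", 40_000, 42_000),
            gene("a2", "c1", 60_000, 62_000),
        ]
        anchors = [MiaAnchor("a1", "STR", 80, 95), MiaAnchor("a2", "GS", 80, 95)]
        domains = [DomainAnnotation("m", "PF00201")]
        regions = scan_clusters(genes, anchors, domains)
        assert len(regions) == 1
        assert set(regions[0].anchors) == {"a1", "a2"}
        assert regions[0].member_gene_ids == {"m"}
        # oracle agrees
        assert scanner_as_tuples(regions) == brute_force_scan(genes, anchors, domains)

    def test_missing_anchor_gene_warned_and_skipped(self):
        genes = [gene("b", "c1", 10_000, 12_000)]
        anchors = [MiaAnchor("ghost", "STR", 80, 95)]
        with pytest.warns(UserWarning, match="absent"):
            assert scan_clusters(genes, anchors, []) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_layouts(self, seed):
        rng = np.random.default_rng(seed)
        genes, anchors, domains = random_layout(rng)
        got = scanner_as_tuples(scan_clusters(genes, anchors, domains))
        assert got == brute_force_scan(genes, anchors, domains)

    @pytest.mark.parametrize("seed", range(4))
    def test_window_monotonicity(self, seed):
        rng = np.random.default_rng(100 + seed)
        genes, anchors, domains = random_layout(rng)
        small = scan_clusters(genes, anchors, domains, window=50_000)
        big = scan_clusters(genes, anchors, domains, window=150_000)
        for s in small:
            genes_small = set(s.anchors) | s.member_gene_ids
            assert any(
                genes_small <= (set(b.anchors) | b.member_gene_ids) for b in big
            )

    def test_invariant_to_gene_order(self):
        rng = np.random.default_rng(55)
        genes, anchors, domains = random_layout(rng)
        fwd = scanner_as_tuples(scan_clusters(genes, anchors, domains))
        rev = scanner_as_tuples(scan_clusters(genes[::-1], anchors, domains))
        assert fwd == rev

    def test_planted_clusters_recovered_exactly(self, default_study, pipeline_result):
        truth = default_study.truth
        recovered = {
            (r.contig, r.anchors, frozenset(r.member_gene_ids))
            for r in pipeline_result.clusters
        }
        planted = {
            (contig, (anchor,), frozenset(members))
            for contig, anchor, members in truth.planted_clusters
        }
        assert recovered == planted
        all_members = set().union(
            *(r.member_gene_ids for r in pipeline_result.clusters)
        )
        assert not all_members & truth.decoy_gene_ids
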