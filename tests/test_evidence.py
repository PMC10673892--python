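import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from miaminer import (
    DomainAnnotation,
    completeness_filter,
    fisher_enrichment,
    latex_oxidoreductases,
    merge_candidates,
    prioritize,
    summarize_annotation,
    summarize_orthogroups,
)
from miaminer.evidence import ValidationError, is_complete_cds


class TestLatexFilter:
    def test_empty_proteome(self):
        assert latex_oxidoreductases([], {}, []).empty

    def test_go_term_plus_sdr_domain(self):
        tab = latex_oxidoreductases(
            ["g1"], {"g1": {"GO:0016491"}}, [DomainAnnotation("g1", "PF00106")]
        )
        assert tab.to_dict("records") == [{"gene_id": "g1", "adh_family": "SDR"}]

    def test_counts_match_hand_enumeration(self):
        # 10 proteins, 4 oxidoreductases (g1..g4), 2 of them ADHs (g1 MDR, g2 AKR)
        proteome = [f"g{i}" for i in range(1, 11)]
        go = {f"g{i}": {"GO:0055114"} for i in range(1, 5)}
        go["g9"] = {"GO:0008150"}
        domains = [
            DomainAnnotation("g1", "PF00107"),
            DomainAnnotation("g2", "PF00248"),
            DomainAnnotation("g7", "PF00106"),  # ADH but not an oxidoreductase hit
        ]
        tab = latex_oxidoreductases(proteome, go, domains)
        assert len(tab) == 4
        fams = dict(zip(tab["gene_id"], tab["adh_family"]))
        assert fams == {"g1": "MDR", "g2": "AKR", "g3": "none", "g4": "none"}

    def test_transcript_ids_collapse_to_locus(self):
        tab = latex_oxidoreductases(
            ["MSTRG.5283.1"],
            {"MSTRG.5283.1": {"GO:0016491"}},
            [DomainAnnotation("MSTRG.5283", "PF00107")],
        )
        assert list(tab["gene_id"]) == ["MSTRG.5283"]
        assert list(tab["adh_family"]) == ["MDR"]


class TestMergeCandidates:
    def test_three_source_example(self):
        cands, venn = merge_candidates({"A": {"a", "b", "c"}, "B": {"b", "c"}, "C": {"c"}})
        assert len(cands) == 3
        assert cands.loc["a", "n_methods"] == 1
        assert cands.loc["b", "n_methods"] == 2
        assert cands.loc["c", "n_methods"] == 3
        assert venn[frozenset({"A"})] == 1
        assert venn[frozenset({"A", "B"})] == 1
        assert venn[frozenset({"A", "B", "C"})] == 1

    def test_single_source_all_one_method(self):
        cands, _ = merge_candidates({"only": {"x", "y"}})
        assert (cands["n_methods"] == 1).all()

    def test_isoforms_collapse_before_merging(self):
        cands, _ = merge_candidates(
            {"A": {"MSTRG.5283.1"}, "B": {"MSTRG.5283.2"}, "C": set(), "D": set()}
        )
        assert list(cands.index) == ["MSTRG.5283"]
        assert cands.loc["MSTRG.5283", "n_methods"] == 2

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_venn_regions_sum_to_union_and_match_powerset_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pool = [f"g{i}" for i in range(20)]
        sources = {
            m: {g for g in pool if rng.random() < 0.4} for m in "ABCD"
        }
        cands, venn = merge_candidates(sources)
        assert sum(venn.values()) == len(cands)
        # oracle: enumerate all 15 regions directly
        union = set().union(*sources.values())
        for r in range(1, 5):
            for combo in itertools.combinations("ABCD", r):
                key = frozenset(combo)
                expected = sum(
                    1
                    for g in union
                    if {m for m in "ABCD" if g in sources[m]} == key
                )
                assert venn[key] == expected

    def test_idempotent_and_order_invariant(self):
        sources = {"A": {"a", "b"}, "B": {"b"}}
        c1, v1 = merge_candidates(sources)
        c2, v2 = merge_candidates(dict(reversed(list(sources.items()))))
        pd.testing.assert_frame_equal(c1, c2[c1.columns])
        assert v1 == v2


class TestCompleteness:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ATGAAATAA", True),
            ("ATGAAA", False),       # no stop codon
            ("TTGAAATAA", False),    # non-ATG start
            ("ATGAATAA", False),     # length not divisible by 3
            ("ATGAAATGA", True),
            ("ATGAAATAG", True),
        ],
    )
    def test_completeness_rule(self, seq, expected):
        assert is_complete_cds(seq) is expected

    def test_unknown_cds_retained_and_flagged(self):
        cands, _ = merge_candidates({"A": {"g1", "g2"}})
        out = completeness_filter(cands, {"g1": "ATGAAATAA"})
        assert bool(out.loc["g1", "complete_cds"]) is True
        assert pd.isna(out.loc["g2", "complete_cds"])
        dropped = completeness_filter(cands, {"g1": "ATGAAA"}, drop_incomplete=True)
        assert list(dropped.index) == ["g2"]

    def test_longest_isoform_cds_evaluated(self):
        cands, _ = merge_candidates({"A": {"MSTRG.9"}})
        cds = {"MSTRG.9.1": "ATGAAA", "MSTRG.9.2": "ATGAAATAA"}
        out = completeness_filter(cands, cds)
        assert bool(out.loc["MSTRG.9", "complete_cds"]) is True


class TestPrioritize:
    def _candidates(self, flags):
        sources = {"A": set(), "B": set(), "C": set(), "D": set()}
        for g, methods in flags.items():
            for m in methods:
                sources[m].add(g)
        return merge_candidates(sources)[0]

    def test_all_single_method_gives_empty_shortlist(self):
        cands = self._candidates({"g1": "A", "g2": "B"})
        assert prioritize(cands, {}, min_methods=2).empty

    def test_min_methods_one_keeps_everything(self):
        cands = self._candidates({"g1": "A", "g2": "BC"})
        assert len(prioritize(cands, {}, min_methods=1)) == 2

    def test_matches_brute_force_filter_and_mdr_first_order(self):
        flags = {"g1": "AB", "g2": "ABC", "g3": "A", "g4": "AB", "g5": "ABCD"}
        fam = {"g1": "SDR", "g2": "AKR", "g4": "MDR", "g5": "MDR"}
        cands = self._candidates(flags)
        short = prioritize(cands, fam, min_methods=2)
        assert set(short.index) == {g for g, f in flags.items() if len(f) >= 2}
        assert list(short.index) == ["g5", "g2", "g4", "g1"]


def fisher_two_sided_oracle(k, n, K, N):
    """Exact two-sided p by hypergeometric tail enumeration: sum the
    probabilities of all tables at least as extreme (pmf <= observed)."""
    rv = hypergeom(N, K, n)
    support = np.arange(max(0, n + K - N), min(n, K) + 1)
    pmf = rv.pmf(support)
    observed = rv.pmf(k)
    return float(pmf[pmf <= observed * (1 + 1e-7)].sum())


class TestFisherEnrichment:
    def test_term_covering_whole_universe_is_null(self):
        universe = [f"g{i}" for i in range(30)]
        terms = {g: {"GO:1"} for g in universe}
        (res,) = fisher_enrichment(universe[:10], universe, terms)
        assert res.p == pytest.approx(1.0)

    def test_known_table_matches_hypergeometric_oracle(self):
        # k=5 of n=20 in the list; K=10 of N=100 in the universe
        universe = [f"g{i}" for i in range(100)]
        terms = {g: {"GO:X"} for g in universe[:5] + universe[20:25]}
        gene_list = universe[:20]
        (res,) = fisher_enrichment(gene_list, universe, terms)
        assert (res.k, res.n, res.K, res.N) == (5, 20, 10, 100)
        assert res.p == pytest.approx(fisher_two_sided_oracle(5, 20, 10, 100), abs=1e-10)

    def test_bh_step_up_hand_example(self):
        from statsmodels.stats.multitest import multipletests

        padj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(padj, 0.04)

    def test_gene_list_outside_universe_rejected(self):
        with pytest.raises(ValidationError):
            fisher_enrichment(["x"], ["y"], {})

    def test_adjusted_p_bounds_and_monotonicity(self):
        rng = np.random.default_rng(17)
        universe = [f"g{i}" for i in range(60)]
        terms = {}
        for g in universe:
            for t in range(6):
                if rng.random() < 0.3:
                    terms.setdefault(g, set()).add(f"GO:{t}")
        results = fisher_enrichment(universe[:15], universe, terms)
        assert results
        by_p = sorted(results, key=lambda r: r.p)
        for r in results:
            assert r.p - 1e-12 <= r.p_adj <= 1.0
            assert r.k <= min(r.K, r.n)
        for a, b in zip(by_p, by_p[1:]):
            assert a.p_adj <= b.p_adj + 1e-12


class TestPrintedSummaries:
    def test_annotation_percentages_from_printed_counts(self):
        pct_any, pct_all = summarize_annotation(
            n_genes=23_228, n_any=18_658, n_all=12_924
        )
        assert pct_any == 80.3
        assert pct_all == 55.6

    def test_annotation_from_table_and_degenerate(self):
        table = {"g1": {"db1", "db2", "db3", "db4"}, "g2": {"db1"}, "g3": set()}
        assert summarize_annotation(table) == (66.7, 33.3)
        assert summarize_annotation(n_genes=10, n_any=0, n_all=0) == (0.0, 0.0)

    def test_orthogroup_summary_from_printed_counts(self):
        pct, mean_size = summarize_orthogroups(
            n_total=295_045, n_assigned=272_661, n_orthogroups=23_480
        )
        assert pct == 92.4
        assert mean_size == 11.6

    def test_orthogroup_degenerate_and_toy_cases(self):
        assignments = {f"g{i}": f"og{i}" for i in range(5)}
        assert summarize_orthogroups(assignments) == (100.0, 1.0)
        toy = {f"g{i}": ("og" + str(i % 3) if i < 7 else None) for i in range(10)}
        pct, mean_size = summarize_orthogroups(toy)
        assert pct == 70.0
        assert mean_size == 2.3
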