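from fractions import Fraction
from itertools import combinations
from math import comb

import pytest

from icclust._errors import ValidationError
from icclust.enrichment_elim import (
    OntologyDAG,
    category_mean_p,
    elim_enrichment,
    fisher_exact_enrichment,
    propagate_annotations,
    read_obo,
)


def _hypergeom_tail_oracle(k, n, K, N):
    """Exact upper-tail probability by enumerating the support."""
    total = Fraction(0)
    for x in range(k, min(n, K) + 1):
        total += Fraction(comb(K, x) * comb(N - K, n - x), comb(N, n))
    return float(total)


class TestReadObo:
    def test_chain_structure(self, obo_chain_path):
        dag = read_obo(obo_chain_path)
        assert dag.roots == {"T:0001"}
        assert dag.parents["T:0003"] == {"T:0002"}
        assert "T:0006" not in dag.terms  # obsolete skipped

    def test_multi_parent_term(self, obo_chain_path):
        dag = read_obo(obo_chain_path)
        assert dag.parents["T:0005"] == {"T:0002", "T:0004"}

    def test_cyclic_input_rejected(self, obo_cyclic_path):
        with pytest.raises(ValidationError, match="cycle"):
            read_obo(obo_cyclic_path)

    def test_depths_follow_longest_path(self, obo_chain_path):
        dag = read_obo(obo_chain_path)
        d = dag.depths()
        assert d["T:0001"] == 0 and d["T:0002"] == 1
        assert d["T:0003"] == 2 and d["T:0005"] == 2


class TestPropagation:
    def test_leaf_annotation_reaches_root(self, obo_chain_path):
        dag = read_obo(obo_chain_path)
        ann = propagate_annotations(dag, {"g1": {"T:0003"}})
        for t in ("T:0003", "T:0002", "T:0001"):
            assert "g1" in ann.propagated[t]
        assert "g1" not in ann.propagated["T:0004"]

    def test_sibling_leaves_union_at_parent(self, obo_chain_path):
        dag = read_obo(obo_chain_path)
        ann = propagate_annotations(dag, {"g1": {"T:0003"}, "g2": {"T:0005"}})
        assert ann.propagated["T:0002"] == {"g1", "g2"}

    def test_diamond_counts_once(self, obo_chain_path):
        dag = read_obo(obo_chain_path)
        ann = propagate_annotations(dag, {"g1": {"T:0005"}})
        assert ann.propagated["T:0001"] == {"g1"}

    def test_unknown_term_skipped_and_counted(self, obo_chain_path):
        dag = read_obo(obo_chain_path)
        ann = propagate_annotations(dag, {"g1": {"T:9999", "T:0003"}})
        assert ann.skipped == 1
        assert "g1" in ann.propagated["T:0003"]

    def test_parent_superset_invariant(self, chain_enrichment_fixture):
        dag, ann, _ = chain_enrichment_fixture
        for child, parents in dag.parents.items():
            for p in parents:
                assert ann.propagated[p] >= ann.propagated[child]


class TestFisherExact:
    def test_derived_value_17_over_70(self):
        # study of 4 with 3 hits, term covering 4 of universe 8
        assert fisher_exact_enrichment(3, 4, 4, 8) == pytest.approx(17 / 70, abs=1e-12)

    def test_degenerate_cases(self):
        assert fisher_exact_enrichment(0, 4, 4, 8) == pytest.approx(1.0)
        assert fisher_exact_enrichment(5, 10, 5, 10) == pytest.approx(1.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_enrichment(5, 4, 4, 8)

    @pytest.mark.parametrize("N", [10, 20, 30])
    def test_tail_matches_exhaustive_enumeration(self, N):
        for K in range(0, N + 1, max(1, N // 4)):
            for n in range(1, N + 1, max(1, N // 4)):
                for k in range(0, min(n, K) + 1):
                    got = fisher_exact_enrichment(k, n, K, N)
                    assert got == pytest.approx(
                        _hypergeom_tail_oracle(k, n, K, N), abs=1e-12
                    )


class TestElim:
    def test_flat_dag_equals_classic_fisher(self):
        terms = {"root": "root", "A": "A", "B": "B", "C": "C"}
        parents = {"root": set(), "A": {"root"}, "B": {"root"}, "C": {"root"}}
        dag = OntologyDAG(terms, parents)
        genes = [f"g{i:02d}" for i in range(30)]
        direct = {g: {["A", "B", "C"][i % 3]} for i, g in enumerate(genes)}
        ann = propagate_annotations(dag, direct)
        study = set(genes[:9])
        results = elim_enrichment(dag, ann, study, set(genes), min_node_size=5)
        for r in results:
            if r.term == "root":
                continue
            classic = fisher_exact_enrichment(
                len(ann.propagated[r.term] & study), len(study),
                len(ann.propagated[r.term]), 30,
            )
            assert r.p_raw == pytest.approx(classic, abs=1e-15)
            assert r.eliminated_genes == 0

    def test_chain_elimination_raises_parent_p(self, chain_enrichment_fixture):
        dag, ann, genes = chain_enrichment_fixture
        # 7 study genes from the leaf + 1 mid-only gene
        study = set(genes[:7]) | {genes[12]}
        results = {r.term: r for r in elim_enrichment(
            dag, ann, study, set(genes), min_node_size=5, node_cutoff=0.01
        )}
        # leaf: 7 of 8 study genes in a 10-gene term over universe 30
        assert results["leaf"].p_raw == pytest.approx(
            _hypergeom_tail_oracle(7, 8, 10, 30), abs=1e-12
        )
        # leaf is significant -> its 7 study genes eliminated at mid:
        # mid tests 1 hit in a 13-gene pool instead of 8 in 20
        assert results["mid"].eliminated_genes == 7
        assert results["mid"].p_raw == pytest.approx(
            _hypergeom_tail_oracle(1, 8, 13, 30), abs=1e-12
        )
        classic_mid = _hypergeom_tail_oracle(8, 8, 20, 30)
        assert results["mid"].p_raw > classic_mid

    def test_raw_elimination_switch(self, chain_enrichment_fixture):
        dag, ann, genes = chain_enrichment_fixture
        study = set(genes[:7]) | {genes[12]}
        # leaf p_raw ~ 4.2e-4 and p_adjusted = 3*p_raw ~ 1.25e-3 straddle
        # a 1e-3 cutoff, so only the raw-p route eliminates
        adj = elim_enrichment(dag, ann, study, set(genes), min_node_size=5,
                              node_cutoff=1e-3, eliminate_on="adjusted")
        raw = elim_enrichment(dag, ann, study, set(genes), min_node_size=5,
                              node_cutoff=1e-3, eliminate_on="raw")
        mid_adj = next(r for r in adj if r.term == "mid")
        mid_raw = next(r for r in raw if r.term == "mid")
        assert mid_adj.eliminated_genes == 0
        assert mid_raw.eliminated_genes == 7

    def test_min_node_size_filters_everything(self, chain_enrichment_fixture):
        dag, ann, genes = chain_enrichment_fixture
        assert elim_enrichment(dag, ann, {genes[0]}, set(genes),
                               min_node_size=100) == []

    def test_bonferroni_uses_kept_term_count(self, chain_enrichment_fixture):
        dag, ann, genes = chain_enrichment_fixture
        study = set(genes[:5])
        results = elim_enrichment(dag, ann, study, set(genes), min_node_size=15)
        # only mid (20) and root (30) survive min_node_size=15 -> m = 2
        assert {r.term for r in results} == {"mid", "root"}
        for r in results:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_raw * 2))
            assert r.p_adjusted >= r.p_raw

    def test_empty_study_rejected(self, chain_enrichment_fixture):
        dag, ann, genes = chain_enrichment_fixture
        with pytest.raises(ValidationError, match="empty study"):
            elim_enrichment(dag, ann, set(), set(genes))


class TestCategoryMeanP:
    def test_per_gene_minimum_then_mean(self, chain_enrichment_fixture):
        dag, ann, genes = chain_enrichment_fixture
        study = set(genes[:7]) | {genes[12]}
        results = elim_enrichment(dag, ann, study, set(genes), min_node_size=5)
        p = {r.term: r.p_raw for r in results}
        # leaf gene g01: annotated (after propagation) to leaf, mid, root
        got = category_mean_p(["g01", "g13"], results, ann)
        expect = (min(p["leaf"], p["mid"], p["root"]) + min(p["mid"], p["root"])) / 2
        assert got == pytest.approx(expect, abs=1e-15)

    def test_no_tested_term_raises(self, chain_enrichment_fixture):
        dag, ann, genes = chain_enrichment_fixture
        results = elim_enrichment(dag, ann, set(genes[:5]), set(genes), min_node_size=5)
        with pytest.raises(ValidationError):
            category_mean_p(["unknown_gene"], results, ann)
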