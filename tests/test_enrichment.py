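"""GO graph handling, true-path propagation, and Fisher over-representation."""

from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np
import pytest

from chepflow import (
    AnnotationSet,
    PlantedEnrichment,
    adjust_pvalues,
    enrich,
    fisher_overrepresentation,
    load_gaf,
    load_obo,
    propagate,
    simulate_go,
)
from chepflow.synthetic import write_gaf, write_obo


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Exact upper-tail sum with integer arithmetic."""
    total = Fraction(0)
    for i in range(k, min(n, K) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
    return float(total)


MINIMAL_OBO = """format-version: 1.2
ontology: test

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: child
namespace: biological_process
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: gone
namespace: biological_process
is_obsolete: true
"""


class TestLoaders:
    def test_minimal_obo_terms_and_edges(self, tmp_path):
        p = tmp_path / "min.obo"
        p.write_text(MINIMAL_OBO)
        g = load_obo(p)
        assert set(g.nodes) == {"GO:0000001", "GO:0000002"}  # obsolete skipped
        assert list(g.edges(keys=True)) == [("GO:0000002", "GO:0000001", "is_a")]

    def test_cyclic_ontology_rejected(self, tmp_path):
        cyclic = MINIMAL_OBO.replace(
            "id: GO:0000001\nname: root\nnamespace: biological_process\n",
            "id: GO:0000001\nname: root\nnamespace: biological_process\nis_a: GO:0000002\n",
        )
        p = tmp_path / "cyc.obo"
        p.write_text(cyclic)
        with pytest.raises(ValueError, match="cycle"):
            load_obo(p)

    def test_gaf_not_qualifier_excluded(self, tmp_path):
        gaf = (
            "!gaf-version: 2.2\n"
            + "DB\tP1\tP1\tinvolved_in\tGO:0000002\tREF\tIEA\t\tP\t\t\tprotein\ttaxon:9031\t20260101\tDB\t\t\n"
            + "DB\tP2\tP2\tNOT|involved_in\tGO:0000002\tREF\tIEA\t\tP\t\t\tprotein\ttaxon:9031\t20260101\tDB\t\t\n"
        )
        p = tmp_path / "a.gaf"
        p.write_text(gaf)
        ann = load_gaf(p)
        assert "P1" in ann.annotations and "P2" not in ann.annotations

    def test_malformed_lines_counted(self, tmp_path):
        good = "DB\tP{i}\tP{i}\tinvolved_in\tGO:0000002\tREF\tIEA\t\tP\t\t\tprotein\ttaxon:9031\t20260101\tDB\t\t\n"
        lines = ["!gaf-version: 2.2\n"]
        for i in range(8):
            lines.append(good.format(i=i))
        lines.append("broken line without tabs\n")
        lines.append("DB\tonly\tthree\n")
        p = tmp_path / "b.gaf"
        p.write_text("".join(lines))
        ann = load_gaf(p)
        assert sum(len(t) for t in ann.annotations.values()) == 8
        assert ann.n_skipped == 2

    def test_writer_loader_round_trip(self, tmp_path):
        ids = [f"P{i}" for i in range(30)]
        graph, ann = simulate_go(
            ids, n_terms=6, planted=None, seed=0, background_rate=0.3
        )
        g2 = load_obo(write_obo(graph, tmp_path / "x.obo"))
        a2 = load_gaf(write_gaf(ann, tmp_path / "x.gaf"))
        assert set(g2.nodes) == set(graph.nodes)
        assert set(g2.edges(keys=True)) == set(graph.edges(keys=True))
        assert a2.annotations == {p: t for p, t in ann.annotations.items() if t}


class TestPropagate:
    def _chain_graph(self):
        g = nx.MultiDiGraph()
        for t in ("GO:1", "GO:2", "GO:3"):
            g.add_node(t, name=t)
        g.add_edge("GO:3", "GO:2", key="is_a")
        g.add_edge("GO:2", "GO:1", key="is_a")
        return g

    def test_leaf_annotation_reaches_every_ancestor(self):
        g = self._chain_graph()
        ann = AnnotationSet({"P1": {"GO:3"}})
        prop = propagate(g, ann)
        assert prop.annotations["P1"] == {"GO:1", "GO:2", "GO:3"}

    def test_idempotent(self):
        g = self._chain_graph()
        prop = propagate(g, AnnotationSet({"P1": {"GO:3"}, "P2": {"GO:2"}}))
        again = propagate(g, AnnotationSet(prop.annotations, propagated=False))
        assert again.annotations == prop.annotations

    def test_unknown_terms_kept_direct_only(self):
        g = self._chain_graph()
        prop = propagate(g, AnnotationSet({"P1": {"GO:999"}}))
        assert prop.annotations["P1"] == {"GO:999"}

    def test_matches_edge_relaxation_closure(self):
        rng = np.random.default_rng(5)
        g = nx.MultiDiGraph()
        terms = [f"GO:{i}" for i in range(20)]
        for i, t in enumerate(terms):
            g.add_node(t)
            if i > 0:
                g.add_edge(t, terms[int(rng.integers(0, i))], key="is_a")
        raw = {
            f"P{j}": set(rng.choice(terms, size=3, replace=False)) for j in range(30)
        }
        prop = propagate(g, AnnotationSet({p: set(t) for p, t in raw.items()}))
        # oracle: repeated relaxation over edges until fixpoint
        closure = {p: set(t) for p, t in raw.items()}
        changed = True
        while changed:
            changed = False
            for p, terms_of_p in closure.items():
                new = set(terms_of_p)
                for t in terms_of_p:
                    for _, parent in g.out_edges(t):
                        new.add(parent)
                if new != terms_of_p:
                    closure[p] = new
                    changed = True
        assert prop.annotations == closure


def _flat_graph(terms):
    g = nx.MultiDiGraph()
    g.add_node("GO:root", name="root", namespace="biological_process")
    for t in terms:
        g.add_node(t, name=t, namespace="biological_process")
        g.add_edge(t, "GO:root", key="is_a")
    return g


class TestEnrich:
    def test_universal_term_is_unenriched(self):
        g = _flat_graph(["GO:a"])
        universe = [f"P{i}" for i in range(20)]
        ann = AnnotationSet({p: {"GO:a", "GO:root"} for p in universe}, propagated=True)
        results = enrich(universe[:5], universe, g, ann, min_term_size=1)
        assert all(r.p_value == pytest.approx(1.0) for r in results)

    def test_worked_hypergeometric_example(self):
        # N=10, K=4, n=5, k=4 -> C(4,4)C(6,1)/C(10,5) = 6/252
        g = _flat_graph(["GO:a"])
        universe = [f"P{i}" for i in range(10)]
        ann = {p: {"GO:root"} for p in universe}
        for p in universe[:4]:
            ann[p].add("GO:a")
        cluster = universe[:4] + [universe[9]]  # contains all 4 annotated
        results = enrich(cluster, universe, g, AnnotationSet(ann, propagated=True), min_term_size=1)
        r = next(r for r in results if r.term == "GO:a")
        assert (r.k, r.n, r.K, r.N) == (4, 5, 4, 10)
        assert r.p_value == pytest.approx(6 / 252, abs=1e-12)
        assert r.fold_enrichment == pytest.approx((4 / 5) / (4 / 10))

    def test_matches_exhaustive_tail_sums(self):
        for N in (5, 12, 25):
            for K in range(1, N + 1):
                for n in range(1, N + 1):
                    for k in range(max(0, n + K - N), min(n, K) + 1):
                        assert fisher_overrepresentation(k, n, K, N) == pytest.approx(
                            hypergeom_tail(k, n, K, N), abs=1e-10
                        )

    def test_planted_term_ranks_first(self, clean_simulation):
        m, truth = clean_simulation
        g, ann = simulate_go(
            list(m.proteins),
            n_terms=15,
            planted=PlantedEnrichment("early_accumulation", "GO:0000001", 8.0),
            seed=3,
            archetype_labels=truth.archetypes,
        )
        prop = propagate(g, ann)
        cluster = [p for p in m.proteins if truth.archetypes[p] == "early_accumulation"]
        results = enrich(cluster, list(m.proteins), g, prop)
        top = [r for r in results if r.K < r.N]  # ignore the universal root
        assert top[0].term == "GO:0000001"

    def test_universe_restriction_changes_only_background(self):
        g = _flat_graph(["GO:a"])
        annotated = [f"P{i}" for i in range(10)]
        unannotated = [f"U{i}" for i in range(5)]
        ann = {p: {"GO:root"} for p in annotated}
        for p in annotated[:4]:
            ann[p].add("GO:a")
        a = AnnotationSet(ann, propagated=True)
        cluster = annotated[:5]
        wide = enrich(cluster, annotated + unannotated, g, a, min_term_size=1)
        narrow = enrich(cluster, annotated, g, a, min_term_size=1)
        fw = next(r for r in wide if r.term == "GO:a")
        fn = next(r for r in narrow if r.term == "GO:a")
        assert (fw.k, fw.n) == (fn.k, fn.n)
        assert (fw.K, fw.N) == (fn.K, fn.N)  # unannotated never count anywhere

    def test_cluster_outside_universe_rejected(self):
        g = _flat_graph(["GO:a"])
        ann = AnnotationSet({"P1": {"GO:a"}}, propagated=True)
        with pytest.raises(ValueError, match="subset"):
            enrich(["P9"], ["P1"], g, ann)

    def test_unpropagated_annotations_rejected(self):
        g = _flat_graph(["GO:a"])
        ann = AnnotationSet({"P1": {"GO:a"}}, propagated=False)
        with pytest.raises(ValueError, match="propagated"):
            enrich(["P1"], ["P1"], g, ann)

    def test_elim_with_zero_alpha_is_classic(self, clean_simulation):
        m, truth = clean_simulation
        g, ann = simulate_go(
            list(m.proteins),
            n_terms=12,
            planted=PlantedEnrichment("invariant", "GO:0000002", 6.0),
            seed=9,
            archetype_labels=truth.archetypes,
        )
        prop = propagate(g, ann)
        cluster = [p for p in m.proteins if truth.archetypes[p] == "invariant"]
        classic = enrich(cluster, list(m.proteins), g, prop, method="classic")
        elim0 = enrich(cluster, list(m.proteins), g, prop, method="elim", elim_alpha=0.0)
        assert [(r.term, r.p_value) for r in classic] == [(r.term, r.p_value) for r in elim0]

    def test_elim_discounts_significant_child_from_parent(self):
        # parent's annotations are exactly the child's; once the child is
        # significant, the parent loses those proteins and its p rises
        g = nx.MultiDiGraph()
        for t in ("GO:root", "GO:parent", "GO:child"):
            g.add_node(t, name=t, namespace="biological_process")
        g.add_edge("GO:parent", "GO:root", key="is_a")
        g.add_edge("GO:child", "GO:parent", key="is_a")
        universe = [f"P{i}" for i in range(40)]
        ann = {p: {"GO:root"} for p in universe}
        for p in universe[:8]:
            ann[p] |= {"GO:child", "GO:parent"}
        a = AnnotationSet(ann, propagated=True)
        cluster = universe[:8]
        classic = {r.term: r for r in enrich(cluster, universe, g, a, method="classic")}
        elim = {r.term: r for r in enrich(cluster, universe, g, a, method="elim", elim_alpha=0.05)}
        assert elim["GO:child"].p_value == classic["GO:child"].p_value
        assert elim["GO:parent"].p_value > classic["GO:parent"].p_value


class TestAdjust:
    def _result(self, p, cluster="c", namespace="biological_process"):
        from chepflow.enrichment import EnrichmentResult

        return EnrichmentResult(
            term=f"GO:{p}", name="t", namespace=namespace, cluster=cluster,
            k=1, n=2, K=2, N=10, p_value=p, method="classic",
        )

    def test_single_test_q_equals_p(self):
        (r,) = adjust_pvalues([self._result(0.04)])
        assert r.q_value == pytest.approx(0.04)

    def test_step_up_hand_example(self):
        results = adjust_pvalues([self._result(p) for p in (0.01, 0.02, 0.03)])
        assert [r.q_value for r in results] == pytest.approx([0.03, 0.03, 0.03])

    def test_q_monotone_in_p(self):
        rng = np.random.default_rng(6)
        results = adjust_pvalues([self._result(float(p)) for p in rng.uniform(0.001, 1, 30)])
        ordered = sorted(results, key=lambda r: r.p_value)
        qs = [r.q_value for r in ordered]
        assert all(b >= a - 1e-12 for a, b in zip(qs, qs[1:]))

    def test_families_adjusted_separately(self):
        results = [self._result(0.01, cluster="c1"), self._result(0.01, cluster="c2")]
        out = adjust_pvalues(results)
        assert all(r.q_value == pytest.approx(0.01) for r in out)
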