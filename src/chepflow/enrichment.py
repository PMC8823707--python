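"""GO-term over-representation in kinetic clusters.

Follows the restricted-universe convention: only proteins that entered the
cluster analysis *and* carry GO annotations form the background, not the
whole proteome.  Annotations are closed under the true-path rule before
testing.  The test statistic is a one-sided Fisher's exact p-value per
term; the graph-aware "elim" variant discounts, from each ancestor term,
the proteins already attributed to a significantly enriched child, so
general terms are not called solely on the strength of a specific one.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

#: Edge keys that carry the true-path (transitive annotation) semantics.
TRUE_PATH_RELATIONS = ("is_a", "part_of")


@dataclass
class AnnotationSet:
    """Protein -> set of GO term IDs, before or after propagation."""

    annotations: dict[str, set[str]]
    propagated: bool = False
    n_skipped: int = 0  # malformed GAF lines dropped at load time

    @property
    def proteins(self) -> set[str]:
        return set(self.annotations)

    def terms(self) -> set[str]:
        out: set[str] = set()
        for t in self.annotations.values():
            out |= t
        return out

    def annotated(self, ids: Iterable[str]) -> set[str]:
        """Subset of ``ids`` that carry at least one annotation."""
        return {p for p in ids if self.annotations.get(p)}


def load_obo(path: str | Path) -> nx.MultiDiGraph:
    """Read an OBO ontology into a child->parent MultiDiGraph.

    Obsolete terms are skipped (with a logged count); only is_a and
    part_of edges are kept.  A cyclic ontology is rejected.
    """
    graph = obonet.read_obo(str(path), ignore_obsolete=False)
    obsolete = [n for n, d in graph.nodes(data=True) if d.get("is_obsolete") in ("true", True)]
    if obsolete:
        logger.info("skipping %d obsolete terms", len(obsolete))
        graph.remove_nodes_from(obsolete)
    drop = [
        (u, v, k)
        for u, v, k in graph.edges(keys=True)
        if k not in TRUE_PATH_RELATIONS
    ]
    graph.remove_edges_from(drop)
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError(f"{path}: ontology graph contains a cycle")
    return graph


def load_gaf(path: str | Path) -> AnnotationSet:
    """Read GAF 2.1/2.2 annotations (unpropagated).

    Rows whose qualifier contains NOT are excluded (negated annotations);
    malformed lines (fewer than 15 tab-separated fields) are skipped,
    counted and logged.
    """
    path = Path(path)
    annotations: dict[str, set[str]] = {}
    n_skipped = 0
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("!"):
                continue
            if len(row) < 15:
                n_skipped += 1
                continue
            db_object_id, qualifier, go_id = row[1], row[3], row[4]
            if not db_object_id or not go_id.startswith("GO:"):
                n_skipped += 1
                continue
            if "NOT" in qualifier.split("|"):
                continue
            annotations.setdefault(db_object_id, set()).add(go_id)
    if n_skipped:
        logger.info("%s: skipped %d malformed GAF lines", path, n_skipped)
    return AnnotationSet(annotations=annotations, propagated=False, n_skipped=n_skipped)


def propagate(g: nx.MultiDiGraph, a: AnnotationSet) -> AnnotationSet:
    """Close annotations under the true-path rule (annotate all ancestors).

    Terms present in the GAF but absent from the graph are kept as
    direct-only annotations and logged.  Idempotent.
    """
    ancestors: dict[str, set[str]] = {}

    def anc(term: str) -> set[str]:
        if term not in ancestors:
            # edges point child -> parent, so graph-descendants are ancestors
            ancestors[term] = set(nx.descendants(g, term))
        return ancestors[term]

    unknown: set[str] = set()
    out: dict[str, set[str]] = {}
    for protein, terms in a.annotations.items():
        closed = set(terms)
        for term in terms:
            if term in g:
                closed |= anc(term)
            else:
                unknown.add(term)
        out[protein] = closed
    if unknown:
        logger.info("%d annotated terms absent from the ontology; kept direct-only", len(unknown))
    return AnnotationSet(annotations=out, propagated=True, n_skipped=a.n_skipped)


@dataclass
class EnrichmentResult:
    """One term x cluster over-representation test."""

    term: str
    name: str
    namespace: str
    cluster: str
    k: int  # annotated in cluster
    n: int  # cluster size
    K: int  # annotated in universe
    N: int  # universe size
    p_value: float
    method: str
    q_value: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.k <= min(self.n, self.K):
            raise ValueError("contingency counts inconsistent")
        if not 0 < self.p_value <= 1:
            raise ValueError("p-value out of (0, 1]")

    @property
    def fold_enrichment(self) -> float:
        if self.K == 0 or self.n == 0:
            return float("nan")
        return (self.k / self.n) / (self.K / self.N)


def fisher_overrepresentation(k: int, n: int, K: int, N: int) -> float:
    """One-sided Fisher's exact p = P(X >= k), X ~ Hypergeom(N, K, n)."""
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    cluster_ids: Iterable[str],
    universe_ids: Iterable[str],
    g: nx.MultiDiGraph,
    a: AnnotationSet,
    method: str = "classic",
    min_term_size: int = 5,
    elim_alpha: float = 0.01,
    cluster_name: str = "cluster",
) -> list[EnrichmentResult]:
    """Test every sufficiently annotated term for over-representation.

    The universe is restricted to annotated proteins before testing; the
    cluster must be a subset of the (unrestricted) universe.  ``classic``
    tests each term independently; ``elim`` walks terms leaf-upward and
    removes from each ancestor's gene set the proteins already attributed
    to a significant child (child p < ``elim_alpha``).  Results are sorted
    by p-value.
    """
    if not a.propagated:
        raise ValueError("annotations must be propagated before enrichment")
    if method not in ("classic", "elim"):
        raise ValueError(f"unknown method {method!r}")
    universe_all = set(universe_ids)
    cluster_all = set(cluster_ids)
    if not cluster_all <= universe_all:
        raise ValueError("cluster is not a subset of the universe")
    universe = a.annotated(universe_all)
    if not universe:
        raise ValueError("empty universe after restriction to annotated proteins")
    cluster = cluster_all & universe
    N, n = len(universe), len(cluster)

    term_proteins: dict[str, set[str]] = {}
    for protein in universe:
        for term in a.annotations.get(protein, ()):
            term_proteins.setdefault(term, set()).add(protein)
    testable = [t for t, ps in term_proteins.items() if len(ps) >= min_term_size and t in g]

    # leaf-upward order: a term precedes its ancestors
    sub = g.subgraph([t for t in g if t in term_proteins])
    topo = [t for t in nx.topological_sort(sub) if t in testable]

    removed: dict[str, set[str]] = {t: set() for t in testable}
    results: list[EnrichmentResult] = []
    alpha = elim_alpha if method == "elim" else 0.0
    for term in topo:
        proteins = term_proteins[term] - removed[term]
        K = len(proteins)
        k = len(proteins & cluster)
        # K can reach 0 under elim when a child absorbed every protein;
        # the term is then trivially unenriched (p = 1)
        p = fisher_overrepresentation(k, n, K, N)
        node = g.nodes[term]
        results.append(
            EnrichmentResult(
                term=term,
                name=node.get("name", term),
                namespace=node.get("namespace", ""),
                cluster=cluster_name,
                k=k,
                n=n,
                K=K,
                N=N,
                p_value=p,
                method=method,
            )
        )
        if alpha > 0 and p < alpha:
            # discount this term's genes from every ancestor still to test
            for ancestor in nx.descendants(g, term):
                if ancestor in removed:
                    removed[ancestor] |= term_proteins[term]
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def adjust_pvalues(
    results: Sequence[EnrichmentResult], method: str = "BH"
) -> list[EnrichmentResult]:
    """Attach Benjamini-Hochberg q-values per cluster x namespace family."""
    from statsmodels.stats.multitest import multipletests

    if method != "BH":
        raise ValueError("only Benjamini-Hochberg ('BH') is supported")
    out = list(results)
    groups: dict[tuple[str, str], list[int]] = {}
    for i, r in enumerate(out):
        groups.setdefault((r.cluster, r.namespace), []).append(i)
    for idx in groups.values():
        pvals = [out[i].p_value for i in idx]
        q = multipletests(pvals, method="fdr_bh")[1]
        for i, qv in zip(idx, q):
            out[i].q_value = float(qv)
    return out


def results_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Flatten results for TSV export."""
    return pd.DataFrame(
        [
            {
                "cluster": r.cluster,
                "term": r.term,
                "name": r.name,
                "namespace": r.namespace,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "fold_enrichment": r.fold_enrichment,
                "method": r.method,
            }
            for r in results
        ]
    )
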