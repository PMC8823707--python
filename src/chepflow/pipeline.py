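"""End-to-end orchestration from a single YAML configuration.

Stage order: quantification IO (read or simulate) -> normalization and
filtering -> k-means and UPGMA clustering at the configured granularities
-> t-SNE embedding -> GO enrichment per cluster -> iBAQ composition.
Every stage writes its TSV outputs into the run directory, and a JSON
manifest records inputs, parameters, derived seeds and row counts, so a
single integer seed reproduces the entire run byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import cluster as _cluster
from . import composition as _composition
from . import embedding as _embedding
from . import enrichment as _enrichment
from . import quant as _quant
from . import synthetic as _synthetic

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "quant", "kmeans", "tree", "embedding", "enrichment", "composition")


def derive_stage_seeds(seed: int) -> dict[str, int]:
    """Expand one global seed into independent per-stage seeds (< 2^31)."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_STAGES))
    return {
        stage: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for stage, child in zip(_STAGES, children)
    }


@dataclass
class PipelineConfig:
    """Validated parameters for one pipeline run."""

    outdir: Path
    seed: int = 0
    # input source: "simulate" or a path to a quantification table
    quant_table: str = "simulate"
    fasta: str | None = None
    obo: str | None = None
    gaf: str | None = None
    histone_ids: tuple[str, ...] = _synthetic.HISTONE_IDS
    max_missing_fraction: float = 0.5
    k_list: tuple[int, ...] = (6,)
    kmeans_restarts: int = 20
    cut_heights: tuple[float, ...] = (1.7, 1.0, 0.6)
    trend_thresholds: tuple[float, float] = (-0.58, 0.58)
    perplexity: float = 50.0
    theta: float = 0.0
    tsne_iterations: int = 1000
    enrichment_method: str = "classic"
    min_term_size: int = 5
    elim_alpha: float = 0.01
    enrich_min_cluster_size: int = 10
    digest_min_len: int = 6
    digest_max_len: int = 30
    missed_cleavages: int = 0
    simulation: _synthetic.SimulationConfig | None = None

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if not self.histone_ids:
            raise ValueError("histone anchor IDs must be configured")
        if self.quant_table != "simulate" and not Path(self.quant_table).exists():
            raise FileNotFoundError(self.quant_table)
        for name in ("fasta", "obo", "gaf"):
            p = getattr(self, name)
            if self.quant_table != "simulate" and p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if any(k < 1 for k in self.k_list):
            raise ValueError("every k must be >= 1")
        if any(h < 0 for h in self.cut_heights):
            raise ValueError("cut heights must be non-negative")
        if self.quant_table == "simulate" and self.simulation is None:
            self.simulation = _synthetic.SimulationConfig(seed=derive_stage_seeds(self.seed)["simulate"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(
            **{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw.items()
            }
        )
        if sim is not None:
            cfg.simulation = _synthetic.SimulationConfig(**sim)
        return cfg


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str | None = None) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)


def run(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full analysis; returns the run manifest.

    On a stage failure, partial outputs are retained and a ``FAILED``
    marker naming the stage is written before the error propagates.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_stage_seeds(config.seed)
    manifest: dict[str, Any] = {
        "config": _config_dict(config),
        "seeds": seeds,
        "counts": {},
        "outputs": [],
    }
    stage = "setup"
    try:
        # -- inputs --------------------------------------------------------
        stage = "simulate"
        sequences: dict[str, str] = {}
        truth = None
        if config.quant_table == "simulate":
            sim = config.simulation
            matrix, truth = _synthetic.simulate_quant_matrix(sim)
            records = _synthetic.simulate_sequences(
                matrix.n_proteins, seed=seeds["simulate"], ids=list(matrix.proteins)
            )
            sequences = {r.id: str(r.seq) for r in records}
            go_graph, go_annotations = _synthetic.simulate_go(
                list(matrix.proteins),
                n_terms=20,
                planted=_synthetic.PlantedEnrichment(
                    archetype="immediate_depletion", term="GO:0000001", enrichment_factor=8.0
                ),
                seed=seeds["simulate"],
                archetype_labels=truth.archetypes,
            )
            inputs = out / "inputs"
            seq_lengths = pd.Series({p: len(s) for p, s in sequences.items()})
            _quant.write_quant_table(matrix, inputs / "quant_table.tsv", sequence_lengths=seq_lengths)
            _synthetic.write_fasta(records, inputs / "proteins.fasta")
            _synthetic.write_obo(go_graph, inputs / "ontology.obo")
            _synthetic.write_gaf(go_annotations, inputs / "annotations.gaf")
            truth.write(inputs / "truth.tsv")
            quant_path = inputs / "quant_table.tsv"
            obo_path, gaf_path, fasta_path = (
                inputs / "ontology.obo",
                inputs / "annotations.gaf",
                inputs / "proteins.fasta",
            )
        else:
            quant_path = Path(config.quant_table)
            obo_path = Path(config.obo) if config.obo else None
            gaf_path = Path(config.gaf) if config.gaf else None
            fasta_path = Path(config.fasta) if config.fasta else None

        # -- quantification ------------------------------------------------
        stage = "quant"
        matrix = _quant.read_quant_table(quant_path, histone_ids=config.histone_ids)
        normalized = _quant.log2_normalize(matrix)
        filtered, report = _quant.filter_by_detection(normalized, config.max_missing_fraction)
        complete = _quant.complete_cases(filtered)
        manifest["counts"]["quant"] = {
            "n_input": report.n_input,
            "n_discarded": report.n_discarded,
            "n_retained": report.n_retained,
            "n_complete": report.n_complete,
        }
        _write_tsv(complete.ratios, out / "normalized_complete.tsv", index_label="protein_id")

        # -- clustering ----------------------------------------------------
        stage = "kmeans"
        kmeans_results = {}
        assignment_table = pd.DataFrame(index=complete.proteins)
        for k in config.k_list:
            res = _cluster.kmeans_profiles(
                complete, k, seed=seeds["kmeans"] + k, n_restarts=config.kmeans_restarts
            )
            kmeans_results[k] = res
            assignment_table[f"kmeans_k{k}"] = res.labels()
            manifest["counts"][f"kmeans_k{k}"] = {
                "variance_explained": res.variance_explained,
                "sizes": res.sizes.to_dict(),
            }

        stage = "tree"
        tree = _cluster.build_tree(complete)
        (out / "tree.nwk").write_text(tree.to_newick() + "\n")
        cuts = {}
        for h in config.cut_heights:
            cut = _cluster.cut_tree(tree, h)
            cuts[h] = cut
            assignment_table[f"cut_h{h}"] = cut.labels
            manifest["counts"][f"cut_h{h}"] = {
                "n_clusters": cut.n_clusters,
                "n_singletons": cut.n_singletons,
            }
        _write_tsv(assignment_table, out / "cluster_assignments.tsv", index_label="protein_id")

        primary_k = config.k_list[0]
        medians = _cluster.cluster_medians(complete, kmeans_results[primary_k])
        _write_tsv(medians, out / "cluster_medians.tsv", index_label="cluster")
        trends = _cluster.classify_trends(medians, config.trend_thresholds)
        _write_tsv(
            pd.DataFrame({"trend": trends.labels, "endcourse_mean": trends.endcourse_means}),
            out / "cluster_trends.tsv",
            index_label="cluster",
        )
        corr = _cluster.timepoint_correlation(complete)
        _write_tsv(corr, out / "timepoint_correlation.tsv", index_label="timepoint")
        scores, evr = _cluster.pca_profiles(complete, n_components=2)
        _write_tsv(scores, out / "pca_scores.tsv", index_label="protein_id")
        manifest["counts"]["pca_explained_variance"] = [float(v) for v in evr]

        # -- embedding -----------------------------------------------------
        stage = "embedding"
        emb = _embedding.tsne_embed(
            complete,
            perplexity=config.perplexity,
            theta=config.theta,
            seed=seeds["embedding"],
            n_iter=config.tsne_iterations,
        )
        emb.write(out / "tsne.tsv")
        overlay = _embedding.overlay_clusters(emb, kmeans_results[primary_k])
        _write_tsv(overlay, out / "tsne_clusters.tsv", index_label="protein_id")

        # -- enrichment ----------------------------------------------------
        stage = "enrichment"
        if obo_path is not None and gaf_path is not None:
            graph = _enrichment.load_obo(obo_path)
            annotations = _enrichment.propagate(graph, _enrichment.load_gaf(gaf_path))
            universe = [p for p in complete.proteins]
            all_results = []
            for h, cut in cuts.items():
                for cluster_id in cut.sizes.index:
                    members = cut.members(int(cluster_id))
                    if len(members) < config.enrich_min_cluster_size:
                        continue
                    name = f"h{h}:{cut.labels[members[0]]}"
                    all_results.extend(
                        _enrichment.enrich(
                            list(members),
                            universe,
                            graph,
                            annotations,
                            method=config.enrichment_method,
                            min_term_size=config.min_term_size,
                            elim_alpha=config.elim_alpha,
                            cluster_name=name,
                        )
                    )
            all_results = _enrichment.adjust_pvalues(all_results)
            _write_tsv(_enrichment.results_table(all_results), out / "go_enrichment.tsv")
            manifest["counts"]["enrichment_tests"] = len(all_results)

        # -- composition ---------------------------------------------------
        stage = "composition"
        if fasta_path is not None:
            from Bio import SeqIO

            seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta_path), "fasta")}
            covered = [p for p in complete.proteins if p in seqs]
            digests = {
                p: _composition.digest(
                    seqs[p],
                    min_len=config.digest_min_len,
                    max_len=config.digest_max_len,
                    missed_cleavages=config.missed_cleavages,
                    protein_id=p,
                )
                for p in covered
            }
            mws = {p: _composition.molecular_weight(seqs[p]) for p in covered}
            ibaq = _composition.compute_ibaq(
                complete.intensities.loc[covered], digests, mws
            )
            comp = _composition.cluster_composition(ibaq, kmeans_results[primary_k])
            comp.write(out / "cluster_composition.tsv")
            manifest["counts"]["composition_proteins"] = len(covered) - len(ibaq.excluded)

        manifest["outputs"] = sorted(
            str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
        )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        _write_summary(out, manifest)
        return manifest
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        raise


def _config_dict(config: PipelineConfig) -> dict[str, Any]:
    d = dataclasses.asdict(config)
    d["outdir"] = str(config.outdir)
    return d


def _write_summary(out: Path, manifest: Mapping[str, Any]) -> None:
    counts = manifest["counts"]
    lines = ["chepflow run summary", "====================", ""]
    q = counts.get("quant", {})
    lines.append(
        f"proteins: {q.get('n_input')} input, {q.get('n_retained')} retained, "
        f"{q.get('n_complete')} complete cases"
    )
    for key in sorted(counts):
        if key.startswith("kmeans_k"):
            ve = counts[key]["variance_explained"]
            lines.append(f"{key}: variance explained {ve:.3f}")
        if key.startswith("cut_h"):
            c = counts[key]
            lines.append(
                f"{key}: {c['n_clusters']} clusters ({c['n_singletons']} singletons)"
            )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
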