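"""Synthetic SILAC time-course generator with known ground truth.

Emulates the statistical structure of a ChEP mitotic-entry experiment:
proteins follow a small set of kinetic archetypes (successive waves of
depletion from chromatin, early/late accumulation, an invariant core),
observed as log2 ratios against a common G2/M reference across 7 time
points x 2 replicates, with replicate noise and intensity-dependent
missing values (low-abundance proteins drop out more often; missing
values are never imputed downstream).

Every simulated protein carries its planted archetype label and
noise-free profile, so clustering, trend classification, enrichment and
composition can all be scored against truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .quant import (
    REPLICATES,
    TIME_MINUTES,
    TIMEPOINTS,
    Design,
    QuantMatrix,
    sample_columns,
)

#: IDs of the simulated core histones; drawn from the invariant archetype
#: and given high abundance, mirroring their role as normalization anchors.
HISTONE_IDS: tuple[str, ...] = ("HIST_H2A", "HIST_H2B", "HIST_H3", "HIST_H4")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class KineticArchetype:
    """A smooth kinetic program for chromatin association.

    The expected log2 ratio follows a logistic transition from 0 (the G2
    reference level) to ``amplitude``, centred at ``onset_time`` with time
    constant ``tau`` (minutes).  The curve is exactly 0 at the G2 arrest
    point and plateaus at ``amplitude`` well before the end of the course.
    """

    name: str
    onset_time: float
    amplitude: float
    tau: float = 1.5
    trend: str = "minor-change"  # planted direction: depleted/accumulated/minor-change

    def shape(self, t_minutes: float) -> float:
        """Expected log2 ratio at time ``t_minutes`` (G2 arrest = -15)."""
        if self.amplitude == 0.0:
            return 0.0
        t_g2 = TIME_MINUTES["G2"]
        s = 1.0 / (1.0 + math.exp(-(t_minutes - self.onset_time) / self.tau))
        s_g2 = 1.0 / (1.0 + math.exp(-(t_g2 - self.onset_time) / self.tau))
        return self.amplitude * (s - s_g2) / (1.0 - s_g2)

    def profile(self, timepoints: Sequence[str] = TIMEPOINTS) -> np.ndarray:
        return np.array([self.shape(TIME_MINUTES[t]) for t in timepoints])


def default_archetypes() -> list[KineticArchetype]:
    """The six kinetic archetypes of mitotic chromatin remodeling.

    Three successive waves of depletion (immediate, mid-prophase at ~5 min,
    post-NEBD at ~10 min), an invariant core, and early/late accumulation.
    All transitions plateau by 15-25 min.
    """
    return [
        KineticArchetype("immediate_depletion", onset_time=0.0, amplitude=-2.5, tau=1.5, trend="depleted"),
        KineticArchetype("mid_prophase_depletion", onset_time=5.0, amplitude=-2.0, tau=1.5, trend="depleted"),
        KineticArchetype("post_nebd_depletion", onset_time=10.0, amplitude=-2.0, tau=1.2, trend="depleted"),
        KineticArchetype("invariant", onset_time=0.0, amplitude=0.0, trend="minor-change"),
        KineticArchetype("early_accumulation", onset_time=0.0, amplitude=1.5, tau=1.5, trend="accumulated"),
        KineticArchetype("late_accumulation", onset_time=10.0, amplitude=1.5, tau=1.2, trend="accumulated"),
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the generator.

    ``noise_sd`` is the replicate-level log2 measurement noise.  Dropout is
    missing-not-at-random: a cell is missing with probability
    ``logistic((dropout_midpoint - log10 intensity) * dropout_steepness)``;
    steepness 0 disables dropout only if the midpoint logic is bypassed,
    so ``dropout`` toggles it explicitly.
    """

    n_proteins_per_archetype: int = 100
    timepoints: tuple[str, ...] = TIMEPOINTS
    n_replicates: int = 2
    noise_sd: float = 0.2
    dropout: bool = True
    dropout_midpoint: float = 5.6  # log10 intensity at 50% dropout
    dropout_steepness: float = 3.0
    intensity_log10_mean: float = 7.0
    intensity_log10_sd: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.timepoints[0] != "G2":
            raise ValueError("timepoints must start with the G2 arrest sample")
        minutes = [TIME_MINUTES[t] for t in self.timepoints]
        if minutes != sorted(minutes):
            raise ValueError("timepoints must be ordered in time")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_proteins_per_archetype < 1:
            raise ValueError("need at least one protein per archetype")

    @property
    def replicates(self) -> tuple[str, ...]:
        return tuple(REPLICATES[: self.n_replicates]) if self.n_replicates <= len(
            REPLICATES
        ) else tuple(f"R{i+1}" for i in range(self.n_replicates))

    @property
    def samples(self) -> list[str]:
        return sample_columns(self.replicates, self.timepoints)


@dataclass
class TruthTable:
    """Ground truth per simulated protein.

    ``table`` has one row per protein: archetype label, true (latent)
    intensity, and sequence when one was attached.  ``profiles`` holds the
    noise-free expected log2 ratio per sample.
    """

    table: pd.DataFrame
    profiles: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.table.index.equals(self.profiles.index):
            raise ValueError("truth table and profiles index different proteins")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate protein IDs in truth table")

    @property
    def archetypes(self) -> pd.Series:
        return self.table["archetype"]

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.table.join(self.profiles)
        path.parent.mkdir(parents=True, exist_ok=True)
        out.to_csv(path, sep="\t", index_label="protein_id")
        return path


def _dropout_probability(
    log10_intensity: np.ndarray, midpoint: float, steepness: float
) -> np.ndarray:
    z = (midpoint - log10_intensity) * steepness
    return 1.0 / (1.0 + np.exp(-z))


def simulate_quant_matrix(
    config: SimulationConfig,
    archetypes: Sequence[KineticArchetype] | None = None,
) -> tuple[QuantMatrix, TruthTable]:
    """Draw a quantification matrix with planted kinetic structure.

    Each protein's observed log2 ratio is its archetype curve evaluated at
    the sample's time point plus independent Normal(0, noise_sd) noise per
    replicate.  Latent per-protein abundance is log-normal over ~3 orders
    of magnitude; cells drop out with the intensity-logistic probability.
    Four core-histone proteins are appended, drawn from the invariant
    archetype at high abundance, and flagged as the normalization anchor.

    Reproducible bit-for-bit from ``config.seed``.
    """
    if archetypes is None:
        archetypes = default_archetypes()
    if not archetypes:
        raise ValueError("need at least one archetype")
    rng = np.random.default_rng(config.seed)
    samples = config.samples
    minutes = np.array([TIME_MINUTES[timepoint] for timepoint in config.timepoints])

    ids: list[str] = []
    labels: list[str] = []
    clean_rows: list[np.ndarray] = []
    for arch in archetypes:
        per_tp = np.array([arch.shape(t) for t in minutes])
        clean = np.tile(per_tp, config.n_replicates)  # replicate-major sample order
        for i in range(config.n_proteins_per_archetype):
            ids.append(f"{arch.name.upper()}_{i:04d}")
            labels.append(arch.name)
            clean_rows.append(clean)

    invariant = next((a for a in archetypes if a.amplitude == 0.0), None)
    histone_profile = (
        np.zeros(len(samples))
        if invariant is None
        else np.tile(np.array([invariant.shape(t) for t in minutes]), config.n_replicates)
    )
    for hid in HISTONE_IDS:
        ids.append(hid)
        labels.append("invariant" if invariant is not None else "histone")
        clean_rows.append(histone_profile)

    index = pd.Index(ids, name="protein_id")
    clean = np.vstack(clean_rows)
    observed = clean + rng.normal(0.0, config.noise_sd, size=clean.shape)

    n = len(ids)
    log10_int = rng.normal(
        config.intensity_log10_mean, config.intensity_log10_sd, size=n
    )
    # histones are among the most abundant chromatin proteins; keep them
    # near the top of the dynamic range so the anchor is always quantified
    log10_int[-len(HISTONE_IDS):] = config.intensity_log10_mean + 2.0
    latent_intensity = 10.0 ** log10_int
    # per-sample intensity jitter around the latent abundance
    intensities = latent_intensity[:, None] * np.exp(
        rng.normal(0.0, 0.1, size=(n, len(samples)))
    )

    if config.dropout:
        p_miss = _dropout_probability(
            log10_int, config.dropout_midpoint, config.dropout_steepness
        )
        if np.all(p_miss >= 1.0):
            raise ValueError("dropout parameters would delete every cell")
        missing = rng.random(size=(n, len(samples))) < p_miss[:, None]
    else:
        missing = np.zeros((n, len(samples)), dtype=bool)

    ratios = pd.DataFrame(observed, index=index, columns=samples).mask(missing)
    intens = pd.DataFrame(intensities, index=index, columns=samples).mask(missing)
    flags = pd.Series(index.isin(HISTONE_IDS), index=index)
    matrix = QuantMatrix(ratios=ratios, intensities=intens, histone_flags=flags, log2=True)

    truth = TruthTable(
        table=pd.DataFrame(
            {"archetype": labels, "intensity": latent_intensity}, index=index
        ),
        profiles=pd.DataFrame(clean, index=index, columns=samples),
    )
    return matrix, truth


def simulate_sequences(
    n: int,
    length_range: tuple[int, int] = (100, 800),
    seed: int = 0,
    kr_frequency: float = 0.1,
    ids: Sequence[str] | None = None,
) -> list[SeqRecord]:
    """Random protein sequences with controlled K/R content.

    ``kr_frequency`` is the combined probability of lysine or arginine at
    each position (split evenly), which sets the expected tryptic peptide
    count; the other 18 residues are drawn uniformly.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    lo, hi = length_range
    if not (20 <= lo <= hi <= 5000):
        raise ValueError("length_range must lie within [20, 5000]")
    if not 0.0 <= kr_frequency < 1.0:
        raise ValueError("kr_frequency must be in [0, 1)")
    if ids is not None and len(ids) != n:
        raise ValueError("ids must match n")
    rng = np.random.default_rng(seed)
    others = [a for a in AMINO_ACIDS if a not in "KR"]
    probs = np.array(
        [kr_frequency / 2 if a in "KR" else (1 - kr_frequency) / len(others) for a in AMINO_ACIDS]
    )
    letters = np.array(list(AMINO_ACIDS))
    records = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(letters, size=length, p=probs))
        name = ids[i] if ids is not None else f"SYN_{i:05d}"
        records.append(SeqRecord(Seq(seq), id=name, description="synthetic protein"))
    return records


@dataclass(frozen=True)
class PlantedEnrichment:
    """A GO term planted to be over-represented in one archetype."""

    archetype: str
    term: str
    enrichment_factor: float

    def __post_init__(self) -> None:
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")


def simulate_go(
    universe_ids: Sequence[str],
    n_terms: int,
    planted: PlantedEnrichment | tuple[str, str, float] | None,
    seed: int = 0,
    archetype_labels: Mapping[str, str] | pd.Series | None = None,
    background_rate: float = 0.05,
    namespace: str = "biological_process",
):
    """Emit a small ontology DAG plus annotations with one planted signal.

    The graph is a root with ``n_terms`` descendants (each term's parent is
    the root or a random earlier term, guaranteeing acyclicity).  The
    planted term annotates proteins of the planted archetype at
    ``enrichment_factor`` times the background rate; every other term
    annotates proteins uniformly at ``background_rate``.

    Returns ``(graph, annotations)`` in the same representation the
    enrichment module uses (child->parent MultiDiGraph, unpropagated
    :class:`~chepflow.enrichment.AnnotationSet`).
    """
    import networkx as nx

    from .enrichment import AnnotationSet

    if isinstance(planted, tuple):
        planted = PlantedEnrichment(*planted)
    if n_terms < 1:
        raise ValueError("need at least one term")
    rng = np.random.default_rng(seed)

    root = "GO:0000000"
    terms = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    graph = nx.MultiDiGraph()
    graph.add_node(root, name="root", namespace=namespace)
    for i, term in enumerate(terms):
        parent = root if i == 0 else (root if rng.random() < 0.5 else terms[int(rng.integers(0, i))])
        graph.add_node(term, name=f"synthetic term {i + 1}", namespace=namespace)
        graph.add_edge(term, parent, key="is_a")

    universe = list(universe_ids)
    annotations: dict[str, set[str]] = {p: set() for p in universe}
    planted_term = None
    if planted is not None:
        if archetype_labels is None:
            raise ValueError("archetype_labels required when planting an enrichment")
        planted_term = planted.term if planted.term in terms else terms[0]
        planted_rate = background_rate * planted.enrichment_factor
        if planted_rate > 1:
            raise ValueError(
                f"planted rate {planted_rate:.3f} exceeds 1; lower the factor or background"
            )
        labels = (
            archetype_labels
            if isinstance(archetype_labels, Mapping)
            else archetype_labels.to_dict()
        )
        for p in universe:
            rate = planted_rate if labels.get(p) == planted.archetype else background_rate
            if rng.random() < rate:
                annotations[p].add(planted_term)
    for term in terms:
        if term == planted_term:
            continue
        hits = rng.random(len(universe)) < background_rate
        for p, hit in zip(universe, hits):
            if hit:
                annotations[p].add(term)
    # every protein gets at least the root, so the universe restriction
    # ("annotated proteins only") keeps the simulated universe intact
    for p in universe:
        annotations[p].add(root)
    return graph, AnnotationSet(annotations={p: set(t) for p, t in annotations.items()}, propagated=False)


# -- writers ---------------------------------------------------------------


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> Path:
    from Bio import SeqIO

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    return path


def write_obo(graph, path: str | Path) -> Path:
    """Write a minimal OBO 1.2 file (id/name/namespace/is_a stanzas)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["format-version: 1.2", "ontology: synthetic-go", ""]
    for node in sorted(graph.nodes):
        data = graph.nodes[node]
        lines.append("[Term]")
        lines.append(f"id: {node}")
        lines.append(f"name: {data.get('name', node)}")
        lines.append(f"namespace: {data.get('namespace', 'biological_process')}")
        for _, parent, key in graph.out_edges(node, keys=True):
            if key == "is_a":
                lines.append(f"is_a: {parent} ! {graph.nodes[parent].get('name', parent)}")
        lines.append("")
    path.write_text("\n".join(lines))
    return path


def write_gaf(annotations, path: str | Path, taxon: str = "taxon:9031") -> Path:
    """Write annotations as GAF 2.2 (synthetic evidence code IEA)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for protein in sorted(annotations.annotations):
        for term in sorted(annotations.annotations[protein]):
            rows.append(
                "\t".join(
                    [
                        "SYN",  # DB
                        protein,  # DB object ID
                        protein,  # symbol
                        "involved_in",  # qualifier
                        term,
                        "SYN:0000001",  # reference
                        "IEA",
                        "",
                        "P",
                        "",
                        "",
                        "protein",
                        taxon,
                        "20260101",
                        "SYN",
                        "",
                        "",
                    ]
                )
            )
    path.write_text("!gaf-version: 2.2\n" + "\n".join(rows) + "\n")
    return path
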