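"""Absolute chromatin composition via iBAQ.

iBAQ (intensity-based absolute quantification) divides a protein's summed
MS intensity by its count of theoretically observable tryptic peptides,
giving a quantity proportional to molar amount.  Normalizing iBAQ values
to 100% per sample yields copy-number fractions; weighting by molecular
mass before normalizing yields mass fractions.  Summing member fractions
per cluster gives the cluster-level composition of the chromatin
preparation across the time course.

Tryptic digestion follows the Keil rule: cleavage C-terminal to K or R,
suppressed when the next residue is proline.  "Observable" peptides are
those within the length window MS routinely samples (6-30 residues by
default, no missed cleavages — the original iBAQ convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster import ClusterAssignment, KMeansResult, _labels_of

#: Average (not monoisotopic) residue masses in Da, appropriate for
#: whole-protein mass budgeting.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

WATER_MASS = 18.0153


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - set(AVERAGE_RESIDUE_MASS)
    if bad:
        raise ValueError(f"non-standard residue(s): {sorted(bad)}")


@dataclass
class DigestResult:
    """In-silico tryptic digest of one protein."""

    protein_id: str
    peptides: list[str]
    n_observable: int

    def __post_init__(self) -> None:
        if self.n_observable < 0:
            raise ValueError("negative observable-peptide count")


def digest(
    sequence: str,
    min_len: int = 6,
    max_len: int = 30,
    missed_cleavages: int = 0,
    proline_rule: bool = True,
    protein_id: str = "",
) -> DigestResult:
    """Tryptic digest: cleave after K/R, not before P (Keil rule).

    ``peptides`` are the fully cleaved fragments, in order, whose
    concatenation reconstructs the input exactly.  ``n_observable`` counts
    fragments — plus, for ``missed_cleavages`` > 0, merged runs of up to
    that many adjacent fragments — whose length lies in
    ``[min_len, max_len]``.
    """
    _check_sequence(sequence)
    if min_len < 1 or max_len < min_len:
        raise ValueError("need 1 <= min_len <= max_len")
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be non-negative")
    peptides: list[str] = []
    start = 0
    for i, residue in enumerate(sequence):
        at_end = i == len(sequence) - 1
        cleave = residue in "KR" and not at_end and not (
            proline_rule and sequence[i + 1] == "P"
        )
        if cleave:
            peptides.append(sequence[start : i + 1])
            start = i + 1
    peptides.append(sequence[start:])

    n_observable = 0
    for mc in range(missed_cleavages + 1):
        for j in range(len(peptides) - mc):
            merged_len = sum(len(p) for p in peptides[j : j + mc + 1])
            if min_len <= merged_len <= max_len:
                n_observable += 1
    return DigestResult(protein_id=protein_id, peptides=peptides, n_observable=n_observable)


def molecular_weight(sequence: str) -> float:
    """Average molecular weight in Da: residue masses plus one water."""
    _check_sequence(sequence)
    return sum(AVERAGE_RESIDUE_MASS[a] for a in sequence) + WATER_MASS


@dataclass
class IBAQTable:
    """Per-protein iBAQ values and per-sample composition fractions.

    ``copy_fraction`` and ``mass_fraction`` are percentages summing to 100
    per sample over proteins with a finite iBAQ value; proteins with no
    observable peptide are excluded from the fractions and listed in
    ``excluded``.
    """

    ibaq: pd.DataFrame  # proteins x samples, MS units per peptide
    copy_fraction: pd.DataFrame  # percent
    mass_fraction: pd.DataFrame  # percent
    n_observable: pd.Series
    molecular_weights: pd.Series  # Da
    excluded: list[str]

    @property
    def proteins(self) -> pd.Index:
        return self.ibaq.index

    @property
    def samples(self) -> list[str]:
        return list(self.ibaq.columns)


def compute_ibaq(
    intensities: pd.DataFrame,
    digest_results: Mapping[str, DigestResult] | Sequence[DigestResult],
    molecular_weights: Mapping[str, float] | pd.Series,
) -> IBAQTable:
    """iBAQ and per-sample copy/mass fractions from raw intensities.

    ``intensities`` is proteins x samples (NaN = not quantified).  Proteins
    whose digest yields no observable peptide are flagged and excluded from
    the fractions.  Negative intensities are rejected.
    """
    if (intensities < 0).to_numpy().any():
        raise ValueError("negative intensity")
    if not isinstance(digest_results, Mapping):
        digest_results = {d.protein_id: d for d in digest_results}
    missing = [p for p in intensities.index if p not in digest_results]
    if missing:
        raise KeyError(f"no digest result for protein(s): {missing[:5]}")
    n_obs = pd.Series(
        {p: digest_results[p].n_observable for p in intensities.index}, dtype=float
    )
    mw = pd.Series(dict(molecular_weights)).reindex(intensities.index)
    if mw.isna().any():
        raise KeyError("molecular weight missing for some proteins")

    excluded = list(intensities.index[n_obs == 0])
    ibaq = intensities.div(n_obs.where(n_obs > 0), axis=0)

    copy_fraction = 100.0 * ibaq.div(ibaq.sum(axis=0, skipna=True), axis=1)
    weighted = ibaq.mul(mw, axis=0)
    mass_fraction = 100.0 * weighted.div(weighted.sum(axis=0, skipna=True), axis=1)
    return IBAQTable(
        ibaq=ibaq,
        copy_fraction=copy_fraction,
        mass_fraction=mass_fraction,
        n_observable=n_obs.astype(int),
        molecular_weights=mw,
        excluded=excluded,
    )


@dataclass
class ClusterComposition:
    """Cluster x sample copy/mass percentages (each summing to 100/sample)."""

    copy_fraction: pd.DataFrame
    mass_fraction: pd.DataFrame

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        long = (
            self.copy_fraction.stack()
            .rename("copy_pct")
            .to_frame()
            .join(self.mass_fraction.stack().rename("mass_pct"))
        )
        long.index.names = ["cluster", "sample"]
        long.reset_index().to_csv(path, sep="\t", index=False)
        return path


def cluster_composition(
    t: IBAQTable, a: ClusterAssignment | KMeansResult | pd.Series
) -> ClusterComposition:
    """Aggregate protein fractions to cluster fractions per sample.

    Proteins not covered by the assignment fall into an ``unassigned``
    pseudo-cluster.
    """
    labels = _labels_of(a).reindex(t.proteins).fillna("unassigned")
    copies = t.copy_fraction.groupby(labels).sum(min_count=1).fillna(0.0)
    mass = t.mass_fraction.groupby(labels).sum(min_count=1).fillna(0.0)
    return ClusterComposition(copy_fraction=copies, mass_fraction=mass)
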