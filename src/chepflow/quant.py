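"""Protein-level SILAC quantification matrices: IO, normalization, filtering.

The experimental design is a mitotic-entry time course: heavy-labeled cells
sampled at G2 arrest and at 0, 5, 10, 15, 20 and 25 min after release, each
mixed with a common light-labeled G2/M reference population, in two
biological replicates (14 samples).  Ratios are stored time-point over
reference, so depletion from chromatin gives negative log2 values.

Normalization is anchored on the core histones: per sample, a constant is
subtracted from every log2 ratio so that the mean log2 ratio of the flagged
histone proteins is exactly zero.  Histones are quantitatively retained on
chromatin throughout mitotic entry, which makes them an internal standard
for the amount of chromatin in each ChEP preparation.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

REPLICATES: tuple[str, ...] = ("A", "B")
TIMEPOINTS: tuple[str, ...] = ("G2", "0", "5", "10", "15", "20", "25")

#: Minutes after release from the G2 arrest.  The arrest point precedes the
#: release by construction; only the ordering matters downstream.
TIME_MINUTES: dict[str, float] = {
    "G2": -15.0,
    "0": 0.0,
    "5": 5.0,
    "10": 10.0,
    "15": 15.0,
    "20": 20.0,
    "25": 25.0,
}

#: Time points considered "end of course" for trend calls: the proteome
#: shows no further significant changes after 15 min.
ENDCOURSE_TIMEPOINTS: tuple[str, ...] = ("15", "20", "25")


def sample_columns(
    replicates: Sequence[str] = REPLICATES,
    timepoints: Sequence[str] = TIMEPOINTS,
) -> list[str]:
    """Ordered sample names of the full replicate x timepoint grid.

    Samples are replicate-major: ``A_G2, A_0, ..., A_25, B_G2, ..., B_25``.
    """
    return [f"{r}_{t}" for r in replicates for t in timepoints]


def replicate_of(sample: str) -> str:
    return sample.split("_", 1)[0]


def timepoint_of(sample: str) -> str:
    return sample.split("_", 1)[1]


@dataclass(frozen=True)
class Design:
    """Maps quantification-table columns onto the replicate/timepoint grid.

    Ratio and intensity columns are expected to be named
    ``<ratio_prefix><rep>_<time>`` and ``<intensity_prefix><rep>_<time>``.
    """

    replicates: tuple[str, ...] = REPLICATES
    timepoints: tuple[str, ...] = TIMEPOINTS
    ratio_prefix: str = "ratio_"
    intensity_prefix: str = "intensity_"
    id_column: str = "protein_id"

    @property
    def samples(self) -> list[str]:
        return sample_columns(self.replicates, self.timepoints)

    def ratio_column(self, sample: str) -> str:
        return f"{self.ratio_prefix}{sample}"

    def intensity_column(self, sample: str) -> str:
        return f"{self.intensity_prefix}{sample}"


DEFAULT_DESIGN = Design()


@dataclass
class QuantMatrix:
    """Proteins x samples of SILAC ratios with a shared missingness mask.

    Attributes
    ----------
    ratios : DataFrame, proteins x samples.  Heavy/light ratios against the
        common G2/M reference; linear scale when ``log2`` is False, log2
        scale afterwards.  NaN marks a cell not quantified.
    intensities : DataFrame, same shape.  Summed MS intensity per protein
        per sample (arbitrary units); NaN wherever the ratio is missing.
    histone_flags : boolean Series over proteins; the flagged set anchors
        the normalization.
    log2 : whether ``ratios`` is on the log2 scale.
    """

    ratios: pd.DataFrame
    intensities: pd.DataFrame
    histone_flags: pd.Series
    log2: bool = False

    def __post_init__(self) -> None:
        if not self.ratios.index.equals(self.intensities.index):
            raise ValueError("ratio and intensity tables index different proteins")
        if list(self.ratios.columns) != list(self.intensities.columns):
            raise ValueError("ratio and intensity tables have different samples")
        if not self.ratios.index.equals(self.histone_flags.index):
            raise ValueError("histone flags do not cover the protein set")
        if self.ratios.index.has_duplicates:
            dupes = self.ratios.index[self.ratios.index.duplicated()].unique()
            raise ValueError(f"duplicate protein IDs: {list(dupes)[:5]}")
        # one mask for both value tables
        mismatch = self.ratios.isna() != self.intensities.isna()
        if mismatch.to_numpy().any():
            raise ValueError("missingness mask differs between ratios and intensities")

    # -- basic views -------------------------------------------------------

    @property
    def proteins(self) -> pd.Index:
        return self.ratios.index

    @property
    def samples(self) -> list[str]:
        return list(self.ratios.columns)

    @property
    def n_proteins(self) -> int:
        return len(self.ratios.index)

    @property
    def n_samples(self) -> int:
        return self.ratios.shape[1]

    @property
    def mask(self) -> pd.DataFrame:
        """True where a cell is quantified."""
        return self.ratios.notna()

    def detection_counts(self) -> pd.Series:
        """Number of quantified samples per protein."""
        return self.ratios.notna().sum(axis=1)

    def is_complete(self) -> bool:
        return not self.ratios.isna().to_numpy().any()

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(
            ratios=self.ratios.copy(),
            intensities=self.intensities.copy(),
            histone_flags=self.histone_flags.copy(),
            log2=self.log2,
        )

    def subset(self, proteins: Iterable[str]) -> "QuantMatrix":
        idx = pd.Index(proteins)
        return QuantMatrix(
            ratios=self.ratios.loc[idx],
            intensities=self.intensities.loc[idx],
            histone_flags=self.histone_flags.loc[idx],
            log2=self.log2,
        )

    def values(self) -> np.ndarray:
        """Profile matrix (proteins x samples) as a float array."""
        return self.ratios.to_numpy(dtype=float)

    def set_histones(self, ids: Iterable[str]) -> "QuantMatrix":
        """Return a copy with the histone anchor set to ``ids``."""
        ids = set(ids)
        missing = ids - set(self.proteins)
        if missing:
            raise KeyError(f"histone anchor IDs not in matrix: {sorted(missing)}")
        flags = pd.Series(self.proteins.isin(ids), index=self.proteins)
        out = self.copy()
        out.histone_flags = flags
        return out


@dataclass(frozen=True)
class FilterReport:
    """Accounting for a detection filter pass."""

    n_input: int
    n_discarded: int
    n_retained: int
    n_complete: int
    rule: str

    def __post_init__(self) -> None:
        if self.n_input != self.n_discarded + self.n_retained:
            raise ValueError("filter report counts do not add up")
        if self.n_complete > self.n_retained:
            raise ValueError("complete-case count exceeds retained count")


def read_quant_table(
    path: str | Path,
    design: Design = DEFAULT_DESIGN,
    histone_ids: Iterable[str] = (),
) -> QuantMatrix:
    """Read a tab-delimited protein-group quantification table.

    One row per protein group.  Ratio cells equal to 0 or absent are
    recorded as missing (a zero ratio means the protein was not quantified
    in that sample).  Intensity cells are masked to match.

    Raises
    ------
    ValueError
        On a malformed header, missing declared columns, or duplicate
        protein IDs.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype={0: str})
    if design.id_column not in table.columns:
        raise ValueError(f"{path}: missing ID column {design.id_column!r}")
    samples = design.samples
    missing_cols = [
        c
        for s in samples
        for c in (design.ratio_column(s), design.intensity_column(s))
        if c not in table.columns
    ]
    if missing_cols:
        raise ValueError(f"{path}: missing declared columns {missing_cols}")
    ids = table[design.id_column]
    if ids.duplicated().any():
        raise ValueError(
            f"{path}: duplicate protein IDs {sorted(ids[ids.duplicated()].unique())[:5]}"
        )
    index = pd.Index(ids, name="protein_id")
    ratios = pd.DataFrame(
        {s: pd.to_numeric(table[design.ratio_column(s)], errors="coerce").to_numpy() for s in samples},
        index=index,
    )
    intensities = pd.DataFrame(
        {s: pd.to_numeric(table[design.intensity_column(s)], errors="coerce").to_numpy() for s in samples},
        index=index,
    )
    # zero means not quantified, for both channels
    ratios = ratios.mask(ratios == 0.0)
    intensities = intensities.mask(intensities == 0.0)
    joint = ratios.notna() & intensities.notna()
    ratios = ratios.where(joint)
    intensities = intensities.where(joint)
    flags = pd.Series(index.isin(set(histone_ids)), index=index)
    return QuantMatrix(ratios=ratios, intensities=intensities, histone_flags=flags, log2=False)


def write_quant_table(
    m: QuantMatrix,
    path: str | Path,
    design: Design = DEFAULT_DESIGN,
    sequence_lengths: pd.Series | None = None,
    gene_names: pd.Series | None = None,
) -> Path:
    """Write a matrix back to the tab-delimited table schema.

    Missing cells are written as 0 in both channels (the convention of
    protein-group tables, where 0 means not quantified).  Ratios are
    written on the linear scale.
    """
    path = Path(path)
    linear = np.exp2(m.ratios) if m.log2 else m.ratios
    out = pd.DataFrame(index=m.proteins)
    out["protein_id"] = m.proteins
    out["gene_name"] = (
        gene_names.reindex(m.proteins)
        if gene_names is not None
        else pd.Series(m.proteins, index=m.proteins).str.lower()
    )
    for s in m.samples:
        out[design.ratio_column(s)] = linear[s].fillna(0.0)
    for s in m.samples:
        out[design.intensity_column(s)] = m.intensities[s].fillna(0.0)
    out["sequence_length"] = (
        sequence_lengths.reindex(m.proteins).fillna(0).astype(int)
        if sequence_lengths is not None
        else 0
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False)
    return path


def log2_normalize(m: QuantMatrix) -> QuantMatrix:
    """Log2-transform and anchor each sample on the core histones.

    Per sample, the mean of the non-missing histone log2 ratios is
    subtracted from every value, making the histone mean exactly zero.
    Already-log2 input is only re-anchored (idempotent when the anchor
    already sits at zero).

    Raises
    ------
    ValueError
        If no histones are flagged, or some sample has no quantified
        histone (the error names the sample).
    """
    if not m.histone_flags.any():
        raise ValueError("no histone proteins flagged; cannot anchor normalization")
    values = m.ratios if m.log2 else np.log2(m.ratios)
    hist = values.loc[m.histone_flags]
    n_obs = hist.notna().sum(axis=0)
    empty = [s for s in m.samples if n_obs[s] == 0]
    if empty:
        raise ValueError(f"no quantified histone in sample(s): {empty}")
    shift = hist.mean(axis=0, skipna=True)
    out = m.copy()
    out.ratios = values.sub(shift, axis=1)
    out.log2 = True
    return out


def filter_by_detection(
    m: QuantMatrix, max_missing_fraction: float = 0.5
) -> tuple[QuantMatrix, FilterReport]:
    """Discard proteins detected in too few samples.

    A protein is discarded iff its number of quantified samples is less
    than or equal to ``floor(max_missing_fraction * n_samples)`` — with the
    default half on 14 samples, detected-in-exactly-7 is discarded and
    8-of-14 retained.  The report also counts the complete-case subset
    (quantified in every sample), which is the input to PCA, t-SNE and
    clustering.
    """
    if not 0 <= max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    cutoff = math.floor(max_missing_fraction * m.n_samples)
    counts = m.detection_counts()
    keep = counts > cutoff
    retained = m.subset(m.proteins[keep])
    n_complete = int((counts == m.n_samples)[keep].sum())
    report = FilterReport(
        n_input=m.n_proteins,
        n_discarded=int((~keep).sum()),
        n_retained=int(keep.sum()),
        n_complete=n_complete,
        rule=f"discard if detected in <= {cutoff} of {m.n_samples} samples",
    )
    return retained, report


def complete_cases(m: QuantMatrix) -> QuantMatrix:
    """Subset to proteins quantified in every sample, order preserved.

    Raises
    ------
    ValueError
        If no protein is complete (clustering would be impossible).
    """
    keep = m.ratios.notna().all(axis=1)
    if not keep.any():
        raise ValueError("no complete cases: every protein has at least one missing sample")
    return m.subset(m.proteins[keep])
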