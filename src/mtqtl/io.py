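"""Typed containers and CSV readers/writers for map, genotype and phenotype data.

All files are comma-separated with a header row.  Genotypes of a biparental
recombinant-inbred population are coded +0.5 / -0.5 for the two homozygous
classes AA / aa; heterozygotes and missing values are rejected rather than
imputed.  Alignment between the map, the genotype columns and the phenotype
rows is validated before any analysis.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mtqtl")

VALID_METHODS = ("all", "mbp", "indv", "seq", "bicdelta")


class DataError(ValueError):
    """Invalid or inconsistent input data."""


@dataclasses.dataclass(frozen=True)
class GeneticMap:
    """Ordered marker positions, in centimorgans, per chromosome."""

    marker_id: tuple[str, ...]
    chromosome: tuple[str, ...]
    position: np.ndarray  # cM, float

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        object.__setattr__(self, "position", pos)
        if len(self.marker_id) != len(self.chromosome) or len(self.marker_id) != pos.size:
            raise DataError("map fields must have equal length")
        if len(self.marker_id) < 2:
            raise DataError("a map needs at least 2 markers")
        if len(set(self.marker_id)) != len(self.marker_id):
            dup = pd.Series(self.marker_id)
            bad = dup[dup.duplicated()].iloc[0]
            raise DataError(f"duplicate marker id: {bad!r}")
        if np.any(pos < 0) or not np.all(np.isfinite(pos)):
            raise DataError("marker positions must be non-negative finite cM values")
        for chrom in dict.fromkeys(self.chromosome):
            idx = [i for i, c in enumerate(self.chromosome) if c == chrom]
            p = pos[idx]
            if np.any(np.diff(p) < 0):
                bad = self.marker_id[idx[int(np.argmax(np.diff(p) < 0)) + 1]]
                raise DataError(
                    f"unsorted positions on chromosome {chrom!r} near marker {bad!r}")

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.chromosome))

    def chromosome_index(self, chrom: str) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.chromosome) if c == chrom])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker": self.marker_id, "chromosome": self.chromosome,
             "position_cM": self.position})


@dataclasses.dataclass(frozen=True)
class GenotypeMatrix:
    """N x L coded genotypes (+0.5 / -0.5), columns in map order."""

    values: np.ndarray
    individuals: tuple[str, ...]
    marker_id: tuple[str, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise DataError("genotype values must be a 2-D matrix")
        if v.shape != (len(self.individuals), len(self.marker_id)):
            raise DataError("genotype shape does not match labels")
        if not np.all(np.isin(v, (0.5, -0.5))):
            raise DataError("genotype entries must be exactly +0.5 or -0.5 "
                            "(missing or heterozygous data are not supported)")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.individuals),
                            columns=list(self.marker_id))


@dataclasses.dataclass(frozen=True)
class PhenotypeMatrix:
    """N x p quantitative trait values."""

    values: np.ndarray
    trait_names: tuple[str, ...]
    individuals: tuple[str, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise DataError("phenotype values must be a 2-D matrix")
        n, p = v.shape
        if p != len(self.trait_names) or n != len(self.individuals):
            raise DataError("phenotype shape does not match labels")
        if not np.all(np.isfinite(v)):
            raise DataError("phenotypes contain missing or non-finite values")
        if p < 1:
            raise DataError("at least one trait is required")
        if n <= p + 2:
            raise DataError(
                f"N={n} individuals cannot support a nonsingular {p}-trait "
                "residual covariance (need N > p + 2)")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.individuals),
                            columns=list(self.trait_names))


@dataclasses.dataclass
class RunConfig:
    """Resampling and significance settings for one analysis run."""

    alpha: float = 0.05
    n_permutations: int = 1200
    n_bootstrap: int = 250
    seed: int = 0
    method: str = "mbp"
    zeroing_cutoff: float = 0.25

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise DataError("alpha must lie in (0, 1)")
        if self.n_permutations < 1 or self.n_bootstrap < 1:
            raise DataError("resampling counts must be positive")
        if self.seed < 0:
            raise DataError("seed must be non-negative")
        if self.method not in VALID_METHODS:
            raise DataError(f"method must be one of {VALID_METHODS}")
        if not 0 <= self.zeroing_cutoff <= 1:
            raise DataError("zeroing_cutoff must lie in [0, 1]")


def read_map(path: str | Path) -> GeneticMap:
    """Read a genetic map CSV with columns marker, chromosome, position_cM."""
    df = pd.read_csv(path, dtype={"marker": str, "chromosome": str})
    required = {"marker", "chromosome", "position_cM"}
    if not required.issubset(df.columns):
        raise DataError(f"map file must have columns {sorted(required)}")
    pos = pd.to_numeric(df["position_cM"], errors="coerce")
    if pos.isna().any():
        bad = df.loc[pos.isna(), "marker"].iloc[0]
        raise DataError(f"non-numeric position for marker {bad!r}")
    return GeneticMap(tuple(df["marker"]), tuple(df["chromosome"]),
                      pos.to_numpy(dtype=float))


def write_map(gmap: GeneticMap, path: str | Path) -> None:
    gmap.to_frame().to_csv(path, index=False)


_LABEL_CODES = {"AA": 0.5, "aa": -0.5}


def read_genotypes(path: str | Path, gmap: GeneticMap,
                   coding: str = "auto") -> GenotypeMatrix:
    """Read an individuals x markers genotype CSV.

    The first column holds individual labels.  Entries may be the labels
    AA / aa or the numeric codes +0.5 / -0.5; `coding` may force 'labels'
    or 'numeric'.  Columns are reordered to match the map.
    """
    df = pd.read_csv(path, index_col=0)
    missing = [m for m in gmap.marker_id if m not in df.columns]
    if missing:
        raise DataError(f"genotype file lacks mapped markers: {missing[:5]}")
    extra = [c for c in df.columns if c not in gmap.marker_id]
    if extra:
        raise DataError(f"genotype file has unmapped markers: {extra[:5]}")
    df = df[list(gmap.marker_id)]
    if df.isna().any().any():
        raise DataError("genotype file contains missing entries")
    first = df.iloc[0, 0]
    is_labels = coding == "labels" or (coding == "auto" and isinstance(first, str))
    if is_labels:
        values = np.empty(df.shape)
        arr = df.to_numpy()
        for lab, code in _LABEL_CODES.items():
            values[arr == lab] = code
        unknown = ~np.isin(arr, list(_LABEL_CODES))
        if unknown.any():
            bad = arr[unknown][0]
            raise DataError(f"unsupported genotype class {bad!r} "
                            "(heterozygotes are not supported for RIL coding)")
    else:
        values = df.to_numpy(dtype=float)
    return GenotypeMatrix(values, tuple(str(i) for i in df.index),
                          tuple(gmap.marker_id))


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    geno.to_frame().to_csv(path, index_label="individual")


def read_phenotypes(path: str | Path) -> PhenotypeMatrix:
    """Read an individuals x traits phenotype CSV (first column = labels)."""
    df = pd.read_csv(path, index_col=0)
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        raise DataError(f"phenotype file has missing values in trait {col!r} "
                        "(imputation is out of scope)")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise DataError(f"non-numeric phenotype entry: {exc}") from exc
    return PhenotypeMatrix(values, tuple(str(c) for c in df.columns),
                           tuple(str(i) for i in df.index))


def write_phenotypes(pheno: PhenotypeMatrix, path: str | Path) -> None:
    pheno.to_frame().to_csv(path, index_label="individual")


def validate_alignment(gmap: GeneticMap, geno: GenotypeMatrix,
                       pheno: PhenotypeMatrix) -> None:
    """Raise unless map markers, genotype columns and phenotype rows agree."""
    if tuple(geno.marker_id) != tuple(gmap.marker_id):
        raise DataError("genotype columns do not match the map marker order")
    if geno.n_individuals != pheno.n_individuals:
        raise DataError("genotype and phenotype row counts differ")
    if tuple(geno.individuals) != tuple(pheno.individuals):
        raise DataError("genotype and phenotype individuals differ or are reordered")
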