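"""Shared in-memory containers for the genomic-selection pipeline.

The pipeline operates on three kinds of data: a genetic map (marker order
and centimorgan positions), a line × marker dosage matrix (0/1/2 coding,
optionally with missing entries), and long-format per-location phenotype
records (adjusted entry means).  These containers are deliberately thin
wrappers around numpy arrays / pandas frames so every stage can work with
plain linear algebra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GeneticMap", "MarkerMatrix", "PhenotypeRecords"]


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker map: ids, chromosome numbers, genetic positions in cM.

    Positions must be strictly increasing within each chromosome; the total
    map length is the sum over chromosomes of (max - min) position.
    """

    marker_ids: np.ndarray
    chromosomes: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker_ids", np.asarray(self.marker_ids, dtype=object))
        object.__setattr__(self, "chromosomes", np.asarray(self.chromosomes, dtype=np.int64))
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        if not (len(self.marker_ids) == len(self.chromosomes) == len(self.positions)):
            raise ValueError("marker_ids, chromosomes and positions must have equal length")
        if np.any(self.positions < 0):
            raise ValueError("map positions must be >= 0 cM")
        for c in np.unique(self.chromosomes):
            pos = self.positions[self.chromosomes == c]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def chromosome_ids(self) -> np.ndarray:
        return np.unique(self.chromosomes)

    def chromosome_span(self, chrom: int) -> tuple[float, float]:
        pos = self.positions[self.chromosomes == chrom]
        return float(pos.min()), float(pos.max())

    @property
    def total_length(self) -> float:
        """Sum of per-chromosome spans (max - min position), in cM."""
        return float(
            sum(hi - lo for lo, hi in (self.chromosome_span(c) for c in self.chromosome_ids))
        )

    def adjacent_gaps(self) -> np.ndarray:
        """All within-chromosome gaps between adjacent markers, in cM."""
        gaps = [
            np.diff(self.positions[self.chromosomes == c]) for c in self.chromosome_ids
        ]
        return np.concatenate(gaps) if gaps else np.empty(0)

    def subset(self, mask: np.ndarray) -> "GeneticMap":
        mask = np.asarray(mask)
        return GeneticMap(self.marker_ids[mask], self.chromosomes[mask], self.positions[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": self.marker_ids,
                "chrom": self.chromosomes,
                "pos_cM": self.positions,
            }
        )


@dataclass
class MarkerMatrix:
    """Lines × markers dosage matrix, 0/1/2 coding, NaN for missing.

    This is the X of the ridge-regression BLUP model.  ``X`` is stored as
    float so missing genotypes can be carried as NaN until imputation.
    """

    X: np.ndarray
    line_ids: np.ndarray
    marker_ids: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional (lines x markers)")
        if self.X.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError("X shape inconsistent with line_ids / marker_ids")
        observed = self.X[~np.isnan(self.X)]
        # mean-imputation can legitimately produce fractional dosages, so the
        # container enforces the 0..2 range; exact 0/1/2 coding is enforced
        # where files are parsed
        if observed.size and (observed.min() < 0.0 or observed.max() > 2.0):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_lines(self) -> int:
        return self.X.shape[0]

    @property
    def n_markers(self) -> int:
        return self.X.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.X).any())

    def allele_frequencies(self) -> np.ndarray:
        """Per-marker frequency of the dosage-counted allele, from observed calls."""
        return np.nanmean(self.X, axis=0) / 2.0

    def subset_lines(self, idx: np.ndarray) -> "MarkerMatrix":
        return MarkerMatrix(self.X[idx], self.line_ids[idx], self.marker_ids)

    def subset_markers(self, idx: np.ndarray) -> "MarkerMatrix":
        return MarkerMatrix(self.X[:, idx], self.line_ids, self.marker_ids[idx])

    def copy(self) -> "MarkerMatrix":
        return MarkerMatrix(self.X.copy(), self.line_ids.copy(), self.marker_ids.copy())


@dataclass
class PhenotypeRecords:
    """Long-format per-location adjusted entry means for one trait.

    ``df`` has columns ``line_id``, ``location_id``, ``value`` with at most
    one record per (line, location).  ``truth`` optionally carries simulator
    ground truth (genetic values, variance components) for validation runs.
    """

    df: pd.DataFrame
    trait: str = "trait"
    truth: dict | None = field(default=None, repr=False)

    REQUIRED = ("line_id", "location_id", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"phenotype records missing columns: {missing}")
        if self.df.duplicated(["line_id", "location_id"]).any():
            raise ValueError("more than one record per (line, location)")

    @property
    def n_records(self) -> int:
        return len(self.df)

    @property
    def line_ids(self) -> np.ndarray:
        return self.df["line_id"].unique()

    def locations_per_line(self) -> pd.Series:
        return self.df.groupby("line_id", sort=False)["location_id"].nunique()

    def subset_lines(self, keep: np.ndarray) -> "PhenotypeRecords":
        keep = set(keep)
        sub = self.df[self.df["line_id"].isin(keep)].reset_index(drop=True)
        return PhenotypeRecords(sub, trait=self.trait, truth=self.truth)
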