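"""Core containers shared across the pipeline.

The pipeline's tabular results (differential expression, enrichment,
regulatory pairs) are plain :class:`pandas.DataFrame` objects with documented
column contracts; the classes here wrap the few structures that carry extra
invariants: library design coordinates, abundance matrices with a stated
unit, miRNA/target duplexes and per-transcript degradome profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

GENOTYPES = ("TG", "SG")
TREATMENTS = ("CG", "WS", "HS", "WH")
TIMEPOINTS_DPA = (5, 15, 25, 35, 45)

#: Valid abundance units. FPKM additionally requires feature lengths.
UNITS = ("raw_count", "RPM", "FPKM")


@dataclass(frozen=True)
class LibraryMeta:
    """Design coordinates of one sequencing library.

    Genotypes follow the tolerant/sensitive grain coding (TG = stress-tolerant
    genotype, SG = stress-sensitive genotype); treatments are control (CG),
    pre-anthesis water deficit (WS), post-anthesis heat (HS) and the combined
    stress (WH); time-points are days post anthesis.
    """

    library_id: str
    genotype: str
    treatment: str
    timepoint_dpa: int
    replicate: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.timepoint_dpa not in TIMEPOINTS_DPA:
            raise ValueError(f"unknown time-point {self.timepoint_dpa!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")


def design_frame(design: Sequence[LibraryMeta]) -> pd.DataFrame:
    """Tabulate a library design, indexed by library_id."""
    rows = [
        {
            "library_id": m.library_id,
            "genotype": m.genotype,
            "treatment": m.treatment,
            "timepoint_dpa": m.timepoint_dpa,
            "replicate": m.replicate,
        }
        for m in design
    ]
    df = pd.DataFrame(rows).set_index("library_id")
    cells = df[["genotype", "treatment", "timepoint_dpa", "replicate"]]
    if cells.duplicated().any():
        raise ValueError("duplicate (genotype, treatment, timepoint, replicate)")
    return df


@dataclass
class AbundanceMatrix:
    """A features x libraries abundance matrix with a stated unit.

    ``values`` holds features on the rows (index = feature ids) and libraries
    on the columns; ``meta`` is indexed by library_id and carries the design
    coordinates for every column, in column order.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    unit: str = "raw_count"
    feature_lengths: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")
        if list(self.values.columns) != list(self.meta.index):
            raise ValueError("matrix columns do not match library metadata order")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative abundance values")
        if self.unit == "FPKM" and self.feature_lengths is None:
            raise ValueError("FPKM matrices require feature lengths")
        if self.feature_lengths is not None:
            missing = self.values.index.difference(self.feature_lengths.index)
            if len(missing):
                raise ValueError(f"missing lengths for {list(missing)[:5]}")
            if (self.feature_lengths.loc[self.values.index] <= 0).any():
                raise ValueError("feature lengths must be positive")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.values.columns)

    def libraries_where(self, **conditions) -> list[str]:
        """Library ids whose metadata matches all given column=value pairs."""
        mask = np.ones(len(self.meta), dtype=bool)
        for col, val in conditions.items():
            mask &= (self.meta[col] == val).to_numpy()
        return list(self.meta.index[mask])

    def subset(self, library_ids: Sequence[str]) -> "AbundanceMatrix":
        return AbundanceMatrix(
            values=self.values[list(library_ids)],
            meta=self.meta.loc[list(library_ids)],
            unit=self.unit,
            feature_lengths=self.feature_lengths,
        )


@dataclass
class TargetSite:
    """A predicted miRNA binding site on a transcript.

    Coordinates are 1-based and inclusive on the transcript sense strand.
    ``site_start`` pairs the miRNA 3'-most base, ``site_end`` pairs miRNA
    position 1, and ``cleavage_pos`` is the transcript nucleotide opposite
    miRNA position 10 (the 10-11 duplex centre where slicing occurs).
    ``per_position_state`` runs over miRNA positions 1..L with values in
    {"match", "GU", "mismatch"}.
    """

    mirna_id: str
    transcript_id: str
    site_start: int
    site_end: int
    score: float
    cleavage_pos: int
    per_position_state: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (self.site_start <= self.cleavage_pos <= self.site_end):
            raise ValueError("cleavage position outside the site")
        if self.score < 0:
            raise ValueError("duplex score must be non-negative")


@dataclass
class DegradomeProfile:
    """Per-position degradome 5'-end tag counts on one transcript (a t-plot).

    ``counts`` is dense over 1..length; position p maps to ``counts[p - 1]``.
    """

    transcript_id: str
    length: int
    counts: np.ndarray
    library_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.length,):
            raise ValueError("counts length does not match transcript length")
        if np.any(self.counts < 0):
            raise ValueError("negative tag counts")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("tag counts must be integral")
            self.counts = self.counts.astype(np.int64)

    def count_at(self, position: int) -> int:
        if not (1 <= position <= self.length):
            raise ValueError(
                f"position {position} outside 1..{self.length} "
                f"on {self.transcript_id}"
            )
        return int(self.counts[position - 1])

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class CategorizedSite:
    """A target site together with its degradome category call."""

    site: TargetSite
    tag_count: int
    category: Optional[int]  # 0..4, or None when no tag supports the site
    library_id: str

    def __post_init__(self) -> None:
        if (self.category is None) != (self.tag_count == 0):
            raise ValueError("category None iff tag count is zero")
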