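"""Shared domain types for the venom gene-regulation pipeline.

Matrices are held as pandas DataFrames (rows = genomic features, columns =
samples); small structured records are dataclasses. Coordinates follow BED
conventions (0-based, half-open) everywhere except :class:`Variant.pos`,
which keeps the VCF 1-based convention of its source format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

_DNA = frozenset("ACGT")


class Genotype(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @property
    def dosage(self) -> float:
        """Numeric alt-allele dosage (0/1/2); NaN when missing."""
        return {"hom_ref": 0.0, "het": 1.0, "hom_alt": 2.0, "missing": float("nan")}[self.value]


class ElementClass(str, Enum):
    PROMOTER = "promoter"
    ENHANCER = "enhancer"
    CTCF = "ctcf"
    DENOVO_PEAK = "denovo_peak"
    OTHER = "other"


class GlandSide(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    COMBINED = "combined"
    NA = "NA"


@dataclass(frozen=True)
class SampleMeta:
    """One sequenced sample: which animal, lineage, latitude group and gland."""

    sample_id: str
    lineage: str
    population: str = ""
    gland_side: GlandSide = GlandSide.NA
    individual: str = ""

    def __post_init__(self):
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if not self.individual:
            object.__setattr__(self, "individual", self.sample_id)


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str = ""
    element_class: ElementClass = ElementClass.OTHER
    gene: Optional[str] = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains_point(self, pos0: int) -> bool:
        """Membership of a 0-based position in the half-open interval."""
        return self.start <= pos0 < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class Variant:
    """A biallelic variant (VCF 1-based ``pos``; multiallelics are split upstream)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    genotypes: dict[str, Genotype] = field(default_factory=dict)

    def __post_init__(self):
        for allele, label in ((self.ref_allele, "ref"), (self.alt_allele, "alt")):
            if not allele or not set(allele) <= _DNA:
                raise ValueError(f"{label} allele {allele!r} must be non-empty over ACGT")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.pos < 1:
            raise ValueError("VCF positions are 1-based")

    @property
    def interval(self) -> GenomicInterval:
        """The reference footprint as a BED-convention interval."""
        return GenomicInterval(self.chrom, self.pos - 1, self.pos - 1 + len(self.ref_allele))

    @property
    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    def carriers(self) -> list[str]:
        """Samples carrying at least one alt allele."""
        return [s for s, g in self.genotypes.items() if g in (Genotype.HET, Genotype.HOM_ALT)]


@dataclass
class Motif:
    """A TF binding motif as a JASPAR-style position frequency matrix.

    ``pfm`` rows are A, C, G, T counts; ``background`` is the base composition
    used for log-odds scoring (uniform by default).
    """

    motif_id: str
    tf_name: str
    pfm: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.pfm = np.asarray(self.pfm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.pfm.ndim != 2 or self.pfm.shape[0] != 4:
            raise ValueError(f"PFM for {self.motif_id} must be 4 x L")
        if self.pfm.shape[1] < 4:
            raise ValueError(f"PFM for {self.motif_id} too short (L >= 4 required)")
        if (self.pfm < 0).any():
            raise ValueError(f"PFM for {self.motif_id} has negative counts")
        if (self.pfm.sum(axis=0) <= 0).any():
            raise ValueError(f"PFM for {self.motif_id} has an all-zero column")
        if self.background.shape != (4,) or not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must be 4 probabilities summing to 1")

    @property
    def length(self) -> int:
        return self.pfm.shape[1]

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.pfm.argmax(axis=0))


@dataclass
class ScoreMatrix:
    """Continuous per-interval, per-sample scores (ATAC accessibility or footprints)."""

    intervals: list[GenomicInterval]
    values: pd.DataFrame  # index = interval names, columns = samples

    def __post_init__(self):
        names = [iv.name for iv in self.intervals]
        if len(set(names)) != len(names):
            raise ValueError("interval names must be unique")
        if list(self.values.index) != names:
            raise ValueError("values index must match interval names in order")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("scores must be finite")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def by_name(self, name: str) -> GenomicInterval:
        for iv in self.intervals:
            if iv.name == name:
                return iv
        raise KeyError(name)

    def subset(self, names: list[str]) -> "ScoreMatrix":
        keep = [iv for iv in self.intervals if iv.name in set(names)]
        return ScoreMatrix(keep, self.values.loc[[iv.name for iv in keep]])


def validate_counts(values: pd.DataFrame) -> pd.DataFrame:
    """Check a genes x samples counts frame: integer dtype, non-negative, unique labels."""
    if values.index.has_duplicates:
        dup = values.index[values.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r}")
    if values.columns.has_duplicates:
        raise ValueError("duplicate sample ids")
    arr = values.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("counts must be integers")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return values
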