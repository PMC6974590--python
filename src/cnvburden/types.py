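"""Core domain types for rare-CNV case-control burden analysis.

All genomic coordinates held in these types are 0-based half-open
(``[start, end)``); readers and writers in :mod:`cnvburden.io_formats`
convert to and from each file format's native convention.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class CnvType(enum.Enum):
    """Dosage direction of a copy-number call."""

    GAIN = "GAIN"
    LOSS = "LOSS"

    @classmethod
    def parse(cls, token: str) -> "CnvType":
        t = token.strip().upper()
        if t in ("GAIN", "DUP", "DUPLICATION", "<DUP>"):
            return cls.GAIN
        if t in ("LOSS", "DEL", "DELETION", "<DEL>"):
            return cls.LOSS
        raise ValueError(f"unknown CNV type token: {token!r}")


class Status(enum.Enum):
    CASE = "CASE"
    CONTROL = "CONTROL"


class Sex(enum.Enum):
    FEMALE = "FEMALE"
    MALE = "MALE"


class T2d(enum.Enum):
    YES = "YES"
    NO = "NO"
    UNKNOWN = "UNKNOWN"


def normalize_chrom(chrom: str) -> str:
    """Normalize a chromosome label to the ``chr``-prefixed form."""
    c = chrom.strip()
    if not c:
        raise ValueError("chromosome label is empty")
    if c.lower().startswith("chr"):
        return "chr" + c[3:]
    return "chr" + c


@dataclass(frozen=True)
class CnvCall:
    """One detected gain/loss segment in one sample.

    Coordinates are 0-based half-open.
    """

    sample_id: str
    cohort: str
    chrom: str
    start: int
    end: int
    cnv_type: CnvType
    n_probes: int = 0
    source: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for sample "
                f"{self.sample_id}: end must exceed start"
            )
        if self.n_probes < 0:
            raise ValueError("n_probes must be non-negative")

    def size(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SampleRecord:
    """Phenotype row: case status, sex, age, BMI, cohort label."""

    sample_id: str
    cohort: str
    status: Status
    sex: Sex
    age: float
    bmi: float
    t2d: T2d = T2d.UNKNOWN

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"sample {self.sample_id}: age must be >= 0")
        if self.bmi <= 0:
            raise ValueError(f"sample {self.sample_id}: bmi must be > 0")


@dataclass(frozen=True)
class GeneModel:
    """Genomic span of one gene, 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end must exceed start")
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")


@dataclass
class GeneSetCollection:
    """Named sets of gene identifiers with free-text provenance tags."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            for g in members:
                if not g:
                    raise ValueError(f"gene set {name!r} has an empty member id")

    def add(self, name: str, members, provenance: str = "") -> None:
        if name in self.sets:
            raise ValueError(f"duplicate gene set name: {name!r}")
        fs = frozenset(members)
        if not fs:
            raise ValueError(f"gene set {name!r} is empty")
        self.sets[name] = fs
        self.provenance[name] = provenance

    def names(self) -> list[str]:
        return list(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]


class TypeStratum(enum.Enum):
    """CNV-type stratification of a burden test."""

    ANY = "ANY"
    GAIN = "GAIN"
    LOSS = "LOSS"

    def matches(self, cnv_type: CnvType) -> bool:
        return self is TypeStratum.ANY or self.value == cnv_type.value


#: Pseudo gene-set name meaning "any call, gene-overlapping or not".
ANY_SET = "any"
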