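"""Core record types shared by every stage of the pipeline.

Coordinates are 1-based inclusive throughout, matching the residue numbering
conventions used for tenascin landmarks (e.g. "C-64" of human TNC) and NCBI
genomic ranges.
"""
from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Optional

#: the 20 standard residues plus X for anything a gene predictor could not call
ALLOWED_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

PARALOG_LABELS = ("TNC", "TNR", "TNW", "TNX")


class DomainKind(str, enum.Enum):
    SIGNAL = "SIGNAL"
    COILED_COIL = "COILED_COIL"
    EGF_TN = "EGF_TN"
    FN3 = "FN3"
    FRED = "FRED"
    DISORDER = "DISORDER"
    OTHER = "OTHER"


class AnnotationMethod(str, enum.Enum):
    BUILTIN = "BUILTIN"
    EXTERNAL = "EXTERNAL"


@dataclass(frozen=True)
class ProteinRecord:
    """A predicted protein: the unit every scanner consumes."""

    id: str
    seq: str
    species: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.seq:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.seq) - ALLOWED_RESIDUES
        if bad:
            raise ValueError(f"{self.id}: disallowed residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class DomainAnnotation:
    """A typed interval on a protein, from the builtin scanners or an
    external (InterProScan/SMART-style) table."""

    protein_id: str
    kind: DomainKind
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    score: Optional[float] = None
    method: AnnotationMethod = AnnotationMethod.BUILTIN

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.protein_id}: invalid interval [{self.start},{self.end}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "DomainAnnotation") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class Architecture:
    """Ordered domain composition of one protein plus the derived flags the
    tenascin grammar is phrased in."""

    protein_id: str
    seq_length: int
    domains: list[DomainAnnotation] = field(default_factory=list)
    has_signal: bool = False
    has_coiled_coil: bool = False
    n_egf: int = 0
    n_fn3: int = 0
    has_terminal_fred: bool = False

    def of_kind(self, kind: DomainKind) -> list[DomainAnnotation]:
        return [d for d in self.domains if d.kind == kind]


@dataclass(frozen=True)
class GeneLocus:
    """One row of a gene-order table."""

    species: str
    chrom: str
    start: int
    end: int
    strand: str
    symbol: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.symbol}: start > end")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"{self.symbol}: bad strand {self.strand!r}")


@dataclass
class TenascinCall:
    """Per-protein verdict with the full evidence bundle."""

    protein_id: str
    species: str
    is_tenascin: bool
    reasons: list[str] = field(default_factory=list)
    fred_label: Optional[str] = None
    fred_margin: Optional[float] = None
    synteny_label: Optional[str] = None
    synteny_score: Optional[float] = None
    final_label: str = "NOT_TENASCIN"
    conflict: bool = False
    motifs: list[dict] = field(default_factory=list)
    assembly: Optional[dict] = None
    architecture: Optional[dict] = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
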