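"""Core record types shared across the pipeline stages.

The in-memory containers here mirror what the standard on-disk formats
carry (SAM alignment lines, BED gene intervals) but keep only the fields
the curation and quantification stages actually consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


class ParameterError(ValueError):
    """A caller-supplied parameter violates an operation's contract."""


@dataclass
class ReadAlignment:
    """One aligned read segment against a reference replicon.

    Coordinates are 0-based half-open on the reference. ``edit_distance``
    is the SAM NM value (substitutions only in the synthetic model);
    ``aligned_len`` the number of reference bases covered. ``seq`` holds
    the read bases over the aligned span and is required only by the
    per-position pileup (``snp_scan``).
    """

    read_id: str
    ref_id: str
    start: int
    end: int
    strand: str
    mapq: int
    edit_distance: int
    aligned_len: int
    seq: Optional[str] = None
    mate_ref: Optional[str] = None
    mate_start: Optional[int] = None
    proper_pair: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ParameterError(
                f"alignment {self.read_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ParameterError(f"alignment {self.read_id}: strand must be '+' or '-'")
        if self.mapq < 0:
            raise ParameterError(f"alignment {self.read_id}: negative MAPQ")
        if self.edit_distance < 0 or self.edit_distance > self.aligned_len:
            raise ParameterError(
                f"alignment {self.read_id}: edit distance {self.edit_distance} "
                f"outside [0, aligned_len={self.aligned_len}]"
            )

    def identity(self) -> float:
        """Per-read nucleotide identity, 1 - NM / aligned length."""
        if self.aligned_len <= 0:
            raise ParameterError(f"alignment {self.read_id}: aligned_len must be > 0")
        return 1.0 - self.edit_distance / self.aligned_len


@dataclass
class GeneModel:
    """A gene interval on a replicon (0-based half-open), optionally
    carrying a functional category label such as a COG class letter."""

    gene_id: str
    ref_id: str
    start: int
    end: int
    strand: str = "+"
    category: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ParameterError(f"gene {self.gene_id}: end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class HomologyHit:
    """A tabular homology hit (BLAST outfmt-6 style) with full sequence
    lengths, as needed by the subject/query length-difference filter."""

    query_id: str
    subject_id: str
    query_len: int
    subject_len: int
    bitscore: float
    evalue: float
    category: Optional[str] = None
    aligned_query_len: Optional[int] = None
    aligned_subject_len: Optional[int] = None

    def __post_init__(self) -> None:
        if self.query_len <= 0 or self.subject_len <= 0:
            raise ParameterError(
                f"hit {self.query_id}->{self.subject_id}: lengths must be positive"
            )
        if self.evalue < 0:
            raise ParameterError(f"hit {self.query_id}: negative e-value")
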