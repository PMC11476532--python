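"""Core domain types shared across the pipeline.

Coordinates follow GFF3 conventions throughout: 1-based, closed intervals,
strand in {'+', '-'}. Sequence slicing converts to Python indexing at a
single point (see :mod:`lacfam.networks` for promoter arithmetic).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True, order=True)
class GeneModel:
    """A located gene: the coordinate backbone for naming, tandem rules and
    promoter extraction."""

    gene_id: str
    chromosome: str
    start: int  # 1-based, inclusive
    end: int  # 1-based, inclusive
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: coordinates are 1-based, got start={self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DomainHit:
    """One row of domain evidence (HMMER domtblout-like)."""

    protein_id: str
    domain_name: str
    evalue: float
    ali_start: int
    ali_end: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative e-value for {self.protein_id}/{self.domain_name}")
        if self.ali_start > self.ali_end:
            raise ValueError(f"{self.protein_id}: ali_start > ali_end")


@dataclass(frozen=True)
class SimilarityHit:
    """One row of similarity evidence (BLAST tabular-like).

    ``identity`` and ``query_coverage`` are fractions in [0, 1].
    """

    query_id: str
    subject_id: str
    evalue: float
    identity: float
    aln_len: int
    query_coverage: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity out of [0,1]: {self.identity}")
        if not 0.0 <= self.query_coverage <= 1.0:
            raise ValueError(f"query_coverage out of [0,1]: {self.query_coverage}")


@dataclass(frozen=True)
class FamilyMember:
    """A verified family member with its position-based name."""

    gene_id: str
    assigned_name: str
    representative_protein_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    domains_present: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class GenePair:
    """An unordered pair of genes with its duplication relation."""

    gene_a: str
    gene_b: str
    relation: str  # tandem | segmental | none
    coverage: float = 0.0
    similarity: float = 0.0

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("a gene cannot pair with itself")
        # canonical order makes pairs hashable irrespective of input order
        if self.gene_a > self.gene_b:
            object.__setattr__(self, "gene_a", self.gene_b)
            object.__setattr__(self, "gene_b", self.gene_a)

    @property
    def key(self) -> frozenset[str]:
        return frozenset((self.gene_a, self.gene_b))


@dataclass(frozen=True)
class MotifHit:
    """A PWM match inside a promoter.

    ``offset`` is 0-based from the 5' end of the promoter (gene orientation);
    ``strand`` is relative to the promoter.
    """

    motif_id: str
    gene_id: str
    offset: int
    strand: str
    score_bits: float
    pvalue: float


@dataclass(frozen=True)
class CorrelationEdge:
    gene_id: str
    metabolite_id: str
    r: float
    pvalue: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"Pearson r out of range: {self.r}")


@dataclass(frozen=True)
class Promoter:
    """An upstream region, 5'->3' relative to its gene; ``truncated`` records
    clamping at a chromosome edge."""

    gene_id: str
    sequence: str
    truncated: bool = False
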