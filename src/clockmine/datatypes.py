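"""Core domain types shared across the analysis stages."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

# 20 standard amino acids; X is the only permitted ambiguity code after
# normalisation (B, Z, U and other non-standard letters are mapped to X).
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
VALID_ALPHABET = frozenset(STANDARD_AA + "X")


class TaxonGroup(str, enum.Enum):
    """Coarse taxonomic grouping used in the homolog distribution summaries."""

    CYANOBACTERIA = "Cyanobacteria"
    PROTEOBACTERIA = "Proteobacteria"
    ARCHAEA = "Archaea"
    OTHER = "Other"

    @classmethod
    def coerce(cls, value: "TaxonGroup | str") -> "TaxonGroup":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            return cls.OTHER


#: Display/sort order of taxon groups (mirrors the standard figure layout).
TAXON_GROUP_ORDER = (
    TaxonGroup.CYANOBACTERIA,
    TaxonGroup.PROTEOBACTERIA,
    TaxonGroup.ARCHAEA,
    TaxonGroup.OTHER,
)


def normalize_sequence(sequence: str) -> str:
    """Uppercase an amino-acid sequence and map non-standard residues to X.

    B, Z, U, J, O and any other letter outside the 20 standard residues are
    replaced by X, which is scored 0 against everything during alignment.
    """
    seq = sequence.upper().replace("*", "").replace("-", "")
    return "".join(c if c in VALID_ALPHABET else "X" for c in seq)


@dataclass(frozen=True)
class ProteinSeq:
    """An amino-acid sequence with organism metadata.

    Parameters
    ----------
    id:
        Unique identifier within a collection.
    organism:
        Full organism/strain name.
    genus:
        Genus; when empty, derived as the first whitespace-delimited token of
        the organism name.
    taxon_group:
        One of Cyanobacteria / Proteobacteria / Archaea / Other.
    sequence:
        Amino-acid string over the 20 standard residues plus X.
    """

    id: str
    sequence: str
    organism: str = ""
    genus: str = ""
    taxon_group: TaxonGroup = TaxonGroup.OTHER

    def __post_init__(self) -> None:
        seq = normalize_sequence(self.sequence)
        if not seq:
            raise ValueError(f"sequence for {self.id!r} is empty")
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "taxon_group", TaxonGroup.coerce(self.taxon_group))
        if not self.genus and self.organism:
            object.__setattr__(self, "genus", self.organism.split()[0])

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SearchHit:
    """A scored local-alignment hit of one query against one subject."""

    query_id: str
    subject_id: str
    subject_organism: str
    score: float
    bitscore: float
    evalue: float
    percent_similarity: float
    aln_length: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        if not 0.0 <= self.percent_similarity <= 100.0:
            raise ValueError("percent_similarity must lie in [0, 100]")

    @property
    def sort_key(self) -> tuple:
        """Best-first ordering: ascending e-value, descending bitscore, id."""
        return (self.evalue, -self.bitscore, self.subject_id)


@dataclass(frozen=True)
class RBHPair:
    """An accepted reciprocal best hit.

    The pair is only valid when the subject's best reverse hit against the
    query genome is the original query (``reverse_best_id == query_id``).
    """

    query_id: str
    subject_id: str
    subject_organism: str
    forward_hit: SearchHit
    reverse_best_id: str
    subtype: str = ""

    def __post_init__(self) -> None:
        if self.reverse_best_id != self.query_id:
            raise ValueError(
                "RBHPair requires the best reverse hit to be the original query "
                f"({self.reverse_best_id!r} != {self.query_id!r})"
            )


@dataclass
class ClockSystem:
    """The set of clock-factor homologs detected in one strain."""

    strain: str
    copy_counts: dict[str, int] = field(default_factory=dict)
    genus: str = ""
    taxon_group: TaxonGroup = TaxonGroup.OTHER

    @property
    def factors(self) -> frozenset[str]:
        return frozenset(f for f, c in self.copy_counts.items() if c >= 1)


@dataclass
class GenusSummary:
    """Per-genus mean percent similarity of accepted hits for each factor."""

    genus: str
    taxon_group: TaxonGroup
    n_genomes: int
    mean_similarity: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class LengthRecord:
    """Length of one accepted homolog, for length-distribution summaries."""

    factor: str
    subject_id: str
    organism: str
    taxon_group: TaxonGroup
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")


@dataclass
class ExpressionSeries:
    """A single gene's expression time course (log2-mean-normalised units)."""

    gene_id: str
    timepoints: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timepoints.shape != self.values.shape:
            raise ValueError("timepoints and values must have equal length")
        if not np.all(np.isfinite(self.timepoints)):
            raise ValueError("timepoints must be finite")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class OscillationResult:
    """Outcome of the harmonic-regression fit for one gene.

    ``phase`` is the peak time of the fitted cosine in circadian-time hours
    within ``[0, period)``; ``amplitude`` is in the (arbitrary) units of the
    transformed expression values. ``q`` and ``oscillating`` are filled by
    :func:`clockmine.rhythm.call_oscillators`.
    """

    gene_id: str
    p: float
    phase: float
    amplitude: float
    q: float = float("nan")
    oscillating: bool = False
    ok: bool = True


@dataclass
class ComparisonResult:
    """Cross-dataset comparison of shared oscillating genes."""

    dataset_a: str
    dataset_b: str
    n_shared: int
    rho_ccc: float
    p_ccc: float
    rho_amplitude: float
    p_amplitude: float
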