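"""Domain types shared across the pipeline.

The central object is :class:`ProteinRecord`, one annotated protein entry:
accession, names, full amino-acid sequence, the optional N-terminal
signal-peptide feature, subcellular-location terms and entry status.
Classification flags and per-dataset summaries live here too so that every
stage exchanges plain, serialisable dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

# 20 standard residues; B/Z are Asx/Glx ambiguity codes, U selenocysteine,
# X unknown -- all occur in curated database sequences.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
SEQUENCE_ALPHABET = frozenset(STANDARD_AA + "BZUX")

#: Entry statuses. Anything but ``active`` is excluded from analysis.
STATUS_ACTIVE = "active"
STATUS_OBSOLETE = "obsolete"
STATUS_DELETED = "deleted"
STATUS_NOT_FOUND = "not_found"


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (half-up), the convention used for
    every reported percentage. ``repr`` guards against binary-float noise."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def format_percentage(value: float) -> str:
    """Half-up to one decimal, with a trailing ``.0`` dropped (``13.6``,
    ``1``, ``30``) -- the style summary tables are reported in."""
    rounded = round_half_up(value, 1)
    text = f"{rounded:.1f}"
    return text[:-2] if text.endswith(".0") else text


@dataclass(frozen=True)
class InputEntry:
    """One row of a three-column identification list."""

    accession: str
    protein_name: str = ""
    gene_name: str = ""
    source_row: int = 1

    def __post_init__(self) -> None:
        if not self.accession.strip():
            raise ValueError("accession must be non-empty")
        if self.source_row < 1:
            raise ValueError("source_row must be >= 1")


@dataclass(frozen=True)
class SignalPeptideFeature:
    """N-terminal signal-peptide feature with 1-based inclusive bounds.

    ``boundary_known`` is False when the source record gives an unknown
    cleavage boundary; presence of the feature still counts as +SP.
    """

    begin: int = 0
    end: int = 0
    boundary_known: bool = True

    def __post_init__(self) -> None:
        if self.boundary_known and not (1 <= self.begin <= self.end):
            raise ValueError(
                f"invalid signal-peptide bounds {self.begin}..{self.end}"
            )


@dataclass
class ProteinRecord:
    accession: str
    protein_name: str = ""
    gene_names: list[str] = field(default_factory=list)
    sequence: str = ""
    signal_peptide: SignalPeptideFeature | None = None
    locations: list[str] = field(default_factory=list)
    status: str = STATUS_ACTIVE
    species: str = ""

    @property
    def has_sp(self) -> bool:
        return self.signal_peptide is not None

    @property
    def c_terminus(self) -> str:
        return self.sequence[-4:]


@dataclass
class AnnotatedRow:
    """One Phase-II output row: the input entry joined with its retrieved
    sequence, signal-peptide span, matched C-terminal tetrapeptide and
    location terms."""

    entry: InputEntry
    full_sequence: str = ""
    signal_sequence: str = ""  # "begin end" or empty
    kdel_found: str = ""  # matched tetrapeptide or empty
    locations: list[str] = field(default_factory=list)


@dataclass
class AnnotationReport:
    n_requested: int = 0
    n_annotated: int = 0
    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


@dataclass
class ClassifiedRecord:
    """+SP / +XXEL flags for one record; membership in the predicted
    classical secretome is ``has_sp and not has_xxel``."""

    record: ProteinRecord
    has_sp: bool
    has_xxel: bool
    matched_tetrapeptide: str = ""

    @property
    def in_predicted_secretome(self) -> bool:
        return self.has_sp and not self.has_xxel


@dataclass
class DatasetSummary:
    """The per-dataset summary row: x1 analysed, x2 (+SP), x3 (+SP +XXEL)
    and the predicted classical secretome x2 - x3."""

    dataset_id: str
    n_total: int
    n_sp: int
    n_sp_xxel: int

    @property
    def n_predicted(self) -> int:
        return self.n_sp - self.n_sp_xxel

    def _pct(self, count: int) -> float:
        return 100.0 * count / self.n_total if self.n_total else 0.0

    @property
    def pct_sp(self) -> float:
        return self._pct(self.n_sp)

    @property
    def pct_sp_xxel(self) -> float:
        return self._pct(self.n_sp_xxel)

    @property
    def pct_predicted(self) -> float:
        return self._pct(self.n_predicted)

    @property
    def pct_reduction(self) -> float:
        """Share of the proteome removed by the +SP/-XXEL filter."""
        return 100.0 - self.pct_predicted if self.n_total else 100.0

    def as_report_row(self) -> dict[str, str | int]:
        return {
            "dataset": self.dataset_id,
            "proteins_analyzed": self.n_total,
            "signal_peptide_sp": f"{self.n_sp} ({format_percentage(self.pct_sp)}%)",
            "er_resident_sp_xxel": f"{self.n_sp_xxel} ({format_percentage(self.pct_sp_xxel)}%)",
            "predicted_secretome_sp_not_xxel": f"{self.n_predicted} ({format_percentage(self.pct_predicted)}%)",
        }


@dataclass
class SecretomeSet:
    """Keyed membership set of predicted classically secreted proteins."""

    dataset_id: str
    keys: frozenset[str]
    key_strategy: str

    def __len__(self) -> int:
        return len(self.keys)
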