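"""Synthetic protein records with planted ground truth.

The generator emulates the statistical structure of a proteomic
identification list: a planted fraction of records carries an N-terminal
signal-peptide feature, a planted fraction of those ends in a KDEL-variant
tetrapeptide, and location terms are assigned consistently (+SP +XXEL
records are ER residents, +SP -XXEL records are annotated secreted).
Planted counts are exact quotas, not Bernoulli draws, so a correct
pipeline recovers them exactly:

    n_sp = round(n * frac_sp)            (half-up)
    n_sp_xxel = round(n_sp * frac_xxel_given_sp)
    n_predicted = n_sp - n_sp_xxel

Defaults mirror a large human-islet proteome: 13.6% +SP, of which ~7.3%
carry the retrieval motif. All randomness flows from ``seed``; no
mass-spectrometry noise, missing values or abundances are simulated --
the downstream tool consumes identification lists only.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

from .errors import ValidationError
from .motif import MotifPattern
from .records import (
    STANDARD_AA,
    InputEntry,
    ProteinRecord,
    SignalPeptideFeature,
    round_half_up,
)

#: Position-1 / position-2 residues observed across functional KDEL
#: variants; crossed with the fixed "EL" tail they form the planting pool.
KDEL_VARIANT_FIRST = "KHSRPEFGD"
KDEL_VARIANT_SECOND = "DTNEVGAIR"
KDEL_VARIANTS = tuple(
    a + b + "EL" for a in KDEL_VARIANT_FIRST for b in KDEL_VARIANT_SECOND
)

_NON_ER_LOCATIONS = ("cytoplasm", "nucleus", "mitochondrion", "cytoskeleton")
_ER_LOCATION = "endoplasmic reticulum lumen"
_SECRETED_LOCATION = "secreted"


@dataclass(frozen=True)
class GenerationSpec:
    n: int = 1000
    frac_sp: float = 0.136
    frac_xxel_given_sp: float = 53 / 725
    frac_er_location: float = 0.01
    seq_length_range: tuple[int, int] = (100, 600)
    seed: int = 0
    species: str = "Homo sapiens"

    def __post_init__(self) -> None:
        for name in ("frac_sp", "frac_xxel_given_sp", "frac_er_location"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {value}")
        lo, hi = self.seq_length_range
        if not (20 <= lo <= hi):
            raise ValidationError(
                f"infeasible sequence length range {self.seq_length_range}; "
                "minimum length must be >= 20"
            )

    @property
    def n_sp(self) -> int:
        return int(round_half_up(self.n * self.frac_sp, 0))

    @property
    def n_sp_xxel(self) -> int:
        return int(round_half_up(self.n_sp * self.frac_xxel_given_sp, 0))


@dataclass
class SyntheticTruth:
    """Planted per-record labels plus the summary counts they imply."""

    labels: dict[str, tuple[bool, bool, bool]] = field(default_factory=dict)
    n_sp: int = 0
    n_sp_xxel: int = 0

    @property
    def n_predicted(self) -> int:
        return self.n_sp - self.n_sp_xxel


def _random_sequence(rng: random.Random, length: int) -> str:
    return "".join(rng.choices(STANDARD_AA, k=length))


def _rejection_sample_tail(rng: random.Random, pattern: MotifPattern) -> str:
    """Four final residues guaranteed NOT to satisfy the motif pattern."""
    while True:
        tail = "".join(rng.choices(STANDARD_AA, k=4))
        if not pattern.matches(tail):
            return tail


def generate_records(spec: GenerationSpec) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Generate ``spec.n`` protein records with exactly planted labels.

    Exactly ``spec.n_sp`` records receive a signal-peptide feature (begin 1,
    end drawn uniformly from 15-30); exactly ``spec.n_sp_xxel`` of those get
    a C-terminus drawn from the KDEL-variant pool; every other record's
    final four residues are rejection-sampled against the default motif
    pattern, so no accidental +XXEL can occur. Fully reproducible from
    ``spec.seed``.
    """
    rng = random.Random(spec.seed)
    pattern = MotifPattern.default()
    lo, hi = spec.seq_length_range

    indices = list(range(spec.n))
    rng.shuffle(indices)
    sp_indices = set(indices[: spec.n_sp])
    xxel_indices = set(indices[: spec.n_sp_xxel])  # subset of sp_indices

    n_er = max(int(round_half_up(spec.n * spec.frac_er_location, 0)), spec.n_sp_xxel)
    er_extra = [i for i in indices if i not in sp_indices][: n_er - spec.n_sp_xxel]
    er_indices = xxel_indices | set(er_extra)

    records: list[ProteinRecord] = []
    truth = SyntheticTruth(n_sp=spec.n_sp, n_sp_xxel=spec.n_sp_xxel)
    for i in range(spec.n):
        accession = f"SYN{spec.seed % 1000:03d}{i:05d}"
        length = rng.randint(lo, hi)
        body = _random_sequence(rng, length - 4)
        has_sp = i in sp_indices
        has_xxel = i in xxel_indices
        if has_xxel:
            tail = rng.choice(KDEL_VARIANTS)
        else:
            tail = _rejection_sample_tail(rng, pattern)
        sequence = body + tail

        signal = None
        if has_sp:
            signal = SignalPeptideFeature(begin=1, end=rng.randint(15, 30))

        if i in er_indices:
            locations = [_ER_LOCATION]
        elif has_sp:
            locations = [_SECRETED_LOCATION]
        else:
            locations = [rng.choice(_NON_ER_LOCATIONS)]

        records.append(
            ProteinRecord(
                accession=accession,
                protein_name=f"Synthetic protein {i + 1}",
                gene_names=[f"SYG{i + 1}"],
                sequence=sequence,
                signal_peptide=signal,
                locations=locations,
                species=spec.species,
            )
        )
        truth.labels[accession] = (has_sp, has_xxel, i in er_indices)
    return records, truth


_NSMAP = {None: "http://uniprot.org/uniprot"}


def build_entry_xml(record: ProteinRecord, obsolete: bool = False) -> etree._Element:
    """One UniProt-style ``entry`` element; ``obsolete`` omits the sequence
    (how a withdrawn entry presents itself)."""
    entry = etree.Element("entry", dataset="Swiss-Prot")
    etree.SubElement(entry, "accession").text = record.accession
    etree.SubElement(entry, "name").text = f"{record.accession}_SYN"
    protein = etree.SubElement(entry, "protein")
    rec_name = etree.SubElement(protein, "recommendedName")
    etree.SubElement(rec_name, "fullName").text = record.protein_name
    if record.gene_names:
        gene = etree.SubElement(entry, "gene")
        for idx, symbol in enumerate(record.gene_names):
            name_type = "primary" if idx == 0 else "synonym"
            etree.SubElement(gene, "name", type=name_type).text = symbol
    organism = etree.SubElement(entry, "organism")
    etree.SubElement(organism, "name", type="scientific").text = record.species
    if record.locations:
        comment = etree.SubElement(entry, "comment", type="subcellular location")
        sub = etree.SubElement(comment, "subcellularLocation")
        for term in record.locations:
            etree.SubElement(sub, "location").text = term.capitalize()
    if record.signal_peptide is not None:
        feature = etree.SubElement(entry, "feature", type="signal peptide")
        location = etree.SubElement(feature, "location")
        if record.signal_peptide.boundary_known:
            etree.SubElement(
                location, "begin", position=str(record.signal_peptide.begin)
            )
            etree.SubElement(location, "end", position=str(record.signal_peptide.end))
        else:
            etree.SubElement(location, "begin", status="unknown")
            etree.SubElement(location, "end", status="unknown")
    if not obsolete:
        etree.SubElement(
            entry,
            "sequence",
            length=str(len(record.sequence)),
            version="1",
        ).text = record.sequence
    return entry


def _wrap_document(entries: list[etree._Element]) -> etree._Element:
    root = etree.Element("uniprot", nsmap=_NSMAP)
    for entry in entries:
        root.append(entry)
    return root


def _strip_namespace_wrap(entry: etree._Element) -> bytes:
    return etree.tostring(
        _wrap_document([entry]), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def generate_uniprot_store(
    records: list[ProteinRecord],
    path: str | Path,
    deleted: set[str] | frozenset[str] = frozenset(),
    obsolete: set[str] | frozenset[str] = frozenset(),
) -> None:
    """Write a directory store: one ``<accession>.xml`` per record, a
    ``<accession>.deleted`` marker for deleted accessions, an entry without
    a sequence for obsolete ones. Round-trips exactly through the parser."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    for record in records:
        if record.accession in deleted:
            (root / f"{record.accession}.deleted").write_text("")
            continue
        payload = _strip_namespace_wrap(
            build_entry_xml(record, obsolete=record.accession in obsolete)
        )
        (root / f"{record.accession}.xml").write_bytes(payload)


def generate_uniprot_xml(
    records: list[ProteinRecord],
    path: str | Path,
    obsolete: set[str] | frozenset[str] = frozenset(),
) -> None:
    """Write all records as a single multi-entry UniProt-style XML file."""
    document = _wrap_document(
        [build_entry_xml(r, obsolete=r.accession in obsolete) for r in records]
    )
    Path(path).write_bytes(
        etree.tostring(document, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    )


def input_entries(records: list[ProteinRecord]) -> list[InputEntry]:
    """The three-column identification list implied by the records."""
    return [
        InputEntry(
            accession=r.accession,
            protein_name=r.protein_name,
            gene_name=r.gene_names[0] if r.gene_names else "",
            source_row=i + 2,
        )
        for i, r in enumerate(records)
    ]


def write_input_list(records: list[ProteinRecord], path: str | Path) -> None:
    """Write the identification list in whichever table dialect ``path``'s
    extension selects (.xlsx/.csv/.tsv)."""
    import pandas as pd

    frame = pd.DataFrame(
        {
            "Accession": [r.accession for r in records],
            "Protein name": [r.protein_name for r in records],
            "Gene name": [r.gene_names[0] if r.gene_names else "" for r in records],
        }
    )
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        frame.to_excel(path, index=False, engine="openpyxl")
    else:
        frame.to_csv(
            path, index=False, sep="\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        )
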