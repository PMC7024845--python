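"""Reading identification lists and writing annotated tables / FASTA.

Input lists are three-column tables (accession, protein name, gene name) as
exported from a publication's supplementary material: XLSX, CSV or TSV.
Headers are matched case-insensitively with a positional fallback (columns
1-3) because supplementary tables use wildly inconsistent headers.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigurationError, ValidationError
from .records import AnnotatedRow, InputEntry, ProteinRecord

logger = logging.getLogger(__name__)

LOCATION_DELIMITER = "; "

#: Header aliases recognised when no explicit column map is supplied.
DEFAULT_HEADER_ALIASES: dict[str, tuple[str, ...]] = {
    "accession": ("accession", "accession number", "accession_number", "entry", "uniprot", "uniprot id", "protein id"),
    "protein_name": ("protein name", "protein_name", "protein names", "protein", "description"),
    "gene_name": ("gene name", "gene_name", "gene names", "gene", "gene symbol"),
}

_ROLES = ("accession", "protein_name", "gene_name")


def _read_table(path: Path) -> pd.DataFrame:
    suffix = path.suffix.lower()
    if suffix in {".xlsx", ".xlsm"}:
        return pd.read_excel(path, header=None, dtype=str, engine="openpyxl")
    sep = "\t" if suffix in {".tsv", ".tab", ".txt"} else ","
    try:
        return pd.read_csv(path, header=None, dtype=str, sep=sep)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def _resolve_columns(
    header_row: list[str], column_map: dict[str, str] | None
) -> tuple[dict[str, int], bool]:
    """Map roles to column indices. Returns (mapping, header_row_present)."""
    lowered = [h.strip().lower() for h in header_row]
    if column_map is not None:
        mapping = {}
        for role in _ROLES:
            header = column_map.get(role)
            if header is None:
                if role == "accession":
                    raise ConfigurationError("column_map must name the accession column")
                continue
            try:
                mapping[role] = lowered.index(header.strip().lower())
            except ValueError:
                raise ConfigurationError(
                    f"mapped column {header!r} for role {role!r} not found in header"
                ) from None
        return mapping, True
    # Alias-based detection; fall back to positional columns 1-3.
    mapping = {}
    for role, aliases in DEFAULT_HEADER_ALIASES.items():
        for alias in aliases:
            if alias in lowered:
                mapping[role] = lowered.index(alias)
                break
    if "accession" in mapping:
        return mapping, True
    return {"accession": 0, "protein_name": 1, "gene_name": 2}, False


def read_protein_list(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    skip_log: list[tuple[int, str]] | None = None,
) -> list[InputEntry]:
    """Read a three-column identification list into :class:`InputEntry` rows.

    Rows with an empty accession cell are skipped; each skip is recorded once
    in ``skip_log`` (if provided) as ``(source_row, reason)`` and logged as a
    warning. Duplicate accessions are retained -- deduplication is a pipeline
    decision. An empty file yields an empty list with a logged warning.
    """
    path = Path(path)
    frame = _read_table(path)
    if frame.empty:
        logger.warning("input list %s is empty", path)
        return []

    header_row = [str(v) if pd.notna(v) else "" for v in frame.iloc[0]]
    mapping, has_header = _resolve_columns(header_row, column_map)
    data = frame.iloc[1:] if has_header else frame

    def cell(row: pd.Series, role: str) -> str:
        idx = mapping.get(role)
        if idx is None or idx >= len(row):
            return ""
        value = row.iloc[idx]
        return "" if pd.isna(value) else str(value).strip()

    entries: list[InputEntry] = []
    for positional_index, (_, row) in enumerate(data.iterrows()):
        source_row = positional_index + (2 if has_header else 1)
        accession = cell(row, "accession")
        if not accession:
            if all(not cell(row, role) for role in _ROLES):
                continue  # fully blank spacer row, not worth a skip entry
            reason = "empty accession"
            logger.warning("skipping row %d of %s: %s", source_row, path, reason)
            if skip_log is not None:
                skip_log.append((source_row, reason))
            continue
        entries.append(
            InputEntry(
                accession=accession,
                protein_name=cell(row, "protein_name"),
                gene_name=cell(row, "gene_name"),
                source_row=source_row,
            )
        )
    if not entries:
        logger.warning("no usable rows found in %s", path)
    return entries


ANNOTATED_COLUMNS = [
    "accession",
    "protein_name",
    "gene_name",
    "full_sequence",
    "signal_sequence",
    "kdel_found",
    "locations",
]


def write_annotated_table(rows: list[AnnotatedRow], path: str | Path) -> None:
    """Write the annotation-stage output table (one row per retained entry).

    ``signal_sequence`` holds the feature span as ``"begin end"`` (empty when
    the record has no signal peptide), ``kdel_found`` the matched C-terminal
    tetrapeptide (empty when none), ``locations`` the delimiter-joined terms.
    The table round-trips losslessly through :func:`read_annotated_table`.
    """
    path = Path(path)
    frame = pd.DataFrame(
        [
            {
                "accession": r.entry.accession,
                "protein_name": r.entry.protein_name,
                "gene_name": r.entry.gene_name,
                "full_sequence": r.full_sequence,
                "signal_sequence": r.signal_sequence,
                "kdel_found": r.kdel_found,
                "locations": LOCATION_DELIMITER.join(r.locations),
            }
            for r in rows
        ],
        columns=ANNOTATED_COLUMNS,
    )
    suffix = path.suffix.lower()
    if suffix in {".xlsx", ".xlsm"}:
        frame.to_excel(path, index=False, engine="openpyxl")
    else:
        frame.to_csv(path, index=False, sep="\t" if suffix in {".tsv", ".tab"} else ",")


def read_annotated_table(path: str | Path) -> list[AnnotatedRow]:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".xlsx", ".xlsm"}:
        frame = pd.read_excel(path, dtype=str, engine="openpyxl")
    else:
        frame = pd.read_csv(
            path, dtype=str, sep="\t" if suffix in {".tsv", ".tab"} else ","
        )
    frame = frame.fillna("")
    rows = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        locations = [t for t in str(row.locations).split(LOCATION_DELIMITER) if t]
        rows.append(
            AnnotatedRow(
                entry=InputEntry(
                    accession=str(row.accession),
                    protein_name=str(row.protein_name),
                    gene_name=str(row.gene_name),
                    source_row=i,
                ),
                full_sequence=str(row.full_sequence),
                signal_sequence=str(row.signal_sequence),
                kdel_found=str(row.kdel_found),
                locations=locations,
            )
        )
    return rows


def write_fasta(records: list[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, header = accession, sequences wrapped at
    ``width`` residues. A record with an empty sequence is a validation
    error naming the accession."""
    for record in records:
        if not record.sequence:
            raise ValidationError(f"record {record.accession} has an empty sequence")
    seqs = [
        SeqRecord(Seq(record.sequence), id=record.accession, description="")
        for record in records
    ]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(seqs)


def read_fasta_sequences(path: str | Path) -> list[str]:
    """Sequences (as plain strings) from a FASTA file, in file order."""
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
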