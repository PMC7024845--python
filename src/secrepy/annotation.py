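"""UniProt-format entry parsing and list annotation.

The annotation stage turns each accession of an input list into a
:class:`~secrepy.records.ProteinRecord` carrying the full amino-acid
sequence, the signal-peptide feature (when annotated) and the
subcellular-location terms. The contract is offline-first: a *store* maps
accessions to entry documents -- a plain directory of per-accession XML
files, or an in-memory mapping -- so annotation is reproducible against a
pinned database snapshot. Obsolete, deleted and unknown accessions are
excluded from the record list and enumerated in the report.
"""

from __future__ import annotations

import time
from pathlib import Path
from typing import Protocol

from lxml import etree

from .errors import ResolverError, TransientResolverError, ValidationError
from .records import (
    STATUS_ACTIVE,
    STATUS_DELETED,
    STATUS_NOT_FOUND,
    STATUS_OBSOLETE,
    AnnotationReport,
    InputEntry,
    ProteinRecord,
    SignalPeptideFeature,
)

UNIPROT_NS = "http://uniprot.org/uniprot"


def _local(tag: str) -> str:
    return etree.QName(tag).localname if "}" in tag else tag


def _findall(element, name: str):
    return [el for el in element.iter() if _local(el.tag) == name]


def parse_uniprot_entry(document: str | bytes) -> ProteinRecord:
    """Parse a single UniProt XML entry into a :class:`ProteinRecord`.

    The sequence is extracted with all whitespace removed; the first
    signal-peptide feature (in document order) is captured with its 1-based
    begin/end positions; every subcellular-location term is captured,
    lower-cased and de-duplicated. An entry without a sequence element is
    returned with status ``obsolete`` rather than raising: that is how a
    withdrawn entry presents itself.
    """
    if isinstance(document, str):
        document = document.encode()
    try:
        root = etree.fromstring(document)
    except etree.XMLSyntaxError as exc:
        raise ValidationError(f"malformed entry document: {exc}") from exc

    entries = [root] if _local(root.tag) == "entry" else _findall(root, "entry")
    if len(entries) != 1:
        raise ValidationError(
            f"expected exactly one entry element, found {len(entries)}"
        )
    entry = entries[0]

    accessions = [el.text.strip() for el in _findall(entry, "accession") if el.text]
    if not accessions:
        raise ValidationError("entry has no accession element")

    protein_name = ""
    for name_el in _findall(entry, "fullName"):
        if name_el.text:
            protein_name = name_el.text.strip()
            break

    gene_names = [
        el.text.strip()
        for gene in _findall(entry, "gene")
        for el in _findall(gene, "name")
        if el.text
    ]

    species = ""
    for org in _findall(entry, "organism"):
        for name_el in _findall(org, "name"):
            if name_el.get("type") == "scientific" and name_el.text:
                species = name_el.text.strip()
                break
        break

    signal_peptide = None
    for feature in _findall(entry, "feature"):
        if feature.get("type") != "signal peptide":
            continue
        begins = _findall(feature, "begin")
        ends = _findall(feature, "end")
        begin_pos = begins[0].get("position") if begins else None
        end_pos = ends[0].get("position") if ends else None
        if begin_pos and end_pos:
            signal_peptide = SignalPeptideFeature(
                begin=int(begin_pos), end=int(end_pos), boundary_known=True
            )
        else:
            # Unknown boundary: the feature still marks the protein as +SP.
            signal_peptide = SignalPeptideFeature(boundary_known=False)
        break  # first feature in document order wins

    locations: list[str] = []
    for comment in _findall(entry, "comment"):
        if comment.get("type") != "subcellular location":
            continue
        for loc in _findall(comment, "location"):
            if loc.text:
                term = loc.text.strip().lower()
                if term and term not in locations:
                    locations.append(term)

    sequence = ""
    for seq_el in _findall(entry, "sequence"):
        if seq_el.text:
            sequence = "".join(seq_el.text.split())
            break

    return ProteinRecord(
        accession=accessions[0],
        protein_name=protein_name,
        gene_names=gene_names,
        sequence=sequence.upper(),
        signal_peptide=signal_peptide,
        locations=locations,
        status=STATUS_ACTIVE if sequence else STATUS_OBSOLETE,
        species=species,
    )


class EntryStore(Protocol):
    """Resolves an accession to an entry document or a status marker."""

    def resolve(self, accession: str) -> tuple[str, bytes | None]:
        """Return ``("document", payload)``, ``("deleted", None)`` or
        ``("not_found", None)``. May raise :class:`TransientResolverError`
        for retryable failures."""
        ...


class DirectoryStore:
    """Store backed by a directory: ``<accession>.xml`` holds the entry
    document; a ``<accession>.deleted`` marker file denotes a deleted entry;
    anything else is not found."""

    def __init__(self, root: str | Path):
        self.root = Path(root)
        if not self.root.is_dir():
            raise ResolverError(f"store directory {self.root} does not exist")

    def resolve(self, accession: str) -> tuple[str, bytes | None]:
        doc = self.root / f"{accession}.xml"
        if doc.exists():
            return "document", doc.read_bytes()
        if (self.root / f"{accession}.deleted").exists():
            return "deleted", None
        return "not_found", None


class MemoryStore:
    """In-memory store, mainly for tests: accession -> document bytes, with
    explicit deleted-accession markers."""

    def __init__(
        self,
        documents: dict[str, bytes | str] | None = None,
        deleted: set[str] | None = None,
    ):
        self.documents = {
            k: v.encode() if isinstance(v, str) else v
            for k, v in (documents or {}).items()
        }
        self.deleted = set(deleted or ())

    def resolve(self, accession: str) -> tuple[str, bytes | None]:
        if accession in self.documents:
            return "document", self.documents[accession]
        if accession in self.deleted:
            return "deleted", None
        return "not_found", None


def _resolve_with_retry(
    store: EntryStore, accession: str, retries: int, backoff: float
) -> tuple[str, bytes | None]:
    last_error: Exception | None = None
    for attempt in range(retries):
        try:
            return store.resolve(accession)
        except TransientResolverError as exc:
            last_error = exc
            if backoff and attempt < retries - 1:
                time.sleep(backoff * (attempt + 1))
    raise last_error  # type: ignore[misc]


def annotate_entries(
    entries: list[InputEntry],
    store: EntryStore,
    retries: int = 3,
    backoff: float = 0.0,
) -> tuple[list[ProteinRecord], AnnotationReport]:
    """Annotate an input list against a store.

    Active records are returned in input order. Obsolete, deleted and
    not-found accessions are excluded and enumerated in the report with
    their reason; the invariant ``n_requested = n_annotated + n_excluded``
    always holds. Transient store failures are retried up to ``retries``
    times per accession; if any accession remains unresolved a
    :class:`ResolverError` listing all of them is raised.
    """
    records: list[ProteinRecord] = []
    excluded: list[tuple[str, str]] = []
    unresolved: list[str] = []

    for entry in entries:
        try:
            kind, payload = _resolve_with_retry(store, entry.accession, retries, backoff)
        except TransientResolverError:
            unresolved.append(entry.accession)
            continue
        if kind == "deleted":
            excluded.append((entry.accession, STATUS_DELETED))
            continue
        if kind == "not_found":
            excluded.append((entry.accession, STATUS_NOT_FOUND))
            continue
        record = parse_uniprot_entry(payload)
        if record.status != STATUS_ACTIVE:
            excluded.append((entry.accession, record.status))
            continue
        records.append(record)

    if unresolved:
        raise ResolverError(
            f"store unreachable for {len(unresolved)} accession(s) after "
            f"{retries} attempts: {', '.join(unresolved)}",
            unresolved=unresolved,
        )

    report = AnnotationReport(
        n_requested=len(entries), n_annotated=len(records), excluded=excluded
    )
    return records, report
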