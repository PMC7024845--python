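"""The objective function: classical secretome = (+SP) minus (+SP and +XXEL).

A protein enters the predicted classical secretome when it carries a
signal peptide (so it is routed into the ER/Golgi pathway) and does NOT end
in an ER-retrieval tetrapeptide (so it is not pulled back to the ER lumen).
With x1 = proteins analysed, x2 = +SP and x3 = +SP +XXEL, the predicted
secretome is x2 - x3, and the per-dataset summary reports all four counts
with their percentages of x1.
"""

from __future__ import annotations

import logging

from .errors import ConfigurationError, ValidationError
from .motif import MotifPattern, match_xxel
from .records import (
    AnnotatedRow,
    ClassifiedRecord,
    DatasetSummary,
    InputEntry,
    ProteinRecord,
    SecretomeSet,
)

logger = logging.getLogger(__name__)

KEY_STRATEGIES = ("accession", "gene_symbol")


def dedupe_by_accession(
    records: list[ProteinRecord],
) -> tuple[list[ProteinRecord], int]:
    """Drop repeated accessions, first occurrence wins. Published lists
    contain isoform/duplicate rows but the summaries count proteins."""
    seen: set[str] = set()
    kept = []
    for record in records:
        if record.accession in seen:
            continue
        seen.add(record.accession)
        kept.append(record)
    n_collapsed = len(records) - len(kept)
    if n_collapsed:
        logger.info("collapsed %d duplicate accession row(s)", n_collapsed)
    return kept, n_collapsed


def classify(
    records: list[ProteinRecord], pattern: MotifPattern | None = None
) -> list[ClassifiedRecord]:
    """Flag each record +SP / +XXEL; order is preserved.

    The motif is evaluated on the full sequence including the signal
    peptide -- matching is anchored at the C-terminus, so the N-terminal SP
    region is irrelevant and no mature-sequence trimming is done.
    """
    pattern = pattern or MotifPattern.default()
    classified = []
    for record in records:
        if not record.sequence:
            raise ValidationError(
                f"record {record.accession} has an empty sequence; cannot classify"
            )
        match = match_xxel(record.sequence, pattern)
        classified.append(
            ClassifiedRecord(
                record=record,
                has_sp=record.has_sp,
                has_xxel=match is not None,
                matched_tetrapeptide=match.tetrapeptide if match else "",
            )
        )
    return classified


def summarize(classified: list[ClassifiedRecord], dataset_id: str) -> DatasetSummary:
    """Tally x1/x2/x3 and derive the predicted-secretome count x2 - x3."""
    if not classified:
        logger.warning("summarize called with no records for %s", dataset_id)
    n_sp = sum(1 for c in classified if c.has_sp)
    n_sp_xxel = sum(1 for c in classified if c.has_sp and c.has_xxel)
    return DatasetSummary(
        dataset_id=dataset_id,
        n_total=len(classified),
        n_sp=n_sp,
        n_sp_xxel=n_sp_xxel,
    )


def filter_by_location(
    classified: list[ClassifiedRecord],
    include_terms: list[str] | None = None,
    exclude_terms: list[str] | None = None,
) -> list[ClassifiedRecord]:
    """Keep records matching at least one include term and no exclude term.

    Terms match by case-insensitive substring against the record's location
    list; an empty include list keeps everything; exclusion takes
    precedence. This mirrors screening the subcellular-location column with
    a spreadsheet auto-filter (e.g. include ["secreted"]).
    """
    includes = [t.strip().lower() for t in (include_terms or []) if t.strip()]
    excludes = [t.strip().lower() for t in (exclude_terms or []) if t.strip()]

    def matches(locations: list[str], terms: list[str]) -> bool:
        return any(term in loc.lower() for loc in locations for term in terms)

    kept = []
    for c in classified:
        if excludes and matches(c.record.locations, excludes):
            continue
        if includes and not matches(c.record.locations, includes):
            continue
        kept.append(c)
    return kept


def build_secretome_set(
    classified: list[ClassifiedRecord],
    dataset_id: str,
    key_strategy: str = "accession",
) -> SecretomeSet:
    """Collect matching keys for the predicted-secretome members.

    ``accession`` uses accessions verbatim (within-species comparisons);
    ``gene_symbol`` uses the first gene symbol upper-cased (cross-species
    comparisons, where accessions cannot match). Records lacking a key
    under the chosen strategy are logged and skipped; duplicate keys
    collapse (logged).
    """
    if key_strategy not in KEY_STRATEGIES:
        raise ConfigurationError(
            f"unknown key strategy {key_strategy!r}; expected one of {KEY_STRATEGIES}"
        )
    keys: set[str] = set()
    n_skipped = n_collapsed = 0
    for c in classified:
        if not c.in_predicted_secretome:
            continue
        if key_strategy == "accession":
            key = c.record.accession
        else:
            key = c.record.gene_names[0].upper() if c.record.gene_names else ""
        if not key:
            n_skipped += 1
            logger.warning(
                "record %s has no %s key; skipped from %s",
                c.record.accession, key_strategy, dataset_id,
            )
            continue
        if key in keys:
            n_collapsed += 1
            logger.info("duplicate key %s collapsed in %s", key, dataset_id)
        keys.add(key)
    if n_skipped or n_collapsed:
        logger.info(
            "%s: %d record(s) skipped (no key), %d collapse(s)",
            dataset_id, n_skipped, n_collapsed,
        )
    return SecretomeSet(dataset_id=dataset_id, keys=frozenset(keys), key_strategy=key_strategy)


def build_annotated_rows(
    entries: list[InputEntry],
    records: list[ProteinRecord],
    pattern: MotifPattern | None = None,
) -> list[AnnotatedRow]:
    """Join input entries with their annotated records into output rows
    (entries whose accession was excluded are dropped)."""
    by_accession = {r.accession: r for r in records}
    pattern = pattern or MotifPattern.default()
    rows = []
    for entry in entries:
        record = by_accession.get(entry.accession)
        if record is None:
            continue
        if record.signal_peptide is not None and record.signal_peptide.boundary_known:
            signal = f"{record.signal_peptide.begin} {record.signal_peptide.end}"
        elif record.signal_peptide is not None:
            signal = "? ?"
        else:
            signal = ""
        match = match_xxel(record.sequence, pattern) if record.sequence else None
        rows.append(
            AnnotatedRow(
                entry=entry,
                full_sequence=record.sequence,
                signal_sequence=signal,
                kdel_found=match.tetrapeptide if match else "",
                locations=list(record.locations),
            )
        )
    return rows
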