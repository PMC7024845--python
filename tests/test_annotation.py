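"""UniProt-format entry parsing and list annotation against a store."""

import io

import pytest
from Bio import SeqIO

from secrepy.annotation import (
    MemoryStore,
    annotate_entries,
    parse_uniprot_entry,
)
from secrepy.errors import ResolverError, TransientResolverError, ValidationError
from secrepy.records import InputEntry

SEQ_120 = ("MKLSLVAAMLLLLSAARA" + "EEEDKKEDVGTVVGIDLGTTYSCVGVFKNGRVEIIANDQGNRITPSYVAFTPEG"
           + "ERLIGDAAKNQLTSNPENTVFDAKRLIGRTWNDPSVQQDIKFLPFK")[:116] + "KDEL"
assert len(SEQ_120) == 120

ENTRY_TEMPLATE = """<?xml version="1.0" encoding="UTF-8"?>
<uniprot xmlns="http://uniprot.org/uniprot">
<entry dataset="Swiss-Prot" created="1990-01-01" modified="2019-04-10" version="200">
  <accession>P11021</accession>
  <accession>P17066</accession>
  <name>BIP_HUMAN</name>
  <protein>
    <recommendedName>
      <fullName>Endoplasmic reticulum chaperone BiP</fullName>
    </recommendedName>
  </protein>
  <gene><name type="primary">HSPA5</name><name type="synonym">GRP78</name></gene>
  <organism>
    <name type="scientific">Homo sapiens</name>
    <name type="common">Human</name>
  </organism>
  <comment type="subcellular location">
    <subcellularLocation>
      <location>Endoplasmic reticulum lumen</location>
    </subcellularLocation>
    <subcellularLocation>
      <location>Cytoplasm</location>
    </subcellularLocation>
  </comment>
  <comment type="function"><text>Chaperone.</text></comment>
  {features}
  {sequence}
</entry>
</uniprot>
"""

SP_FEATURE = (
    '<feature type="signal peptide" evidence="3">'
    '<location><begin position="1"/><end position="24"/></location></feature>'
)
SEQUENCE_EL = f'<sequence length="120" mass="13000" version="2">{SEQ_120}</sequence>'


def make_entry(features: str = SP_FEATURE, sequence: str = SEQUENCE_EL) -> str:
    return ENTRY_TEMPLATE.format(features=features, sequence=sequence)


class TestParseUniprotEntry:
    def test_full_entry(self):
        record = parse_uniprot_entry(make_entry())
        assert record.accession == "P11021"  # primary accession wins
        assert record.protein_name == "Endoplasmic reticulum chaperone BiP"
        assert record.gene_names == ["HSPA5", "GRP78"]
        assert record.species == "Homo sapiens"
        assert record.status == "active"
        assert len(record.sequence) == 120
        assert record.has_sp
        assert (record.signal_peptide.begin, record.signal_peptide.end) == (1, 24)
        assert record.locations == ["endoplasmic reticulum lumen", "cytoplasm"]

    def test_sequence_whitespace_removed(self):
        chunked = "\n".join(SEQ_120[i : i + 60] for i in range(0, 120, 60))
        record = parse_uniprot_entry(
            make_entry(sequence=f'<sequence length="120">{chunked}</sequence>')
        )
        assert record.sequence == SEQ_120

    def test_no_signal_peptide_feature(self):
        record = parse_uniprot_entry(make_entry(features=""))
        assert not record.has_sp

    def test_first_of_multiple_signal_peptide_features_wins(self):
        second = SP_FEATURE.replace('position="24"', 'position="30"')
        record = parse_uniprot_entry(make_entry(features=SP_FEATURE + second))
        assert record.signal_peptide.end == 24

    def test_unknown_boundary_still_counts_as_sp(self):
        feature = (
            '<feature type="signal peptide">'
            '<location><begin status="unknown"/><end status="unknown"/></location>'
            "</feature>"
        )
        record = parse_uniprot_entry(make_entry(features=feature))
        assert record.has_sp
        assert not record.signal_peptide.boundary_known

    def test_entry_without_sequence_is_obsolete(self):
        record = parse_uniprot_entry(make_entry(sequence=""))
        assert record.status == "obsolete"
        assert record.sequence == ""

    def test_malformed_document_raises(self):
        with pytest.raises(ValidationError, match="malformed"):
            parse_uniprot_entry("<entry><accession>")

    def test_agrees_with_biopython_uniprot_parser(self):
        """Independent cross-check: Biopython's uniprot-xml reader must see
        the same accession, sequence and signal-peptide span."""
        document = make_entry()
        ours = parse_uniprot_entry(document)
        theirs = next(SeqIO.parse(io.BytesIO(document.encode()), "uniprot-xml"))
        assert theirs.id == ours.accession
        assert str(theirs.seq) == ours.sequence
        sp = [f for f in theirs.features if f.type == "signal peptide"]
        assert len(sp) == 1
        # Biopython reports 0-based half-open coordinates
        assert int(sp[0].location.start) == ours.signal_peptide.begin - 1
        assert int(sp[0].location.end) == ours.signal_peptide.end
        bio_locations = [
            t.lower()
            for t in theirs.annotations["comment_subcellularlocation_location"]
        ]
        assert bio_locations == ours.locations


def _entries(*accessions: str) -> list[InputEntry]:
    return [InputEntry(accession=a, source_row=i + 2) for i, a in enumerate(accessions)]


def _store_with(accessions, deleted=()):
    docs = {}
    for acc in accessions:
        docs[acc] = make_entry().replace("P11021", acc)
    return MemoryStore(documents=docs, deleted=set(deleted))


class TestAnnotateEntries:
    def test_deleted_entry_excluded_with_reason(self):
        store = _store_with(["A1", "A2", "A4", "A5"], deleted=["A3"])
        records, report = annotate_entries(_entries("A1", "A2", "A3", "A4", "A5"), store)
        assert [r.accession for r in records] == ["A1", "A2", "A4", "A5"]
        assert report.n_requested == 5
        assert report.n_annotated == 4
        assert report.excluded == [("A3", "deleted")]
        assert report.n_requested == report.n_annotated + report.n_excluded

    def test_obsolete_and_not_found_reasons(self):
        store = MemoryStore(documents={"A1": make_entry(sequence="")})
        records, report = annotate_entries(_entries("A1", "A2"), store)
        assert records == []
        assert report.excluded == [("A1", "obsolete"), ("A2", "not_found")]

    def test_empty_input(self):
        records, report = annotate_entries([], MemoryStore())
        assert records == []
        assert (report.n_requested, report.n_annotated, report.n_excluded) == (0, 0, 0)

    def test_repeated_annotation_is_identical(self):
        store = _store_with(["A1", "A2", "A3"])
        entries = _entries("A1", "A2", "A3")
        first = annotate_entries(entries, store)
        second = annotate_entries(entries, store)
        assert repr(first) == repr(second)

    def test_transient_failures_are_retried(self):
        inner = _store_with(["A1"])
        attempts = {"n": 0}

        class Flaky:
            def resolve(self, accession):
                attempts["n"] += 1
                if attempts["n"] < 3:
                    raise TransientResolverError("blip")
                return inner.resolve(accession)

        records, report = annotate_entries(_entries("A1"), Flaky(), retries=3)
        assert [r.accession for r in records] == ["A1"]
        assert attempts["n"] == 3

    def test_unreachable_store_raises_listing_accessions(self):
        class Dead:
            def resolve(self, accession):
                raise TransientResolverError("down")

        with pytest.raises(ResolverError) as excinfo:
            annotate_entries(_entries("A1", "A2"), Dead(), retries=3)
        assert excinfo.value.unresolved == ["A1", "A2"]
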