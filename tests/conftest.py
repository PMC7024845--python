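import pytest

from secrepy.pipeline import classify
from secrepy.records import ProteinRecord, SignalPeptideFeature


def make_record(
    accession: str = "P00001",
    sequence: str = "MKTAYIAKQRQISFVKSHFSRQGSGK",
    sp: bool = False,
    sp_bounds: tuple[int, int] = (1, 20),
    locations: list[str] | None = None,
    gene_names: list[str] | None = None,
    protein_name: str = "Test protein",
) -> ProteinRecord:
    return ProteinRecord(
        accession=accession,
        protein_name=protein_name,
        gene_names=gene_names if gene_names is not None else ["TST1"],
        sequence=sequence,
        signal_peptide=SignalPeptideFeature(*sp_bounds) if sp else None,
        locations=locations or [],
    )


def make_planted_classified(n_total: int, n_sp: int, n_sp_xxel: int):
    """Records with exactly the requested +SP / +SP+XXEL counts, run
    through the real classifier."""
    assert 0 <= n_sp_xxel <= n_sp <= n_total
    body = "MKWVTFISLLFLFSSAYSRGV"  # 21 aa, no terminal EL
    records = []
    for i in range(n_total):
        has_sp = i < n_sp
        tail = "KDEL" if i < n_sp_xxel else "GSGK"
        records.append(
            make_record(
                accession=f"T{i:05d}",
                sequence=body + tail,
                sp=has_sp,
                sp_bounds=(1, 18),
            )
        )
    return classify(records)


@pytest.fixture
def planted_classified():
    return make_planted_classified
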