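import pandas as pd
import pytest

from genusrank import AlignedSequence, TaxonTable


def aseq(species, residues, record_id=None, accession=""):
    return AlignedSequence(
        record_id=record_id or species,
        species_id=species,
        accession=accession,
        residues=residues,
    )


@pytest.fixture
def toy_table():
    return TaxonTable(
        pd.DataFrame(
            {
                "species_id": ["A1", "A2", "B1", "B2", "C1", "C2"],
                "genus": ["GenA", "GenA", "GenB", "GenB", "GenC", "GenC"],
            }
        )
    )


def make_table(mapping):
    """TaxonTable from {species_id: genus}."""
    return TaxonTable(
        pd.DataFrame(
            {"species_id": list(mapping), "genus": [mapping[s] for s in mapping]}
        )
    )
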