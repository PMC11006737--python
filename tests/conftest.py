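import pytest

from mirrorcoev.sequence_io import Alignment, SequenceRecord, validate_alignment


def make_alignment(seqs: dict[str, str]) -> Alignment:
    """Alignment from a species->residues mapping (ids equal species)."""
    return validate_alignment(
        [SequenceRecord(id=s, species=s, residues=r) for s, r in seqs.items()]
    )


@pytest.fixture
def toy_alignment() -> Alignment:
    return make_alignment(
        {
            "danio_rerio": "AAAA",
            "homo_sapiens": "AAAT",
            "mus_musculus": "TTTT",
        }
    )


@pytest.fixture
def nterm_alignment() -> Alignment:
    """Synthetic N-terminal block emulating the pump's regulatory tail.

    Position 7 is a tyrosine in an acidic context in every species except the
    cartilaginous fish, which carries F there; a serine near the C-terminal
    end sits in a lysine-rich context.
    """
    #            pos: 123456789012345
    return make_alignment(
        {
            "homo_sapiens":     "MGKAENYELYSVEKK",
            "mus_musculus":     "MGKAENYELYSVEKK",
            "monodelphis_domestica": "MGKAENYELHSVEKK",
            "xenopus_laevis":   "MGKAENYELYSVEKK",
            "danio_rerio":      "MGKAENYELFSVEKK",
            "dasyatis_sabina":  "MGKAENFELFSVEKK",
        }
    )


@pytest.fixture
def nterm_groups() -> dict[str, str]:
    return {
        "homo_sapiens": "placental_mammals",
        "mus_musculus": "placental_mammals",
        "monodelphis_domestica": "marsupials",
        "xenopus_laevis": "amphibians",
        "danio_rerio": "bony_fish",
        "dasyatis_sabina": "cartilaginous_fish",
    }
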