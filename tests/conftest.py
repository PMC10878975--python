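import numpy as np
import pytest

from crisprtile.genemodel import GeneModel, Guide

# 60-nt toy exon: ATG + 19 stop-free codons, followed by a 20-nt intron
TOY_EXON = "ATG" + "GCTGTTCTTGATGAAGGTCATATTAAATTTTTCCCTAATGCTGTTCTTGATGAAGGT"
TOY_INTRON = "GTAAGTCCTTACGGATCAGT"


@pytest.fixture(scope="session")
def toy_model():
    """Single 60-nt exon with a start codon at its 5' end and one donor
    junction at position 60 (the 3' amplicon edge is intronic)."""
    assert len(TOY_EXON) == 60
    return GeneModel(
        amplicon_seq=TOY_EXON + TOY_INTRON,
        exons=((0, 60),),
        phase=0,
        start_codon=(0, 3),
        protein_offset=1,
    )


@pytest.fixture(scope="session")
def midgene_model():
    """60-nt internal exon with intronic flanks on both sides, no start
    codon in the amplicon (frame given by phase)."""
    left = "CTTTCTTTGCAGTTGACCTT"  # 20 nt, acceptor-style
    return GeneModel(
        amplicon_seq=left + TOY_EXON[3:] + "AAA" + TOY_INTRON,
        exons=((20, 80),),
        phase=0,
        start_codon=None,
        protein_offset=100,
    )


def make_guide(cut: int, amplicon: str, name: str = "g") -> Guide:
    return Guide(
        name=name,
        protospacer=amplicon[cut - 17 : cut + 3],
        protospacer_interval=(cut - 17, cut + 3),
        pam_interval=(cut + 3, cut + 6),
        orientation="+",
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
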