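"""Canonical small study configurations used by the CLI, tests and docs.

Two toy amplicons mirror the two tiling designs the package targets:

* an *exon-2-like* amplicon — a 14-codon exon carrying the translational
  start, flanked by intronic sequence, with six guides tiling the coding
  region and one critical residue (default residue 12, after the critical
  phenylalanine in the real screen);
* an *exon-27-like* amplicon — a mid-gene 16-codon exon in high residue
  numbering, where C-terminal truncations before/at a three-residue motif
  are sensitive to PARP inhibitors.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

from .genemodel import GeneModel, Guide
from .simulate import SimConfig

__all__ = ["exon2_like_model", "exon2_like_config", "exon27_like_model", "exon27_like_config"]

# intronic flanks: acceptor-style "...AG" on the left, donor "GT..." on the right
_LEFT_INTRON = "CCTCTTACTGTCATTACCTTTCTTTGACAG"  # 30 nt
_RIGHT_INTRON = "GTAAGTATTTCCTGTTCGAAACCTGACTCA"  # 30 nt
_UTR5 = "TTCAGT"  # 6 nt of exonic 5'UTR before the start codon

# 14 codons, no stop in frame; residue 12 is the "critical" phenylalanine
_CDS = (
    "ATG" "GCT" "GTT" "CTT" "GAT" "GAA" "GGT" "CAT" "ATT" "AAA" "TTT" "TTC" "CCT" "AAT"
)


def _plus_guide(name: str, cut: int, amplicon: str) -> Guide:
    """A plus-strand guide whose blunt cut falls at ``cut``."""
    return Guide(
        name=name,
        protospacer=amplicon[cut - 17 : cut + 3],
        protospacer_interval=(cut - 17, cut + 3),
        pam_interval=(cut + 3, cut + 6),
        orientation="+",
    )


def exon2_like_model() -> GeneModel:
    amplicon = _LEFT_INTRON + _UTR5 + _CDS + _RIGHT_INTRON
    exon_start = len(_LEFT_INTRON)
    exon_end = exon_start + len(_UTR5) + len(_CDS)
    cds0 = exon_start + len(_UTR5)
    return GeneModel(
        amplicon_seq=amplicon,
        exons=((exon_start, exon_end),),
        phase=0,
        start_codon=(cds0, cds0 + 3),
        native_stop=None,
        strand="+",
        protein_offset=1,
    )


def exon2_like_config(
    seed: int = 0,
    critical_site: int = 12,
    theta: float = 2.0,
    treatments: Sequence[str] = ("mock",),
) -> SimConfig:
    """Exon-2-like tiling screen: 6 guides, one critical residue.

    Cut sites are spread so single-residue (3-bp codon-aligned) deletions
    cover most residues including the critical one; category penalties are
    on the day21/day7 log2FC scale.
    """
    model = exon2_like_model()
    cds0 = model.start_codon[0]
    cuts = [cds0 + o for o in (4, 11, 18, 25, 32, 39)]
    guides = [_plus_guide(f"g{i+1}", c, model.amplicon_seq) for i, c in enumerate(cuts)]
    return SimConfig(
        model=model,
        guides=guides,
        theta_star={critical_site: theta},
        category_penalties={
            "frame_shift": 2.0,
            "start_codon_deletion": 2.0,
            "splicing_variant": 1.5,
            "de_novo_stop": 2.0,
            "in_frame": 0.0,
            "unedited": 0.0,
        },
        treatments=tuple(treatments),
        seed=seed,
    )


# exon-27-like: mid-gene exon, residues numbered around the critical motif
_CDS27 = (
    "CCT" "GAA" "GGT" "CAT" "ATT" "AAA" "GCT" "GTT" "CTT" "GAT"
    "CCA" "CCA" "AGA" "GAA" "GGT" "AAT"
)  # 16 codons; codons 11-13 are the critical PPR-style motif


def exon27_like_model(protein_offset: int = 3290) -> GeneModel:
    amplicon = _LEFT_INTRON + _CDS27 + _RIGHT_INTRON
    exon_start = len(_LEFT_INTRON)
    exon_end = exon_start + len(_CDS27)
    return GeneModel(
        amplicon_seq=amplicon,
        exons=((exon_start, exon_end),),
        phase=0,
        start_codon=None,
        native_stop=None,
        strand="+",
        protein_offset=protein_offset,
    )


def exon27_like_config(
    seed: int = 0,
    protein_offset: int = 3290,
    treatments: Sequence[str] = ("mock", "irradiation_2Gy", "niraparib_1uM", "niraparib_2uM"),
) -> SimConfig:
    """Exon-27-like drug screen: truncations before/at the motif (residues
    offset+10..offset+12, mirroring P-P-R at 3300-3302) are PARPi-sensitive.

    Truncating alleles deplete only mildly in mock so they survive the
    presence filter through day 28, as C-terminal truncations do in the
    real locus; PARPi arms add a strong penalty for truncations whose first
    divergent residue is at or before the motif's last position.
    """
    model = exon27_like_model(protein_offset)
    exon_start = len(_LEFT_INTRON)
    cuts = [exon_start + o for o in (7, 14, 21, 28, 35, 41)]
    guides = [_plus_guide(f"g{i+1}", c, model.amplicon_seq) for i, c in enumerate(cuts)]
    return SimConfig(
        model=model,
        guides=guides,
        theta_star={},
        category_penalties={
            "frame_shift": 0.3,
            "start_codon_deletion": 0.3,
            "splicing_variant": 0.5,
            "de_novo_stop": 0.3,
            "in_frame": 0.0,
            "unedited": 0.0,
        },
        treatment_penalties={
            "mock": 0.0,
            "irradiation_2Gy": 0.2,
            "niraparib_1uM": 3.0,
            "niraparib_2uM": 4.0,
            "olaparib_1uM": 3.0,
            "olaparib_2uM": 4.0,
        },
        sensitive_boundary=protein_offset + 12,
        treatments=tuple(treatments),
        seed=seed,
    )
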