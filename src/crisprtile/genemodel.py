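"""Amplicon-local gene models, guides and splice-aware translation.

A tiling screen works on a short amplicon (a few hundred bp) spanning one or
more exons of the target gene.  The :class:`GeneModel` holds the reference
amplicon, the exon intervals in amplicon coordinates, the reading-frame
phase and (optionally) start/stop codons, and knows how to translate an
edited allele by excising introns at the *native* splice junctions before
translation.  All coordinates are 0-based, half-open; cut sites and
insertion points are between-base coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "Guide",
    "ProteinAlignment",
    "InvalidGuideError",
    "GeneModelError",
    "UntranslatableError",
    "compute_cut_site",
    "splice_windows",
    "translate_edited",
    "load_gene_model",
    "load_guides",
]


class InvalidGuideError(ValueError):
    """Guide geometry violates the SpCas9 protospacer/PAM layout."""


class GeneModelError(ValueError):
    """Gene model is internally inconsistent."""


class UntranslatableError(ValueError):
    """Edited allele cannot be translated (edit exceeds amplicon bounds)."""


@dataclass(frozen=True)
class GeneModel:
    """Reference amplicon plus the exon structure needed for translation.

    Parameters
    ----------
    amplicon_seq
        Reference amplicon nucleotide sequence (uppercase ACGT).
    exons
        Sorted, non-overlapping ``(start, end)`` intervals in amplicon
        coordinates, 0-based half-open.
    phase
        Reading-frame offset of the first exonic base: the number of bases
        of the first codon that fall *before* the amplicon's first exonic
        base (0 means the first exonic base starts a codon).
    start_codon, native_stop
        Optional ``(start, end)`` intervals of the translational start and
        native stop codon, in amplicon coordinates.
    strand
        ``"+"`` or ``"-"``; informational — all internal logic operates on
        amplicon coordinates after strand mapping at load time.
    protein_offset
        Residue number (gene numbering) of the first amino acid fully
        encoded by the amplicon, e.g. 1 for a start-codon exon.
    """

    amplicon_seq: str
    exons: tuple
    phase: int = 0
    start_codon: Optional[tuple] = None
    native_stop: Optional[tuple] = None
    strand: str = "+"
    protein_offset: int = 1

    def __post_init__(self):
        n = len(self.amplicon_seq)
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        if self.start_codon is not None:
            object.__setattr__(self, "start_codon", tuple(self.start_codon))
        if self.native_stop is not None:
            object.__setattr__(self, "native_stop", tuple(self.native_stop))
        if self.phase not in (0, 1, 2):
            raise GeneModelError(f"phase must be 0, 1 or 2, got {self.phase}")
        if not self.exons:
            raise GeneModelError("gene model needs at least one exon")
        prev_end = 0
        for s, e in self.exons:
            if not (0 <= s < e <= n):
                raise GeneModelError(f"exon ({s},{e}) outside amplicon [0,{n})")
            if s < prev_end:
                raise GeneModelError("exons must be sorted and non-overlapping")
            prev_end = e
        if self.start_codon is not None:
            s, e = self.start_codon
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise GeneModelError("start codon must lie inside an exon")
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def exonic_positions(self) -> frozenset:
        return frozenset(p for s, e in self.exons for p in range(s, e))

    def exonic_sequence(self) -> str:
        return "".join(self.amplicon_seq[s:e] for s, e in self.exons)

    def splice_junctions(self) -> list:
        """Exon boundaries adjacent to intronic sequence within the amplicon.

        A boundary at the amplicon edge is not a junction: there is no
        flanking intron to disrupt inside the amplicon.
        """
        n = len(self.amplicon_seq)
        junctions = []
        for s, e in self.exons:
            if s > 0:
                junctions.append(("acceptor", s))
            if e < n:
                junctions.append(("donor", e))
        return junctions


@dataclass(frozen=True)
class Guide:
    """An SpCas9 guide mapped onto the amplicon.

    ``orientation`` is the strand of the protospacer relative to the
    amplicon; for ``+`` the PAM sits immediately 3' (right) of the
    protospacer, for ``-`` immediately left.  ``cut_site`` is the blunt-cut
    between-base coordinate, 3 bp 5' of the PAM.
    """

    name: str
    protospacer: str
    protospacer_interval: tuple
    pam_interval: tuple
    orientation: str
    cut_site: int = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "protospacer_interval", tuple(self.protospacer_interval))
        object.__setattr__(self, "pam_interval", tuple(self.pam_interval))
        if len(self.protospacer) < 17:
            raise InvalidGuideError(
                f"guide {self.name!r}: protospacer must be >=17 nt, got {len(self.protospacer)}"
            )
        ps, pe = self.protospacer_interval
        if pe - ps != len(self.protospacer):
            raise InvalidGuideError(f"guide {self.name!r}: interval/protospacer length mismatch")
        ms, me = self.pam_interval
        if self.orientation == "+":
            if ms != pe:
                raise InvalidGuideError(f"guide {self.name!r}: PAM not adjacent 3' of protospacer")
            cut = pe - 3
        elif self.orientation == "-":
            if me != ps:
                raise InvalidGuideError(f"guide {self.name!r}: PAM not adjacent 5' of protospacer")
            cut = ps + 3
        else:
            raise InvalidGuideError(f"guide {self.name!r}: orientation must be '+' or '-'")
        object.__setattr__(self, "cut_site", cut)


def compute_cut_site(guide: Guide, model: GeneModel) -> int:
    """Blunt SpCas9 cut coordinate (between-base), 3 bp 5' of the PAM.

    The cut falls between protospacer positions 17 and 18 counting from the
    PAM-distal end.  Raises :class:`InvalidGuideError` if the cut would fall
    outside the amplicon.
    """
    cut = guide.cut_site
    if not (0 <= cut <= len(model.amplicon_seq)):
        raise InvalidGuideError(f"guide {guide.name!r}: cut site {cut} outside amplicon")
    return cut


def splice_windows(model: GeneModel, k: int = 3) -> frozenset:
    """Nucleotide positions within ±k of every annotated splice junction.

    For a junction at between-base coordinate ``j`` this is the k exonic and
    k intronic bases flanking it, i.e. positions ``j-k .. j+k-1``, clipped
    to the amplicon.  Mutations touching these positions are classified as
    splicing variants.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(model.amplicon_seq)
    out = set()
    for _kind, j in model.splice_junctions():
        for p in range(j - k, j + k):
            if 0 <= p < n:
                out.add(p)
    return frozenset(out)


# Per-residue alignment status codes used throughout the package.
MATCH, MISMATCH, DELETION, INSERTION = "match", "mismatch", "deletion", "insertion"


@dataclass(frozen=True)
class ProteinAlignment:
    """End-anchored alignment of an edited peptide to the WT peptide.

    ``statuses`` holds one entry per WT residue (match / mismatch /
    deletion); insertions are recorded as ``(wt_residue_index, inserted
    peptide)`` pairs, where the insertion precedes that residue.  Residue
    indices are in gene numbering (``protein_offset``-based).
    """

    statuses: tuple
    substitutions: tuple  # (residue_index, wt_aa, alt_aa)
    insertions: tuple  # (residue_index_before_which, inserted_seq)
    premature_stop: bool
    first_divergent: Optional[int]
    offset: int

    @property
    def is_identity(self) -> bool:
        return (
            not self.premature_stop
            and self.first_divergent is None
            and all(s == MATCH for s in self.statuses)
        )

    def deleted_residues(self) -> list:
        return [self.offset + i for i, s in enumerate(self.statuses) if s == DELETION]

    def mismatched_residues(self) -> list:
        return [self.offset + i for i, s in enumerate(self.statuses) if s == MISMATCH]

    def key(self) -> str:
        """Canonical string for collapse-by-translation grouping."""
        code = {MATCH: "=", MISMATCH: "X", DELETION: "-"}
        s = "".join(code[x] for x in self.statuses)
        ins = ";".join(f"{i}+{seq}" for i, seq in self.insertions)
        sub = ";".join(f"{i}{a}>{b}" for i, a, b in self.substitutions)
        stop = "*" if self.premature_stop else ""
        div = "" if self.first_divergent is None else f"@{self.first_divergent}"
        return f"{s}|{sub}|{ins}|{stop}{div}"


def _translate(cds: str) -> str:
    usable = len(cds) - len(cds) % 3
    return str(Seq(cds[:usable]).translate())


def _wt_peptide_and_frame(model: GeneModel):
    """WT peptide from the amplicon's exonic sequence, plus the amplicon
    coordinate at which translation starts."""
    exonic_sorted = sorted(model.exonic_positions)
    if model.start_codon is not None:
        start_ref = model.start_codon[0]
        begin = exonic_sorted.index(start_ref)
    else:
        begin = (3 - model.phase) % 3
        start_ref = exonic_sorted[begin] if begin < len(exonic_sorted) else len(model.amplicon_seq)
    return _translate(model.exonic_sequence()[begin:]), start_ref


def translate_edited(model: GeneModel, aligned_read: str, aligned_ref: str) -> ProteinAlignment:
    """Splice-aware translation of an edited allele, aligned to WT.

    The aligned read/reference pair (CRISPResso-style, equal length, ``-``
    for gaps) is walked column by column; read bases over exonic reference
    positions — plus insertions whose insertion point lies strictly inside
    an exon — form the edited coding sequence.  Introns are excised at the
    native junctions, i.e. splice-site edits are *not* modelled (alleles
    classified as splicing variants must not be passed here).

    The edited peptide is aligned to WT by longest common prefix then
    longest common suffix of the remainder, matching the heat-map style
    representation of tiling screens.  A premature-stop flag is set when a
    stop codon appears upstream of the native stop.
    """
    if len(aligned_read) != len(aligned_ref):
        raise UntranslatableError("aligned read and reference differ in length")
    exonic = model.exonic_positions
    wt_pep, start_ref = _wt_peptide_and_frame(model)

    edited = []  # (base, upstream_of_start)
    r = 0  # current reference coordinate
    for cr, cf in zip(aligned_read, aligned_ref):
        if cf == "-":  # insertion in read at point r
            if cr == "-":
                raise UntranslatableError("column gapped in both read and reference")
            # inserted base is coding iff it falls strictly inside an exon
            if (r - 1) in exonic and r in exonic:
                edited.append((cr, r <= start_ref))
        else:
            if r >= len(model.amplicon_seq):
                raise UntranslatableError("edit extends beyond amplicon")
            if r in exonic and cr != "-":
                edited.append((cr, r < start_ref))
            r += 1
    if r != len(model.amplicon_seq):
        raise UntranslatableError("aligned reference does not cover the amplicon")

    # Translation is anchored at the start coordinate: edits upstream of the
    # start do not shift the reading frame of the start codon itself
    # (start-codon edits are categorized before translation is attempted).
    ed_cds = "".join(b for b, up in edited if not up)
    ed_pep_full = _translate(ed_cds)

    wt_stop = wt_pep.find("*")
    wt_core = wt_pep if wt_stop < 0 else wt_pep[: wt_stop + 1]
    ed_stop = ed_pep_full.find("*")
    ed_core = ed_pep_full if ed_stop < 0 else ed_pep_full[: ed_stop + 1]

    premature = False
    if ed_stop >= 0:
        if wt_stop < 0 or ed_stop < wt_stop:
            premature = True

    wt_res = wt_core.rstrip("*")
    ed_res = ed_core.rstrip("*")

    # end-anchored greedy alignment
    pre = 0
    while pre < min(len(wt_res), len(ed_res)) and wt_res[pre] == ed_res[pre]:
        pre += 1
    suf = 0
    while (
        suf < min(len(wt_res), len(ed_res)) - pre
        and wt_res[len(wt_res) - 1 - suf] == ed_res[len(ed_res) - 1 - suf]
    ):
        suf += 1
    wt_mid = wt_res[pre : len(wt_res) - suf]
    ed_mid = ed_res[pre : len(ed_res) - suf]

    statuses = [MATCH] * pre
    subs = []
    inss = []
    npair = min(len(wt_mid), len(ed_mid))
    for i in range(npair):
        statuses.append(MISMATCH)
        subs.append((model.protein_offset + pre + i, wt_mid[i], ed_mid[i]))
    statuses.extend([DELETION] * (len(wt_mid) - npair))
    if len(ed_mid) > npair:
        inss.append((model.protein_offset + pre + npair, ed_mid[npair:]))
    statuses.extend([MATCH] * suf)

    first_div = None
    if wt_mid or ed_mid or premature:
        if wt_mid or ed_mid:
            first_div = model.protein_offset + pre
        else:  # pure premature stop with identical residues (e.g. stop in 3' extension)
            first_div = model.protein_offset + len(wt_res)

    return ProteinAlignment(
        statuses=tuple(statuses),
        substitutions=tuple(subs),
        insertions=tuple(inss),
        premature_stop=premature,
        first_divergent=first_div,
        offset=model.protein_offset,
    )


# ---------------------------------------------------------------------------
# loaders


def load_gene_model(config_path, fasta_path=None) -> GeneModel:
    """Build a :class:`GeneModel` from a YAML config plus a FASTA amplicon.

    The config may carry the amplicon inline (``amplicon_seq``) or reference
    a FASTA file (``amplicon_fasta`` or the explicit ``fasta_path``).
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    if fasta_path is None and "amplicon_fasta" in cfg:
        fasta_path = config_path.parent / cfg["amplicon_fasta"]
    if "amplicon_seq" in cfg:
        seq = cfg["amplicon_seq"].upper()
    elif fasta_path is not None:
        rec = next(SeqIO.parse(str(fasta_path), "fasta"))
        seq = str(rec.seq).upper()
    else:
        raise GeneModelError("no amplicon sequence: provide amplicon_seq or a FASTA")
    return GeneModel(
        amplicon_seq=seq,
        exons=tuple(tuple(e) for e in cfg["exons"]),
        phase=int(cfg.get("phase", 0)),
        start_codon=tuple(cfg["start_codon"]) if cfg.get("start_codon") else None,
        native_stop=tuple(cfg["native_stop"]) if cfg.get("native_stop") else None,
        strand=cfg.get("strand", "+"),
        protein_offset=int(cfg.get("protein_offset", 1)),
    )


def load_guides(path, model: GeneModel) -> list:
    """Read a guide TSV (name, protospacer, orientation, pam_start).

    Minus-strand guides are expressed in amplicon coordinates here already;
    downstream logic is strand-free.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"name", "protospacer", "orientation", "pam_start"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"guide table missing columns: {sorted(missing)}")
    guides = []
    for _, row in df.iterrows():
        proto = str(row["protospacer"]).upper()
        pam_start = int(row["pam_start"])
        orient = str(row["orientation"])
        pam_len = int(row.get("pam_len", 3)) if "pam_len" in df.columns else 3
        if orient == "+":
            proto_iv = (pam_start - len(proto), pam_start)
        else:
            proto_iv = (pam_start + pam_len, pam_start + pam_len + len(proto))
        g = Guide(
            name=str(row["name"]),
            protospacer=proto,
            protospacer_interval=proto_iv,
            pam_interval=(pam_start, pam_start + pam_len),
            orientation=orient,
        )
        compute_cut_site(g, model)
        guides.append(g)
    return guides
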