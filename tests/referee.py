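"""Independent brute-force referee for allele classification.

Applies the category rules by direct string surgery and translation on the
toy single-exon amplicon, sharing no code with the package implementation.
Only single clean edits (one deletion or one insertion) are supported —
exactly what the exhaustive agreement check enumerates.
"""

CODON_TABLE = {}


def _codon_table():
    if CODON_TABLE:
        return CODON_TABLE
    bases = "TCAG"
    aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                CODON_TABLE[b1 + b2 + b3] = aas[i]
                i += 1
    return CODON_TABLE


def _translate(seq):
    table = _codon_table()
    return "".join(table[seq[i : i + 3]] for i in range(0, len(seq) - len(seq) % 3, 3))


def referee_classify(
    amplicon: str,
    exon_end: int,
    kind: str,
    pos: int,
    length: int,
    ins_seq: str = "",
    start_codon=(0, 3),
    splice_k: int = 3,
):
    """Category of a single clean edit on a [0, exon_end) exon amplicon.

    ``pos`` is the deletion start or the between-base insertion point.
    """
    windows = set(range(exon_end - splice_k, exon_end + splice_k))

    if kind == "deletion":
        touched = set(range(pos, pos + length))
        net = -length
    elif kind == "insertion":
        touched = set()
        net = len(ins_seq)
    else:
        raise ValueError(kind)

    # 1. start codon mutagenized
    s0, e0 = start_codon
    if kind == "deletion" and touched & set(range(s0, e0)):
        return "start_codon_deletion"
    if kind == "insertion" and s0 < pos < e0:
        return "start_codon_deletion"

    # 2. splice window
    if kind == "deletion" and touched & windows:
        return "splicing_variant"
    if kind == "insertion" and pos in windows:
        return "splicing_variant"

    # 3. frame
    if net % 3 != 0:
        return "frame_shift"

    # 4. translate the edited exon by direct string surgery
    if kind == "deletion":
        edited = amplicon[:pos] + amplicon[pos + length :]
    else:
        edited = amplicon[:pos] + ins_seq + amplicon[pos:]
    # the edit is either fully exonic (< exon_end - splice_k, given it passed
    # the splice rule) or fully intronic (> exon_end + splice_k - 1)
    if kind == "deletion":
        fully_exonic = max(touched) < exon_end
        edited_exon = edited[: exon_end + net] if fully_exonic else amplicon[:exon_end]
    else:
        fully_exonic = 0 < pos < exon_end
        edited_exon = edited[: exon_end + net] if fully_exonic else amplicon[:exon_end]

    wt_pep = _translate(amplicon[:exon_end])
    ed_pep = _translate(edited_exon)
    assert "*" not in wt_pep, "toy exon must be stop-free"
    if "*" in ed_pep:
        return "de_novo_stop"
    return "in_frame"


def referee_translate_align(wt_pep: str, ed_pep: str):
    """End-anchored alignment oracle: (n_match, n_mismatch, n_del, n_ins)."""
    pre = 0
    while pre < min(len(wt_pep), len(ed_pep)) and wt_pep[pre] == ed_pep[pre]:
        pre += 1
    suf = 0
    while (
        suf < min(len(wt_pep), len(ed_pep)) - pre
        and wt_pep[-1 - suf] == ed_pep[-1 - suf]
    ):
        suf += 1
    wt_mid, ed_mid = wt_pep[pre : len(wt_pep) - suf], ed_pep[pre : len(ed_pep) - suf]
    paired = min(len(wt_mid), len(ed_mid))
    return (
        pre + suf,
        paired,
        len(wt_mid) - paired,
        max(len(ed_mid) - paired, 0),
    )
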