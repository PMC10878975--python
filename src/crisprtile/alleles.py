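"""Allele tables, mutation events, proximity filtering and classification.

Consumes CRISPResso2-style per-sample allele frequency tables (columns
``Aligned_Sequence``, ``Reference_Sequence``, ``#Reads``) and turns each
aligned allele into mutation events, filters by proximity to the predicted
Cas9 cut sites, classifies kept alleles into the five tiling-screen
categories, and collapses alleles with identical translations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .genemodel import (
    GeneModel,
    ProteinAlignment,
    splice_windows,
    translate_edited,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Category",
    "FilterDecision",
    "ObservedAllele",
    "MutationEvent",
    "ClassifiedAllele",
    "AlleleTableFormatError",
    "read_allele_table",
    "extract_events",
    "proximity_filter",
    "merge_technical_replicates",
    "classify_allele",
    "collapse_by_translation",
    "background_filter",
]


class Category(str, Enum):
    """Five-way allele classification, plus the unedited reference allele."""

    START_CODON_DELETION = "start_codon_deletion"
    SPLICING_VARIANT = "splicing_variant"
    FRAME_SHIFT = "frame_shift"
    IN_FRAME = "in_frame"
    DE_NOVO_STOP = "de_novo_stop"
    UNEDITED = "unedited"


class FilterDecision(str, Enum):
    KEEP = "keep"
    DROP_DISTAL = "drop_distal"
    DROP_COMPLEX = "drop_complex"


class AlleleTableFormatError(ValueError):
    pass


@dataclass(frozen=True)
class ObservedAllele:
    """One row of an aligned-allele table: the gapped read/reference pair
    and its read count in one sample."""

    aligned_read: str
    aligned_ref: str
    reads: int
    sample_id: str = ""

    def __post_init__(self):
        if len(self.aligned_read) != len(self.aligned_ref):
            raise AlleleTableFormatError("aligned read and reference differ in length")
        for a, b in zip(self.aligned_read, self.aligned_ref):
            if a == "-" and b == "-":
                raise AlleleTableFormatError("column gapped in both read and reference")
        if self.reads < 0:
            raise AlleleTableFormatError("negative read count")

    @property
    def key(self):
        return (self.aligned_read, self.aligned_ref)

    @property
    def uid(self) -> str:
        """Stable string identifier usable as a DataFrame index."""
        return f"{self.aligned_read}|{self.aligned_ref}"


@dataclass(frozen=True)
class MutationEvent:
    """A maximal contiguous edit: insertion, deletion or substitution run.

    ``ref_interval`` is in amplicon coordinates (empty ``(p, p)`` interval
    for insertions, carrying the between-base insertion point ``p``);
    ``size`` is the signed net-length contribution.
    """

    kind: str  # insertion | deletion | substitution
    ref_interval: tuple
    alt_seq: str

    @property
    def size(self) -> int:
        s, e = self.ref_interval
        if self.kind == "substitution":
            return 0
        return len(self.alt_seq) - (e - s)

    def ref_positions(self) -> range:
        return range(*self.ref_interval)


def read_allele_table(path, sample_id: str) -> List[ObservedAllele]:
    """Read a CRISPResso2-dialect allele frequency table.

    Only ``Aligned_Sequence``, ``Reference_Sequence`` and ``#Reads`` are
    used; percentage columns are ignored and recomputed downstream.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("Aligned_Sequence", "Reference_Sequence", "#Reads"):
        if col not in df.columns:
            raise AlleleTableFormatError(f"{path}: missing required column {col!r}")
    out = []
    for idx, row in df.iterrows():
        try:
            reads = int(row["#Reads"])
            if reads != float(row["#Reads"]):
                raise ValueError
        except (TypeError, ValueError):
            raise AlleleTableFormatError(f"{path}: non-integer read count at row {idx}")
        out.append(
            ObservedAllele(
                aligned_read=str(row["Aligned_Sequence"]).upper(),
                aligned_ref=str(row["Reference_Sequence"]).upper(),
                reads=reads,
                sample_id=sample_id,
            )
        )
    if not out:
        logger.warning("%s: empty allele table", path)
    return out


def extract_events(allele: ObservedAllele) -> List[MutationEvent]:
    """Decompose an aligned pair into maximal mutation-event runs.

    Runs of read-gaps become one deletion, runs of reference-gaps one
    insertion, runs of mismatching bases one substitution; at least one
    matching column separates distinct events (a change of run type also
    ends an event, keeping complex-allele counting deterministic).
    """
    events: List[MutationEvent] = []
    r = 0  # reference coordinate
    cur: Optional[str] = None  # current run kind
    start = 0
    alt: List[str] = []

    def flush(end):
        nonlocal cur, alt
        if cur is not None:
            events.append(MutationEvent(kind=cur, ref_interval=(start, end), alt_seq="".join(alt)))
        cur, alt = None, []

    for cr, cf in zip(allele.aligned_read, allele.aligned_ref):
        if cf == "-":  # insertion column at point r
            if cur != "insertion":
                flush(r)
                cur, start = "insertion", r
            alt.append(cr)
        elif cr == "-":  # deletion column over ref base r
            if cur != "deletion":
                flush(r)
                cur, start = "deletion", r
            r += 1
        elif cr != cf:  # mismatch column
            if cur != "substitution":
                flush(r)
                cur, start = "substitution", r
            alt.append(cr)
            r += 1
        else:  # match
            flush(r)
            r += 1
    flush(r)
    return events


def _event_distance(event: MutationEvent, cut: int) -> int:
    """Distance between an event and a between-base cut coordinate.

    A reference base at position p occupies [p, p+1); distance 0 means the
    event touches the cut.  Insertions use their insertion point.
    """
    s, e = event.ref_interval
    if event.kind == "insertion":
        return abs(s - cut)
    # min over base positions s..e-1 of distance between [p,p+1) and cut
    if s <= cut <= e:
        return 0
    if cut < s:
        return s - cut
    return cut - e


def proximity_filter(
    events: Sequence[MutationEvent], cut_sites: Sequence[int], radius: int = 2
) -> FilterDecision:
    """Keep an allele only if it carries exactly one edit, near a cut site.

    Edits within ``radius`` bp of a predicted cut site are genuine editing
    outcomes; anything distal is treated as a sequencing artefact, and
    alleles with more than one event are complex outcomes that cannot be
    interpreted.  Zero events (the unedited allele) are kept.
    """
    if not cut_sites:
        raise ValueError("at least one cut site is required")
    if len(events) == 0:
        return FilterDecision.KEEP
    if len(events) > 1:
        return FilterDecision.DROP_COMPLEX
    near = any(_event_distance(events[0], c) <= radius for c in cut_sites)
    return FilterDecision.KEEP if near else FilterDecision.DROP_DISTAL


def merge_technical_replicates(
    tables: Sequence[Sequence[ObservedAllele]], sample_id: str = ""
) -> List[ObservedAllele]:
    """Combine read counts of identical aligned alleles across independent
    PCRs from the same genomic DNA sample."""
    if len(tables) == 1:
        return list(tables[0])
    refs = {t[0].aligned_ref.replace("-", "") for t in tables if t}
    if len(refs) > 1:
        raise ValueError("technical replicates disagree on the reference amplicon")
    counts: Dict[tuple, int] = {}
    order: List[tuple] = []
    for table in tables:
        for a in table:
            if a.key not in counts:
                counts[a.key] = 0
                order.append(a.key)
            counts[a.key] += a.reads
    sid = sample_id or (tables[0][0].sample_id if tables and tables[0] else "")
    return [
        ObservedAllele(aligned_read=k[0], aligned_ref=k[1], reads=counts[k], sample_id=sid)
        for k in order
    ]


@dataclass(frozen=True)
class ClassifiedAllele:
    allele_uid: str
    events: tuple
    category: Category
    protein_alignment: Optional[ProteinAlignment]
    net_indel: int

    def collapse_key(self, by_translation: bool):
        if not by_translation:
            return ("nt", self.allele_uid)
        if self.category == Category.SPLICING_VARIANT:
            # splicing variants have no defined translation; collapse on the
            # nucleotide-level event signature
            return (
                self.category.value,
                tuple((e.kind, e.ref_interval, e.alt_seq) for e in self.events),
            )
        if self.protein_alignment is None:
            return (self.category.value, None)
        return (self.category.value, self.protein_alignment.key())


def _touches_start_codon(events, start_codon) -> bool:
    if start_codon is None:
        return False
    s0, e0 = start_codon
    for ev in events:
        s, e = ev.ref_interval
        if ev.kind == "insertion":
            if s0 < s < e0:  # insertion splitting the codon
                return True
        elif s < e0 and e > s0:  # deletion/substitution overlapping it
            return True
    return False


def _touches_splice_window(events, windows) -> bool:
    for ev in events:
        if ev.kind == "insertion":
            p = ev.ref_interval[0]
            if p in windows:
                return True
        else:
            if any(pos in windows for pos in ev.ref_positions()):
                return True
    return False


def classify_allele(
    allele: ObservedAllele,
    model: GeneModel,
    events: Optional[List[MutationEvent]] = None,
    splice_k: int = 3,
) -> ClassifiedAllele:
    """Assign one of the five tiling-screen categories to a kept allele.

    Precedence: start-codon edit > splice-window edit > frame-shift (net
    indel not a multiple of 3) > de novo stop (premature stop after
    splice-aware translation) > in-frame.  Zero events is the unedited
    reference allele.
    """
    if events is None:
        events = extract_events(allele)
    net = sum(ev.size for ev in events)

    if not events:
        category = Category.UNEDITED
    elif _touches_start_codon(events, model.start_codon):
        category = Category.START_CODON_DELETION
    elif _touches_splice_window(events, splice_windows(model, splice_k)):
        category = Category.SPLICING_VARIANT
    elif net % 3 != 0:
        category = Category.FRAME_SHIFT
    else:
        category = None  # in_frame vs de_novo_stop decided by translation

    pa = None
    if category != Category.SPLICING_VARIANT:
        pa = translate_edited(model, allele.aligned_read, allele.aligned_ref)
    if category is None:
        category = Category.DE_NOVO_STOP if pa.premature_stop else Category.IN_FRAME

    return ClassifiedAllele(
        allele_uid=allele.uid,
        events=tuple(events),
        category=category,
        protein_alignment=pa,
        net_indel=net,
    )


def collapse_by_translation(
    classified: Sequence[ClassifiedAllele],
    counts: pd.DataFrame,
    enabled: bool = True,
) -> pd.DataFrame:
    """Merge alleles with identical translations, summing per-sample counts.

    ``counts`` is an alleles x samples integer DataFrame indexed by allele
    uid.  When disabled (designer mutation / HDR experiments), nucleotide
    identity is the key and the table passes through with classification
    annotations only.  Total reads are conserved exactly either way.
    """
    by_key: Dict = {}
    rows: List = []
    groups: Dict = {}
    for ca in classified:
        k = ca.collapse_key(by_translation=enabled)
        if k not in by_key:
            by_key[k] = ca
            rows.append(k)
        groups.setdefault(k, []).append(ca.allele_uid)

    records = []
    index = []
    for k in rows:
        members = groups[k]
        rep = by_key[k]
        pa = rep.protein_alignment
        rec = {
            "n_merged": len(members),
            "category": rep.category.value,
            "net_indel": rep.net_indel,
            "protein_key": pa.key() if pa is not None else "",
            "protein_offset": pa.offset if pa is not None else 1,
            "first_divergent": pa.first_divergent if pa is not None else None,
            "premature_stop": pa.premature_stop if pa is not None else False,
        }
        rec.update(counts.loc[members].sum(axis=0).astype(int).to_dict())
        records.append(rec)
        index.append(members[0])
    out = pd.DataFrame(records, index=pd.Index(index, name="allele_uid"))
    return out


def background_filter(
    table: pd.DataFrame,
    sample_cols: Sequence[str],
    control: pd.Series,
) -> pd.DataFrame:
    """Flag alleles at or below their unedited-control frequency.

    ``control`` is the per-allele frequency in the unedited control sample,
    aligned to ``table``'s index (0 where absent).  An allele-sample cell is
    below the limit of detection if its frequency is <= the control
    frequency; flagged alleles stay in the table but are excluded from
    statistics downstream.  Returns a boolean DataFrame of flags.
    """
    freqs = table[list(sample_cols)].div(table[list(sample_cols)].sum(axis=0), axis=1)
    ctrl = control.reindex(table.index).fillna(0.0)
    flags = freqs.le(ctrl, axis=0)
    flags.loc[ctrl <= 0, :] = False  # absent from control: nothing to flag
    return flags
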