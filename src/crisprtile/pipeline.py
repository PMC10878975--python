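"""High-level pipeline: sample sheet in, classified/fitness/score tables out.

Thin orchestration over the stage modules; the CLI and the tests call these
functions, so runs from either entry point are identical given the same
configuration and seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

from . import alleles as al
from . import fitness as fq
from .genemodel import GeneModel, Guide, compute_cut_site, load_gene_model, load_guides
from .sitemodel import SiteEffectModel, build_design

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_experiment", "classify_experiment", "fitness_contrast", "score_sites"]


@dataclass
class RunConfig:
    """Thresholds and switches of a pipeline run (defaults per the screen)."""

    radius: int = 2
    splice_k: int = 3
    min_reads: int = 20
    collapse: bool = True
    fdr_level: float = 0.05
    pseudocount: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("radius", "splice_k", "min_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def load_experiment(fixture_dir) -> dict:
    """Load a fixture directory (gene model, guides, sample sheet, tables)."""
    fixture_dir = Path(fixture_dir)
    model = load_gene_model(fixture_dir / "gene_model.yaml")
    guides = load_guides(fixture_dir / "guides.tsv", model)
    sheet = pd.read_csv(fixture_dir / "sample_sheet.tsv", sep="\t")
    samples: Dict[str, list] = {}
    meta: Dict[str, fq.SampleMeta] = {}
    groups: Dict[str, list] = {}
    for _, row in sheet.iterrows():
        sid = str(row["sample_id"])
        table = al.read_allele_table(fixture_dir / row["file"], sid)
        groups.setdefault(sid, []).append(table)
        meta[sid] = fq.SampleMeta(
            sample_id=sid,
            replicate=str(row["replicate"]),
            day=int(row["day"]),
            treatment=str(row["treatment"]),
        )
    for sid, tables in groups.items():
        samples[sid] = al.merge_technical_replicates(tables, sample_id=sid)
    return {"model": model, "guides": guides, "samples": samples, "meta": meta}


def classify_experiment(
    experiment: dict, config: Optional[RunConfig] = None
) -> dict:
    """Classify every observed allele and build the collapsed count table.

    Returns the collapsed protein-level table (annotations + per-sample
    counts), plus per-stage tallies for provenance.
    """
    config = config or RunConfig()
    model: GeneModel = experiment["model"]
    cut_sites = [compute_cut_site(g, model) for g in experiment["guides"]]

    counts: Dict[str, Dict[str, int]] = {}
    allele_by_uid: Dict[str, al.ObservedAllele] = {}
    for sid, table in experiment["samples"].items():
        for a in table:
            counts.setdefault(a.uid, {})[sid] = counts.get(a.uid, {}).get(sid, 0) + a.reads
            allele_by_uid.setdefault(a.uid, a)

    tallies = {"observed": len(allele_by_uid), "kept": 0, "drop_distal": 0, "drop_complex": 0}
    classified: List[al.ClassifiedAllele] = []
    kept_uids = []
    for uid, a in allele_by_uid.items():
        events = al.extract_events(a)
        decision = al.proximity_filter(events, cut_sites, radius=config.radius)
        if decision != al.FilterDecision.KEEP:
            tallies[decision.value] += 1
            continue
        tallies["kept"] += 1
        classified.append(al.classify_allele(a, model, events=events, splice_k=config.splice_k))
        kept_uids.append(uid)

    count_df = (
        pd.DataFrame.from_dict(counts, orient="index").reindex(kept_uids).fillna(0).astype(int)
    )
    count_df.index.name = "allele_uid"
    protein_table = al.collapse_by_translation(classified, count_df, enabled=config.collapse)

    meta = experiment["meta"]
    control_cols = [s for s, m in meta.items() if m.treatment == "unedited_control"]
    sample_cols = [
        c for c in protein_table.columns if c in meta and c not in control_cols
    ]

    below_lod = None
    if control_cols:
        ctrl = protein_table[control_cols].sum(axis=1)
        ctrl_freq = ctrl / ctrl.sum()
        below_lod = al.background_filter(protein_table, sample_cols, ctrl_freq)

    return {
        "protein_table": protein_table,
        "sample_cols": sample_cols,
        "classified": classified,
        "tallies": tallies,
        "below_lod": below_lod,
    }


def fitness_contrast(
    protein_table: pd.DataFrame,
    sample_cols: Sequence[str],
    meta: Dict[str, fq.SampleMeta],
    *,
    day: int,
    baseline_day: int = 7,
    treatment: str = "mock",
    baseline_treatment: Optional[str] = None,
    anchor_unedited: bool = False,
    config: Optional[RunConfig] = None,
) -> dict:
    """Presence-filter, normalize and compute log2FC for one contrast.

    Time-course contrast: ``day`` vs ``baseline_day`` within the mock arm.
    Drug contrast: ``treatment`` vs mock at the same day (pass
    ``baseline_treatment='mock'``).  Baselines are matched within each
    biological replicate.

    With ``anchor_unedited`` each replicate's fold changes are further
    normalized to the unedited allele's fold change in that replicate.
    Frequencies are compositional: when deleterious alleles deplete, the
    remaining alleles' frequencies inflate even at constant abundance;
    anchoring to the neutral reference cancels this pool-composition drift
    and is required for the site-effect fit, which has no intercept.
    """
    config = config or RunConfig()
    counts = protein_table[list(sample_cols)]
    matrix = fq.FrequencyMatrix(counts=counts, meta={s: meta[s] for s in sample_cols},
                                pseudocount=config.pseudocount)

    if baseline_treatment is None:
        base = matrix.samples_where(day=baseline_day, treatment=treatment)
        tgt = matrix.samples_where(day=day, treatment=treatment)
    else:
        base = matrix.samples_where(day=day, treatment=baseline_treatment)
        tgt = matrix.samples_where(day=day, treatment=treatment)
    if not base or not tgt:
        raise ValueError("contrast has no baseline or no target samples")

    baseline_of = {}
    base_by_rep = {meta[s].replicate: s for s in base}
    for s in tgt:
        rep = meta[s].replicate
        if rep not in base_by_rep:
            raise ValueError(f"no baseline sample for replicate {rep!r}")
        baseline_of[s] = base_by_rep[rep]

    retained = fq.presence_filter(matrix, base, min_reads=config.min_reads)
    log2fc = fq.normalize_to_baseline(matrix, baseline_of, alleles=retained)
    # one column per biological replicate
    log2fc.columns = [meta[s].replicate for s in log2fc.columns]
    if anchor_unedited:
        unedited = protein_table.index[protein_table["category"] == "unedited"]
        unedited = [u for u in unedited if u in log2fc.index]
        if not unedited:
            raise ValueError("anchor_unedited requires the unedited allele in the retained set")
        log2fc = log2fc.sub(log2fc.loc[unedited[0]], axis=1)
    return {"matrix": matrix, "retained": retained, "log2fc": log2fc, "baseline_of": baseline_of}


def score_sites(
    protein_table: pd.DataFrame,
    log2fc: pd.DataFrame,
    lam: float = 1e-3,
    B: int = 200,
    seed: Optional[int] = None,
    excluded: Optional[pd.Index] = None,
):
    """Fit the site-effect model and bootstrap its uncertainties."""
    design = build_design(protein_table, log2fc, excluded=excluded)
    res = SiteEffectModel(design).fit(lam=lam)
    if B:
        res.bootstrap(B=B, seed=seed)
    return res
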