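"""Synthetic tiling experiments with known ground truth.

Emulates the full experimental design of an RNP mutation-tiling screen: a
panel of guides cutting across the amplicon, cut-site-centred indel spectra
(deletions of 1-12 bp, +1/+2 insertions), per-allele fitness determined by
classification category and additive per-residue effects, biological
triplicates propagated over day 7/14/21 timepoints plus day-28 treatment
arms (mock, irradiation, PARP inhibitors at two doses), and
Dirichlet-multinomial read sampling.  Output is written in the exact
aligned-allele table dialect consumed by :mod:`crisprtile.alleles`, with a
ground-truth JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .genemodel import GeneModel, Guide, compute_cut_site
from .alleles import Category, ObservedAllele, classify_allele, extract_events

__all__ = ["SimConfig", "GroundTruth", "TilingSimulation", "default_treatments"]

TREATMENTS = (
    "mock",
    "irradiation_2Gy",
    "niraparib_1uM",
    "niraparib_2uM",
    "olaparib_1uM",
    "olaparib_2uM",
)


def default_treatments() -> Tuple[str, ...]:
    return TREATMENTS


@dataclass
class SimConfig:
    """Study design and ground-truth parameters of a simulated screen.

    Defaults mirror the screen's scale: three biological replicates
    followed over three weeks (samples at days 7, 14, 21), drug arms
    applied for one week after day 21 and collected at day 28, sequencing
    depth of 1e5 reads per sample with mild Dirichlet overdispersion, and
    ~34% editing across guides.
    """

    model: GeneModel = None
    guides: Sequence[Guide] = ()
    edit_rate: float = 0.34
    deletion_weights: Dict[int, float] = field(
        default_factory=lambda: {1: 4, 2: 3, 3: 3, 4: 2, 5: 1.5, 6: 1.5, 7: 1, 8: 0.8, 9: 0.8, 10: 0.5, 11: 0.4, 12: 0.3}
    )
    insertion_weights: Dict[int, float] = field(default_factory=lambda: {1: 2, 2: 0.5})
    theta_star: Dict[int, float] = field(default_factory=dict)  # residue -> effect
    category_penalties: Dict[str, float] = field(
        default_factory=lambda: {
            "frame_shift": 2.0,
            "start_codon_deletion": 2.0,
            "splicing_variant": 1.5,
            "de_novo_stop": 2.0,
            "in_frame": 0.0,
            "unedited": 0.0,
        }
    )
    # extra penalty per category for truncations before/at a critical residue
    treatment_penalties: Dict[str, float] = field(
        default_factory=lambda: {
            "mock": 0.0,
            "irradiation_2Gy": 0.2,
            "niraparib_1uM": 1.5,
            "niraparib_2uM": 2.5,
            "olaparib_1uM": 1.5,
            "olaparib_2uM": 2.5,
        }
    )
    sensitive_boundary: Optional[int] = None  # truncations with first divergence <= this are drug-sensitive
    replicates: int = 3
    days: Sequence[int] = (7, 14, 21)
    treatments: Sequence[str] = ("mock",)
    treatment_day: int = 28
    depth: int = 100_000
    # Dirichlet concentration; larger = closer to pure multinomial.  1e6 at
    # depth 1e5 gives ~10% extra variance on a 50-read allele (mild PCR/
    # bottleneck overdispersion); per-replicate biology is log2fc_noise_sd.
    overdispersion: float = 1e6
    log2fc_noise_sd: float = 0.3  # per-replicate biological noise on log2FC
    # days per unit of deficit: 14 makes theta* land 1:1 on the day21/day7
    # log2FC scale (the screen's fitness readout)
    duration_scale: float = 14.0
    tiling_mode: bool = True
    # uniform sequencing-error floor: one 1-nt substitution allele per guide
    # at this frequency, present at the same rate in the unedited control
    sequencing_noise: float = 0.0
    emit_control: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not (0 <= self.edit_rate < 1):
            raise ValueError("edit_rate must be in [0, 1)")


@dataclass
class GroundTruth:
    """Per-allele truth emitted alongside the fixture."""

    alleles: pd.DataFrame  # uid, category, first_divergent, p0, deficit per arm
    theta_star: Dict[int, float]

    def to_json_dict(self) -> dict:
        return {
            "schema_version": 1,
            "theta_star": {str(k): v for k, v in self.theta_star.items()},
            "alleles": self.alleles.reset_index().to_dict(orient="records"),
        }


def _aligned_pair(ref: str, kind: str, pos: int, length: int, ins_seq: str = "") -> Tuple[str, str]:
    """Aligned read/reference strings for a single clean edit."""
    if kind == "deletion":
        read = ref[:pos] + "-" * length + ref[pos + length :]
        return read, ref
    if kind == "insertion":
        read = ref[:pos] + ins_seq + ref[pos:]
        aref = ref[:pos] + "-" * len(ins_seq) + ref[pos:]
        return read, aref
    raise ValueError(kind)


class TilingSimulation:
    """Generates a complete synthetic tiling experiment.

    The stages mirror the real screen: :meth:`spectrum` draws the editing
    outcome alleles and their initial frequencies, :meth:`assign_fitness`
    derives each allele's growth deficit from its classification and the
    additive site effects, :meth:`propagate_and_sample` produces per-sample
    read counts, and :meth:`write_fixture` emits the on-disk fixture.
    """

    def __init__(self, config: SimConfig):
        if config.model is None or not config.guides:
            raise ValueError("config needs a gene model and at least one guide")
        self.config = config
        self.rng = np.random.default_rng(config.seed)

    # -- allele spectrum ----------------------------------------------------

    def spectrum(self) -> pd.DataFrame:
        """Alleles and initial frequencies; index is allele uid.

        Deletions start within +/-2 bp of each cut site; in tiling mode all
        3/6/9-bp deletions in that window are guaranteed present so that
        in-frame coverage tiles the exon like the real spectrum.
        """
        cfg = self.config
        ref = cfg.model.amplicon_seq
        n = len(ref)
        records: Dict[str, dict] = {}

        for guide in cfg.guides:
            cut = compute_cut_site(guide, cfg.model)
            candidates: List[Tuple[str, int, int, str, float]] = []
            for length, wgt in cfg.deletion_weights.items():
                for start in range(cut - 2, cut + 3):
                    if start < 0 or start + length > n:
                        continue
                    candidates.append(("deletion", start, length, "", wgt))
            for length, wgt in cfg.insertion_weights.items():
                ins = "".join(self.rng.choice(list("ACGT"), size=length))
                for point in range(cut - 1, cut + 2):
                    if point <= 0 or point >= n:
                        continue
                    candidates.append(("insertion", point, length, ins, wgt))

            if not cfg.tiling_mode:
                # thin to a random weighted subset; tiling mode keeps the
                # exhaustive cut-site-centred spectrum (all D3/D6/D9 present)
                probs = np.array([c[-1] for c in candidates], dtype=float)
                probs = probs / probs.sum()
                keep = self.rng.choice(
                    len(candidates), size=max(1, len(candidates) // 2), replace=False, p=probs
                )
                candidates = [candidates[i] for i in sorted(keep)]

            total_w = sum(c[-1] for c in candidates)
            for kind, pos, length, ins, wgt in candidates:
                read, aref = _aligned_pair(ref, kind, pos, length, ins)
                uid = f"{read}|{aref}"
                frac = cfg.edit_rate * wgt / total_w / len(cfg.guides)
                rec = records.setdefault(
                    uid,
                    {"aligned_read": read, "aligned_ref": aref, "p0": 0.0},
                )
                rec["p0"] += frac

        for rec in records.values():
            rec["is_noise"] = False
        # sequencing-error alleles: 1-nt substitutions at each cut site,
        # present regardless of editing (they arise from the sequencer)
        if cfg.sequencing_noise > 0:
            for guide in cfg.guides:
                cut = compute_cut_site(guide, cfg.model)
                pos = min(cut, n - 1)
                alt = "C" if ref[pos] != "C" else "T"
                read = ref[:pos] + alt + ref[pos + 1 :]
                records[f"{read}|{ref}"] = {
                    "aligned_read": read,
                    "aligned_ref": ref,
                    "p0": cfg.sequencing_noise,
                    "is_noise": True,
                }

        # unedited allele takes the remaining mass
        uid_wt = f"{ref}|{ref}"
        noise_total = cfg.sequencing_noise * len(cfg.guides) if cfg.sequencing_noise > 0 else 0.0
        records[uid_wt] = {
            "aligned_read": ref,
            "aligned_ref": ref,
            "p0": 1.0 - cfg.edit_rate - noise_total,
            "is_noise": False,
        }
        df = pd.DataFrame.from_dict(records, orient="index")
        df.index.name = "uid"
        df = df[df["p0"] > 0]
        df["p0"] = df["p0"] / df["p0"].sum()
        return df

    # -- fitness ------------------------------------------------------------

    def assign_fitness(self, spectrum: pd.DataFrame) -> GroundTruth:
        """Ground-truth growth deficits per arm, derived from the package's
        own classifier so categories are self-consistent by construction."""
        from .sitemodel import similarity_matrix

        cfg = self.config
        sim = similarity_matrix()
        cats, fdivs = [], []
        base_deficit = []
        for uid, row in spectrum.iterrows():
            allele = ObservedAllele(
                aligned_read=row["aligned_read"], aligned_ref=row["aligned_ref"], reads=0
            )
            ca = classify_allele(allele, cfg.model)
            cats.append(ca.category.value)
            pa = ca.protein_alignment
            fdiv = pa.first_divergent if pa is not None else None
            fdivs.append(fdiv)
            deficit = cfg.category_penalties.get(ca.category.value, 0.0)
            if ca.category == Category.IN_FRAME and pa is not None:
                # same disturbance weights as the estimation model: full for
                # a deleted residue, similarity-discounted for a substitution
                for s in pa.deleted_residues():
                    deficit += cfg.theta_star.get(s, 0.0)
                for s, wt_aa, alt_aa in pa.substitutions:
                    deficit += cfg.theta_star.get(s, 0.0) * (1.0 - sim.get((wt_aa, alt_aa), 0.0))
            base_deficit.append(deficit / cfg.duration_scale)

        truth = spectrum.copy()
        truth["category"] = cats
        truth["first_divergent"] = fdivs
        truth["deficit_per_day"] = base_deficit

        truncating = truth["category"].isin(["frame_shift", "de_novo_stop"])
        for arm in cfg.treatments:
            extra = np.zeros(len(truth))
            pen = cfg.treatment_penalties.get(arm, 0.0)
            if pen and cfg.sensitive_boundary is not None:
                sens = truncating & (
                    pd.to_numeric(truth["first_divergent"], errors="coerce")
                    <= cfg.sensitive_boundary
                )
                extra[sens.to_numpy()] = pen / cfg.duration_scale
            truth[f"deficit_{arm}"] = truth["deficit_per_day"] + extra
        return GroundTruth(alleles=truth, theta_star=dict(cfg.theta_star))

    # -- propagation and sampling ------------------------------------------

    def expected_frequencies(self, truth: GroundTruth) -> Dict[str, pd.Series]:
        """Deterministic expectation of each sample's allele frequencies.

        During days 0..21 all arms share the base deficit; treatment arms
        add their penalty during the one-week window ending at the
        treatment-collection day.
        """
        cfg = self.config
        t = truth.alleles
        out = {}
        for day in cfg.days:
            w = t["p0"] * np.power(2.0, -t["deficit_per_day"] * day)
            out[f"day{day}"] = w / w.sum()
        for arm in cfg.treatments:
            window = cfg.treatment_day - max(cfg.days)
            w = t["p0"] * np.power(2.0, -t["deficit_per_day"] * max(cfg.days))
            w = w * np.power(2.0, -t[f"deficit_{arm}"] * window)
            out[f"{arm}_day{cfg.treatment_day}"] = w / w.sum()
        return out

    def propagate_and_sample(self, truth: GroundTruth) -> Tuple[pd.DataFrame, Dict[str, dict]]:
        """Per-sample read counts plus sample metadata.

        Each biological replicate perturbs the expected frequencies with a
        Dirichlet draw (overdispersion) and samples reads multinomially at
        the configured depth.  Fully reproducible from the config seed.
        """
        cfg = self.config
        expect = self.expected_frequencies(truth)
        baseline_day = min(cfg.days)
        counts = {}
        meta = {}
        for rep in range(1, cfg.replicates + 1):
            for cond, freq in expect.items():
                sid = f"rep{rep}_{cond}"
                p = freq.to_numpy()
                is_baseline = cond == f"day{baseline_day}"
                if cfg.log2fc_noise_sd and not is_baseline:
                    # biological replicate variability acts multiplicatively
                    # on frequency, i.e. additively on the log2FC readout
                    eps = self.rng.normal(0.0, cfg.log2fc_noise_sd, size=len(p))
                    p = p * np.power(2.0, eps)
                    p = p / p.sum()
                if cfg.overdispersion and np.isfinite(cfg.overdispersion):
                    alpha = np.maximum(p * cfg.overdispersion, 1e-9)
                    p = self.rng.dirichlet(alpha)
                counts[sid] = self.rng.multinomial(cfg.depth, p / p.sum())
                if cond.startswith("day"):
                    day, treatment = int(cond[3:]), "mock"
                else:
                    arm, d = cond.rsplit("_day", 1)
                    day, treatment = int(d), arm
                meta[sid] = {"replicate": f"rep{rep}", "day": day, "treatment": treatment}
        df = pd.DataFrame(counts, index=truth.alleles.index)
        return df, meta

    def control_counts(self, truth: GroundTruth) -> pd.Series:
        """Read counts for an unedited control sample: the reference allele
        plus the sequencing-error floor, no editing outcomes."""
        cfg = self.config
        t = truth.alleles
        p = pd.Series(0.0, index=t.index)
        if "is_noise" in t.columns:
            p[t["is_noise"].fillna(False).astype(bool)] = cfg.sequencing_noise
        wt_uid = f"{cfg.model.amplicon_seq}|{cfg.model.amplicon_seq}"
        p.loc[wt_uid] = 1.0 - p.sum()
        return pd.Series(
            self.rng.multinomial(cfg.depth, p.to_numpy()), index=t.index, name="unedited_control"
        )

    # -- fixture I/O ---------------------------------------------------------

    def write_fixture(self, outdir) -> Path:
        """Run the full simulation and write the fixture directory.

        Layout: ``samples/<sample_id>.tsv`` aligned-allele tables,
        ``gene_model.yaml``, ``guides.tsv``, ``sample_sheet.tsv`` and
        ``ground_truth.json``.
        """
        outdir = Path(outdir)
        (outdir / "samples").mkdir(parents=True, exist_ok=True)
        cfg = self.config

        spec = self.spectrum()
        truth = self.assign_fitness(spec)
        counts, meta = self.propagate_and_sample(truth)

        if cfg.emit_control:
            counts = counts.copy()
            counts["unedited_control"] = self.control_counts(truth)
            meta["unedited_control"] = {
                "replicate": "ctrl",
                "day": 0,
                "treatment": "unedited_control",
            }

        sheet_rows = []
        for sid in counts.columns:
            tab = pd.DataFrame(
                {
                    "Aligned_Sequence": spec["aligned_read"],
                    "Reference_Sequence": spec["aligned_ref"],
                    "#Reads": counts[sid],
                }
            )
            tab = tab[tab["#Reads"] > 0]
            tab["%Reads"] = 100.0 * tab["#Reads"] / tab["#Reads"].sum()
            path = outdir / "samples" / f"{sid}.tsv"
            tab.to_csv(path, sep="\t", index=False)
            sheet_rows.append({"file": f"samples/{sid}.tsv", "sample_id": sid, **meta[sid]})

        pd.DataFrame(sheet_rows).to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)

        gm = cfg.model
        with open(outdir / "gene_model.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "amplicon_seq": gm.amplicon_seq,
                    "exons": [list(e) for e in gm.exons],
                    "phase": gm.phase,
                    "start_codon": list(gm.start_codon) if gm.start_codon else None,
                    "native_stop": list(gm.native_stop) if gm.native_stop else None,
                    "strand": gm.strand,
                    "protein_offset": gm.protein_offset,
                },
                fh,
            )
        guide_rows = []
        for g in cfg.guides:
            guide_rows.append(
                {
                    "name": g.name,
                    "protospacer": g.protospacer,
                    "orientation": g.orientation,
                    "pam_start": g.pam_interval[0],
                }
            )
        pd.DataFrame(guide_rows).to_csv(outdir / "guides.tsv", sep="\t", index=False)

        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(truth.to_json_dict(), fh, indent=1, default=str)
        return outdir
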