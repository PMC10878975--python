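"""Frequencies, presence filters, normalization and depletion statistics.

Counts from classified allele tables become frequencies per sample; the
screen's presence/read filter selects alleles observed in every baseline
replicate with at least 20 reads somewhere; log2 fold changes are computed
against the matched baseline (day 7 for fitness, mock for drug response) or
against a control allele, with a 0.5-read pseudocount so fold changes stay
finite; per-allele Student's t-tests are corrected by Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_qvalues",
    "SampleMeta",
    "FrequencyMatrix",
    "to_frequencies",
    "presence_filter",
    "normalize_to_baseline",
    "normalize_to_control_allele",
    "fitness_stats",
    "positional_binning",
    "bin_summary",
    "coverage_calculator",
]


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (the screen's FDR)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one biological sample (after technical-replicate merge)."""

    sample_id: str
    replicate: str
    day: int
    treatment: str = "mock"


@dataclass
class FrequencyMatrix:
    """Alleles x samples counts with per-sample metadata.

    ``counts`` is indexed by allele uid with one integer column per sample;
    ``meta`` maps each sample column to its replicate / day / treatment.
    """

    counts: pd.DataFrame
    meta: Dict[str, SampleMeta]
    pseudocount: float = 0.5
    _totals: pd.Series = field(init=False, repr=False)

    def __post_init__(self):
        missing = set(self.counts.columns) - set(self.meta)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        self._totals = self.counts.sum(axis=0)
        zero = self._totals[self._totals <= 0]
        if len(zero):
            raise ValueError(f"sample(s) with zero total reads: {list(zero.index)}")

    @property
    def totals(self) -> pd.Series:
        return self._totals

    def frequencies(self, pseudo: bool = False) -> pd.DataFrame:
        """count / sample total; with ``pseudo`` the pseudocount is added to
        each allele count (totals unchanged) so zeros stay finite in ratios."""
        c = self.counts.astype(float)
        if pseudo:
            c = c + self.pseudocount
        return c.div(self._totals, axis=1)

    def samples_where(self, **conditions) -> List[str]:
        out = []
        for sid, m in self.meta.items():
            if all(getattr(m, k) == v for k, v in conditions.items()):
                out.append(sid)
        return out


def to_frequencies(counts: pd.DataFrame, meta: Dict[str, SampleMeta]) -> FrequencyMatrix:
    return FrequencyMatrix(counts=counts, meta=meta)


def presence_filter(
    matrix: FrequencyMatrix,
    baseline_samples: Sequence[str],
    min_reads: int = 20,
) -> pd.Index:
    """Alleles present in every baseline sample and with >=min_reads somewhere.

    Baseline samples are the day-7 (or mock) replicates of the contrast at
    hand.  Returns the retained allele index; order-independent.
    """
    baseline_samples = list(baseline_samples)
    if not baseline_samples:
        raise ValueError("no baseline samples identified")
    c = matrix.counts
    in_all_baseline = (c[baseline_samples] >= 1).all(axis=1)
    enough_reads = (c >= min_reads).any(axis=1)
    return c.index[in_all_baseline & enough_reads]


def normalize_to_baseline(
    matrix: FrequencyMatrix,
    baseline_of: Dict[str, str],
    alleles: Optional[pd.Index] = None,
) -> pd.DataFrame:
    """log2 of each allele's frequency relative to its matched baseline.

    ``baseline_of`` maps each non-baseline sample to the baseline sample of
    the same biological replicate (day 7 for time courses, mock for drug
    arms).  The 0.5-read pseudocount is applied to both numerator and
    denominator counts before frequencies are formed.
    """
    freqs = matrix.frequencies(pseudo=True)
    if alleles is not None:
        freqs = freqs.loc[alleles]
    cols = {}
    for sample, base in baseline_of.items():
        if base not in freqs.columns:
            raise ValueError(f"baseline sample {base!r} not in matrix")
        cols[sample] = np.log2(freqs[sample] / freqs[base])
    return pd.DataFrame(cols)


def normalize_to_control_allele(
    matrix: FrequencyMatrix,
    control_uid: str,
    alleles: Optional[pd.Index] = None,
) -> pd.DataFrame:
    """Within-sample frequencies divided by a control allele's frequency.

    Used for designer-mutation (HDR) experiments where each allele is read
    against the WT or a synonymous control allele in the same sample;
    ratios across conditions are then taken by the caller.
    """
    freqs = matrix.frequencies(pseudo=True)
    if control_uid not in freqs.index:
        raise ValueError(f"control allele {control_uid!r} absent from the table")
    ctrl = freqs.loc[control_uid]
    if alleles is not None:
        freqs = freqs.loc[alleles]
    return freqs.div(ctrl, axis=1)


def fitness_stats(
    log2fc: pd.DataFrame,
    reference: "pd.Series | pd.DataFrame | str",
    alternative: str = "two-sided",
    excluded: Optional[pd.Index] = None,
) -> pd.DataFrame:
    """Per-allele Student's t-test of log2 fold changes against a reference.

    ``log2fc`` holds one row per allele and one column per replicate
    (already normalized).  ``reference`` is either the uid of a reference
    allele in the table (test vs WT/Syn), a Series of per-replicate
    reference values, or a DataFrame aligned like ``log2fc`` (paired
    allele-wise contrast such as treatment vs mock, tested as two-sample).
    Equal-variance two-sample t; ``alternative`` in {two-sided, less,
    greater}.  Benjamini-Hochberg q values are computed across the tested
    family, excluding below-LOD alleles via ``excluded``.
    """
    if log2fc.shape[1] < 2:
        raise ValueError("need >=2 replicates per condition for a t-test")
    tested = log2fc.index
    if excluded is not None:
        tested = tested.difference(excluded, sort=False)

    rows = []
    for uid in tested:
        x = log2fc.loc[uid].to_numpy(dtype=float)
        if isinstance(reference, str):
            y = log2fc.loc[reference].to_numpy(dtype=float)
        elif isinstance(reference, pd.DataFrame):
            y = reference.loc[uid].to_numpy(dtype=float)
        else:
            y = np.asarray(reference, dtype=float)
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            # degenerate: no within-group variance, t undefined
            import warnings

            warnings.warn(f"zero variance in both groups for {uid!r}; p set to 1")
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(x, y, equal_var=True, alternative=alternative)
        rows.append({"allele_uid": uid, "mean_log2fc": float(np.mean(x)), "t": t, "p": p})
    res = pd.DataFrame(rows).set_index("allele_uid")
    valid = res["p"].notna()
    q = pd.Series(np.nan, index=res.index)
    if valid.any():
        q.loc[valid] = bh_qvalues(res.loc[valid, "p"])
    res["q"] = q
    for rep in log2fc.columns:
        res[f"log2fc_{rep}"] = log2fc.loc[res.index, rep]
    return res


def positional_binning(
    first_divergent: pd.Series,
    boundaries: Sequence[int],
    values: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Bin truncating alleles by first divergent residue around key positions.

    ``boundaries`` are consecutive residue numbers of interest (e.g. the
    PPR motif 3300-3302): bins are "before <b0>", "at <b>" for each
    boundary, and "after <b_last>".  Alleles without a divergence point
    (pure in-frame matches) are excluded.  If per-replicate values are
    given, grouped box statistics (quartiles, 10th/90th percentiles of the
    per-allele mean) are attached per bin.
    """
    boundaries = sorted(boundaries)
    div = first_divergent.dropna().astype(int)

    def label(pos: int) -> str:
        if pos < boundaries[0]:
            return f"before {boundaries[0]}"
        for b in boundaries:
            if pos == b:
                return f"at {b}"
        return f"after {boundaries[-1]}"

    bins = div.map(label)
    out = pd.DataFrame({"first_divergent": div, "bin": bins})
    if values is not None:
        means = values.mean(axis=1).reindex(out.index)
        out["mean_log2fc"] = means
    return out


def bin_summary(binned: pd.DataFrame, boundaries: Sequence[int]) -> pd.DataFrame:
    """Box-plot statistics (median, quartiles, 10th/90th pct) per bin."""
    boundaries = sorted(boundaries)
    order = [f"before {boundaries[0]}"] + [f"at {b}" for b in boundaries] + [
        f"after {boundaries[-1]}"
    ]
    rows = []
    for b in order:
        vals = binned.loc[binned["bin"] == b, "mean_log2fc"].dropna()
        if len(vals) == 0:
            continue
        rows.append(
            {
                "bin": b,
                "n": len(vals),
                "median": float(vals.median()),
                "q1": float(vals.quantile(0.25)),
                "q3": float(vals.quantile(0.75)),
                "p10": float(vals.quantile(0.10)),
                "p90": float(vals.quantile(0.90)),
            }
        )
    return pd.DataFrame(rows).set_index("bin")


def coverage_calculator(n_cells: float, survival_fraction: float, variant_frequency: float) -> float:
    """Expected number of independent cells carrying a variant.

    n_cells x post-nucleofection survival x variant frequency; e.g. one
    million nucleofected cells at 5% survival give 25x coverage of a
    variant at 0.05% frequency.
    """
    for name, frac in (("survival_fraction", survival_fraction), ("variant_frequency", variant_frequency)):
        if not (0 <= frac <= 1):
            raise ValueError(f"{name} must be in [0, 1], got {frac}")
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    return n_cells * survival_fraction * variant_frequency
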