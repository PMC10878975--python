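"""Maximum-likelihood per-residue functional scores from in-frame alleles.

The tiling screen produces overlapping in-frame deletions (one, two, three
residues) and substitutions covering each residue several times.  The model
treats the per-replicate log2 fold change of allele *a* as additive in the
effects of the residues it disturbs:

    w_{a,r} ~ Normal( -sum_{s in S_a} theta_s * g(d_{a,s}),  sigma^2 )

where theta_s >= 0 is the functional score of residue s (0 = dispensable,
large = deleterious when mutated), g(deleted) = 1, and for a substitution
aa -> aa' the disturbance is discounted by amino-acid similarity,
g = 1 - sim(aa, aa'), with sim derived from BLOSUM62 rescaled to [0, 1].
Alleles in the control categories (frame-shift, start-codon deletion,
splicing variant, de novo stop) enter with a single category effect
gamma_c instead of site terms and act as positive controls.

With Gaussian noise the penalized maximum-likelihood estimate is a ridge
least-squares solve (penalty lambda ||theta||^2 gives identifiability for
residues covered only jointly); uncertainty comes from a nonparametric
bootstrap over alleles.

Usage follows the statsmodels pattern::

    design = build_design(protein_table, log2fc)
    model = SiteEffectModel(design)
    res = model.fit(lam=1e-3)
    res.bootstrap(B=200, seed=0)
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "similarity_matrix",
    "SiteDesign",
    "build_design",
    "SiteEffectModel",
    "SiteEffectResults",
]

_CONTROL_CATEGORIES = (
    "frame_shift",
    "start_codon_deletion",
    "splicing_variant",
    "de_novo_stop",
)


from functools import lru_cache


@lru_cache(maxsize=1)
def similarity_matrix() -> Dict[Tuple[str, str], float]:
    """Amino-acid similarity in [0, 1] from BLOSUM62.

    Off-diagonal scores are min-max rescaled over the 20x20 standard
    residue block; identical residues are pinned to similarity 1.
    """
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    aas = [a for a in blosum.alphabet if a.isalpha() and a not in ("B", "Z", "X", "J", "U", "O")]
    vals = [blosum[a, b] for a in aas for b in aas if a != b]
    lo, hi = min(vals), max(vals)
    sim = {}
    for a in aas:
        for b in aas:
            if a == b:
                sim[(a, b)] = 1.0
            else:
                sim[(a, b)] = (blosum[a, b] - lo) / (hi - lo)
    return sim


@dataclass
class SiteDesign:
    """Observations and dispositions for the site-effect fit.

    One row per (allele, replicate) observation; ``X_site`` carries the
    disturbance weight g of each residue for that allele (0 if unaffected),
    ``X_cat`` the control-category indicators, ``w`` the observed log2 fold
    change.  ``allele_of`` maps rows to allele ids so the bootstrap can
    resample whole alleles.
    """

    sites: List[int]
    categories: List[str]
    X_site: np.ndarray
    X_cat: np.ndarray
    w: np.ndarray
    allele_of: np.ndarray
    allele_sites: Dict[str, Dict[int, float]]
    delta1_covered: frozenset

    @property
    def n_obs(self) -> int:
        return len(self.w)

    @property
    def alleles(self) -> List[str]:
        seen = dict.fromkeys(self.allele_of.tolist())
        return list(seen)

    def coverage(self) -> pd.Series:
        """Number of distinct alleles disturbing each site."""
        counts = {s: 0 for s in self.sites}
        for sites in self.allele_sites.values():
            for s, g in sites.items():
                if g > 0:
                    counts[s] += 1
        return pd.Series(counts, name="n_alleles")


def _allele_dispositions(row, sim) -> Optional[Dict[int, float]]:
    """Map a protein-table row to per-site disturbance weights."""
    key = row["protein_key"]
    if not key:
        return None
    status_part, sub_part, _ins, _tail = key.split("|")
    out: Dict[int, float] = {}
    offset = int(row["protein_offset"]) if "protein_offset" in row else 1
    for i, c in enumerate(status_part):
        if c == "-":
            out[offset + i] = 1.0
    if sub_part:
        for token in sub_part.split(";"):
            pos_aa, alt = token.split(">")
            pos, wt_aa = int(pos_aa[:-1]), pos_aa[-1]
            out[pos] = 1.0 - sim.get((wt_aa, alt), 0.0)
    return out


def build_design(
    protein_table: pd.DataFrame,
    log2fc: pd.DataFrame,
    excluded: Optional[pd.Index] = None,
    sim: Optional[Dict] = None,
) -> SiteDesign:
    """Assemble the site-effect design from the collapsed protein table.

    In-frame alleles contribute site dispositions (deleted residues with
    weight 1, substituted residues with weight 1 - sim); alleles in the
    control categories contribute one category indicator each.  Alleles
    flagged below the detection limit are excluded via ``excluded``.
    ``log2fc`` is the replicate-wise fold-change table from
    :func:`crisprtile.fitness.normalize_to_baseline`, aligned on allele uid.
    """
    if sim is None:
        sim = similarity_matrix()
    idx = protein_table.index.intersection(log2fc.index)
    if excluded is not None:
        idx = idx.difference(excluded, sort=False)

    allele_sites: Dict[str, Dict[int, float]] = {}
    allele_cat: Dict[str, str] = {}
    delta1 = set()
    for uid in idx:
        row = protein_table.loc[uid]
        cat = row["category"]
        if cat == "in_frame":
            disp = _allele_dispositions(row, sim)
            if not disp:
                continue  # translation-identical in-frame allele: no signal
            allele_sites[uid] = disp
            deleted = [s for s, g in disp.items() if g == 1.0]
            if len(disp) == 1 and len(deleted) == 1:
                delta1.add(deleted[0])
        elif cat in _CONTROL_CATEGORIES:
            allele_cat[uid] = cat

    if not allele_sites:
        raise ValueError("no in-frame alleles with site dispositions in the design")

    sites = sorted({s for d in allele_sites.values() for s in d})
    cats = sorted({c for c in allele_cat.values()})
    site_ix = {s: j for j, s in enumerate(sites)}
    cat_ix = {c: j for j, c in enumerate(cats)}

    rows_site, rows_cat, ws, owners = [], [], [], []
    reps = list(log2fc.columns)
    for uid in list(allele_sites) + list(allele_cat):
        for rep in reps:
            w = log2fc.at[uid, rep]
            if not np.isfinite(w):
                continue
            xs = np.zeros(len(sites))
            xc = np.zeros(len(cats))
            if uid in allele_sites:
                for s, g in allele_sites[uid].items():
                    xs[site_ix[s]] = g
            else:
                xc[cat_ix[allele_cat[uid]]] = 1.0
            rows_site.append(xs)
            rows_cat.append(xc)
            ws.append(w)
            owners.append(uid)

    return SiteDesign(
        sites=sites,
        categories=cats,
        X_site=np.asarray(rows_site),
        X_cat=np.asarray(rows_cat),
        w=np.asarray(ws, dtype=float),
        allele_of=np.asarray(owners, dtype=object),
        allele_sites=allele_sites,
        delta1_covered=frozenset(delta1),
    )


class SiteEffectModel:
    """Penalized Gaussian ML model for per-residue functional scores.

    Parameters
    ----------
    design
        A :class:`SiteDesign` from :func:`build_design`.

    Notes
    -----
    The negative log-likelihood in (theta, gamma) at fixed sigma is
    proportional to ``||w + X beta||^2``; adding the ridge ``lam *
    ||theta||^2`` yields a strictly convex problem with the unique
    closed-form solution ``beta = -(X'X + lam D)^{-1} X' w`` (D selects the
    theta block).  sigma is then profiled as the RMS residual.
    """

    def __init__(self, design: SiteDesign):
        self.design = design

    def fit(self, lam: float = 1e-3, tol: float = 1e-8) -> "SiteEffectResults":
        d = self.design
        theta, gamma, sigma, resid = self._solve(d.X_site, d.X_cat, d.w, lam)
        return SiteEffectResults(
            model=self,
            theta=pd.Series(theta, index=pd.Index(d.sites, name="residue"), name="theta"),
            gamma=pd.Series(gamma, index=pd.Index(d.categories, name="category"), name="gamma"),
            sigma=sigma,
            lam=lam,
            resid=resid,
            converged=True,
        )

    @staticmethod
    def _solve(X_site, X_cat, w, lam):
        X = np.hstack([X_site, X_cat]) if X_cat.size else X_site
        k_site = X_site.shape[1]
        D = np.zeros(X.shape[1])
        D[:k_site] = lam
        A = X.T @ X + np.diag(D)
        b = -(X.T @ w)
        beta = np.linalg.solve(A, b)
        resid = w + X @ beta
        sigma = float(np.sqrt(np.mean(resid**2)))
        return beta[:k_site], beta[k_site:], sigma, resid


class SiteEffectResults:
    """Fit results: scores, category effects, noise scale, bootstrap SDs."""

    def __init__(self, model, theta, gamma, sigma, lam, resid, converged):
        self.model = model
        self.theta = theta
        self.gamma = gamma
        self.sigma = sigma
        self.lam = lam
        self.resid = resid
        self.converged = converged
        self.theta_sd: Optional[pd.Series] = None
        self.gamma_sd: Optional[pd.Series] = None
        self._B: Optional[int] = None
        self._seed: Optional[int] = None

    # -- uncertainty --------------------------------------------------------

    def bootstrap(self, B: int = 200, seed: Optional[int] = None) -> pd.Series:
        """Nonparametric bootstrap over alleles: resample alleles with
        replacement, refit, and take the SD of each score across B refits.

        Sites absent from a bootstrap replicate keep NaN in that replicate;
        the SD is over the replicates where the site was estimable.
        """
        if B < 10:
            raise ValueError("B must be >= 10 for a usable SD")
        d = self.model.design
        rng = np.random.default_rng(seed)
        alleles = np.asarray(d.alleles, dtype=object)
        rows_of: Dict[str, np.ndarray] = {
            a: np.flatnonzero(d.allele_of == a) for a in alleles
        }
        thetas = np.full((B, len(d.sites)), np.nan)
        gammas = np.full((B, len(d.categories)), np.nan)
        for b in range(B):
            chosen = rng.choice(alleles, size=len(alleles), replace=True)
            rows = np.concatenate([rows_of[a] for a in chosen])
            Xs, Xc, w = d.X_site[rows], d.X_cat[rows], d.w[rows]
            covered = Xs.any(axis=0)
            cat_covered = Xc.any(axis=0) if Xc.size else np.zeros(0, dtype=bool)
            th, ga, _, _ = SiteEffectModel._solve(
                Xs[:, covered], Xc[:, cat_covered] if Xc.size else Xc, w, self.lam
            )
            thetas[b, covered] = th
            if Xc.size:
                gammas[b, cat_covered] = ga
        self.theta_sd = pd.Series(
            np.nanstd(thetas, axis=0, ddof=1), index=self.theta.index, name="sd"
        )
        self.gamma_sd = pd.Series(
            np.nanstd(gammas, axis=0, ddof=1) if gammas.size else [],
            index=self.gamma.index,
            name="sd",
        )
        self._B, self._seed = B, seed
        return self.theta_sd

    # -- reporting ----------------------------------------------------------

    def score_table(self, delta1_mask: bool = True) -> pd.DataFrame:
        """Per-residue functional scores with SDs and coverage.

        With ``delta1_mask`` (default) only residues covered by at least
        one single-residue deletion are reported — multi-residue coverage
        alone does not separate a residue's effect from its neighbours'.
        Control-category effects are appended as labelled rows.
        """
        d = self.model.design
        cov = d.coverage()
        rows = self.theta.index
        if delta1_mask:
            rows = rows[rows.isin(sorted(d.delta1_covered))]
        tab = pd.DataFrame(
            {
                "score": self.theta.loc[rows],
                "sd": self.theta_sd.loc[rows] if self.theta_sd is not None else np.nan,
                "n_alleles": cov.loc[rows],
                "delta1_covered": [s in d.delta1_covered for s in rows],
            }
        )
        tab.index = pd.Index([str(s) for s in rows], name="site")
        if len(self.gamma):
            cat_rows = pd.DataFrame(
                {
                    "score": self.gamma.values,
                    "sd": self.gamma_sd.values if self.gamma_sd is not None else np.nan,
                    "n_alleles": np.nan,
                    "delta1_covered": False,
                },
                index=pd.Index(self.gamma.index, name="site"),
            )
            tab = pd.concat([tab, cat_rows])
        return tab

    def summary(self) -> str:
        d = self.model.design
        lines = [
            "Site-effect model (Gaussian ML, ridge-penalized)",
            f"  observations: {d.n_obs}   alleles: {len(d.alleles)}   sites: {len(d.sites)}",
            f"  lambda: {self.lam:g}   sigma-hat: {self.sigma:.4f}   converged: {self.converged}",
        ]
        if self._B:
            lines.append(f"  bootstrap: B={self._B} seed={self._seed}")
        lines.append("")
        lines.append(self.score_table(delta1_mask=True).to_string(float_format=lambda v: f"{v:.3f}"))
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {
            "lambda": self.lam,
            "sigma": self.sigma,
            "converged": self.converged,
            "bootstrap_B": self._B,
            "bootstrap_seed": self._seed,
            "n_obs": int(self.model.design.n_obs),
            "n_alleles": len(self.model.design.alleles),
        }
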