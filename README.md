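# crisprtile

Analysis of CRISPR saturation **mutation-tiling** screens: pooled experiments
in which every available SpCas9 guide across a coding region mutagenizes a
cell population, and deep amplicon sequencing follows the resulting allele
spectrum over weeks of competitive growth — optionally under selective
pressure such as ionizing radiation or PARP inhibitors (niraparib,
olaparib). Screens of this design are used to map, at single-amino-acid
resolution, which residues of a gene such as *BRCA2* are required for
fitness and which truncations sensitize cells to drugs.

The package is aimed at analysts who already have per-sample aligned-allele
tables (the `Alleles_frequency_table` dialect produced by CRISPResso2-style
allele calling) and need everything downstream:

* **Allele classification** — mutation events are extracted from each
  aligned read/reference pair, filtered by proximity to the predicted Cas9
  cut sites (single edit within 2 bp of a cut; complex or distal alleles
  are set aside), and classified into five categories: *start-codon
  deletion*, *splicing variant* (edit within ±3 bp of a splice junction),
  *frame-shift*, *de novo stop*, and *in-frame*. Alleles with identical
  splice-aware translations are collapsed.
* **Fitness / drug-response quantification** — frequencies are normalized
  per biological replicate to the matched day-7 (or mock) baseline with a
  0.5-read pseudocount; the presence filter keeps alleles seen in every
  baseline replicate with ≥ 20 reads somewhere; per-allele Student's
  *t*-tests are FDR-corrected by Benjamini–Hochberg; truncating alleles can
  be binned by their first divergent residue around a critical motif.
* **Per-residue functional scores** — the core statistical model (below).
* **Synthetic screens** — a generator producing complete fixtures
  (cut-site-centred indel spectra, additive ground-truth fitness, replicate
  time courses, treatment arms, Dirichlet-multinomial read sampling) in the
  exact input dialect, with a ground-truth sidecar.

## The site-effect model

In-frame deletions of one, two or three residues tile the region and
overlap; each allele's fitness readout therefore mixes the effects of the
residues it disturbs. The model treats the per-replicate log2 fold change
of allele *a* as additive in per-residue effects:

    w_{a,r} ~ Normal( − Σ_{s ∈ S_a} θ_s · g(d_{a,s}) ,  σ² )

where θ_s ≥ 0 is the **functional score** of residue *s* (0 = dispensable,
large = deleterious when mutated), g = 1 for a deleted residue, and
g = 1 − sim(aa, aa′) for a substitution, with amino-acid similarity taken
from BLOSUM62 rescaled to [0, 1]. Control categories (frame-shift,
start-codon deletion, splicing variant, de novo stop) enter as single
category effects γ_c and act as positive controls. The penalized maximum-
likelihood fit (ridge λ‖θ‖² for residues only covered jointly) is a
closed-form least-squares solve; uncertainty comes from a nonparametric
bootstrap over alleles. Scores are reported for residues covered by at
least one single-residue deletion.

The API follows the statsmodels pattern:

```python
from crisprtile import SiteEffectModel, build_design

design = build_design(protein_table, log2fc)   # from the pipeline stages
res = SiteEffectModel(design).fit(lam=1e-3)
res.bootstrap(B=200, seed=0)
print(res.summary())
```

## Worked example

Simulate a screen on the bundled exon-2-like amplicon (14 codons, 6 guides,
one critical residue at position 12 with true effect θ = 2, three
biological replicates sampled at days 7/14/21 at depth 10⁵), then fit
scores:

```
$ crisprtile simulate --outdir fx --seed 7
fixture written to fx
$ crisprtile score --fixture fx --out scores.tsv --bootstrap 100 --seed 7
Site-effect model (Gaussian ML, ridge-penalized)
  observations: 738   alleles: 246   sites: 12
  lambda: 0.001   sigma-hat: 0.6989   converged: True
  bootstrap: B=100 seed=7

                      score    sd  n_alleles  delta1_covered
site
2                     0.091 0.169      5.000            True
3                     0.221 0.106      8.000            True
4                    -0.166 0.083     13.000            True
5                     0.196 0.108     14.000            True
6                    -0.192 0.108     15.000            True
7                     0.145 0.116     18.000            True
8                     0.073 0.137     18.000            True
9                     0.060 0.112     16.000            True
10                    0.186 0.100     13.000            True
12                    2.072 0.335      9.000            True
frame_shift           2.136 0.030        NaN           False
splicing_variant      1.608 0.034        NaN           False
start_codon_deletion  2.121 0.106        NaN           False
```

The critical residue 12 stands out (θ̂ = 2.07 ± 0.34 against a true effect
of 2) while the other residues sit near zero; the control-category rows
recover their configured growth penalties (frame-shifts at ≈ 2, splicing
variants at ≈ 1.6 against a truth of 1.5). `n_alleles` counts the distinct
alleles informing each residue; residue 11 is absent because its deletion
is indistinguishable from residue 12's (adjacent identical amino acids).

The coverage arithmetic of the experimental design is also exposed:

```
$ crisprtile coverage --n-cells 1e6 --survival 0.05 --frequency 0.0005
25
```

i.e. a variant at 0.05% frequency in one million nucleofected cells with 5%
survival is expected in 25 independent cells.

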