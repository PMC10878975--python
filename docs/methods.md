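# Methods

## Scope and data model

The package consumes per-sample aligned-allele tables (columns
`Aligned_Sequence`, `Reference_Sequence`, `#Reads`; extra percentage
columns are ignored and recomputed), an amplicon-local gene model (YAML +
FASTA: exon intervals, reading-frame phase, optional start/stop codons,
strand, protein numbering offset), and a guide table (name, protospacer,
orientation, PAM start). All coordinates are 0-based half-open; cut sites
and insertion points are between-base coordinates. Minus-strand guides are
mapped to amplicon coordinates at load time, so everything downstream is
strand-free. Read alignment, trimming and quality filtering are upstream
concerns (CRISPResso2 or equivalent); genome-scale annotation formats are
out of scope — gene models are amplicon-local by design.

## Allele classification

**Cut sites.** The blunt SpCas9 cut is placed 3 bp 5′ of the PAM (between
protospacer positions 17 and 18). This is the accepted SpCas9 geometry; the
proximity filter depends on it.

**Events.** Maximal runs of read-gaps become one deletion, of
reference-gaps one insertion, of mismatching bases one substitution. A run
ends at a matching column or at a change of run type. This makes "number
of mutations" well defined for the complexity filter; folding
substitutions adjacent to indels into a single event would be an
alternative convention, and would only reclassify alleles that we
currently set aside as complex.

**Proximity filter** (radius 2 bp, configurable): an allele is kept iff it
carries exactly one event and that event touches a window of ±radius
around some cut site (insertions by their insertion point); zero events is
the unedited allele. Any second event — near or far — drops the allele as
complex, since a pooled screen cannot interpret multi-edit genotypes. The
distance between a base and a between-base cut coordinate is 0 when the
base is adjacent to the cut on either side.

**Categories**, in precedence order (the first matching rule wins):

1. *start-codon deletion* — any start-codon base deleted or substituted,
   or an insertion splitting the codon. Substitutions count as
   "mutagenized": a start-codon missense must be classifiable even though
   the category keeps its conventional name.
2. *splicing variant* — any mutated base (or insertion point) within ±3 bp
   of an annotated splice junction. Only exon boundaries with flanking
   intronic sequence inside the amplicon count as junctions; an amplicon
   edge is not a junction.
3. *frame-shift* — net indel size not a multiple of 3 (a DNA-level rule:
   it applies even to edits outside the coding sequence).
4. *de novo stop* — in-frame at the DNA level, but the splice-aware
   translation contains a premature stop (at the deletion junction or
   within inserted sequence).
5. *in-frame* — everything else, including substitution-only alleles
   (net 0), which designer-mutation (HDR) experiments require.

**Translation.** The edited coding sequence is reconstructed by walking the
aligned pair: read bases over exonic reference positions, plus inserted
bases whose insertion point lies strictly inside an exon; introns are
excised at the native junctions (splice-site edits are never translated —
they are classified before this step). Translation is anchored at the
start codon (or the phase-implied first complete codon), so edits upstream
of the start cannot shift its frame. The edited peptide is aligned to WT
end-anchored: longest common prefix, then longest common suffix of the
remainder; the middle is paired as mismatches with the surplus as
deletions/insertions. This greedy scheme matches the heat-map
representation conventional for tiling screens and gives each frame-shift
a well-defined first divergent residue (its truncation point). Note that
end-anchoring attributes a deletion within a run of identical residues to
the last position of the run (e.g. a deletion of one of two adjacent
phenylalanines is reported at the second).

**Collapse.** Alleles with identical (category, protein alignment) merge
with summed counts; frame-shifts carry their divergence point in the key.
Splicing variants have no defined translation, so they collapse on their
nucleotide-level event signature instead. With collapse disabled (HDR
designer-mutation mode) the nucleotide sequence is the key. Total reads
are conserved exactly either way.

**Background filter.** When an unedited control sample is present, any
allele whose per-sample frequency is at or below its frequency in the
control is flagged below the limit of detection. Flags exclude alleles
from statistics but never delete rows, so tables stay alignable across
samples.

## Fitness quantification

Frequencies are counts over the sample total. The presence filter retains
alleles observed (≥ 1 read) in **every** baseline replicate of the contrast
at hand — day-7 samples for time courses, mock samples for drug contrasts —
and with ≥ 20 reads in at least one sample. Fold changes are computed per
biological replicate against the matched baseline, with a 0.5-read
pseudocount added to allele counts (totals unchanged) so that dropouts
stay finite: an allele at 40 reads in mock and 0 under drug at 10⁵ total
reads scores log2(0.5/40.5) ≈ −6.34.

Frequencies are compositional: when deleterious alleles deplete, every
remaining allele's frequency inflates at constant abundance. For the
site-effect fit (which has no intercept) fold changes are therefore
anchored to the unedited allele within each replicate; this cancels the
pool-composition drift and any replicate-wide multiplicative noise.
Reporting-level filters from figure conventions (frequency > 0.5%, ≥ 100
reads at baseline) are output-time options, not part of estimation.

Per-allele tests are two-sample equal-variance Student's *t* on
per-replicate log2 values (allele vs WT/synonymous control, or treatment
vs mock), one- or two-tailed as the contrast dictates; q values are
Benjamini–Hochberg across the tested family, excluding below-LOD alleles.
If both groups have zero variance the test is degenerate and p is set to 1
with a warning. Truncating alleles (frame-shift / de novo stop) can be
binned by first divergent residue around configured boundary positions
(e.g. a critical three-residue motif), with box-plot statistics (median,
quartiles, 10th/90th percentiles) per bin.

Coverage arithmetic: expected independent cells carrying a variant =
n_cells × survival fraction × variant frequency.

## The site-effect model

Per-replicate log2 fold change of in-frame allele *a*:

    w_{a,r} ~ Normal( − Σ_{s ∈ S_a} θ_s · g(d_{a,s}) ,  σ² )

with g(deleted) = 1 and g(substituted aa→aa′) = 1 − sim(aa, aa′).
Similarity is BLOSUM62 min-max rescaled to [0, 1] over off-diagonal pairs
with the diagonal pinned to 1 (configurable). Alleles of the control
categories enter with one indicator effect γ_c each. The penalized
negative log-likelihood is ‖w + Xβ‖² + λ‖θ‖² (θ block only), a strictly
convex problem with the unique closed-form solution
β̂ = −(XᵀX + λD)⁻¹Xᵀw; σ̂ is the RMS residual. Because the optimum is
closed-form, the fit is deterministic and needs no optimizer restarts;
randomness enters only through the bootstrap.

* **λ = 1e−3** (default): inert for residues with independent coverage,
  but makes residues observed only jointly identifiable (the effect is
  split equally across a never-separated pair). λ is reported with
  results.
* **Sign convention**: θ_s ≥ 0 means mutating residue *s* is deleterious;
  important residues score high.
* **Uncertainty**: nonparametric bootstrap resampling *alleles* (all their
  replicate observations together) with replacement, B = 200 by default
  (B ≥ 10 enforced); the per-residue SD is taken across refits in which
  the residue was estimable. Small coverage (2–3 alleles) makes the
  bootstrap SD itself noisy — a known small-sample deficiency discussed in
  the limitations.
* **Reporting mask**: by default only residues covered by at least one
  single-residue deletion are reported; multi-residue coverage alone does
  not separate a residue from its neighbours.

A Gaussian likelihood on log2 fold changes is the simplest model meeting
the design goals (maximum likelihood, multi-site information sharing,
similarity weighting). Count-level alternatives (e.g.
Dirichlet-multinomial observation models) would propagate sampling noise
more faithfully for low-count alleles at the cost of a non-convex fit; the
read-depth regimes this package targets (10⁵–10⁶ reads/sample with a ≥ 20
read presence filter) keep per-observation sampling noise well below the
biological replicate noise.

## Synthetic screens

The generator emulates the experimental design end to end, with defaults
sized to the real screens:

* **Spectrum**: per guide, deletions of 1–12 bp starting within ±2 bp of
  the cut (weights decreasing with length) and +1/+2 insertions at the
  cut; in tiling mode all 3/6/9-bp deletions in the window are guaranteed
  present, mirroring the near-complete in-frame tiling such screens
  achieve. The unedited allele keeps 1 − edit rate (default 34%, the
  RNP-delivery efficiency regime). An optional uniform sequencing-error
  floor adds 1-nt substitution alleles present equally in an emitted
  unedited control, to exercise the background filter.
* **Fitness**: each allele is classified by the package's own classifier
  (self-consistency by construction); its growth deficit per day is
  (category penalty + Σ θ*_s · g)/duration-scale, with the same
  disturbance weights g as the estimator. The duration scale of 14 days
  puts θ* one-to-one on the day-21/day-7 log2FC scale. Treatment arms add
  a configured penalty — e.g. an extra PARPi penalty for truncations whose
  first divergent residue is at or before a critical motif boundary —
  during the one-week window between day 21 and the day-28 collection.
* **Propagation/sampling**: expected frequency at day *t* ∝
  p₀ · 2^(−deficit·t), renormalized (deterministic, closed-form
  expectations for tests). Per biological replicate, non-baseline samples
  get multiplicative per-allele noise 2^ε with ε ~ N(0, 0.3) (the
  replicate-to-replicate variability of the log2FC readout), then a
  Dirichlet perturbation (concentration 10⁶: mild PCR/bottleneck
  overdispersion at depth 10⁵) and a multinomial read draw. Three
  replicates, days 7/14/21, day-28 treatment arms, depth 10⁵ by default;
  everything is reproducible from one seed.

What the generator does **not** emulate: PCR jackpotting and UMI
structure, alignment artefacts (alleles are emitted pre-aligned), guide
cross-contamination, position-dependent editing efficiency, and any
nonlinearity between growth deficit and log-frequency (the decay model is
exactly log-linear). Passing recovery tests on these fixtures therefore
demonstrates correctness of the estimation machinery under the assumed
noise structure, not robustness to real-data artefacts upstream of the
allele table.

## Numerical and degenerate-input choices

* Pseudocount 0.5 reads in ratio computation only (never in raw counts or
  the presence filter).
* Zero-total samples, missing baselines, empty in-frame designs, < 2
  replicates, and bootstrap B < 10 raise errors naming the offending
  input; zero-variance tests warn and return p = 1.
* Sites with no covering allele are reported as undefined, never as 0.
* Ties in category precedence (start codon and splice window both hit)
  resolve to the start-codon category, following rule order.
* BH q values come from statsmodels (`fdr_bh`); the test suite verifies
  them against a from-scratch step-up implementation to float rounding.

## Known limitations

* The greedy end-anchored protein alignment can place indels ambiguously
  within repeated residues (reported at the run's last position); scores
  at such residues aggregate their neighbours' signal.
* The bootstrap underestimates score uncertainty at residues covered by
  very few (≈ 2) alleles.
* The site model assumes additivity across residues; epistasis within
  multi-residue deletions biases θ at jointly covered sites.
* The background filter is a per-sample LOD rule, not an error model; it
  assumes the control went through the identical pipeline.
* Complex (multi-event) alleles are discarded rather than decomposed; at
  high editing multiplicity this loses a fraction of genuine outcomes.
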