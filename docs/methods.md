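# Methods

This note records the statistical definitions, modelling assumptions and
design choices behind `mirmut`, in the order the pipeline applies them.

## Coordinate frame and gene model

Every gene is represented by its *extended sequence*: the pre-miRNA hairpin
of length L plus exactly 25 nt of flanking sequence on each side.
Positions use `n.` numbering: `n.1` is the first precursor nucleotide, the
5′ flank is `-25 … -1` (no zero), the 3′ flank `L+1 … L+25`. Variant
tokens follow the noncoding-RNA HGVS style (`n.35C>T`, `n.5-7delAGC`,
`n.97_98dupGG`, `n.10_11insAC`); indels longer than 4 nt are rejected as
unreliable annotations. Genes missing either mature-arm annotation are
rejected (`arm_undefined`): without both arms, subregions and strand
balance are undefined.

Subregion labels (`flank5, duplex5p, seed5p, loop, duplex3p, seed3p,
flank3`) are derived **only** from the annotated mature spans: everything
5′ of the mature-5p start is 5p flank, everything 3′ of the mature-3p end
is 3p flank, the seed is mature positions 2–8 of each arm. This means
basal-stem positions inside the hairpin carry flank labels — a deliberate
choice that matches how such positions are labelled in practice and frees
the labels from any assumption about the exact hairpin boundary.

## IsomiR taxonomy

A read maps to two signed end shifts relative to the canonical ends:
`shift5` and `shift3`, positive = downstream (3′-ward) for both ends.
Collapsing each shift to its sign gives the nine basic classes
`0|0, 0|−, 0|+, +|0, −|0, +|−, −|+, +|+, −|−` (the sign map {−,0,+}² is
total and its image has exactly 9 elements). In the ten-class scheme,
reads carrying nontemplated 3′ additions form a separate `(nt)` class
regardless of their shifts. Note the asymmetric length semantics: `+1|0`
is 1 nt *shorter* at the 5′ end, while `0|+1` is 1 nt *longer* at the 3′
end. Profiles are weight-normalized fraction vectors (raw counts for
allele-resolved work, RPM for cross-sample work); the "5p-isomiR" view
coarsens the full profile by `shift5` only, which matters when a mutation
shifts the DROSHA cleavage site and thereby the seed.

Shifts beyond ±10 nt are not trusted and such records are rejected at
ingestion (`shift_out_of_range`).

## Eligibility

Dataset-level exclusions (each mutation may accumulate several reason
codes): redundant multicopy genes; >1 mutation per gene per sample; indels
>4 nt; samples without sRNA-seq data or with more than one dataset; genes
without reads in the mutated sample; samples whose reads for the gene are
dominated by ambiguous mappings (default threshold: ambiguous > 50% of the
gene's reads — no standard value exists, so this is configurable); and
variants absent from the somatic-variant catalog *when the mutation lies
in a mature miRNA or within ±2 nt of a DROSHA/DICER1 cleavage site* (such
mutations must be visible in the read data to be analyzable; catalog
membership is supplied as an input flag, the catalog itself is not
bundled).

Per-experiment inclusion floors: E1 ≥50 reads on the mutated arm; E2 ≥50
reads per allele; E3 ≥10 RPM on both sides; E4 ≥20 RPM for a strand on
both sides (both strands analyzed when both qualify); E5 ≥50 reads in the
mutated sample, wild-type samples under 50 reads dropped from the cohort.
E1/E2 additionally require the mutation to lie inside a mature miRNA.

## Within-sample tests (E1, E2)

**E1.** For a mutation visible at the RNA level, the 2×2 table
(mut/wt RNA reads vs mut/wt DNA reads) is tested with a two-sided Fisher
exact test. The implementation sums hypergeometric probabilities no
larger than the observed table's, comparing probabilities as exact
integers over the common denominator, so tie-breaking is deterministic and
platform-independent (two-sided exact p-values are definition-dependent;
this is the common "sum of ≤-probability outcomes" convention, the one
scipy also uses). The fold change is the ratio of mutant-allele
*fractions* (RNA over DNA) on the log2 scale; when any cell is zero a
Haldane-style +0.5 is applied to all cells **for the fold change only** —
the exact test always runs on raw counts. Call: adjusted p < 0.05 and
|log2FC| ≥ 1.

**E2.** The two alleles' nine-class count vectors form a 2×9 table; +5
reads are added to every class before the chi-square (stabilizing classes
with zero reads), and Cramer's V = sqrt(chi²/N) (min(r−1,c−1)=1) is
computed on the same pseudocounted table for internal consistency.
Strength bins: <0.1 none, 0.1–0.2 small, 0.2–0.4 medium, >0.4 large.
Call: adjusted p < 1e-11 and V > 0.2. The `pairwise_profile_v` utility
computes the V distribution among same-allele profiles across samples,
verifying that 0.2 sits above ordinary inter-sample variability.

The multiplicity adjustment for E1/E2 defaults to Benjamini–Hochberg with
Bonferroni available by configuration (no method is canonical here;
Bonferroni is explicit only in the cross-sample tests).

## Cross-sample tests (E3, E4, E5)

All three share one engine. Given one mutated sample's value and n ≥ 3
wild-type values of the same cancer-type cohort: a one-sample t test of
the wild-type values against the hypothesized mean equal to the mutated
sample's value (the only orientation a single observation permits;
two-sided, df = n−1); z = (mut − mean_wt)/sd_wt with a two-sided normal p
(sidedness is a package choice); and a Tukey outlier flag (beyond 1.5×IQR
outside the quartiles, linear-interpolation quartiles). The Bonferroni
denominator for the t p-value is the number of mutations tested in the
same experiment in the run.

* **E3** works on log2(RPM+1) gene levels (total RPM of both arms,
  exclusive + nontemplate + mutated reads; ambiguous mappings excluded).
  log2FC is the mutated sample's log level minus the mean wild-type log
  level — consistent with testing on the transformed scale (a raw-ratio
  variant is exposed by configuration). Call: Bonferroni t p < 0.05 ∧
  z p < 0.05 ∧ |log2FC| > 1 ∧ outlier.
* **E4** uses ten-class RPM-weighted profiles. The reference is the
  arithmetic per-class mean of the wild-type sample profiles; the mutated
  sample's L1 distance to it is compared against each wild-type sample's
  distance to the *same* mean (no leave-one-out — with the cohort sizes
  involved the bias of including a sample in its own reference mean is
  O(1/n) and a fixed reference keeps all distances exchangeable). The L1
  distance ranges 0–2 and reaches 2 only on disjoint isomiR sets. Call:
  Bonferroni t p < 0.05 ∧ z p < 0.05 ∧ distance > 0.2.
* **E5** uses B = log2((c5p+1)/(c3p+1)) on raw counts (antisymmetric under
  arm swap). The effect floor ">10% change in strand fractions" is read
  as 10 *percentage points* of the 5p fraction — the stricter, plainer
  reading. Call: Bonferroni t p < 0.05 ∧ z p < 0.05 ∧ |Δf5p| > 10 points
  ∧ outlier.

A mutation called in ≥1 experiment is *functional* in the roll-up, and the
`functional_enrichment` summary compares functional-call rates between
homozygous and nonhomozygous mutations (fold enrichment = ratio of
proportions; two-sided Fisher exact test on the implied 2×2 table).

## Precursor stability (ddG)

The extended sequence (L+50 nt) is folded for the wild-type and mutant
alleles; ddG = dG_mut − dG_wt, positive = destabilizing. Folding is a
backend contract: the shipped `StubFoldBackend` is a deterministic
base-pairing proxy (it pairs the sequence naively against its reverse and
scores GC/AU/GU pairs 3/2/1) so that all ddG bookkeeping and statistics
are exactly reproducible everywhere; `RNAfoldBackend` shells out to the
ViennaRNA `RNAfold` executable for real minimum-free-energy estimates.
Cohort statistics: a paired t test of dG_mut vs dG_wt across mutations
(overall destabilization) and a Welch two-sample t test of ddG in
functional vs remaining mutations (Student's available by configuration).
No quantitative energy claims are attached to the stub backend.

## The synthetic-cohort generator

The generator emulates the data structure the experiments assume — it is
the package's own stated model, not a claim about any particular dataset:

* gene baseline expression log-normal (default 2¹⁰ = 1024 RPM, log2 SD 1)
  with log-normal per-sample noise (log2 SD 0.4, a typical cohort spread
  after normalization); library size 10⁶ reads, Poisson total counts;
* per-gene mean 5p fraction from Beta(8, 2) (most precursors have a
  dominant arm), per-sample Beta noise with precision 300;
* per-arm 10-class templates drawn from a Dirichlet prior with a dominant
  canonical class; per-sample class counts Dirichlet-multinomial with
  precision (overdispersion) 150;
* DNA support Binomial(100, VAF); ambiguous reads at rate 0.02.

A mutated sample mixes two alleles: the mutant allele's expected output is
λ × the wild-type allele's, so its RNA read share is
ρ = vλ/(1−v+vλ) for DNA VAF v, and the sample's total output scales by
(1−v+vλ). Class shifts (mass moved between template classes; moving mass
0.4 gives allele-level L1 distance exactly 0.8) and strand shifts
(replacement of the mutant allele's 5p fraction) act on the mutant allele
only. All draws come from one seeded generator; identical seeds give
byte-identical outputs.

What the generator does **not** emulate: batch effects and their
correction (the pipeline takes normalized matrices as given), cancer-type-
specific expression landscapes, sequence-dependent processing (class
shifts are injected, not mechanistically derived), mapping artifacts
beyond a flat ambiguous-read rate, and tumor purity / subclonality beyond
the single VAF parameter. Passing the simulation-based tests therefore
demonstrates the statistical machinery's calibration and sensitivity under
the stated model — not performance on raw TCGA-like data.

## Calibration and recovery conditions

The simulation-backed guarantees in `tests/test_acceptance.py` use 50
wild-type samples per cohort (a mid-sized cancer-type cohort), 200 null
replicates for type-I control and 100 replicates per recovery scenario —
sizes at which a 5% rate is estimated to within ±3 points while the whole
suite stays fast. The three recovery scenarios mirror the three endpoint
archetypes:

* a homozygous 64× level drop in a highly expressed gene (~8000 RPM
  baseline, so the gene stays above the 10-RPM floor after the collapse);
* a 40%-mass class shift at VAF 0.5 (allele L1 = 0.8, observed sample
  distance ≈ 0.4); the class template is concentrated around its prior
  mean here because the injected shift is defined on template mass;
* a strand flip in a gene with a 99.7%-dominant 5p arm whose observed 5p
  fraction falls to 65% at DNA VAF 0.19. With equal allele output the
  sample fraction could not drop below ~81% at that VAF, so the scenario
  gives the mutant allele pure 3p output with λ ≈ 2.28 chosen in closed
  form from the mixing formula — i.e. the mutant allele overproduces the
  3p strand, which is exactly what an observed collapse of that size at
  low VAF implies.

## Numerical choices and degenerate inputs

* Fisher p on tables with any zero margin is 1 by convention.
* Very large tables (total > ~10⁶) still use exact integer arithmetic;
  cost grows with the support size, which is acceptable at read depths
  this pipeline sees.
* Cohorts with n < 3 or zero variance are flagged (`cohort_too_small`,
  `degenerate_cohort`) and produce no call rather than a NaN cascade.
* An all-zero-weight profile raises `empty_profile`; mismatched class
  label sets in a distance computation are a hard error.
* Equality of serialized outputs is guaranteed by fixed column orders and
  fixed float formatting in every writer.

## Known limitations

* The isoMiRmap adapter consumes a documented minimal column subset
  (sample, gene, arm, shifts, nontemplate flag, count) from the three
  per-source files; richer annotations in those files are ignored.
* The sign convention (+ = downstream for both ends) is applied uniformly;
  published figures occasionally describe 5′ shifts in length terms
  ("extension"/"shortening"), which can read as the opposite sign.
* Antisense reads, genome alignment, read QC and batch correction are out
  of scope; inputs are taken as mapped, allele-assigned and normalized.
* The stub folding backend is a reproducibility device; use the ViennaRNA
  backend (or export FASTA for an external folder) for real energies.
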