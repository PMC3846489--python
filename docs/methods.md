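# Methods

`hdimpute` evaluates the accuracy of statistical genotype imputation from a
medium-density SNP panel up to a high-density (HD) panel, within and across
livestock breeds, together with the population factors that drive that
accuracy. Everything runs on simulated data with known truth, so every
accuracy number the package reports is an exact count of wrongly imputed
alleles.

## Study design

A breed is simulated as a pedigreed population genotyped on a two-panel
chip pair: an HD set of biallelic SNPs, of which an evenly spread subset
(default 5%) is shared with the medium-density panel. The oldest animals
form the reference (training) population; the youngest 20% (by birth year,
ties broken by animal id) form the validation set. Validation animals have
their HD-only markers masked, mimicking animals genotyped only on the
medium-density chip; the masked genotypes are re-imputed from the phased
reference and compared with the simulated truth.

The headline statistic is the **allelic imputation error rate**: wrongly
imputed alleles over all imputed alleles, where a het/hom disagreement
counts one allele and opposite homozygotes count two. It is a ratio of
totals, not a mean of per-animal rates (per-animal and per-SNP breakdowns
are also reported).

## Synthetic data

* **Founder haplotypes** are sampled per chromosome from a neutral
  coalescent (msprime) with recombination at 1 cM/Mb. Coalescent founders
  share identity-by-descent segments exactly as the haplotypes of a real
  breed do; this sharing — not the marginal LD curve — is what makes
  population phasing and imputation work, and a marker-wise correlation
  process cannot produce it. The `ld_strength` knob is the LD half-decay
  distance in bp and fixes N_e = 1/(4 × 10⁻⁸ × ld_strength); the default
  35 kb (N_e ≈ 714) yields mean r² at 70 kb of ≈ 0.20–0.23, the level
  observed in dairy cattle. `ld_strength = 0` produces independent sites.
  Markers are segregating sites with MAF ≥ 5% (chip-like ascertainment of
  common variants), thinned evenly to the requested count; the mutation
  rate is set from the expected segregating-site count so enough common
  sites exist at any configuration.
* **Pedigree**: discrete generations; founders alternate sex; every male
  of a generation sires `1 + Poisson(mean − 1)` progeny (so the realized
  mean matches `progeny_per_sire_mean`, default 2.5, the dairy-breed
  family size) with dams drawn at random. Birth year = generation index.
* **Gene drop**: each offspring receives one recombined gamete per parent;
  crossover counts are Poisson with mean equal to the genetic length
  (Haldane model, uniform 1 cM/Mb, no interference).
* **Artifacts** (all off by default): missing calls and genotyping errors
  are injected independently per call; mismapped markers are created by
  deranging the map positions of `n_mismapped` randomly chosen HD-only
  markers (each moved at least a quarter chromosome or to another
  chromosome), leaving their genotype values attached to the marker id —
  the corruption is therefore invisible to QC and detectable only through
  imputation error, as a genome-assembly error would be. A mismapping
  plan can be shared across breed datasets, as a real assembly error is.

### Scaling choice

The default dataset is 5 chromosomes of 7 Mb with 2000 HD markers each.
This keeps both marker densities at their real values — HD markers every
3.5 kb, shared (anchor) markers every 70 kb, which is the mean distance
between informative medium-density markers — while shrinking total genome
size to desk scale. Preserving the anchor-spacing-to-LD geometry preserves
the difficulty of the imputation problem; shrinking by chromosome count
instead (e.g. fewer 100 Mb chromosomes with sparser markers) makes anchors
~14× sparser in LD units and inflates even the best achievable error rate
far above what dense chips exhibit. The cost of this choice is less
within-chromosome recombination per meiosis (0.07 Morgan instead of ~1)
than a real autosome; consequences for generalization are noted under
Limitations.

## Quality control

The editing cascade reproduces routine array QC with strict inequalities
throughout and a fixed order: animal call rate (< 0.95 removed) → marker
filters (exact Hardy–Weinberg test p < 0.001, or > 10% missing) →
cross-chip concordance (> 1% discordant dual-genotyped animals) →
parentage (opposing homozygotes on the 500 most informative markers —
complete-call markers ranked by MAF; > 10 incompatibilities flags a pair;
a sire with ≥ 2 flagged progeny is removed instead of the progeny) →
Mendelian repair (per marker, a parent contradicted by > 20% of its
genotyped progeny loses its call, otherwise the conflicting progeny calls
are blanked). The HWE test is the full exact enumeration over heterozygote
counts, valid at low counts where the chi-square approximation is not.
The cascade emits a replayable report: applying it to the raw input
reproduces the edited dataset bit-exactly.

## Imputation engine

The engine is a Li–Stephens-style haplotype-copying HMM: hidden states are
reference haplotypes, the chain stays on its template between adjacent
markers with probability `exp(−recomb_rate_per_bp × d)` and otherwise
re-draws a template uniformly; emissions match the template allele with
probability `1 − copy_error` (defaults: 10⁻⁸/bp, matching the simulated
genetic map, and 10⁻³). Chromosomes are unlinked (the chain re-draws its
template across a chromosome boundary). No pedigree information is used
at any stage.

* **Reference phasing** is iterative conditional phasing: each animal is
  re-phased against the current haplotypes of the others, starting from a
  random het orientation with the configured seed. The conditional step
  is an exact diploid Viterbi (ordered template pairs; the pair transition
  factorizes, so the maximization needs only row/column/global maxima of
  the previous value matrix, O(K²) per marker) against a small surrogate
  panel: the animal's `n_surrogates` (default 20) most IBS-similar
  animals, which hold its parents, progeny and sibs. Animals are first
  phased progressively (each conditioned only on the already-phased
  subset, avoiding frustrated random-start optima), then refinement
  sweeps run until the panel stops changing materially. Missing calls are
  imputed from the Viterbi path during phasing. Per-site orientation
  *marginals* are useless here — the two chains are exchangeable, so the
  marginal is ½ by symmetry; the Viterbi path breaks that symmetry
  globally, which is why the conditional step is a path decoder.
* **Target imputation**: each validation animal is first phased at its
  observed markers by the same diploid Viterbi against the most similar
  reference animals; each of its two haploid chains then runs
  forward–backward over the full reference panel and the full HD marker
  frame (masked markers emit nothing). The two chain posteriors combine
  independently into genotype posteriors; the dosage is the expected
  alternate-allele count, the hard call the posterior argmax, and
  observed calls pass through unchanged.

Measured on the default study conditions, phasing reaches a switch-error
rate of ~0.5–2% per heterozygote and the full pipeline imputes masked
HD-only markers with ~0.1–0.3% allelic error with > 300 reference animals.

## Population metrics

* **LD**: r² from phased haplotype frequencies,
  r² = (p_AB − p_A p_B)² / (p_A (1−p_A) p_B (1−p_B)), computed pairwise
  within chromosomes, discarding pairs in which either marker has
  MAF < 5%; pair values are averaged in 10 kb distance bins and the
  70 kb summary is the mean of the bin containing 70 kb.
* **Relationships**: Wright's numerator relationship by the recursive
  tabular method (unknown parents contribute zero); R_T/V is its mean over
  all training × validation pairs.
* **Effective ancestors**: greedy probability-of-gene-origin selection.
  Each round propagates expected reference gene flow up the pedigree,
  blocked at already-selected ancestors, and multiplies each candidate's
  arriving flow by the fraction of its own genome not yet explained by
  selected ancestors (a descendant of a selected ancestor can only add
  its non-inherited share); N_a = 1 / Σ (marginal contribution)².

## Factor regression

Breed-level error rate (in percent, so coefficients keep their published
magnitudes) is regressed by OLS on reference population size, R_T/V, LD at
70 kb and the effective number of ancestors. Variance shares are
sequential (type-I) R² increments in that fixed order; the shares sum to
the model R², and permuting the factor order changes the shares but not
the coefficients (asserted in tests). A collinearity guard rejects designs
whose standardized condition number exceeds 10⁸, naming the most
correlated factor pair. The packaged 16-breed table (15 complete rows)
drives the worked example; any table with the same columns can be fitted.

## Numerical and design notes

* Genotypes are int8 dosage codes with −1 for missing; haplotypes are
  binary with two adjacent rows per animal. Coordinates are 1-based bp.
* Forward/backward vectors are rescaled every marker; the Viterbi value
  matrix is renormalized by its maximum. Posterior ties in hard calls
  resolve to the smaller genotype code; het-orientation ties in the
  Viterbi read-off resolve deterministically.
* The validation split uses `floor(fraction × N)`; published designs
  rounded slightly differently per breed, so the fraction is overridable.
* Every stage is deterministic given its config seed; two runs of the
  same configuration produce bit-identical datasets and reports.
* The per-SNP outlier rule (error > breed mean + 3 SD, strict, SD over all
  evaluated SNPs including zeros) is applied per breed; markers flagged in
  at least `min_breeds` breeds are reported with chromosome, marker name,
  breed count and mean error.

## What the simulations do and do not show

The generator reproduces the features that drive two-panel imputation in
livestock: IBD haplotype sharing with realistic LD decay, family
structure with genotyped sires and 2–3 progeny, an age-structured
reference/validation split, chip-density marker geometry, and
assembly-style mismapping. It does not model selection or migration, sex
chromosomes, genotype-intensity artifacts, chip-specific cluster failures,
per-locus mutation/genotyping-error heterogeneity, or recombination
hotspots; chromosomes are short (see Scaling), so long-range phasing over
multiple crossovers per meiosis is under-exercised. Passing tests
demonstrate the pipeline's correctness and the qualitative factor
structure (size and relatedness dominate; LD and ancestor diversity are
secondary), not calibrated error predictions for any real breed.
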