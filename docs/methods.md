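# Methods

## Consensus genotyping from replicate amplifications

Fecal DNA yields little template, so single amplifications of a
heterozygote frequently show only one allele (allelic dropout) and
occasionally a spurious peak.  The multi-tube rule set treats a
genotype as accepted only when independent replicates agree:

* **Heterozygote**: the identical unordered allele pair observed in at
  least `het_min_amplifications` (default 4) amplifications in total,
  distributed over at least `het_min_samples` (default 2) distinct
  samples of the same individual.  The reading "≥ 4 in total across
  ≥ 2 samples" is the most literal one; a stricter per-sample variant
  is one configuration flag away.
* **Homozygote**: the single allele observed, with no contradicting
  amplification, at least `hom_min_amplifications` (default 6) times.
  Any credible second allele diverts the call to the heterozygote path.
* **Third allele**: when more than two distinct alleles appear, both
  thresholds are multiplied by `third_allele_multiplier` (default 2:
  4→8, 6→12).  Once the doubled threshold is met, an extra allele seen
  in fewer than two amplifications is treated as spurious and ignored;
  one seen twice or more blocks acceptance.

Insufficient evidence yields `UNRESOLVED` (missing), never an error.
Allele identity is exact integer base-pair equality — fragment sizes
are integers after peak calling, so no binning tolerance is applied.
The implementation is verified exhaustively against an independent
rule-table evaluator on every amplification multiset of size ≤ 8 over
≤ 3 alleles and ≤ 3 samples.  The enumeration runs over unordered
collections of per-sample multisets; sample exchangeability (renaming
samples never changes a call) is checked separately, so this covers the
full input space.

Inter-laboratory concordance is allele-level: each (individual, locus)
called in both panels contributes two alleles, and the rate is
mismatching alleles over alleles compared.

## Diversity statistics

Frequencies are gene-counting estimates over typed individuals.
Expected heterozygosity defaults to the small-sample-corrected
Hₑ = [2n/(2n−1)](1 − Σpᵢ²); the uncorrected variant is a flag.  PIC is
Botstein's 1 − Σpᵢ² − Σ_{i<j} 2pᵢ²pⱼ².  Report tables round to three
decimals half-up (full precision is kept internally) and summary rows
use the population SD (ddof = 0), which is the convention the standard
genotyping software uses for such tables.

**Hardy–Weinberg**: an exact conditional test.  The statistic is the
Levene probability of the genotype table given its allele counts; the
p-value sums the probability of all tables no more probable than the
observed one.  The state space is fully enumerated for two-allele loci
and for tiny multi-allele tables; otherwise the p-value is Monte-Carlo
(vectorised permutation of the flattened allele vector, add-one
smoothing).  Under the null the p-values are calibrated: over 500
simulated panels (n = 500, five alleles) the rejection rate at
α = 0.05 sits inside the 99% binomial band and the p-value ECDF inside
the 99% Kolmogorov–Smirnov band.  Across loci, Bonferroni correction is
the intended multiple-testing adjustment.

**Null alleles**: three estimators are reported side by side.
Chakraborty (Hₑ−Hₒ)/(Hₑ+Hₒ) and Brookfield (Hₑ−Hₒ)/(1+Hₑ) are closed
forms; the default iterative estimator is an EM treating the null as a
hidden extra allele — each apparent homozygote is a mixture of a true
homozygote and a visible/null heterozygote, amplification blanks count
as null homozygotes — iterated to the conditional maximum-likelihood
frequency.  On simulated data with a true null at frequency 0.10
(n = 5000) the EM recovers it within ±0.03.  When Hₒ exceeds Hₑ the
signed Chakraborty value is returned so heterozygote excess keeps its
negative sign.

**F_IS**: the ratio estimator 1 − Hₒ/Hₑ per locus, and Weir &
Cockerham's f from the single-population reduction of the 1984
variance components, f = 1 − Σc/(Σ(b+c)) with per-allele
b = n/(n−1)[p(1−p) − (2n−1)/(4n)·h] and c = h/2.  The two agree within
0.01 on Hardy–Weinberg simulations at n = 5000.

**Marker QC**: hard filters (amplification success ≥ 0.5, ≥ 3 alleles,
reliable scoring) plus a tetranucleotide-over-dinucleotide preference
when a panel cap forces a choice — tetra repeats produce less stutter
and are scored more reliably.

## Parentage

A putative mother–offspring pair mismatches at a locus when the two
share no allele.  A candidate sire mismatches a trio at a locus when no
maternal transmission leaves a paternal allele he carries; when mother
and offspring share both alleles, either allele may serve as the
paternal contribution.  Loci missing anywhere in the trio are skipped,
and a case needs at least `min_typed_loci` (default 10) jointly typed
loci.

Exclusion categories over the per-candidate mismatch counts: STRICT
(unique zero-mismatch male, all others ≥ 2), RELAXED (unique
zero-mismatch male, some other at exactly 1), BEST_MATCH (unique
one-mismatch male, all others ≥ 2), TIE (two or more zero-mismatch
males), else UNRESOLVED.

The LOD score per locus is ln[((1−ε)T + εP)/P], with T the Mendelian
trio transition probability, P the offspring probability given the
mother and a random male drawn from the allele frequencies, and ε the
genotyping error rate (default 0.01).  With ε = 0 an excluded locus
would send the LOD to −∞; a −10⁹ sentinel keeps the ranking total.  The
LOD gap Δ between the top two positive-LOD candidates (or the top LOD
itself when only one is positive) is compared with a critical value
calibrated by simulation: offspring are generated from random
Hardy–Weinberg parents, the true father is included among the
candidates with probability `prop_candidates_sampled` (default 0.96),
loci are typed with probability `prop_loci_typed` (0.99) and mistyped
with probability ε, and the critical Δ is the smallest gap at which the
top candidate is the true father in at least the stated fraction
(default 0.95; an 80% tier is reported but never assigns) of clearing
cases.  Default simulation size is 100 offspring against 56 candidates,
matching the field configuration.

Assignment requires the exclusion pick and the likelihood pick to be
the same male at 95% confidence; a TIE is resolved to the likelihood
pick when he is in the zero-mismatch set.  The combined rule is applied
uniformly to BEST_MATCH cases as well.  Assigned sires are flagged
*extragroup* when not resident in the offspring's birth group on the
conception date, and *natal breeding* when their known natal group is
the birth group and they are still resident there; an unknown natal
group leaves the flag undetermined rather than counting as non-natal.

On error-free synthetic studies at the target scale (12 loci, 56
candidates, 65 offspring) the pipeline assigns 100% of cases correctly,
all by strict or relaxed exclusion; under the field error structure the
assigned fraction is typically 94–97% across replicate studies.

## Reproductive skew

Residency intervals are half-open `[start, end)`, so adjacent tenures
never double-count a day; nᵢ is male-days over total male-days in the
calendar group-year, and males with at least one day are the potential
sires.  The B index is as given in the README; the closed form makes
E[B] = 0 exact under multinomial allocation with probabilities nᵢ, and
this property gates the implementation (the mean over 10⁵ null draws
must sit within 3 SE of zero for arbitrary configurations).

The p-value is one-tailed (high skew): P(B_null ≥ B_obs), by full
enumeration of the composition space when it is small (≤ 20 000
compositions) and by Monte-Carlo with add-one smoothing otherwise.  The
default CI is a percentile interval over multinomial resamples of the
observed paternity shares; a fully monopolized year resamples to itself
and is reported as a point interval.  Null-distribution quantiles are
available as an alternative because published CI constructions for this
index vary and are not always reproducible.

Group-years enter the skew table only when offspring sampling coverage
reaches `sampling_coverage_min` (default 0.45).  Offspring are
attributed to the group-year of their birth group and birth year
(conception-year attribution is a flag).  The alpha paternity share
counts paternities by the male who was alpha at each offspring's
conception; the alpha tenure share is the year's modal alpha's days
over the year.  David's scores come from dyadic win proportions
(DS = w + w₂ − l − l₂, unobserved dyads contributing nothing); the
alpha is the top score, and on complete matrices the scores sum to
zero.

The sex-ratio posthoc uses average-rank Spearman correlation with an
exact permutation p-value for n ≤ 8 (Monte-Carlo beyond).  On the seven
published group-years, potential sires / adult females against B gives
ρ = −0.857.

## Synthetic data generator

The generator emulates the target study system: 12 loci (10 tetra-, 2
dinucleotide), allele counts uniform on 4–9 with symmetric Dirichlet(1)
frequencies, three groups of philopatric females (20 adults each), 56
candidate males with residency histories, 65 offspring born 2007–2009,
96% of sires genotyped.  Alpha successions partition the study window
into tenure segments (exponential lengths, mean 365 days, clipped to
120–1400); each alpha's residency covers his tenure and other males get
random intervals.  An offspring's true sire is the alpha at conception
with probability `monopolization` (default 0.6, chosen so the expected
alpha paternity share lands near the observed ~65%), otherwise a
residency-share-weighted draw from the males resident at conception.
Gestation is fixed at 170 days for conception-date bookkeeping; the
conception date is carried explicitly, so the constant is plumbing
only.

The error model has four independent knobs: per-amplification dropout
(default 0.2 — a free parameter, as no quantitative dropout rate is
established for this system), false alleles (0.02, added only when a
single allele is showing, since a replicate record carries two
observation slots), consensus-level mistyping (0.01, replacement by a
random Hardy–Weinberg genotype) and per-locus typing failure (0.99
typed).

What the generator does **not** emulate: linkage between loci, allele
mutation, relatedness structure beyond the simulated pedigree (mothers
and candidate males are unrelated Hardy–Weinberg draws), group-size
dynamics, spatially explicit dispersal and partial-year female
residency.  Passing tests therefore demonstrate the correctness of the
statistical machinery under the stated generative model, not robustness
to cryptic relatedness or population structure in real data.

## Numerical choices

* Missing alleles are coded 0 (GenePop convention); genotypes are
  unordered pairs normalised to (low, high).
* GenePop export recodes alleles per locus as 1-based registry indices
  (3 digits per allele), so arbitrary fragment lengths fit the format.
* Report rounding is decimal half-up at 3 decimals; summary SDs use
  ddof = 0.
* Ties in exact tests are counted conservatively (simulated tables
  equal to the observed statistic, within 1e-9 relative tolerance,
  count toward the p-value).
* Monte-Carlo p-values use add-one smoothing, (1 + hits)/(N + 1).
* All randomness flows through `numpy.random.default_rng` seeds;
  repeated runs with the same seed are byte-identical.

## Known limitations

* The iterative null-allele estimator assumes blanks are null
  homozygotes; with amplification failure from other causes it
  overestimates the null frequency.
* The delta calibration simulates unrelated candidate males; relatives
  of the true sire in the candidate set would lower the effective
  confidence, as it does in the standard likelihood software.
* Single-parent (motherless) LOD scoring is out of scope; every case
  requires a genotyped mother.
* The skew analysis treats the calendar year as the accounting period;
  tenure-block skew across years is not implemented.
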