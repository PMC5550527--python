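# satskew

Noninvasive microsatellite genotyping, parentage analysis and male
reproductive skew for wild primate study populations.

The package implements the full analytical chain used in field studies
of the Tangkoko crested macaque (*Macaca nigra*) population — a
three-group system with ~176 genotyped individuals, 12 microsatellite
loci and 56 candidate sires — working from fecal-DNA replicate
amplifications all the way to annual reproductive-skew tables:

1. **Consensus genotyping** (`satskew.consensus`) — multi-tube
   acceptance rules for dropout-prone fecal DNA: a heterozygote needs
   the same allele pair in ≥ 4 amplifications over ≥ 2 independent
   samples, a homozygote ≥ 6 consistent amplifications, and both
   thresholds double when a third allele appears.  Inter-laboratory
   concordance rates are computed at the allele level.
2. **Marker QC and diversity** (`satskew.popgen`) — gene-counting
   allele frequencies, observed/expected heterozygosity (Hₒ, Hₑ with the
   2n/(2n−1) correction), Botstein's polymorphic information content
   PIC = 1 − Σpᵢ² − ΣΣ 2pᵢ²pⱼ², exact conditional Hardy–Weinberg tests,
   null-allele estimators (Chakraborty, Brookfield, EM iteration) and
   the inbreeding coefficient F_IS (1 − Hₒ/Hₑ and Weir & Cockerham's f).
3. **Parentage** (`satskew.parentage`) — mother–offspring Mendelian
   checks, trio-aware paternal exclusion (strict / relaxed / best-match
   / tie), LOD scores ln[((1−ε)T + εP)/P] against the random-male
   hypothesis, and a simulation-calibrated critical LOD gap (Δ);
   paternity is assigned only when exclusion and likelihood agree at
   95% confidence.
4. **Reproductive skew** (`satskew.skew`) — David's-score dominance
   ranking, residency shares from half-open male-residency intervals,
   and Nonacs' binomial skew index

       B = Σᵢ (pᵢ − nᵢ)² − (1 − Σᵢ nᵢ²)/K

   where pᵢ is male *i*'s share of the K paternities and nᵢ his share of
   male-days in the group-year.  E[B] = 0 under residency-proportional
   random paternity; significance and CIs come from the multinomial
   null (exact for small cases) and a multinomial bootstrap.
5. **Synthetic studies** (`satskew.synth`) — a ground-truth generator
   (pedigree, residency histories, alpha successions, Dirichlet allele
   frequencies, dropout/false-allele/mistyping error model) so that
   every stage is testable against known truth.

## Worked example

```python
from satskew import parentage, skew, synth
from satskew.config import LikelihoodParams

# a study at the real system's scale: 12 loci (4-9 alleles), 3 groups,
# 56 candidate sires, 65 mother-offspring pairs
study = synth.simulate_study(seed=1)

params = LikelihoodParams(error_rate=0.0, prop_candidates_sampled=1.0,
                          prop_loci_typed=1.0, n_simulated_offspring=200)
crit = parentage.calibrate_delta(study.allele_freqs, params, seed=2)
males = [i.id for i in study.demography.candidate_sires()]
cases, summary = parentage.assign_paternities(
    study.demography.offspring_cases, study.truth_panel, males,
    study.allele_freqs, crit, study.demography)
print(summary["n_assigned"], summary["n_strict"], summary["n_relaxed"])
# 65 62 3   -> all 65 paternities solved, 62 by strict exclusion

b = skew.b_index({"M1": 7}, {"M1": 0.5, "M2": 0.5})
p, lo, hi = skew.b_index_test({"M1": 7}, {"M1": 0.5, "M2": 0.5}, seed=0)
print(round(b, 3), p)
# 0.429 0.015625  -> a 7-offspring monopoly between two equally resident
#                    males; exact binomial-null p = 2/128
```

With error-free genotypes every case resolves to the true sire; with
the field error structure (1% mistyping, 99% of loci typed, 96% of
sires sampled) the assigned fraction stays around 94–97%.

The same stages are available from the shell:

```bash
mk simulate --seed 4 --out-dir demo/
mk consensus demo/amplifications.tsv -o demo/genotypes_called.tsv
mk diversity demo/genotypes.tsv demo/individuals.csv -o demo/diversity.csv
mk parentage demo/genotypes.tsv demo/individuals.csv demo/residency.csv \
             demo/offspring.csv -o demo/paternity.csv
mk skew demo/paternity.csv demo/individuals.csv demo/residency.csv \
        demo/offspring.csv demo/truth.json -o demo/skew.csv
```

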