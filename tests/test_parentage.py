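"""Mendelian checking, exclusion classification and LOD likelihood."""

import itertools
import math

import numpy as np
import pytest

from satskew import parentage, synth
from satskew.config import LikelihoodParams
from satskew.parentage import (
    ExclusionCategory,
    classify_exclusion,
    lod_score,
    mendelian_check,
    paternal_mismatches,
)

A, B, C, D, E = 100, 104, 108, 112, 116


def gmap(**kw):
    return {k: v for k, v in kw.items()}


class TestMendelian:
    def test_shared_allele_is_compatible(self):
        assert mendelian_check({"L": (A, B)}, {"L": (B, C)}) == []

    def test_no_shared_allele_is_mismatch(self):
        assert mendelian_check({"L": (A, A)}, {"L": (B, C)}) == ["L"]

    def test_missing_loci_skipped(self):
        mism = mendelian_check({"L1": (A, A), "L2": None}, {"L1": (A, B), "L2": (C, C)})
        assert mism == []

    def test_no_shared_typed_locus_is_error(self):
        with pytest.raises(ValueError):
            mendelian_check({"L": None}, {"L": (A, B)})

    def test_error_free_pairs_and_single_flip(self, small_study):
        panel = small_study.truth_panel
        loci = panel.loci
        for case in small_study.demography.offspring_cases:
            mom = {l: g.alleles if (g := panel.get(case.mother_id, l)) else None for l in loci}
            off = {l: g.alleles if (g := panel.get(case.offspring_id, l)) else None for l in loci}
            assert mendelian_check(mom, off) == []
        # flipping one maternal allele at one locus makes exactly one mismatch
        case = small_study.demography.offspring_cases[0]
        mom = {l: panel.get(case.mother_id, l).alleles for l in loci}
        off = {l: panel.get(case.offspring_id, l).alleles for l in loci}
        locus = loci[0]
        shared = set(mom[locus]) & set(off[locus])
        other = max(max(mom[locus]), max(off[locus])) + 4
        flipped = tuple(other if a in shared else a for a in mom[locus])
        if set(flipped) & set(off[locus]):
            flipped = (other, other)
        mom[locus] = flipped
        assert mendelian_check(mom, off) == [locus]


class TestPaternalMismatches:
    @pytest.mark.parametrize(
        "mother, offspring, candidate, expect",
        [
            ((A, B), (A, C), (C, D), 0),
            ((A, B), (A, C), (D, E), 1),
            ((A, B), (A, B), (B, B), 0),  # maternal ambiguity: either allele works
            ((A, A), (A, A), (B, C), 1),
            ((A, B), (C, C), (C, D), 1),  # maternal incompatibility counts
        ],
    )
    def test_trio_rules(self, mother, offspring, candidate, expect):
        n, mism = paternal_mismatches(
            {"L": offspring}, {"L": mother}, {"L": candidate}
        )
        assert n == 1
        assert len(mism) == expect

    def test_min_typed_loci_enforced(self):
        with pytest.raises(ValueError):
            paternal_mismatches(
                {"L": (A, B)}, {"L": (A, B)}, {"L": None}, min_typed_loci=1
            )


def oracle_classify(counts):
    """Literal re-statement of the exclusion rules."""
    zeros = sorted(m for m, c in counts.items() if c == 0)
    ones = sorted(m for m, c in counts.items() if c == 1)
    if len(zeros) >= 2:
        return ExclusionCategory.TIE, None
    if len(zeros) == 1:
        rest = [counts[m] for m in counts if m != zeros[0]]
        if all(c >= 2 for c in rest):
            return ExclusionCategory.STRICT, zeros[0]
        if any(c == 1 for c in rest):
            return ExclusionCategory.RELAXED, zeros[0]
        return ExclusionCategory.RELAXED, zeros[0]
    if len(ones) == 1 and all(c >= 2 for m, c in counts.items() if m != ones[0]):
        return ExclusionCategory.BEST_MATCH, ones[0]
    return ExclusionCategory.UNRESOLVED, None


class TestExclusion:
    @pytest.mark.parametrize(
        "counts, expect",
        [
            ({"M1": 0, "M2": 2, "M3": 3}, (ExclusionCategory.STRICT, "M1")),
            ({"M1": 0, "M2": 1, "M3": 4}, (ExclusionCategory.RELAXED, "M1")),
            ({"M1": 0, "M2": 0, "M3": 2}, (ExclusionCategory.TIE, None)),
            ({"M1": 1, "M2": 2, "M3": 2}, (ExclusionCategory.BEST_MATCH, "M1")),
            ({"M1": 1, "M2": 1}, (ExclusionCategory.UNRESOLVED, None)),
        ],
    )
    def test_rule_examples(self, counts, expect):
        assert classify_exclusion(counts) == expect

    def test_exhaustive_against_rule_table(self):
        """All mismatch vectors with <= 5 candidates, counts <= 3."""
        for n in range(1, 6):
            for vec in itertools.product(range(4), repeat=n):
                counts = {f"M{i}": c for i, c in enumerate(vec)}
                assert classify_exclusion(counts) == oracle_classify(counts)


def brute_force_locus_lod(offspring, mother, candidate, freqs):
    """Classic likelihood ratio via explicit transmission enumeration."""
    t = 0.0
    for ma in mother:
        for fa in candidate:
            if tuple(sorted((ma, fa))) == tuple(sorted(offspring)):
                t += 0.25
    p = 0.0
    alleles = list(freqs)
    for ma in mother:
        for fa in alleles:  # random male transmits by frequency
            if tuple(sorted((ma, fa))) == tuple(sorted(offspring)):
                p += 0.5 * freqs[fa]
    return t, p


class TestLod:
    def test_single_locus_example(self):
        freqs = {"L": {A: 0.5, B: 0.25, C: 0.25}}
        lod = lod_score({"L": (A, C)}, {"L": (A, B)}, {"L": (C, C)}, freqs, 0.0)
        assert lod == pytest.approx(math.log(4))

    def test_excluded_locus_uses_sentinel(self):
        freqs = {"L": {A: 0.5, B: 0.25, C: 0.25}}
        lod = lod_score({"L": (A, C)}, {"L": (A, B)}, {"L": (B, B)}, freqs, 0.0)
        assert lod == parentage.LOD_EXCLUDED

    def test_zero_informative_loci_raises(self):
        with pytest.raises(ValueError):
            lod_score({"L": None}, {"L": (A, B)}, {"L": (A, B)}, {"L": {A: 1.0}}, 0.0)

    def test_matches_brute_force_enumeration(self):
        """epsilon-free and epsilon=0.01 LODs agree with transmission
        enumeration over random 2-3 allele toys."""
        rng = np.random.default_rng(5)
        for _ in range(300):
            k = rng.integers(2, 4)
            alleles = [A + 4 * i for i in range(k)]
            p = rng.dirichlet(np.ones(k))
            freqs = {a: float(x) for a, x in zip(alleles, p)}

            def geno():
                return tuple(sorted(rng.choice(alleles, size=2, p=p)))

            mother, cand = geno(), geno()
            ma = mother[rng.integers(2)]
            fa = cand[rng.integers(2)]
            off = tuple(sorted((ma, fa)))
            t, pr = brute_force_locus_lod(off, mother, cand, freqs)
            for eps in (0.0, 0.01):
                expected = (
                    math.log(((1 - eps) * t + eps * pr) / pr)
                    if (1 - eps) * t + eps * pr > 0
                    else parentage.LOD_EXCLUDED
                )
                got = lod_score(
                    {"L": off}, {"L": mother}, {"L": cand}, {"L": freqs}, eps
                )
                assert got == pytest.approx(expected, abs=1e-9)

    def test_true_father_has_higher_expected_lod(self):
        """Averaged over simulated trios the sire outscores a random male."""
        rng = np.random.default_rng(6)
        alleles = [A + 4 * i for i in range(5)]
        p = np.array([0.3, 0.25, 0.2, 0.15, 0.1])
        freqs = {"L": {a: float(x) for a, x in zip(alleles, p)}}

        def geno():
            return tuple(sorted(rng.choice(alleles, size=2, p=p)))

        diffs = []
        for _ in range(2000):
            mother, father, rand = geno(), geno(), geno()
            off = tuple(sorted((mother[rng.integers(2)], father[rng.integers(2)])))
            lf = lod_score({"L": off}, {"L": mother}, {"L": father}, freqs, 0.01)
            lr = lod_score({"L": off}, {"L": mother}, {"L": rand}, freqs, 0.01)
            diffs.append(lf - lr)
        assert np.mean(diffs) > 0


class TestCalibration:
    def test_no_error_all_sampled_is_near_perfect(self, study):
        params = LikelihoodParams(
            error_rate=0.0,
            prop_candidates_sampled=1.0,
            prop_loci_typed=1.0,
            n_simulated_offspring=500,
        )
        crit = parentage.calibrate_delta(study.allele_freqs, params, seed=8)
        assert crit.critical_delta < 1.0
        assert crit.assignment_rate >= 0.99

    def test_unsampled_fathers_flag_criterion(self, study):
        params = LikelihoodParams(
            prop_candidates_sampled=0.0, n_simulated_offspring=50
        )
        crit = parentage.calibrate_delta(study.allele_freqs, params, seed=9)
        assert not crit.feasible or crit.assignment_rate == 0.0

    def test_dispersion_over_seeds_is_binomial(self, study):
        params = LikelihoodParams()  # field parameter set
        rates = [
            parentage.calibrate_delta(study.allele_freqs, params, seed=s).assignment_rate
            for s in range(6)
        ]
        assert all(math.isfinite(r) for r in rates)
        sd = np.std(rates)
        p = np.mean(rates)
        assert sd < 4 * math.sqrt(max(p * (1 - p), 0.01) / params.n_simulated_offspring)


class TestAssignment:
    def test_agreement_required(self, study):
        params = LikelihoodParams(
            error_rate=0.0, prop_candidates_sampled=1.0, prop_loci_typed=1.0
        )
        crit = parentage.calibrate_delta(study.allele_freqs, params, seed=10)
        cands = [i.id for i in study.demography.candidate_sires()]
        results, summary = parentage.assign_paternities(
            study.demography.offspring_cases,
            study.truth_panel,
            cands,
            study.allele_freqs,
            crit,
            study.demography,
        )
        for r in results:
            if r.assigned_sire is not None:
                assert r.assigned_sire == r.likelihood_pick
                assert r.confidence == 95
                truth = study.truth_pedigree[r.offspring_id][1]
                assert r.assigned_sire == truth
                assert r.extragroup is False

    @staticmethod
    def _tie_fixture():
        import datetime as dt

        from satskew.types import Genotype, GenotypePanel, OffspringCase

        # both males carry the required paternal allele B at the only
        # locus, but the homozygote transmits it with certainty and so
        # outscores the heterozygote
        freqs = {"L1": {A: 0.4, B: 0.3, C: 0.3}}
        panel = GenotypePanel(
            [
                Genotype("O", "L1", A, B),
                Genotype("Mo", "L1", A, C),
                Genotype("M1", "L1", B, B),
                Genotype("M2", "L1", B, C),
            ]
        )
        case = OffspringCase("O", "Mo", "G", dt.date(2008, 6, 1), dt.date(2008, 1, 1))
        return freqs, panel, case

    def test_tie_resolved_by_likelihood_pick(self):
        freqs, panel, case = self._tie_fixture()
        params = LikelihoodParams(min_typed_loci=1, error_rate=0.0)
        crit = parentage.DeltaCriterion(0.95, 0.0, params, 1.0, 0.0)
        results, _ = parentage.assign_paternities(
            [case], panel, ["M1", "M2"], freqs, crit
        )
        r = results[0]
        assert r.exclusion_category is ExclusionCategory.TIE
        assert r.exclusion_pick is None
        assert r.likelihood_pick == "M1"
        assert r.assigned_sire == "M1"

    def test_low_confidence_blocks_assignment(self):
        freqs, panel, case = self._tie_fixture()
        params = LikelihoodParams(min_typed_loci=1, error_rate=0.0)
        crit = parentage.DeltaCriterion(0.95, 5.0, params, 0.5, 4.0)
        results, _ = parentage.assign_paternities(
            [case], panel, ["M1", "M2"], freqs, crit
        )
        r = results[0]
        assert r.likelihood_pick == "M1"
        assert r.confidence != 95
        assert r.assigned_sire is None
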