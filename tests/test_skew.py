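"""David's score, residency shares and the Nonacs B machinery."""

import datetime as dt
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from satskew import skew, synth
from satskew.types import ResidencyRecord


class TestDavidScore:
    def test_two_males_one_sided(self):
        W = pd.DataFrame([[0, 8], [0, 0]], index=["A", "B"], columns=["A", "B"])
        ds = skew.david_score(W)
        assert ds.scores == {"A": 1.0, "B": -1.0}
        assert ds.alpha_id == "A"

    def test_three_male_transitive_hierarchy(self):
        W = pd.DataFrame(
            [[0, 3, 3], [0, 0, 3], [0, 0, 0]],
            index=list("ABC"), columns=list("ABC"),
        )
        ds = skew.david_score(W)
        assert [ds.scores[m] for m in "ABC"] == [3.0, 0.0, -3.0]
        assert sum(ds.scores.values()) == pytest.approx(0.0)

    def test_symmetric_dyads_are_flat(self):
        W = pd.DataFrame(
            [[0, 5, 5], [5, 0, 5], [5, 5, 0]],
            index=list("ABC"), columns=list("ABC"),
        )
        assert all(v == 0 for v in skew.david_score(W).scores.values())

    def test_transpose_antisymmetry(self):
        rng = np.random.default_rng(12)
        W = pd.DataFrame(
            rng.integers(0, 9, size=(5, 5)), index=list("ABCDE"), columns=list("ABCDE")
        )
        np.fill_diagonal(W.values, 0)
        ds = skew.david_score(W)
        ds_t = skew.david_score(W.T)
        for m in "ABCDE":
            assert ds.scores[m] == pytest.approx(-ds_t.scores[m])
        assert sum(ds.scores.values()) == pytest.approx(0.0)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            skew.david_score(pd.DataFrame())


class TestResidencyShares:
    def test_three_to_one_split(self):
        recs = [
            ResidencyRecord("A", "G", dt.date(2008, 1, 1), dt.date(2008, 10, 27)),
            ResidencyRecord("B", "G", dt.date(2008, 1, 1), dt.date(2008, 4, 10)),
        ]
        shares, days = skew.residency_shares(recs, "G", 2008)
        assert days == {"A": 300, "B": 100}
        assert shares == {"A": 0.75, "B": 0.25}

    def test_single_male_full_year(self):
        recs = [ResidencyRecord("A", "G", dt.date(2007, 6, 1), dt.date(2009, 6, 1))]
        shares, _ = skew.residency_shares(recs, "G", 2008)
        assert shares == {"A": 1.0}

    def test_matches_day_iteration_oracle(self, small_study):
        recs = small_study.demography.residencies
        group, year = "R1", 2008
        shares, days = skew.residency_shares(recs, group, year)
        # brute force: iterate every day of the year
        expected: dict[str, int] = {}
        day = dt.date(year, 1, 1)
        while day < dt.date(year + 1, 1, 1):
            for r in recs:
                if r.group == group and r.covers(day):
                    expected[r.male_id] = expected.get(r.male_id, 0) + 1
            day += dt.timedelta(days=1)
        assert days == expected

    def test_no_residency_is_an_error(self):
        with pytest.raises(ValueError):
            skew.residency_shares([], "G", 2008)


class TestBIndex:
    def test_single_male_is_zero(self):
        assert skew.b_index({"A": 5}, {"A": 1.0}) == pytest.approx(0.0)

    def test_even_split_closed_form(self):
        assert skew.b_index({"A": 1, "B": 1}, {"A": 0.5, "B": 0.5}) == pytest.approx(-0.25)

    def test_monopoly_closed_form(self):
        b = skew.b_index({"A": 7}, {"A": 0.5, "B": 0.5})
        assert b == pytest.approx(0.5 - 0.5 / 7)

    def test_relabeling_invariance(self):
        counts = {"A": 3, "B": 1, "C": 0}
        shares = {"A": 0.5, "B": 0.3, "C": 0.2}
        b1 = skew.b_index(counts, shares)
        ren = {"A": "x", "B": "y", "C": "z"}
        b2 = skew.b_index(
            {ren[m]: c for m, c in counts.items()},
            {ren[m]: s for m, s in shares.items()},
        )
        assert b1 == pytest.approx(b2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            skew.b_index({}, {"A": 1.0})
        with pytest.raises(ValueError):
            skew.b_index({"A": 1}, {"A": 0.6, "B": 0.6})

    def test_null_expectation_is_zero(self):
        """E[B] = 0 under multinomial allocation by residency share."""
        rng = np.random.default_rng(13)
        for _ in range(3):
            n = rng.dirichlet(np.ones(rng.integers(2, 8)))
            K = int(rng.integers(3, 25))
            draws = rng.multinomial(K, n, size=100_000).astype(float)
            b = skew._b_from_vector(draws, n)
            se = b.std() / np.sqrt(b.size)
            assert abs(b.mean()) < 3 * se


class TestBIndexTest:
    def test_exact_two_male_monopoly(self):
        p, _, _ = skew.b_index_test({"A": 7}, {"A": 0.5, "B": 0.5}, seed=1)
        assert p == pytest.approx(2 / 2**7)

    def test_exact_agrees_with_enumeration_oracle(self):
        """Exhaustive independent enumeration for N <= 3, K <= 8."""
        rng = np.random.default_rng(14)
        for _ in range(20):
            N = int(rng.integers(2, 4))
            K = int(rng.integers(1, 9))
            n = rng.dirichlet(np.ones(N))
            shares = {f"m{i}": float(x) for i, x in enumerate(n / n.sum())}
            counts_vec = rng.multinomial(K, n)
            counts = {f"m{i}": int(c) for i, c in enumerate(counts_vec)}
            b_obs = skew.b_index(counts, shares)
            # oracle: total multinomial probability of B >= observed
            expect = 0.0
            for comp in itertools.product(range(K + 1), repeat=N):
                if sum(comp) != K:
                    continue
                vec = {f"m{i}": c for i, c in enumerate(comp)}
                if skew.b_index(vec, shares) >= b_obs - 1e-12:
                    expect += stats.multinomial.pmf(comp, K, list(shares.values()))
            p, _, _ = skew.b_index_test(counts, shares, seed=2)
            assert p == pytest.approx(expect, abs=1e-9)

    def test_proportional_counts_are_unremarkable(self):
        shares = {"A": 0.5, "B": 0.25, "C": 0.25}
        counts = {"A": 8, "B": 4, "C": 4}
        p, lo, hi = skew.b_index_test(counts, shares, seed=3)
        assert p > 0.4
        assert lo < 0 < hi

    def test_degenerate_single_male(self):
        assert skew.b_index_test({"A": 3}, {"A": 1.0}) == (1.0, 0.0, 0.0)

    def test_monopoly_ci_is_point(self):
        _, lo, hi = skew.b_index_test({"A": 7}, {"A": 0.5, "B": 0.5}, seed=4)
        b = skew.b_index({"A": 7}, {"A": 0.5, "B": 0.5})
        assert lo == hi == pytest.approx(b)


class TestSpearman:
    def test_identity_is_one(self):
        rho, _ = skew.spearman_rho([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            x = rng.integers(0, 5, size=7).astype(float)
            y = rng.integers(0, 5, size=7).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, _ = skew.spearman_rho(x, y)
            assert rho == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            skew.spearman_rho([1, 1, 1], [1, 2, 3])


class TestSkewTable:
    @staticmethod
    def _run(study, paternities, coverage_min=0.45, births=None):
        return skew.skew_table(
            paternities,
            study.demography,
            births if births is not None else study.births,
            study.alpha_at,
            {g: study.config.n_females_per_group for g in study.config.groups},
            coverage_min=coverage_min,
            mc_replicates=2000,
            seed=5,
        )

    def test_truth_paternities_produce_records(self, study):
        pat = {o: sire for o, (_, sire) in study.truth_pedigree.items()}
        records = self._run(study, pat)
        assert records
        for r in records:
            assert sum(r.residency_shares.values()) == pytest.approx(1.0)
            assert sum(r.paternity_shares.values()) == pytest.approx(1.0)
            assert r.sires_observed <= r.potential_sires
            assert 0 <= r.alpha_paternity_share <= 100
            assert 0 < r.alpha_tenure_share <= 100

    def test_alpha_monopoly_pattern(self):
        """All paternities by a year-long alpha give 100%/100% shares."""
        from satskew.types import Demography, Individual, OffspringCase, Sex

        inds = {
            "ALF": Individual("ALF", Sex.MALE, group="G", candidate_sire=True),
            "M2": Individual("M2", Sex.MALE, group="G", candidate_sire=True),
            "F1": Individual("F1", Sex.FEMALE, group="G"),
        }
        recs = [
            ResidencyRecord("ALF", "G", dt.date(2007, 1, 1), dt.date(2009, 1, 1)),
            ResidencyRecord("M2", "G", dt.date(2008, 1, 1), dt.date(2009, 1, 1)),
        ]
        cases = [
            OffspringCase(
                f"O{i}", "F1", "G",
                dt.date(2008, 7, 1 + i), dt.date(2008, 1, 10 + i),
            )
            for i in range(7)
        ]
        demo = Demography(inds, recs, cases)
        records = skew.skew_table(
            {c.offspring_id: "ALF" for c in cases},
            demo,
            {("G", 2008): 7},
            lambda g, d: "ALF",
            {"G": 10},
            mc_replicates=2000,
            seed=6,
        )
        (r,) = records
        assert r.alpha_paternity_share == pytest.approx(100.0)
        assert r.alpha_tenure_share == pytest.approx(100.0)
        assert r.K == 7 and r.potential_sires == 2

    def test_coverage_filter_excludes_group_year(self, study):
        pat = {o: sire for o, (_, sire) in study.truth_pedigree.items()}
        births = {k: int(np.ceil(v / 0.44)) for k, v in study.births.items()}
        records = self._run(study, pat, coverage_min=0.45, births=births)
        assert records == []

    def test_monopolization_knob_raises_mean_b(self):
        """Pipeline property: mean B increases along m = 0, 0.5, 1."""
        means = []
        for m in (0.0, 0.5, 1.0):
            cfg = synth.SynthConfig(monopolization=m, n_offspring=60)
            study = synth.simulate_study(cfg, seed=17)
            pat = {o: sire for o, (_, sire) in study.truth_pedigree.items()}
            records = self._run(study, pat)
            means.append(np.mean([r.B for r in records]))
        assert means[0] < means[1] < means[2]
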