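"""Paternity analysis: Mendelian checks, exclusion, and LOD likelihood.

The assignment strategy is deliberately conservative: a sire is accepted
only when two independent routes agree —

* **exclusion**: trio-incompatibility counts per candidate.  STRICT: a
  unique zero-mismatch male with every other candidate excluded at >= 2
  loci; RELAXED: unique zero-mismatch male with some candidate excluded
  at exactly one locus; BEST_MATCH: a unique one-mismatch male with all
  others at >= 2; TIE: two or more males with zero mismatches (the
  likelihood ranking breaks the tie).
* **likelihood**: per-candidate LOD scores against the random-male
  hypothesis, with a genotyping-error term, and the LOD gap (delta) to
  the runner-up calibrated by simulation to a stated confidence level.

A case is assigned when the exclusion pick (or the tie set) and the top
likelihood candidate coincide at 95% confidence.  Demographic flags mark
extragroup paternity (sire not resident in the birth group at
conception) and natal breeding (sire still in his natal group).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .config import LikelihoodParams
from .types import Demography, GenotypePanel, OffspringCase

#: sentinel for an excluded locus under a zero error rate
LOD_EXCLUDED = -1e9


class ExclusionCategory(str, Enum):
    STRICT = "STRICT"
    RELAXED = "RELAXED"
    BEST_MATCH = "BEST_MATCH"
    TIE = "TIE"
    UNRESOLVED = "UNRESOLVED"


# ---------------------------------------------------------------------------
# Mendelian checking


def mendelian_check(
    mother: Mapping[str, tuple[int, int] | None],
    offspring: Mapping[str, tuple[int, int] | None],
) -> list[str]:
    """Loci at which a putative mother-offspring pair shares no allele.

    Loci missing on either side are skipped; raises if no locus is
    typed in both.
    """
    shared = 0
    mismatches = []
    for locus, mg in mother.items():
        og = offspring.get(locus)
        if mg is None or og is None:
            continue
        shared += 1
        if not set(mg) & set(og):
            mismatches.append(locus)
    if shared == 0:
        raise ValueError("no locus typed in both mother and offspring")
    return mismatches


def _trio_compatible(
    mother: tuple[int, int], offspring: tuple[int, int], candidate: tuple[int, int]
) -> bool:
    """True when the candidate can supply a paternal allele consistent
    with some maternal transmission."""
    cand = set(candidate)
    a, b = offspring
    for maternal in set(mother):
        # fixing the maternal transmission determines the paternal allele;
        # when mother and offspring share both alleles either works
        if maternal == a and b in cand:
            return True
        if maternal == b and a in cand:
            return True
    return False


def paternal_mismatches(
    offspring: Mapping[str, tuple[int, int] | None],
    mother: Mapping[str, tuple[int, int] | None],
    candidate: Mapping[str, tuple[int, int] | None],
    min_typed_loci: int = 1,
) -> tuple[int, list[str]]:
    """Trio-incompatible locus count for one candidate male.

    A locus mismatches when no maternal transmission leaves a paternal
    allele the candidate carries.  Loci with missing data anywhere in
    the trio are skipped.  Returns ``(n_compared, mismatching_loci)``;
    raises when fewer than *min_typed_loci* loci are jointly typed.
    """
    compared = 0
    mism = []
    for locus, og in offspring.items():
        mg = mother.get(locus)
        cg = candidate.get(locus)
        if og is None or mg is None or cg is None:
            continue
        compared += 1
        if not _trio_compatible(mg, og, cg):
            mism.append(locus)
    if compared < min_typed_loci:
        raise ValueError(
            f"only {compared} jointly typed loci (< {min_typed_loci})"
        )
    return compared, mism


def classify_exclusion(
    mismatch_counts: Mapping[str, int],
) -> tuple[ExclusionCategory, str | None]:
    """Apply the exclusion rule table to per-candidate mismatch counts."""
    if not mismatch_counts:
        raise ValueError("no candidates evaluated")
    zero = [m for m, c in mismatch_counts.items() if c == 0]
    one = [m for m, c in mismatch_counts.items() if c == 1]
    if len(zero) >= 2:
        return ExclusionCategory.TIE, None
    if len(zero) == 1:
        others = [c for m, c in mismatch_counts.items() if m != zero[0]]
        if all(c >= 2 for c in others):
            return ExclusionCategory.STRICT, zero[0]
        return ExclusionCategory.RELAXED, zero[0]
    if len(one) == 1:
        others = [c for m, c in mismatch_counts.items() if m != one[0]]
        if all(c >= 2 for c in others):
            return ExclusionCategory.BEST_MATCH, one[0]
    return ExclusionCategory.UNRESOLVED, None


# ---------------------------------------------------------------------------
# likelihood


def _transition_prob(
    offspring: tuple[int, int], mother: tuple[int, int], father: tuple[int, int]
) -> float:
    """Mendelian P(offspring | mother, father) with unordered genotypes."""
    t = 0.0
    for ma in mother:
        for fa in father:
            if tuple(sorted((ma, fa))) == tuple(sorted(offspring)):
                t += 0.25
    return t


def _offspring_given_mother(
    offspring: tuple[int, int], mother: tuple[int, int], freqs: Mapping[int, float]
) -> float:
    """P(offspring | mother, random male) under the allele frequencies."""
    p = 0.0
    for ma in mother:
        a, b = sorted(offspring)
        if ma == a:
            p += 0.5 * freqs.get(b, 0.0)
        if ma == b and a != b:
            p += 0.5 * freqs.get(a, 0.0)
        elif ma == b and a == b:
            pass  # already counted above
    return p


def lod_score(
    offspring: Mapping[str, tuple[int, int] | None],
    mother: Mapping[str, tuple[int, int] | None],
    candidate: Mapping[str, tuple[int, int] | None],
    allele_freqs: Mapping[str, Mapping[int, float]],
    error_rate: float = 0.01,
) -> float:
    """Log-odds that *candidate* is the sire versus a random male.

    Per locus ``ln[((1-e) T + e P) / P]`` with T the Mendelian trio
    transition probability and P the random-male offspring probability;
    summed over loci typed in the whole trio.  With ``error_rate`` 0 an
    excluded locus contributes the LOD_EXCLUDED sentinel so that the
    ranking stays total.
    """
    total = 0.0
    informative = 0
    for locus, og in offspring.items():
        mg = mother.get(locus)
        cg = candidate.get(locus)
        if og is None or mg is None or cg is None:
            continue
        freqs = allele_freqs[locus]
        t = _transition_prob(og, mg, cg)
        p = _offspring_given_mother(og, mg, freqs)
        if p <= 0:
            continue
        informative += 1
        num = (1.0 - error_rate) * t + error_rate * p
        if num <= 0:
            total += LOD_EXCLUDED
        else:
            total += math.log(num / p)
    if informative == 0:
        raise ValueError("zero informative loci for LOD")
    return total


# ---------------------------------------------------------------------------
# delta calibration (simulation)


@dataclass
class DeltaCriterion:
    confidence_level: float
    critical_delta: float
    params: LikelihoodParams
    assignment_rate: float
    relaxed_critical_delta: float | None = None

    @property
    def feasible(self) -> bool:
        return math.isfinite(self.critical_delta)


def _sim_genotype(rng, alleles: np.ndarray, cum: np.ndarray) -> tuple[int, int]:
    i = int(np.searchsorted(cum, rng.random()))
    j = int(np.searchsorted(cum, rng.random()))
    a, b = int(alleles[i]), int(alleles[j])
    return (a, b) if a <= b else (b, a)


def calibrate_delta(
    allele_freqs: Mapping[str, Mapping[int, float]],
    params: LikelihoodParams,
    seed: int = 0,
) -> DeltaCriterion:
    """Simulation calibration of the critical LOD gap.

    Offspring are simulated from random Hardy-Weinberg parents; the true
    father is among the candidates with probability
    ``prop_candidates_sampled``.  Typing failure and mistyping are
    applied per locus, LODs computed for every candidate, and the
    critical delta is the smallest gap such that, among simulated cases
    whose top candidate clears it, at least ``confidence_level`` are the
    true father.
    """
    rng = np.random.default_rng(seed)
    loci = list(allele_freqs)
    tables = {}
    for locus in loci:
        alleles = np.array(sorted(allele_freqs[locus]))
        p = np.array([allele_freqs[locus][a] for a in alleles], dtype=float)
        tables[locus] = (alleles, np.cumsum(p / p.sum()))

    def noisy(g: tuple[int, int], locus: str) -> tuple[int, int] | None:
        if rng.random() >= params.prop_loci_typed:
            return None
        if rng.random() < params.error_rate:
            return _sim_genotype(rng, *tables[locus])
        return g

    deltas: list[tuple[float, bool]] = []
    for _ in range(params.n_simulated_offspring):
        mother = {loc: _sim_genotype(rng, *tables[loc]) for loc in loci}
        father = {loc: _sim_genotype(rng, *tables[loc]) for loc in loci}
        child = {}
        for loc in loci:
            ma = mother[loc][int(rng.integers(2))]
            fa = father[loc][int(rng.integers(2))]
            child[loc] = (ma, fa) if ma <= fa else (fa, ma)

        father_sampled = rng.random() < params.prop_candidates_sampled
        candidates: list[tuple[bool, dict]] = []
        n_random = params.n_candidates - (1 if father_sampled else 0)
        if father_sampled:
            candidates.append(
                (True, {loc: noisy(father[loc], loc) for loc in loci})
            )
        for _ in range(n_random):
            male = {loc: _sim_genotype(rng, *tables[loc]) for loc in loci}
            candidates.append((False, {loc: noisy(male[loc], loc) for loc in loci}))

        obs_child = {loc: noisy(child[loc], loc) for loc in loci}
        obs_mother = {loc: noisy(mother[loc], loc) for loc in loci}
        typed = sum(1 for loc in loci if obs_child[loc] is not None)
        if typed < params.min_typed_loci:
            continue
        scored = []
        for is_true, male in candidates:
            try:
                lod = lod_score(
                    obs_child, obs_mother, male, allele_freqs, params.error_rate
                )
            except ValueError:
                continue
            scored.append((lod, is_true))
        if not scored:
            continue
        scored.sort(key=lambda x: -x[0])
        top_lod, top_true = scored[0]
        positive = [s for s in scored if s[0] > 0]
        if not positive:
            continue
        if len(positive) == 1:
            delta = positive[0][0]
        else:
            delta = positive[0][0] - positive[1][0]
        deltas.append((delta, top_true and top_lod > 0))

    if not deltas:
        return DeltaCriterion(
            params.confidence_level, math.inf, params, 0.0, math.inf
        )

    def critical(conf: float) -> tuple[float, float]:
        # walk thresholds downward over observed deltas; pick the
        # smallest with success rate >= conf among clearing cases
        order = sorted(deltas, key=lambda x: -x[0])
        best = math.inf
        hits = 0
        for i, (delta, ok) in enumerate(order, start=1):
            hits += ok
            if hits / i >= conf:
                best = delta
        if not math.isfinite(best):
            return math.inf, 0.0
        n_assigned = sum(1 for d, _ in deltas if d >= best)
        return best, n_assigned / params.n_simulated_offspring

    crit95, rate = critical(params.confidence_level)
    crit80, _ = critical(params.relaxed_confidence_level)
    return DeltaCriterion(
        confidence_level=params.confidence_level,
        critical_delta=crit95,
        params=params,
        assignment_rate=rate,
        relaxed_critical_delta=crit80,
    )


# ---------------------------------------------------------------------------
# case assembly


@dataclass
class PaternityCase:
    offspring_id: str
    mother_id: str
    n_candidates: int
    exclusion_category: ExclusionCategory
    exclusion_pick: str | None
    likelihood_pick: str | None
    lod_top: float | None
    delta: float | None
    confidence: int | None          # 95, 80 or None
    assigned_sire: str | None
    extragroup: bool | None = None
    natal_breeding: bool | None = None
    mismatches: dict[str, int] = field(default_factory=dict)


def _genotype_map(panel: GenotypePanel, ind: str) -> dict[str, tuple[int, int] | None]:
    return {loc: (g.alleles if (g := panel.get(ind, loc)) else None) for loc in panel.loci}


def assign_paternities(
    cases: Sequence[OffspringCase],
    panel: GenotypePanel,
    candidate_ids: Sequence[str],
    allele_freqs: Mapping[str, Mapping[int, float]],
    criterion: DeltaCriterion,
    demography: Demography | None = None,
) -> tuple[list[PaternityCase], dict[str, float]]:
    """Run combined exclusion + likelihood paternity over all cases.

    Candidates untyped in the panel are skipped per case; a case with
    fewer than ``min_typed_loci`` jointly typed trio loci, or with no
    genotyped mother or offspring, stays UNRESOLVED.
    """
    params = criterion.params
    results: list[PaternityCase] = []
    for case in cases:
        off = _genotype_map(panel, case.offspring_id)
        mom = _genotype_map(panel, case.mother_id)
        per_cand_mism: dict[str, int] = {}
        per_cand_lod: dict[str, float] = {}
        for male in candidate_ids:
            if male == case.offspring_id:
                continue
            cand = _genotype_map(panel, male)
            if all(v is None for v in cand.values()):
                continue
            try:
                _, mism = paternal_mismatches(off, mom, cand, params.min_typed_loci)
                lod = lod_score(off, mom, cand, allele_freqs, params.error_rate)
            except ValueError:
                continue
            per_cand_mism[male] = len(mism)
            per_cand_lod[male] = lod

        if not per_cand_mism:
            results.append(
                PaternityCase(
                    case.offspring_id, case.mother_id, 0,
                    ExclusionCategory.UNRESOLVED, None, None, None, None,
                    None, None,
                )
            )
            continue

        category, pick = classify_exclusion(per_cand_mism)

        ranked = sorted(per_cand_lod.items(), key=lambda x: -x[1])
        top_male, top_lod = ranked[0]
        positive = [(m, l) for m, l in ranked if l > 0]
        if not positive:
            lik_pick, delta = None, None
        elif len(positive) == 1:
            lik_pick, delta = positive[0][0], positive[0][1]
        else:
            lik_pick = positive[0][0]
            delta = positive[0][1] - positive[1][1]

        confidence: int | None = None
        if delta is not None and criterion.feasible:
            if delta >= criterion.critical_delta:
                confidence = 95
            elif (
                criterion.relaxed_critical_delta is not None
                and math.isfinite(criterion.relaxed_critical_delta)
                and delta >= criterion.relaxed_critical_delta
            ):
                confidence = 80

        assigned = None
        if lik_pick is not None and confidence == 95:
            if category is ExclusionCategory.TIE:
                # both exclusion-compatible; accept the likelihood pick
                zero = [m for m, c in per_cand_mism.items() if c == 0]
                if lik_pick in zero:
                    assigned = lik_pick
            elif pick is not None and pick == lik_pick:
                assigned = pick

        extragroup = natal = None
        if assigned is not None and demography is not None:
            extragroup = not demography.resident_in(
                assigned, case.birth_group, case.conception_date
            )
            sire = demography.individuals.get(assigned)
            if sire is None or sire.natal_group is None:
                natal = None
            else:
                natal = sire.natal_group == case.birth_group and demography.resident_in(
                    assigned, case.birth_group, case.conception_date
                )
        results.append(
            PaternityCase(
                case.offspring_id, case.mother_id, len(per_cand_mism),
                category, pick, lik_pick, top_lod,
                delta, confidence, assigned, extragroup, natal, per_cand_mism,
            )
        )

    n = len(results)
    solved = sum(1 for r in results if r.assigned_sire is not None)
    summary = {
        "n_cases": n,
        "n_assigned": solved,
        "prop_assigned": solved / n if n else 0.0,
    }
    for cat in ExclusionCategory:
        summary[f"n_{cat.value.lower()}"] = sum(
            1 for r in results if r.exclusion_category is cat
        )
    return results, summary
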