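"""Synthetic study generator.

Builds a ground-truth population — pedigree, demography, residency
histories, per-locus allele frequencies — shaped like a three-group wild
macaque study, then emits the noisy observable tables (per-amplification
replicates, consensus-level genotypes with mistyping) that the rest of
the pipeline consumes.  Every downstream stage is therefore testable
against known truth without any field data.

Scale defaults mirror the study system this package targets: 12
microsatellite loci with 4-9 alleles each, three social groups, 56
candidate sires of which 96% are genotyped, 65 mother-offspring pairs
born 2007-2009, 99% of loci typed and a 1% mistyping rate.

The male side is driven by two knobs:

``monopolization`` (m)
    Probability that an offspring's true sire is the alpha male of its
    birth group at conception; with probability 1-m the sire is drawn
    from the males resident at conception, weighted by their residency
    share of the birth year.  m=1 gives complete monopolization, m=0
    residency-proportional random mating.
``mean_alpha_tenure_days``
    Mean length of an alpha tenure segment; short tenures emulate high
    takeover rates.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    Demography,
    Genotype,
    GenotypePanel,
    Individual,
    Locus,
    OffspringCase,
    RepeatClass,
    ResidencyRecord,
    Sex,
)

_STUDY_START = _dt.date(2006, 1, 1)
_STUDY_END = _dt.date(2010, 7, 1)


@dataclass
class ErrorModel:
    """Observation-error model for noninvasive (fecal) genotyping.

    dropout_rate
        Probability that a true heterozygote shows only one of its two
        alleles in a single amplification.
    false_allele_rate
        Probability that an amplification showing a single allele gains
        a spurious allele drawn from the locus registry.
    mistype_rate
        Probability that a consensus-level genotype is replaced by a
        random Hardy-Weinberg draw (scoring/transcription error).
    typed_rate
        Probability that an individual is typed at all at a locus.
    """

    dropout_rate: float = 0.2
    false_allele_rate: float = 0.02
    mistype_rate: float = 0.01
    typed_rate: float = 0.99

    def __post_init__(self) -> None:
        for name in ("dropout_rate", "false_allele_rate", "mistype_rate", "typed_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class SynthConfig:
    n_loci: int = 12
    n_tetra: int = 10
    allele_count_range: tuple[int, int] = (4, 9)
    groups: tuple[str, ...] = ("R1", "R2", "PB")
    n_females_per_group: int = 20
    n_candidate_males: int = 56
    prop_sires_sampled: float = 0.96
    birth_years: tuple[int, ...] = (2007, 2008, 2009)
    n_offspring: int = 65
    monopolization: float = 0.6
    mean_alpha_tenure_days: int = 365
    sampled_fraction: float = 1.0
    gestation_days: int = 170

    def __post_init__(self) -> None:
        lo, hi = self.allele_count_range
        if not (2 <= lo <= hi):
            raise ValueError("allele_count_range must satisfy 2 <= lo <= hi")
        if not 0.0 <= self.monopolization <= 1.0:
            raise ValueError("monopolization must lie in [0, 1]")
        if self.n_candidate_males < len(self.groups):
            raise ValueError("need at least one candidate male per group")
        if self.n_offspring < 1:
            raise ValueError("n_offspring must be positive")


@dataclass
class SyntheticStudy:
    """Ground truth plus emitted demography for one simulated study."""

    config: SynthConfig
    seed: int
    loci: dict[str, Locus]
    allele_freqs: dict[str, dict[int, float]]
    truth_panel: GenotypePanel          # everyone, error-free
    sampled_ids: set[str]               # individuals with DNA samples
    demography: Demography
    truth_pedigree: dict[str, tuple[str, str]]  # offspring -> (mother, sire)
    alpha_segments: list[tuple[str, _dt.date, _dt.date, str]]
    births: dict[tuple[str, int], int] = field(default_factory=dict)

    def alpha_at(self, group: str, day: _dt.date) -> str | None:
        for g, start, end, male in self.alpha_segments:
            if g == group and start <= day < end:
                return male
        return None

    def alpha_roster(self) -> dict[tuple[str, _dt.date], str]:
        """Per (group, day-resolution) alpha series, as segment endpoints."""
        return {(g, s): m for g, s, e, m in self.alpha_segments}

    def sampled_panel(self) -> GenotypePanel:
        return self.truth_panel.subset_individuals(self.sampled_ids)

    def observed_panel(
        self, error_model: ErrorModel, seed: int | None = None
    ) -> GenotypePanel:
        """Consensus-level observed genotypes for sampled individuals.

        Applies per-locus typing failure (``typed_rate``) and mistyping
        (``mistype_rate``: the genotype is replaced by a random
        Hardy-Weinberg draw), the error structure that the likelihood
        calibration assumes.  Amplification-level noise is the job of
        :func:`simulate_amplifications`.
        """
        rng = np.random.default_rng(self.seed + 104729 if seed is None else seed)
        panel = GenotypePanel()
        for g in self.truth_panel:
            if g.individual_id not in self.sampled_ids:
                continue
            if rng.random() >= error_model.typed_rate:
                continue
            a, b = g.alleles
            if rng.random() < error_model.mistype_rate:
                a, b = _hwe_draw(rng, self.allele_freqs[g.locus])
            panel.add(Genotype(g.individual_id, g.locus, a, b))
        return panel


def _hwe_draw(rng: np.random.Generator, freqs: dict[int, float]) -> tuple[int, int]:
    alleles = np.fromiter(freqs.keys(), dtype=int)
    p = np.fromiter(freqs.values(), dtype=float)
    a, b = rng.choice(alleles, size=2, p=p / p.sum())
    return int(a), int(b)


def _mendelian_child(
    rng: np.random.Generator, mother: tuple[int, int], father: tuple[int, int]
) -> tuple[int, int]:
    return (
        int(mother[rng.integers(2)]),
        int(father[rng.integers(2)]),
    )


def draw_sires(
    rng: np.random.Generator,
    n: int,
    monopolization: float,
    alpha_id: str,
    males: list[str],
    weights: list[float],
) -> list[str]:
    """Draw *n* true sires: alpha with probability m, otherwise a
    residency-share-weighted draw from *males*."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    out = []
    for _ in range(n):
        if rng.random() < monopolization:
            out.append(alpha_id)
        else:
            out.append(males[int(rng.choice(len(males), p=w))])
    return out


def _simulate_loci(
    rng: np.random.Generator, cfg: SynthConfig
) -> tuple[dict[str, Locus], dict[str, dict[int, float]]]:
    loci: dict[str, Locus] = {}
    freqs: dict[str, dict[int, float]] = {}
    lo, hi = cfg.allele_count_range
    for i in range(cfg.n_loci):
        name = f"L{i + 1:02d}"
        tetra = i < cfg.n_tetra
        step = 4 if tetra else 2
        k = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(100, 260))
        alleles = [start + j * step for j in range(k)]
        # symmetric Dirichlet(1) over k alleles
        p = rng.dirichlet(np.ones(k))
        loci[name] = Locus(
            name,
            RepeatClass.TETRA if tetra else RepeatClass.DI,
            frozenset(alleles),
        )
        freqs[name] = {a: float(pi) for a, pi in zip(alleles, p)}
    return loci, freqs


def _alpha_succession(
    rng: np.random.Generator,
    group: str,
    males: list[str],
    mean_tenure: int,
) -> list[tuple[str, _dt.date, _dt.date, str]]:
    """Partition the study window into alpha-tenure segments."""
    segments = []
    day = _STUDY_START
    order = list(rng.permutation(males))
    i = 0
    while day < _STUDY_END:
        length = int(np.clip(rng.exponential(mean_tenure), 120, 1400))
        end = min(day + _dt.timedelta(days=length), _STUDY_END)
        segments.append((group, day, end, order[i % len(order)]))
        day = end
        i += 1
    return segments


def simulate_study(config: SynthConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate one reproducible synthetic study from *seed*."""
    cfg = config or SynthConfig()
    rng = np.random.default_rng(seed)
    loci, freqs = _simulate_loci(rng, cfg)

    individuals: dict[str, Individual] = {}
    residencies: list[ResidencyRecord] = []
    genotypes: dict[str, dict[str, tuple[int, int]]] = {}

    def genotype_hwe(ind_id: str) -> None:
        genotypes[ind_id] = {
            loc: tuple(sorted(_hwe_draw(rng, freqs[loc]))) for loc in loci
        }

    # adult females, philopatric
    females_by_group: dict[str, list[str]] = {g: [] for g in cfg.groups}
    for g in cfg.groups:
        for j in range(cfg.n_females_per_group):
            fid = f"F_{g}_{j + 1:02d}"
            individuals[fid] = Individual(
                fid, Sex.FEMALE, group=g, natal_group=g,
                birth_date=_dt.date(1995 + j % 10, 1 + j % 12, 1),
            )
            females_by_group[g].append(fid)
            genotype_hwe(fid)

    # candidate males with residency histories
    males_by_group: dict[str, list[str]] = {g: [] for g in cfg.groups}
    all_males: list[str] = []
    for j in range(cfg.n_candidate_males):
        g = cfg.groups[j % len(cfg.groups)]
        mid = f"M{j + 1:02d}"
        natal = cfg.groups[int(rng.integers(len(cfg.groups)))]
        individuals[mid] = Individual(
            mid, Sex.MALE, group=g, natal_group=natal,
            birth_date=_dt.date(1994 + j % 8, 1 + j % 12, 1),
            candidate_sire=True,
        )
        males_by_group[g].append(mid)
        all_males.append(mid)
        genotype_hwe(mid)

    # alpha successions first: the alpha's residency covers his tenure
    alpha_segments: list[tuple[str, _dt.date, _dt.date, str]] = []
    covered: dict[str, list[tuple[_dt.date, _dt.date]]] = {m: [] for m in all_males}
    for g in cfg.groups:
        segs = _alpha_succession(rng, g, males_by_group[g], cfg.mean_alpha_tenure_days)
        alpha_segments.extend(segs)
        for _, start, end, male in segs:
            covered[male].append((start, end))

    total_days = (_STUDY_END - _STUDY_START).days
    for g in cfg.groups:
        for m in males_by_group[g]:
            if covered[m]:
                start = min(s for s, _ in covered[m])
                end = max(e for _, e in covered[m])
                # lead-in before first tenure, linger after the last
                start = max(_STUDY_START, start - _dt.timedelta(days=int(rng.integers(0, 400))))
                end = min(_STUDY_END, end + _dt.timedelta(days=int(rng.integers(0, 400))))
            else:
                a = int(rng.integers(0, total_days - 180))
                b = int(rng.integers(a + 180, min(a + 1500, total_days) + 1))
                start = _STUDY_START + _dt.timedelta(days=a)
                end = _STUDY_START + _dt.timedelta(days=b)
            residencies.append(ResidencyRecord(m, g, start, end))

    resident_lookup = {(r.male_id, r.group): r for r in residencies}

    def residents_at(group: str, day: _dt.date) -> list[str]:
        return [
            m for m in males_by_group[group]
            if resident_lookup[(m, group)].covers(day)
        ]

    # offspring: one per mother-offspring pair, allocated over group-years
    offspring_cases: list[OffspringCase] = []
    truth_pedigree: dict[str, tuple[str, str]] = {}
    births: dict[tuple[str, int], int] = {}
    group_years = [(g, y) for g in cfg.groups for y in cfg.birth_years]
    alloc = rng.multinomial(cfg.n_offspring, np.ones(len(group_years)) / len(group_years))
    counter = 0
    for (g, year), n_born in zip(group_years, alloc):
        births[(g, year)] = int(n_born)
        year_days = (_dt.date(year + 1, 1, 1) - _dt.date(year, 1, 1)).days
        year_shares = {
            m: resident_lookup[(m, g)].days_in_year(year) for m in males_by_group[g]
        }
        for _ in range(int(n_born)):
            counter += 1
            oid = f"O{counter:03d}"
            # keep conception inside the study window
            offset = int(rng.integers(cfg.gestation_days, year_days))
            birth = _dt.date(year, 1, 1) + _dt.timedelta(days=offset)
            conception = birth - _dt.timedelta(days=cfg.gestation_days)
            mother = females_by_group[g][int(rng.integers(len(females_by_group[g])))]
            alpha = _alpha_for(alpha_segments, g, conception)
            pool = residents_at(g, conception)
            weights = [max(year_shares[m], 1) for m in pool]
            sire = draw_sires(rng, 1, cfg.monopolization, alpha, pool, weights)[0]
            individuals[oid] = Individual(
                oid,
                Sex.FEMALE if rng.random() < 0.5 else Sex.MALE,
                group=g, natal_group=g, birth_date=birth, mother_id=mother,
            )
            genotypes[oid] = {
                loc: tuple(
                    sorted(
                        _mendelian_child(rng, genotypes[mother][loc], genotypes[sire][loc])
                    )
                )
                for loc in loci
            }
            truth_pedigree[oid] = (mother, sire)
            offspring_cases.append(
                OffspringCase(oid, mother, g, birth, conception)
            )

    # sampling: a fixed fraction of candidate sires has DNA; offspring
    # coverage per the sampled_fraction knob
    sampled = set(individuals)
    n_unsampled = round((1 - cfg.prop_sires_sampled) * cfg.n_candidate_males)
    if n_unsampled:
        drop = rng.choice(all_males, size=n_unsampled, replace=False)
        sampled -= set(str(m) for m in drop)
    if cfg.sampled_fraction < 1.0:
        kept = []
        for case in offspring_cases:
            if rng.random() < cfg.sampled_fraction:
                kept.append(case)
            else:
                sampled.discard(case.offspring_id)
        offspring_cases = kept

    panel = GenotypePanel(
        Genotype(ind, loc, a, b)
        for ind, locs in genotypes.items()
        for loc, (a, b) in locs.items()
    )
    demography = Demography(
        individuals=individuals,
        residencies=residencies,
        offspring_cases=offspring_cases,
    )
    return SyntheticStudy(
        config=cfg,
        seed=seed,
        loci=loci,
        allele_freqs=freqs,
        truth_panel=panel,
        sampled_ids=sampled,
        demography=demography,
        truth_pedigree=truth_pedigree,
        alpha_segments=alpha_segments,
        births=births,
    )


def _alpha_for(
    segments: list[tuple[str, _dt.date, _dt.date, str]], group: str, day: _dt.date
) -> str:
    for g, start, end, male in segments:
        if g == group and start <= day < end:
            return male
    raise RuntimeError(f"no alpha segment covers {group} on {day}")


def simulate_amplifications(
    study: SyntheticStudy,
    error_model: ErrorModel,
    samples_per_individual: int = 3,
    amplifications_per_sample: int = 3,
    seed: int = 1,
    individuals: list[str] | None = None,
) -> pd.DataFrame:
    """Emit a per-amplification replicate table for the sampled individuals.

    Each individual contributes up to ``samples_per_individual`` fecal
    samples, each amplified ``amplifications_per_sample`` times per
    locus.  Dropout acts independently per amplification on
    heterozygotes; a spurious allele can be added when a single allele
    is showing.
    """
    if samples_per_individual < 1 or amplifications_per_sample < 1:
        raise ValueError("replicate counts must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    ids = individuals if individuals is not None else sorted(study.sampled_ids)
    registries = {
        loc: sorted(study.allele_freqs[loc]) for loc in study.loci
    }
    for ind in ids:
        for s in range(samples_per_individual):
            sample_id = f"{ind}_s{s + 1}"
            for loc in study.loci:
                g = study.truth_panel.get(ind, loc)
                if g is None:
                    continue
                for _ in range(amplifications_per_sample):
                    shown = list(g.alleles) if g.is_het else [g.allele_a]
                    if g.is_het and rng.random() < error_model.dropout_rate:
                        shown = [shown[int(rng.integers(2))]]
                    if len(shown) == 1 and rng.random() < error_model.false_allele_rate:
                        others = [a for a in registries[loc] if a not in g.alleles]
                        if others:
                            shown.append(int(others[int(rng.integers(len(others)))]))
                    shown = sorted(set(shown))
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "individual_id": ind,
                            "locus": loc,
                            "obs_allele_1": shown[0],
                            "obs_allele_2": shown[1] if len(shown) > 1 else 0,
                        }
                    )
    return pd.DataFrame(rows)
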