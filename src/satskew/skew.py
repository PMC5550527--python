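"""Male reproductive skew: dominance, residency and the Nonacs B index.

The B index compares each male's share of paternities (p_i) with his
share of residency time (n_i, male-days in the group-year):

    B = sum_i (p_i - n_i)^2  -  (1 - sum_i n_i^2) / K

where K is the number of paternities.  Under residency-proportional
random allocation (multinomial with probabilities n_i) the expectation
of B is exactly 0; positive values mean monopolization, negative values
a more even distribution than expected.  Significance comes from the
multinomial null (full enumeration for tiny cases, Monte-Carlo
otherwise) and confidence intervals from a multinomial bootstrap of the
observed shares or from null quantiles.

Dominance ranks come from David's scores on dyadic win proportions; the
alpha male is the top score.
"""

from __future__ import annotations

import datetime as _dt
import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import Demography, ResidencyRecord


# ---------------------------------------------------------------------------
# David's score


@dataclass
class DavidScoreTable:
    period: str
    scores: dict[str, float]
    ranking: list[str]

    @property
    def alpha_id(self) -> str:
        return self.ranking[0]


def david_score(win_matrix: pd.DataFrame, period: str = "") -> DavidScoreTable:
    """David's scores from a square win-count matrix (rows beat columns).

    Dyadic win proportions P_ij = w_ij / (w_ij + w_ji); unobserved dyads
    contribute nothing.  DS_i = w_i + w2_i - l_i - l2_i where w is the
    row sum of P, l the column sum, and w2/l2 the opponent-weighted
    second-order sums.
    """
    if win_matrix.empty:
        raise ValueError("empty win matrix")
    if list(win_matrix.index) != list(win_matrix.columns):
        raise ValueError("win matrix must be square with matching labels")
    ids = list(win_matrix.index)
    wins = win_matrix.to_numpy(dtype=float)
    if np.any(np.diag(wins) != 0):
        raise ValueError("diagonal of a win matrix must be zero")
    if np.any(wins < 0):
        raise ValueError("win counts must be non-negative")
    total = wins + wins.T
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(total > 0, wins / np.where(total > 0, total, 1), 0.0)
    w = P.sum(axis=1)
    l = P.sum(axis=0)
    w2 = P @ w
    l2 = P.T @ l
    ds = w + w2 - l - l2
    scores = {i: float(s) for i, s in zip(ids, ds)}
    ranking = sorted(ids, key=lambda i: -scores[i])
    return DavidScoreTable(period=period, scores=scores, ranking=ranking)


# ---------------------------------------------------------------------------
# residency


def residency_shares(
    residencies: Sequence[ResidencyRecord], group: str, year: int
) -> tuple[dict[str, float], dict[str, int]]:
    """Residency shares n_i = male-days_i / total male-days for one
    group-year; also returns the raw day counts.  Males with zero days
    are excluded."""
    days: dict[str, int] = {}
    for r in residencies:
        if r.group != group:
            continue
        d = r.days_in_year(year)
        if d > 0:
            days[r.male_id] = days.get(r.male_id, 0) + d
    total = sum(days.values())
    if total == 0:
        raise ValueError(f"no male residency in {group} {year}")
    return {m: d / total for m, d in days.items()}, days


# ---------------------------------------------------------------------------
# B index


def b_index(counts: Mapping[str, int], shares: Mapping[str, float]) -> float:
    """Nonacs' binomial skew index B.

    *counts*: paternities per male (males absent from the mapping hold
    zero); *shares*: residency share n_i per male, summing to 1.
    """
    total_share = sum(shares.values())
    if abs(total_share - 1.0) > 1e-9:
        raise ValueError(f"residency shares sum to {total_share}, not 1")
    K = sum(counts.values())
    if K < 1:
        raise ValueError("need at least one paternity")
    unknown = set(counts) - set(shares)
    if unknown:
        raise ValueError(f"paternity counts for males without residency: {unknown}")
    sum_sq_dev = 0.0
    sum_n_sq = 0.0
    for male, n_i in shares.items():
        p_i = counts.get(male, 0) / K
        sum_sq_dev += (p_i - n_i) ** 2
        sum_n_sq += n_i * n_i
    return sum_sq_dev - (1.0 - sum_n_sq) / K


def _b_from_vector(counts: np.ndarray, shares: np.ndarray) -> np.ndarray:
    K = counts.sum(axis=-1, keepdims=True)
    p = counts / K
    return ((p - shares) ** 2).sum(axis=-1) - (1.0 - (shares**2).sum()) / K[..., 0]


def b_index_test(
    counts: Mapping[str, int],
    shares: Mapping[str, float],
    mc_replicates: int = 10_000,
    ci_method: str | None = "bootstrap_multinomial",
    seed: int = 0,
    exact_limit: int = 20_000,
) -> tuple[float, float, float]:
    """Significance and CI for the observed B.

    Null: the K paternities fall multinomially with probabilities n_i.
    The one-tailed p-value is P(B_null >= B_obs), computed by full
    enumeration when the composition space is small and by Monte-Carlo
    with add-one smoothing otherwise.  The CI is a percentile interval
    of B over multinomial resamples of the observed paternity shares
    (``bootstrap_multinomial``) or the central 95% of the null
    distribution (``null_quantiles``).  Returns (p, ci_low, ci_high).
    """
    males = sorted(shares)
    n = np.array([shares[m] for m in males], dtype=float)
    k_vec = np.array([counts.get(m, 0) for m in males], dtype=float)
    K = int(k_vec.sum())
    if len(males) == 1:
        return 1.0, 0.0, 0.0
    b_obs = b_index(counts, shares)
    tol = 1e-12

    n_compositions = math.comb(K + len(males) - 1, len(males) - 1)
    rng = np.random.default_rng(seed)

    if ci_method is None and n_compositions > exact_limit:
        null_draws = rng.multinomial(K, n, size=mc_replicates).astype(float)
        null_b = _b_from_vector(null_draws, n)
        p_val = (1 + int((null_b >= b_obs - tol).sum())) / (mc_replicates + 1)
        return float(p_val), math.nan, math.nan

    if n_compositions <= exact_limit:
        p_val = 0.0
        logK = math.lgamma(K + 1)
        with np.errstate(divide="ignore"):
            log_n = np.log(n)
        for comp in itertools.combinations_with_replacement(range(len(males)), K):
            vec = np.bincount(comp, minlength=len(males)).astype(float)
            b_sim = float(_b_from_vector(vec, n))
            if b_sim >= b_obs - tol:
                if np.any((vec > 0) & (n == 0)):
                    continue
                logp = logK - sum(math.lgamma(c + 1) for c in vec)
                logp += float((vec * np.where(n > 0, log_n, 0.0)).sum())
                p_val += math.exp(logp)
        p_val = min(1.0, p_val)
        if ci_method is None:
            return float(p_val), math.nan, math.nan
        null_draws = rng.multinomial(K, n, size=max(mc_replicates, 2000)).astype(float)
        null_b = _b_from_vector(null_draws, n)
    else:
        null_draws = rng.multinomial(K, n, size=mc_replicates).astype(float)
        null_b = _b_from_vector(null_draws, n)
        p_val = (1 + int((null_b >= b_obs - tol).sum())) / (mc_replicates + 1)

    if ci_method == "null_quantiles":
        ci_low, ci_high = np.percentile(null_b, [2.5, 97.5])
    elif ci_method == "bootstrap_multinomial":
        p_hat = k_vec / K
        if np.max(p_hat) >= 1.0 - 1e-12:
            # full monopoly resamples to itself: point interval
            return p_val, b_obs, b_obs
        boot = rng.multinomial(K, p_hat, size=mc_replicates).astype(float)
        boot_b = _b_from_vector(boot, n)
        ci_low, ci_high = np.percentile(boot_b, [2.5, 97.5])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return float(p_val), float(ci_low), float(ci_high)


# ---------------------------------------------------------------------------
# group-year skew table


@dataclass
class SkewRecord:
    group: str
    year: int
    potential_sires: int
    sires_observed: int
    adult_females: int
    K: int
    residency_shares: dict[str, float]
    paternity_shares: dict[str, float]
    B: float
    p_value: float
    ci_low: float
    ci_high: float
    alpha_paternity_share: float
    alpha_tenure_share: float
    coverage: float

    @property
    def sex_ratio(self) -> float:
        return self.potential_sires / self.adult_females


def skew_table(
    paternities: Mapping[str, str],
    demography: Demography,
    births: Mapping[tuple[str, int], int],
    alpha_at,
    adult_females: Mapping[str, int],
    coverage_min: float = 0.45,
    mc_replicates: int = 10_000,
    ci_method: str = "bootstrap_multinomial",
    seed: int = 0,
) -> list[SkewRecord]:
    """One skew record per group-year passing the sampling-coverage filter.

    *paternities* maps offspring_id -> assigned sire for solved cases;
    offspring are attributed to the group-year of their birth group and
    birth year.  *births* gives the number of offspring born per
    (group, year) for the coverage filter; *alpha_at(group, date)*
    resolves the alpha male at a conception date; *adult_females* the
    female count per group.
    """
    cases = {c.offspring_id: c for c in demography.offspring_cases}
    by_gy: dict[tuple[str, int], list[str]] = {}
    for oid, sire in paternities.items():
        case = cases.get(oid)
        if case is None:
            continue
        by_gy.setdefault((case.birth_group, case.birth_date.year), []).append(oid)

    records = []
    for (group, year), oids in sorted(by_gy.items()):
        born = births.get((group, year), len(oids))
        coverage = len(oids) / born if born else 1.0
        if coverage < coverage_min or not oids:
            continue
        shares, days = residency_shares(demography.residencies, group, year)
        counts: dict[str, int] = {}
        alpha_hits = 0
        for oid in oids:
            sire = paternities[oid]
            counts[sire] = counts.get(sire, 0) + 1
            alpha = alpha_at(group, cases[oid].conception_date)
            if alpha is not None and sire == alpha:
                alpha_hits += 1
        if set(counts) - set(shares):
            # a sire without residency days (extragroup): give him the
            # minimal one-day share so the index stays defined
            for m in set(counts) - set(shares):
                days[m] = 1
            total = sum(days.values())
            shares = {m: d / total for m, d in days.items()}
        K = len(oids)
        B = b_index(counts, shares)
        p, lo, hi = b_index_test(
            counts, shares, mc_replicates=mc_replicates,
            ci_method=ci_method,
            seed=seed + year + sum(ord(c) for c in group) % 1000,
        )
        # modal alpha of the calendar year, by days held
        alpha_days: dict[str, int] = {}
        day = _dt.date(year, 1, 1)
        while day < _dt.date(year + 1, 1, 1):
            a = alpha_at(group, day)
            if a is not None:
                alpha_days[a] = alpha_days.get(a, 0) + 1
            day += _dt.timedelta(days=1)
        year_days = (_dt.date(year + 1, 1, 1) - _dt.date(year, 1, 1)).days
        tenure_share = max(alpha_days.values()) / year_days if alpha_days else 0.0
        records.append(
            SkewRecord(
                group=group, year=year,
                potential_sires=len(shares),
                sires_observed=len(counts),
                adult_females=adult_females.get(group, 0),
                K=K,
                residency_shares=shares,
                paternity_shares={m: c / K for m, c in counts.items()},
                B=B, p_value=p, ci_low=lo, ci_high=hi,
                alpha_paternity_share=100.0 * alpha_hits / K,
                alpha_tenure_share=100.0 * tenure_share,
                coverage=coverage,
            )
        )
    return records


def skew_summary(records: Sequence[SkewRecord]) -> dict[str, float]:
    if not records:
        return {}
    bs = [r.B for r in records]
    alpha = [r.alpha_paternity_share for r in records]
    return {
        "n_group_years": len(records),
        "mean_B": float(np.mean(bs)),
        "sd_B": float(np.std(bs)),
        "mean_alpha_paternity_pct": float(np.mean(alpha)),
        "sd_alpha_paternity_pct": float(np.std(alpha)),
    }


# ---------------------------------------------------------------------------
# posthoc correlation


def spearman_rho(
    x: Sequence[float],
    y: Sequence[float],
    mc_replicates: int = 100_000,
    seed: int = 0,
    exact_n: int = 8,
) -> tuple[float, float]:
    """Average-rank Spearman correlation with a permutation p-value.

    Exact permutation distribution for n <= *exact_n*, Monte-Carlo with
    add-one smoothing otherwise; two-tailed on |rho|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rho undefined")

    def avg_rank(v: np.ndarray) -> np.ndarray:
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty_like(v)
        sv = v[order]
        r = np.arange(1, v.size + 1, dtype=float)
        # average ranks over ties
        i = 0
        while i < v.size:
            j = i
            while j + 1 < v.size and sv[j + 1] == sv[i]:
                j += 1
            r[i : j + 1] = r[i : j + 1].mean()
            i = j + 1
        ranks[order] = r
        return ranks

    rx, ry = avg_rank(x), avg_rank(y)

    def corr(a: np.ndarray, b: np.ndarray) -> float:
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / math.sqrt((a @ a) * (b @ b)))

    rho = corr(rx, ry)
    n = x.size
    if n <= exact_n:
        hits = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(corr(rx, ry[list(perm)])) >= abs(rho) - 1e-12:
                hits += 1
        return rho, hits / total
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(mc_replicates):
        if abs(corr(rx, rng.permutation(ry))) >= abs(rho) - 1e-12:
            hits += 1
    return rho, (1 + hits) / (mc_replicates + 1)
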