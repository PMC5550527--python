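"""Marker QC and per-locus diversity statistics.

Implements the descriptive population-genetic layer: gene-counting
allele frequencies, observed heterozygosity (Ho), unbiased expected
heterozygosity (He), Botstein's polymorphic information content (PIC),
an exact conditional Hardy-Weinberg test (full enumeration for small
state spaces, Monte-Carlo otherwise), null-allele frequency estimators
(Chakraborty, Brookfield, and an EM iteration on homozygote excess), and
the within-group inbreeding coefficient F_IS (ratio estimator and
Weir & Cockerham's f).

Conventions: statistics are computed over typed individuals only;
reports round to 3 decimals (half-up) while full precision is kept
internally; summary rows use the population SD (ddof=0).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .types import GenotypePanel, RepeatClass

ALL = "ALL"


@dataclass
class LocusDiversity:
    locus: str
    group: str
    n_typed: int
    k: int
    ho: float
    he: float
    pic: float
    fis: float | None = None
    hwe_p: float | None = None
    null_freq_estimate: float | None = None


@dataclass
class MarkerQCRecord:
    locus: str
    repeat_class: RepeatClass
    amplification_success: float
    k: int
    scoring_reliable: bool
    selected: bool


# ---------------------------------------------------------------------------
# allele frequencies and heterozygosity


def _genotypes_for(
    panel: GenotypePanel, locus: str, individuals: Sequence[str] | None = None
):
    ids = individuals if individuals is not None else panel.individuals
    out = []
    for ind in ids:
        g = panel.get(ind, locus)
        if g is not None:
            out.append(g)
    return out


def allele_frequencies(
    panel: GenotypePanel,
    grouping: Mapping[str, str] | None = None,
) -> dict[str, dict[str, dict[int, float]]]:
    """Gene-counting allele frequency estimates.

    Returns ``{group: {locus: {allele: freq}}}`` with the pooled
    estimate under the key ``ALL``.  Loci with zero typed individuals in
    a group are omitted from that group's table.
    """
    groups: dict[str, list[str]] = {ALL: list(panel.individuals)}
    if grouping:
        for ind in panel.individuals:
            g = grouping.get(ind)
            if g is not None:
                groups.setdefault(g, []).append(ind)
    out: dict[str, dict[str, dict[int, float]]] = {}
    for gname, ids in groups.items():
        table: dict[str, dict[int, float]] = {}
        for locus in panel.loci:
            gts = _genotypes_for(panel, locus, ids)
            if not gts:
                continue
            counts: dict[int, int] = {}
            for gt in gts:
                for a in gt.alleles:
                    counts[a] = counts.get(a, 0) + 1
            total = 2 * len(gts)
            table[locus] = {a: c / total for a, c in sorted(counts.items())}
        out[gname] = table
    return out


def expected_heterozygosity(freqs: Mapping[int, float], n: int, unbiased: bool = True) -> float:
    """He = 1 - sum(p_i^2), with the 2n/(2n-1) small-sample correction by default."""
    he = 1.0 - sum(p * p for p in freqs.values())
    if unbiased and n > 0:
        he *= (2 * n) / (2 * n - 1)
    return he


def pic(freqs: Mapping[int, float]) -> float:
    """Botstein's polymorphic information content."""
    p = list(freqs.values())
    s2 = sum(x * x for x in p)
    cross = sum(
        2.0 * p[i] ** 2 * p[j] ** 2 for i in range(len(p)) for j in range(i + 1, len(p))
    )
    return 1.0 - s2 - cross


def locus_diversity(
    panel: GenotypePanel,
    grouping: Mapping[str, str] | None = None,
    unbiased_he: bool = True,
) -> list[LocusDiversity]:
    """Per-(locus, group) diversity summary: k, Ho, He, PIC and simple F_IS."""
    freq_tables = allele_frequencies(panel, grouping)
    groups: dict[str, list[str]] = {ALL: list(panel.individuals)}
    if grouping:
        for ind in panel.individuals:
            g = grouping.get(ind)
            if g is not None:
                groups.setdefault(g, []).append(ind)
    out = []
    for gname, ids in groups.items():
        for locus in panel.loci:
            gts = _genotypes_for(panel, locus, ids)
            if not gts:
                continue
            n = len(gts)
            ho = sum(1 for g in gts if g.is_het) / n
            freqs = freq_tables[gname][locus]
            he = expected_heterozygosity(freqs, n, unbiased=unbiased_he)
            fis = None if he == 0 else 1.0 - ho / he
            out.append(
                LocusDiversity(
                    locus=locus, group=gname, n_typed=n, k=len(freqs),
                    ho=ho, he=he, pic=pic(freqs), fis=fis,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def _log_table_prob(counts: Mapping[tuple[int, int], int]) -> float:
    """Log conditional probability of a genotype table given its allele counts
    (Levene's distribution)."""
    n = sum(counts.values())
    allele_counts: dict[int, int] = {}
    h = 0
    for (a, b), c in counts.items():
        allele_counts[a] = allele_counts.get(a, 0) + c
        allele_counts[b] = allele_counts.get(b, 0) + c
        if a != b:
            h += c
    logp = gammaln(n + 1) + h * np.log(2.0) - gammaln(2 * n + 1)
    logp += sum(gammaln(c + 1) for c in allele_counts.values())
    logp -= sum(gammaln(c + 1) for c in counts.values())
    return float(logp)


def _enumerate_tables(allele_counts: list[int], limit: int):
    """Yield all genotype count tables consistent with *allele_counts*.

    Raises ``OverflowError`` once more than *limit* tables were produced,
    signalling that the state space is too large for full enumeration.
    """
    k = len(allele_counts)
    cells = [(i, j) for i in range(k) for j in range(i, k)]
    produced = 0

    def rec(idx: int, remaining: list[int], current: dict):
        nonlocal produced
        if idx == len(cells):
            if all(r == 0 for r in remaining):
                produced += 1
                if produced > limit:
                    raise OverflowError
                yield dict(current)
            return
        i, j = cells[idx]
        if i == j:
            cap = remaining[i] // 2
        else:
            cap = min(remaining[i], remaining[j])
        for c in range(cap + 1):
            if i == j:
                remaining[i] -= 2 * c  # a homozygote uses two copies
            else:
                remaining[i] -= c
                remaining[j] -= c
            current[(i, j)] = c
            yield from rec(idx + 1, remaining, current)
            if i == j:
                remaining[i] += 2 * c
            else:
                remaining[i] += c
                remaining[j] += c
        current.pop((i, j), None)

    yield from rec(0, list(allele_counts), {})


def hwe_test(
    genotype_counts: Mapping[tuple[int, int], int],
    mc_replicates: int = 10_000,
    seed: int = 0,
    enumeration_limit: int = 100_000,
) -> float:
    """Exact conditional test for Hardy-Weinberg proportions.

    The test statistic is the conditional probability of the genotype
    table given its allele counts; the p-value is the total probability
    of tables no more probable than the observed one.  The full state
    space is enumerated when it holds at most *enumeration_limit*
    tables; otherwise the p-value is estimated by Monte-Carlo
    (permutation of the allele vector, add-one smoothing).

    *genotype_counts* maps unordered allele pairs ``(a, b)`` with
    ``a <= b`` to individual counts.  A monomorphic locus returns 1.
    """
    counts = {tuple(sorted(k)): v for k, v in genotype_counts.items() if v > 0}
    alleles = sorted({a for pair in counts for a in pair})
    if len(alleles) < 2:
        return 1.0
    index = {a: i for i, a in enumerate(alleles)}
    allele_counts = [0] * len(alleles)
    for (a, b), c in counts.items():
        allele_counts[index[a]] += c
        allele_counts[index[b]] += c

    obs_logp = _log_table_prob(counts)
    tol = 1e-9
    n_ind = sum(counts.values())

    # full enumeration is worthwhile for two-allele loci (linear state
    # space) and tiny multi-allele tables; everything else goes Monte-Carlo
    if len(alleles) == 2 or n_ind <= 12:
        try:
            total = 0.0
            for table in _enumerate_tables(allele_counts, enumeration_limit):
                named = {
                    (alleles[i], alleles[j]): c for (i, j), c in table.items() if c > 0
                }
                lp = _log_table_prob(named) if named else 0.0
                if lp <= obs_logp + tol:
                    total += float(np.exp(lp))
            return min(1.0, total)
        except OverflowError:
            pass

    # Monte-Carlo: permute the flattened allele vector and re-pair
    rng = np.random.default_rng(seed)
    vec = np.concatenate(
        [np.full(c, i, dtype=np.int64) for i, c in enumerate(allele_counts)]
    )
    k = len(alleles)
    obs_stat = _mc_stat_from_counts(counts, index)
    hits = 0
    two_n = vec.size
    batch = max(1, min(mc_replicates, 4_000_000 // max(two_n, 1)))
    done = 0
    diag = np.arange(k) * k + np.arange(k)
    while done < mc_replicates:
        b = min(batch, mc_replicates - done)
        keys = rng.random((b, two_n)).argsort(axis=1)
        arr = vec[keys]
        lo = np.minimum(arr[:, 0::2], arr[:, 1::2])
        hi = np.maximum(arr[:, 0::2], arr[:, 1::2])
        codes = lo * k + hi + (np.arange(b)[:, None] * k * k)
        cnt = np.bincount(codes.ravel(), minlength=b * k * k).reshape(b, k * k)
        h = n_ind - cnt[:, diag].sum(axis=1)
        stats = h * np.log(2.0) - gammaln(cnt + 1).sum(axis=1)
        hits += int((stats <= obs_stat + tol).sum())
        done += b
    return (1 + hits) / (mc_replicates + 1)


def _mc_stat_from_counts(
    counts: Mapping[tuple[int, int], int], index: Mapping[int, int]
) -> float:
    h = sum(c for (a, b), c in counts.items() if a != b)
    return float(
        h * np.log(2.0) - sum(gammaln(c + 1) for c in counts.values())
    )


def genotype_counts(
    panel: GenotypePanel, locus: str, individuals: Sequence[str] | None = None
) -> dict[tuple[int, int], int]:
    out: dict[tuple[int, int], int] = {}
    for g in _genotypes_for(panel, locus, individuals):
        out[g.alleles] = out.get(g.alleles, 0) + 1
    return out


# ---------------------------------------------------------------------------
# null alleles


def null_allele_estimate(
    ho: float | None = None,
    he: float | None = None,
    method: str = "iterative",
    counts: Mapping[tuple[int, int], int] | None = None,
    n_blanks: int = 0,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> float:
    """Estimate the frequency of a segregating null allele at one locus.

    ``chakraborty``: (He-Ho)/(He+Ho); ``brookfield``: (He-Ho)/(1+He);
    ``iterative``: EM on the apparent genotype counts, treating each
    apparent homozygote as a mixture of a true homozygote and a
    visible/null heterozygote, and *n_blanks* failed individuals as
    null homozygotes.  Estimates are negative when Ho exceeds He.
    """
    if method == "chakraborty":
        if ho is None or he is None:
            raise ValueError("chakraborty needs ho and he")
        if he + ho == 0:
            raise ValueError("He + Ho = 0")
        return (he - ho) / (he + ho)
    if method == "brookfield":
        if ho is None or he is None:
            raise ValueError("brookfield needs ho and he")
        return (he - ho) / (1.0 + he)
    if method != "iterative":
        raise ValueError(f"unknown method {method!r}")
    if not counts:
        raise ValueError("iterative estimator needs genotype counts")

    het_counts = {k: v for k, v in counts.items() if k[0] != k[1]}
    hom_counts = {k[0]: v for k, v in counts.items() if k[0] == k[1]}
    alleles = sorted({a for pair in counts for a in pair})
    n_ind = sum(counts.values()) + n_blanks
    total_genes = 2 * n_ind

    # start from gene counting, a pinch of null
    gene: dict[int, float] = {a: 0.0 for a in alleles}
    for (a, b), c in counts.items():
        gene[a] += c
        gene[b] += c
    r = max(1e-4, n_blanks / max(n_ind, 1))
    p = {a: g / total_genes * (1 - r) for a, g in gene.items()}
    for _ in range(max_iter):
        new_gene = {a: 0.0 for a in alleles}
        null_genes = 2.0 * n_blanks
        for (a, b), c in het_counts.items():
            new_gene[a] += c
            new_gene[b] += c
        for a, c in hom_counts.items():
            denom = p[a] ** 2 + 2 * p[a] * r
            w_true = 1.0 if denom == 0 else p[a] ** 2 / denom
            new_gene[a] += c * (2 * w_true + (1 - w_true))
            null_genes += c * (1 - w_true)
        new_r = null_genes / total_genes
        new_p = {a: g / total_genes for a, g in new_gene.items()}
        delta = abs(new_r - r) + sum(abs(new_p[a] - p[a]) for a in alleles)
        p, r = new_p, new_r
        if delta < tol:
            break
    if ho is not None and he is not None and ho > he:
        # heterozygote excess: report the signed homozygote-deficit analogue
        return (he - ho) / (he + ho)
    return r


# ---------------------------------------------------------------------------
# F_IS


def fis_weir_cockerham(counts: Mapping[tuple[int, int], int]) -> float | None:
    """Weir & Cockerham's within-population f from one locus's genotype counts."""
    n = sum(counts.values())
    if n < 2:
        return None
    alleles = sorted({a for pair in counts for a in pair})
    if len(alleles) < 2:
        return None
    p = {a: 0.0 for a in alleles}
    het_with: dict[int, float] = {a: 0.0 for a in alleles}
    for (a, b), c in counts.items():
        p[a] += c
        p[b] += c
        if a != b:
            het_with[a] += c
            het_with[b] += c
    num = 0.0
    den = 0.0
    for a in alleles:
        pa = p[a] / (2 * n)
        ha = het_with[a] / n
        b_comp = n / (n - 1) * (pa * (1 - pa) - (2 * n - 1) / (4 * n) * ha)
        c_comp = ha / 2.0
        num += c_comp
        den += b_comp + c_comp
    if den == 0:
        return None
    return 1.0 - num / den


def fis(
    panel: GenotypePanel,
    grouping: Mapping[str, str] | None = None,
    estimator: str = "simple",
) -> dict[str, dict[str, float]]:
    """Per-locus and mean F_IS for the pooled sample and each group.

    ``simple`` is 1 - Ho/He; ``weir_cockerham`` is W&C (1984) f.  Loci
    with He = 0 are excluded from the means.  Returns
    ``{group: {locus: fis, "MEAN": mean}}``.
    """
    if estimator not in ("simple", "weir_cockerham"):
        raise ValueError(f"unknown estimator {estimator!r}")
    groups: dict[str, list[str]] = {ALL: list(panel.individuals)}
    if grouping:
        for ind in panel.individuals:
            g = grouping.get(ind)
            if g is not None:
                groups.setdefault(g, []).append(ind)
    div = {
        (d.group, d.locus): d for d in locus_diversity(panel, grouping)
    }
    out: dict[str, dict[str, float]] = {}
    for gname, ids in groups.items():
        per_locus: dict[str, float] = {}
        for locus in panel.loci:
            if estimator == "simple":
                d = div.get((gname, locus))
                if d is None or d.fis is None:
                    continue
                per_locus[locus] = d.fis
            else:
                f = fis_weir_cockerham(genotype_counts(panel, locus, ids))
                if f is not None:
                    per_locus[locus] = f
        if per_locus:
            per_locus["MEAN"] = float(np.mean(list(per_locus.values())))
        out[gname] = per_locus
    return out


# ---------------------------------------------------------------------------
# marker QC and reporting


def marker_qc(
    stats: pd.DataFrame,
    panel_cap: int | None = None,
    min_success: float = 0.5,
    min_alleles: int = 3,
) -> list[MarkerQCRecord]:
    """Select markers: amplification success >= 50%, >= 3 alleles,
    reliable scoring; tetra-repeats preferred over di-repeats when a
    panel cap forces a choice.

    *stats* needs columns locus, repeat_class, amplification_success, k,
    scoring_reliable.
    """
    records = []
    for r in stats.itertuples(index=False):
        rc = RepeatClass(r.repeat_class)
        passes = (
            float(r.amplification_success) >= min_success
            and int(r.k) >= min_alleles
            and bool(r.scoring_reliable)
        )
        records.append(
            MarkerQCRecord(
                locus=str(r.locus),
                repeat_class=rc,
                amplification_success=float(r.amplification_success),
                k=int(r.k),
                scoring_reliable=bool(r.scoring_reliable),
                selected=passes,
            )
        )
    if panel_cap is not None:
        passing = [m for m in records if m.selected]
        # tetra first, then higher allele count, then success
        passing.sort(
            key=lambda m: (
                m.repeat_class is not RepeatClass.TETRA,
                -m.k,
                -m.amplification_success,
            )
        )
        keep = {m.locus for m in passing[:panel_cap]}
        for m in records:
            m.selected = m.locus in keep
    return records


def round3(x: float) -> float:
    """Report rounding: 3 decimals, ties away from zero (half-up)."""
    return float(
        Decimal(repr(float(x))).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP)
    )


def summarize_columns(df: pd.DataFrame, decimals: int = 3) -> pd.DataFrame:
    """Append Mean and SD rows (population SD, ddof=0) to a numeric
    per-locus table, rounding to *decimals* (half-up)."""
    q = Decimal(1).scaleb(-decimals)

    def _round(x: float) -> float:
        return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))

    numeric = df.select_dtypes("number")
    mean = {c: _round(numeric[c].mean()) for c in numeric.columns}
    sd = {c: _round(numeric[c].std(ddof=0)) for c in numeric.columns}
    out = df.copy()
    out.loc["Mean"] = pd.Series(mean)
    out.loc["SD"] = pd.Series(sd)
    return out


def diversity_table(
    panel: GenotypePanel,
    grouping: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-locus diversity report across the pooled sample and each group,
    with Mean and SD summary rows.

    Columns are ``<stat>_<group>`` for stat in (k, Ho, He, PIC, FIS),
    pooled columns first; one row per locus.
    """
    div = locus_diversity(panel, grouping)
    groups = [ALL] + sorted({d.group for d in div} - {ALL})
    rows: dict[str, dict[str, float]] = {}
    for d in div:
        row = rows.setdefault(d.locus, {})
        row[f"k_{d.group}"] = d.k
        row[f"Ho_{d.group}"] = round3(d.ho)
        row[f"He_{d.group}"] = round3(d.he)
        row[f"PIC_{d.group}"] = round3(d.pic)
        if d.fis is not None:
            row[f"FIS_{d.group}"] = round3(d.fis)
    cols = [
        f"{stat}_{g}" for stat in ("k", "Ho", "He", "PIC", "FIS") for g in groups
    ]
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df.reindex(columns=[c for c in cols if c in df.columns])
    df.index.name = "locus"
    return summarize_columns(df)
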