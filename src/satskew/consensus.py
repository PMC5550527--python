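"""Multi-tube consensus genotype calling.

Fecal DNA carries little template and suffers frequent allelic dropout,
so a genotype is accepted only after repeated independent amplifications
agree.  The rule set:

* heterozygote: the identical allele pair seen in >= 4 amplifications in
  total, spread over >= 2 distinct samples of the same individual;
* homozygote: the single allele seen, with no contradicting
  amplification, in >= 6 amplifications;
* third allele: when more than two distinct alleles turn up, both
  required counts are doubled; an extra allele seen in fewer than two
  amplifications is then treated as spurious and ignored.

Anything short of these thresholds is UNRESOLVED (missing), never an
error.  All thresholds live in :class:`~satskew.config.ConsensusThresholds`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .config import ConsensusThresholds
from .types import Genotype, GenotypePanel


class CallStatus(str, Enum):
    ACCEPTED_HET = "ACCEPTED_HET"
    ACCEPTED_HOM = "ACCEPTED_HOM"
    UNRESOLVED = "UNRESOLVED"


@dataclass(frozen=True)
class AmplificationRecord:
    """One PCR result: the allele(s) observed in a single amplification
    of one sample at one locus."""

    sample_id: str
    alleles: tuple[int, ...]  # 1 (apparent homozygote) or 2 alleles, sorted

    def __post_init__(self) -> None:
        if not 1 <= len(self.alleles) <= 2:
            raise ValueError("an amplification shows one or two alleles")
        object.__setattr__(self, "alleles", tuple(sorted(set(self.alleles))))


@dataclass(frozen=True)
class ConsensusCall:
    individual_id: str
    locus: str
    status: CallStatus
    genotype: tuple[int, int] | None
    n_amplifications_supporting: int
    n_samples_supporting: int
    third_allele_seen: bool


def call_consensus(
    individual_id: str,
    locus: str,
    amplifications: list[AmplificationRecord],
    thresholds: ConsensusThresholds | None = None,
) -> ConsensusCall:
    """Apply the multi-tube acceptance rules to one individual x locus."""
    if not amplifications:
        raise ValueError("need at least one amplification record")
    t = thresholds or ConsensusThresholds()

    distinct = sorted({a for rec in amplifications for a in rec.alleles})
    third_seen = len(distinct) > 2
    mult = t.third_allele_multiplier if third_seen else 1

    allele_amp_count = Counter(
        a for rec in amplifications for a in set(rec.alleles)
    )
    # with the doubled thresholds in force, alleles seen in <2
    # amplifications are spurious and do not block acceptance
    blocking = set(distinct)
    if third_seen:
        blocking = {a for a in distinct if allele_amp_count[a] >= 2}

    def unresolved() -> ConsensusCall:
        return ConsensusCall(
            individual_id, locus, CallStatus.UNRESOLVED, None, 0, 0, third_seen
        )

    # heterozygote path: the best-supported identical pair
    pair_support: dict[tuple[int, int], list[AmplificationRecord]] = {}
    for rec in amplifications:
        if len(rec.alleles) == 2:
            pair_support.setdefault(rec.alleles, []).append(rec)
    best_het: ConsensusCall | None = None
    for pair, recs in pair_support.items():
        if blocking - set(pair):
            continue  # another credible allele contradicts this pair
        n_amp = len(recs)
        n_samples = len({r.sample_id for r in recs})
        if n_amp >= t.het_min_amplifications * mult and n_samples >= t.het_min_samples:
            if best_het is None or n_amp > best_het.n_amplifications_supporting:
                best_het = ConsensusCall(
                    individual_id, locus, CallStatus.ACCEPTED_HET, pair,
                    n_amp, n_samples, third_seen,
                )
    if best_het is not None:
        return best_het

    # homozygote path: a single credible allele, zero contradictions
    if len(blocking) == 1:
        (allele,) = blocking
        recs = [r for r in amplifications if r.alleles == (allele,)]
        n_amp = len(recs)
        contradicted = any(
            set(r.alleles) - {allele} & blocking for r in amplifications
        )
        if not contradicted and n_amp >= t.hom_min_amplifications * mult:
            return ConsensusCall(
                individual_id, locus, CallStatus.ACCEPTED_HOM, (allele, allele),
                n_amp, len({r.sample_id for r in recs}), third_seen,
            )
    return unresolved()


def call_panel(
    amplifications: pd.DataFrame,
    thresholds: ConsensusThresholds | None = None,
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Run consensus calling over a full amplification table.

    Returns the accepted-genotype panel and a per-call audit table
    (one row per individual x locus, including UNRESOLVED calls).
    """
    panel = GenotypePanel()
    audit_rows = []
    grouped = amplifications.groupby(["individual_id", "locus"], sort=False)
    for (ind, locus), sub in grouped:
        recs = [
            AmplificationRecord(
                str(r.sample_id),
                (int(r.obs_allele_1),)
                if int(r.obs_allele_2) == 0
                else (int(r.obs_allele_1), int(r.obs_allele_2)),
            )
            for r in sub.itertuples(index=False)
        ]
        call = call_consensus(str(ind), str(locus), recs, thresholds)
        audit_rows.append(
            {
                "individual_id": call.individual_id,
                "locus": call.locus,
                "status": call.status.value,
                "allele_a": call.genotype[0] if call.genotype else 0,
                "allele_b": call.genotype[1] if call.genotype else 0,
                "n_amplifications_supporting": call.n_amplifications_supporting,
                "n_samples_supporting": call.n_samples_supporting,
                "third_allele_seen": call.third_allele_seen,
            }
        )
        if call.status is not CallStatus.UNRESOLVED:
            panel.add(Genotype(call.individual_id, call.locus, *call.genotype))
    return panel, pd.DataFrame(audit_rows)


def concordance_rate(
    calls_a: GenotypePanel, calls_b: GenotypePanel
) -> dict[str, float]:
    """Allele-level concordance between two independently produced panels.

    Every (individual, locus) called in both panels contributes two
    alleles; a mismatch is an allele of one call not matched (as a
    multiset) in the other.  Returns counts and the mismatch rate.
    """
    n_alleles = 0
    n_mismatches = 0
    for g in calls_a:
        other = calls_b.get(g.individual_id, g.locus)
        if other is None or g.is_missing:
            continue
        n_alleles += 2
        shared = sum((Counter(g.alleles) & Counter(other.alleles)).values())
        n_mismatches += 2 - shared
    if n_alleles == 0:
        raise ValueError("no overlapping calls between the two panels")
    return {
        "n_alleles_compared": n_alleles,
        "n_mismatches": n_mismatches,
        "rate": n_mismatches / n_alleles,
    }
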