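"""Readers and writers for the tabular interchange formats.

Everything is plain delimited text (TSV/CSV).  The canonical genotype
table is *long*: one row per individual x locus with two allele columns
in base pairs, ``0`` marking a missing allele.  A *wide* layout (one row
per individual, two columns per locus named ``<locus>_a``/``<locus>_b``)
is accepted on input only.  GenePop export provides interoperability
with the classic population-genetics tool chain.
"""

from __future__ import annotations

import datetime as _dt
import io as _io
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .types import (
    MISSING,
    Demography,
    Genotype,
    GenotypePanel,
    Individual,
    OffspringCase,
    ResidencyRecord,
    Sex,
)

_GENOTYPE_COLUMNS = ["individual_id", "locus", "allele_a", "allele_b"]


def _sep_for(path_or_text: str) -> str:
    return "\t" if str(path_or_text).endswith((".tsv", ".tab")) else ","


def _read_df(source: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a delimited table from a path or from literal text."""
    text = source
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        path = Path(source)
        sep = sep or _sep_for(str(path))
        text = path.read_text()
    if sep is None:
        first = str(text).splitlines()[0]
        sep = "\t" if "\t" in first else ","
    return pd.read_csv(_io.StringIO(str(text)), sep=sep, dtype=str).fillna("")


def read_genotype_table(source: str | Path, dialect: str = "long") -> GenotypePanel:
    """Load a genotype table into a :class:`GenotypePanel`.

    Parameters
    ----------
    source
        Path to a TSV/CSV file, or the table text itself.
    dialect
        ``"long"`` (individual_id, locus, allele_a, allele_b) or
        ``"wide"`` (individual_id plus ``<locus>_a``/``<locus>_b`` pairs).
    """
    df = _read_df(source)
    if dialect == "long":
        missing_cols = set(_GENOTYPE_COLUMNS) - set(df.columns)
        if missing_cols:
            raise ValueError(f"genotype table lacks columns {sorted(missing_cols)}")
        rows = df[_GENOTYPE_COLUMNS].itertuples(index=False)
    elif dialect == "wide":
        loci = sorted(
            {c[:-2] for c in df.columns if c.endswith("_a")}
            & {c[:-2] for c in df.columns if c.endswith("_b")}
        )
        if "individual_id" not in df.columns or not loci:
            raise ValueError("wide genotype table needs individual_id and <locus>_a/_b pairs")
        rows = (
            (r["individual_id"], loc, r[f"{loc}_a"], r[f"{loc}_b"])
            for _, r in df.iterrows()
            for loc in loci
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    panel = GenotypePanel()
    for ind, locus, a, b in rows:
        try:
            ai, bi = int(a), int(b)
        except ValueError as exc:
            raise ValueError(f"non-integer allele for {ind}@{locus}: {a!r}/{b!r}") from exc
        panel.add(Genotype(str(ind), str(locus), ai, bi))
    return panel


def write_genotype_table(panel: GenotypePanel, path: str | Path) -> None:
    df = pd.DataFrame(
        [(g.individual_id, g.locus, g.allele_a, g.allele_b) for g in panel],
        columns=_GENOTYPE_COLUMNS,
    )
    df.to_csv(path, sep=_sep_for(str(path)), index=False)


def read_amplifications(source: str | Path) -> pd.DataFrame:
    """Per-amplification observations: sample_id, individual_id, locus,
    obs_allele_1, obs_allele_2 (0 = not seen / apparent homozygote)."""
    df = _read_df(source)
    required = {"sample_id", "individual_id", "locus", "obs_allele_1", "obs_allele_2"}
    if missing := required - set(df.columns):
        raise ValueError(f"amplification table lacks columns {sorted(missing)}")
    df["obs_allele_1"] = df["obs_allele_1"].astype(int)
    df["obs_allele_2"] = df["obs_allele_2"].astype(int)
    return df


def write_amplifications(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep=_sep_for(str(path)), index=False)


# ---------------------------------------------------------------------------
# demography


def _parse_date(s: str, what: str) -> _dt.date | None:
    s = s.strip()
    if not s:
        return None
    try:
        return _dt.date.fromisoformat(s)
    except ValueError as exc:
        raise ValueError(f"{what}: bad ISO date {s!r}") from exc


def read_individuals(source: str | Path) -> dict[str, Individual]:
    df = _read_df(source)
    out: dict[str, Individual] = {}
    for _, r in df.iterrows():
        ind = Individual(
            id=str(r["id"]),
            sex=Sex(r.get("sex", "U") or "U"),
            group=str(r["group"]) or None if "group" in r else None,
            natal_group=str(r.get("natal_group", "")) or None,
            birth_date=_parse_date(str(r.get("birth_date", "")), r["id"]),
            mother_id=str(r.get("mother_id", "")) or None,
            candidate_sire=str(r.get("candidate_sire", "")).lower()
            in ("1", "true", "yes"),
        )
        if ind.id in out:
            raise ValueError(f"duplicate individual id {ind.id}")
        out[ind.id] = ind
    return out


def read_residencies(source: str | Path) -> list[ResidencyRecord]:
    df = _read_df(source)
    return [
        ResidencyRecord(
            male_id=str(r["male_id"]),
            group=str(r["group"]),
            start_date=_parse_date(str(r["start_date"]), r["male_id"]),
            end_date=_parse_date(str(r["end_date"]), r["male_id"]),
        )
        for _, r in df.iterrows()
    ]


def read_offspring(source: str | Path) -> list[OffspringCase]:
    df = _read_df(source)
    return [
        OffspringCase(
            offspring_id=str(r["offspring_id"]),
            mother_id=str(r["mother_id"]),
            birth_group=str(r["birth_group"]),
            birth_date=_parse_date(str(r["birth_date"]), r["offspring_id"]),
            conception_date=_parse_date(str(r["conception_date"]), r["offspring_id"]),
        )
        for _, r in df.iterrows()
    ]


def read_demography(
    individuals: str | Path,
    residencies: str | Path,
    offspring: str | Path,
    dominance: Mapping[str, str | Path] | None = None,
) -> Demography:
    """Load and cross-validate the full demography bundle."""
    dom = {}
    for period, src in (dominance or {}).items():
        df = _read_df(src)
        df = df.set_index(df.columns[0]).astype(float)
        dom[period] = df
    return Demography(
        individuals=read_individuals(individuals),
        residencies=read_residencies(residencies),
        offspring_cases=read_offspring(offspring),
        dominance_periods=dom,
    )


def write_individuals(inds: Mapping[str, Individual], path: str | Path) -> None:
    rows = [
        {
            "id": i.id,
            "sex": i.sex.value,
            "group": i.group or "",
            "natal_group": i.natal_group or "",
            "birth_date": i.birth_date.isoformat() if i.birth_date else "",
            "mother_id": i.mother_id or "",
            "candidate_sire": int(i.candidate_sire),
        }
        for i in inds.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(str(path)), index=False)


def write_residencies(recs: Sequence[ResidencyRecord], path: str | Path) -> None:
    rows = [
        {
            "male_id": r.male_id,
            "group": r.group,
            "start_date": r.start_date.isoformat(),
            "end_date": r.end_date.isoformat(),
        }
        for r in recs
    ]
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(str(path)), index=False)


def write_offspring(cases: Sequence[OffspringCase], path: str | Path) -> None:
    rows = [
        {
            "offspring_id": c.offspring_id,
            "mother_id": c.mother_id,
            "birth_group": c.birth_group,
            "birth_date": c.birth_date.isoformat(),
            "conception_date": c.conception_date.isoformat(),
        }
        for c in cases
    ]
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(str(path)), index=False)


# ---------------------------------------------------------------------------
# GenePop export


def export_genepop(
    panel: GenotypePanel,
    pop_assignment: Mapping[str, str],
    title: str = "satskew export",
) -> str:
    """Serialise a panel in GenePop format (3 digits per allele).

    Allele lengths are recoded per locus as 1-based indices into the
    sorted allele registry, so arbitrary fragment lengths fit the
    3-digit code space.  Missing genotypes become ``000000``.  One POP
    block is emitted per group, groups in sorted order.
    """
    loci = list(panel.loci)
    codes: dict[str, dict[int, int]] = {}
    for locus in loci:
        registry = panel.allele_registry(locus)
        if len(registry) > 999:
            raise ValueError(f"{locus}: more than 999 distinct alleles")
        codes[locus] = {a: i + 1 for i, a in enumerate(registry)}

    lines = [title]
    lines.extend(loci)
    groups: dict[str, list[str]] = {}
    for ind in panel.individuals:
        groups.setdefault(pop_assignment.get(ind, "UNKNOWN"), []).append(ind)
    for group in sorted(groups):
        lines.append("POP")
        for ind in groups[group]:
            fields = []
            for locus in loci:
                g = panel.get(ind, locus)
                if g is None:
                    fields.append("000000")
                else:
                    fields.append(
                        f"{codes[locus][g.allele_a]:03d}{codes[locus][g.allele_b]:03d}"
                    )
            lines.append(f"{ind} ,  " + " ".join(fields))
    return "\n".join(lines) + "\n"
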