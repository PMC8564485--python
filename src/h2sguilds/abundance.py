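"""Species-level taxonomic profiles and per-sample guild abundance.

Species relative abundances come either from Kraken2-style report files
(one per sample) or from a generic species x sample TSV matrix of
fractions. A guild's abundance in a sample is the sum of the relative
abundances of its member species; its prevalence in a cohort is the
fraction of samples (or subjects) in which that sum is positive.

Fractions parsed from Kraken2 reports are recomputed from read counts —
clade reads at the requested rank divided by total reads (root clade plus
unclassified) — rather than trusting the report's rounded percentage
column.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, TextIO, Union

import numpy as np
import pandas as pd

from .classify import GenomeAnnotation
from .errors import DegenerateInputError, TableParseError

logger = logging.getLogger(__name__)

_COLSUM_TOL = 1e-9


class Guild(str, enum.Enum):
    """Functional guilds whose abundance is tracked per sample."""

    PRIMARY_CD = "primary_cd"
    SECONDARY_CD = "secondary_cd"
    ERRONEOUS_CD = "erroneous_cd"
    SRB = "srb"


#: GenomeAnnotation attribute backing each guild.
_GUILD_FLAG = {
    Guild.PRIMARY_CD: "is_primary_cd",
    Guild.SECONDARY_CD: "is_secondary_cd",
    Guild.ERRONEOUS_CD: "is_erroneous_cd",
    Guild.SRB: "is_srb",
}


@dataclass
class AbundanceMatrix:
    """Species x sample relative-abundance fractions with sample metadata.

    ``values`` is a DataFrame indexed by species id with one column per
    sample; entries are fractions in [0, 1] and each column sums to at
    most 1 (up to 1e-9). ``sample_meta`` maps sample id to a dict with at
    least ``cohort`` and optionally ``study`` and ``subject_id`` keys.
    """

    values: pd.DataFrame
    sample_meta: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise ValueError("duplicate species ids")
        if v.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        arr = v.to_numpy(dtype=float)
        if arr.size and (arr.min() < 0 or arr.max() > 1):
            raise ValueError("abundance fractions must lie in [0, 1]")
        if arr.size and (arr.sum(axis=0) > 1 + _COLSUM_TOL).any():
            raise ValueError("a sample's fractions sum to more than 1")

    @property
    def species_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def cohort_of(self, sample_id: str) -> str:
        return self.sample_meta[sample_id]["cohort"]

    def samples_in_cohort(self, cohort: str) -> list[str]:
        return [s for s in self.sample_ids
                if self.sample_meta.get(s, {}).get("cohort") == cohort]


@dataclass(frozen=True)
class GuildAbundance:
    """Per-sample summed relative abundance of one guild."""

    guild: Guild
    per_sample: dict[str, float]

    def vector(self, samples: Optional[Sequence[str]] = None) -> np.ndarray:
        keys = list(self.per_sample) if samples is None else list(samples)
        return np.array([self.per_sample[s] for s in keys], dtype=float)


def parse_kraken_report(
    stream: Union[TextIO, Iterable[str]], rank: str = "S"
) -> dict[str, float]:
    """Parse one Kraken2 report into a species -> fraction mapping.

    Expects the six-column report dialect (percent, clade reads, direct
    reads, rank code, taxid, indented name). Rows whose rank code equals
    *rank* (default ``"S"``, species) are retained; each fraction is
    clade reads divided by the total of root-assigned plus unclassified
    reads, recomputed from the count columns.
    """
    total = 0
    rows: list[tuple[str, int]] = []
    n_data = 0
    for line_no, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 6:
            raise TableParseError(
                f"expected 6 tab-separated columns, got {len(fields)}", line_no
            )
        try:
            clade_reads = int(fields[1])
        except ValueError:
            raise TableParseError(
                f"non-integer clade read count: {fields[1]!r}", line_no
            ) from None
        rank_code = fields[3].strip()
        name = fields[5].strip()
        n_data += 1
        if rank_code in ("U", "R"):
            total += clade_reads
        if rank_code == rank:
            rows.append((name, clade_reads))
    if n_data == 0 or total == 0:
        raise DegenerateInputError("report has zero total assigned reads")
    return {name: reads / total for name, reads in rows}


def matrix_from_kraken_reports(
    reports: Mapping[str, Union[TextIO, Iterable[str]]],
    sample_meta: Optional[Mapping[str, Mapping[str, str]]] = None,
    rank: str = "S",
) -> AbundanceMatrix:
    """Assemble an :class:`AbundanceMatrix` from per-sample report streams."""
    columns = {
        sample: parse_kraken_report(stream, rank=rank)
        for sample, stream in reports.items()
    }
    df = pd.DataFrame(columns).fillna(0.0)
    df = df.sort_index()
    meta = {s: dict(m) for s, m in (sample_meta or {}).items()}
    return AbundanceMatrix(values=df, sample_meta=meta)


def read_abundance_tsv(
    path: Union[str, Path],
    meta_path: Optional[Union[str, Path]] = None,
) -> AbundanceMatrix:
    """Read a generic abundance TSV (species rows, sample columns,
    fractions) plus an optional metadata TSV
    (sample_id, cohort[, study, subject_id])."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    meta: dict[str, dict[str, str]] = {}
    if meta_path is not None:
        mdf = pd.read_csv(meta_path, sep="\t", dtype=str)
        for _, row in mdf.iterrows():
            meta[row["sample_id"]] = {
                k: row[k] for k in mdf.columns if k != "sample_id" and pd.notna(row[k])
            }
    return AbundanceMatrix(values=df, sample_meta=meta)


def write_abundance_tsv(matrix: AbundanceMatrix, path: Union[str, Path],
                        meta_path: Optional[Union[str, Path]] = None) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="species_id")
    if meta_path is not None:
        keys = sorted({k for m in matrix.sample_meta.values() for k in m})
        rows = []
        for s in matrix.sample_ids:
            m = matrix.sample_meta.get(s, {})
            rows.append({"sample_id": s, **{k: m.get(k, "") for k in keys}})
        pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)


def guild_members(
    annotations: Iterable[GenomeAnnotation], guild: Guild
) -> frozenset[str]:
    """Genome ids carrying the guild flag."""
    flag = _GUILD_FLAG[guild]
    return frozenset(a.genome_id for a in annotations if getattr(a, flag))


def guild_abundance(
    matrix: AbundanceMatrix,
    annotations: Sequence[GenomeAnnotation],
    guild: Guild,
    species_map: Optional[Mapping[str, str]] = None,
) -> GuildAbundance:
    """Sum member-species fractions per sample for one guild.

    *species_map* translates the matrix's species ids to annotation genome
    ids; it defaults to the identity (species id == genome id, the UHGG
    convention). Species that resolve to no annotated genome are counted,
    logged and treated as non-members.
    """
    members = guild_members(annotations, guild)
    annotated = {a.genome_id for a in annotations}
    member_rows = []
    n_unresolved = 0
    for sp in matrix.species_ids:
        gid = species_map.get(sp, sp) if species_map is not None else sp
        if gid not in annotated:
            n_unresolved += 1
            continue
        if gid in members:
            member_rows.append(sp)
    if n_unresolved:
        logger.warning(
            "guild_abundance(%s): %d/%d species unresolved to an annotated "
            "genome; treated as non-members",
            guild.value, n_unresolved, len(matrix.species_ids),
        )
    if member_rows:
        sums = matrix.values.loc[member_rows].sum(axis=0)
    else:
        sums = pd.Series(0.0, index=matrix.values.columns)
    return GuildAbundance(
        guild=guild,
        per_sample={s: float(sums[s]) for s in matrix.sample_ids},
    )


def prevalence(
    ga: GuildAbundance,
    samples: Optional[Sequence[str]] = None,
    subject_of: Optional[Mapping[str, str]] = None,
) -> float:
    """Fraction of samples (or subjects) with positive guild abundance.

    With *subject_of* (sample id -> subject id), samples collapse to
    subjects and a subject is positive when any of its samples is — the
    convention used when prevalence is quoted per subject rather than per
    sample.
    """
    keys = list(ga.per_sample) if samples is None else list(samples)
    if not keys:
        raise ValueError("prevalence of an empty sample set")
    missing = [s for s in keys if s not in ga.per_sample]
    if missing:
        raise KeyError(f"samples not in guild abundance: {missing[:5]}")
    if subject_of is None:
        positive = sum(ga.per_sample[s] > 0 for s in keys)
        return positive / len(keys)
    by_subject: dict[str, bool] = {}
    for s in keys:
        subj = subject_of.get(s, s)
        by_subject[subj] = by_subject.get(subj, False) or ga.per_sample[s] > 0
    return sum(by_subject.values()) / len(by_subject)
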