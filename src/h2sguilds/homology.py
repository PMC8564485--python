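"""Profile-HMM homology hits: parsing HMMER tabular output and filtering.

Genomes are annotated by searching each proteome against the catalog's
profile HMMs with ``hmmscan`` (profiles as targets, proteins as queries).
This module consumes the resulting ``--tblout`` / ``--domtblout`` files and
applies a source-aware filtering policy:

* every hit must pass a conservative E-value ceiling (default
  ``E < 1e-110``, strict inequality);
* hits to TIGRFAM profiles must additionally meet the family's bit-score
  floor (non-strict, ``score >= floor``);
* hits to HAMAP and custom profiles are filtered on E-value alone.

Scoring of the profiles themselves is out of scope — use HMMER (or the
optional :func:`run_hmmscan` subprocess adapter) to produce the tables.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, TextIO, Union

from .catalog import GeneCatalog, PhmmSource
from .errors import HmmerParseError

logger = logging.getLogger(__name__)

#: Default E-value ceiling (hits kept only when strictly below it).
DEFAULT_E_MAX = 1e-110

# column indices in HMMER 3 tabular output (hmmscan orientation:
# target = profile, query = protein)
_TBLOUT_MIN_FIELDS = 18
_DOMTBLOUT_MIN_FIELDS = 22


@dataclass(frozen=True)
class ProfileHit:
    """A single homology hit of a profile HMM against one protein."""

    genome_id: str
    protein_id: str
    phmm_id: str
    e_value: float
    bit_score: float
    gene_symbol: Optional[str] = None  # resolved against a catalog in filter_hits

    def __post_init__(self) -> None:
        if self.e_value <= 0:
            raise ValueError(f"e_value must be positive, got {self.e_value}")
        if not self.genome_id or not self.phmm_id:
            raise ValueError("genome_id and phmm_id must be non-empty")


@dataclass(frozen=True)
class FilterPolicy:
    """Hit-retention policy.

    ``e_max`` is the E-value ceiling (strict ``<``). ``apply_bit_floor_to``
    lists the profile sources whose catalog bit-score floors are enforced;
    by default only TIGRFAM.
    """

    e_max: float = DEFAULT_E_MAX
    apply_bit_floor_to: frozenset[PhmmSource] = frozenset({PhmmSource.TIGRFAM})

    def __post_init__(self) -> None:
        if self.e_max <= 0:
            raise ValueError("e_max must be positive")


def _split_query(query_name: str, genome_id: Optional[str]) -> tuple[str, str]:
    """Resolve (genome_id, protein_id) from a query name.

    When *genome_id* is not supplied, query names of the form
    ``"<genome>|<protein>"`` are split at the first ``|``; otherwise the
    whole name serves as both genome and protein id.
    """
    if genome_id is not None:
        return genome_id, query_name
    if "|" in query_name:
        g, p = query_name.split("|", 1)
        return g, p
    return query_name, query_name


def _parse_float(raw: str, what: str, line_no: int) -> float:
    try:
        return float(raw)
    except ValueError:
        raise HmmerParseError(f"non-numeric {what}: {raw!r}", line_no) from None


def parse_hmmer_table(
    stream: Union[TextIO, Iterable[str]],
    dialect: str = "tblout",
    genome_id: Optional[str] = None,
) -> list[ProfileHit]:
    """Parse HMMER 3 ``tblout`` or ``domtblout`` text into hits.

    ``tblout`` rows yield one hit each, using the full-sequence E-value and
    score (columns 5-6). ``domtblout`` rows are collapsed to the best domain
    per (protein, profile) pair by smallest independent E-value (column 13),
    ties broken by higher bit score then lexicographic protein id. ``#``
    comment lines are skipped; row order is preserved.

    Raises :class:`HmmerParseError` with the offending 1-based line number
    on malformed rows, and :class:`ValueError` on an unknown dialect.
    """
    if dialect not in ("tblout", "domtblout"):
        raise ValueError(f"unknown dialect {dialect!r}; expected tblout or domtblout")

    hits: list[ProfileHit] = []
    # domtblout: best row per (protein, phmm), remembering first-seen order
    best: dict[tuple[str, str], tuple[float, float, str, ProfileHit]] = {}
    order: list[tuple[str, str]] = []

    for line_no, line in enumerate(stream, start=1):
        if line.startswith("#") or not line.strip():
            continue
        fields = line.split()
        if dialect == "tblout":
            if len(fields) < _TBLOUT_MIN_FIELDS:
                raise HmmerParseError(
                    f"expected >= {_TBLOUT_MIN_FIELDS} columns, got {len(fields)}",
                    line_no,
                )
            phmm, query = fields[0], fields[2]
            e = _parse_float(fields[4], "E-value", line_no)
            score = _parse_float(fields[5], "bit score", line_no)
            g, p = _split_query(query, genome_id)
            try:
                hits.append(
                    ProfileHit(
                        genome_id=g, protein_id=p, phmm_id=phmm,
                        e_value=e, bit_score=score,
                    )
                )
            except ValueError as exc:
                raise HmmerParseError(str(exc), line_no) from None
        else:
            if len(fields) < _DOMTBLOUT_MIN_FIELDS:
                raise HmmerParseError(
                    f"expected >= {_DOMTBLOUT_MIN_FIELDS} columns, got {len(fields)}",
                    line_no,
                )
            phmm, query = fields[0], fields[3]
            e = _parse_float(fields[12], "independent E-value", line_no)
            score = _parse_float(fields[13], "domain bit score", line_no)
            g, p = _split_query(query, genome_id)
            try:
                hit = ProfileHit(
                    genome_id=g, protein_id=p, phmm_id=phmm,
                    e_value=e, bit_score=score,
                )
            except ValueError as exc:
                raise HmmerParseError(str(exc), line_no) from None
            key = (p, phmm)
            cand = (e, -score, p, hit)
            if key not in best:
                best[key] = cand
                order.append(key)
            elif cand[:3] < best[key][:3]:
                best[key] = cand

    if dialect == "domtblout":
        hits = [best[k][3] for k in order]
    return hits


def filter_hits(
    hits: Iterable[ProfileHit],
    catalog: GeneCatalog,
    policy: FilterPolicy = FilterPolicy(),
) -> list[ProfileHit]:
    """Apply the source-aware retention policy; resolve gene symbols.

    Hits whose ``phmm_id`` has no catalog entry are dropped (counted in the
    log, never raising). Retained hits satisfy ``e_value < policy.e_max``
    and, for profiles whose source is in ``policy.apply_bit_floor_to`` and
    which carry a floor, ``bit_score >= floor``. The output is a subset of
    the input (order preserved) with ``gene_symbol`` filled in. Filtering
    is idempotent.
    """
    kept: list[ProfileHit] = []
    n_unresolved = 0
    n_in = 0
    for hit in hits:
        n_in += 1
        entry = catalog.entry_for_phmm(hit.phmm_id)
        if entry is None and hit.gene_symbol is not None:
            try:
                entry = catalog.entry(hit.gene_symbol)
            except KeyError:
                entry = None
        if entry is None:
            n_unresolved += 1
            continue
        if not (hit.e_value < policy.e_max):
            continue
        if (
            entry.phmm_source in policy.apply_bit_floor_to
            and entry.bit_score_min is not None
            and hit.bit_score < entry.bit_score_min
        ):
            continue
        kept.append(replace(hit, gene_symbol=entry.symbol))
    if n_unresolved:
        logger.warning(
            "filter_hits: dropped %d/%d hits with phmm_ids absent from catalog "
            "version %s", n_unresolved, n_in, catalog.version,
        )
    logger.info("filter_hits: retained %d of %d hits", len(kept), n_in)
    return kept


def genes_present(hits: Iterable[ProfileHit]) -> dict[str, set[str]]:
    """Group filtered hits into a genome -> gene-set mapping (deduplicated).

    Only genomes with at least one hit appear. Hits must already be
    filtered and symbol-resolved (``gene_symbol`` set).
    """
    out: dict[str, set[str]] = {}
    for hit in hits:
        if hit.gene_symbol is None:
            raise ValueError(
                f"hit {hit.phmm_id} on {hit.genome_id} has no resolved gene "
                "symbol; run filter_hits first"
            )
        out.setdefault(hit.genome_id, set()).add(hit.gene_symbol)
    return out


def write_hit_table(hits: Iterable[ProfileHit], dest: Union[str, Path]) -> None:
    """Write hits as a TSV (genome_id, protein_id, gene_symbol, phmm_id,
    e_value, bit_score)."""
    lines = ["genome_id\tprotein_id\tgene_symbol\tphmm_id\te_value\tbit_score"]
    for h in hits:
        lines.append(
            f"{h.genome_id}\t{h.protein_id}\t{h.gene_symbol or ''}\t"
            f"{h.phmm_id}\t{h.e_value:.6g}\t{h.bit_score:.6g}"
        )
    Path(dest).write_text("\n".join(lines) + "\n", encoding="utf-8")


# -- optional subprocess adapters (never required by tests) ----------------

def hmmer_available() -> bool:
    return shutil.which("hmmscan") is not None


def run_hmmscan(
    hmm_db: Union[str, Path],
    proteome_fasta: Union[str, Path],
    tblout: Union[str, Path],
    extra_args: tuple[str, ...] = (),
) -> None:
    """Invoke ``hmmscan`` writing a ``--tblout`` table. Requires the HMMER
    binaries on PATH; raises :class:`RuntimeError` when absent."""
    if not hmmer_available():
        raise RuntimeError("hmmscan not found on PATH")
    subprocess.run(
        ["hmmscan", "--tblout", str(tblout), *extra_args, str(hmm_db),
         str(proteome_fasta)],
        check=True, capture_output=True,
    )


def run_hmmbuild(
    msa: Union[str, Path], hmm_out: Union[str, Path], name: Optional[str] = None
) -> None:
    """Invoke ``hmmbuild`` to construct a custom profile from an alignment."""
    if shutil.which("hmmbuild") is None:
        raise RuntimeError("hmmbuild not found on PATH")
    args = ["hmmbuild"]
    if name:
        args += ["-n", name]
    args += [str(hmm_out), str(msa)]
    subprocess.run(args, check=True, capture_output=True)
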