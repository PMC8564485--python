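"""Guild classification of genomes from gene content.

A genome is a putative *primary*, *secondary* or *erroneous* cysteine
degrader when it carries at least one gene of the corresponding catalog
tier, and a sulfate-reducing bacterium (SRB) when it carries the
dissimilatory sulfite reductase operon. The guild labels are not mutually
exclusive. The default SRB rule requires both *dsrA* and *dsrB* (an operon
reading); ``srb_rule="either"`` relaxes this to a single subunit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Sequence, Union

from .catalog import GeneCatalog, Tier
from .errors import ConsistencyError

logger = logging.getLogger(__name__)

SrbRule = Literal["both", "either"]


@dataclass(frozen=True)
class GenomeAnnotation:
    """A genome's marker-gene content and derived guild flags.

    Construct through :func:`classify_genome` — flags are derived from
    gene content, never set freely.
    """

    genome_id: str
    genes: frozenset[str]
    species_label: str = ""
    is_primary_cd: bool = False
    is_secondary_cd: bool = False
    is_erroneous_cd: bool = False
    is_srb: bool = False


@dataclass(frozen=True)
class TierCensus:
    """Catalog-wide counts of guild membership with printed percentages."""

    n_genomes: int
    n_primary: int
    n_secondary: int
    n_erroneous: int
    n_srb: int

    @property
    def pct_primary(self) -> float:
        return round(100.0 * self.n_primary / self.n_genomes, 1)

    @property
    def pct_secondary(self) -> float:
        return round(100.0 * self.n_secondary / self.n_genomes, 1)

    @property
    def pct_erroneous(self) -> float:
        return round(100.0 * self.n_erroneous / self.n_genomes, 1)


def classify_genome(
    genome_id: str,
    genes: Iterable[str],
    catalog: GeneCatalog,
    species_label: str = "",
    srb_rule: SrbRule = "both",
) -> GenomeAnnotation:
    """Derive guild flags for one genome from its marker-gene set.

    Gene symbols absent from the catalog are ignored (logged). Flags are
    monotone in gene content: adding a gene can only switch flags on.
    """
    gene_set = frozenset(genes)
    known = set(catalog.symbols())
    unknown = gene_set - known
    if unknown:
        logger.warning(
            "classify_genome(%s): ignoring %d symbols not in catalog: %s",
            genome_id, len(unknown), ", ".join(sorted(unknown)),
        )
        gene_set = gene_set & known

    dsr_genes = catalog.genes_in_tier(Tier.DSR)
    present_dsr = gene_set & dsr_genes
    if srb_rule == "both":
        is_srb = bool(dsr_genes) and present_dsr == dsr_genes
    elif srb_rule == "either":
        is_srb = bool(present_dsr)
    else:
        raise ValueError(f"srb_rule must be 'both' or 'either', got {srb_rule!r}")

    return GenomeAnnotation(
        genome_id=genome_id,
        genes=gene_set,
        species_label=species_label,
        is_primary_cd=bool(gene_set & catalog.genes_in_tier(Tier.PRIMARY)),
        is_secondary_cd=bool(gene_set & catalog.genes_in_tier(Tier.SECONDARY)),
        is_erroneous_cd=bool(gene_set & catalog.genes_in_tier(Tier.ERRONEOUS)),
        is_srb=is_srb,
    )


def classify_all(
    gene_map: Mapping[str, Iterable[str]],
    catalog: GeneCatalog,
    universe: Optional[Sequence[str]] = None,
    species_labels: Optional[Mapping[str, str]] = None,
    srb_rule: SrbRule = "both",
) -> list[GenomeAnnotation]:
    """Classify every genome independently; deterministic order by genome id.

    When *universe* is given it must contain every key of *gene_map*;
    genomes in the universe without hits are annotated with empty gene sets
    (all flags false).
    """
    if universe is not None:
        missing = set(gene_map) - set(universe)
        if missing:
            raise ConsistencyError(
                f"universe is missing {len(missing)} genome(s) present in "
                f"gene_map, e.g. {sorted(missing)[:5]}"
            )
        genome_ids = sorted(set(universe))
    else:
        genome_ids = sorted(gene_map)
    labels = species_labels or {}
    return [
        classify_genome(
            gid, gene_map.get(gid, ()), catalog,
            species_label=labels.get(gid, ""), srb_rule=srb_rule,
        )
        for gid in genome_ids
    ]


def census(annotations: Sequence[GenomeAnnotation]) -> TierCensus:
    """Count guild members across annotations.

    Permutation-invariant; raises on an empty collection. Percentages are
    rounded to one decimal for printing; raw counts are retained.
    """
    if not annotations:
        raise ValueError("census of an empty annotation collection")
    return TierCensus(
        n_genomes=len(annotations),
        n_primary=sum(a.is_primary_cd for a in annotations),
        n_secondary=sum(a.is_secondary_cd for a in annotations),
        n_erroneous=sum(a.is_erroneous_cd for a in annotations),
        n_srb=sum(a.is_srb for a in annotations),
    )


def write_annotation_table(
    annotations: Iterable[GenomeAnnotation], dest: Union[str, Path]
) -> None:
    """Write annotations as TSV (genes comma-joined and sorted, flags 0/1)."""
    lines = [
        "genome_id\tspecies_label\tgenes\tis_primary_cd\tis_secondary_cd"
        "\tis_erroneous_cd\tis_srb"
    ]
    for a in annotations:
        lines.append(
            f"{a.genome_id}\t{a.species_label}\t{','.join(sorted(a.genes))}\t"
            f"{int(a.is_primary_cd)}\t{int(a.is_secondary_cd)}\t"
            f"{int(a.is_erroneous_cd)}\t{int(a.is_srb)}"
        )
    Path(dest).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_annotation_table(source: Union[str, Path]) -> list[GenomeAnnotation]:
    """Read a TSV written by :func:`write_annotation_table`."""
    lines = Path(source).read_text(encoding="utf-8").splitlines()
    out = []
    for line in lines[1:]:
        gid, label, genes, p, s, e, srb = line.split("\t")
        out.append(
            GenomeAnnotation(
                genome_id=gid,
                species_label=label,
                genes=frozenset(g for g in genes.split(",") if g),
                is_primary_cd=bool(int(p)),
                is_secondary_cd=bool(int(s)),
                is_erroneous_cd=bool(int(e)),
                is_srb=bool(int(srb)),
            )
        )
    return out
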