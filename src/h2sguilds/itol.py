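"""iTOL EXTERNALSHAPE dataset export of per-genome gene presence.

Renders genome annotations as an iTOL external-shapes dataset for display
alongside a taxonomic tree: one field per marker gene, colored by tier
(green = primary, yellow = secondary, red = erroneous; dsr in blue), one
data row per genome with 1/0 presence values. A parser for the same
format supports round-trip checks and re-ingestion.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .catalog import GeneCatalog, Tier
from .classify import GenomeAnnotation

TIER_COLORS = {
    Tier.PRIMARY: "#4daf4a",      # green
    Tier.SECONDARY: "#ffd92f",    # yellow
    Tier.ERRONEOUS: "#e41a1c",    # red
    Tier.DSR: "#377eb8",          # blue
    Tier.METHANOGENESIS: "#999999",
}

_DEFAULT_TIERS = (Tier.PRIMARY, Tier.SECONDARY, Tier.ERRONEOUS, Tier.DSR)


def write_itol_externalshape(
    annotations: Sequence[GenomeAnnotation],
    catalog: GeneCatalog,
    dest: Union[str, Path],
    genes: Optional[Sequence[str]] = None,
    dataset_label: str = "H2S gene presence",
) -> None:
    """Write an EXTERNALSHAPE dataset file for *annotations*.

    *genes* defaults to the catalog's cysteine-degradation and dsr genes
    in catalog order. Raises on an empty annotation collection.
    """
    if not annotations:
        raise ValueError("cannot export an empty annotation collection")
    if genes is None:
        genes = [
            e.symbol for e in catalog.entries if e.tier in _DEFAULT_TIERS
        ]
    colors = [TIER_COLORS[catalog.tier_of(g)] for g in genes]
    lines = [
        "DATASET_EXTERNALSHAPE",
        "SEPARATOR COMMA",
        f"DATASET_LABEL,{dataset_label}",
        "COLOR,#4daf4a",
        "FIELD_LABELS," + ",".join(genes),
        "FIELD_COLORS," + ",".join(colors),
        "DATA",
    ]
    for a in annotations:
        presence = ((str(int(g in a.genes))) for g in genes)
        lines.append(f"{a.genome_id}," + ",".join(presence))
    Path(dest).write_text("\n".join(lines) + "\n", encoding="utf-8")


def parse_itol_externalshape(
    source: Union[str, Path],
) -> tuple[list[str], dict[str, set[str]]]:
    """Parse an EXTERNALSHAPE file back into (field genes, genome -> genes
    with nonzero presence)."""
    lines = Path(source).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].strip() != "DATASET_EXTERNALSHAPE":
        raise ValueError("not an EXTERNALSHAPE dataset")
    sep = ","
    genes: list[str] = []
    presence: dict[str, set[str]] = {}
    in_data = False
    for line in lines[1:]:
        if not line.strip():
            continue
        if line.startswith("SEPARATOR"):
            sep = {"COMMA": ",", "TAB": "\t", "SPACE": " "}[
                line.split(None, 1)[1].strip()
            ]
            continue
        if not in_data and line.split(sep)[0] == "FIELD_LABELS":
            genes = line.split(sep)[1:]
            continue
        if line.strip() == "DATA":
            in_data = True
            continue
        if in_data:
            parts = line.split(sep)
            gid, values = parts[0], parts[1:]
            if len(values) != len(genes):
                raise ValueError(
                    f"row for {gid} has {len(values)} fields, expected "
                    f"{len(genes)}"
                )
            presence[gid] = {
                g for g, v in zip(genes, values) if float(v) != 0
            }
    return genes, presence
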