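"""Gene catalog: which genes mark which hydrogen sulfide producing guild.

The catalog is data, not code. It ships as a versioned TSV
(``data/default_catalog.tsv``) listing, for every marker gene, its guild
tier, the profile HMM used to detect it, the profile's source database and
an optional bit-score floor. Three cysteine-degradation tiers are
distinguished by how central H2S release is to the enzyme's function:

``primary``
    enzymes whose main activity degrades cysteine to H2S
    (*dcyD*, *yhaM*, *mgl*, *sseA*);
``secondary``
    enzymes that release H2S but also participate in other pathways
    (*metC*, *malY*, *cysK*, *cysM*, *mccB*);
``erroneous``
    enzymes with a well-defined non-H2S main function
    (*tnaA*, *iscS*, *mccA*).

Two further tiers carry the dissimilatory sulfate reduction operon
(``dsr``: *dsrA*, *dsrB*) and a 16-gene methanogenesis panel used for
metatranscriptomic methane calling.

Bit-score floors only ever apply to TIGRFAM profiles; HAMAP and custom
profiles are filtered on E-value alone (see :mod:`h2sguilds.homology`).
"""

from __future__ import annotations

import csv
import enum
import io
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, TextIO, Union

from .errors import CatalogSchemaError, CatalogValidationError

#: Conservative fallback bit-score floor for TIGRFAM profiles whose
#: per-family threshold is not given in the catalog file.
DEFAULT_TIGRFAM_BIT_FLOOR = 25.0

_REQUIRED_COLUMNS = ("symbol", "tier", "phmm_id", "phmm_source", "bit_score_min")


class Tier(str, enum.Enum):
    """Functional tier of a marker gene."""

    PRIMARY = "primary"
    SECONDARY = "secondary"
    ERRONEOUS = "erroneous"
    DSR = "dsr"
    METHANOGENESIS = "methanogenesis"


class PhmmSource(str, enum.Enum):
    """Database of origin of a profile HMM."""

    TIGRFAM = "TIGRFAM"
    HAMAP = "HAMAP"
    CUSTOM = "custom"


@dataclass(frozen=True)
class GeneDefinition:
    """One catalog entry.

    Parameters
    ----------
    symbol
        Gene name, e.g. ``"mgl"``. Unique within a catalog.
    tier
        Functional tier of the gene.
    phmm_id
        Identifier of the profile HMM used to detect the gene.
    phmm_source
        Database the profile comes from. Bit-score floors are only
        meaningful for TIGRFAM profiles.
    bit_score_min
        Optional per-family bit-score floor (bits, non-negative). Must be
        absent for non-TIGRFAM profiles.
    notes
        Free-text annotation.
    """

    symbol: str
    tier: Tier
    phmm_id: str
    phmm_source: PhmmSource
    bit_score_min: Optional[float] = None
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.symbol:
            raise CatalogValidationError("gene symbol must be non-empty")
        if not self.phmm_id:
            raise CatalogValidationError(f"{self.symbol}: phmm_id must be non-empty")
        if self.bit_score_min is not None:
            if self.phmm_source is not PhmmSource.TIGRFAM:
                raise CatalogValidationError(
                    f"{self.symbol}: bit_score_min is only valid for TIGRFAM "
                    f"profiles, not {self.phmm_source.value}"
                )
            if self.bit_score_min < 0:
                raise CatalogValidationError(
                    f"{self.symbol}: bit_score_min must be non-negative"
                )


@dataclass(frozen=True)
class GeneCatalog:
    """An ordered, validated collection of :class:`GeneDefinition`.

    Invariants enforced at construction: at least one entry; no duplicate
    symbols; no profile id mapped to two different symbols. Every symbol
    belongs to exactly one tier (tiers partition the catalog).
    """

    entries: tuple[GeneDefinition, ...]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        if not self.entries:
            raise CatalogValidationError("catalog has no entries")
        seen_symbols: set[str] = set()
        phmm_to_symbol: dict[str, str] = {}
        for e in self.entries:
            if e.symbol in seen_symbols:
                raise CatalogValidationError(f"duplicate symbol: {e.symbol}")
            seen_symbols.add(e.symbol)
            prev = phmm_to_symbol.get(e.phmm_id)
            if prev is not None and prev != e.symbol:
                raise CatalogValidationError(
                    f"phmm_id {e.phmm_id} mapped to both {prev} and {e.symbol}"
                )
            phmm_to_symbol[e.phmm_id] = e.symbol

    # -- lookups ---------------------------------------------------------

    def symbols(self) -> tuple[str, ...]:
        return tuple(e.symbol for e in self.entries)

    def entry(self, symbol: str) -> GeneDefinition:
        for e in self.entries:
            if e.symbol == symbol:
                return e
        raise KeyError(
            f"unknown gene symbol {symbol!r}; known symbols: "
            f"{', '.join(self.symbols())}"
        )

    def tier_of(self, symbol: str) -> Tier:
        """Tier of *symbol*; raises :class:`KeyError` listing known symbols."""
        return self.entry(symbol).tier

    def genes_in_tier(self, tier: Tier) -> frozenset[str]:
        return frozenset(e.symbol for e in self.entries if e.tier is tier)

    def entry_for_phmm(self, phmm_id: str) -> Optional[GeneDefinition]:
        for e in self.entries:
            if e.phmm_id == phmm_id:
                return e
        return None

    def methanogenesis_genes(self) -> tuple[str, ...]:
        """The methanogenesis panel, in catalog order."""
        return tuple(
            e.symbol for e in self.entries if e.tier is Tier.METHANOGENESIS
        )

    def with_overrides(self, overrides: Mapping[str, object]) -> "GeneCatalog":
        """Return a copy with threshold overrides applied (idempotent).

        Supported keys:

        ``"bit_score_min"``
            mapping of gene symbol to a new floor (or ``None`` to clear it);
        ``"default_bit_score_min"``
            floor applied to TIGRFAM entries whose floor is unset;
        ``"version"``
            replacement version string.
        """
        unknown = set(overrides) - {"bit_score_min", "default_bit_score_min", "version"}
        if unknown:
            raise CatalogValidationError(f"unknown override keys: {sorted(unknown)}")
        per_symbol = dict(overrides.get("bit_score_min", {}))  # type: ignore[arg-type]
        missing = set(per_symbol) - set(self.symbols())
        if missing:
            raise CatalogValidationError(
                f"bit_score_min override for unknown symbols: {sorted(missing)}"
            )
        default_floor = overrides.get("default_bit_score_min")
        new_entries = []
        for e in self.entries:
            if e.symbol in per_symbol:
                e = replace(e, bit_score_min=per_symbol[e.symbol])
            elif (
                default_floor is not None
                and e.phmm_source is PhmmSource.TIGRFAM
                and e.bit_score_min is None
            ):
                e = replace(e, bit_score_min=float(default_floor))  # type: ignore[arg-type]
            new_entries.append(e)
        version = str(overrides.get("version", self.version))
        return GeneCatalog(entries=tuple(new_entries), version=version)


def _coerce_tier(raw: str, line: int) -> Tier:
    try:
        return Tier(raw)
    except ValueError:
        raise CatalogValidationError(
            f"line {line}: unknown tier {raw!r}; expected one of "
            f"{[t.value for t in Tier]}"
        ) from None


def _coerce_source(raw: str, line: int) -> PhmmSource:
    try:
        return PhmmSource(raw)
    except ValueError:
        raise CatalogValidationError(
            f"line {line}: unknown phmm_source {raw!r}; expected one of "
            f"{[s.value for s in PhmmSource]}"
        ) from None


def load_catalog(
    source: Union[str, Path, TextIO],
    overrides: Optional[Mapping[str, object]] = None,
) -> GeneCatalog:
    """Load and validate a gene catalog from a TSV file.

    The file is UTF-8, tab-separated, with a header row and columns
    ``symbol``, ``tier``, ``phmm_id``, ``phmm_source``, ``bit_score_min``
    (empty cell = no floor) and optionally ``notes``. Leading ``#`` lines
    are comments; a ``#version=<string>`` line sets the catalog version.

    TIGRFAM entries without an explicit bit-score floor receive
    :data:`DEFAULT_TIGRFAM_BIT_FLOOR`; pass
    ``overrides={"default_bit_score_min": x}`` or a per-symbol
    ``{"bit_score_min": {...}}`` mapping to change thresholds without
    editing the file. Applying the same overrides twice is a no-op.
    """
    if hasattr(source, "read"):
        text = source.read()  # type: ignore[union-attr]
    else:
        text = Path(source).read_text(encoding="utf-8")  # type: ignore[arg-type]

    version = "unversioned"
    data_lines: list[tuple[int, str]] = []
    for i, line in enumerate(text.splitlines(), start=1):
        if line.startswith("#"):
            if line.startswith("#version="):
                version = line[len("#version=") :].strip()
            continue
        if line.strip() == "":
            continue
        data_lines.append((i, line))

    if not data_lines:
        raise CatalogSchemaError("catalog file has no header row")

    header_line_no, header = data_lines[0]
    columns = header.split("\t")
    for col in _REQUIRED_COLUMNS:
        if col not in columns:
            raise CatalogSchemaError(f"missing required column: {col!r}")

    reader = csv.DictReader(
        io.StringIO("\n".join(line for _, line in data_lines)), delimiter="\t"
    )
    entries: list[GeneDefinition] = []
    for (line_no, _), row in zip(data_lines[1:], reader):
        raw_floor = (row.get("bit_score_min") or "").strip()
        floor: Optional[float]
        if raw_floor == "":
            floor = None
        else:
            try:
                floor = float(raw_floor)
            except ValueError:
                raise CatalogValidationError(
                    f"line {line_no}: bit_score_min {raw_floor!r} is not a number"
                ) from None
        source_db = _coerce_source((row.get("phmm_source") or "").strip(), line_no)
        if floor is None and source_db is PhmmSource.TIGRFAM:
            floor = float(
                (overrides or {}).get(
                    "default_bit_score_min", DEFAULT_TIGRFAM_BIT_FLOOR
                )  # type: ignore[arg-type]
            )
        entries.append(
            GeneDefinition(
                symbol=(row.get("symbol") or "").strip(),
                tier=_coerce_tier((row.get("tier") or "").strip(), line_no),
                phmm_id=(row.get("phmm_id") or "").strip(),
                phmm_source=source_db,
                bit_score_min=floor,
                notes=(row.get("notes") or "").strip(),
            )
        )

    if not entries:
        raise CatalogValidationError("no entries")
    catalog = GeneCatalog(entries=tuple(entries), version=version)
    if overrides:
        catalog = catalog.with_overrides(overrides)
    return catalog


def write_catalog(catalog: GeneCatalog, dest: Union[str, Path, TextIO]) -> None:
    """Write *catalog* as TSV; ``load_catalog`` round-trips the output."""
    buf = io.StringIO()
    buf.write(f"#version={catalog.version}\n")
    buf.write("\t".join(_REQUIRED_COLUMNS + ("notes",)) + "\n")
    for e in catalog.entries:
        floor = "" if e.bit_score_min is None else repr(e.bit_score_min)
        buf.write(
            "\t".join(
                (e.symbol, e.tier.value, e.phmm_id, e.phmm_source.value, floor, e.notes)
            )
            + "\n"
        )
    if hasattr(dest, "write"):
        dest.write(buf.getvalue())  # type: ignore[union-attr]
    else:
        Path(dest).write_text(buf.getvalue(), encoding="utf-8")  # type: ignore[arg-type]


def default_catalog(
    overrides: Optional[Mapping[str, object]] = None,
) -> GeneCatalog:
    """The shipped default catalog (12 cysteine-degradation genes, the dsrAB
    operon, and an example 16-gene methanogenesis panel)."""
    ref = resources.files("h2sguilds").joinpath("data/default_catalog.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        return load_catalog(fh, overrides=overrides)
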