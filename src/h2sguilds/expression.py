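"""Metatranscriptomic expression calling.

Raw per-gene read counts (from a quantifier such as salmon, or any count
table) are normalized to transcripts per million (TPM):

    TPM[g, s] = 1e6 * (counts[g, s] / length[g]) / sum_g' (counts[g', s] / length[g'])

A marker gene counts as *expressed* in a sample when its TPM is at least
10 (non-strict boundary). A sample expresses a guild tier when at least
one gene of that tier is expressed; dissimilatory sulfate reduction
requires both *dsrA* and *dsrB* by default. A sample is called *methane
producing* when at least 80% of the 16-gene methanogenesis panel recruits
one or more raw reads — note this rule deliberately uses read recruitment,
not the TPM threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Literal, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .catalog import GeneCatalog, Tier
from .errors import ConsistencyError

logger = logging.getLogger(__name__)

#: TPM at or above which a gene is called expressed.
DEFAULT_TPM_THRESHOLD = 10.0

#: Fraction of the methanogenesis panel that must recruit reads.
DEFAULT_METHANOGENESIS_FRACTION = 0.8


def tpm_from_counts(
    counts: pd.DataFrame, lengths: Mapping[str, float]
) -> pd.DataFrame:
    """TPM-normalize a gene x sample count matrix.

    *lengths* maps each gene id to its (effective) length in bases. Each
    nonzero sample column of the result sums to 1e6; an all-zero column
    stays all-zero with a logged warning.
    """
    lens = pd.Series({g: float(lengths[g]) for g in counts.index}, dtype=float)
    if (lens <= 0).any():
        bad = list(lens.index[lens <= 0])[:5]
        raise ValueError(f"gene lengths must be positive; offending: {bad}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    rate = counts.div(lens, axis=0)
    denom = rate.sum(axis=0)
    zero_cols = denom[denom == 0].index
    if len(zero_cols):
        logger.warning(
            "tpm_from_counts: %d all-zero sample column(s): %s",
            len(zero_cols), list(zero_cols)[:5],
        )
    denom = denom.replace(0.0, np.nan)
    return (rate.div(denom, axis=1) * 1e6).fillna(0.0)


@dataclass
class ExpressionMatrix:
    """Gene x sample read counts plus per-gene effective lengths.

    ``tpm`` is derived lazily from counts and lengths; counts are
    authoritative.
    """

    counts: pd.DataFrame
    lengths: dict[str, float]
    _tpm: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        missing = set(self.counts.index) - set(self.lengths)
        if missing:
            raise ValueError(f"genes without lengths: {sorted(missing)[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def tpm(self) -> pd.DataFrame:
        if self._tpm is None:
            self._tpm = tpm_from_counts(self.counts, self.lengths)
        return self._tpm


@dataclass(frozen=True)
class SampleCall:
    """Per-sample expression calls; built by :func:`sample_tier_expression`."""

    sample_id: str
    expresses_primary: bool = False
    expresses_secondary: bool = False
    expresses_erroneous: bool = False
    expresses_dsr: bool = False
    is_methanogenic: bool = False


def read_quant_sf(
    path: Union[str, Path],
    tpm_rel_tol: float = 1e-3,
    strict: bool = False,
) -> pd.DataFrame:
    """Read one salmon ``quant.sf`` table (Name, Length, EffectiveLength,
    TPM, NumReads).

    TPM is recomputed from NumReads and EffectiveLength and compared to
    the file's TPM column as a provenance check; deviations beyond
    *tpm_rel_tol* (relative, default 0.1%) are logged, or raised when
    ``strict``. Returns the parsed frame indexed by gene name with the
    recomputed TPM in column ``tpm_recomputed``.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"Name", "Length", "EffectiveLength", "TPM", "NumReads"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"quant.sf is missing columns: {sorted(missing)}")
    df = df.set_index("Name")
    rate = df["NumReads"] / df["EffectiveLength"]
    total = rate.sum()
    df["tpm_recomputed"] = 0.0 if total == 0 else rate / total * 1e6
    scale = np.maximum(df["TPM"].to_numpy(), 1.0)
    rel = np.abs(df["tpm_recomputed"].to_numpy() - df["TPM"].to_numpy()) / scale
    worst = float(rel.max()) if len(rel) else 0.0
    if worst > tpm_rel_tol:
        msg = (
            f"{path}: recomputed TPM deviates from file TPM by up to "
            f"{worst:.2%} (tolerance {tpm_rel_tol:.2%})"
        )
        if strict:
            raise ConsistencyError(msg)
        logger.warning(msg)
    return df


def matrix_from_quant_files(
    quants: Mapping[str, Union[str, Path]], strict: bool = False
) -> ExpressionMatrix:
    """Assemble an :class:`ExpressionMatrix` from per-sample quant.sf files.

    Effective lengths are taken from the quantifier output (averaged over
    samples when they differ, which they may under fragment-length
    modeling).
    """
    count_cols: dict[str, pd.Series] = {}
    length_acc: dict[str, list[float]] = {}
    for sample, path in quants.items():
        df = read_quant_sf(path, strict=strict)
        count_cols[sample] = df["NumReads"]
        for gene, eff in df["EffectiveLength"].items():
            length_acc.setdefault(str(gene), []).append(float(eff))
    counts = pd.DataFrame(count_cols).fillna(0.0).sort_index()
    lengths = {g: float(np.mean(v)) for g, v in length_acc.items()}
    return ExpressionMatrix(counts=counts, lengths=lengths)


def read_count_matrix(
    counts_path: Union[str, Path], lengths_path: Union[str, Path]
) -> ExpressionMatrix:
    """Read a generic count-matrix TSV plus a two-column lengths TSV
    (gene_id, length)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    ldf = pd.read_csv(lengths_path, sep="\t")
    lengths = {str(r[0]): float(r[1]) for r in ldf.itertuples(index=False)}
    return ExpressionMatrix(counts=counts, lengths=lengths)


def call_expressed(
    tpm: pd.DataFrame, threshold: float = DEFAULT_TPM_THRESHOLD
) -> pd.DataFrame:
    """Boolean gene x sample matrix: TPM >= threshold (non-strict)."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return tpm >= threshold


def sample_tier_expression(
    flags: pd.DataFrame,
    catalog: GeneCatalog,
    dsr_rule: Literal["both", "either"] = "both",
    methanogenic: Optional[Mapping[str, bool]] = None,
) -> list[SampleCall]:
    """Collapse per-gene expression flags into per-sample tier calls.

    A sample expresses a cysteine-degradation tier when any gene of that
    tier is flagged. ``expresses_dsr`` requires both *dsrA* and *dsrB*
    flagged under the default operon rule (``dsr_rule="either"`` relaxes
    this). Genes absent from the catalog are ignored with a log message.
    *methanogenic* optionally supplies per-sample methane calls (see
    :func:`methanogenesis_call`) to carry on the result objects.
    """
    known = set(catalog.symbols())
    unknown = [g for g in flags.index if g not in known]
    if unknown:
        logger.warning(
            "sample_tier_expression: ignoring %d gene(s) not in catalog: %s",
            len(unknown), unknown[:5],
        )
    tiers = {
        t: sorted(catalog.genes_in_tier(t) & set(flags.index))
        for t in (Tier.PRIMARY, Tier.SECONDARY, Tier.ERRONEOUS, Tier.DSR)
    }

    def any_of(genes: Sequence[str], sample: str) -> bool:
        return bool(genes) and bool(flags.loc[genes, sample].any())

    dsr_genes = sorted(catalog.genes_in_tier(Tier.DSR))
    calls = []
    for sample in flags.columns:
        present_dsr = [g for g in dsr_genes if g in flags.index
                       and bool(flags.at[g, sample])]
        if dsr_rule == "both":
            dsr_ok = len(dsr_genes) > 0 and set(present_dsr) == set(dsr_genes)
        elif dsr_rule == "either":
            dsr_ok = bool(present_dsr)
        else:
            raise ValueError(f"dsr_rule must be 'both' or 'either', got {dsr_rule!r}")
        calls.append(
            SampleCall(
                sample_id=str(sample),
                expresses_primary=any_of(tiers[Tier.PRIMARY], sample),
                expresses_secondary=any_of(tiers[Tier.SECONDARY], sample),
                expresses_erroneous=any_of(tiers[Tier.ERRONEOUS], sample),
                expresses_dsr=dsr_ok,
                is_methanogenic=bool((methanogenic or {}).get(str(sample), False)),
            )
        )
    return calls


def methanogenesis_call(
    counts: Mapping[str, float],
    gene_list: Sequence[str],
    min_fraction: float = DEFAULT_METHANOGENESIS_FRACTION,
) -> bool:
    """Methane-producing call for one sample from raw read recruitment.

    True when the fraction of panel genes with at least one mapped read
    is >= *min_fraction* (default 0.8 over the 16-gene panel, so 13/16
    passes and 12/16 does not). Raw counts, not TPM, drive this rule.
    """
    if not gene_list:
        raise ValueError("methanogenesis gene list must be non-empty")
    n_hit = sum(1 for g in gene_list if counts.get(g, 0.0) >= 1)
    return n_hit / len(gene_list) >= min_fraction


def methanogenesis_calls(
    matrix: ExpressionMatrix,
    gene_list: Sequence[str],
    min_fraction: float = DEFAULT_METHANOGENESIS_FRACTION,
) -> dict[str, bool]:
    """Per-sample methane calls over an expression matrix."""
    return {
        str(s): methanogenesis_call(
            {g: float(matrix.counts.at[g, s]) for g in gene_list
             if g in matrix.counts.index},
            gene_list, min_fraction,
        )
        for s in matrix.sample_ids
    }


def co_expression_fraction(
    calls: Sequence[SampleCall],
    predicate_a: Callable[[SampleCall], bool],
    predicate_b: Callable[[SampleCall], bool],
) -> float:
    """Fraction of samples satisfying both predicates simultaneously.

    Used e.g. for the fraction of samples co-expressing dissimilatory
    sulfate reduction and methanogenesis. Bounded above by either
    marginal fraction.
    """
    if not calls:
        raise ValueError("co_expression_fraction of an empty call collection")
    both = sum(1 for c in calls if predicate_a(c) and predicate_b(c))
    return both / len(calls)


def write_call_table(calls: Iterable[SampleCall], dest: Union[str, Path]) -> None:
    """Write per-sample calls as TSV (booleans as 0/1)."""
    lines = [
        "sample_id\texpresses_primary\texpresses_secondary\texpresses_erroneous"
        "\texpresses_dsr\tis_methanogenic"
    ]
    for c in calls:
        lines.append(
            f"{c.sample_id}\t{int(c.expresses_primary)}\t"
            f"{int(c.expresses_secondary)}\t{int(c.expresses_erroneous)}\t"
            f"{int(c.expresses_dsr)}\t{int(c.is_methanogenic)}"
        )
    Path(dest).write_text("\n".join(lines) + "\n", encoding="utf-8")
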