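"""Pipeline orchestration: staged, resumable, logged runs.

A run is described by a declarative config (YAML or JSON; see
:class:`PipelineConfig`) and executed stage by stage. Each stage writes
TSV artifacts into the output directory and appends structured records to
a line-delimited run log (inputs, thresholds, counts dropped at each
filter). Later stages resume from the artifacts of earlier ones, so
``stages=["compare"]`` works as long as an ``abundance`` run already left
its table behind — and raises a :class:`DependencyError` naming the
missing file otherwise.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from . import abundance as ab
from . import classify as cl
from . import expression as ex
from . import homology as hom
from . import itol
from . import simulate as sim
from . import stats as st
from .catalog import GeneCatalog, default_catalog, load_catalog
from .errors import DependencyError, H2SGuildsError

ARTIFACTS = {
    "classify": ("annotations.tsv",),
    "abundance": ("guild_abundance.tsv",),
    "compare": ("comparisons.tsv",),
    "expression": ("sample_calls.tsv",),
    "report": ("itol_externalshape.txt", "summary.json"),
    "simulate": ("inputs/hits.tblout", "inputs/abundance.tsv",
                 "inputs/sample_meta.tsv", "inputs/counts.tsv",
                 "inputs/lengths.tsv", "inputs/truth_genomes.tsv"),
}

STAGE_ORDER = ("simulate", "classify", "abundance", "compare", "expression",
               "report")


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run.

    Paths are resolved relative to the config file's directory when
    loaded from disk. Thresholds default to the package's standard
    values; command-line flags may override any field.
    """

    out_dir: str = "h2sguilds_out"
    catalog_path: Optional[str] = None        # None -> shipped default catalog
    hit_files: list[str] = field(default_factory=list)
    hit_dialect: str = "tblout"
    abundance_tsv: Optional[str] = None
    sample_meta_tsv: Optional[str] = None
    counts_tsv: Optional[str] = None
    lengths_tsv: Optional[str] = None
    quant_files: dict[str, str] = field(default_factory=dict)
    # thresholds
    e_max: float = hom.DEFAULT_E_MAX
    default_bit_score_min: Optional[float] = None
    tpm_threshold: float = ex.DEFAULT_TPM_THRESHOLD
    methanogenesis_fraction: float = ex.DEFAULT_METHANOGENESIS_FRACTION
    srb_rule: str = "both"
    dsr_rule: str = "both"
    # synthetic-input generation (used by the "simulate" stage)
    seed: int = 0
    sim: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not (0 < self.e_max):
            raise H2SGuildsError("e_max must be positive")
        if self.tpm_threshold < 0:
            raise H2SGuildsError("tpm_threshold must be non-negative")
        if not (0 < self.methanogenesis_fraction <= 1):
            raise H2SGuildsError("methanogenesis_fraction must be in (0, 1]")
        for p in self.hit_files:
            if not Path(p).exists():
                raise H2SGuildsError(f"hit file does not exist: {p}")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise H2SGuildsError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        # resolve relative paths against the config file's directory
        base = path.parent
        def _resolve(p: Optional[str]) -> Optional[str]:
            return None if p is None else str((base / p).resolve()) \
                if not Path(p).is_absolute() else p
        cfg.out_dir = _resolve(cfg.out_dir) or cfg.out_dir
        cfg.catalog_path = _resolve(cfg.catalog_path)
        cfg.hit_files = [_resolve(p) for p in cfg.hit_files]  # type: ignore[misc]
        cfg.abundance_tsv = _resolve(cfg.abundance_tsv)
        cfg.sample_meta_tsv = _resolve(cfg.sample_meta_tsv)
        cfg.counts_tsv = _resolve(cfg.counts_tsv)
        cfg.lengths_tsv = _resolve(cfg.lengths_tsv)
        cfg.quant_files = {k: _resolve(v) for k, v in cfg.quant_files.items()}  # type: ignore[misc]
        return cfg

    def load_catalog(self) -> GeneCatalog:
        overrides = (
            {"default_bit_score_min": self.default_bit_score_min}
            if self.default_bit_score_min is not None else None
        )
        if self.catalog_path is None:
            return default_catalog(overrides)
        return load_catalog(self.catalog_path, overrides)


class _RunLog:
    def __init__(self, out_dir: Path):
        self.path = out_dir / "run_log.jsonl"

    def record(self, stage: str, **fields: object) -> None:
        rec = {"stage": stage, "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
               **fields}
        with self.path.open("a", encoding="utf-8") as fh:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def _require(out_dir: Path, artifact: str, produced_by: str) -> Path:
    p = out_dir / artifact
    if not p.exists():
        raise DependencyError(
            f"missing artifact {p} — run the '{produced_by}' stage first"
        )
    return p


def _stage_simulate(cfg: PipelineConfig, out: Path, log: _RunLog) -> None:
    sim_cfg = sim.SimConfig(seed=cfg.seed, **cfg.sim)
    catalog = cfg.load_catalog()
    inputs = out / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    truths, tbl = sim.gen_genome_hits(sim_cfg, catalog)
    sim.write_tblout(tbl, inputs / "hits.tblout")
    sim.write_truth_table(truths, inputs / "truth_genomes.tsv")
    annotations = [t.expected_annotation(catalog) for t in truths]
    matrix = sim.gen_abundance_cohorts(sim_cfg, annotations)
    ab.write_abundance_tsv(matrix, inputs / "abundance.tsv",
                           inputs / "sample_meta.tsv")
    em, _truth_calls = sim.gen_expression_matrix(sim_cfg, catalog)
    em.counts.to_csv(inputs / "counts.tsv", sep="\t", index_label="gene_id")
    pd.DataFrame(
        {"gene_id": list(em.lengths), "length": list(em.lengths.values())}
    ).to_csv(inputs / "lengths.tsv", sep="\t", index=False)
    log.record("simulate", seed=cfg.seed, n_genomes=sim_cfg.n_genomes,
               n_species=sim_cfg.n_species,
               n_samples=2 * sim_cfg.n_samples_per_cohort)
    # point downstream stages at the generated inputs
    cfg.hit_files = [str(inputs / "hits.tblout")]
    cfg.abundance_tsv = str(inputs / "abundance.tsv")
    cfg.sample_meta_tsv = str(inputs / "sample_meta.tsv")
    cfg.counts_tsv = str(inputs / "counts.tsv")
    cfg.lengths_tsv = str(inputs / "lengths.tsv")


def _stage_classify(cfg: PipelineConfig, out: Path, log: _RunLog) -> None:
    if not cfg.hit_files:
        raise DependencyError("no hit files configured for the classify stage")
    catalog = cfg.load_catalog()
    hits: list[hom.ProfileHit] = []
    for path in cfg.hit_files:
        with open(path, encoding="utf-8") as fh:
            hits.extend(hom.parse_hmmer_table(fh, dialect=cfg.hit_dialect))
    policy = hom.FilterPolicy(e_max=cfg.e_max)
    kept = hom.filter_hits(hits, catalog, policy)
    gene_map = hom.genes_present(kept)
    annotations = cl.classify_all(gene_map, catalog, srb_rule=cfg.srb_rule)  # type: ignore[arg-type]
    cl.write_annotation_table(annotations, out / "annotations.tsv")
    c = cl.census(annotations) if annotations else None
    log.record(
        "classify", n_hits_in=len(hits), n_hits_retained=len(kept),
        n_hits_dropped=len(hits) - len(kept), e_max=cfg.e_max,
        n_genomes=len(annotations),
        census=None if c is None else dataclasses.asdict(c),
    )


def _stage_abundance(cfg: PipelineConfig, out: Path, log: _RunLog) -> None:
    if cfg.abundance_tsv is None:
        raise DependencyError("no abundance_tsv configured")
    ann_path = _require(out, "annotations.tsv", "classify")
    annotations = cl.read_annotation_table(ann_path)
    matrix = ab.read_abundance_tsv(cfg.abundance_tsv, cfg.sample_meta_tsv)
    rows = []
    for guild in ab.Guild:
        ga = ab.guild_abundance(matrix, annotations, guild)
        for sample, value in ga.per_sample.items():
            rows.append({
                "sample_id": sample, "guild": guild.value,
                "abundance": value,
                "cohort": matrix.sample_meta.get(sample, {}).get("cohort", ""),
            })
    pd.DataFrame(rows).to_csv(out / "guild_abundance.tsv", sep="\t",
                              index=False)
    log.record("abundance", n_species=len(matrix.species_ids),
               n_samples=len(matrix.sample_ids), n_guilds=len(ab.Guild))


def _stage_compare(cfg: PipelineConfig, out: Path, log: _RunLog) -> None:
    ga_path = _require(out, "guild_abundance.tsv", "abundance")
    df = pd.read_csv(ga_path, sep="\t")
    cohorts = sorted(c for c in df["cohort"].dropna().unique() if c != "")
    rows = []
    for guild in sorted(df["guild"].unique()):
        sub = df[df["guild"] == guild]
        for a, b in combinations(cohorts, 2):
            res = st.rank_sum_test(
                sub.loc[sub["cohort"] == a, "abundance"].to_numpy(),
                sub.loc[sub["cohort"] == b, "abundance"].to_numpy(),
            )
            rows.append({"guild": guild, "cohort_a": a, "cohort_b": b,
                         "result": res})
    st.write_comparison_table(rows, out / "comparisons.tsv")
    log.record("compare", n_comparisons=len(rows), n_cohorts=len(cohorts))


def _stage_expression(cfg: PipelineConfig, out: Path, log: _RunLog) -> None:
    if cfg.quant_files:
        em = ex.matrix_from_quant_files(cfg.quant_files)
    elif cfg.counts_tsv and cfg.lengths_tsv:
        em = ex.read_count_matrix(cfg.counts_tsv, cfg.lengths_tsv)
    else:
        raise DependencyError(
            "expression stage needs quant_files or counts_tsv+lengths_tsv"
        )
    catalog = cfg.load_catalog()
    flags = ex.call_expressed(em.tpm, cfg.tpm_threshold)
    meth = ex.methanogenesis_calls(
        em, catalog.methanogenesis_genes(), cfg.methanogenesis_fraction
    )
    calls = ex.sample_tier_expression(
        flags, catalog, dsr_rule=cfg.dsr_rule, methanogenic=meth  # type: ignore[arg-type]
    )
    ex.write_call_table(calls, out / "sample_calls.tsv")
    log.record(
        "expression", n_genes=len(em.gene_ids), n_samples=len(em.sample_ids),
        tpm_threshold=cfg.tpm_threshold,
        n_expressing_primary=sum(c.expresses_primary for c in calls),
        n_methanogenic=sum(c.is_methanogenic for c in calls),
    )


def _stage_report(cfg: PipelineConfig, out: Path, log: _RunLog) -> None:
    ann_path = _require(out, "annotations.tsv", "classify")
    annotations = cl.read_annotation_table(ann_path)
    catalog = cfg.load_catalog()
    itol.write_itol_externalshape(annotations, catalog,
                                  out / "itol_externalshape.txt")
    c = cl.census(annotations)
    summary = {
        "n_genomes": c.n_genomes,
        "n_primary": c.n_primary, "pct_primary": c.pct_primary,
        "n_secondary": c.n_secondary, "pct_secondary": c.pct_secondary,
        "n_erroneous": c.n_erroneous, "pct_erroneous": c.pct_erroneous,
        "n_srb": c.n_srb,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2),
                                      encoding="utf-8")
    log.record("report", **summary)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "classify": _stage_classify,
    "abundance": _stage_abundance,
    "compare": _stage_compare,
    "expression": _stage_expression,
    "report": _stage_report,
}


def run_pipeline(cfg: PipelineConfig, stages: Sequence[str]) -> int:
    """Run the requested stages in canonical order.

    Returns 0 when every requested stage produced its artifacts; raises
    on the first failure. Unknown stage names raise ``ValueError``.
    """
    unknown = set(stages) - set(_STAGE_FUNCS)
    if unknown:
        raise ValueError(
            f"unknown stages {sorted(unknown)}; choose from {STAGE_ORDER}"
        )
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out)
    for stage in STAGE_ORDER:
        if stage not in stages:
            continue
        _STAGE_FUNCS[stage](cfg, out, log)
        for artifact in ARTIFACTS[stage]:
            if not (out / artifact).exists():
                raise H2SGuildsError(
                    f"stage {stage} finished without artifact {artifact}"
                )
    return 0
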