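# h2sguilds

Annotation and cohort comparison of hydrogen sulfide (H2S) producing
functional guilds of the human gut microbiome.

Gut bacteria produce H2S — a gasotransmitter with concentration-dependent
effects on mucosal integrity, inflammation and genotoxicity — by two main
routes: dissimilatory sulfate reduction (DSR, the *dsrAB* operon) and
degradation of the amino acid cysteine. `h2sguilds` is for microbiome
researchers who want to annotate which species carry the genes for either
route, classify genomes into guilds, compare guild abundance across
cohorts (healthy / IBD / CRC and similar designs), and confirm in vivo
expression from metatranscriptomes.

The package takes the outputs of standard tools — `hmmscan` tabular hit
files, Kraken2-style taxonomic reports, salmon `quant.sf` or generic
count tables — and implements the analysis layer:

- **Gene catalog** — a versioned TSV of marker genes in five tiers:
  primary cysteine degraders (*dcyD*, *yhaM*, *mgl*, *sseA*), secondary
  (*metC*, *malY*, *cysK*, *cysM*, *mccB*), erroneous (*tnaA*, *iscS*,
  *mccA*), the *dsrA*/*dsrB* operon, and a 16-gene methanogenesis panel.
- **Hit filtering** — retain hits with E-value < 1e-110; TIGRFAM profiles
  must additionally meet a per-family bit-score floor; HAMAP/custom
  profiles are E-value-only.
- **Guild classification** — a genome joins a cysteine-degrader tier when
  it carries ≥ 1 tier gene, and is a sulfate-reducing bacterium (SRB)
  when it carries both *dsrA* and *dsrB*.
- **Guild abundance & prevalence** — per-sample sums of member-species
  relative abundances; prevalence per sample or per subject.
- **Statistics** — two-sided Wilcoxon rank-sum tests
  (W = U + n₁(n₁+1)/2 reported alongside U; exact for small tie-free
  groups, tie-corrected normal approximation with continuity otherwise).
- **Expression calling** — TPM normalization
  (TPMᵍ = 10⁶·(cᵍ/ℓᵍ)/Σ(c/ℓ)); a gene is expressed at TPM ≥ 10; a sample
  is methane-producing when ≥ 80% of the methanogenesis panel recruits
  ≥ 1 read.
- **Synthetic data** — seeded generators that plant known gene content,
  cohort effects and expression prevalence, so the whole pipeline is
  testable end to end without downloads.
- **CLI** — `h2sguilds simulate|classify|abundance|compare|expression|report`
  over a declarative YAML config, with iTOL EXTERNALSHAPE export for
  displaying gene presence alongside a taxonomic tree.

## Worked example

```python
import io
from h2sguilds import (default_catalog, parse_hmmer_table, filter_hits,
                       genes_present, classify_all, census, Guild,
                       guild_abundance, compare_guild_between_cohorts,
                       prevalence)
from h2sguilds.simulate import (SimConfig, gen_genome_hits,
                                gen_abundance_cohorts)

catalog = default_catalog()
cfg = SimConfig(seed=7, n_genomes=300, guild_effect_multiplier=10.0)
truths, tblout_text = gen_genome_hits(cfg, catalog)

hits = parse_hmmer_table(io.StringIO(tblout_text))
gene_map = genes_present(filter_hits(hits, catalog))
annotations = classify_all(gene_map, catalog,
                           universe=[t.genome_id for t in truths])

c = census(annotations)
print(f"{c.n_genomes} genomes: {c.n_primary} primary ({c.pct_primary}%), "
      f"{c.n_secondary} secondary ({c.pct_secondary}%), {c.n_srb} SRB")

matrix = gen_abundance_cohorts(cfg, annotations)
primary = guild_abundance(matrix, annotations, Guild.PRIMARY_CD)
print(f"primary guild prevalence: {prevalence(primary):.2f}")
res = compare_guild_between_cohorts(primary, matrix.sample_meta,
                                    "case", "control")
print(f"case vs control, primary guild: W = {res.w_statistic:,.0f}, "
      f"p = {res.formatted_p()}")
```

prints

```
300 genomes: 148 primary (49.3%), 137 secondary (45.7%), 18 SRB
primary guild prevalence: 1.00
case vs control, primary guild: W = 60,100, p = < 2.2e-16
```

Reading the output: of 300 synthetic genomes, 148 carry at least one
primary cysteine-degradation gene after hit filtering; every sample
contains at least one primary-guild species (prevalence 1.00); and with a
10× abundance effect planted on the primary guild in the case cohort, the
rank-sum test rejects exchangeability far below the 2.2e-16 printing
floor.

The same flow runs from the shell:

```sh
h2sguilds simulate -o out --seed 7
h2sguilds classify -o out --hits out/inputs/hits.tblout
h2sguilds abundance -o out --matrix out/inputs/abundance.tsv \
    --meta out/inputs/sample_meta.tsv
h2sguilds compare -o out
h2sguilds report -o out          # census summary + iTOL dataset
```

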