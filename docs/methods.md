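# Methods

## The problem and the model

Gut microbial hydrogen sulfide (H2S) has two main sources: dissimilatory
sulfate reduction (DSR) and degradation of the sulfur amino acid
cysteine. `h2sguilds` annotates which bacterial species can produce H2S,
by which route, and how those functional guilds behave across cohorts and
in metatranscriptomes. The analysis has four layers:

1. **Homology -> gene content.** Each genome's proteome is searched with
   profile HMMs for a catalog of marker genes (search itself is external;
   the package consumes `hmmscan` tabular output). A hit is accepted when
   its E-value is strictly below 1e-110 and, for TIGRFAM profiles only,
   its bit score is at or above the family's floor. HAMAP and custom
   profiles carry no bit floor: they were chosen or built narrowly enough
   that the E-value ceiling suffices.
2. **Gene content -> guilds.** A genome is a *primary*, *secondary* or
   *erroneous* cysteine degrader when it carries >= 1 gene of that tier
   (tiers reflect how central H2S release is to the enzyme's function),
   and a sulfate-reducing bacterium (SRB) when it carries the *dsrAB*
   operon. Labels are not mutually exclusive, and they are monotone in
   gene content.
3. **Guilds -> cohort ecology.** Species relative abundances (Kraken2
   reports or a generic fraction matrix) are summed over guild members
   per sample; guilds are compared between cohorts, or against each other
   within a cohort, with the two-sided Wilcoxon rank-sum test. Prevalence
   is the fraction of samples — or subjects, when a subject mapping is
   supplied — with positive guild abundance.
4. **Counts -> expression calls.** Per-gene read counts are normalized to
   TPM; a gene is *expressed* at TPM >= 10; a sample expresses a tier when
   any tier gene is expressed (DSR needs both *dsrA* and *dsrB*); a sample
   is *methane producing* when >= 80% of a 16-gene methanogenesis panel
   recruits >= 1 raw read. The methanogenesis rule deliberately uses read
   recruitment, not TPM.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `e_max` | 1e-110 | E-value | conservative homology ceiling; strict `<` |
| TIGRFAM bit floor | 25 per family | bits | conservative fallback when a per-family floor is not configured; non-strict `>=` |
| `tpm_threshold` | 10 | TPM | expression call boundary, non-strict |
| `methanogenesis_fraction` | 0.8 | fraction of panel | 13/16 passes, 12/16 fails |
| `srb_rule` / `dsr_rule` | `both` | — | *dsrAB* operon reading; `either` available as a sensitivity switch |

Boundary conventions (strict E-value, non-strict bit floor and TPM) are
pinned by dedicated tests because single-sided choices at these edges
change genome and sample calls.

The shipped catalog (`data/default_catalog.tsv`, version 2021.1) is data,
not code: profile accessions are stable placeholders (`PH_<gene>`) meant
to be replaced by the user's curated TIGRFAM/HAMAP accessions, and every
threshold is overridable per symbol without editing the file. The
16-gene methanogenesis panel ships as an example hydrogenotrophic list
(fwd/ftr/mch/mtd/mer/mtr/mcr/hdr subunits); only its length interacts
with the 80% rule, so users with a different curated panel can swap it
freely.

## Statistics

`rank_sum_test` reports both Mann–Whitney U and the rank sum
W = U + n1(n1+1)/2 (the form usually quoted alongside these analyses).
For pooled sizes <= 12 without ties the exact null distribution is used;
otherwise the normal approximation with midranks, tie-corrected variance
and continuity correction — the same convention as R's `wilcox.test`, so
W and p match what that ecosystem prints. Identical constant groups
return p = 1 with a warning rather than dividing by a zero variance.
p-values below 2.2e-16 are printed as `< 2.2e-16` while the raw float is
kept. Raw p-values are reported by default; Benjamini–Hochberg
adjustment is available (`bh_adjust`) for batch comparisons.

Relative abundances parsed from Kraken2 reports are recomputed from read
counts, with unclassified reads included in the denominator — the
report's rounded percentage column is never trusted. This is a
normalization choice: excluding unclassified reads would scale every
sample's fractions up by a sample-specific factor, which rank-based
comparisons would largely absorb but prevalence thresholds would not.

## Synthetic data: what it emulates and what it does not

The generator (`h2sguilds.simulate`) plants known truth at every layer:

- **Genome hits** are planted with per-tier probabilities defaulting to
  the observed guild frequencies among gut species representatives
  (44.1% primary, 42.0% secondary, 0.1% erroneous); the SRB fraction
  defaults to 5%, a realistic order of magnitude for gut SRB carriage.
  Planted hits sit >= 5 decades below the E-value ceiling and decoys sit
  above it (or below the bit floor), so exact recovery is the expected
  outcome, not luck. An optional jitter fraction places hits within one
  decade of the ceiling and marks those genomes ambiguous; they exercise
  boundary behavior and are excluded from exact-recovery scoring because
  the strict-vs-non-strict convention there is a policy, not truth.
- **Cohort abundances** are log-normal per species (the standard marginal
  shape for microbiome fractions), with the case cohort's guild members
  multiplied by a configurable effect and every sample renormalized.
  This is deliberately simple: no compositional covariance, no
  phylogenetic correlation of gene content, no zero inflation beyond
  what the log-normal tail produces.
- **Expression matrices** plant tier expression at the observed
  metatranscriptomic prevalences (86.5% primary, 89.7% secondary, 84.1%
  dsrAB; erroneous set to 15% to reflect that those genes are markedly
  less transcribed) and methane production at 25.8%. Expressed genes
  receive Poisson(100)+1 counts on equal-length transcripts, which
  clears TPM >= 10 by two orders of magnitude given the ~30-gene panel;
  unexpressed marker genes receive zero counts.

Passing recovery tests therefore shows the pipeline's bookkeeping and
thresholds are exact under clean separation; it does not validate
behavior on real data's messy margins (near-threshold homologs,
cross-mapping reads, compositional artifacts).

All randomness flows from a single integer seed; generation is
`numpy.random.default_rng`-driven and byte-identical across runs for a
fixed seed.

## Numerical and design choices

- `domtblout` input is collapsed to the best domain per (protein,
  profile) by smallest independent E-value, ties broken by higher score
  then lexicographic protein id; `tblout` uses full-sequence E-values.
  Which of the two a user feeds is their choice; the filtering rules are
  identical.
- `hmmscan` output carries no genome identifier, so query names of the
  form `genome|protein` are split at the first `|`; a per-file
  `genome_id` argument overrides this.
- Hits whose profile id is absent from the catalog are dropped and
  counted in the log rather than raising — catalogs evolve, and the
  logged tally prevents silent loss. The same pattern applies to unknown
  gene symbols at classification and unresolved species at aggregation.
- Census percentages are rounded to one decimal for printing; raw counts
  stay on the object. With 5 erroneous species among 4,644 the census
  prints 0.1%.
- Degenerate inputs fail loudly: empty catalogs, empty groups, zero-read
  reports and empty sample sets raise; all-zero expression columns and
  constant rank-sum inputs degrade gracefully with warnings.

## Problem sizes

Test and acceptance runs use 1,000 synthetic genomes for classification
recovery, 2,000 null replicates at n=200/200 for rank-sum calibration,
100 replicates of a 10x planted effect at n=200/200 for power, and the
printed numerators/denominators of the cohort analyses (4,644 genomes;
736, 677 and 59 samples) for the arithmetic checks. The full suite runs
in well under a minute on one CPU.

## Known limitations

- The package consumes quantifier/profiler outputs; it does not run
  hmmscan, Kraken2 or salmon (thin optional subprocess adapters exist for
  HMMER only).
- No pan-genome or accessory-gene handling: a species is its
  representative genome.
- No mixed-effects handling of repeated samples per subject; prevalence
  offers a subject-level collapse, but rank-sum tests treat samples as
  exchangeable.
- The shipped profile ids are placeholders; reproducing a real
  genome-scale census requires the user's curated pHMM set and
  per-family floors.
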