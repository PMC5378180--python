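# Methods notes

This document records the model assumptions, parameter choices, numerical
conventions, and known limitations behind `strainscope`.

## Model and assumptions

The unit of reconstruction is the *dominant strain*: the most abundant
strain of a species in one sample. The method assumes that (i) marker genes
are species-specific, so every read recruited by a marker belongs to that
species; (ii) one strain is sufficiently dominant that the per-site
majority base reflects its sequence; and (iii) strain variation within
markers is dominated by substitutions. Indels and gene gain/loss are out of
scope — consensus calling is substitution-only, and reads' deletions simply
leave positions uncovered.

The binomial polymorphism test formalizes assumption (ii): under a
single-strain null, minor bases at a site arise only from sequencing error
at rate E, so the dominant-allele count T_s out of N_s covering reads
follows Binomial(N_s, 1 − E). The one-sided p-value is the CDF inclusive at
T_s, with no continuity correction and no multiple-testing correction
across sites (the per-site error rate is the quantity of interest;
Benjamini–Hochberg is available as an option). Because the binomial is
discrete, the test is conservative: its empirical type-I error at matched E
is well below α (measured ≈ 0.014 at α = 0.05 across depths 10–200×).

## Parameters

| Parameter | Default | Meaning / rationale |
|---|---|---|
| `min_base_quality` | 30 (Phred) | bases below q30 are excluded from pileups; applied uniformly to consensus and polymorphism (uniform application is the conservative reading; see below) |
| `min_depth` | 1 read | a base is called wherever any quality-passing coverage exists; zero coverage gives N |
| `marker_strip_length` | 50 nt | terminal marker positions are systematically under-covered because reads overhanging the marker ends cannot be mapped |
| `max_ambiguous_fraction` | 0.20 | markers with > 20 % N after stripping are discarded |
| `min_marker_fraction` | 0.80 | a species is profiled only when reconstructed markers strictly exceed 80 % of its database markers |
| `gap_in_trailing_col` | 0.20 | alignment ends are trimmed inward while a column has ≥ 20 % gaps |
| `gap_in_internal_col` | 0.30 | internal columns present in < 30 % of rows are removed |
| `n_col` | 0.80 | N-containing columns are deleted when they are < 80 % of columns, else kept (guard against degenerate alignments); surviving N become gaps |
| `long_gap_percentage` | 0.80 | columns inside ≥ 3-gap runs are removed when < 80 % of columns |
| `gap_in_sample` | 0.20 | strains with > 20 % gaps in the concatenated alignment are dropped |
| `error_rate` E | 0.01 | Illumina-scale per-base substitution error assumed by the polymorphism test |
| `alpha` | 0.05 | per-site significance level |
| `max_intra_snv` | 0.001 | subclades: all pairwise SNV rates below 0.1 % |
| country subtree | ≥ 80 % one country, ≥ 5 leaves | geographic enrichment rule |
| mixture threshold | μ_low + 3 σ_low | same-strain range of the retention mixture |
| `seed` | 42 | every stochastic step (EM initialization, k-means, spectral clustering, simulation) takes an explicit seed |

Reference-marker extraction uses exact 15-mer seeding plus affine-gap local
alignment (match +1, mismatch −1, gap open −3, extend −1) with defaults
`min_identity = 0.90` and `min_coverage_frac = 0.80`. No identity/coverage
convention is canonical for this step; these defaults admit the upper range
of within-species marker divergence (up to ~5 %) while rejecting
cross-species hits, and both are exposed as arguments.

## Design choices where the design was open

* **Tie-breaking in consensus.** An exact tie between bases yields N rather
  than a random base: reproducibility is worth more than the ~depth⁻¹
  fraction of extra ambiguity, and downstream trimming handles N anyway.
* **Order of the marker QC cascade.** Ends are stripped *before* the 20 %
  ambiguity filter is applied, because terminal positions are exactly where
  coverage-driven Ns concentrate; measuring ambiguity on the stripped
  sequence judges the part of the marker that is actually used. The
  opposite order is available (`filter_before_strip=True`) and a test
  documents that the two differ.
* **Long-gap columns.** A column counts as long-gap when *any* row has it
  inside a run of ≥ 3 consecutive gaps (an all-rows interpretation would
  almost never fire on realistic cohorts).
* **Marker concatenation order** is lexicographic in marker id, fixed
  across runs.
* **Rooting for subtree enumeration.** NJ trees are unrooted; "subtree" is
  made well-defined by midpoint rooting. Subclade disjointness is enforced
  greedily, largest subtree first, with lexicographic tie-breaking, so
  output is invariant to input order.
* **μ as median.** The polymorphic-species flag uses the cohort *median* +
  sample SD: the median is robust to the very samples the flag is meant to
  catch.
* **NJ instead of ML.** Within-species strain trees live in a near-clonal
  regime where distance methods are adequate and deterministic;
  `export_alignment` emits relaxed PHYLIP/FASTA so users can run external
  maximum-likelihood software on the identical alignment. Negative NJ
  branch-length estimates are clamped to zero with a warning.
* **Retention mixture.** Two-component full-covariance Gaussian mixture,
  k-means initialization, three restarts, fixed seed; fits whose components
  overlap at 3σ are flagged unreliable rather than silently trusted.
* **Quality filter scope.** The q30 filter is applied when pileups are
  built, so it affects both consensus calling and the polymorphism test;
  applying it only to the test would admit low-quality bases into
  consensus calls for no benefit.

## The simulator: what it does and does not emulate

`strainscope.simulate` generates i.i.d. uniform-ACGT markers, strains by
independent per-site substitution at a configurable rate (default 0.45 %,
a realistic within-species divergence for consistent gut genera), reads
with uniform start positions, independent substitution errors (default
1 %), and a two-point quality model — correct bases at q38, erroneous bases
at q15 — bracketing the q30 filter. Multi-strain samples draw reads
proportionally to mixture ratios; background spiking adds reads from
random genomes rejection-sampled to share no 15-mer (either strand) with
the marker database. Everything is deterministic under (seed, config).

Deliberately not emulated: position-dependent quality decay, indel errors,
GC bias, realistic community abundance distributions, paired-end structure,
and real cross-species homology. Consequently, passing tests demonstrate
the correctness and calibration of the algorithms under their stated
assumptions — not robustness to mapping ambiguity against real genomes,
which depends on the quality of the marker database. In particular, with
the two-point quality model nearly every erroneous base is removed by the
q30 filter, so measured consensus error rates on synthetic data are
essentially zero; on real data the error rate is bounded by how often a
high-quality base is wrong.

## Numerical conventions

* Coordinates are 0-based half-open throughout; SAM's 1-based starts are
  converted at the parsing boundary. Mapping quality is ignored (markers
  are species-unique by construction); unmapped, secondary, and
  supplementary records are skipped.
* All threshold comparisons follow strict/non-strict conventions as listed
  in the parameter table (e.g. ambiguity *strictly greater than* 20 % is
  discarded; the species gate requires *strictly more than* 80 %).
* SNV rates compare only columns where both strains have A/C/G/T; pairs
  compared over < 1000 columns are flagged low-confidence. A pair with zero
  comparable columns is an error, not a silent zero.
* PCoA components are ordered by eigenvalue with signs fixed by making each
  component's largest-magnitude coordinate positive, so ordinations are
  reproducible across runs and platforms.
* The built-in mapper requires full read containment within a marker,
  tolerates ≤ 10 % mismatches, and prefers fewer mismatches with
  first-candidate tie-breaking; it is intended for fixtures and synthetic
  benchmarks, not as a production aligner — any aligner's SAM output can be
  ingested instead.

## Problem sizes used by the benchmark suite

The accuracy benchmarks simulate one species with 100 markers of
900–1100 nt (~10⁵ nt of strain sequence) at mean 5× coverage with 150 nt
reads — within the 2–10× range where marker reconstruction is expected to
work — and, for the spiked benchmark, 10 background reads per target read
from unrelated random genomes. The calibration benchmark tests 100,000
sites at each depth in {10, 20, 50, 100, 200}. These sizes give stable
estimates (binomial SE of the calibration estimate < 0.0002) while keeping
a full run under a minute on one CPU.

## Known limitations

* Only the dominant strain is reconstructed; secondary strains are
  *detected* (and their aggregate frequency estimated) but never assembled
  or phased.
* Species absent from the marker database are invisible; marker databases
  are consumed, not built (`markerdb` validates and extends, but de novo
  marker discovery is a different problem).
* The center-star aligner assumes near-identical inputs (the operating
  regime for within-species consensus sequences); it is not a
  general-purpose MSA tool, and an external aligner can be substituted via
  `marker_alignment_from_rows`.
* Retention calling needs ≥ 20 distance values and a genuinely bimodal
  cohort; unimodal cohorts produce an explicit "unreliable" flag.
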