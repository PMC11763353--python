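# Methods

## Problem and procedure

`sampletrack` verifies that two genotype readouts of the same nominal
sample — an OpenArray-style SNP fingerprint (diploid calls, including
no-calls, at a small panel of biallelic SNVs) and a whole-exome-sequencing
VCF (variants-only, single sample, hg19) — belong to the same individual.

The pipeline is: read panel manifest → read call table → per-probe QC →
read per-sample VCFs → per-site classification → concordance + profile RMP
→ verdict → two-sheet report. Every step is exposed as a library function;
the `sampletrack` CLI is a thin orchestration layer.

## Site classification

Alignment is by normalized (chromosome, position); "chr7" and "7" collide
to one key. Because a variants-only VCF legitimately omits homozygous
reference sites, presence/absence of a record is part of the signal. The
full truth table (array genotype × record presence/content):

| array call | VCF record        | status              | sheet    |
|------------|-------------------|---------------------|----------|
| hom-ref    | absent            | EXPECTED_ABSENT_WT  | NO MERGE |
| hom-ref    | present           | DISCORDANT          | MERGE    |
| het/hom-alt| equal genotype    | CONCORDANT          | MERGE    |
| het/hom-alt| unequal genotype  | DISCORDANT          | MERGE    |
| het/hom-alt| absent            | UNEXPECTED_ABSENT   | NO MERGE |
| no-call    | anything          | OA_NO_CALL          | NO MERGE |

A record whose REF disagrees with the probe, or whose genotype uses an
alternative allele the biallelic probe cannot express (multi-allelic
records are resolved against the probe's alt), counts as DISCORDANT
evidence. Half-calls (`0/.`), indels at panel loci, and duplicate records
(first PASS/unfiltered wins) are handled at read time with warnings. An
array no-call has no genotype to merge on, so it is placed on the NO MERGE
sheet even when a record exists; it is excluded from all concordance
denominators because assay dropout is not evidence about identity.

## Concordance counting and verdict

Two documented modes: `INCLUDE_WT` (default) counts EXPECTED_ABSENT_WT as
agreement with denominator = all non-no-call sites; `STRICT_MERGE` scores
CONCORDANT / MERGE-sheet only. The default is the mode under which
unrelated pairs score near the panel-averaged per-locus match probability
(~46% for a MAF ~ U(0.1, 0.5) panel), giving the different-sample
distribution its expected location; under `STRICT_MERGE` unrelated pairs
score lower. Both modes coincide when the NO MERGE sheet is empty.

Verdict thresholds (percent): SAME ≥ 85, DIFFERENT ≤ 65, otherwise
INCONCLUSIVE; an undefined rate (no informative sites) is INCONCLUSIVE.
The defaults separate the observed identical (~97 ± 4) and different
(~46 ± 9) distributions by more than two SDs each and are configurable.
The profile RMP of the concordant loci is attached to every result as the
weight of evidence that the agreement is non-coincidental.

## Population-genetics statistics

All statistics assume unlinked autosomal biallelic loci in HWE.

- Allele frequencies from a cohort: allele counting over called genotypes,
  `p̂ = (2·n_homref + n_het) / (2·n_called)`.
- Panel RMP: product over loci of `Σ_g f(g)² = p⁴ + 4p²q² + q⁴` (the
  forensic probability of identity, per-locus minimum 0.375 at p = 0.5).
- Profile RMP: product over loci of the HWE frequency of the observed
  genotype. Callers pass concordant loci only.
- Both products accumulate as sums of log10 factors; `rmp = 10^Σ`.
- Frequency concordance vs a reference population: chi-square
  goodness-of-fit on allele counts (df = 1, no continuity correction),
  per-SNP α = 0.05 by default with an optional Bonferroni flag; a
  genotype-count mode (df = 2, HWE expectations) is available but not
  default. Monomorphic reference frequencies are untestable and skipped.

## Bundled synthetic panel

`src/sampletrack/data/synthetic_eur_panel.tsv` is a synthetic 60-SNP
manifest, not a published panel. It encodes the design constraints of a
WES-tracking fingerprint: 55 common SNPs (MAF evenly spread on
[0.05, 0.40]) plus 5 rare ancestry-informative SNPs (MAF 0.005), spread
over the 22 autosomes, with the five probes used in the QC worked example
(two below the 90% call-rate bar, three manually excluded after
amplification-plot review) placed at high MAF (0.42–0.50). Its
probability-of-identity is ~2×10⁻¹⁷ over 60 loci and ~3×10⁻¹⁵ over the 55
QC survivors — the discriminative power expected of such a panel.

## Synthetic-data generator

`simulate.SimulationConfig` defines the study conditions:

| parameter            | default      | meaning / rationale                          |
|----------------------|--------------|----------------------------------------------|
| `n_samples`          | 100          | cohort size of a validation batch            |
| `panel_size`         | 55           | post-QC panel size                           |
| `maf_low, maf_high`  | 0.1, 0.5     | uniform MAF law for common fingerprint SNPs  |
| `n_rare, rare_maf`   | 0, 0.005     | optional rare ancestry-informative SNPs      |
| `nocall_rate`        | 0.04         | per-call dropout → ~96% call rate            |
| `genotype_error_rate`| 0.03         | per-call misclassification → ~97% identical-pair concordance |
| `seed`               | 0            | all randomness; identical seed ⇒ byte-identical outputs |

Genotypes are drawn per sample × SNP from `(p², 2pq, q²)`, independently
across loci and individuals. The error model is applied to the array side
only (misclassification uniformly to one of the two other genotypes, then
dropout); the VCF side is emitted from truth, since the ≥20× exome calls
the tool consumes are far more accurate than array calls. Noise defaults
were set from the aggregate rates of a real 55-probe panel (call rate
96.04 ± 1.5%, identical-sample concordance 96.63 ± 3.6%).

The mix-up experiment pairs an array table with a VCF from the same
individual (IDENTICAL) or from two independent draws (DIFFERENT). Pairing
files from unrelated individuals and drawing independent individuals are
equivalent in expectation, and the DIFFERENT arm's mean converges to the
panel-averaged per-locus match probability — a tested link between the
simulator and the analytic statistics. The two arms are compared with a
two-sided Welch t-test.

What the generator does **not** emulate: probe- or sample-specific error
rates (every call is i.i.d.), linkage between loci, related individuals,
contamination /
mixtures, or raw fluorescence data (cluster-shape QC failures are modelled
as a manual exclusion list). Passing tests therefore demonstrate correct
engine behaviour under idealized assay noise, not performance on degraded
chemistry or kinship-confounded cohorts.

## Numerical and degenerate-input choices

- Concordance with an empty denominator is reported as missing, never 0.
- `panel_rmp([])` returns the product identity 1 with a warning.
- Observed genotypes with zero HWE frequency (e.g. an alt call at MAF 0)
  make the profile RMP undefined and raise, rather than returning 0.
- Chi-square requires a reference frequency strictly inside (0, 1).
- QC call-rate threshold must lie in (0, 1]; a probe both below threshold
  and manually listed records the manual reason (human review outranks the
  automatic rule).
- Problem sizes in the test suite — ≤10⁴-sample cohorts, 2×10⁴
  Monte-Carlo pairs, 100 mix-up pairs per arm, 1000 chi-square replicates —
  keep every statistical check within three standard errors of its
  analytic target while the whole suite runs in seconds.

## Known limitations

- Identity decisions assume unrelated individuals; monozygotic twins are
  indistinguishable by design, and close relatives compress the gap
  between the two concordance distributions.
- RMP products assume independent loci and HWE; no θ/F_ST correction.
- The matching engine is SNV-only and build-locked to the manifest's
  coordinates (no liftover).
- Sample pairing is always explicit (pairs file); identity is never
  inferred from filenames.
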