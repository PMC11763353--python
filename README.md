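# sampletrack

Sample-identity tracking for centralized sequencing labs. When a laboratory
runs whole-exome sequencing (WES) at scale, a swapped tube or a mislabelled
file can silently attach one patient's variants to another patient's name.
A cheap, orthogonal guard is to genotype every sample on a small fingerprint
panel of SNPs — for example with OpenArray-style real-time-PCR assays — and
check that the panel genotypes agree with the genotypes implied by the
sample's exome VCF. `sampletrack` implements that check: it aligns array
calls with VCF records by chromosome and position, classifies every panel
site, scores per-sample concordance, decides SAME / DIFFERENT /
INCONCLUSIVE, and quantifies the panel's discriminative power with
random-match-probability statistics.

It is written for lab bioinformaticians running identity QC in a diagnostic
or research pipeline, and for anyone designing a fingerprint panel who wants
to simulate its behaviour before committing to assays.

## The model

A panel is a set of `L` unlinked biallelic SNVs with known reference-allele
frequencies `p_i` (alt `q_i = 1 − p_i`). Under Hardy–Weinberg equilibrium
the genotype frequencies at locus `i` are `p_i², 2p_i q_i, q_i²`.

**Matching.** A variants-only VCF omits homozygous-reference sites, so
absence of a record is informative: each panel site falls on a **MERGE**
sheet (a VCF record exists at the locus) or a **NO MERGE** sheet (no
record). On MERGE, equal genotypes are CONCORDANT and anything else —
zygosity mismatch, a variant record where the array says hom-ref, or
alleles the biallelic probe cannot express — is DISCORDANT (red). On
NO MERGE, an array hom-ref is EXPECTED_ABSENT_WT (green), an array variant
is UNEXPECTED_ABSENT (red), and an assay no-call is neutral. The
concordance rate is, by default (`INCLUDE_WT`),

```
rate = 100 · (#CONCORDANT + #EXPECTED_ABSENT_WT) / (#sites − #no-calls)
```

with a `STRICT_MERGE` alternative that scores only the MERGE sheet. The
verdict thresholds default to SAME ≥ 85%, DIFFERENT ≤ 65%.

**Random match probability.** Two conventions, kept separate:

- *panel RMP* (probability of identity): `Π_i (p_i⁴ + 4p_i²q_i² + q_i⁴)` —
  the chance two unrelated people share the whole profile; the per-locus
  factor is minimized at 0.375 when `p = 0.5`.
- *profile RMP*: `Π_i f(g_i)` over a sample's observed genotypes at its
  concordant loci — the chance a random person carries this profile,
  reported per sample in the MERGE summary.

Products accumulate in log10 space. A per-SNP chi-square goodness-of-fit
test (allele counts, df = 1) checks cohort frequencies against the
reference population the panel was designed for.

## Worked example

Simulate a small self-consistent dataset and track it:

```
$ sampletrack simulate --n-samples 4 --panel-size 12 --seed 17 --out demo
$ sampletrack match --oa demo/calls.tsv --vcf-dir demo/vcf \
    --pairs demo/pairs.tsv --panel demo/panel.tsv --out demo/report.tsv
INFO sampletrack: probe SIM_0012 excluded (LOW_CALL_RATE, call rate 0.500)
INFO sampletrack: flag S0004/S0004 UNEXPECTED_ABSENT at 6:36228803 oa=HET wes=ABSENT
INFO sampletrack: 4 pairs: mean concordance 96.43%, 4 SAME / 0 DIFFERENT / 0 INCONCLUSIVE
$ echo $?
0
```

One probe fell under the 90% call-rate bar and was excluded before
matching; one site where the array saw a heterozygote but the VCF had no
record was flagged red; every pair still scored well above the SAME
threshold, so the exit status is 0 (any DIFFERENT verdict exits nonzero,
for pipeline gating). `demo/report.tsv` holds the per-site MERGE/NO-MERGE
rows and `demo/report.summary.tsv` the per-sample concordance, profile RMP
and verdict; an `--out report.xlsx` path writes the same content as a
three-sheet workbook.

The mix-up experiment contrasts correctly paired samples with deliberately
mismatched ones (55 SNPs, MAF ~ U(0.1, 0.5), default assay noise):

```
$ sampletrack mixup --mode both --pairs 100 --seed 17
IDENTICAL mean=97.10% sd=2.462 (n=100)
DIFFERENT mean=43.41% sd=7.229 (n=100)
welch_p=2.251e-100
```

The two distributions do not overlap: identical pairs sit near 97%,
unrelated pairs near the panel-averaged per-locus match probability
(~44–46%), so a swap is unambiguous.

Panel discriminative power, using the bundled synthetic 60-SNP manifest:

```
$ sampletrack panel-stats --panel src/sampletrack/data/synthetic_eur_panel.tsv
...
# n_snps        60
# panel_rmp     1.9541e-17
# log10_rmp     -16.7090
```

i.e. roughly a 1-in-10¹⁷ chance that two unrelated individuals share the
full 60-SNP profile.

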