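"""The matching engine: align array calls with VCF records and decide identity.

For each panel site the array call (hom-ref / het / hom-alt / no-call) is
compared with the sample's VCF, which by construction omits homozygous
reference sites. The comparison partitions sites into two report sheets:

MERGE (a VCF record exists at the locus)
    CONCORDANT when genotypes agree, DISCORDANT on any zygosity mismatch or
    when the array says hom-ref but a variant record exists ("unexpected
    call"), or when the record's alleles cannot be reconciled with the
    probe's ref/alt.
NO_MERGE (no VCF record at the locus)
    EXPECTED_ABSENT_WT when the array call is hom-ref (legitimately absent
    from a variants-only VCF, flagged green), UNEXPECTED_ABSENT when the
    array reports a variant the VCF lacks (red), OA_NO_CALL when the assay
    gave no genotype (neutral, excluded from concordance denominators).

Concordance is reported as a percentage under one of two counting modes, and
the identity verdict (SAME / DIFFERENT / INCONCLUSIVE) is a thresholded
decision on that rate, annotated with the profile random-match probability
of the concordant loci as weight of evidence.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .model import (
    Genotype,
    GenotypeMatrix,
    MatchRecord,
    MatchResult,
    Panel,
    PanelSNP,
    Sheet,
    Status,
    ValidationError,
    VariantSet,
    VcfRecord,
    Verdict,
)
from .popgen import FrequencyTable, profile_rmp

logger = logging.getLogger("sampletrack")

#: Counting modes for the concordance rate.
INCLUDE_WT = "INCLUDE_WT"
STRICT_MERGE = "STRICT_MERGE"

#: Default identity thresholds (percent): chosen to separate the observed
#: identical-sample (~97 +/- 4) and different-sample (~48 +/- 10) concordance
#: distributions by more than two standard deviations each.
SAME_THRESHOLD = 85.0
DIFFERENT_THRESHOLD = 65.0


def resolve_wes_genotype(record: VcfRecord, snp: PanelSNP) -> Optional[Genotype]:
    """Panel-alt dosage encoded by a VCF record, or None if irreconcilable.

    Biallelic panel assays only recognise the probe's ref and alt; a record
    whose REF disagrees with the probe, or whose called alleles involve any
    other alternative allele, cannot be expressed on the probe's axis and
    returns None (treated as discordant evidence by the classifier).
    """
    if record.ref != snp.ref_allele:
        return None
    alleles = []
    for idx in record.gt:
        if idx is None:
            return None
        if idx == 0:
            alleles.append(record.ref)
        else:
            if idx - 1 >= len(record.alts):
                return None
            alleles.append(record.alts[idx - 1])
    if any(a not in (snp.ref_allele, snp.alt_allele) for a in alleles):
        return None
    return Genotype(sum(a == snp.alt_allele for a in alleles))


def classify_site(
    oa_call: Genotype, vcf_record: Optional[VcfRecord], snp: PanelSNP
) -> MatchRecord:
    """Classify one panel site into a status and a report sheet."""
    if vcf_record is not None and vcf_record.locus != snp.locus:
        raise ValidationError(
            f"record locus {vcf_record.locus} does not match probe "
            f"{snp.probe_id} at {snp.locus}"
        )
    if oa_call is Genotype.NO_CALL:
        # assay dropout: nothing to merge on, uninformative either way
        wes = resolve_wes_genotype(vcf_record, snp) if vcf_record is not None else None
        return MatchRecord(snp, oa_call, wes, Status.OA_NO_CALL, Sheet.NO_MERGE)
    if vcf_record is None:
        if oa_call is Genotype.HOM_REF:
            return MatchRecord(
                snp, oa_call, None, Status.EXPECTED_ABSENT_WT, Sheet.NO_MERGE
            )
        return MatchRecord(snp, oa_call, None, Status.UNEXPECTED_ABSENT, Sheet.NO_MERGE)
    wes = resolve_wes_genotype(vcf_record, snp)
    if wes is None or oa_call is Genotype.HOM_REF or wes != oa_call:
        return MatchRecord(snp, oa_call, wes, Status.DISCORDANT, Sheet.MERGE)
    return MatchRecord(snp, oa_call, wes, Status.CONCORDANT, Sheet.MERGE)


def concordance_rate(
    records: Sequence[MatchRecord], mode: str = INCLUDE_WT
) -> Optional[float]:
    """Percent of informative panel sites on which the two platforms agree.

    INCLUDE_WT (default): hom-ref sites absent from the VCF count as
    agreement; denominator is every site except assay no-calls.
    STRICT_MERGE: only sites with a VCF record count; numerator is
    CONCORDANT, denominator the MERGE sheet (the reading under which the
    NO MERGE sheet is not informative for identity).

    Returns None when the denominator is empty.
    """
    if mode == INCLUDE_WT:
        denom = [r for r in records if r.status is not Status.OA_NO_CALL]
        numer = [
            r for r in denom
            if r.status in (Status.CONCORDANT, Status.EXPECTED_ABSENT_WT)
        ]
    elif mode == STRICT_MERGE:
        denom = [
            r for r in records
            if r.sheet is Sheet.MERGE and r.status is not Status.OA_NO_CALL
        ]
        numer = [r for r in denom if r.status is Status.CONCORDANT]
    else:
        raise ValidationError(f"unknown counting mode {mode!r}")
    if not denom:
        return None
    return 100.0 * len(numer) / len(denom)


def decide_identity(
    rate: Optional[float],
    same_threshold: float = SAME_THRESHOLD,
    different_threshold: float = DIFFERENT_THRESHOLD,
) -> Verdict:
    """Threshold the concordance rate into SAME / DIFFERENT / INCONCLUSIVE."""
    if same_threshold <= different_threshold:
        raise ValidationError(
            "same_threshold must exceed different_threshold "
            f"({same_threshold} <= {different_threshold})"
        )
    if rate is None:
        return Verdict.INCONCLUSIVE
    if rate >= same_threshold:
        return Verdict.SAME
    if rate <= different_threshold:
        return Verdict.DIFFERENT
    return Verdict.INCONCLUSIVE


def match_sample(
    oa_profile: Mapping[str, Genotype],
    variants: VariantSet,
    panel: Panel,
    freqs: FrequencyTable,
    mode: str = INCLUDE_WT,
    oa_sample_id: str = "",
    same_threshold: float = SAME_THRESHOLD,
    different_threshold: float = DIFFERENT_THRESHOLD,
) -> MatchResult:
    """Match one array profile against one sample's variant set.

    Produces one MatchRecord per panel SNP, the concordance rate under the
    requested counting mode, the profile RMP over the concordant loci, and
    the identity verdict. Deterministic for fixed inputs.
    """
    missing = freqs.covers(panel)
    if missing:
        raise ValidationError(f"frequency table missing panel SNPs: {missing}")
    records = []
    for snp in panel:
        oa_call = oa_profile.get(snp.probe_id, Genotype.NO_CALL)
        records.append(classify_site(oa_call, variants.at(*snp.locus), snp))
    rate = concordance_rate(records, mode=mode)
    concordant = {
        r.panel_snp.probe_id: r.oa_call
        for r in records
        if r.status is Status.CONCORDANT
    }
    rmp = profile_rmp(concordant, freqs).rmp if concordant else None
    for rec in records:
        if rec.status in (Status.DISCORDANT, Status.UNEXPECTED_ABSENT):
            logger.info(
                "flag %s/%s %s at %s:%d oa=%s wes=%s",
                oa_sample_id or "?", variants.sample_id, rec.status.value,
                rec.panel_snp.chrom, rec.panel_snp.pos,
                rec.oa_call.name,
                rec.wes_genotype.name if rec.wes_genotype is not None else "ABSENT",
            )
    return MatchResult(
        oa_sample_id=oa_sample_id,
        vcf_sample_id=variants.sample_id,
        records=records,
        concordance_rate=rate,
        profile_rmp=rmp,
        verdict=decide_identity(rate, same_threshold, different_threshold),
    )


@dataclass
class CohortSummary:
    n_pairs: int
    mean_concordance: Optional[float]
    sd_concordance: Optional[float]
    n_same: int
    n_different: int
    n_inconclusive: int


def match_cohort(
    oa_matrix: GenotypeMatrix,
    variant_sets: Mapping[str, VariantSet],
    pairing: Mapping[str, str],
    panel: Panel,
    freqs: FrequencyTable,
    mode: str = INCLUDE_WT,
    same_threshold: float = SAME_THRESHOLD,
    different_threshold: float = DIFFERENT_THRESHOLD,
) -> tuple[list[MatchResult], CohortSummary]:
    """Match every paired (array sample -> VCF sample) in a cohort.

    ``pairing`` maps array sample IDs to VCF sample IDs; unmatched IDs on
    either side of a pair raise an error listing them.
    """
    if not pairing:
        raise ValidationError("empty pairing: nothing to match")
    missing_oa = [s for s in pairing if s not in oa_matrix.calls.index]
    missing_vcf = [v for v in pairing.values() if v not in variant_sets]
    if missing_oa or missing_vcf:
        raise ValidationError(
            f"unmatched sample IDs: array={missing_oa} vcf={missing_vcf}"
        )
    results = []
    for oa_id, vcf_id in pairing.items():
        results.append(
            match_sample(
                oa_matrix.sample_profile(oa_id),
                variant_sets[vcf_id],
                panel,
                freqs,
                mode=mode,
                oa_sample_id=oa_id,
                same_threshold=same_threshold,
                different_threshold=different_threshold,
            )
        )
    rates = [r.concordance_rate for r in results if r.concordance_rate is not None]
    summary = CohortSummary(
        n_pairs=len(results),
        mean_concordance=statistics.fmean(rates) if rates else None,
        sd_concordance=statistics.stdev(rates) if len(rates) > 1 else (0.0 if rates else None),
        n_same=sum(r.verdict is Verdict.SAME for r in results),
        n_different=sum(r.verdict is Verdict.DIFFERENT for r in results),
        n_inconclusive=sum(r.verdict is Verdict.INCONCLUSIVE for r in results),
    )
    return results, summary
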