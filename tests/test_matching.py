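"""Site classification truth table, concordance counting, identity verdicts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sampletrack.matching import (
    INCLUDE_WT,
    STRICT_MERGE,
    classify_site,
    concordance_rate,
    decide_identity,
    match_cohort,
    match_sample,
    resolve_wes_genotype,
)
from sampletrack.model import (
    Genotype,
    MatchRecord,
    Sheet,
    Status,
    ValidationError,
    VariantSet,
    VcfRecord,
    Verdict,
)
from sampletrack.popgen import FrequencyTable
from sampletrack.simulate import (
    SimulationConfig,
    apply_error_model,
    simulate_cohort,
    simulate_panel,
    variant_set_from_profile,
)

from conftest import make_panel, matrix_from_codes, profile_from_codes


def record_at(snp, genotype):
    """Variant record for a genotype at a panel locus (None for hom-ref)."""
    if genotype is Genotype.HOM_REF:
        return None
    gt = (0, 1) if genotype is Genotype.HET else (1, 1)
    return VcfRecord(
        chrom=snp.chrom, pos=snp.pos, ref=snp.ref_allele,
        alts=(snp.alt_allele,), gt=gt,
    )


class TestClassifySite:
    """Exhaustive truth table over array genotype x VCF presence/content.

    A variants-only VCF legitimately lacks hom-ref sites, so absence plus an
    array hom-ref is expected (green); any other disagreement is flagged.
    """

    # (oa_call, wes side as genotype-or-None, expected status, expected sheet)
    TRUTH_TABLE = [
        (Genotype.HOM_REF, None, Status.EXPECTED_ABSENT_WT, Sheet.NO_MERGE),
        (Genotype.HOM_REF, Genotype.HET, Status.DISCORDANT, Sheet.MERGE),
        (Genotype.HOM_REF, Genotype.HOM_ALT, Status.DISCORDANT, Sheet.MERGE),
        (Genotype.HET, None, Status.UNEXPECTED_ABSENT, Sheet.NO_MERGE),
        (Genotype.HET, Genotype.HET, Status.CONCORDANT, Sheet.MERGE),
        (Genotype.HET, Genotype.HOM_ALT, Status.DISCORDANT, Sheet.MERGE),
        (Genotype.HOM_ALT, None, Status.UNEXPECTED_ABSENT, Sheet.NO_MERGE),
        (Genotype.HOM_ALT, Genotype.HET, Status.DISCORDANT, Sheet.MERGE),
        (Genotype.HOM_ALT, Genotype.HOM_ALT, Status.CONCORDANT, Sheet.MERGE),
        (Genotype.NO_CALL, None, Status.OA_NO_CALL, Sheet.NO_MERGE),
        (Genotype.NO_CALL, Genotype.HET, Status.OA_NO_CALL, Sheet.NO_MERGE),
        (Genotype.NO_CALL, Genotype.HOM_ALT, Status.OA_NO_CALL, Sheet.NO_MERGE),
    ]

    @pytest.mark.parametrize(
        "oa_call,wes,status,sheet", TRUTH_TABLE,
        ids=[f"{o.name}-vs-{w.name if w else 'ABSENT'}" for o, w, _, _ in TRUTH_TABLE],
    )
    def test_truth_table(self, small_panel, oa_call, wes, status, sheet):
        snp = small_panel.snps[0]
        rec = record_at(snp, wes) if wes is not None else None
        result = classify_site(oa_call, rec, snp)
        assert result.status is status
        assert result.sheet is sheet

    def test_unresolvable_record_is_discordant(self, small_panel):
        # genotype uses an alt allele the biallelic probe cannot express
        snp = small_panel.snps[0]  # ref A, alt G
        rec = VcfRecord(chrom=snp.chrom, pos=snp.pos, ref="A", alts=("T",), gt=(1, 1))
        result = classify_site(Genotype.HET, rec, snp)
        assert result.status is Status.DISCORDANT
        assert result.sheet is Sheet.MERGE
        assert result.wes_genotype is None

    def test_ref_mismatch_is_discordant(self, small_panel):
        snp = small_panel.snps[0]
        rec = VcfRecord(chrom=snp.chrom, pos=snp.pos, ref="C", alts=("G",), gt=(0, 1))
        assert classify_site(Genotype.HET, rec, snp).status is Status.DISCORDANT

    def test_locus_mismatch_raises(self, small_panel):
        snp = small_panel.snps[0]
        rec = VcfRecord(chrom=snp.chrom, pos=snp.pos + 5, ref="A", alts=("G",), gt=(0, 1))
        with pytest.raises(ValidationError, match="locus"):
            classify_site(Genotype.HET, rec, snp)


class TestResolveWesGenotype:
    def test_multiallelic_resolved_to_panel_alt(self, small_panel):
        snp = small_panel.snps[0]  # ref A, alt G
        rec = VcfRecord(chrom=snp.chrom, pos=snp.pos, ref="A", alts=("G", "T"), gt=(1, 1))
        assert resolve_wes_genotype(rec, snp) is Genotype.HOM_ALT

    def test_mixed_other_alt_unresolvable(self, small_panel):
        snp = small_panel.snps[0]
        rec = VcfRecord(chrom=snp.chrom, pos=snp.pos, ref="A", alts=("G", "T"), gt=(1, 2))
        assert resolve_wes_genotype(rec, snp) is None


class TestConcordanceRate:
    def _records(self, small_panel, statuses):
        panel = make_panel([0.3] * len(statuses))
        sheet_of = {
            Status.CONCORDANT: Sheet.MERGE,
            Status.DISCORDANT: Sheet.MERGE,
            Status.EXPECTED_ABSENT_WT: Sheet.NO_MERGE,
            Status.UNEXPECTED_ABSENT: Sheet.NO_MERGE,
            Status.OA_NO_CALL: Sheet.NO_MERGE,
        }
        return [
            MatchRecord(snp, Genotype.HET, None, status, sheet_of[status])
            for snp, status in zip(panel, statuses)
        ]

    def test_include_wt_counts_expected_absence_as_match(self, small_panel):
        statuses = (
            [Status.CONCORDANT] * 50
            + [Status.EXPECTED_ABSENT_WT] * 3
            + [Status.DISCORDANT] * 2
        )
        rate = concordance_rate(self._records(small_panel, statuses), INCLUDE_WT)
        assert rate == pytest.approx(100 * 53 / 55)

    def test_strict_merge_ignores_no_merge_sheet(self, small_panel):
        statuses = (
            [Status.CONCORDANT] * 50
            + [Status.EXPECTED_ABSENT_WT] * 3
            + [Status.DISCORDANT] * 2
        )
        rate = concordance_rate(self._records(small_panel, statuses), STRICT_MERGE)
        assert rate == pytest.approx(100 * 50 / 52)

    @pytest.mark.parametrize("mode", [INCLUDE_WT, STRICT_MERGE])
    def test_all_concordant_is_100_in_both_modes(self, small_panel, mode):
        records = self._records(small_panel, [Status.CONCORDANT] * 10)
        assert concordance_rate(records, mode) == 100.0

    def test_all_discordant_is_zero(self, small_panel):
        records = self._records(small_panel, [Status.DISCORDANT] * 10)
        assert concordance_rate(records, INCLUDE_WT) == 0.0

    def test_empty_denominator_is_undefined(self, small_panel):
        records = self._records(small_panel, [Status.OA_NO_CALL] * 5)
        assert concordance_rate(records, INCLUDE_WT) is None

    def test_modes_agree_when_no_merge_sheet_empty(self, small_panel):
        statuses = [Status.CONCORDANT] * 7 + [Status.DISCORDANT] * 3
        records = self._records(small_panel, statuses)
        assert concordance_rate(records, INCLUDE_WT) == concordance_rate(
            records, STRICT_MERGE
        )

    def test_unknown_mode_rejected(self, small_panel):
        records = self._records(small_panel, [Status.CONCORDANT])
        with pytest.raises(ValidationError):
            concordance_rate(records, "BOTH")


class TestDecideIdentity:
    @pytest.mark.parametrize(
        "rate,verdict",
        [
            (96.6, Verdict.SAME),
            (48.3, Verdict.DIFFERENT),
            (75.0, Verdict.INCONCLUSIVE),
            (85.0, Verdict.SAME),       # boundary: >= same threshold
            (65.0, Verdict.DIFFERENT),  # boundary: <= different threshold
            (None, Verdict.INCONCLUSIVE),
        ],
    )
    def test_threshold_bands(self, rate, verdict):
        assert decide_identity(rate) is verdict

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValidationError):
            decide_identity(90.0, same_threshold=60.0, different_threshold=70.0)


class TestMatchSample:
    def test_error_free_self_match_is_100_percent(self, small_panel):
        freqs = FrequencyTable.from_panel(small_panel)
        profile = profile_from_codes(small_panel, [0, 1, 2, 1, 0])
        vs = variant_set_from_profile(profile, small_panel, "S1")
        result = match_sample(profile, vs, small_panel, freqs, oa_sample_id="S1")
        assert result.concordance_rate == 100.0
        assert result.verdict is Verdict.SAME

    def test_all_no_call_is_inconclusive_with_missing_rate(self, small_panel):
        freqs = FrequencyTable.from_panel(small_panel)
        profile = profile_from_codes(small_panel, [-1] * 5)
        vs = VariantSet(sample_id="S1")
        result = match_sample(profile, vs, small_panel, freqs)
        assert result.concordance_rate is None
        assert result.verdict is Verdict.INCONCLUSIVE
        assert result.profile_rmp is None

    def test_missing_frequency_entry_raises(self, small_panel):
        freqs = FrequencyTable(p_ref={"P001": 0.5})  # others missing
        profile = profile_from_codes(small_panel, [0, 1, 2, 1, 0])
        vs = variant_set_from_profile(profile, small_panel, "S1")
        with pytest.raises(ValidationError, match="missing panel SNPs"):
            match_sample(profile, vs, small_panel, freqs)

    def test_profile_rmp_multiplies_concordant_genotype_freqs(self):
        panel = make_panel([0.5, 0.5])
        freqs = FrequencyTable.from_panel(panel)
        profile = profile_from_codes(panel, [1, 1])  # two hets at p=q=0.5
        vs = variant_set_from_profile(profile, panel, "S1")
        result = match_sample(profile, vs, panel, freqs)
        assert result.profile_rmp == pytest.approx(0.25)

    def test_one_record_per_panel_snp_partition(self, small_panel, rng):
        freqs = FrequencyTable.from_panel(small_panel)
        profile = profile_from_codes(small_panel, rng.integers(-1, 3, size=5))
        vs = variant_set_from_profile(
            profile_from_codes(small_panel, rng.integers(0, 3, size=5)),
            small_panel, "S1",
        )
        result = match_sample(profile, vs, small_panel, freqs)
        assert [r.panel_snp.probe_id for r in result.records] == small_panel.probe_ids
        assert len(result.merge_records) + len(result.no_merge_records) == 5


@settings(max_examples=100, derandomize=True, deadline=None)
@given(seed=st.integers(0, 2**31 - 1), size=st.integers(2, 60))
def test_noise_free_self_match_property(seed, size):
    """Zero-noise self-match gives 100% concordance and verdict SAME for any
    random panel and MAF spectrum."""
    config = SimulationConfig(
        n_samples=1, panel_size=size, maf_low=0.0, maf_high=0.5,
        nocall_rate=0.0, genotype_error_rate=0.0, seed=seed,
    )
    panel, truth = simulate_cohort(config)
    freqs = FrequencyTable.from_panel(panel)
    profile = truth.sample_profile(truth.sample_ids[0])
    vs = variant_set_from_profile(profile, panel, "V")
    result = match_sample(profile, vs, panel, freqs)
    assert result.concordance_rate == 100.0
    assert result.verdict is Verdict.SAME


class TestMatchCohort:
    def _self_cohort(self, n=10, noise=0.0, seed=5):
        config = SimulationConfig(
            n_samples=n, panel_size=20, nocall_rate=0.0,
            genotype_error_rate=noise, seed=seed,
        )
        panel, truth = simulate_cohort(config)
        matrix = apply_error_model(truth, config)
        variant_sets = {
            s: variant_set_from_profile(truth.sample_profile(s), panel, s)
            for s in truth.sample_ids
        }
        freqs = FrequencyTable.from_panel(panel)
        return matrix, variant_sets, panel, freqs, truth

    def test_error_free_self_pairs_mean_100_sd_0(self):
        matrix, vsets, panel, freqs, truth = self._self_cohort()
        pairing = {s: s for s in truth.sample_ids}
        results, summary = match_cohort(matrix, vsets, pairing, panel, freqs)
        assert summary.mean_concordance == 100.0
        assert summary.sd_concordance == 0.0
        assert summary.n_same == 10

    def test_empty_pairing_rejected(self):
        matrix, vsets, panel, freqs, _ = self._self_cohort()
        with pytest.raises(ValidationError, match="empty pairing"):
            match_cohort(matrix, vsets, {}, panel, freqs)

    def test_unmatched_ids_listed(self):
        matrix, vsets, panel, freqs, truth = self._self_cohort()
        pairing = {"GHOST": truth.sample_ids[0], truth.sample_ids[0]: "MISSING"}
        with pytest.raises(ValidationError, match="GHOST.*MISSING"):
            match_cohort(matrix, vsets, pairing, panel, freqs)

    def test_injected_discordance_matches_binomial_expectation(self):
        """3% per-call misclassification on one side of self-pairs drops the
        mean concordance to ~97% (a misclassified call always mismatches)."""
        config = SimulationConfig(
            n_samples=100, panel_size=55, nocall_rate=0.0,
            genotype_error_rate=0.03, seed=42,
        )
        panel, truth = simulate_cohort(config)
        matrix = apply_error_model(truth, config)
        vsets = {
            s: variant_set_from_profile(truth.sample_profile(s), panel, s)
            for s in truth.sample_ids
        }
        freqs = FrequencyTable.from_panel(panel)
        _, summary = match_cohort(matrix, vsets, {s: s for s in truth.sample_ids},
                                  panel, freqs)
        n_calls = 100 * 55
        se = 100 * np.sqrt(0.03 * 0.97 / n_calls)
        assert summary.mean_concordance == pytest.approx(97.0, abs=3 * se)
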