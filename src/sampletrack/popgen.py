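"""Population-genetics statistics for the fingerprint panel.

The discriminative power of the panel is summarized by the random match
probability (RMP). Two standard conventions are implemented and kept apart:

panel-level RMP (probability of identity)
    product over loci of the probability that two unrelated individuals share
    a genotype, sum_g f(g)^2 = p^4 + 4 p^2 q^2 + q^4 under Hardy-Weinberg
    equilibrium (HWE) with reference-allele frequency p and q = 1 - p.
profile RMP
    probability of one observed profile: product over loci of the HWE
    frequency of the genotype actually seen (p^2, 2pq or q^2). Reported per
    sample over its concordant (matching) loci.

Both accumulate in log10 space so 50+ locus products do not underflow.
A chi-square goodness-of-fit test compares cohort allele counts against a
reference population (df=1 on allele counts by default; a genotype-count
mode with df=2 is available).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .model import Genotype, GenotypeMatrix, Panel, ValidationError

logger = logging.getLogger("sampletrack")


@dataclass
class FrequencyTable:
    """Per-SNP reference-allele frequencies with HWE genotype expansion.

    ``p_ref`` maps a SNP key (probe_id) to the frequency of the probe's
    reference allele; the alternative allele has q = 1 - p. ``source`` tags
    where the numbers came from (REFERENCE_EUR or COHORT_ESTIMATED).
    """

    p_ref: dict[str, float]
    source: str = "REFERENCE_EUR"

    def __post_init__(self) -> None:
        for key, p in self.p_ref.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"frequency for {key} outside [0,1]: {p}")

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.p_ref

    def p(self, snp_id: str) -> float:
        try:
            return self.p_ref[snp_id]
        except KeyError:
            raise ValidationError(f"no frequency entry for SNP {snp_id!r}") from None

    def genotype_freqs(self, snp_id: str) -> tuple[float, float, float]:
        return hwe_genotype_freqs(self.p(snp_id))

    def genotype_freq(self, snp_id: str, genotype: Genotype) -> float:
        """HWE frequency of one observed genotype at one locus."""
        f = self.genotype_freqs(snp_id)
        return f[int(genotype)]

    def covers(self, panel: Panel) -> list[str]:
        """Probe IDs of the panel missing from this table."""
        return [s.probe_id for s in panel if s.probe_id not in self.p_ref]

    @classmethod
    def from_panel(cls, panel: Panel) -> "FrequencyTable":
        """Reference table from manifest MAFs, taking alt as the minor allele."""
        return cls(
            p_ref={s.probe_id: 1.0 - s.ref_maf for s in panel},
            source="REFERENCE_EUR",
        )

    @classmethod
    def from_matrix(cls, matrix: GenotypeMatrix, panel: Panel) -> "FrequencyTable":
        """Cohort-estimated table via per-probe allele counting."""
        p_ref = {}
        for snp in panel:
            p, _ = estimate_allele_freqs(matrix, snp.probe_id)
            p_ref[snp.probe_id] = p
        return cls(p_ref=p_ref, source="COHORT_ESTIMATED")


@dataclass
class RmpResult:
    """A multiplied-out match probability with its per-locus factors."""

    rmp: float
    n_snps: int
    log10_rmp: float
    per_snp_factors: dict[str, float] = field(default_factory=dict)


@dataclass
class ChiSquareResult:
    snp_id: str
    chi2: float
    df: int
    p_value: float
    significant: bool
    observed: tuple[float, ...]
    expected: tuple[float, ...]


def hwe_genotype_freqs(p: float) -> tuple[float, float, float]:
    """Genotype frequencies (hom-ref, het, hom-alt) implied by HWE.

    ``p`` is the reference-allele frequency; returns (p^2, 2p(1-p), (1-p)^2).
    """
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"allele frequency {p} outside [0,1]")
    q = 1.0 - p
    return (p * p, 2.0 * p * q, q * q)


def snp_match_probability(p: float) -> float:
    """Probability two unrelated individuals share a genotype at one locus.

    Sum of squared HWE genotype frequencies; minimized at 0.375 when p=0.5.
    """
    f = hwe_genotype_freqs(p)
    return f[0] * f[0] + f[1] * f[1] + f[2] * f[2]


def estimate_allele_freqs(matrix: GenotypeMatrix, probe_id: str) -> tuple[float, float]:
    """Cohort reference/alt allele frequencies at one probe by allele counting.

    No-calls are excluded; raises if the probe has zero called genotypes.
    """
    if probe_id not in matrix.calls.columns:
        raise ValidationError(f"probe {probe_id!r} not in matrix")
    col = matrix.calls[probe_id].to_numpy()
    called = col[col != int(Genotype.NO_CALL)]
    if called.size == 0:
        raise ValidationError(f"probe {probe_id!r} has no called genotypes")
    n_alt = int(called.sum())  # codes are alt-allele dosages
    q = n_alt / (2 * called.size)
    return 1.0 - q, q


def panel_rmp(
    freqs: FrequencyTable, snp_ids: Optional[Sequence[str]] = None
) -> RmpResult:
    """Panel-level random match probability over the listed loci.

    Product of per-locus match probabilities (probability of identity),
    accumulated in log10 space. An empty locus list returns the product
    identity rmp=1 with a warning.
    """
    ids = list(snp_ids) if snp_ids is not None else list(freqs.p_ref)
    if not ids:
        logger.warning("panel_rmp over zero loci: returning rmp=1")
        return RmpResult(rmp=1.0, n_snps=0, log10_rmp=0.0)
    factors = {sid: snp_match_probability(freqs.p(sid)) for sid in ids}
    log10_rmp = float(sum(math.log10(f) for f in factors.values()))
    return RmpResult(
        rmp=10.0 ** log10_rmp,
        n_snps=len(ids),
        log10_rmp=log10_rmp,
        per_snp_factors=factors,
    )


def profile_rmp(
    genotypes: Mapping[str, Genotype], freqs: FrequencyTable
) -> RmpResult:
    """Probability of the observed genotype profile under HWE.

    ``genotypes`` maps SNP id to the observed (non-missing) genotype; callers
    pass the concordant loci of a matched sample. Product of per-locus HWE
    genotype frequencies in log10 space.
    """
    if not genotypes:
        logger.warning("profile_rmp over zero loci: returning rmp=1")
        return RmpResult(rmp=1.0, n_snps=0, log10_rmp=0.0)
    factors = {}
    for sid, g in genotypes.items():
        if g is Genotype.NO_CALL:
            raise ValidationError(f"profile_rmp: missing genotype at {sid!r}")
        factors[sid] = freqs.genotype_freq(sid, g)
    if any(f == 0.0 for f in factors.values()):
        zero = [s for s, f in factors.items() if f == 0.0]
        raise ValidationError(
            f"profile_rmp: observed genotype has zero HWE frequency at {zero}"
        )
    log10_rmp = float(sum(math.log10(f) for f in factors.values()))
    return RmpResult(
        rmp=10.0 ** log10_rmp,
        n_snps=len(factors),
        log10_rmp=log10_rmp,
        per_snp_factors=factors,
    )


def chi_square_counts(
    n_ref: int, n_alt: int, ref_p: float, alpha: float = 0.05, snp_id: str = ""
) -> ChiSquareResult:
    """Goodness-of-fit of observed allele counts against a reference frequency.

    df=1, no continuity correction; ``significant`` iff p < alpha.
    """
    if not 0.0 < ref_p < 1.0:
        raise ValidationError(
            f"reference frequency must be in (0,1) for a chi-square test, got {ref_p}"
        )
    n = n_ref + n_alt
    if n == 0:
        raise ValidationError("chi-square needs at least one observed allele")
    expected = (n * ref_p, n * (1.0 - ref_p))
    chi2 = (n_ref - expected[0]) ** 2 / expected[0] + (n_alt - expected[1]) ** 2 / expected[1]
    p_value = float(stats.chi2.sf(chi2, df=1))
    return ChiSquareResult(
        snp_id=snp_id,
        chi2=float(chi2),
        df=1,
        p_value=p_value,
        significant=p_value < alpha,
        observed=(float(n_ref), float(n_alt)),
        expected=expected,
    )


def chi_square_vs_reference(
    matrix: GenotypeMatrix,
    probe_id: str,
    ref_p: float,
    alpha: float = 0.05,
    mode: str = "allele",
) -> ChiSquareResult:
    """Compare cohort frequencies at one probe against a reference population.

    ``mode='allele'`` (default) tests allele counts with df=1; ``'genotype'``
    tests the three genotype counts against HWE expectations with df=2.
    """
    col = matrix.calls[probe_id].to_numpy()
    called = col[col != int(Genotype.NO_CALL)]
    if called.size == 0:
        raise ValidationError(f"probe {probe_id!r} has no called genotypes")
    if mode == "allele":
        n_alt = int(called.sum())
        n_ref = 2 * called.size - n_alt
        return chi_square_counts(n_ref, n_alt, ref_p, alpha=alpha, snp_id=probe_id)
    if mode != "genotype":
        raise ValidationError(f"unknown chi-square mode {mode!r}")
    if not 0.0 < ref_p < 1.0:
        raise ValidationError(
            f"reference frequency must be in (0,1) for a chi-square test, got {ref_p}"
        )
    obs = np.array(
        [int((called == g).sum()) for g in (0, 1, 2)], dtype=float
    )
    exp = np.array(hwe_genotype_freqs(ref_p)) * called.size
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    p_value = float(stats.chi2.sf(chi2, df=2))
    return ChiSquareResult(
        snp_id=probe_id,
        chi2=chi2,
        df=2,
        p_value=p_value,
        significant=p_value < alpha,
        observed=tuple(obs),
        expected=tuple(exp),
    )


def frequency_concordance_report(
    matrix: GenotypeMatrix,
    panel: Panel,
    reference: FrequencyTable,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> list[ChiSquareResult]:
    """Per-SNP chi-square tests of the cohort against reference frequencies.

    Mirrors the suitability check run on a fingerprint panel before use:
    no SNP should show a significant frequency departure from the reference
    population. ``bonferroni`` divides alpha by the number of testable SNPs.
    """
    testable = [
        s for s in panel
        if s.probe_id in reference and 0.0 < reference.p(s.probe_id) < 1.0
    ]
    eff_alpha = alpha / len(testable) if (bonferroni and testable) else alpha
    results = []
    for snp in testable:
        try:
            results.append(
                chi_square_vs_reference(
                    matrix, snp.probe_id, reference.p(snp.probe_id), alpha=eff_alpha
                )
            )
        except ValidationError as exc:
            logger.warning("frequency test skipped for %s: %s", snp.probe_id, exc)
    return results
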