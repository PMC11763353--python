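"""Core containers for the sample-identity tracking engine.

A fingerprint panel is a small set of biallelic SNVs genotyped on an
orthogonal platform (an OpenArray-style real-time-PCR array) for every sample
that is also exome sequenced. Each sample then has two genotype sources: the
panel call table (diploid calls incl. no-calls) and a single-sample VCF that,
by convention, contains only non-reference records. The matching engine
aligns the two by chromosome/position and classifies every panel site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Iterator, Optional

import pandas as pd

VALID_BASES = frozenset("ACGT")


class Genotype(IntEnum):
    """Diploid genotype of a biallelic SNV, coded by alt-allele dosage."""

    NO_CALL = -1
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2


class Status(str, Enum):
    """Per-site comparison outcome between the array call and the VCF."""

    CONCORDANT = "CONCORDANT"
    DISCORDANT = "DISCORDANT"
    EXPECTED_ABSENT_WT = "EXPECTED_ABSENT_WT"
    UNEXPECTED_ABSENT = "UNEXPECTED_ABSENT"
    OA_NO_CALL = "OA_NO_CALL"


class Sheet(str, Enum):
    """Report partition: MERGE iff a VCF record exists at the panel locus."""

    MERGE = "MERGE"
    NO_MERGE = "NO_MERGE"


class Verdict(str, Enum):
    SAME = "SAME"
    DIFFERENT = "DIFFERENT"
    INCONCLUSIVE = "INCONCLUSIVE"


#: STATUS values that flag a discrepancy (rendered red in the report).
RED_STATUSES = frozenset({Status.DISCORDANT, Status.UNEXPECTED_ABSENT})


class ValidationError(ValueError):
    """Raised when an input file violates a documented invariant."""


def normalize_chrom(chrom: str) -> str:
    """Collapse 'chr7'/'7' (and 'MT'/'M') to a single chromosome key."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.upper() == "MT":
        c = "M"
    return c.upper() if c.upper() in {"X", "Y", "M"} else c


@dataclass(frozen=True)
class PanelSNP:
    """One fingerprint SNP: assay probe, dbSNP id, hg19 locus, alleles, MAF."""

    probe_id: str
    rsid: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    ref_maf: float

    def __post_init__(self) -> None:
        if self.ref_allele not in VALID_BASES or self.alt_allele not in VALID_BASES:
            raise ValidationError(
                f"{self.probe_id}: alleles must be single bases in ACGT, "
                f"got ref={self.ref_allele!r} alt={self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValidationError(f"{self.probe_id}: ref and alt alleles are identical")
        if not 0.0 <= self.ref_maf <= 0.5:
            raise ValidationError(
                f"{self.probe_id}: MAF {self.ref_maf} outside [0, 0.5]"
            )
        if self.pos < 1:
            raise ValidationError(f"{self.probe_id}: position {self.pos} < 1")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))

    @property
    def locus(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass
class Panel:
    """Ordered collection of fingerprint SNPs with unique probes and loci."""

    snps: list[PanelSNP]

    def __post_init__(self) -> None:
        seen_probe: dict[str, PanelSNP] = {}
        seen_locus: dict[tuple[str, int], PanelSNP] = {}
        for snp in self.snps:
            if snp.probe_id in seen_probe:
                raise ValidationError(f"duplicate probe_id {snp.probe_id!r}")
            other = seen_locus.get(snp.locus)
            if other is not None:
                raise ValidationError(
                    f"duplicate locus {snp.chrom}:{snp.pos} shared by probes "
                    f"{other.probe_id!r} and {snp.probe_id!r}"
                )
            seen_probe[snp.probe_id] = snp
            seen_locus[snp.locus] = snp
        self._by_probe = seen_probe
        self._by_locus = seen_locus

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self) -> Iterator[PanelSNP]:
        return iter(self.snps)

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self._by_probe

    @property
    def probe_ids(self) -> list[str]:
        return [s.probe_id for s in self.snps]

    def by_probe(self, probe_id: str) -> PanelSNP:
        return self._by_probe[probe_id]

    def by_locus(self, chrom: str, pos: int) -> Optional[PanelSNP]:
        return self._by_locus.get((normalize_chrom(chrom), pos))

    def subset(self, probe_ids: list[str]) -> "Panel":
        """New panel keeping only the listed probes, original order preserved."""
        keep = set(probe_ids)
        return Panel([s for s in self.snps if s.probe_id in keep])


@dataclass(frozen=True)
class GenotypeCall:
    """One sample x probe diploid call; alleles empty for a no-call."""

    sample_id: str
    probe_id: str
    call: Genotype
    alleles: frozenset = frozenset()


@dataclass
class GenotypeMatrix:
    """Sample x probe grid of genotype codes (see :class:`Genotype`).

    ``calls`` is an int8 DataFrame indexed by sample_id with probe_id columns;
    missing (sample, probe) pairs are NO_CALL. ``rejects`` collects rows whose
    alleles did not match the panel's ref/alt, rather than dropping them
    silently.
    """

    calls: pd.DataFrame
    rejects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["sample_id", "probe_id", "alleles", "reason"]
        )
    )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.calls.columns)

    def genotype(self, sample_id: str, probe_id: str) -> Genotype:
        return Genotype(int(self.calls.at[sample_id, probe_id]))

    def sample_profile(self, sample_id: str) -> dict[str, Genotype]:
        """Probe -> genotype map for one sample."""
        row = self.calls.loc[sample_id]
        return {p: Genotype(int(v)) for p, v in row.items()}


@dataclass(frozen=True)
class VcfRecord:
    """One single-sample VCF data line restricted to what matching needs."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    gt: tuple[Optional[int], Optional[int]]

    @property
    def locus(self) -> tuple[str, int]:
        return (normalize_chrom(self.chrom), self.pos)


@dataclass
class VariantSet:
    """Non-reference records for one sample, keyed by normalized locus."""

    sample_id: str
    records: dict[tuple[str, int], VcfRecord] = field(default_factory=dict)

    def at(self, chrom: str, pos: int) -> Optional[VcfRecord]:
        return self.records.get((normalize_chrom(chrom), pos))

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class MatchRecord:
    """Comparison of one panel site: array call vs (possibly absent) VCF call."""

    panel_snp: PanelSNP
    oa_call: Genotype
    wes_genotype: Optional[Genotype]  # None = no usable record at the locus
    status: Status
    sheet: Sheet


@dataclass
class MatchResult:
    """Per sample-pair outcome: site records, concordance, RMP, verdict."""

    oa_sample_id: str
    vcf_sample_id: str
    records: list[MatchRecord]
    concordance_rate: Optional[float]  # percent in [0, 100]; None if undefined
    profile_rmp: Optional[float]
    verdict: Verdict

    @property
    def merge_records(self) -> list[MatchRecord]:
        return [r for r in self.records if r.sheet is Sheet.MERGE]

    @property
    def no_merge_records(self) -> list[MatchRecord]:
        return [r for r in self.records if r.sheet is Sheet.NO_MERGE]

    def status_counts(self) -> dict[Status, int]:
        counts = {s: 0 for s in Status}
        for rec in self.records:
            counts[rec.status] += 1
        return counts
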