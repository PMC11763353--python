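"""Readers and writers for the tabular formats the engine consumes.

Formats
-------
Panel manifest
    TSV/CSV with header ``probe_id, rsid, chrom, pos, ref, alt, ref_maf``
    (``ref_allele``/``alt_allele`` accepted as synonyms). One row per
    fingerprint SNP, hg19 coordinates, 1-based.
Array call table (canonical long format)
    TSV/CSV with header ``sample_id, probe_id, alleles`` where alleles is an
    unordered base pair like ``A/G``; no-calls are ``NOCALL``
    (case-insensitive), ``./.`` or empty. Vendor exports with other column
    names are handled via a column mapping.
Variant input
    VCF v4.x, plain or bgzipped, exactly one sample, GT present. Only SNV
    records at panel loci are kept.
Frequency table
    TSV with header ``snp_id, p_ref, source`` (reference-allele frequency).
Match report
    XLSX workbook with "MERGE" / "NO MERGE" / "SUMMARY" sheets, or a TSV
    fallback carrying a ``sheet`` column plus a sibling ``.summary.tsv``.
"""

from __future__ import annotations

import logging
import os
from typing import Optional, Sequence

import pandas as pd
import pysam

from .model import (
    Genotype,
    GenotypeMatrix,
    MatchResult,
    Panel,
    PanelSNP,
    RED_STATUSES,
    Status,
    ValidationError,
    VariantSet,
    VcfRecord,
    normalize_chrom,
)
from .popgen import FrequencyTable

logger = logging.getLogger("sampletrack")

NO_CALL_TOKENS = {"nocall", "./.", ".", ""}

_PANEL_SYNONYMS = {
    "ref": "ref_allele",
    "alt": "alt_allele",
    "maf": "ref_maf",
    "position": "pos",
    "chromosome": "chrom",
}


def _read_table(path: str) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_panel(path: str) -> Panel:
    """Load a panel manifest, enforcing allele/locus/probe invariants.

    Duplicate probe IDs or loci raise :class:`ValidationError` naming the
    offending rows; an empty manifest yields an empty panel with a warning.
    """
    df = _read_table(path)
    df = df.rename(columns={c: _PANEL_SYNONYMS.get(c.lower(), c.lower()) for c in df.columns})
    required = ["probe_id", "rsid", "chrom", "pos", "ref_allele", "alt_allele", "ref_maf"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: panel manifest missing columns {missing}")
    snps = [
        PanelSNP(
            probe_id=row.probe_id,
            rsid=row.rsid,
            chrom=row.chrom,
            pos=int(row.pos),
            ref_allele=row.ref_allele.upper(),
            alt_allele=row.alt_allele.upper(),
            ref_maf=float(row.ref_maf),
        )
        for row in df.itertuples(index=False)
    ]
    if not snps:
        logger.warning("%s: empty panel manifest (header only)", path)
    return Panel(snps)


def write_panel(panel: Panel, path: str) -> None:
    pd.DataFrame(
        {
            "probe_id": [s.probe_id for s in panel],
            "rsid": [s.rsid for s in panel],
            "chrom": [s.chrom for s in panel],
            "pos": [s.pos for s in panel],
            "ref": [s.ref_allele for s in panel],
            "alt": [s.alt_allele for s in panel],
            "ref_maf": [s.ref_maf for s in panel],
        }
    ).to_csv(path, sep="\t", index=False)


def _classify_alleles(alleles: str, snp: PanelSNP) -> tuple[Genotype, Optional[str]]:
    """Map an unordered allele-pair string onto a genotype code.

    Returns (genotype, rejection reason). Allele order carries no meaning.
    """
    raw = alleles.strip()
    if raw.lower() in NO_CALL_TOKENS:
        return Genotype.NO_CALL, None
    pair = [a for a in raw.replace("|", "/").upper().split("/") if a]
    if len(pair) == 1 and len(pair[0]) == 2:  # compact "AG" form
        pair = list(pair[0])
    if len(pair) != 2:
        return Genotype.NO_CALL, f"unparseable allele pair {alleles!r}"
    bad = [a for a in pair if a not in {snp.ref_allele, snp.alt_allele}]
    if bad:
        return (
            Genotype.NO_CALL,
            f"allele(s) {'/'.join(bad)} not in probe alleles "
            f"{snp.ref_allele}/{snp.alt_allele}",
        )
    dosage = sum(a == snp.alt_allele for a in pair)
    return Genotype(dosage), None


def read_oa_calls(
    path: str,
    panel: Panel,
    columns: Optional[dict[str, str]] = None,
) -> GenotypeMatrix:
    """Load an array call table into a sample x probe genotype matrix.

    Probes absent from the panel are dropped with a warning; (sample, probe)
    pairs absent from the file become NO_CALL; rows whose alleles contradict
    the probe's ref/alt land in the matrix as NO_CALL and are collected in
    the rejects report.

    Parameters
    ----------
    columns
        Optional mapping from canonical names (``sample_id``, ``probe_id``,
        ``alleles``) to the column names used in the file.
    """
    df = _read_table(path)
    colmap = {"sample_id": "sample_id", "probe_id": "probe_id", "alleles": "alleles"}
    if columns:
        colmap.update(columns)
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise ValidationError(f"{path}: call table missing columns {missing}")
    df = df.rename(columns={v: k for k, v in colmap.items()})

    samples: list[str] = []
    seen = set()
    for s in df["sample_id"]:
        if s not in seen:
            seen.add(s)
            samples.append(s)

    calls = pd.DataFrame(
        int(Genotype.NO_CALL),
        index=pd.Index(samples, name="sample_id"),
        columns=pd.Index(panel.probe_ids, name="probe_id"),
        dtype="int8",
    )
    rejects: list[dict] = []
    unknown_probes: set[str] = set()
    for row in df.itertuples(index=False):
        sample = row.sample_id
        probe = row.probe_id
        alleles = row.alleles
        if probe not in panel:
            unknown_probes.add(probe)
            continue
        geno, reason = _classify_alleles(alleles, panel.by_probe(probe))
        if reason is not None:
            rejects.append(
                {"sample_id": sample, "probe_id": probe, "alleles": alleles, "reason": reason}
            )
        calls.at[sample, probe] = int(geno)
    for probe in sorted(unknown_probes):
        logger.warning("%s: probe %s not in panel; rows dropped", path, probe)
    return GenotypeMatrix(
        calls=calls,
        rejects=pd.DataFrame(rejects, columns=["sample_id", "probe_id", "alleles", "reason"]),
    )


def write_oa_calls(matrix: GenotypeMatrix, panel: Panel, path: str) -> None:
    """Serialize a genotype matrix back to the canonical long call table."""
    rows = []
    for sample in matrix.sample_ids:
        for probe in matrix.probe_ids:
            geno = matrix.genotype(sample, probe)
            snp = panel.by_probe(probe)
            rows.append(
                {
                    "sample_id": sample,
                    "probe_id": probe,
                    "alleles": genotype_allele_string(geno, snp),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def genotype_allele_string(geno: Genotype, snp: PanelSNP) -> str:
    """Render a genotype code as an allele pair (``NOCALL`` for no-calls)."""
    if geno is Genotype.NO_CALL:
        return "NOCALL"
    a = {
        Genotype.HOM_REF: (snp.ref_allele, snp.ref_allele),
        Genotype.HET: (snp.ref_allele, snp.alt_allele),
        Genotype.HOM_ALT: (snp.alt_allele, snp.alt_allele),
    }[geno]
    return f"{a[0]}/{a[1]}"


def read_vcf(path: str, panel: Panel) -> VariantSet:
    """Load the panel-locus records of a single-sample VCF.

    Chromosome labels are normalized so "chr1" and "1" collide; indels at
    panel loci are ignored with a warning; at a duplicated locus the first
    PASS/unfiltered record wins; half-calls (e.g. ``0/.``) are dropped so the
    locus reads as absent.
    """
    vf = pysam.VariantFile(path)
    samples = list(vf.header.samples)
    if len(samples) != 1:
        raise ValidationError(
            f"{path}: expected exactly one sample per VCF, found {len(samples)} "
            f"({samples}); split multi-sample files first"
        )
    sample = samples[0]
    records: dict[tuple[str, int], VcfRecord] = {}
    filtered_at: dict[tuple[str, int], bool] = {}  # locus -> kept record passed filter
    for rec in vf:
        locus = (normalize_chrom(rec.chrom), rec.pos)
        snp = panel.by_locus(*locus)
        if snp is None:
            continue
        alts = tuple(a for a in (rec.alts or ()) if a is not None)
        if len(rec.ref) != 1 or any(len(a) != 1 for a in alts):
            logger.warning(
                "%s: non-SNV record at panel locus %s:%d ignored", path, rec.chrom, rec.pos
            )
            continue
        sdata = rec.samples[sample]
        if "GT" not in sdata or sdata["GT"] is None:
            raise ValidationError(f"{path}: record {rec.chrom}:{rec.pos} has no GT field")
        gt = tuple(sdata["GT"])
        if len(gt) != 2 or any(a is None for a in gt):
            logger.warning(
                "%s: half-call at %s:%d treated as absent", path, rec.chrom, rec.pos
            )
            continue
        passed = len(rec.filter) == 0 or "PASS" in rec.filter
        if locus in records:
            if filtered_at[locus] or not passed:
                logger.warning(
                    "%s: duplicate record at %s:%d ignored (first usable kept)",
                    path, rec.chrom, rec.pos,
                )
                continue
            logger.warning(
                "%s: duplicate record at %s:%d replaces non-PASS record",
                path, rec.chrom, rec.pos,
            )
        records[locus] = VcfRecord(
            chrom=locus[0], pos=rec.pos, ref=rec.ref.upper(),
            alts=tuple(a.upper() for a in alts), gt=gt,
        )
        filtered_at[locus] = passed
    sample_id = os.path.basename(str(path))
    for suffix in (".vcf.gz", ".vcf"):
        if sample_id.endswith(suffix):
            sample_id = sample_id[: -len(suffix)]
    return VariantSet(sample_id=sample if sample else sample_id, records=records)


def read_freq_table(path: str) -> FrequencyTable:
    """Load a per-SNP reference-allele frequency table."""
    df = _read_table(path)
    required = {"snp_id", "p_ref"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: frequency table needs columns {sorted(required)}")
    source = "REFERENCE_EUR"
    if "source" in df.columns and len(df) and df["source"].iloc[0]:
        source = df["source"].iloc[0]
    return FrequencyTable(
        p_ref={row.snp_id: float(row.p_ref) for row in df.itertuples(index=False)},
        source=source,
    )


def write_freq_table(freqs: FrequencyTable, path: str) -> None:
    pd.DataFrame(
        {
            "snp_id": list(freqs.p_ref),
            "p_ref": [freqs.p_ref[k] for k in freqs.p_ref],
            "source": freqs.source,
        }
    ).to_csv(path, sep="\t", index=False)


def _flag(status: Status) -> str:
    if status in RED_STATUSES:
        return "red"
    if status is Status.EXPECTED_ABSENT_WT:
        return "green"
    return ""


def _records_frame(results: Sequence[MatchResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for rec in res.records:
            snp = rec.panel_snp
            rows.append(
                {
                    "oa_sample": res.oa_sample_id,
                    "vcf_sample": res.vcf_sample_id,
                    "probe_id": snp.probe_id,
                    "rsid": snp.rsid,
                    "chrom": snp.chrom,
                    "pos": snp.pos,
                    "oa_genotype": genotype_allele_string(rec.oa_call, snp),
                    "wes_genotype": (
                        genotype_allele_string(rec.wes_genotype, snp)
                        if rec.wes_genotype is not None
                        else ("ABSENT" if rec.sheet.value == "NO_MERGE" else "UNEXPECTED")
                    ),
                    "status": rec.status.value,
                    "flag": _flag(rec.status),
                    "sheet": rec.sheet.value,
                }
            )
    return pd.DataFrame(rows)


def _summary_frame(results: Sequence[MatchResult]) -> pd.DataFrame:
    import numpy as np

    rows = []
    for res in results:
        counts = res.status_counts()
        rows.append(
            {
                "oa_sample": res.oa_sample_id,
                "vcf_sample": res.vcf_sample_id,
                "n_sites": len(res.records),
                "n_merge": len(res.merge_records),
                "n_no_merge": len(res.no_merge_records),
                "n_concordant": counts[Status.CONCORDANT],
                "n_discordant": counts[Status.DISCORDANT],
                "n_expected_absent_wt": counts[Status.EXPECTED_ABSENT_WT],
                "n_unexpected_absent": counts[Status.UNEXPECTED_ABSENT],
                "n_oa_no_call": counts[Status.OA_NO_CALL],
                "concordance_pct": res.concordance_rate,
                "profile_rmp": res.profile_rmp,
                "log10_profile_rmp": (
                    float(np.log10(res.profile_rmp))
                    if res.profile_rmp not in (None, 0)
                    else None
                ),
                "verdict": res.verdict.value,
            }
        )
    return pd.DataFrame(rows)


def write_report(results: Sequence[MatchResult], path: str) -> None:
    """Write the two-sheet match report.

    ``.xlsx`` paths get a workbook with "MERGE", "NO MERGE" and "SUMMARY"
    sheets; any other extension gets a TSV with a ``sheet`` column plus a
    sibling ``<stem>.summary.tsv``. Every (sample, panel SNP) pair appears in
    exactly one of the two sheets.
    """
    if not results:
        raise ValidationError("write_report: no match results to write")
    records = _records_frame(results)
    summary = _summary_frame(results)
    path = str(path)
    if path.endswith(".xlsx"):
        with pd.ExcelWriter(path, engine="openpyxl") as xl:
            records[records["sheet"] == "MERGE"].drop(columns="sheet").to_excel(
                xl, sheet_name="MERGE", index=False
            )
            records[records["sheet"] == "NO_MERGE"].drop(columns="sheet").to_excel(
                xl, sheet_name="NO MERGE", index=False
            )
            summary.to_excel(xl, sheet_name="SUMMARY", index=False)
    else:
        records.to_csv(path, sep="\t", index=False)
        stem, _ = os.path.splitext(path)
        summary.to_csv(stem + ".summary.tsv", sep="\t", index=False)
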