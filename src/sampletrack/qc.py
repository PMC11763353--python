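"""Probe-level quality control: call rates and the panel exclusion filter.

A probe's call rate is the fraction of loaded samples for which the assay
returned a genotype. Probes are excluded either automatically (call rate
below a threshold, default 90%) or via a manual exclusion list standing in
for failures only visible on amplification plots — reduced amplification
efficiency or poor discrimination of heterozygous clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import Genotype, GenotypeMatrix, Panel, ValidationError


@dataclass
class QcReport:
    """Per-probe call rates with exclusion flags and reasons.

    ``table`` columns: probe_id, call_rate, excluded, reason where reason is
    LOW_CALL_RATE, MANUAL_EXCLUSION or NONE (excluded iff reason != NONE).
    """

    table: pd.DataFrame
    threshold: float

    @property
    def retained_probe_ids(self) -> list[str]:
        return list(self.table.loc[~self.table["excluded"], "probe_id"])

    @property
    def excluded_probe_ids(self) -> list[str]:
        return list(self.table.loc[self.table["excluded"], "probe_id"])

    @property
    def mean_call_rate(self) -> float:
        return float(self.table["call_rate"].mean())

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def probe_call_rate(matrix: GenotypeMatrix, probe_id: str) -> float:
    """Fraction of samples with a genotype (non no-call) at one probe."""
    if probe_id not in matrix.calls.columns:
        raise ValidationError(f"unknown probe {probe_id!r}")
    col = matrix.calls[probe_id]
    if len(col) == 0:
        raise ValidationError("call rate undefined: matrix has no samples")
    return float((col != int(Genotype.NO_CALL)).mean())


def sample_call_rates(matrix: GenotypeMatrix) -> pd.Series:
    """Per-sample call rate across probes (diagnostic companion report)."""
    return (matrix.calls != int(Genotype.NO_CALL)).mean(axis=1)


def apply_probe_filters(
    matrix: GenotypeMatrix,
    panel: Panel,
    threshold: float = 0.90,
    manual_exclusions: list[str] | None = None,
) -> tuple[Panel, QcReport]:
    """Exclude low-call-rate and manually flagged probes from the panel.

    Probes with call rate < ``threshold`` are excluded as LOW_CALL_RATE;
    probes listed in ``manual_exclusions`` as MANUAL_EXCLUSION (taking
    precedence when both apply would be arbitrary — manual review outranks
    the automatic rule, so the manual reason is recorded). The retained
    panel preserves the original probe order.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValidationError(f"call-rate threshold must be in (0,1], got {threshold}")
    manual = list(manual_exclusions or [])
    unknown = [p for p in manual if p not in panel]
    if unknown:
        raise ValidationError(f"manual exclusions name unknown probes: {unknown}")
    rows = []
    for snp in panel:
        rate = probe_call_rate(matrix, snp.probe_id)
        if snp.probe_id in manual:
            reason = "MANUAL_EXCLUSION"
        elif rate < threshold:
            reason = "LOW_CALL_RATE"
        else:
            reason = "NONE"
        rows.append(
            {
                "probe_id": snp.probe_id,
                "call_rate": rate,
                "excluded": reason != "NONE",
                "reason": reason,
            }
        )
    report = QcReport(table=pd.DataFrame(rows), threshold=threshold)
    retained = panel.subset(report.retained_probe_ids)
    return retained, report
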