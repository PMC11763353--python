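import numpy as np
import pandas as pd
import pytest

from sampletrack.data import synthetic_panel_path
from sampletrack.io import read_panel
from sampletrack.model import Genotype, GenotypeMatrix, Panel, PanelSNP


@pytest.fixture(scope="session")
def bundled_panel() -> Panel:
    """The bundled synthetic 60-SNP manifest."""
    return read_panel(str(synthetic_panel_path()))


def make_panel(mafs, chrom_start=1) -> Panel:
    """Small hand-built panel with the given minor-allele frequencies."""
    pairs = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    snps = []
    for i, maf in enumerate(mafs):
        ref, alt = pairs[i % len(pairs)]
        snps.append(
            PanelSNP(
                probe_id=f"P{i + 1:03d}",
                rsid=f"rs{i + 1}",
                chrom=str(((chrom_start + i - 1) % 22) + 1),
                pos=1000 + i * 10,
                ref_allele=ref,
                alt_allele=alt,
                ref_maf=float(maf),
            )
        )
    return Panel(snps)


@pytest.fixture
def small_panel() -> Panel:
    return make_panel([0.5, 0.3, 0.1, 0.25, 0.4])


def matrix_from_codes(codes: dict, probe_ids) -> GenotypeMatrix:
    """Build a genotype matrix from {sample_id: [codes...]}."""
    calls = pd.DataFrame.from_dict(codes, orient="index", dtype="int8")
    calls.columns = pd.Index(list(probe_ids), name="probe_id")
    calls.index.name = "sample_id"
    return GenotypeMatrix(calls=calls)


def profile_from_codes(panel: Panel, codes) -> dict:
    return {s.probe_id: Genotype(int(c)) for s, c in zip(panel, codes)}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
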