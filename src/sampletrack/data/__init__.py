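"""Bundled synthetic reference tables.

``synthetic_eur_panel.tsv`` is a synthetic 60-SNP fingerprint panel manifest
with EUR-style minor-allele frequencies. It is not a published panel: the
MAF spectrum was constructed to honor the design constraints of a WES
sample-tracking panel (55 common SNPs with MAF > 1% spread over the
autosomes, 5 rare ancestry-informative SNPs at MAF 0.5%) and to carry the
discriminative power expected of such a panel (log10 probability of
identity near -17 over 60 loci, near -14.6 over the 55 QC-passing loci).
The five probes that fail QC in the bundled worked example sit at high MAF.
"""

from importlib import resources


def synthetic_panel_path():
    """Filesystem path of the bundled synthetic 60-SNP panel manifest."""
    return resources.files(__package__) / "synthetic_eur_panel.tsv"


#: Probes with call rate below 90% in the bundled worked example.
LOW_CALL_RATE_PROBES = ["C__29554891_10", "C___2259382_10"]

#: Probes excluded after manual amplification-plot review in the worked
#: example: one with reduced amplification efficiency, two with poor
#: heterozygote discrimination.
MANUAL_EXCLUSION_PROBES = ["C___2171394_10", "C___2592567_10", "C___2567433_10"]
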