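"""Bundled reference tables from a published multi-breed Brazilian cattle
panel (19 breeds in four ancestry groups), used as worked-example inputs
and as fixtures for convention checks.

The tables carry per-breed sample and marker counts after QC, the fitted
LD-decay coefficients (beta) with standard errors, and the reported ROH
islands (chromosome, bounds, marker count, sharing frequency).  They are
inputs to the clustering and bookkeeping utilities, not outputs of this
package.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["breed_panel", "ld_decay_estimates", "roh_islands"]

_PANEL = [
    # breed, group, n_animals, n_markers
    ("ANG", "taurine", 31, 41580),
    ("BWS", "taurine", 34, 39780),
    ("JER", "taurine", 260, 35269),
    ("HOL", "taurine", 107, 38946),
    ("BRA", "indicine", 30, 31284),
    ("GIR", "indicine", 127, 24062),
    ("IND", "indicine", 45, 28776),
    ("NEL", "indicine", 23, 69448),
    ("SIN", "indicine", 92, 32264),
    ("TAB", "indicine", 49, 69808),
    ("CCD", "locally_adapted", 55, 37108),
    ("CCB", "locally_adapted", 24, 36353),
    ("CRI", "locally_adapted", 62, 40796),
    ("CUR", "locally_adapted", 17, 30332),
    ("FRA", "locally_adapted", 54, 35444),
    ("MOC", "locally_adapted", 20, 38266),
    ("PAN", "locally_adapted", 49, 36641),
    ("CAN", "crossbred", 121, 37174),
    ("GIO", "crossbred", 120, 47295),
]

#: Reported group totals for cross-checking the per-breed counts.
GROUP_TOTALS = {"taurine": 432, "indicine": 366, "locally_adapted": 281,
                "crossbred": 241}
PANEL_TOTAL = 1320

_BETA = [
    # breed, beta_hat, se
    ("GIO", 3.211e-5, 2.4640e-2),
    ("CRI", 3.193e-5, 2.2346e-2),
    ("CAN", 3.150e-5, 2.2845e-2),
    ("IND", 2.780e-5, 2.8360e-2),
    ("GIR", 2.544e-5, 2.8594e-2),
    ("TAB", 2.441e-5, 4.2235e-2),
    ("SIN", 2.375e-5, 3.9809e-2),
    ("PAN", 2.344e-5, 3.3130e-2),
    ("ANG", 2.277e-5, 3.4902e-2),
    ("BRA", 2.277e-5, 3.8608e-2),
    ("MOC", 2.259e-5, 3.1316e-2),
    ("CCB", 2.205e-5, 3.1080e-2),
    ("FRA", 2.153e-5, 3.5613e-2),
    ("BWS", 2.038e-5, 3.3468e-2),
    ("NEL", 1.907e-5, 5.2770e-2),
    ("HOL", 1.812e-5, 4.0766e-2),
    ("CCD", 1.734e-5, 4.3804e-2),
    ("JER", 1.401e-5, 5.6142e-2),
    ("CUR", 1.102e-5, 6.2879e-2),
]

_ISLANDS = [
    # group, breed, chrom, start_bp, end_bp, reported_length_bp, n_snp, freq_pct
    ("taurine", "JER", "7", 42_096_163, 43_741_249, 1_645_086, 17, 68),
    ("indicine", "BRA", "14", 23_498_304, 23_964_115, 465_811, 9, 63),
    ("indicine", "IND", "6", 36_614_641, 40_780_850, 4_166_209, 35, 58),
    # the reported TAB length (823) is inconsistent with its bounds and is
    # kept verbatim; compute end - start for the consistent value
    ("indicine", "TAB", "1", 2_210_624, 3_033_433, 823, 30, 55),
    ("locally_adapted", "CCD", "20", 38_452_484, 39_965_197, 1_512_713, 21, 69),
    ("locally_adapted", "CCB", "20", 38_108_826, 38_675_350, 566_524, 9, 79),
    ("locally_adapted", "CUR", "11", 54_590_248, 60_271_069, 5_680_821, 57, 59),
]


def breed_panel() -> pd.DataFrame:
    """Per-breed sample and marker counts with ancestry group labels."""
    return pd.DataFrame(_PANEL, columns=["breed", "group", "n_animals", "n_markers"])


def ld_decay_estimates() -> pd.DataFrame:
    """Fitted decay coefficients (beta) and SEs for the 19 breeds."""
    return pd.DataFrame(_BETA, columns=["breed", "beta_hat", "se"])


def roh_islands() -> pd.DataFrame:
    """Reported ROH islands shared by >50% of individuals per breed."""
    return pd.DataFrame(
        _ISLANDS,
        columns=["group", "breed", "chrom", "start_bp", "end_bp",
                 "reported_length_bp", "n_snp", "freq_pct"],
    )
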