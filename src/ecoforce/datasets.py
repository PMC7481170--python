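"""Published worked-example data bundled with the package.

The values below are the published evaluation of the 18-member
EURO-CORDEX GCM-downscaling ensemble against the Maastricht Airport
station (1951-2005), and the ETCCDI characterisation of the selected
CCLM4-8-17 / EC-EARTH forcing windows at the ecotron site. They serve
as inputs to worked examples and regression checks of the ranking and
bookkeeping logic; they are not recomputable without the EURO-CORDEX
archive.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "eurocordex_maastricht_precip_bias",
    "forcing_window_index_changes",
    "warming_window_years",
]

# (RCM, driving GCM, annual precipitation bias mm/yr, published rank)
_PRECIP_BIAS_ROWS = [
    ("CCLM4-8-17", "CNRM-CERFACS-CNRM-CM5", 145, 8),
    ("CCLM4-8-17", "ICHEC-EC-EARTH", 8, 1),
    ("CCLM4-8-17", "MOHC-HadGEM2-ES", -174, 9),
    ("CCLM4-8-17", "MPI-M-MPI-ESM-LR", 24, 2),
    ("ALADIN53", "CNRM-CERFACS-CNRM-CM5", 550, 14),
    ("HIRHAM5", "ICHEC-EC-EARTH", 323, 12),
    ("HIRHAM5", "MOHC-HadGEM2-ES", 101, 6),
    ("HIRHAM5", "NCC-NorESM1-M", 571, 16),
    ("WRF331F", "IPSL-IPSL-CM5A-MR", 726, 18),
    ("RACMO22E", "ICHEC-EC-EARTH", 99, 5),
    ("RACMO22E", "MOHC-HadGEM2-ES", 36, 3),
    ("REMO2009", "MPI-M-MPI-ESM-LR", 225, 10),
    ("ALARO-0", "CNRM-CERFACS-CNRM-CM5", 560, 15),
    ("RCA4", "CNRM-CERFACS-CNRM-CM5", 319, 11),
    ("RCA4", "ICHEC-EC-EARTH", 386, 13),
    ("RCA4", "IPSL-IPSL-CM5A-MR", 691, 17),
    ("RCA4", "MOHC-HadGEM2-ES", 111, 7),
    ("RCA4", "MPI-M-MPI-ESM-LR", 70, 4),
]


def eurocordex_maastricht_precip_bias() -> pd.DataFrame:
    """Annual precipitation bias (mm/yr) and published 1-18 rank per run."""
    frame = pd.DataFrame(
        _PRECIP_BIAS_ROWS, columns=["rcm", "gcm", "bias_mm_yr", "published_rank"]
    )
    frame.index = frame["rcm"] + "/" + frame["gcm"]
    return frame


# Reference-period (1951-1955) absolute values and per-threshold changes of
# the ETCCDI indices for the selected CCLM4-8-17 / EC-EARTH forcing.
_INDEX_CHANGES = {
    #            ref      +1     +1.5    +2      +3      +4
    "T":        (8.17,    1.13,  1.14,   1.81,   3.15,   4.49),
    "TXx":      (30.98,   0.82,  1.66,   1.34,   5.24,   6.30),
    "TNn":      (-12.73,  6.75,  3.34,   5.94,   8.27,  10.21),
    "frost_days": (103,  -22.0, -14.8,  -36.4,  -59.0,  -76.2),
    "summer_days": (11.4,  4.0,  12.2,    8.6,   26.2,   36.6),
    "GSL":      (225.6,    9.6,  20.0,   33.6,   45.8,   80.0),
    "PRCPTOT":  (771.09, -81.32, -57.2,  25.12, -23.14, -136.05),
    "Rx1day":   (14.38,  -0.2,   0.35,   1.92,   2.34,   0.5),
    "R10mm":    (14.6,    0.0,  -1.0,    3.2,    3.6,   -1.2),
    "CDD":      (17.2,    2.4,   9.6,    1.6,    7.2,   11.8),
    "CWD":      (9.6,    -0.2,   1.2,    1.4,    0.0,   -1.8),
}

_THRESHOLDS = (1.0, 1.5, 2.0, 3.0, 4.0)


def forcing_window_index_changes() -> pd.DataFrame:
    """Index changes per warming threshold; column 'reference' holds 0 degC values."""
    frame = pd.DataFrame(
        {name: vals for name, vals in _INDEX_CHANGES.items()},
        index=["reference", *_THRESHOLDS],
    ).T
    return frame


def warming_window_years() -> dict[float, tuple[int, int]]:
    """Published 5-year extraction windows per warming threshold."""
    return {
        0.0: (1951, 1955),
        1.0: (2011, 2015),
        1.5: (2028, 2032),
        2.0: (2043, 2047),
        3.0: (2067, 2071),
        4.0: (2091, 2095),
    }
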