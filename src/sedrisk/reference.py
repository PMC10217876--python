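"""Published reference constants for sediment heavy-metal risk assessment.

Toxic-response coefficients for Håkanson's ecological-risk index, TEL/PEL
sediment-quality guidelines, and the summary statistics of the Warta River
monitoring panel (2010–2021, 35 sites) that the synthetic generator and the
worked examples are calibrated to.

All concentrations are mg·kg⁻¹ dry weight unless noted; TOC in percent, pH
unitless.
"""

from __future__ import annotations

# Controlled analyte vocabulary.  The ten risk-assessed metals, the EF
# reference element, and the two auxiliary sediment descriptors.
METALS: tuple[str, ...] = ("As", "Cd", "Co", "Cr", "Cu", "Hg", "Mn", "Ni", "Pb", "Zn")
REFERENCE_ELEMENT = "Fe"
AUXILIARY: tuple[str, ...] = ("TOC", "pH")
ANALYTES: tuple[str, ...] = METALS + (REFERENCE_ELEMENT,) + AUXILIARY

# Håkanson toxic-response coefficients Tr for the single-metal ecological
# risk Er = Tr × (C / GB).  Unitless.
TRI_COEFF: dict[str, float] = {
    "As": 10.0,
    "Cd": 30.0,
    "Co": 5.0,
    "Cr": 2.0,
    "Cu": 5.0,
    "Hg": 40.0,
    "Mn": 1.0,
    "Ni": 5.0,
    "Pb": 5.0,
    "Zn": 1.0,
}

# Threshold effect level (TEL) and probable effect level (PEL) sediment
# quality guidelines, mg·kg⁻¹.  Defined for seven of the ten metals.
GUIDELINES: dict[str, tuple[float, float]] = {
    "As": (7.2, 41.6),
    "Cd": (0.68, 4.2),
    "Cr": (52.3, 160.4),
    "Cu": (18.7, 108.2),
    "Ni": (15.9, 42.8),
    "Pb": (30.2, 112.2),
    "Zn": (124.0, 271.0),
}

# Summary statistics of the monitoring panel (concentrations over all
# site-years pooled).  Keys: min, mean, median, max, sd, skew, kurtosis, IQR.
PANEL_SUMMARY: dict[str, dict[str, float]] = {
    "As": {"min": 0.198, "mean": 2.59, "median": 1.5, "max": 22.9, "sd": 2.87, "skew": 4.05, "kurtosis": 20.6, "iqr": 0.0},
    "Cd": {"min": 0.025, "mean": 0.852, "median": 0.25, "max": 20.21, "sd": 2.01, "skew": 6.13, "kurtosis": 47.1, "iqr": 0.389},
    "Co": {"min": 0.10, "mean": 3.05, "median": 1.59, "max": 69.15, "sd": 5.90, "skew": 7.39, "kurtosis": 72.1, "iqr": 1.92},
    "Cr": {"min": 0.782, "mean": 19.08, "median": 7.78, "max": 33.16, "sd": 33.9, "skew": 5.22, "kurtosis": 36.6, "iqr": 12.7},
    "Cu": {"min": 0.20, "mean": 29.23, "median": 6.16, "max": 3170.0, "sd": 214.6, "skew": 14.05, "kurtosis": 202.0, "iqr": 10.7},
    "Hg": {"min": 0.0005, "mean": 0.0615, "median": 0.019, "max": 1.57, "sd": 0.1614, "skew": 6.53, "kurtosis": 50.3, "iqr": 0.0388},
    "Mn": {"min": 14.4, "mean": 359.9, "median": 204.8, "max": 3644.0, "sd": 428.5, "skew": 3.54, "kurtosis": 18.6, "iqr": 334.0},
    "Ni": {"min": 0.50, "mean": 7.20, "median": 3.92, "max": 107.1, "sd": 10.1, "skew": 5.41, "kurtosis": 44.1, "iqr": 5.86},
    "Pb": {"min": 0.50, "mean": 20.75, "median": 7.71, "max": 1050.0, "sd": 72.8, "skew": 12.61, "kurtosis": 174.1, "iqr": 14.5},
    "Zn": {"min": 0.25, "mean": 88.59, "median": 40.25, "max": 1050.0, "sd": 138.6, "skew": 4.09, "kurtosis": 21.4, "iqr": 74.8},
    "TOC": {"min": 0.05, "mean": 1.86, "median": 0.51, "max": 51.50, "sd": 4.20, "skew": 8.06, "kurtosis": 86.7, "iqr": 1.69},
    "pH": {"min": 6.10, "mean": 7.66, "median": 7.62, "max": 8.93, "sd": 0.42, "skew": -0.32, "kurtosis": 1.2, "iqr": 0.50},
}

# Geochemical background: site-mean and between-site sd, mg·kg⁻¹, from the
# area-weighted upstream-buffer backgrounds of the 35 sites.
BACKGROUND_SUMMARY: dict[str, tuple[float, float]] = {
    "As": (2.50, 0.0),
    "Cd": (0.42, 0.43),
    "Co": (1.49, 0.71),
    "Cr": (4.74, 3.41),
    "Cu": (5.49, 2.13),
    "Hg": (0.046, 0.024),
    "Mn": (194.5, 49.3),
    "Ni": (3.53, 1.43),
    "Pb": (16.83, 12.38),
    "Zn": (40.49, 15.83),
}

# Spearman rank correlations between analyte concentrations (lower triangle
# of the published matrix; order as listed).  Used as copula targets by the
# synthetic generator.
SPEARMAN_ORDER: tuple[str, ...] = ("As", "Cd", "Co", "Cr", "Cu", "Hg", "Mn", "Ni", "Pb", "Zn", "TOC", "pH")
SPEARMAN_LOWER: dict[tuple[str, str], float] = {
    ("Cd", "As"): 0.38,
    ("Co", "As"): 0.57, ("Co", "Cd"): 0.29,
    ("Cr", "As"): 0.56, ("Cr", "Cd"): 0.63, ("Cr", "Co"): 0.59,
    ("Cu", "As"): 0.47, ("Cu", "Cd"): 0.61, ("Cu", "Co"): 0.48, ("Cu", "Cr"): 0.73,
    ("Hg", "As"): 0.37, ("Hg", "Cd"): 0.53, ("Hg", "Co"): 0.16, ("Hg", "Cr"): 0.64, ("Hg", "Cu"): 0.57,
    ("Mn", "As"): 0.43, ("Mn", "Cd"): 0.41, ("Mn", "Co"): 0.60, ("Mn", "Cr"): 0.67, ("Mn", "Cu"): 0.44, ("Mn", "Hg"): 0.37,
    ("Ni", "As"): 0.57, ("Ni", "Cd"): 0.47, ("Ni", "Co"): 0.76, ("Ni", "Cr"): 0.82, ("Ni", "Cu"): 0.59, ("Ni", "Hg"): 0.48, ("Ni", "Mn"): 0.78,
    ("Pb", "As"): 0.55, ("Pb", "Cd"): 0.57, ("Pb", "Co"): 0.52, ("Pb", "Cr"): 0.74, ("Pb", "Cu"): 0.76, ("Pb", "Hg"): 0.61, ("Pb", "Mn"): 0.53, ("Pb", "Ni"): 0.65,
    ("Zn", "As"): 0.59, ("Zn", "Cd"): 0.57, ("Zn", "Co"): 0.58, ("Zn", "Cr"): 0.73, ("Zn", "Cu"): 0.68, ("Zn", "Hg"): 0.53, ("Zn", "Mn"): 0.56, ("Zn", "Ni"): 0.74, ("Zn", "Pb"): 0.76,
    ("TOC", "As"): 0.28, ("TOC", "Cd"): 0.08, ("TOC", "Co"): 0.41, ("TOC", "Cr"): 0.34, ("TOC", "Cu"): 0.37, ("TOC", "Hg"): 0.19, ("TOC", "Mn"): 0.33, ("TOC", "Ni"): 0.37, ("TOC", "Pb"): 0.29, ("TOC", "Zn"): 0.31,
    ("pH", "As"): -0.11, ("pH", "Cd"): 0.01, ("pH", "Co"): -0.26, ("pH", "Cr"): -0.05, ("pH", "Cu"): -0.03, ("pH", "Hg"): 0.13, ("pH", "Mn"): -0.02, ("pH", "Ni"): -0.02, ("pH", "Pb"): -0.13, ("pH", "Zn"): -0.10, ("pH", "TOC"): -0.11,
}

# Catchment land-cover areal shares (Corine groups).
LANDCOVER_SHARES: dict[str, float] = {
    "agricultural": 0.602,
    "forest_seminatural": 0.325,
    "anthropogenic": 0.056,
    "water": 0.014,
    "wetland": 0.003,
}


def spearman_target_matrix() -> "tuple[tuple[str, ...], list[list[float]]]":
    """Full symmetric Spearman target matrix in SPEARMAN_ORDER order."""
    n = len(SPEARMAN_ORDER)
    mat = [[1.0 if i == j else 0.0 for j in range(n)] for i in range(n)]
    idx = {a: i for i, a in enumerate(SPEARMAN_ORDER)}
    for (a, b), rho in SPEARMAN_LOWER.items():
        i, j = idx[a], idx[b]
        mat[i][j] = rho
        mat[j][i] = rho
    return SPEARMAN_ORDER, mat
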