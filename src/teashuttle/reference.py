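"""Published Oolong-tea reference measurements used as worked examples.

These tables accompany the package as fixed study data: microbial-fuel-cell
power densities for four Oolong-tea extract preparations (solvent-extracted
``OTL`` and supercritical-fluid-extracted ``OTS``, each in water ``W`` or
ethanol ``E``), the per-subtype breast-cancer hub-gene lists produced by the
four-centrality consensus, and the linear calibration curves of the
phytochemical content assays.

``MFC_POWER_DENSITY`` maps extract -> condition -> (mean, sd) in mW/m2,
measured across a 250-2000 ppm dosing ladder bracketed by two blanks, with
0.3 mM dopamine as the electron-shuttle positive control.
"""

from __future__ import annotations

# Extract -> condition -> (mean power density, sd), mW/m2.
MFC_POWER_DENSITY: dict[str, dict[str, tuple[float, float]]] = {
    "OTL-W": {
        "blank1": (9.882, 0.494),
        "250ppm": (16.349, 1.138),
        "500ppm": (18.946, 1.741),
        "750ppm": (20.129, 1.507),
        "1000ppm": (21.369, 1.875),
        "1500ppm": (22.166, 2.026),
        "2000ppm": (24.374, 4.113),
        "blank2": (12.070, 0.506),
        "dopamine": (33.531, 2.089),
    },
    "OTL-E": {
        "blank1": (11.193, 0.798),
        "250ppm": (23.500, 4.757),
        "500ppm": (22.158, 4.717),
        "750ppm": (17.459, 2.446),
        "1000ppm": (16.001, 2.385),
        "1500ppm": (15.091, 2.024),
        "2000ppm": (14.376, 1.963),
        "blank2": (9.929, 0.762),
        "dopamine": (29.407, 2.975),
    },
    "OTS-W": {
        "blank1": (7.604, 0.471),
        "250ppm": (8.477, 1.509),
        "500ppm": (9.404, 1.414),
        "750ppm": (10.617, 1.426),
        "blank2": (7.488, 0.309),
        "dopamine": (24.496, 2.323),
    },
    "OTS-E": {
        "blank1": (7.150, 0.365),
        "250ppm": (11.636, 1.509),
        "500ppm": (12.363, 1.414),
        "750ppm": (12.874, 1.426),
        "1000ppm": (13.614, 1.475),
        "1500ppm": (14.961, 1.446),
        "blank2": (8.051, 0.430),
        "dopamine": (20.473, 1.661),
    },
}

# Reported amplification subscripts (fold vs blank 1), 2 d.p., for the same
# table; kept separate so recomputation can be checked against them.
MFC_REPORTED_AMPLIFICATION: dict[str, dict[str, float]] = {
    "OTL-W": {
        "blank1": 1.00, "250ppm": 1.65, "500ppm": 1.92, "750ppm": 2.04,
        "1000ppm": 2.16, "1500ppm": 2.24, "2000ppm": 2.47, "blank2": 1.22,
        "dopamine": 3.39,
    },
    "OTL-E": {
        "blank1": 1.00, "250ppm": 2.10, "500ppm": 1.98, "750ppm": 1.56,
        "1000ppm": 1.43, "1500ppm": 1.35, "2000ppm": 1.28, "blank2": 0.89,
        "dopamine": 2.63,
    },
    "OTS-W": {
        "blank1": 1.00, "250ppm": 1.11, "500ppm": 1.24, "750ppm": 1.40,
        "blank2": 0.98, "dopamine": 3.22,
    },
    "OTS-E": {
        "blank1": 1.00, "250ppm": 1.63, "500ppm": 1.73, "750ppm": 1.80,
        "1000ppm": 1.90, "1500ppm": 2.09, "blank2": 1.13, "dopamine": 2.86,
    },
}

# Consensus hub genes per breast-cancer subtype and regulation direction,
# from the four-centrality (MCC/MNC/degree/closeness) top-15 overlap of the
# tea-compound x subtype target networks.
HUB_GENES: dict[str, dict[str, list[str]]] = {
    "LaBC": {
        "up": ["PIK3R1", "PIK3CA", "EGFR", "KIT", "PDGFRA", "FGFR1",
               "MET", "INSR"],
        "down": ["STAT3", "ESR1", "MMP9", "MAPK1", "HSP90AB1", "NFKB1",
                 "PIK3CA", "IGF1R"],
    },
    "LbBC": {
        "up": ["EGFR", "PIK3CA", "PIK3R1", "KIT", "ALB", "BCL2", "APP",
               "PDGFRA"],
        "down": ["AKT1", "ESR1", "MMP9", "STAT1", "HSP90AB1", "MAPK1",
                 "GSK3B"],
    },
    "Her2BC": {
        "up": ["EGFR", "PIK3R1", "PIK3CA", "ESR1", "IGF1R", "BCL2",
               "INSR", "PDGFRA"],
        "down": ["AKT1", "STAT1", "MMP9", "MAPK1", "GSK3B", "HSP90AB1",
                 "PTPN11", "CDK1"],
    },
    "TNBC": {
        "up": ["PIK3CA", "PIK3R1", "ESR1", "IGF1R", "KIT", "BCL2", "MME",
               "INSR"],
        "down": ["STAT3", "SRC", "HSP90AB1", "STAT1", "GSK3B", "MAPK1"],
    },
}

# Assay -> (slope AU per mg/mL, intercept AU, R^2, equivalent unit) of the
# reported standard calibration lines.
CALIBRATION_CURVES: dict[str, tuple[float, float, float, str]] = {
    "TPC": (3.8354, -0.0132, 0.9998, "GAE"),
    "TFC": (4.9008, 0.0287, 0.9994, "RE"),
    "TCTC": (7.7867, -0.0242, 0.9974, "CE"),
}

# Extract -> DPPH IC50 (mg/mL) and FRAP Trolox equivalents (mg/g).
ANTIOXIDANT_ACTIVITY: dict[str, dict[str, float]] = {
    "OTL-E": {"dpph_ic50": 0.07282, "frap_trolox": 177.604},
    "OTL-W": {"dpph_ic50": 0.10907, "frap_trolox": 142.21},
    "OTS-W": {"dpph_ic50": 0.099131, "frap_trolox": 150.14},
}

SUBTYPES = ("LaBC", "LbBC", "Her2BC", "TNBC")

# GSE45827-style design: tumor group sizes vs normal tissue.
GSE45827_GROUP_SIZES: dict[str, int] = {
    "LaBC": 29, "LbBC": 30, "Her2BC": 30, "TNBC": 41, "normal": 11,
}
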