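"""Published reference estimates for *Betula alnoides* provenance trials.

A multi-site provenance trial of *B. alnoides* (25 provenances coded A-Y,
four sites in southern China: Mengla, Pingxiang, Hua'an, Changning) is the
motivating dataset for this package.  The raw per-tree measurements are not
publicly deposited, but the published per-provenance growth summaries and
the fitted height-diameter model parameters are, and they serve two roles
here:

* defaults for the synthetic trial generator (:mod:`hdtrial.synthetic`),
  so simulated data carry the documented site/provenance structure;
* inputs for worked examples — the selection rule, clustering, and gain
  computations can be re-run directly from these numbers.

All heights are metres, diameters centimetres.  ``None`` marks a missing
provenance-by-site cell (provenance G was not planted at Changning).
"""

from __future__ import annotations

import pandas as pd

SITES = ["Mengla", "Pingxiang", "Huaan", "Changning"]
#: stand age (years) at measurement, per site
SITE_AGES = {"Mengla": 15, "Pingxiang": 15, "Huaan": 14, "Changning": 10}
#: number of trees retained for analysis per site (total 7,724)
SITE_N_TREES = {"Mengla": 3403, "Pingxiang": 953, "Huaan": 1438, "Changning": 1930}

PROVENANCES = [chr(c) for c in range(ord("A"), ord("Z"))]  # A..Y
REFERENCE_SITE = "Changning"
REFERENCE_PROVENANCE = "Y"

# ---------------------------------------------------------------------------
# Per-provenance growth summaries: (n, dbh mean, dbh se, height mean, height se)
# ---------------------------------------------------------------------------

_GROWTH = {
    "Mengla": {
        "A": (114, 22.91, 1.11, 20.61, 0.74),
        "B": (129, 21.53, 0.92, 18.82, 0.58),
        "C": (149, 20.99, 0.45, 19.77, 0.31),
        "D": (111, 21.63, 0.42, 20.25, 0.29),
        "E": (135, 20.45, 0.42, 18.45, 0.29),
        "F": (131, 21.20, 0.49, 20.01, 0.32),
        "G": (133, 18.98, 0.44, 18.52, 0.32),
        "H": (149, 21.13, 0.39, 19.33, 0.27),
        "I": (133, 21.77, 0.52, 20.08, 0.34),
        "J": (146, 20.72, 0.42, 18.95, 0.29),
        "K": (134, 21.45, 0.38, 19.44, 0.26),
        "L": (148, 21.70, 0.43, 19.98, 0.28),
        "M": (138, 20.40, 0.43, 19.52, 0.29),
        "N": (151, 20.67, 0.43, 18.64, 0.31),
        "O": (114, 20.34, 0.51, 18.01, 0.42),
        "P": (130, 20.79, 0.37, 18.74, 0.27),
        "Q": (128, 19.85, 0.86, 18.39, 0.49),
        "R": (155, 19.89, 0.35, 18.53, 0.26),
        "S": (136, 19.88, 0.83, 18.04, 0.73),
        "T": (120, 20.33, 0.64, 18.27, 0.45),
        "U": (151, 18.88, 0.34, 18.00, 0.29),
        "V": (140, 19.58, 0.34, 18.18, 0.27),
        "W": (140, 20.79, 0.42, 18.53, 0.30),
        "X": (159, 19.28, 0.33, 18.39, 0.28),
        "Y": (129, 20.64, 0.38, 18.97, 0.27),
    },
    "Pingxiang": {
        "A": (42, 11.65, 0.81, 11.93, 0.80),
        "B": (36, 12.85, 0.85, 12.05, 0.62),
        "C": (35, 12.33, 0.57, 11.73, 0.51),
        "D": (34, 12.94, 0.71, 12.57, 0.53),
        "E": (44, 16.89, 0.60, 14.88, 0.64),
        "F": (32, 11.88, 0.73, 11.24, 0.67),
        "G": (33, 13.12, 0.96, 13.18, 0.91),
        "H": (36, 13.81, 1.08, 12.48, 0.77),
        "I": (39, 14.05, 0.95, 13.42, 0.83),
        "J": (43, 12.17, 0.65, 12.17, 0.61),
        "K": (41, 15.12, 0.56, 13.77, 0.50),
        "L": (32, 12.26, 0.65, 11.33, 0.49),
        "M": (49, 13.32, 0.85, 12.93, 0.76),
        "N": (32, 12.12, 0.69, 11.88, 0.74),
        "O": (39, 16.59, 0.83, 13.75, 0.49),
        "P": (51, 17.06, 0.59, 14.62, 0.44),
        "Q": (30, 15.26, 0.79, 13.39, 0.52),
        "R": (48, 17.99, 0.67, 14.62, 0.45),
        "S": (29, 16.02, 1.00, 13.96, 0.69),
        "T": (24, 15.92, 0.78, 14.47, 0.61),
        "U": (39, 17.01, 0.47, 14.24, 0.41),
        "V": (47, 17.22, 0.51, 15.58, 0.44),
        "W": (39, 16.72, 0.58, 14.79, 0.55),
        "X": (46, 15.85, 0.54, 14.14, 0.46),
        "Y": (33, 17.20, 0.61, 15.36, 0.48),
    },
    "Huaan": {
        "A": (67, 19.56, 1.77, 16.34, 1.37),
        "B": (43, 19.16, 0.84, 16.12, 0.58),
        "C": (53, 19.34, 0.68, 16.13, 0.41),
        "D": (65, 18.92, 0.83, 16.16, 0.49),
        "E": (71, 20.94, 0.49, 16.29, 0.39),
        "F": (54, 20.71, 1.32, 15.96, 0.43),
        "G": (61, 23.46, 1.30, 19.02, 0.88),
        "H": (49, 20.13, 0.69, 16.71, 0.37),
        "I": (64, 20.66, 0.86, 16.44, 0.52),
        "J": (54, 21.58, 0.55, 16.83, 0.39),
        "K": (51, 20.08, 0.59, 16.54, 0.45),
        "L": (55, 17.94, 0.96, 15.88, 0.69),
        "M": (41, 21.01, 0.71, 16.85, 0.47),
        "N": (64, 20.90, 1.43, 15.68, 0.82),
        "O": (46, 20.42, 0.61, 17.05, 0.53),
        "P": (59, 22.80, 0.78, 18.24, 0.50),
        "Q": (64, 23.26, 0.78, 17.14, 0.48),
        "R": (76, 22.38, 0.47, 16.97, 0.30),
        "S": (73, 19.60, 1.02, 15.15, 0.54),
        "T": (52, 20.68, 0.77, 15.90, 0.48),
        "U": (61, 22.31, 0.64, 17.02, 0.46),
        "V": (51, 21.05, 0.75, 15.16, 0.51),
        "W": (64, 22.24, 0.40, 16.28, 0.26),
        "X": (45, 20.40, 0.47, 15.81, 0.29),
        "Y": (55, 21.23, 0.41, 16.44, 0.26),
    },
    "Changning": {
        "A": (108, 7.59, 0.13, 8.46, 0.14),
        "B": (78, 8.72, 0.40, 8.95, 0.36),
        "C": (67, 7.88, 0.23, 8.25, 0.21),
        "D": (84, 7.61, 0.15, 8.28, 0.15),
        "E": (102, 7.79, 0.14, 8.24, 0.16),
        "F": (59, 7.74, 0.26, 8.08, 0.20),
        "G": None,
        "H": (78, 7.99, 0.26, 8.66, 0.29),
        "I": (61, 7.16, 0.44, 8.17, 0.55),
        "J": (58, 8.26, 0.26, 8.91, 0.22),
        "K": (76, 7.87, 0.50, 8.79, 0.51),
        "L": (92, 7.84, 0.12, 8.39, 0.12),
        "M": (104, 7.68, 0.15, 8.27, 0.15),
        "N": (82, 7.90, 0.17, 8.38, 0.16),
        "O": (98, 7.74, 0.15, 8.04, 0.14),
        "P": (61, 7.91, 0.27, 8.15, 0.23),
        "Q": (76, 7.92, 0.49, 8.84, 0.55),
        "R": (68, 7.79, 0.17, 8.29, 0.15),
        "S": (76, 7.41, 0.30, 8.09, 0.42),
        "T": (76, 8.17, 0.31, 8.48, 0.30),
        "U": (80, 7.34, 0.17, 7.92, 0.19),
        "V": (84, 8.23, 0.24, 8.53, 0.19),
        "W": (63, 8.00, 0.23, 8.18, 0.17),
        "X": (101, 7.30, 0.10, 7.90, 0.10),
        "Y": (98, 7.61, 0.14, 7.94, 0.13),
    },
}

#: per-site overall means across all trees: (dbh mean, dbh se, height mean, height se)
SITE_MEANS = {
    "Mengla": (20.58, 0.09, 19.00, 0.06),
    "Pingxiang": (15.57, 0.15, 13.89, 0.12),
    "Huaan": (21.12, 0.14, 16.46, 0.09),
    "Changning": (7.74, 0.04, 8.26, 0.04),
}


def growth_summaries(site: str) -> pd.DataFrame:
    """Per-provenance growth means at one site as a tidy DataFrame.

    Columns: provenance, n, mean_dbh, se_dbh, mean_height, se_height.
    Missing provenance-by-site cells are dropped (absent groups, never imputed).
    """
    rows = []
    for prov, cell in _GROWTH[site].items():
        if cell is None:
            continue
        n, dbh, dbh_se, h, h_se = cell
        rows.append((prov, n, dbh, dbh_se, h, h_se))
    return pd.DataFrame(
        rows, columns=["provenance", "n", "mean_dbh", "se_dbh", "mean_height", "se_height"]
    )


# ---------------------------------------------------------------------------
# Fitted nonlinear mixed-effects models (Weibull asymptote with dummy offsets)
# ---------------------------------------------------------------------------

#: site-level model: H = 1.3 + (phi0 + x_site + u0)(1 - exp(-phi2 * D^(phi1 + u1)))
SITE_MODEL = {
    "phi0": 23.760,
    "phi1": 1.101,
    "phi2": 0.037,
    "x": {"Mengla": 4.388, "Pingxiang": 0.493, "Huaan": -0.002, "Changning": 0.0},
    "sigma0_block": 0.000,
    "sigma1_block": 0.010,
    "sigma": 0.186,
    "gamma": 0.885,
}

#: per-site provenance-level models; k is the provenance asymptote offset
#: (reference provenance Y has offset 0 by construction)
PROVENANCE_MODELS = {
    "Mengla": {
        "phi0": 22.404,
        "phi1": 1.556,
        "phi2": 0.015,
        "k": {
            "A": 1.041, "B": -0.577, "C": 0.910, "D": 1.087, "E": -0.607,
            "F": 1.040, "G": 0.722, "H": 0.167, "I": 1.128, "J": -0.068,
            "K": 0.136, "L": 0.616, "M": 1.008, "N": -0.058, "O": -1.068,
            "P": -0.303, "Q": -0.615, "R": -0.181, "S": -0.587, "T": -0.753,
            "U": -0.023, "V": -0.371, "W": -0.682, "X": 0.226, "Y": 0.0,
        },
        "sigma0_block": 0.609,
        "sigma1_block": 0.017,
        "sigma": 3.128,
        "gamma": -0.106,
    },
    "Pingxiang": {
        "phi0": 29.345,
        "phi1": 1.158,
        "phi2": 0.024,
        "k": {
            "A": 2.374, "B": -0.212, "C": -0.047, "D": 0.530, "E": -0.750,
            "F": -1.335, "G": 1.268, "H": -0.426, "I": 0.373, "J": 1.749,
            "K": -0.332, "L": -1.072, "M": 1.175, "N": 0.381, "O": -1.998,
            "P": -1.026, "Q": -1.880, "R": -2.043, "S": -0.795, "T": 0.318,
            "U": -2.152, "V": 0.514, "W": -0.459, "X": -0.329, "Y": 0.0,
        },
        "sigma0_block": 1.494,
        "sigma1_block": 0.000,
        "sigma": 0.308,
        "gamma": 0.670,
    },
    "Huaan": {
        "phi0": 25.506,
        "phi1": 0.971,
        "phi2": 0.048,
        "k": {
            "A": 0.753, "B": 1.009, "C": 0.786, "D": 1.178, "E": -0.286,
            "F": -0.568, "G": 2.632, "H": 1.284, "I": 0.318, "J": 0.059,
            "K": 0.611, "L": 1.600, "M": 0.612, "N": -0.905, "O": 1.413,
            "P": 1.721, "Q": -0.546, "R": 0.089, "S": -0.976, "T": -0.467,
            "U": 0.007, "V": -2.210, "W": -0.953, "X": -0.404, "Y": 0.0,
        },
        "sigma0_block": 0.741,
        "sigma1_block": 0.000,
        "sigma": 0.362,
        "gamma": 0.681,
    },
    "Changning": {
        "phi0": 11.636,
        "phi1": 1.411,
        "phi2": 0.051,
        "k": {
            "A": 0.853, "B": 0.312, "C": 0.262, "D": 0.465, "E": 0.062,
            "F": -0.061, "H": 0.460, "I": 0.735, "J": 0.654, "K": 0.865,
            "L": 0.329, "M": 0.363, "N": 0.312, "O": -0.018, "P": -0.004,
            "Q": 0.911, "R": 0.317, "S": 0.475, "T": 0.299, "U": 0.342,
            "V": 0.171, "W": -0.111, "X": 0.187, "Y": 0.0,
        },
        "sigma0_block": 0.000,
        "sigma1_block": 0.000,
        "sigma": 0.159,
        "gamma": 0.857,
    },
}

# ---------------------------------------------------------------------------
# Goodness-of-fit comparison: base Weibull fit vs the mixed-effects extension
# ---------------------------------------------------------------------------

#: log-likelihoods of the base Weibull height-diameter fit, per analysis level
BASE_MODEL_LOGLIK = {
    "site": -5261.027,
    "Mengla": -2927.487,
    "Pingxiang": -666.481,
    "Huaan": -1336.704,
    "Changning": 5.598,
}

#: log-likelihoods of the corresponding dummy-variable NLME fits
NLME_LOGLIK = {
    "site": -4620.790,
    "Mengla": -2811.776,
    "Pingxiang": -560.513,
    "Huaan": -1279.860,
    "Changning": 32.705,
}

# ---------------------------------------------------------------------------
# Provenance grouping and selection outcomes (published)
# ---------------------------------------------------------------------------

#: published cluster memberships of provenances by asymptote offset (groups
#: ordered by descending group-mean offset, members by descending offset)
PUBLISHED_GROUPS = {
    "Mengla": [
        ["I", "D", "A", "F", "M", "C", "G", "L"],
        ["X", "H", "K", "Y", "U", "N", "J", "R"],
        ["P", "V", "B", "S", "E", "Q", "W", "T", "O"],
    ],
    "Pingxiang": [
        ["A", "J", "G", "M"],
        ["D", "V", "N", "I", "T"],
        ["Y", "C", "B", "X", "K", "H", "W"],
        ["E", "S", "P", "L", "F"],
        ["Q", "O", "R", "U"],
    ],
    "Huaan": [
        ["G", "P", "L", "O", "H", "D", "B"],
        ["C", "A", "M", "K"],
        ["I", "R", "J", "U", "Y"],
        ["E", "X", "T", "Q", "F", "N", "W", "S", "V"],
    ],
    "Changning": [
        ["Q", "K", "A", "I", "J"],
        ["S", "D", "H"],
        ["M", "U", "L", "R", "N", "B", "T", "C", "X", "V"],
        ["E", "Y", "P", "O", "F", "W"],
    ],
}

#: number of published groups per site
PUBLISHED_N_GROUPS = {"Mengla": 3, "Pingxiang": 5, "Huaan": 4, "Changning": 4}

#: published selected provenance sets (20% selection rate)
PUBLISHED_SELECTED = {
    "Mengla": {"B", "W", "P", "J", "N"},
    "Pingxiang": {"R", "P", "U", "E", "W"},
    "Huaan": {"Q", "R", "U", "W", "J"},
    "Changning": {"B", "V", "T", "W", "P"},
}

#: published selected-set vs total means: trait -> (selected mean, total mean)
PUBLISHED_SELECTION_MEANS = {
    "Mengla": {
        "height": (18.74, 19.00), "dbh": (20.90, 20.60),
        "hd_ratio": (0.92, 0.95), "volume": (0.331, 0.324), "k": (-0.338, 0.087),
    },
    "Pingxiang": {
        "height": (14.62, 13.90), "dbh": (17.14, 15.60),
        "hd_ratio": (0.87, 0.91), "volume": (0.181, 0.147), "k": (-1.286, -0.247),
    },
    "Huaan": {
        "height": (16.85, 16.50), "dbh": (22.35, 21.10),
        "hd_ratio": (0.77, 0.80), "volume": (0.327, 0.293), "k": (-0.269, 0.270),
    },
    "Changning": {
        "height": (8.60, 8.30), "dbh": (8.21, 7.70),
        "hd_ratio": (1.07, 1.11), "volume": (0.023, 0.018), "k": (0.316, 0.341),
    },
}
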