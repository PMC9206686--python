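"""Reference characterization data for the CelC307 endoglucanase.

CelC307 is a GH5 endoglucanase from the thermophilic bacterium *Cohnella* sp.
A01 (coding sequence GenBank MN105992.1), characterized on carboxymethyl
cellulose at 40 °C / pH 7.  This module stores the reported quantitative
record — kinetic constants, activation and inactivation thermodynamic tables,
and the 20-run response-surface optimization of its recombinant expression —
as plain Python data, so the analysis stages can be exercised and
cross-checked against a real characterization without any download.

The thermodynamic tables are reproduced as reported, including entries that
are mutually inconsistent with their own inputs; see
:mod:`enzkit.diagnostics` for the consistency audit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .doe import FactorSpec

#: Michaelis constant on CMC, mM
KM_MM = 0.46
#: Maximal velocity, U/mg (specific activity scale)
VMAX = 62.58
#: Turnover number, s^-1 (reported; not derivable from VMAX and MW as printed)
KCAT = 104.30e-3
#: Catalytic efficiency, M^-1 s^-1
KCAT_OVER_KM = 226.73
#: Optimum assay temperature, K (40 °C)
T_OPT_K = 313.15
#: Molecular weight of the translated protein, kDa
MW_KDA = 56.86
#: Translated protein length, aa
PROTEIN_LENGTH = 491
#: Reported isoelectric point
PI = 5.85
#: Reported instability index
INSTABILITY_INDEX = 37.17
#: Reported aliphatic index
ALIPHATIC_INDEX = 69.80
#: Reported GRAVY
GRAVY = -0.520

#: Activation (catalysis) thermodynamics at 40 °C, as reported
ACTIVATION_TABLE = {
    "Ea_act": 25.36,  # kJ/mol
    "dG_act": 58.60,  # kJ/mol (reported; not reproducible from KCAT — see diagnostics)
    "dH_act": 22.75,  # kJ/mol
    "dS_act_magnitude": 114.51,  # J/(mol K), printed unsigned
    "dG_ET": -14.11,  # kJ/mol
    "dG_ES": 2.01,  # kJ/mol (1/Km evaluated with Km in mM)
    "Ka": 2.17,  # 1/Km, Km in mM
}

#: Irreversible thermal inactivation, as reported (temperatures °C)
INACTIVATION_TABLE = pd.DataFrame(
    {
        "temp_C": [40.0, 60.0, 70.0, 80.0, 90.0],
        "k_in": [1.62e-2, 14.60e-2, 29.70e-2, 41.68e-2, 56.67e-2],  # min^-1
        "t_half": [427.86, 47.47, 25.76, 16.63, 12.23],  # min, as reported
        "D_value": [1606.34, 189.62, 96.01, 70.41, 53.25],  # min, as reported
        "dH": [56.69, 56.52, 56.44, 56.43, 56.27],  # kJ/mol
        "dG": [87.58, 87.08, 87.67, 89.24, 90.83],  # kJ/mol
        "dS": [98.72, 91.76, 91.05, 93.05, 95.20],  # J/(mol K), printed unsigned
    }
)

#: Reported inactivation activation energy, kJ/mol
EA_INACT = 59.29

#: Substrate specificity panel, % relative activity (CMC reference)
SUBSTRATE_SPECIFICITY = {
    "CMC": 100.0,
    "laminarin": 21.6,
    "chitin": 8.4,
    "pectic acid": 1.9,
}

#: Purified specific activity (U/mg) after Ni-NTA purification
SPECIFIC_ACTIVITY_PURIFIED = 13.6

# ---------------------------------------------------------------------------
# Expression optimization: rotatable central-composite layout (labelled
# Box-Behnken in the original report, but geometrically a CCD: axial points
# sit at ±1.682 half-ranges), 20 runs in two blocks.
# ---------------------------------------------------------------------------

#: Factor specifications of the expression optimization
RSM_FACTORS = [
    FactorSpec(name="pH", symbol="A", center=6.5, half_range=1.5),
    FactorSpec(name="temperature", symbol="B", center=30.0, half_range=10.0),
    FactorSpec(name="inoculum_od600", symbol="C", center=0.65, half_range=0.35),
]

#: The 20 optimization runs: natural factor levels, block label and measured
#: cellulase activity (U/ml).  Block 1 = 8 factorial corners + 4 center runs;
#: block 2 = 6 axial runs + 2 center runs.
RSM_RUNS = pd.DataFrame(
    [
        (1, 5.00, 20.00, 0.30, 1, 47.0),
        (2, 8.00, 40.00, 1.00, 1, 49.3),
        (3, 6.50, 30.00, 0.65, 1, 49.0),
        (4, 5.00, 40.00, 0.30, 1, 46.2),
        (5, 6.50, 30.00, 0.65, 1, 51.4),
        (6, 5.00, 40.00, 1.00, 1, 47.6),
        (7, 8.00, 20.00, 0.30, 1, 48.5),
        (8, 8.00, 20.00, 1.00, 1, 56.1),
        (9, 6.50, 30.00, 0.65, 1, 51.9),
        (10, 5.00, 20.00, 1.00, 1, 52.1),
        (11, 8.00, 40.00, 0.30, 1, 46.4),
        (12, 6.50, 30.00, 0.65, 1, 50.6),
        (13, 6.50, 13.18, 0.65, 2, 52.86),
        (14, 9.02, 30.00, 0.65, 2, 49.0),
        (15, 3.97, 30.00, 0.65, 2, 48.7),
        (16, 6.50, 30.00, 0.65, 2, 51.7),
        (17, 6.50, 30.00, 0.65, 2, 52.4),
        (18, 6.50, 30.00, 0.06, 2, 45.1),
        (19, 6.50, 46.81, 0.65, 2, 47.5),
        (20, 6.50, 30.00, 1.23, 2, 53.0),
    ],
    columns=["run", "pH", "temperature", "inoculum_od600", "block", "response"],
)

#: Reported natural-unit coefficients of the fitted second-order polynomial
RSM_EQUATION = {
    "Intercept": 20.04144,
    "A": 5.56251,
    "B": 0.44628,
    "C": 17.38737,
    "AB": -0.030000,
    "AC": 0.95238,
    "BC": -0.30000,
    "A^2": -0.37659,
    "B^2": -3.77106e-3,
    "C^2": -6.33976,
}

#: Reported ANOVA landmarks of the expression optimization
RSM_ANOVA_REPORTED = {
    "model_F": 15.34,
    "lack_of_fit_F": 0.6572,
    "block_SS": 0.6135,
    "pure_error_SS": 5.07,
    "cor_total_SS": 151.57,
}

#: Reported optimum of the expression response surface
RSM_OPTIMUM_REPORTED = {"pH": 7.5, "temperature": 20.0, "inoculum_od600": 1.0,
                        "predicted_U_per_ml": 58.4, "validated_U_per_ml": 62.58}

#: Box bounds used when maximizing the fitted surface (natural units)
RSM_BOUNDS = [(5.0, 8.0), (20.0, 40.0), (0.3, 1.0)]


def rsm_dataframe() -> pd.DataFrame:
    """The optimization runs as a fresh copy (factor columns + block + response)."""
    return RSM_RUNS.copy()


def inactivation_rates() -> tuple[np.ndarray, np.ndarray]:
    """(temperatures in K, reported k_in in min^-1)."""
    return (
        INACTIVATION_TABLE["temp_C"].to_numpy() + 273.15,
        INACTIVATION_TABLE["k_in"].to_numpy(),
    )
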