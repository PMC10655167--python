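"""Shared frozen reference values for the golden tests.

Printed values are stored as strings so each cell's own printed
precision (half a unit in the last digit) can be recovered.
"""

import pytest

# Published cross-tabulation of discrimination metrics, one row per AUC:
# (auc, opera, delta, variance, frr_mz, iqrr, uqrr)
TABLE1_PRINTED = [
    ("0.50", "1", "0", "0", "1", "1", "1"),
    ("0.55", "1.2", "0.18", "0.03", "1.04", "1.6", "1.2"),
    ("0.60", "1.4", "0.36", "0.13", "1.14", "2.5", "1.5"),
    ("0.65", "1.7", "0.54", "0.30", "1.34", "4.0", "1.8"),
    ("0.70", "2.1", "0.74", "0.55", "1.74", "6.7", "2.1"),
    ("0.75", "2.6", "0.95", "0.91", "2.50", "12", "2.4"),
    ("0.80", "3.3", "1.19", "1.42", "4.12", "22", "2.8"),
    ("0.85", "4.3", "1.47", "2.15", "8.58", "49", "3.1"),
    ("0.90", "6.1", "1.81", "3.28", "26.8", "135", "3.5"),
    ("0.95", "10", "2.33", "5.41", "224", "706", "3.8"),
]

# Published Nordic twin breast-cancer strata:
# (age_band, frr_mz, frr_dz, cov_mz, cov_dz, A, C, auc_max)
TABLE2_PRINTED = [
    ("<50", 5.91, 3.51, 1.78, 1.26, 1.04, 0.74, 0.83),
    ("50-59", 4.93, 2.77, 1.60, 1.02, 1.15, 0.44, 0.81),
    ("60-69", 2.98, 2.24, 1.09, 0.81, 0.57, 0.52, 0.77),
    ("70-79", 2.5, 1.8, 0.92, 0.59, 0.66, 0.26, 0.75),
]


def half_ulp(printed: str) -> float:
    """Half a unit in the last printed digit of a decimal string."""
    if "." in printed:
        return 0.5 * 10 ** (-len(printed.split(".")[1]))
    return 0.5


@pytest.fixture(scope="session")
def table1_printed():
    return TABLE1_PRINTED


@pytest.fixture(scope="session")
def table2_printed():
    return TABLE2_PRINTED
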