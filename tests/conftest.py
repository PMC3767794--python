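"""Shared fixtures: default calibration and the printed study-table cells.

The published trajectory tables were assembled by chained hand computation:
the derived columns round through their printed precursors (erf and
exp(-x^2) evaluated at the x column as printed; Q assembled from the printed
erf/exp cells with the structural limit used at its printed value 5.08).  A
cell check therefore accepts a match at printed precision from either the
full-precision computation or that chained-rounding path.  One cell matches
neither (the erf cell at t = 25.9 prints 0.595; both paths give 0.594) and
is excluded as a tabulation slip, like the published leaf-fraction cell
0.549 at t = 26.4 whose own component cells give 0.365.
"""

import math

import pytest
from scipy.special import erf

from growthquant import GrowthParams

K_OVER_SQRT_PI_PRINTED = 5.08  # structural limit k/sqrt(pi) as printed, k = 9


@pytest.fixture(scope="session")
def default_params() -> GrowthParams:
    return GrowthParams()


# Printed quantifier columns of the California trajectory table:
# (t, x, erf_x, gauss_x, q_struct, q_total), each as printed.
CALIFORNIA_QUANT_ROWS = [
    (21.2, "0.000", "0.000", "1.0000", "0.000", "0.00"),
    (21.9, "0.088", "0.099", "0.9924", "0.039", "0.14"),
    (26.4, "0.650", "0.642", "0.655", "1.75", "2.39"),
    (30.1, "1.112", "0.884", "0.290", "3.61", "4.49"),
    (35.1, "1.738", "0.986", "0.0488", "4.83", "5.82"),
]

# Printed quantifier columns of the Alabama trajectory table:
# (t, x, erf_x, gauss_x, q_total).
ALABAMA_QUANT_ROWS = [
    (21.2, "0.000", "0.000", "1.0000", "0.000"),
    (21.6, "0.050", "0.056", "0.9975", "0.069"),
    (23.7, "0.312", "0.341", "0.907", "0.813"),
    (25.9, "0.588", "0.595", "0.708", "2.08"),
    (28.0, "0.850", "0.771", "0.486", "3.38"),
    (30.3, "1.138", "0.892", "0.274", "4.58"),
    (32.4, "1.400", "0.952", "0.141", "5.32"),
    (34.7, "1.688", "0.9830", "0.0580", "5.77"),
]

# Cells no computational path reproduces at printed precision (see module
# docstring): field name by (site, t).
EXCLUDED_CELLS = {("alabama", 25.9): {"erf_x"}}

# Seasonal limits as printed: q_struct -> 5.08, q_total -> 6.08 for k = 9.
LIMIT_ROW = {"q_struct": "5.08", "q_total": "6.08"}


def _matches(value: float, printed: str) -> bool:
    decimals = len(printed.split(".")[1]) if "." in printed else 0
    return abs(value - float(printed)) <= 0.5 * 10.0 ** (-decimals) + 1e-12


def assert_printed(value: float, printed: str, alt: float | None = None) -> None:
    """Assert a computed value matches a table cell at its printed precision,
    directly or through the table's chained-rounding path (``alt``)."""
    if _matches(value, printed):
        return
    if alt is not None and _matches(alt, printed):
        return
    assert False, (
        f"computed {value!r} (chained {alt!r}) does not round to {printed!r}"
    )


def check_quantifier_row(point, x_p, erf_p, gauss_p, qs_p=None, qt_p=None,
                         exclude=()) -> None:
    """Check one table row's derived cells against a quantifier point."""
    x_r = float(x_p)
    alt_erf = float(erf(x_r))
    alt_gauss = math.exp(-x_r * x_r)
    alt_qs = K_OVER_SQRT_PI_PRINTED * (1.0 - float(gauss_p))
    alt_qt = float(erf_p) + alt_qs
    assert_printed(point.x, x_p)
    if "erf_x" not in exclude:
        assert_printed(point.erf_x, erf_p, alt=alt_erf)
    assert_printed(point.gauss_x, gauss_p, alt=alt_gauss)
    if qs_p is not None:
        assert_printed(point.q_struct, qs_p, alt=alt_qs)
    if qt_p is not None:
        assert_printed(point.q_total, qt_p, alt=alt_qt)


@pytest.fixture(scope="session")
def printed_cell_check():
    return assert_printed
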