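"""Reference coefficient estimates for the maize weather-yield regression.

These are published least-squares estimates from a county-level panel
regression of eastern-U.S. maize yield anomalies (1979-2018) on six
growing-season weather covariates: growing degree days (GDD), extreme
degree days (EDD), mean daily maximum and minimum temperature, total
precipitation and mean vapor pressure deficit (VPD), each entering up to
quadratically plus an intercept (13 coefficients in all).

Two fitted models are carried:

* the *full* model with every linear and quadratic term, whose best
  estimates and standard errors seed the pre-calibration sampling ranges;
* the *reference* (cross-validation selected) model, which drops the
  maximum-temperature terms and the quadratic EDD term.

The module also records the published sampling-range bounds themselves so
that range construction can be checked against them, and ships the
reference values as the ground truth of the ``realistic`` synthetic preset.
"""

from __future__ import annotations

import numpy as np

#: Canonical coefficient order used for every 13-vector in the package.
COEF_NAMES: tuple[str, ...] = (
    "gdd", "gdd2", "edd", "edd2",
    "tmax", "tmax2", "tmin", "tmin2",
    "pr", "pr2", "vpd", "vpd2",
    "intercept",
)

#: The six weather variables, in canonical order.
VARIABLES: tuple[str, ...] = ("gdd", "edd", "tmax", "tmin", "pr", "vpd")

#: Covariate-table column backing each variable.
VARIABLE_COLUMNS: dict[str, str] = {
    "gdd": "gdd",
    "edd": "edd",
    "tmax": "tmax_mean",
    "tmin": "tmin_mean",
    "pr": "pr_total",
    "vpd": "vpd_mean",
}

#: Full-model best estimates (canonical order).
FULL_MODEL_BEST = np.array([
    0.355,      # gdd
    -1.18e-4,   # gdd2
    -0.272,     # edd
    3.48e-4,    # edd2
    0.809,      # tmax
    -6.05e-2,   # tmax2
    -21.8,      # tmin
    1.35,       # tmin2
    8.73e-2,    # pr
    -7.92e-5,   # pr2
    0.693,      # vpd
    -2.75e-3,   # vpd2
    -222.0,     # intercept
])

#: Full-model standard errors (canonical order).
FULL_MODEL_SE = np.array([
    1.60e-2,
    5.01e-6,
    6.80e-3,
    2.04e-5,
    2.38,
    5.04e-2,
    1.39,
    5.92e-2,
    4.91e-3,
    3.52e-6,
    6.35e-2,
    3.00e-4,
    21.0,
])

#: Best estimates of the cross-validation selected reference model.
#: Excluded terms (tmax, tmax2, edd2) are exactly zero.
REFERENCE_MODEL_BEST = np.array([
    0.315,
    -1.16e-4,
    -0.172,
    0.0,
    0.0,
    0.0,
    -21.7,
    1.42,
    9.36e-2,
    -8.22e-5,
    0.681,
    -2.75e-3,
    -193.0,
])

#: Published sampling-range bounds, as printed. The gdd2 row is not
#: consistent with best +/- 10*SE (an apparent exponent typo); strict-table
#: mode reproduces it verbatim, the default recomputes from best and SE.
PUBLISHED_RANGES: dict[str, tuple[float, float]] = {
    "gdd": (0.195, 0.515),
    "gdd2": (-6.79e-4, -1.68e-4),
    "edd": (-0.612, 6.80e-2),
    "edd2": (-6.72e-4, 1.37e-3),
    "tmax": (-23.0, 24.6),
    "tmax2": (-0.565, 0.444),
    "tmin": (-35.7, -7.9),
    "tmin2": (0.76, 1.94),
    "pr": (3.82e-2, 0.136),
    "pr2": (-1.14e-4, -4.4e-5),
    "vpd": (5.80e-2, 1.33),
    "vpd2": (-5.75e-3, 2.5e-4),
    "intercept": (-432.0, -12.0),
}
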