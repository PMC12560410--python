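"""Shared straight-line regression used by every fitting stage.

All of the models in this package (Stern-Volmer, double-logarithmic binding,
van't Hoff) are linearised and fitted by unweighted ordinary least squares;
this module wraps :func:`scipy.stats.linregress` and packages the statistics
the report tables need (slope +/- SD, intercept +/- SD, r, SD of residuals).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .datatypes import LinearFitResult


def linear_fit(x, y) -> LinearFitResult:
    """Unweighted OLS of ``y`` on ``x``.

    Parameters must hold at least two points with non-constant ``x``.
    ``r`` is the Pearson correlation coefficient (0 when ``y`` is constant);
    ``sd_residuals`` is sqrt(RSS / (n - 2)), 0 for n = 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 points for a line fit")
    if np.ptp(x) == 0:
        raise ValueError("x values are all identical; slope is undefined")

    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    sd_resid = math.sqrt(float(resid @ resid) / (n - 2)) if n > 2 else 0.0
    slope_sd = 0.0 if n == 2 else float(res.stderr)
    intercept_sd = 0.0 if n == 2 else float(res.intercept_stderr)
    # linregress yields NaN stderr/r for constant y; a flat response is a
    # perfectly valid zero-slope fit here
    if not math.isfinite(slope_sd):
        slope_sd = 0.0
    if not math.isfinite(intercept_sd):
        intercept_sd = 0.0
    r = float(res.rvalue)
    if not math.isfinite(r):
        r = 0.0
    return LinearFitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_sd=slope_sd,
        intercept_sd=intercept_sd,
        r=max(-1.0, min(1.0, r)),
        sd_residuals=sd_resid,
        n_points=int(n),
    )
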