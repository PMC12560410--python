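"""Fluorescence quenching: inner-filter correction, Stern-Volmer fits and
mechanism classification.

The Stern-Volmer law ``F0/F = 1 + Ksv [Q]`` is fitted by unweighted OLS with
a free intercept, and the quenching mechanism is inferred from how Ksv moves
with temperature: static quenching (ground-state complex) weakens on heating,
collisional (dynamic) quenching strengthens with faster diffusion.
"""

from __future__ import annotations

import enum
import logging

import numpy as np
from pydantic import BaseModel

from .datatypes import AnalysisConfig, LinearFitResult, TitrationSeries
from .fitting import linear_fit

log = logging.getLogger("bsabind.quench")

#: F >= f0 beyond this tolerance is flagged as an anti-quenching point.
_ANTI_QUENCH_TOL = 1e-9


class Mechanism(str, enum.Enum):
    static = "static"
    dynamic = "dynamic"
    indeterminate = "indeterminate"


class QuenchResult(BaseModel):
    """Stern-Volmer fit at one temperature; ``ksv`` is the slope in L/mol."""

    temperature_K: float
    ksv: float
    fit: LinearFitResult
    corrected: bool = False


class MechanismCall(BaseModel):
    """Quenching-mechanism verdict from the Ksv-vs-temperature trend."""

    call: Mechanism
    trend_statistic: float  # OLS slope of Ksv against T, L mol^-1 K^-1
    n_temperatures: int


def ife_correct(f_observed: float, a_ex: float, a_em: float) -> float:
    """Correct an intensity for the inner filter effect.

    ``F_corrected = F_observed * 10^((A_ex + A_em)/2)`` where ``A_ex`` and
    ``A_em`` are the solution absorbances at the excitation and emission
    wavelengths.  The correction can only increase the intensity.
    """
    if f_observed <= 0:
        raise ValueError("observed intensity must be positive")
    if a_ex < 0 or a_em < 0:
        raise ValueError(
            "absorbances must be non-negative (negative values usually mean "
            "the blank was subtracted in the wrong order)"
        )
    return f_observed * 10.0 ** ((a_ex + a_em) / 2.0)


def ife_correct_series(
    series: TitrationSeries, a_ex, a_em
) -> TitrationSeries:
    """Apply the inner-filter correction point-wise to a titration.

    ``a_ex``/``a_em`` are per-point absorbance sequences aligned with the
    titration points; ``f0`` is left untouched (zero quencher, blank-matched).
    """
    a_ex = np.asarray(a_ex, dtype=float)
    a_em = np.asarray(a_em, dtype=float)
    if a_ex.shape != (len(series),) or a_em.shape != (len(series),):
        raise ValueError("absorbance arrays must match the number of titration points")
    corrected = [
        ife_correct(f, ax, am)
        for f, ax, am in zip(series.intensity, a_ex, a_em)
    ]
    return series.model_copy(update={"intensity": corrected})


def stern_volmer_fit(series: TitrationSeries, corrected: bool = False) -> QuenchResult:
    """Fit ``F0/F`` against ``[Q]`` (mol/L); the slope is Ksv in L/mol.

    The intercept is fitted freely rather than pinned at 1, so the regression
    statistics mirror what a spreadsheet fit of real data reports.  Points
    with F >= F0 (anti-quenching, usually noise at low quencher) are kept in
    the fit but logged as warnings.
    """
    if len(series) < 3:
        raise ValueError("Stern-Volmer fit needs at least 3 titration points")
    f = np.asarray(series.intensity, dtype=float)
    n_anti = int(np.sum(f >= series.f0 + _ANTI_QUENCH_TOL))
    if n_anti:
        log.warning(
            "series %r at %g K: %d point(s) with F >= F0 (anti-quenching); "
            "kept in the fit",
            series.label, series.temperature_K, n_anti,
        )
    fit = linear_fit(series.quencher_conc, series.f0 / f)
    return QuenchResult(
        temperature_K=series.temperature_K,
        ksv=fit.slope,
        fit=fit,
        corrected=corrected,
    )


def classify_mechanism(
    results: list[QuenchResult], config: AnalysisConfig | None = None
) -> MechanismCall:
    """Classify quenching as static or dynamic from the Ksv(T) trend.

    The trend statistic is the OLS slope of Ksv against temperature.  The
    call is ``static`` only when the slope is negative *and* Ksv strictly
    decreases across the sorted temperatures (``dynamic`` for the mirror
    image); anything weaker is ``indeterminate``.  Order of the input list
    is irrelevant.
    """
    config = config or AnalysisConfig()
    if len(results) < config.mechanism_trend_min_points:
        raise ValueError(
            f"need at least {config.mechanism_trend_min_points} temperatures "
            f"for a mechanism call, got {len(results)}"
        )
    temps = [r.temperature_K for r in results]
    if len(set(temps)) != len(temps):
        raise ValueError("duplicate temperatures in mechanism classification")
    ordered = sorted(results, key=lambda r: r.temperature_K)
    ksv = [r.ksv for r in ordered]
    trend = linear_fit([r.temperature_K for r in ordered], ksv).slope
    decreasing = all(b < a for a, b in zip(ksv, ksv[1:]))
    increasing = all(b > a for a, b in zip(ksv, ksv[1:]))
    if trend < 0 and decreasing:
        call = Mechanism.static
    elif trend > 0 and increasing:
        call = Mechanism.dynamic
    else:
        call = Mechanism.indeterminate
    return MechanismCall(call=call, trend_statistic=trend, n_temperatures=len(results))


def relative_difference(a: float, b: float) -> float:
    """Percent difference of ``a`` relative to ``b``: ``100 |a - b| / |b|``."""
    if b == 0:
        raise ValueError("reference value must be non-zero")
    return 100.0 * abs(a - b) / abs(b)
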