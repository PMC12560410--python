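"""Binding constants and thermodynamics.

Three linearisations drive this module:

* the double-logarithmic (modified Stern-Volmer) plot
  ``log10((F0 - F)/F) = log10 Ka + n log10 [Q]``, whose intercept gives the
  association constant Ka and whose slope gives the apparent number of
  binding sites n;
* the van't Hoff line ``ln Ka = -dH/(R T) + dS/R`` over a set of
  temperatures, giving the binding enthalpy and entropy;
* the Gibbs energy, by either route of
  ``dG = -R T ln Ka = dH - T dS``.

The signs of (dH, dS) classify the dominant intermolecular forces by the
Ross-Subramanian convention: both negative -> hydrogen bonding / van der
Waals; both positive -> hydrophobic; dH < 0 with dS > 0 -> electrostatic.
"""

from __future__ import annotations

import enum
import logging
import math

import numpy as np
from pydantic import BaseModel

from .datatypes import GAS_CONSTANT_R, AnalysisConfig, LinearFitResult, TitrationSeries
from .fitting import linear_fit

log = logging.getLogger("bsabind.binding")


class BindingForce(str, enum.Enum):
    hbond_vdw = "hbond_vdw"
    hydrophobic = "hydrophobic"
    electrostatic = "electrostatic"
    indeterminate = "indeterminate"


class BindingResult(BaseModel):
    """Double-log fit at one temperature: Ka (L/mol) and site number n."""

    temperature_K: float
    log10_ka: float
    ka: float
    n_sites: float
    fit: LinearFitResult
    label: str = "blank"

    def is_unity_stoichiometry(self, tol: float = 0.15) -> bool:
        """Whether the fitted n is consistent with a 1:1 complex."""
        return abs(self.n_sites - 1.0) < tol


class ThermoResult(BaseModel):
    """van't Hoff decomposition with per-temperature Gibbs energies.

    ``delta_G_by_T`` is computed as -R T ln Ka from each temperature's own
    fitted Ka (not from dH - T dS, which only coincides when the points sit
    exactly on the van't Hoff line).
    """

    delta_H: float  # J/mol
    delta_S: float  # J/mol/K
    delta_G_by_T: dict[float, float]  # J/mol
    vant_hoff_fit: LinearFitResult
    force_call: BindingForce
    spontaneous: bool


def double_log_fit(series: TitrationSeries) -> BindingResult:
    """Fit ``log10((F0-F)/F)`` on ``log10 [Q]`` for Ka and n.

    Points with F >= F0 have no defined log-ratio and are dropped with a
    warning; at least 3 usable points must remain.
    """
    conc = np.asarray(series.quencher_conc, dtype=float)
    f = np.asarray(series.intensity, dtype=float)
    usable = f < series.f0
    n_dropped = int((~usable).sum())
    if n_dropped:
        log.warning(
            "series %r at %g K: dropped %d point(s) with F >= F0 from the "
            "double-log fit", series.label, series.temperature_K, n_dropped,
        )
    if usable.sum() < 3:
        raise ValueError("fewer than 3 points with F < F0; cannot fit binding model")
    x = np.log10(conc[usable])
    y = np.log10((series.f0 - f[usable]) / f[usable])
    fit = linear_fit(x, y)
    return BindingResult(
        temperature_K=series.temperature_K,
        log10_ka=fit.intercept,
        ka=10.0 ** fit.intercept,
        n_sites=fit.slope,
        fit=fit,
        label=series.label,
    )


def vant_hoff_fit(
    points: list[tuple[float, float]]
) -> tuple[float, float, LinearFitResult]:
    """OLS of ln Ka on 1/T; returns (dH, dS, fit) in J/mol and J/mol/K.

    ``dH = -R * slope`` and ``dS = R * intercept`` with R = 8.314.
    """
    if len(points) < 2:
        raise ValueError("van't Hoff fit needs at least 2 (T, Ka) pairs")
    temps = [t for t, _ in points]
    if len(set(temps)) != len(temps):
        raise ValueError("duplicate temperatures in van't Hoff fit")
    if any(t <= 0 for t in temps):
        raise ValueError("temperatures must be positive (kelvin)")
    if any(ka <= 0 for _, ka in points):
        raise ValueError("association constants must be positive")
    inv_t = [1.0 / t for t, _ in points]
    ln_ka = [math.log(ka) for _, ka in points]
    fit = linear_fit(inv_t, ln_ka)
    return -GAS_CONSTANT_R * fit.slope, GAS_CONSTANT_R * fit.intercept, fit


def gibbs_from_ka(ka: float, temperature_K: float) -> float:
    """Gibbs energy of association, ``-R T ln Ka``, in J/mol."""
    if ka <= 0 or temperature_K <= 0:
        raise ValueError("ka and temperature must be positive")
    return -GAS_CONSTANT_R * temperature_K * math.log(ka)


def gibbs_from_enthalpy(delta_H: float, delta_S: float, temperature_K: float) -> float:
    """Gibbs energy via ``dH - T dS``, in J/mol."""
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    return delta_H - temperature_K * delta_S


def classify_forces(delta_H: float, delta_S: float) -> BindingForce:
    """Ross-Subramanian sign rules for the dominant binding forces."""
    if delta_H < 0 and delta_S < 0:
        return BindingForce.hbond_vdw
    if delta_H > 0 and delta_S > 0:
        return BindingForce.hydrophobic
    if delta_H < 0 and delta_S > 0:
        return BindingForce.electrostatic
    return BindingForce.indeterminate


def thermo_summary(
    results: list[BindingResult], config: AnalysisConfig | None = None
) -> ThermoResult:
    """Full thermodynamic work-up of per-temperature binding results."""
    if len(results) < 3:
        raise ValueError("need binding results at >= 3 temperatures")
    points = [(r.temperature_K, r.ka) for r in results]
    delta_H, delta_S, fit = vant_hoff_fit(points)
    delta_g = {t: gibbs_from_ka(ka, t) for t, ka in points}
    return ThermoResult(
        delta_H=delta_H,
        delta_S=delta_S,
        delta_G_by_T=delta_g,
        vant_hoff_fit=fit,
        force_call=classify_forces(delta_H, delta_S),
        spontaneous=all(g < 0 for g in delta_g.values()),
    )
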