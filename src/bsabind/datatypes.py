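"""Core domain types shared by every analysis stage.

The pipeline operates on fluorescence titrations of a protein (here serum
albumin, whose intrinsic Trp/Tyr emission is the probe signal) against a
small-molecule quencher, and on wavelength / wavenumber spectra.  All
concentrations are held internally in mol/L; binding and quenching constants
are therefore in L/mol throughout, so values printed as "x 10^3 L/mol" in the
literature compare directly.
"""

from __future__ import annotations

import enum
import math
from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator

#: Universal gas constant, J mol^-1 K^-1.
GAS_CONSTANT_R = 8.314


class AxisKind(str, enum.Enum):
    """Physical meaning of a spectrum's abscissa."""

    wavelength_nm = "wavelength_nm"
    wavenumber_cm1 = "wavenumber_cm1"


class AnalysisConfig(BaseModel):
    """Pipeline-wide settings.

    Parameters
    ----------
    gas_constant_R : float
        Fixed at 8.314 J mol^-1 K^-1; validated, not tunable.
    concentration_input_unit : str
        Unit of the ``conc`` column in input titration files; converted to
        mol/L on read.  One of ``M``, ``mM``, ``uM`` (``µM`` accepted).
    significance_ratio_threshold : float
        Half-width of the "no significant change" band for competition
        Ka ratios: a condition is called unchanged when
        ``|1 - Ka_condition/Ka_blank| <= threshold`` (boundary inclusive).
    mechanism_trend_min_points : int
        Minimum number of distinct temperatures required before a
        quenching-mechanism call is attempted.
    stoichiometry_unity_tol : float
        A fitted site number n is annotated as "approximately 1:1" when
        ``|n - 1| < stoichiometry_unity_tol``.
    """

    gas_constant_R: float = GAS_CONSTANT_R
    concentration_input_unit: str = "uM"
    significance_ratio_threshold: float = Field(default=0.25, gt=0.0, lt=1.0)
    mechanism_trend_min_points: int = Field(default=3, ge=3)
    stoichiometry_unity_tol: float = Field(default=0.15, gt=0.0, lt=1.0)

    @field_validator("gas_constant_R")
    @classmethod
    def _r_is_fixed(cls, v: float) -> float:
        if v != GAS_CONSTANT_R:
            raise ValueError(f"gas constant is fixed at {GAS_CONSTANT_R} J/mol/K")
        return v

    @field_validator("concentration_input_unit", mode="before")
    @classmethod
    def _normalise_unit(cls, v: str) -> str:
        unit = str(v).replace("µ", "u").replace("μ", "u")
        if unit not in CONCENTRATION_FACTORS:
            raise ValueError(f"unsupported concentration unit {v!r}; use M, mM or uM")
        return unit

    @property
    def concentration_factor(self) -> float:
        """Multiplier taking the input unit to mol/L."""
        return CONCENTRATION_FACTORS[self.concentration_input_unit]


#: Exact conversion factors to mol/L for the supported input units.
CONCENTRATION_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6}


class TitrationSeries(BaseModel):
    """One quencher titration at a single temperature and condition.

    ``quencher_conc`` (mol/L, strictly increasing, all > 0) and ``intensity``
    are the titration points; ``f0`` is the fluorescence at zero quencher.
    """

    temperature_K: float = Field(gt=0.0)
    quencher_conc: list[float]
    intensity: list[float]
    f0: float = Field(gt=0.0)
    label: str = "blank"
    excitation_nm: Optional[float] = None
    emission_nm: Optional[float] = None

    @model_validator(mode="after")
    def _check_points(self) -> "TitrationSeries":
        c, f = self.quencher_conc, self.intensity
        if len(c) != len(f):
            raise ValueError("quencher_conc and intensity must have equal length")
        if any(x < 0 for x in c):
            raise ValueError("quencher concentrations must be non-negative")
        if any(b <= a for a, b in zip(c, c[1:])):
            raise ValueError("quencher concentrations must be strictly increasing")
        if any(not math.isfinite(v) or v <= 0 for v in f):
            raise ValueError("intensities must be finite and strictly positive")
        return self

    def __len__(self) -> int:
        return len(self.quencher_conc)


class Spectrum(BaseModel):
    """A sampled spectrum: intensity on a strictly monotone axis.

    Used for emission spectra (nm), synchronous-fluorescence spectra (nm,
    with the excitation-emission offset recorded in ``delta_lambda``) and
    FT-IR-style spectra (cm^-1).
    """

    axis: list[float]
    intensity: list[float]
    axis_kind: AxisKind = AxisKind.wavelength_nm
    delta_lambda: Optional[float] = None

    @model_validator(mode="after")
    def _check_grid(self) -> "Spectrum":
        a, f = self.axis, self.intensity
        if len(a) != len(f):
            raise ValueError("axis and intensity must have equal length")
        if len(a) < 2:
            raise ValueError("spectrum needs at least 2 points")
        diffs = [b - x for x, b in zip(a, a[1:])]
        if not (all(d > 0 for d in diffs) or all(d < 0 for d in diffs)):
            raise ValueError("axis must be strictly monotone")
        if any(not math.isfinite(v) for v in f):
            raise ValueError("intensities must be finite")
        return self

    def __len__(self) -> int:
        return len(self.axis)


class LinearFitResult(BaseModel):
    """Straight-line OLS summary: slope/intercept with standard deviations,
    Pearson r and the standard deviation of residuals."""

    slope: float
    intercept: float
    slope_sd: float = Field(ge=0.0)
    intercept_sd: float = Field(ge=0.0)
    r: float = Field(ge=-1.0, le=1.0)
    sd_residuals: float = Field(ge=0.0)
    n_points: int = Field(ge=2)
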