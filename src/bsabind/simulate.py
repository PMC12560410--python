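"""Seeded synthetic-data generator standing in for the spectrofluorometer.

The forward model is the 1:1 static-quenching equilibrium: a ground-state
protein-ligand complex is dark, so the surviving fluorescence at total
quencher concentration [Q] is ``F = F0 / (1 + Ka(T) [Q])`` — exactly the
relation whose linear form the Stern-Volmer and double-log fits consume.
Ka(T) follows the van't Hoff law from a fixed (dH, dS), so the whole
temperature series is governed by two thermodynamic numbers.  Ligand
depletion is ignored: the emulated design keeps the quencher at 10-60x the
protein concentration.

Defaults mirror a typical serum-albumin titration: 30-180 uM quencher in six
steps, five temperatures from 285 to 308 K, dH = -52.434 kJ/mol and
dS = -99.63 J/mol/K (a hydrogen-bond/van-der-Waals-driven binder with
Ka ~ 2e4 L/mol at 285 K), and 1% multiplicative detector noise.

Randomness: one global seed expands into independent per-series substreams
keyed by (label, temperature), so adding a condition never perturbs the
series already generated.
"""

from __future__ import annotations

import math
import zlib
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .datatypes import GAS_CONSTANT_R, AxisKind, Spectrum, TitrationSeries

_DEFAULT_TEMPS = [285.0, 290.0, 295.0, 303.0, 308.0]
_DEFAULT_CONC = [3e-5, 6e-5, 9e-5, 1.2e-4, 1.5e-4, 1.8e-4]


class SimulationSpec(BaseModel):
    """Ground truth and design of a simulated titration experiment."""

    delta_H: float = -52434.0           # J/mol
    delta_S: float = -99.63             # J/mol/K
    temperatures: list[float] = Field(default_factory=lambda: list(_DEFAULT_TEMPS))
    conc_grid: list[float] = Field(default_factory=lambda: list(_DEFAULT_CONC))
    f0: float = Field(default=1000.0, gt=0.0)
    noise_cv: float = Field(default=0.01, ge=0.0)
    mechanism: str = "static"
    seed: int = 0
    #: molar absorptivities (L/mol, excitation and emission wavelengths) of the
    #: quencher; when set, inner-filter attenuation 10^(-[Q](e_ex+e_em)/2) is
    #: applied to the generated intensities.
    ife_absorbance_per_molar: Optional[tuple[float, float]] = None

    @model_validator(mode="after")
    def _check(self) -> "SimulationSpec":
        if len(set(self.temperatures)) != len(self.temperatures):
            raise ValueError("temperatures must be distinct")
        c = self.conc_grid
        if any(x <= 0 for x in c) or any(b <= a for a, b in zip(c, c[1:])):
            raise ValueError("conc_grid must be positive and strictly increasing")
        if self.mechanism not in ("static", "dynamic"):
            raise ValueError("mechanism must be 'static' or 'dynamic'")
        return self


def ka_of_T(spec: SimulationSpec, temperature_K: float) -> float:
    """Association constant at T from the van't Hoff law,
    ``Ka = exp(-dH/(R T) + dS/R)`` (L/mol)."""
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    return math.exp(
        -spec.delta_H / (GAS_CONSTANT_R * temperature_K)
        + spec.delta_S / GAS_CONSTANT_R
    )


def _rng(spec: SimulationSpec, label: str, temperature_K: float) -> np.random.Generator:
    """Independent substream for one (label, temperature) series."""
    key = zlib.crc32(label.encode("utf-8"))
    tkey = int(round(temperature_K * 1000))
    return np.random.default_rng(np.random.SeedSequence([spec.seed, key, tkey]))


def _water_viscosity(temperature_K: float) -> float:
    """Vogel equation for liquid water, mPa s (valid ~273-373 K)."""
    return 0.02939 * math.exp(507.88 / (temperature_K - 149.3))


def _quench_constant(spec: SimulationSpec, temperature_K: float) -> float:
    if spec.mechanism == "static":
        return ka_of_T(spec, temperature_K)
    # dynamic stand-in: collisional quenching tracks the diffusion rate,
    # Ksv ~ T/eta(T) (Stokes-Einstein), anchored to the coldest static
    # constant so the magnitudes stay comparable.  Over 285-308 K this
    # raises Ksv by ~86%.
    t_ref = min(spec.temperatures)
    scale = (temperature_K / t_ref) * (
        _water_viscosity(t_ref) / _water_viscosity(temperature_K)
    )
    return ka_of_T(spec, t_ref) * scale


def generate_titration(
    spec: SimulationSpec,
    temperature_K: float,
    label: str = "blank",
    ka_scale: float = 1.0,
) -> TitrationSeries:
    """One noisy titration series at the given temperature.

    ``ka_scale`` rescales the effective constant (used for competition
    conditions).  Multiplicative Gaussian noise N(1, noise_cv) is applied
    independently to F0 and to every titration point; optional inner-filter
    attenuation is applied after the noise.
    """
    if temperature_K not in spec.temperatures:
        raise ValueError(f"{temperature_K} K is not in the simulated design")
    k = _quench_constant(spec, temperature_K) * ka_scale
    conc = np.asarray(spec.conc_grid, dtype=float)
    f = spec.f0 / (1.0 + k * conc)
    rng = _rng(spec, label, temperature_K)
    noise = rng.normal(1.0, spec.noise_cv, size=conc.size + 1) if spec.noise_cv > 0 else np.ones(conc.size + 1)
    f0 = spec.f0 * noise[0]
    f = f * noise[1:]
    if spec.ife_absorbance_per_molar is not None:
        e_ex, e_em = spec.ife_absorbance_per_molar
        f = f * 10.0 ** (-(conc * e_ex + conc * e_em) / 2.0)
    return TitrationSeries(
        temperature_K=temperature_K,
        quencher_conc=conc.tolist(),
        intensity=f.tolist(),
        f0=float(f0),
        label=label,
        excitation_nm=295.0,
        emission_nm=348.0,
    )


def generate_temperature_series(spec: SimulationSpec, label: str = "blank") -> list[TitrationSeries]:
    """One titration per design temperature."""
    return [generate_titration(spec, t, label=label) for t in spec.temperatures]


def generate_spectrum_pair(
    center_free: float,
    shift: float,
    width: float,
    quench_fraction: float,
    grid: tuple[float, float, int],
    axis_kind: AxisKind = AxisKind.wavelength_nm,
    amplitude: float = 1000.0,
) -> tuple[Spectrum, Spectrum]:
    """Gaussian band pair: the free spectrum at ``center_free`` and the
    ligand-bound one displaced by ``shift`` with amplitude scaled by
    ``(1 - quench_fraction)``.

    ``grid`` is (start, stop, n_points); it must cover both band centers
    +/- 3 widths so neither peak is truncated.
    """
    if width <= 0:
        raise ValueError("band width must be positive")
    if not 0.0 <= quench_fraction <= 1.0:
        raise ValueError("quench_fraction must lie in [0, 1]")
    start, stop, n = grid
    center_bound = center_free + shift
    lo = min(center_free, center_bound) - 3 * width
    hi = max(center_free, center_bound) + 3 * width
    if start > lo or stop < hi:
        raise ValueError(
            f"grid [{start}, {stop}] does not cover both bands +/- 3 widths "
            f"([{lo:.6g}, {hi:.6g}])"
        )
    axis = np.linspace(start, stop, int(n))

    def band(center: float, amp: float) -> np.ndarray:
        return amp * np.exp(-0.5 * ((axis - center) / width) ** 2)

    free = Spectrum(
        axis=axis.tolist(),
        intensity=band(center_free, amplitude).tolist(),
        axis_kind=axis_kind,
    )
    bound = Spectrum(
        axis=axis.tolist(),
        intensity=band(center_bound, amplitude * (1.0 - quench_fraction)).tolist(),
        axis_kind=axis_kind,
    )
    return free, bound


def generate_synchronous_channels(
    spec: SimulationSpec,
    temperature_K: float,
    ka_scale_15: float = 1.0,
    ka_scale_60: float = 0.5,
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """(conc, F) pairs for the two synchronous offset channels, F0 included.

    The default scales quench the 15 nm (tyrosine) channel more deeply than
    the 60 nm (tryptophan) one, emulating a ligand bound near tyrosines.
    """
    s15 = generate_titration(spec, temperature_K, label="sync15", ka_scale=ka_scale_15)
    s60 = generate_titration(spec, temperature_K, label="sync60", ka_scale=ka_scale_60)
    ch15 = [(0.0, s15.f0)] + list(zip(s15.quencher_conc, s15.intensity))
    ch60 = [(0.0, s60.f0)] + list(zip(s60.quencher_conc, s60.intensity))
    return ch15, ch60


def generate_competition_dataset(
    spec: SimulationSpec,
    ratio_map: dict[str, float],
    temperature_K: float = 295.0,
) -> list[TitrationSeries]:
    """Blank plus per-condition titrations at one temperature.

    Each condition's effective Ka is the blank's times ``ratio_map[label]``
    (a site-probe that displaces the ligand has ratio < 1).  Series draw from
    independent substreams, so the blank is identical with or without extra
    conditions.
    """
    if any(r <= 0 for r in ratio_map.values()):
        raise ValueError("Ka ratios must be positive")
    out = [generate_titration(spec, temperature_K, label="blank")]
    for label, ratio in ratio_map.items():
        out.append(generate_titration(spec, temperature_K, label=label, ka_scale=ratio))
    return out
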