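"""Delimited-text readers/writers and the report emitter.

Titration files are long-format CSV with mandatory header
``label,temperature_K,conc,intensity`` — one row per titration point, the
zero-quencher row carrying F0 for its (label, temperature) group.  Spectrum
files are two-column CSV whose axis column name declares the axis kind.
Reports are emitted twice: a machine-readable JSON document and a
human-readable table laid out like the regression/thermodynamics tables of
a binding-study paper.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Iterable, Optional

import pandas as pd
import yaml

from .binding import ThermoResult
from .datatypes import AnalysisConfig, AxisKind, Spectrum, TitrationSeries

log = logging.getLogger("bsabind.io")

_TITRATION_COLUMNS = ["label", "temperature_K", "conc", "intensity"]


def load_config(path: str | Path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from a YAML mapping."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return AnalysisConfig(**data)


def read_titration(path: str | Path, config: AnalysisConfig | None = None) -> list[TitrationSeries]:
    """Parse a long-format titration CSV into one series per (label, T) group.

    The ``conc`` column is converted from ``config.concentration_input_unit``
    to mol/L.  Each group must contain exactly one conc = 0 row (its F0) and
    strictly increasing concentrations thereafter, in file order.
    """
    config = config or AnalysisConfig()
    df = pd.read_csv(path)
    missing = [c for c in _TITRATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"titration file {path} lacks columns {missing}")
    factor = config.concentration_factor
    series: list[TitrationSeries] = []
    for (label, temp), grp in df.groupby(["label", "temperature_K"], sort=False):
        conc = (grp["conc"].to_numpy(dtype=float) * factor).tolist()
        inten = grp["intensity"].to_numpy(dtype=float).tolist()
        zero_idx = [i for i, c in enumerate(conc) if c == 0]
        if not zero_idx:
            raise ValueError(
                f"group ({label!r}, {temp} K) has no conc = 0 row to provide F0"
            )
        if len(zero_idx) > 1:
            raise ValueError(f"group ({label!r}, {temp} K) has multiple conc = 0 rows")
        f0 = inten[zero_idx[0]]
        pts = [(c, f) for i, (c, f) in enumerate(zip(conc, inten)) if i != zero_idx[0]]
        cs = [c for c, _ in pts]
        if any(b <= a for a, b in zip(cs, cs[1:])):
            raise ValueError(
                f"group ({label!r}, {temp} K): concentrations are not strictly increasing"
            )
        if any(f <= 0 for f in inten):
            raise ValueError(f"group ({label!r}, {temp} K): non-positive intensity")
        series.append(
            TitrationSeries(
                temperature_K=float(temp),
                quencher_conc=cs,
                intensity=[f for _, f in pts],
                f0=f0,
                label=str(label),
            )
        )
    log.info("read %d titration series from %s", len(series), path)
    return series


def write_titration(series: Iterable[TitrationSeries], path: str | Path,
                    config: AnalysisConfig | None = None) -> None:
    """Write series back to the long-format CSV dialect ``read_titration``
    accepts (concentrations in the configured input unit)."""
    config = config or AnalysisConfig()
    factor = config.concentration_factor
    rows = []
    for s in series:
        rows.append((s.label, s.temperature_K, 0.0, s.f0))
        for c, f in zip(s.quencher_conc, s.intensity):
            rows.append((s.label, s.temperature_K, c / factor, f))
    pd.DataFrame(rows, columns=_TITRATION_COLUMNS).to_csv(path, index=False)


_AXIS_NAMES = {
    "wavelength_nm": AxisKind.wavelength_nm,
    "wavenumber_cm1": AxisKind.wavenumber_cm1,
}


def read_spectrum(path: str | Path, axis_kind: Optional[AxisKind] = None) -> Spectrum:
    """Two-column CSV -> :class:`Spectrum`, axis sorted ascending.

    The axis kind is taken from the first column's header when it is one of
    ``wavelength_nm``/``wavenumber_cm1``, else from the ``axis_kind``
    argument.  Duplicate axis values or fewer than 5 points are errors.
    """
    df = pd.read_csv(path)
    if df.shape[1] != 2:
        raise ValueError(f"spectrum file {path} must have exactly 2 columns")
    axis_col = df.columns[0]
    kind = _AXIS_NAMES.get(axis_col.strip(), axis_kind)
    if kind is None:
        raise ValueError(
            f"axis kind of {path} is neither declared in the header "
            f"({axis_col!r}) nor passed explicitly"
        )
    if len(df) < 5:
        raise ValueError(f"spectrum {path} has fewer than 5 points")
    axis = df.iloc[:, 0].to_numpy(dtype=float)
    if len(set(axis.tolist())) != len(axis):
        raise ValueError(f"spectrum {path} has duplicate axis values")
    order = axis.argsort()
    return Spectrum(
        axis=axis[order].tolist(),
        intensity=df.iloc[:, 1].to_numpy(dtype=float)[order].tolist(),
        axis_kind=AxisKind(kind),
    )


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    pd.DataFrame(
        {spectrum.axis_kind.value: spectrum.axis, "intensity": spectrum.intensity}
    ).to_csv(path, index=False)


def _to_jsonable(obj: Any) -> Any:
    if isinstance(obj, ThermoResult):
        # reported on the scale the tables print: kJ/mol for dH and dG
        return {
            "delta_H_kJ_mol": obj.delta_H / 1000.0,
            "delta_S_J_mol_K": obj.delta_S,
            "delta_G_kJ_mol_by_T": {str(t): g / 1000.0 for t, g in obj.delta_G_by_T.items()},
            "force_call": obj.force_call.value,
            "spontaneous": obj.spontaneous,
            "vant_hoff_fit": _to_jsonable(obj.vant_hoff_fit),
        }
    if hasattr(obj, "model_dump"):
        return _to_jsonable(obj.model_dump())
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if hasattr(obj, "value") and not isinstance(obj, (int, float, str)):
        return obj.value
    return obj


def _format_record(name: str, rec: Any, out: list[str]) -> None:
    d = _to_jsonable(rec)
    out.append(f"== {name} ==")
    if isinstance(d, dict) and "delta_H_kJ_mol" in d:
        out.append(f"  dH = {d['delta_H_kJ_mol']:.3f} kJ/mol   dS = {d['delta_S_J_mol_K']:.2f} J/mol/K")
        out.append(f"  forces: {d.get('force_call')}   spontaneous: {d.get('spontaneous')}")
        out.append("  T (K)    dG (kJ/mol)")
        for t, g in d.get("delta_G_kJ_mol_by_T", {}).items():
            out.append(f"  {float(t):7.1f}  {g:10.3f}")
    elif isinstance(d, dict) and "ksv" in d:
        fit = d["fit"]
        out.append(
            f"  T = {d['temperature_K']:.0f} K  Ksv = {d['ksv']:.4g} L/mol  "
            f"r = {fit['r']:.4f}  slope = {fit['slope']:.4g} +/- {fit['slope_sd']:.2g}  "
            f"intercept = {fit['intercept']:.4f} +/- {fit['intercept_sd']:.2g}  "
            f"SDres = {fit['sd_residuals']:.4g}"
        )
    elif isinstance(d, dict) and "log10_ka" in d and "fit" in d:
        fit = d["fit"]
        out.append(
            f"  T = {d['temperature_K']:.0f} K  logKa = {d['log10_ka']:.4f}  "
            f"Ka = {d['ka']:.4g} L/mol  n = {d['n_sites']:.3f}  r = {fit['r']:.4f}"
        )
    elif isinstance(d, dict) and "ka_ratio_to_blank" in d:
        out.append(
            f"  {d['condition']}: logKa = {d['log10_ka']:.4f}  "
            f"Ka/Ka(blank) = {d['ka_ratio_to_blank']:.3f}  effect = {d['effect']}"
        )
    else:
        out.append("  " + json.dumps(d, default=str))


def write_report(results: dict[str, Any], path: str | Path) -> None:
    """Emit ``path`` (JSON) plus a ``.txt`` sibling with formatted tables.

    ``results`` maps section names to result records (or lists of records)
    from any pipeline stage; it must not be empty.
    """
    if not results:
        raise ValueError("refusing to write an empty report")
    path = Path(path)
    payload = _to_jsonable(results)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, default=str)
    lines: list[str] = []
    for name, rec in results.items():
        if isinstance(rec, (list, tuple)):
            lines.append(f"== {name} ==")
            for item in rec:
                sub: list[str] = []
                _format_record(name, item, sub)
                lines.extend(sub[1:])
        else:
            _format_record(name, rec, lines)
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
    log.info("report written to %s (+.txt)", path)
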