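# bsabind

Analysis pipeline for fluorescence-titration studies of small-molecule
binding to serum albumin — the standard spectroscopic work-up a
pharmaceutical-analysis lab runs to characterise how a drug candidate rides
on the blood's carrier protein.

Serum albumin's intrinsic Trp/Tyr fluorescence is quenched when a ligand
binds. From titrations of that quenching this package extracts, stage by
stage:

1. **Quenching analysis** — Stern–Volmer fits of F₀/F = 1 + K_sv[Q] per
   temperature, optional inner-filter correction
   (F_corr = F_obs·10^((A_ex+A_em)/2)), and a static-vs-dynamic mechanism
   call from the sign of dK_sv/dT (static quenching weakens on heating;
   collisional quenching strengthens).
2. **Binding constants and thermodynamics** — double-logarithmic fits
   log((F₀−F)/F) = log K_a + n·log[Q] for the association constant and site
   number; van't Hoff decomposition ln K_a = −ΔH/RT + ΔS/R; ΔG = −RT ln K_a;
   Ross–Subramanian force classification from the signs of (ΔH, ΔS).
3. **Synchronous fluorescence** — RSFQ = 1 − F/F₀ in the Δλ = 15 nm (Tyr)
   and Δλ = 60 nm (Trp) channels, residue-proximity call, and sub-grid peak
   localisation for red/blue shifts and infrared band displacements.
4. **Competition** — site-marker displacement (indomethacin for Sudlow
   site I, diazepam for site II) and common-ion effects as K_a ratios
   against a blank, with a preferential-site assignment.
5. **Synthetic data** — a seeded generator producing 1:1 static-quenching
   titrations, spectra and competition datasets with the statistical
   structure the fitters assume, replacing the spectrofluorometer so the
   whole pipeline is testable end to end.

## Worked example

```python
from bsabind import (SimulationSpec, generate_temperature_series,
                     stern_volmer_fit, double_log_fit, classify_mechanism,
                     thermo_summary)

spec = SimulationSpec(seed=20240817)          # 285-308 K, 30-180 uM, 1% noise
series = generate_temperature_series(spec)

quench = [stern_volmer_fit(s) for s in series]
print(classify_mechanism(quench).call.value)  # -> static

th = thermo_summary([double_log_fit(s) for s in series])
print(f"dH = {th.delta_H/1000:.1f} kJ/mol, dS = {th.delta_S:.1f} J/mol/K")
print(th.force_call.value, th.spontaneous)
```

prints

```
static
dH = -51.3 kJ/mol, dS = -94.9 J/mol/K
hbond_vdw True
```

i.e. the fitted enthalpy/entropy recover the generator's ground truth
(−52.4 kJ/mol, −99.6 J/mol/K) to within the noise, both negative — a
hydrogen-bonding / van der Waals binder — and ΔG < 0 at every temperature,
so binding is spontaneous throughout.

The same stages are packaged as narrative drivers under `analysis/`
(`01_simulate.py` … `05_competition.py`); run them in order from the
repository root to regenerate everything under `results/`, including the
site-marker assay that assigns the ligand to Sudlow's site II.

A thin CLI mirrors the library (`bsabind quench|bind|thermo|sync|compete|
simulate|report`, see `bsabind --help`) for shell use on CSV titration
files: long format with columns `label,temperature_K,conc,intensity`, the
`conc = 0` row carrying F₀.

## Layout

```
src/bsabind/     library: datatypes, io, fitting, quenching, binding,
                 spectra, competition, simulate, cli
analysis/        numbered drivers reproducing the study stages
tests/           pytest suite (unit, property-based, acceptance)
scripts/         acceptance.py
docs/methods.md  model assumptions, parameter choices, limitations
```
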