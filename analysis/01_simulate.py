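#!/usr/bin/env python
"""Generate the synthetic study datasets every downstream stage consumes.

Emulates a serum-albumin / small-molecule titration campaign: five
temperatures (285-308 K), quencher 30-180 uM in six steps plus a zero-
quencher reference, 1% multiplicative detector noise, static quenching
governed by dH = -52.434 kJ/mol and dS = -99.63 J/mol/K.  Also writes the
site-marker competition titrations (295 K) and Gaussian spectrum pairs for
the peak-shift stage.

Writes results/synthetic/: titration.csv, competition.csv, and four
spectrum CSVs.
"""

from pathlib import Path

from bsabind import (
    AnalysisConfig,
    AxisKind,
    SimulationSpec,
    generate_competition_dataset,
    generate_spectrum_pair,
    generate_temperature_series,
    write_spectrum,
    write_titration,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 20240817


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = AnalysisConfig(concentration_input_unit="uM")
    spec = SimulationSpec(seed=SEED)

    series = generate_temperature_series(spec)
    write_titration(series, OUT / "titration.csv", cfg)
    print(f"titration.csv: {len(series)} temperature series, "
          f"{len(series[0])} points each + F0")

    competition = generate_competition_dataset(
        spec, {"diazepam": 0.19, "indomethacin": 1.2}, temperature_K=295.0
    )
    write_titration(competition, OUT / "competition.csv", cfg)
    print(f"competition.csv: {len(competition)} series at 295 K "
          f"(blank + site probes)")

    free, bound = generate_spectrum_pair(348.0, 2.0, 15.0, 0.3, (280.0, 420.0, 281))
    write_spectrum(free, OUT / "sync15_free.csv")
    write_spectrum(bound, OUT / "sync15_bound.csv")
    free, bound = generate_spectrum_pair(
        1610.0, 26.0, 20.0, 0.0, (1000.0, 4000.0, 1501),
        axis_kind=AxisKind.wavenumber_cm1,
    )
    write_spectrum(free, OUT / "ftir_free.csv")
    write_spectrum(bound, OUT / "ftir_bound.csv")
    print("spectra: synchronous band pair (348 nm, +2 nm shift) and "
          "amide band pair (1610 -> 1636 cm^-1)")


if __name__ == "__main__":
    main()
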