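# Methods

## The measurement and the model

A protein with intrinsic Trp/Tyr fluorescence (serum albumin in the system
this package was built around) is titrated with a small-molecule ligand that
quenches that fluorescence. Everything downstream is squeezed out of how the
intensity falls with ligand concentration, at several temperatures and in
several spectral channels.

The forward model adopted throughout — in the fitters' assumptions and in
the synthetic-data generator — is 1:1 static quenching: ligand and protein
form a non-fluorescent ground-state complex with association constant
Ka(T), so at total quencher concentration [Q]

    F([Q]) = F0 / (1 + Ka(T) [Q]),

with [Q] identified with the *total* ligand concentration. No free-ligand
(depletion) correction is applied: in the emulated design the quencher
(30–180 µM) exceeds the protein (3 µM) ten- to sixty-fold, so bound ligand
is a negligible fraction of the total. Ka(T) obeys the van't Hoff law with
temperature-independent ΔH and ΔS:

    ln Ka = −ΔH/(R T) + ΔS/R,     R = 8.314 J mol⁻¹ K⁻¹.

## Fitted linearisations

All fits are unweighted ordinary least squares on a linearised model
(`scipy.stats.linregress` behind a single `linear_fit` surface that also
reports slope/intercept SDs, Pearson r and the SD of residuals — the columns
a binding-study regression table prints).

* **Stern–Volmer** (`stern_volmer_fit`): F0/F vs [Q]; the slope is Ksv
  (L/mol). The intercept is fitted freely rather than pinned at its
  theoretical value 1, because real tables report intercepts like
  0.93–1.01 and the residual statistics are part of the output. Points with
  F ≥ F0 (anti-quenching; noise at low quencher) are kept but logged.
* **Double-logarithmic** (`double_log_fit`): log₁₀((F0−F)/F) vs log₁₀[Q];
  intercept = log₁₀ Ka, slope = apparent site number n. Base-10 logs, so a
  tabulated "log Ka ≈ 4.4" maps to Ka ≈ 2.4×10⁴ L/mol. Points with F ≥ F0
  are dropped (their log-ratio is undefined) with a warning; at least three
  usable points are required. n is reported exactly as fitted; a "~1:1"
  annotation is attached when |n − 1| < 0.15 (configurable).
* **van't Hoff** (`vant_hoff_fit`): ln Ka vs 1/T (natural logs);
  ΔH = −R·slope, ΔS = R·intercept.

ΔG per temperature is computed as −RT ln Ka from that temperature's own
fitted Ka, not as ΔH − TΔS. The two routes coincide only when the points
sit exactly on the van't Hoff line; on real (rounded or noisy) per-T
constants they differ by ~0.1 kJ/mol, and the −RT ln Ka route is the one
whose values per-temperature tables actually print. `gibbs_from_enthalpy`
provides the other route for consistency checks.

## Classifications

* **Quenching mechanism** (`classify_mechanism`): the trend statistic is
  the OLS slope of Ksv against T. "static" requires both a negative slope
  and strictly decreasing Ksv across the sorted temperatures ("dynamic" the
  mirror image); anything weaker — one reversal, a flat series — returns
  "indeterminate". The strict-monotonicity requirement is deliberately
  conservative: with ≥3 temperatures it refuses to over-read a noisy trend.
* **Binding forces** (`classify_forces`): Ross–Subramanian sign rules.
  ΔH < 0 ∧ ΔS < 0 → hydrogen bonding / van der Waals; both positive →
  hydrophobic; ΔH < 0 ∧ ΔS > 0 → electrostatic; a zero component →
  indeterminate.
* **Residue proximity** (`rsfq_profile`): RSFQ = 1 − F/F0 per concentration
  in the Δλ = 15 nm (Tyr) and Δλ = 60 nm (Trp) synchronous channels; the
  call is a majority vote over concentrations rather than a comparison of
  mean RSFQ, so one noisy point cannot flip it.
* **Site assignment** (`assign_site`): "site_II" when at least one site-II
  probe (diazepam class) produces a Ka decrease and no site-I probe
  (indomethacin/warfarin class) does; symmetric for site I; any other
  pattern is ambiguous. "Decrease/increase/unchanged" is a Ka-ratio test
  with a ±25% band (boundary inclusive). The band is a design choice — no
  numeric criterion is standard in the assay — set so that a ~23% rise
  counts as "no significant change" while a 5-fold drop counts as
  displacement; it is configurable (`significance_ratio_threshold`).

## Inner-filter correction

`ife_correct` applies F·10^((A_ex+A_em)/2). The correction matters only
through the *concentration-dependent part* of the absorbance: any constant
(protein-dominated) contribution multiplies F0 and F alike and cancels in
F0/F. With every absorbance at or below 0.05 and the quencher contributing
only a small drift across the titration, the corrected Ksv moves by well
under 1.2% — which is why titrations run at total absorbance < 0.05
routinely skip the correction. Negative absorbances are rejected (they
signal blank subtraction applied in the wrong order).

## Peak localisation

`peak_position` refines the grid argmax by a three-point parabolic
interpolation (exact for quadratic peaks; < 0.1 grid step error for
Gaussian bands at least ~5 grid steps wide, verified against a 100× denser
grid). Parabolic interpolation was chosen over centroids or spline fits
because it is deterministic, assumption-light and resolution-appropriate
for the ~2 nm synchronous and ~26 cm⁻¹ infrared shifts at stake. A maximum
on the grid boundary is an error (truncated band). "Red"/"blue" labels are
applied only on wavelength axes, thresholded at `resolution` (default 0.5
axis units); for wavenumber axes the direction label is suppressed.

## Synthetic-data generator

`SimulationSpec` defaults encode the emulated study: temperatures
{285, 290, 295, 303, 308} K; quencher 30–180 µM in six steps; F0 = 1000
(arbitrary units — every estimator is scale-invariant); ΔH = −52.434 kJ/mol
and ΔS = −99.63 J mol⁻¹ K⁻¹ (an exothermic, entropically penalised binder,
Ka ≈ 2.5×10⁴ L/mol at 285 K); multiplicative Gaussian intensity noise with
1% coefficient of variation, applied independently to F0 and to every
titration point. The 1% figure is a conventional spectrofluorometer
repeatability — no raw intensities exist to anchor it empirically.

Optional inner-filter attenuation multiplies the generated intensities by
10^(−[Q](ε_ex+ε_em)/2) given molar absorptivities of the quencher.

For the **dynamic-quenching** variant (used only to test the mechanism
classifier — no dynamic system is fitted here), Ksv(T) scales as the
diffusion rate via Stokes–Einstein, Ksv ∝ T/η(T), with water viscosity from
the Vogel equation, anchored at the coldest temperature's static constant.
This raises Ksv by ~86% over 285–308 K, a realistic collisional trend;
a gentler power-law stand-in was considered and rejected because its ~7%
steps between adjacent design temperatures are routinely swallowed by 2%
intensity noise, making the generated "dynamic" datasets fail their own
strict-monotonicity classification.

Randomness: the global seed expands into independent `SeedSequence`
substreams keyed by (label, temperature), so generating an extra condition
never changes the series already drawn, and identical specs are
byte-identical across runs.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: ligand depletion at high affinity or low
quencher excess; combined static+dynamic (sphere-of-action) quenching;
wavelength-dependent detector response; baseline drift or scatter peaks in
spectra; replicate-to-replicate instrument drift (noise is i.i.d. per
point); any ternary protein–probe–ligand equilibrium in the competition
assay (conditions simply rescale Ka, which is the empirical content of a
displacement assay but not its mechanism).

## Estimator conditioning: a practical note

Under the static model, the Stern–Volmer slope *is* the association
constant, and it is by far the better-conditioned estimate: at 1% noise
and the default design its median relative error is ~1%. The double-log
intercept must be extrapolated ~4 decades from the sampled log[Q] range
(≈ −4.5 … −3.7) to log[Q] = 0, which amplifies slope noise into a median
Ka error near 8%. Parameter-recovery statements in the tests therefore use
the Stern–Volmer route; the double-log fit remains the estimator of n and
of log Ka for table-style reporting, as in the assay tradition.

The same consideration applies to competition ratios: a Ka ratio formed
from two independent double-log intercepts inherits both intercepts' noise
(the printed intercept SDs of such fits reach ±0.35 log units, a factor
two in Ka), so a single-replicate site call through that route is
unreliable at 1% intensity noise. Where a robust single-replicate call is
wanted — as in the reproduction script — per-condition Ka is taken from
the Stern–Volmer slope and fed through the same ratio/threshold machinery.

## Problem sizes

Monte-Carlo statements use 100 seeded replicates of the 6-concentration ×
5-temperature design; mechanism-fidelity checks use 50 seeds per mechanism
at 2% noise; the dense-grid peak oracle uses a 100× refinement. These sizes
give stable medians while keeping the whole suite fast.

## Known limitations

* All fits are unweighted; heteroscedastic intensities (e.g.
  shot-noise-limited detection) would call for weighted regression.
* The mechanism call is qualitative; no bimolecular rate constant
  kq = Ksv/τ0 is computed because the fluorophore lifetime τ0 is not an
  input, and no mixed static/dynamic model is fitted.
* The double-log model assumes identical independent sites; cooperative
  binding (Hill/Adair) is out of scope.
* Spectra are treated as single-band for peak localisation; overlapping
  bands would need deconvolution, which the package does not attempt.
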