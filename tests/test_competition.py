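"""Site-marker displacement and ion-effect Ka comparisons."""

import math

import pytest

from bsabind import (
    AnalysisConfig,
    Effect,
    Site,
    assign_site,
    compare_conditions,
    generate_competition_dataset,
    ion_effect,
)
from bsabind.binding import BindingResult, double_log_fit
from bsabind.fitting import linear_fit

from conftest import TABLE_LOGKA_MARKERS


def _result(label, log10_ka, t=295.0, n=1.05):
    return BindingResult(
        temperature_K=t,
        log10_ka=log10_ka,
        ka=10.0 ** log10_ka,
        n_sites=n,
        fit=linear_fit([1.0, 2.0, 3.0], [0.9, 2.1, 2.9]),
        label=label,
    )


@pytest.fixture
def marker_results():
    blank = _result("blank", TABLE_LOGKA_MARKERS["blank"])
    conds = [
        _result("indomethacin", TABLE_LOGKA_MARKERS["indomethacin"]),
        _result("diazepam", TABLE_LOGKA_MARKERS["diazepam"]),
    ]
    return blank, conds


class TestCompareConditions:
    def test_published_marker_pattern(self, marker_results, config):
        blank, conds = marker_results
        out = {r.condition: r for r in compare_conditions(blank, conds, config)}
        # diazepam knocks Ka down to ~19% of blank; indomethacin's ~23%
        # rise sits inside the +/-25% "no significant change" band
        assert out["diazepam"].ka_ratio_to_blank == pytest.approx(0.192, abs=0.001)
        assert out["diazepam"].effect is Effect.decrease
        assert out["indomethacin"].ka_ratio_to_blank == pytest.approx(1.231, abs=0.001)
        assert out["indomethacin"].effect is Effect.unchanged

    def test_identical_condition_unchanged(self, config):
        blank = _result("blank", 4.0)
        (r,) = compare_conditions(blank, [_result("x", 4.0)], config)
        assert r.ka_ratio_to_blank == pytest.approx(1.0)
        assert r.effect is Effect.unchanged

    def test_doubled_ka_increases(self, config):
        blank = _result("blank", 4.0)
        (r,) = compare_conditions(blank, [_result("x", 4.0 + math.log10(2))], config)
        assert r.ka_ratio_to_blank == pytest.approx(2.0, rel=1e-9)
        assert r.effect is Effect.increase

    def test_boundary_is_inclusive(self):
        cfg = AnalysisConfig(significance_ratio_threshold=0.25)
        blank = _result("blank", 4.0)
        (lo,) = compare_conditions(blank, [_result("lo", 4.0 + math.log10(0.75))], cfg)
        (hi,) = compare_conditions(blank, [_result("hi", 4.0 + math.log10(1.25))], cfg)
        assert lo.effect is Effect.unchanged
        assert hi.effect is Effect.unchanged

    def test_mixed_temperatures_error(self, config):
        blank = _result("blank", 4.0, t=295.0)
        with pytest.raises(ValueError, match="295"):
            compare_conditions(blank, [_result("x", 4.0, t=303.0)], config)

    def test_ratio_reproducible_from_log_ka(self, marker_results, config):
        blank, conds = marker_results
        for r in compare_conditions(blank, conds, config):
            assert r.ka_ratio_to_blank == pytest.approx(
                10.0 ** (r.log10_ka - blank.log10_ka), rel=1e-12
            )


class TestAssignSite:
    probe_map = {"indomethacin": Site.site_I, "diazepam": Site.site_II}

    def test_published_pattern_gives_site_two(self, marker_results, config):
        blank, conds = marker_results
        results = compare_conditions(blank, conds, config)
        assignment = assign_site(results, self.probe_map)
        assert assignment.site is Site.site_II
        assert assignment.displacing_probe == "diazepam"

    def test_permutation_invariance(self, marker_results, config):
        blank, conds = marker_results
        results = compare_conditions(blank, conds, config)
        assert assign_site(results, self.probe_map) == assign_site(
            results[::-1], self.probe_map
        )

    def test_both_probes_displacing_is_ambiguous(self, config):
        blank = _result("blank", 4.5)
        results = compare_conditions(
            blank, [_result("indomethacin", 3.5), _result("diazepam", 3.5)], config
        )
        assert assign_site(results, self.probe_map).site is Site.ambiguous

    def test_no_displacement_is_ambiguous(self, config):
        blank = _result("blank", 4.5)
        results = compare_conditions(
            blank, [_result("indomethacin", 4.5), _result("diazepam", 4.5)], config
        )
        assert assign_site(results, self.probe_map).site is Site.ambiguous

    def test_empty_probe_map_error(self, marker_results, config):
        blank, conds = marker_results
        results = compare_conditions(blank, conds, config)
        with pytest.raises(ValueError):
            assign_site(results, {})


class TestIonEffect:
    def test_direction_pattern(self, config):
        blank = _result("blank", 4.0)
        conds = [
            _result("Co2+", 4.0 + math.log10(1.5)),
            _result("Ca2+", 4.0 + math.log10(0.6)),
            _result("Cu2+", 4.0 + math.log10(0.5)),
        ]
        effects = {r.condition: r.effect for r in ion_effect(blank, conds, config)}
        assert effects == {
            "Co2+": Effect.increase,
            "Ca2+": Effect.decrease,
            "Cu2+": Effect.decrease,
        }


class TestEndToEnd:
    def test_synthetic_displacement_recovers_site_two(self, config):
        from bsabind import SimulationSpec

        spec = SimulationSpec(noise_cv=0.005, seed=11)
        data = generate_competition_dataset(
            spec, {"diazepam": 0.19, "indomethacin": 1.2}, temperature_K=295.0
        )
        fits = {s.label: double_log_fit(s) for s in data}
        blank = fits.pop("blank")
        results = compare_conditions(blank, list(fits.values()), config)
        assignment = assign_site(
            results, {"indomethacin": Site.site_I, "diazepam": Site.site_II}
        )
        assert assignment.site is Site.site_II

    def test_ratios_scale_invariant(self, config):
        from bsabind import SimulationSpec

        spec = SimulationSpec(noise_cv=0.005, seed=3)
        data = generate_competition_dataset(spec, {"probe": 0.3})
        fits = {s.label: double_log_fit(s) for s in data}
        base = compare_conditions(fits["blank"], [fits["probe"]], config)
        scaled = [
            s.model_copy(
                update={
                    "intensity": [f * 7.5 for f in s.intensity],
                    "f0": s.f0 * 7.5,
                }
            )
            for s in data
        ]
        sfits = {s.label: double_log_fit(s) for s in scaled}
        after = compare_conditions(sfits["blank"], [sfits["probe"]], config)
        assert after[0].ka_ratio_to_blank == pytest.approx(
            base[0].ka_ratio_to_blank, rel=1e-9
        )
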