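import pytest

from bsabind import AnalysisConfig, SimulationSpec

# Published regression results used as fixed inputs throughout the suite:
# Stern-Volmer constants (L/mol) per temperature for a static quencher of
# serum albumin, and the matching double-log binding table.
TABLE_KSV = {285.0: 11100.0, 290.0: 9635.0, 295.0: 7096.0, 303.0: 5288.0, 308.0: 3800.0}
TABLE_KA = {285.0: 24171.0, 290.0: 17434.0, 295.0: 13103.0, 303.0: 6924.0, 308.0: 4639.0}
TABLE_DG_KJ = {285.0: -23.915, 290.0: -23.546, 295.0: -23.252, 303.0: -22.276, 308.0: -21.618}
TABLE_DH_KJ = -52.434
TABLE_DS = -99.63
# site-marker displacement assay at 295 K: log10 Ka per condition
TABLE_LOGKA_MARKERS = {"blank": 4.1593, "indomethacin": 4.2494, "diazepam": 3.4424}


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def noiseless_spec() -> SimulationSpec:
    return SimulationSpec(noise_cv=0.0)


@pytest.fixture
def noisy_spec() -> SimulationSpec:
    return SimulationSpec(noise_cv=0.01, seed=42)
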